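"""Two-class Fisher discriminant analysis and cross-validated grids.

The discriminant weights maximise the Rayleigh quotient
w' S_B w / w' S_W w with S_B = (mu1 - mu2)(mu1 - mu2)' and S_W = S1 + S2
(sum of the unbiased per-class covariance matrices, not a pooled-weighted
estimate).  The closed form is

    w = S_W^{-1} (mu1 - mu2),
    z0 = (s2 <w, mu1> + s1 <w, mu2>) / (s1 + s2),   s_c = sqrt(<w, S_c w>),

so the threshold sits between the projected class means, closer to the
tighter class.  A new sample f is assigned to class 1 iff <w, f> >= z0
(boundary to class 1).  Ridge regularisation defaults to zero and is
escalated to 1e-8 * trace(S_W)/dim only when S_W is numerically singular;
the magnitude actually used is recorded in the model.

``cross_validate`` draws a seeded uniform (unstratified) partition into k
near-equal folds, each fold serving once as the test set, and reports the
mean classification rate in percent with its SEM over folds.
``classification_grid`` evaluates every (band | ALL) x (day | ALL) feature
subset for each pairwise strain objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureMatrix, assemble_feature_vectors
from .spectral import BAND_ORDER

__all__ = [
    "FDAModel",
    "fit_fda",
    "classify",
    "CVResult",
    "cross_validate",
    "classification_grid",
    "two_axis_projection",
]


@dataclass
class FDAModel:
    """Fitted two-class Fisher discriminant."""

    w: np.ndarray
    z0: float
    classes: tuple
    mu1: np.ndarray
    mu2: np.ndarray
    S1: np.ndarray
    S2: np.ndarray
    s1: float
    s2: float
    ridge: float = 0.0

    @property
    def S_W(self) -> np.ndarray:
        return self.S1 + self.S2

    @property
    def S_B(self) -> np.ndarray:
        d = (self.mu1 - self.mu2)[:, None]
        return d @ d.T

    def to_dict(self) -> dict:
        return {
            "w": self.w.tolist(),
            "z0": self.z0,
            "classes": list(self.classes),
            "mu1": self.mu1.tolist(),
            "mu2": self.mu2.tolist(),
            "s1": self.s1,
            "s2": self.s2,
            "ridge": self.ridge,
        }


def fit_fda(X: np.ndarray, y: np.ndarray, ridge: float | None = None,
            class_order: tuple | None = None) -> FDAModel:
    """Fit the closed-form two-class Fisher discriminant.

    ``class_order`` fixes which label is class 1 (the ">= z0" side);
    by default labels are taken in sorted order.  ``ridge=None`` means
    auto: exactly zero unless S_W is numerically singular.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n_samples, n_features) aligned with y")
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    labels = tuple(class_order) if class_order is not None else tuple(np.unique(y))
    if len(labels) != 2:
        raise ValueError(f"exactly two classes required, got {labels}")
    m1, m2 = (y == labels[0]), (y == labels[1])
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("each class needs at least 2 samples")

    X1, X2 = X[m1], X[m2]
    mu1, mu2 = X1.mean(axis=0), X2.mean(axis=0)
    S1 = np.cov(X1, rowvar=False, ddof=1)
    S2 = np.cov(X2, rowvar=False, ddof=1)
    S1 = np.atleast_2d(S1)
    S2 = np.atleast_2d(S2)
    S_W = S1 + S2
    d = mu1 - mu2
    dim = X.shape[1]

    if not np.any(S_W) and not np.any(d):
        raise ValueError("all features constant within and across classes (S_W = 0)")

    used_ridge = 0.0 if ridge is None else float(ridge)
    A = S_W + used_ridge * np.eye(dim)
    w = _solve_or_escalate(A, d, S_W, dim, auto=ridge is None)
    if w is None:
        used_ridge = 1e-8 * np.trace(S_W) / dim
        if used_ridge <= 0:
            used_ridge = 1e-8
        w = np.linalg.solve(S_W + used_ridge * np.eye(dim), d)

    s1 = float(np.sqrt(max(w @ S1 @ w, 0.0)))
    s2 = float(np.sqrt(max(w @ S2 @ w, 0.0)))
    p1, p2 = float(w @ mu1), float(w @ mu2)
    z0 = (s2 * p1 + s1 * p2) / (s1 + s2) if (s1 + s2) > 0 else 0.5 * (p1 + p2)
    return FDAModel(
        w=w, z0=float(z0), classes=labels, mu1=mu1, mu2=mu2,
        S1=S1, S2=S2, s1=s1, s2=s2, ridge=used_ridge,
    )


def _solve_or_escalate(A, d, S_W, dim, auto: bool):
    """Solve A w = d; return None when auto-ridge escalation is needed."""
    try:
        w = np.linalg.solve(A, d)
    except np.linalg.LinAlgError:
        if auto:
            return None
        raise
    if not np.isfinite(w).all():
        return None if auto else w
    # numerically singular S_W gives garbage solutions; detect via residual
    if auto:
        resid = np.linalg.norm(A @ w - d)
        scale = np.linalg.norm(d) + 1e-300
        if resid / scale > 1e-6:
            return None
    return w


def classify(model: FDAModel, X_new: np.ndarray) -> np.ndarray:
    """Assign each row of X_new: class 1 iff <w, f> >= z0."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.w.shape[0]:
        raise ValueError(
            f"feature dimension {X_new.shape[1]} does not match model ({model.w.shape[0]})"
        )
    proj = X_new @ model.w
    out = np.where(proj >= model.z0, 0, 1)
    return np.asarray([model.classes[i] for i in out])


@dataclass
class CVResult:
    """k-fold cross-validated classification rate (percent)."""

    mean_rate: float
    sem: float
    fold_rates: np.ndarray
    fold_assignments: np.ndarray  # (n_repeats, n_samples) fold id per sample
    seed: int
    k: int
    n_repeats: int = 1


def _draw_partition(rng, n, k, y, max_attempts=100):
    for _ in range(max_attempts):
        perm = rng.permutation(n)
        folds = np.empty(n, dtype=int)
        for f, idx in enumerate(np.array_split(perm, k)):
            folds[idx] = f
        ok = True
        for f in range(k):
            train_y = y[folds != f]
            if len(np.unique(train_y)) < 2:
                ok = False
                break
        if not ok:
            warnings.warn("training fold lost a class; re-drawing partition", stacklevel=3)
            continue
        return folds
    raise RuntimeError(f"no valid partition in {max_attempts} attempts")


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    seed: int = 0,
    n_repeats: int = 1,
    ridge: float | None = None,
) -> CVResult:
    """k-fold CV of the FDA classifier; seeded, unstratified partition.

    Returns the mean rate (percent) and its SEM across all folds of all
    repeats; bit-reproducible for a fixed seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    rng = np.random.default_rng(seed)
    rates = []
    assignments = np.empty((n_repeats, n), dtype=int)
    for r in range(n_repeats):
        folds = _draw_partition(rng, n, k, y)
        assignments[r] = folds
        for f in range(k):
            test = folds == f
            model = fit_fda(X[~test], y[~test], ridge=ridge)
            pred = classify(model, X[test])
            rates.append(100.0 * float(np.mean(pred == y[test])))
    rates = np.asarray(rates)
    sem = float(rates.std(ddof=1) / np.sqrt(len(rates))) if len(rates) > 1 else 0.0
    return CVResult(
        mean_rate=float(rates.mean()),
        sem=sem,
        fold_rates=rates,
        fold_assignments=assignments,
        seed=seed,
        k=k,
        n_repeats=n_repeats,
    )


def classification_grid(
    feature_table: pd.DataFrame,
    objectives: tuple[tuple[str, str], ...] | None = None,
    bands: tuple[str, ...] | None = None,
    days: tuple[str, ...] | None = None,
    parameters: tuple[str, ...] = ("slope", "intercept"),
    k: int = 10,
    seed: int = 0,
    n_repeats: int = 10,
    include_all_bands: bool = True,
    include_all_days: bool = True,
) -> pd.DataFrame:
    """CV rates for every (band | ALL) x (day | ALL) cell and strain pair.

    A (band, day) cell uses len(parameters) features; a (band, ALL) cell
    uses n_days * len(parameters) (16 for the full design), (ALL, day)
    n_bands * len(parameters) (18), and (ALL, ALL) the full matrix (144).
    Rates are the mean over ``n_repeats`` seeded partitions.
    """
    strains = list(dict.fromkeys(feature_table["strain"]))
    if objectives is None:
        objectives = tuple(
            (strains[i], strains[j])
            for i in range(len(strains))
            for j in range(i + 1, len(strains))
        )
    present = set(feature_table["band"].unique())
    if bands is None:
        bands = tuple(b for b in BAND_ORDER if b in present) or tuple(sorted(present))
    if days is None:
        days = tuple(sorted(feature_table["day"].unique()))
    band_cells = list(bands) + (["ALL"] if include_all_bands else [])
    day_cells = list(days) + (["ALL"] if include_all_days else [])

    rows = []
    rng = np.random.default_rng(seed)
    for s1, s2 in objectives:
        pair = feature_table[feature_table["strain"].isin([s1, s2])]
        for band in band_cells:
            for day in day_cells:
                fm = assemble_feature_vectors(
                    pair,
                    parameters=parameters,
                    days=None if day == "ALL" else (day,),
                    bands=None if band == "ALL" else (band,),
                )
                cv = cross_validate(
                    fm.X, fm.y, k=k, seed=int(rng.integers(2**31)), n_repeats=n_repeats
                )
                rows.append(
                    {
                        "objective": f"{s1} vs {s2}",
                        "band": band,
                        "day": day,
                        "mean_rate": cv.mean_rate,
                        "rounded_rate": round(cv.mean_rate),
                        "sem": cv.sem,
                        "n_samples": fm.X.shape[0],
                        "n_features": fm.X.shape[1],
                    }
                )
    return pd.DataFrame(rows)


def two_axis_projection(
    feature_table: pd.DataFrame,
    parameters: tuple[str, ...] = ("slope", "intercept"),
    train_fraction: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Three-strain visualisation via two sequential two-class FDA axes.

    X-axis separates the first strain from the rest; Y-axis separates the
    remaining two.  Only a random half of the samples (per strain) trains
    the axes, guarding against overfitting; all samples are projected.
    """
    fm = assemble_feature_vectors(feature_table, parameters=parameters)
    strains = list(dict.fromkeys(fm.y))
    if len(strains) != 3:
        raise ValueError("two_axis_projection expects exactly 3 strains")
    rng = np.random.default_rng(seed)
    train = np.zeros(len(fm.y), dtype=bool)
    for s in strains:
        idx = np.nonzero(fm.y == s)[0]
        take = rng.permutation(idx)[: max(2, int(train_fraction * len(idx)))]
        train[take] = True

    y_first = np.where(fm.y == strains[0], strains[0], "rest")
    mx = fit_fda(fm.X[train], y_first[train], class_order=(strains[0], "rest"))
    rest = np.isin(fm.y, strains[1:])
    my = fit_fda(
        fm.X[train & rest], fm.y[train & rest], class_order=(strains[1], strains[2])
    )
    return pd.DataFrame(
        {
            "strain": fm.y,
            "animal": [a for (_, a, _) in fm.sample_index],
            "channel": [c for (_, _, c) in fm.sample_index],
            "x": fm.X @ mx.w - mx.z0,
            "y": fm.X @ my.w - my.z0,
            "train": train,
        }
    )
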