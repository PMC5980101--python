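"""Semi-automatic composite biomarker search.

The search has three steps:

1. **Candidate bands** — keep the sub-bands whose strain factor is highly
   significant in the two-way ANOVA (alpha = 0.01 for at least two of the
   three parameters) *and* whose per-band classifier reaches a median
   pairwise CV rate of at least 80% across the strain objectives.  The
   aggregate Total band is excluded by default.

2. **Weight inspection** — fit the Fisher discriminant repeatedly on
   bootstrap resamples of a two-class objective over the candidate bands
   and report mean +/- SEM of the *normalised* weights: each weight is
   multiplied by its feature's training-set standard deviation (making
   bands with very different power scales comparable) and the vector is
   scaled to unit L1 norm.  Normalisation never changes the classifier's
   decisions.  Class 1 is the target group, so a positive weight means the
   feature is larger in the target.

3. **Consolidation** — mechanise the heuristic that turns a weight
   pattern into a parsimonious composite biomarker: the top-k mPower
   weights by magnitude form a ratio (positive bands in the numerator,
   negative in the denominator) and the top-k slope weights a signed
   linear term added with a mixing weight lambda chosen from {0.1, 0.01}:

       value = (prod numerator mPower) / (prod denominator mPower)
               + lambda * sum(sign_b * slope_b).

   The low-band symbols follow the field convention m = lDelta,
   delta = Delta, theta = Theta, alpha = Alpha, beta = Beta.  Nine named
   presets (three strain biomarkers; MPH and ATX effects per strain) ship
   with the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fda import cross_validate, fit_fda
from .features import assemble_feature_vectors
from .spectral import LOW_BANDS
from .stats import one_tailed_ttest

__all__ = [
    "CompositeBiomarker",
    "PRESETS",
    "BAND_SYMBOLS",
    "select_candidate_bands",
    "Objective",
    "strain_objective",
    "agent_objective",
    "objective_samples",
    "WeightReportEntry",
    "weight_report",
    "evaluate_biomarker",
    "biomarker_significance",
    "consolidate",
]

BAND_SYMBOLS: dict[str, str] = {
    "lDelta": "m",
    "Delta": "delta",
    "Theta": "theta",
    "Alpha": "alpha",
    "Beta": "beta",
}

P_LEVELS: tuple[float, ...] = (0.05, 0.005, 0.001, 1e-5, 1e-10)


@dataclass(frozen=True)
class CompositeBiomarker:
    """Ratio of band mPowers plus a lambda-weighted signed sum of band slopes."""

    name: str
    num_bands: tuple[str, ...]
    den_bands: tuple[str, ...]
    slope_terms: tuple[tuple[str, int], ...]  # (band, +1 | -1)
    lam: float

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        for band, sign in self.slope_terms:
            if sign not in (-1, 1):
                raise ValueError(f"slope term sign must be +/-1, got {sign} for {band}")
        if not self.num_bands and not self.den_bands:
            raise ValueError("biomarker needs at least one mPower band")

    def expression(self) -> str:
        sym = lambda b: BAND_SYMBOLS.get(b, b)
        num = "*".join(f"{sym(b)}^(p)" for b in self.num_bands) or "1"
        den = "*".join(f"{sym(b)}^(p)" for b in self.den_bands)
        ratio = f"{num}/({den})" if den else num
        if not self.slope_terms or self.lam == 0:
            return ratio
        parts = []
        for band, sign in self.slope_terms:
            parts.append(("+" if sign > 0 else "-") + f"{sym(band)}^(s)")
        slope = "".join(parts).lstrip("+")
        return f"{ratio} + {self.lam}*({slope})"

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "num_bands": list(self.num_bands),
            "den_bands": list(self.den_bands),
            "slope_terms": [[b, s] for b, s in self.slope_terms],
            "lambda": self.lam,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CompositeBiomarker":
        return cls(
            name=d["name"],
            num_bands=tuple(d["num_bands"]),
            den_bands=tuple(d["den_bands"]),
            slope_terms=tuple((b, int(s)) for b, s in d["slope_terms"]),
            lam=float(d["lambda"]),
        )


def _bm(name, num, den, slopes, lam) -> CompositeBiomarker:
    return CompositeBiomarker(
        name=name, num_bands=tuple(num), den_bands=tuple(den),
        slope_terms=tuple(slopes), lam=lam,
    )


#: The nine built-in composite biomarkers (strain stratification and
#: per-strain agent effects), entered exactly in their published forms.
PRESETS: dict[str, CompositeBiomarker] = {
    bm.name: bm
    for bm in (
        _bm("SHR", ["Alpha"], ["Delta", "Beta"],
            [("Delta", 1), ("lDelta", -1), ("Theta", -1)], 0.01),
        _bm("WKY", ["Delta", "Alpha"], ["Theta", "Beta"],
            [("lDelta", 1), ("Delta", -1)], 0.1),
        _bm("WIS", ["Theta", "Beta"], ["lDelta", "Alpha"],
            [("Delta", 1), ("Theta", 1), ("lDelta", -1)], 0.1),
        _bm("MPH_SHR", ["Theta"], ["Delta", "Alpha"],
            [("lDelta", 1), ("Theta", 1), ("Delta", -1)], 0.01),
        _bm("MPH_WKY", ["Theta", "Beta"], ["Delta", "Alpha"],
            [("Delta", 1), ("lDelta", -1)], 0.01),
        _bm("MPH_WIS", ["Theta"], ["Alpha"],
            [("lDelta", 1), ("Delta", -1)], 0.1),
        _bm("ATX_SHR", ["Delta"], ["lDelta", "Beta"],
            [("Theta", 1), ("Alpha", -1), ("lDelta", -1)], 0.01),
        _bm("ATX_WKY", ["Delta"], ["lDelta", "Beta"],
            [("Theta", 1), ("Alpha", -1), ("lDelta", -1)], 0.01),
        _bm("ATX_WIS", ["Alpha"], ["Theta", "Beta"],
            [("Theta", 1), ("Alpha", -1), ("lDelta", -1)], 0.01),
    )
}


# ---------------------------------------------------------------------------
# Step 1: candidate band selection
# ---------------------------------------------------------------------------

def select_candidate_bands(
    anova: pd.DataFrame,
    grid: pd.DataFrame,
    alpha: float = 0.01,
    min_significant_params: int = 2,
    rate_threshold: float = 80.0,
    exclude: tuple[str, ...] = ("Total",),
) -> list[str]:
    """Bands passing both the ANOVA strain-significance and CV-rate rules.

    ``anova`` is an ``stats.anova_table`` frame; ``grid`` a
    ``fda.classification_grid`` frame (its day='ALL' rows are used).
    Returns bands in canonical order; emits a warning (not an error) when
    empty.
    """
    sig = (
        anova[anova["p_strain"] <= alpha]
        .groupby("band")["parameter"]
        .nunique()
    )
    anova_ok = set(sig[sig >= min_significant_params].index)

    g = grid[grid["day"] == "ALL"]
    med = g.groupby("band")["mean_rate"].median()
    rate_ok = set(med[med >= rate_threshold].index) - {"ALL"}

    order = list(anova["band"].unique())
    selected = [
        b for b in order if b in anova_ok and b in rate_ok and b not in exclude
    ]
    if not selected:
        import warnings

        warnings.warn("no candidate bands passed the selection rule", stacklevel=2)
    return selected


# ---------------------------------------------------------------------------
# Step 2: objectives and bootstrap weight reports
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Objective:
    """A two-class contrast over the feature table.

    ``target``/``reference`` are (strains, days) selectors; samples are
    (strain, animal, channel, day) cells of the requested day(s).  The
    target side is class 1, so positive FDA weights mean larger values in
    the target group.
    """

    name: str
    target_strains: tuple[str, ...]
    target_days: tuple[str, ...]
    reference_strains: tuple[str, ...]
    reference_days: tuple[str, ...]


def strain_objective(target: str, others: tuple[str, ...], day: str = "D1") -> Objective:
    """Target strain vs the remaining strains on the vehicle day."""
    return Objective(
        name=f"{target} vs rest ({day})",
        target_strains=(target,),
        target_days=(day,),
        reference_strains=tuple(others),
        reference_days=(day,),
    )


def agent_objective(
    strain: str, agent: str, dose_days: tuple[str, ...], vehicle: str = "D1"
) -> Objective:
    """Agent dose day(s) vs the vehicle day within one strain."""
    return Objective(
        name=f"{agent} vs vehicle in {strain}",
        target_strains=(strain,),
        target_days=tuple(dose_days),
        reference_strains=(strain,),
        reference_days=(vehicle,),
    )


def objective_samples(
    feature_table: pd.DataFrame,
    objective: Objective,
    bands: tuple[str, ...],
    parameters: tuple[str, ...],
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str]]]:
    """(X, y, feature_names) for a two-class objective.

    One sample per (strain, animal, channel, day); features are the
    requested (band, parameter) pairs averaged over the selected days of
    that sample's side (days enter as separate samples, preserving the
    per-day dose structure).
    """
    frames = []
    for cls, strains, days in (
        (1, objective.target_strains, objective.target_days),
        (0, objective.reference_strains, objective.reference_days),
    ):
        sub = feature_table[
            feature_table["strain"].isin(strains)
            & feature_table["day"].isin(days)
            & feature_table["band"].isin(bands)
        ].copy()
        sub["cls"] = cls
        frames.append(sub)
    data = pd.concat(frames)
    if data.empty:
        raise ValueError(f"objective {objective.name!r} selects no samples")
    wide = data.pivot_table(
        index=["strain", "animal", "channel", "day", "cls"],
        columns="band",
        values=list(parameters),
        aggfunc="first",
    )
    feature_names = [(b, p) for b in bands for p in parameters]
    cols = pd.MultiIndex.from_tuples([(p, b) for b, p in feature_names])
    wide = wide.reindex(columns=cols).dropna()
    X = wide.to_numpy(dtype=float)
    y = wide.index.get_level_values("cls").to_numpy()
    return X, y, feature_names


FEATURE_SETS: tuple[tuple[str, ...], ...] = (
    ("slope",),
    ("intercept",),
    ("mPower",),
    ("slope", "intercept"),
    ("slope", "mPower"),
)


@dataclass
class WeightReportEntry:
    """Bootstrap mean +/- SEM of normalised FDA weights for one objective."""

    objective: str
    feature_set: tuple[str, ...]
    bands: tuple[str, ...]
    weights_mean: pd.Series = field(repr=False)  # index (band, parameter)
    weights_sem: pd.Series = field(repr=False)
    cv_rate: float = float("nan")
    cv_sem: float = float("nan")
    n_repeats: int = 0

    def weight(self, band: str, parameter: str) -> float:
        return float(self.weights_mean.loc[(band, parameter)])


def _normalise_weights(w: np.ndarray, X: np.ndarray) -> np.ndarray:
    scaled = w * X.std(axis=0, ddof=1)
    norm = np.abs(scaled).sum()
    return scaled / norm if norm > 0 else scaled


def weight_report(
    feature_table: pd.DataFrame,
    objective: Objective,
    feature_set: tuple[str, ...] = ("slope", "mPower"),
    bands: tuple[str, ...] = LOW_BANDS,
    n_repeats: int = 50,
    seed: int = 0,
    k: int = 10,
    ridge: float | None = None,
) -> WeightReportEntry:
    """Bootstrap-resampled FDA weights for one objective and feature set."""
    X, y, names = objective_samples(feature_table, objective, tuple(bands), tuple(feature_set))
    rng = np.random.default_rng(seed)
    n = len(y)
    all_w = np.empty((n_repeats, X.shape[1]))
    for r in range(n_repeats):
        for _ in range(100):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) == 2 and min(
                (y[idx] == 1).sum(), (y[idx] == 0).sum()
            ) >= 2:
                break
        else:
            raise RuntimeError("bootstrap resample kept losing a class")
        model = fit_fda(X[idx], y[idx], ridge=ridge, class_order=(1, 0))
        all_w[r] = _normalise_weights(model.w, X[idx])
    mean = all_w.mean(axis=0)
    sem = all_w.std(axis=0, ddof=1) / np.sqrt(n_repeats)
    index = pd.MultiIndex.from_tuples(names, names=["band", "parameter"])
    cv = cross_validate(X, y, k=min(k, n), seed=seed, ridge=ridge)
    return WeightReportEntry(
        objective=objective.name,
        feature_set=tuple(feature_set),
        bands=tuple(bands),
        weights_mean=pd.Series(mean, index=index),
        weights_sem=pd.Series(sem, index=index),
        cv_rate=cv.mean_rate,
        cv_sem=cv.sem,
        n_repeats=n_repeats,
    )


# ---------------------------------------------------------------------------
# Step 3: evaluation and consolidation
# ---------------------------------------------------------------------------

def evaluate_biomarker(
    biomarker: CompositeBiomarker,
    feature_table: pd.DataFrame,
    day: str,
    strain: str | None = None,
) -> pd.DataFrame:
    """Biomarker value per (strain, animal, channel) sample on one day."""
    needed = set(biomarker.num_bands) | set(biomarker.den_bands) | {
        b for b, _ in biomarker.slope_terms
    }
    sub = feature_table[
        (feature_table["day"] == day) & feature_table["band"].isin(needed)
    ]
    if strain is not None:
        sub = sub[sub["strain"] == strain]
    if sub.empty:
        raise ValueError(f"no features for day {day!r}")
    wide = sub.pivot_table(
        index=["strain", "animal", "channel"],
        columns="band",
        values=["mPower", "slope"],
        aggfunc="first",
    ).dropna()

    mp = wide["mPower"]
    for b in biomarker.den_bands:
        bad = mp.index[mp[b] <= 0]
        if len(bad):
            raise ValueError(
                f"non-positive mPower in denominator band {b!r} for sample {bad[0]}"
            )
    value = np.ones(len(wide))
    for b in biomarker.num_bands:
        value = value * mp[b].to_numpy()
    for b in biomarker.den_bands:
        value = value / mp[b].to_numpy()
    if biomarker.lam and biomarker.slope_terms:
        sl = wide["slope"]
        term = np.zeros(len(wide))
        for b, sign in biomarker.slope_terms:
            term = term + sign * sl[b].to_numpy()
        value = value + biomarker.lam * term
    out = wide.index.to_frame(index=False)
    out["value"] = value
    out["day"] = day
    out["biomarker"] = biomarker.name
    return out


def biomarker_significance(values_by_group: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise one-tailed t-tests between the groups of biomarker values.

    The first group is treated as the target; rows compare it against each
    other group and report the p-level bucket used for rendering marks.
    """
    names = list(values_by_group)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    target = names[0]
    rows = []
    for other in names[1:]:
        r = one_tailed_ttest(values_by_group[target], values_by_group[other])
        met = [lv for lv in P_LEVELS if r.p_one_tailed <= lv]
        rows.append(
            {
                "target": target,
                "comparison": other,
                "t": r.t,
                "p_one_tailed": r.p_one_tailed,
                "direction": r.direction,
                "level": min(met) if met else None,
            }
        )
    return pd.DataFrame(rows)


def _top_k(series: pd.Series, k: int, band_order: tuple[str, ...]) -> pd.Series:
    """Top-k entries by |value|, ties broken by canonical band order."""
    order = {b: i for i, b in enumerate(band_order)}
    ranked = sorted(
        series.items(), key=lambda kv: (-abs(kv[1]), order.get(kv[0], len(order)))
    )
    return pd.Series(dict(ranked[:k]))


def consolidate(
    report: WeightReportEntry,
    top_k: int = 3,
    lambda_candidates: tuple[float, ...] = (0.1, 0.01),
    feature_table: pd.DataFrame | None = None,
    objective: Objective | None = None,
    seed: int = 0,
    name: str = "proposal",
) -> list[CompositeBiomarker]:
    """Turn a weight pattern into ranked composite-biomarker proposals.

    The top-k mPower weights by magnitude define the ratio (positive ->
    numerator, negative -> denominator); the top-k slope weights define
    the signed slope term; one proposal is emitted per lambda candidate.
    When ``feature_table`` and ``objective`` are given, proposals are
    ranked by the one-tailed t statistic they achieve on a held-out
    50/50 stratified split (best first); otherwise input order is kept.
    """
    import warnings

    wm = report.weights_mean
    params = set(wm.index.get_level_values("parameter"))
    if "mPower" not in params:
        raise ValueError("consolidation needs mPower weights in the report")
    mpw = wm.xs("mPower", level="parameter")
    if top_k > len(mpw):
        warnings.warn(
            f"top_k={top_k} exceeds the {len(mpw)} available bands; clamping",
            stacklevel=2,
        )
        top_k = len(mpw)
    band_order = tuple(report.bands)
    top_p = _top_k(mpw, top_k, band_order)
    num = tuple(b for b in band_order if b in top_p.index and top_p[b] > 0)
    den = tuple(b for b in band_order if b in top_p.index and top_p[b] <= 0)

    slope_terms: tuple[tuple[str, int], ...] = ()
    if "slope" in params:
        slw = wm.xs("slope", level="parameter")
        top_s = _top_k(slw, top_k, band_order)
        slope_terms = tuple(
            (b, 1 if top_s[b] > 0 else -1) for b in band_order if b in top_s.index
        )

    proposals = [
        CompositeBiomarker(
            name=f"{name}(lambda={lam})",
            num_bands=num,
            den_bands=den,
            slope_terms=slope_terms,
            lam=lam,
        )
        for lam in lambda_candidates
    ]

    if feature_table is None or objective is None:
        return proposals

    # rank by held-out separation
    rng = np.random.default_rng(seed)
    scored = []
    for bm in proposals:
        vals_t = _objective_values(bm, feature_table, objective, side="target")
        vals_r = _objective_values(bm, feature_table, objective, side="reference")
        hold_t = _holdout(vals_t, rng)
        hold_r = _holdout(vals_r, rng)
        r = one_tailed_ttest(hold_t, hold_r)
        scored.append((abs(r.t), bm))
    scored.sort(key=lambda x: -x[0])
    return [bm for _, bm in scored]


def _objective_values(bm, feature_table, objective, side: str) -> np.ndarray:
    strains = getattr(objective, f"{side}_strains")
    days = getattr(objective, f"{side}_days")
    vals = []
    for day in days:
        sub = feature_table[feature_table["strain"].isin(strains)]
        vals.append(evaluate_biomarker(bm, sub, day)["value"].to_numpy())
    return np.concatenate(vals)


def _holdout(values: np.ndarray, rng) -> np.ndarray:
    idx = rng.permutation(len(values))
    return values[idx[len(values) // 2 :]]
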