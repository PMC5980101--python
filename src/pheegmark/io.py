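"""Readers, writers, pipeline configuration and the end-to-end runner.

Band-power datasets persist in two interchangeable formats:

* **HDF5**: ``/power`` holding the 6-way array
  ``[band, time, channel, day, animal, strain]`` and a ``/meta`` JSON
  attribute with the axis labels, band definitions, step and injection
  index;
* **long CSV**: one row per (strain, animal, channel, day, band, time_s)
  with a ``power`` column — order-independent on read.

All emitted tables are UTF-8 comma-separated with a header row and '.'
decimals, keeping them diffable.  ``run_pipeline`` executes the full
analysis — simulate (or load) -> smooth -> outlier-detect -> features ->
ANOVA/t-tests -> FDA classification grid -> biomarker search — writing
every artifact plus a JSON run log, and is idempotent for a fixed
config + seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import biomarkers as bmk
from . import fda as fda_mod
from . import stats as stats_mod
from .features import FitWindow, build_feature_table
from .preprocess import detect_outliers, smooth_dataset
from .spectral import PAPER_BANDS, BandDefinition, BandPowerDataset
from .synthetic import SyntheticConfig, adhd_strain_scenario, generate_dataset

logger = logging.getLogger("pheegmark")

__all__ = [
    "write_band_power",
    "read_band_power",
    "write_long_csv",
    "read_long_csv",
    "read_raw_signals",
    "PipelineConfig",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# band-power containers
# ---------------------------------------------------------------------------

def _meta_dict(ds: BandPowerDataset) -> dict:
    return {
        "step_s": ds.step_s,
        "injection_index": int(ds.injection_index),
        "bands": [[b.name, b.f_low, b.f_high] for b in ds.band_defs],
        "strains": list(ds.strains),
        "days": list(ds.days),
        "channels": list(ds.channels),
        "animals": list(ds.animals),
    }


def _from_meta(power: np.ndarray, meta: dict) -> BandPowerDataset:
    return BandPowerDataset(
        power=power,
        step_s=float(meta["step_s"]),
        injection_index=int(meta["injection_index"]),
        band_defs=tuple(BandDefinition(n, lo, hi) for n, lo, hi in meta["bands"]),
        strains=tuple(meta["strains"]),
        days=tuple(meta["days"]),
        channels=tuple(meta["channels"]),
        animals=tuple(meta["animals"]),
    )


def write_band_power(dataset: BandPowerDataset, path) -> None:
    """Write a dataset to HDF5 (/power array + /meta JSON attrs)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("power", data=dataset.power)
        f["power"].attrs["dims"] = "band,time,channel,day,animal,strain"
        f.attrs["meta"] = json.dumps(_meta_dict(dataset))


def _read_h5(path) -> BandPowerDataset:
    with h5py.File(path, "r") as f:
        if "power" not in f or "meta" not in f.attrs:
            missing = [k for k in ("power", "meta") if k not in f and k not in f.attrs]
            raise ValueError(f"schema error: missing {missing} in {path}")
        power = f["power"][...]
        meta = json.loads(f.attrs["meta"])
    return _from_meta(power, meta)


_CSV_COLUMNS = ["strain", "animal", "channel", "day", "band", "time_s", "power"]


def write_long_csv(dataset: BandPowerDataset, path) -> None:
    """Write the dataset in long format (one row per sample point)."""
    nb, nt, nc, nd, na, ns = dataset.power.shape
    idx = pd.MultiIndex.from_product(
        [dataset.band_names, dataset.time_s, dataset.channels,
         dataset.days, dataset.animals, dataset.strains],
        names=["band", "time_s", "channel", "day", "animal", "strain"],
    )
    df = pd.DataFrame({"power": dataset.power.ravel()}, index=idx).reset_index()
    df = df[_CSV_COLUMNS]
    header = json.dumps(_meta_dict(dataset))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# meta: {header}\n")
        df.to_csv(fh, index=False)


def read_long_csv(path) -> BandPowerDataset:
    """Read a long-format CSV regardless of row order."""
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith("# meta:"):
            raise ValueError(f"schema error: missing '# meta:' header line in {path}")
        meta = json.loads(first[len("# meta:"):])
        df = pd.read_csv(fh)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"schema error: missing columns {missing} in {path}")
    neg = df[df["power"] < 0]
    if len(neg):
        row = neg.iloc[0]
        raise ValueError(
            "validation error: negative power at "
            f"(strain={row['strain']}, animal={row['animal']}, channel={row['channel']}, "
            f"day={row['day']}, band={row['band']}, time_s={row['time_s']})"
        )
    axes = {
        "band": meta["bands"] and [b[0] for b in meta["bands"]],
        "time_s": sorted(df["time_s"].unique()),
        "channel": meta["channels"],
        "day": meta["days"],
        "animal": meta["animals"],
        "strain": meta["strains"],
    }
    ordered = df.set_index(["band", "time_s", "channel", "day", "animal", "strain"])
    full = pd.MultiIndex.from_product(list(axes.values()), names=list(axes.keys()))
    power = ordered.reindex(full)["power"].to_numpy().reshape(
        [len(v) for v in axes.values()]
    )
    if np.isnan(power).any():
        raise ValueError(f"schema error: incomplete grid in {path}")
    return _from_meta(power, meta)


def read_band_power(path, format: str | None = None) -> BandPowerDataset:
    """Load a dataset from HDF5 or long CSV (format inferred from suffix)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("hdf5" if path.suffix in (".h5", ".hdf5") else "csv")
    if fmt == "hdf5":
        return _read_h5(path)
    if fmt == "csv":
        return read_long_csv(path)
    raise ValueError(f"unknown format {fmt!r}")


def read_raw_signals(path, sampling_rate_hz: float | None = None):
    """Read raw multichannel EEG from EDF or a plain numeric CSV/TSV matrix.

    CSV/TSV matrices are (n_samples, n_channels) with a header row;
    ``sampling_rate_hz`` is then required.  EDF files carry their own rate
    and need the optional ``mne`` dependency.  Returns
    (signals ``(n_channels, n_samples)``, sampling_rate_hz).
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        try:
            import mne
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError("reading EDF requires the optional 'mne' dependency") from exc
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return raw.get_data(), float(raw.info["sfreq"])
    if sampling_rate_hz is None:
        raise ValueError("sampling_rate_hz is required for plain matrix input")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    return df.to_numpy(dtype=float).T, float(sampling_rate_hz)


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs; JSON round-trip safe."""

    input_path: str | None = None  # None -> simulate
    scenario: str = "adhd_strain"  # 'adhd_strain' | 'null'
    step_s: float = 0.25
    duration_s: float = 3600.0
    n_animals_per_strain: int = 10
    median_window: int = 241
    fence_factor: float = 1.5
    central_fraction: float = 0.5
    fit_start_min: float = 2.0
    fit_length_min: float = 49.0
    cv_folds: int = 10
    cv_repeats: int = 10
    candidate_alpha: float = 0.01
    candidate_rate_threshold: float = 80.0
    weight_repeats: int = 50
    lambda_candidates: tuple[float, ...] = (0.1, 0.01)
    welch: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.median_window < 1 or self.median_window % 2 == 0:
            raise ValueError("median_window must be odd and >= 1")
        if self.fit_length_min <= 0:
            raise ValueError("fit window length must be positive")
        if self.cv_folds < 2 or self.cv_repeats < 1:
            raise ValueError("cv_folds >= 2 and cv_repeats >= 1 required")
        if not (0 < self.central_fraction <= 1):
            raise ValueError("central_fraction must lie in (0, 1]")
        if self.fence_factor < 0:
            raise ValueError("fence_factor must be non-negative")

    def to_json(self, path=None) -> str:
        d = dataclasses.asdict(self)
        d["lambda_candidates"] = list(self.lambda_candidates)
        text = json.dumps(d, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source) -> "PipelineConfig":
        if isinstance(source, (str, Path)) and Path(source).exists():
            d = json.loads(Path(source).read_text(encoding="utf-8"))
        else:
            d = json.loads(source)
        d["lambda_candidates"] = tuple(d.get("lambda_candidates", (0.1, 0.01)))
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @property
    def fit_window(self) -> FitWindow:
        return FitWindow(self.fit_start_min, self.fit_length_min)


# ---------------------------------------------------------------------------
# the runner
# ---------------------------------------------------------------------------

def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                logger.info("stage %s", name)
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(config: PipelineConfig, outdir, seed: int | None = None) -> dict:
    """Execute the full analysis and write all artifacts under ``outdir``.

    Returns a dict of in-memory results (dataset, feature table, ANOVA and
    t-test tables, grid, candidate bands, weight report, biomarker
    proposals and evaluations) mirroring what was written.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    @_stage("load")
    def load():
        if config.input_path:
            return read_band_power(config.input_path), None
        if config.scenario == "adhd_strain":
            sc = adhd_strain_scenario(
                step_s=config.step_s,
                duration_s=config.duration_s,
                n_animals_per_strain=config.n_animals_per_strain,
                seed=seed,
            )
        elif config.scenario == "null":
            sc = SyntheticConfig(
                step_s=config.step_s,
                duration_s=config.duration_s,
                n_animals_per_strain=config.n_animals_per_strain,
                seed=seed,
            )
        else:
            raise ValueError(f"unknown scenario {config.scenario!r}")
        min_post = config.fit_start_min + config.fit_length_min
        return generate_dataset(sc, min_post_injection_min=min_post)

    loaded = load()
    dataset, truth = loaded if isinstance(loaded, tuple) else (loaded, None)

    smoothed = _stage("smooth")(smooth_dataset)(dataset, config.median_window)
    report = _stage("outliers")(detect_outliers)(
        smoothed, central_fraction=config.central_fraction, fence_factor=config.fence_factor
    )
    report.to_csv(outdir / "outliers.csv")

    # Outlier-removed table for the univariate statistics; full table for the
    # multivariate classification path, which keeps every (animal, channel)
    # sample so the all-days x all-bands matrix stays complete (the study's
    # 10-fold CV likewise used all 150 samples, outliers included).
    table = _stage("features")(build_feature_table)(
        smoothed, outlier_report=report, smoothing_window=None, window=config.fit_window
    )
    table.to_csv(outdir / "features.csv", index=False)
    table_full = build_feature_table(
        smoothed, outlier_report=report, smoothing_window=None,
        window=config.fit_window, drop_outliers=False,
    )

    anova = _stage("stats")(stats_mod.anova_table)(table)
    anova.to_csv(outdir / "anova.csv", index=False)
    ttests = stats_mod.ttest_table(table, welch=config.welch)
    ttests.to_csv(outdir / "ttests.csv", index=False)

    grid = _stage("fda")(fda_mod.classification_grid)(
        table_full, k=config.cv_folds, seed=seed, n_repeats=config.cv_repeats
    )
    grid.to_csv(outdir / "classification_grid.csv", index=False)

    @_stage("biomarker")
    def biomarker_stage():
        candidates = bmk.select_candidate_bands(
            anova, grid,
            alpha=config.candidate_alpha,
            rate_threshold=config.candidate_rate_threshold,
        )
        strains = list(dict.fromkeys(table_full["strain"]))
        results = {"candidate_bands": candidates, "objectives": {}}
        if len(candidates) >= 2 and len(strains) >= 2:
            target = strains[0]
            obj = bmk.strain_objective(target, tuple(strains[1:]))
            wr = bmk.weight_report(
                table_full, obj, bands=tuple(candidates),
                n_repeats=config.weight_repeats, seed=seed,
            )
            proposals = bmk.consolidate(
                wr, lambda_candidates=config.lambda_candidates,
                feature_table=table_full, objective=obj, seed=seed,
                name=f"{target}_auto",
            )
            results["objectives"][obj.name] = {
                "weights_mean": {f"{b}/{p}": v for (b, p), v in wr.weights_mean.items()},
                "weights_sem": {f"{b}/{p}": v for (b, p), v in wr.weights_sem.items()},
                "cv_rate": wr.cv_rate,
                "cv_sem": wr.cv_sem,
                "proposals": [p.to_dict() for p in proposals],
            }
        return results

    bio = biomarker_stage()
    (outdir / "biomarkers.json").write_text(
        json.dumps(bio, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )

    evals = []
    vehicle_day = "D1" if "D1" in set(table["day"]) else sorted(set(table["day"]))[0]
    for name, preset in bmk.PRESETS.items():
        try:
            evals.append(bmk.evaluate_biomarker(preset, table, vehicle_day))
        except ValueError:
            continue
    if evals:
        pd.concat(evals).to_csv(outdir / "preset_values.csv", index=False)

    log = {
        "seed": seed,
        "config": json.loads(config.to_json()),
        "n_feature_rows": int(len(table)),
        "n_outlier_groups": int(report.n_groups),
        "n_flagged_curves": int(report.table["flagged"].sum()),
        "candidate_bands": bio["candidate_bands"],
    }
    (outdir / "run_log.json").write_text(
        json.dumps(log, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return {
        "dataset": dataset,
        "truth": truth,
        "outlier_report": report,
        "feature_table": table,
        "anova": anova,
        "ttests": ttests,
        "grid": grid,
        "biomarkers": bio,
        "log": log,
    }
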