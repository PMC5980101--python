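"""Synthetic pharmaco-EEG band-power generator.

Emulates the study design the rest of the package targets: 3 rat strains
(SHR, the ADHD model; WKY; WIS) x 10 animals x 5 EEG channels x 8
experimental days, 9 spectral sub-bands sampled every 250 ms for one hour,
with the injection 9 minutes after record start.  Each band-power curve is

    y(t) = baseline_b * strain_offset_{s,b}
           + slope_{s,d,b} * max(0, t - t_inj)   [minutes]
           + AR(1) noise + sparse positive spikes,

optionally multiplied as a whole by a level-shift factor drawn from {3, 5}
to create outlier curves of the kind a functional boxplot flags.  Powers
are floored at 1e-9 so ratio biomarkers stay defined.

The noise is AR(1) with coefficient 0.9 on the sampling grid (persistent
drift the median filter targets) with stationary standard deviation
``noise_sd`` expressed *relative* to the curve's baseline level, because
band baselines span two orders of magnitude.  Spikes are i.i.d. positive
exponential bursts.

``generate_dataset`` returns the dataset together with a ``GroundTruth``
holding the realised slope/intercept of every curve and the outlier labels,
so parameter-recovery and outlier-detection tests need no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .spectral import BAND_ORDER, LOW_BANDS, PAPER_BANDS, BandDefinition, BandPowerDataset

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "ConfigurationError",
    "generate_dataset",
    "adhd_strain_scenario",
    "shr_slope_scenario",
    "DEFAULT_BASELINES",
]


class ConfigurationError(ValueError):
    """Invalid synthetic-design configuration."""


#: Default per-band baseline power (arbitrary power units), strictly
#: decreasing over lDelta > Delta > Theta > Alpha > Beta as real rodent
#: EEG band powers are.
DEFAULT_BASELINES: dict[str, float] = {
    "Total": 100.0,
    "lDelta": 50.0,
    "Delta": 30.0,
    "Theta": 15.0,
    "Alpha": 8.0,
    "Beta": 4.0,
    "Gamma": 2.0,
    "High": 1.0,
    "vHigh": 0.5,
}

_POWER_FLOOR = 1e-9
_AR_COEF = 0.9
_OUTLIER_FACTORS = (3.0, 5.0)


@dataclass
class SyntheticConfig:
    """Design parameters of a synthetic recording campaign.

    ``strain_offsets`` has shape (n_strains, n_bands) (multiplicative);
    ``dose_slope_effects`` has shape (n_strains, n_days, n_bands) in power
    units per minute, applied after the injection.
    """

    n_strains: int = 3
    n_animals_per_strain: int = 10
    n_channels: int = 5
    n_days: int = 8
    bands: tuple[str, ...] = BAND_ORDER
    step_s: float = 0.25
    duration_s: float = 3600.0
    injection_offset_s: float = 540.0
    baseline_power_per_band: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINES)
    )
    strain_offsets: np.ndarray | None = None
    dose_slope_effects: np.ndarray | None = None
    noise_sd: float = 0.1
    spike_rate: float = 0.002
    outlier_curve_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strain_offsets is None:
            self.strain_offsets = np.ones((self.n_strains, len(self.bands)))
        if self.dose_slope_effects is None:
            self.dose_slope_effects = np.zeros((self.n_strains, self.n_days, len(self.bands)))
        self.strain_offsets = np.asarray(self.strain_offsets, dtype=float)
        self.dose_slope_effects = np.asarray(self.dose_slope_effects, dtype=float)
        self.validate()

    def validate(self) -> None:
        nb = len(self.bands)
        for b in self.bands:
            if b not in self.baseline_power_per_band:
                raise ConfigurationError(f"no baseline power given for band {b!r}")
            if self.baseline_power_per_band[b] <= 0:
                raise ConfigurationError(f"baseline power for band {b!r} must be positive")
        chain = [b for b in ("lDelta", "Delta", "Theta", "Alpha", "Beta") if b in self.bands]
        vals = [self.baseline_power_per_band[b] for b in chain]
        if any(a <= b for a, b in zip(vals, vals[1:])):
            raise ConfigurationError(
                "baseline powers must strictly decrease over lDelta > Delta > Theta > Alpha > Beta"
            )
        if not (0 < self.injection_offset_s < self.duration_s):
            raise ConfigurationError("need 0 < injection_offset_s < duration_s")
        for name in ("spike_rate", "outlier_curve_rate"):
            r = getattr(self, name)
            if not (0 <= r <= 1):
                raise ConfigurationError(f"{name} must lie in [0, 1], got {r}")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.strain_offsets.shape != (self.n_strains, nb):
            raise ConfigurationError("strain_offsets must have shape (n_strains, n_bands)")
        if self.dose_slope_effects.shape != (self.n_strains, self.n_days, nb):
            raise ConfigurationError(
                "dose_slope_effects must have shape (n_strains, n_days, n_bands)"
            )
        if self.step_s <= 0 or self.duration_s <= 0:
            raise ConfigurationError("step_s and duration_s must be positive")

    @property
    def n_time(self) -> int:
        return int(np.floor(self.duration_s / self.step_s))

    @property
    def injection_index(self) -> int:
        return int(round(self.injection_offset_s / self.step_s))

    def band_defs(self) -> tuple[BandDefinition, ...]:
        by_name = {b.name: b for b in PAPER_BANDS}
        return tuple(
            by_name.get(name, BandDefinition(name, 0.0, 1.0)) for name in self.bands
        )


@dataclass
class GroundTruth:
    """Realised per-curve generative parameters, axes (band, channel, day, animal, strain).

    ``slope``/``intercept`` include the outlier level-shift factor, i.e. they
    describe the curve actually present in the dataset; ``outlier_flags``
    marks level-shifted curves; ``outlier_factor`` is 1 for clean curves.
    """

    slope: np.ndarray
    intercept: np.ndarray
    outlier_flags: np.ndarray
    outlier_factor: np.ndarray


def _check_fit_window(config: SyntheticConfig, min_post_injection_min: float | None) -> None:
    if min_post_injection_min is None:
        return
    needed = config.injection_offset_s + min_post_injection_min * 60.0
    if config.duration_s < needed:
        raise ConfigurationError(
            f"duration {config.duration_s} s is shorter than injection offset plus the "
            f"{min_post_injection_min}-minute fit window ({needed} s)"
        )


def generate_dataset(
    config: SyntheticConfig,
    min_post_injection_min: float | None = 51.0,
) -> tuple[BandPowerDataset, GroundTruth]:
    """Draw one full synthetic campaign; bit-deterministic given ``config.seed``.

    ``min_post_injection_min`` guards against records too short for the
    default regression window (2-51 min after injection); pass a smaller
    value (or None) when a custom fit window will be used downstream.
    """
    config.validate()
    _check_fit_window(config, min_post_injection_min)
    rng = np.random.default_rng(config.seed)

    nb = len(config.bands)
    nt, nc = config.n_time, config.n_channels
    nd, na, ns = config.n_days, config.n_animals_per_strain, config.n_strains
    shape = (nb, nt, nc, nd, na, ns)

    t_min = (np.arange(nt) - config.injection_index) * config.step_s / 60.0
    post = np.clip(t_min, 0.0, None)  # minutes since injection, 0 before

    base_b = np.array([config.baseline_power_per_band[b] for b in config.bands])
    level = base_b[:, None] * config.strain_offsets.T  # (band, strain)
    # dose_slope_effects is (strain, day, band); want (band, day, strain)
    slope_bds = np.transpose(config.dose_slope_effects, (2, 1, 0))

    y = np.empty(shape)
    y[:] = level[:, None, None, None, None, :]
    y += slope_bds[:, None, None, :, None, :] * post[None, :, None, None, None, None]

    sd = config.noise_sd * level  # (band, strain) stationary sd
    if config.noise_sd > 0:
        innov = rng.standard_normal(shape)
        innov *= (sd * np.sqrt(1.0 - _AR_COEF**2))[:, None, None, None, None, :]
        noise = lfilter([1.0], [1.0, -_AR_COEF], innov, axis=1)
        y += noise
    if config.spike_rate > 0:
        mask = rng.random(shape) < config.spike_rate
        amp = rng.exponential(scale=3.0, size=shape)  # in units of local noise sd
        y += mask * amp * sd[:, None, None, None, None, :]

    factor = np.ones((nb, nc, nd, na, ns))
    flags = np.zeros((nb, nc, nd, na, ns), dtype=bool)
    if config.outlier_curve_rate > 0:
        flags = rng.random((nb, nc, nd, na, ns)) < config.outlier_curve_rate
        draw = rng.integers(0, len(_OUTLIER_FACTORS), size=flags.shape)
        factor = np.where(flags, np.asarray(_OUTLIER_FACTORS)[draw], 1.0)
        y *= factor[:, None]

    np.clip(y, _POWER_FLOOR, None, out=y)

    truth = GroundTruth(
        slope=slope_bds[:, None, :, None, :].repeat(nc, 1).repeat(na, 3) * factor,
        intercept=level[:, None, None, None, :] * np.ones((nb, nc, nd, na, ns)) * factor,
        outlier_flags=flags,
        outlier_factor=factor,
    )

    dataset = BandPowerDataset(
        power=y,
        step_s=config.step_s,
        injection_index=config.injection_index,
        band_defs=config.band_defs(),
        strains=tuple(("SHR", "WKY", "WIS")[:ns]) if ns <= 3
        else tuple(f"S{i}" for i in range(ns)),
        days=tuple(f"D{i}" for i in range(nd)),
        channels=tuple(("LF", "RF", "LP", "RP", "RO")[:nc]) if nc <= 5
        else tuple(f"C{i}" for i in range(nc)),
        animals=tuple(f"A{i}" for i in range(na)),
    )
    return dataset, truth


def adhd_strain_scenario(
    step_s: float = 0.25,
    duration_s: float = 3600.0,
    n_animals_per_strain: int = 10,
    noise_sd: float = 0.1,
    spike_rate: float = 0.002,
    outlier_curve_rate: float = 0.02,
    seed: int = 0,
) -> SyntheticConfig:
    """Study-like scenario: strain effects planted in the lDelta-Beta bands only.

    Encodes the qualitative structure the real experiment reports: the three
    strains differ in low-frequency band levels (each band with a distinct
    ordering so every pairwise strain contrast is informative), SHR shows
    depressed lDelta/Theta drift after injection, and the high-frequency
    bands (Gamma, High, vHigh) carry no strain signal.  Total is left
    neutral as an aggregate band.  MPH/ATX dosing days (D2-D6) add
    dose-scaled post-injection Theta/Alpha trends.
    """
    bands = BAND_ORDER
    ib = {b: i for i, b in enumerate(bands)}
    ns, nd = 3, 8

    offsets = np.ones((ns, len(bands)))
    # rows: SHR, WKY, WIS
    planted = {
        "lDelta": (1.25, 1.00, 0.80),
        "Delta": (0.90, 1.00, 1.10),
        "Theta": (1.15, 1.00, 0.85),
        "Alpha": (1.25, 1.00, 0.95),
        "Beta": (0.85, 1.00, 1.10),
    }
    for band, (shr, wky, wis) in planted.items():
        offsets[:, ib[band]] = (shr, wky, wis)

    slopes = np.zeros((ns, nd, len(bands)))
    # Strain-specific spontaneous drift, present on every day (vehicle included):
    # SHR loses lDelta and Theta power after the handling/injection event.
    slopes[0, :, ib["lDelta"]] = -0.20
    slopes[0, :, ib["Theta"]] = -0.05
    # Agent days: dose-proportional Theta decrease / Alpha increase, stronger in SHR.
    mph_doses = {2: 0.3, 3: 1.0, 4: 3.0}  # D2-D4, mg/kg
    atx_doses = {5: 1.0, 6: 2.0}  # D5-D6
    gain = (1.5, 1.0, 0.8)  # SHR most responsive
    for day, dose in {**mph_doses, **atx_doses}.items():
        for s in range(ns):
            slopes[s, day, ib["Theta"]] += -0.04 * dose * gain[s]
            slopes[s, day, ib["Alpha"]] += +0.02 * dose * gain[s]

    return SyntheticConfig(
        n_animals_per_strain=n_animals_per_strain,
        step_s=step_s,
        duration_s=duration_s,
        strain_offsets=offsets,
        dose_slope_effects=slopes,
        noise_sd=noise_sd,
        spike_rate=spike_rate,
        outlier_curve_rate=outlier_curve_rate,
        seed=seed,
    )


def shr_slope_scenario(
    step_s: float = 0.25,
    duration_s: float = 3600.0,
    n_animals_per_strain: int = 10,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> SyntheticConfig:
    """Strain contrast carried by the *slope* alone.

    SHR loses lDelta and Theta power after the injection on every day
    (the spontaneous drift pattern of the ADHD model); band levels are
    identical across strains, so any mPower-ratio separation is purely
    the time-averaged shadow of the trend.  This isolates the scenario a
    hybrid (mPower + slope) biomarker exists for: signal that a pure
    mPower form cannot see directly.
    """
    bands = BAND_ORDER
    ib = {b: i for i, b in enumerate(bands)}
    slopes = np.zeros((3, 8, len(bands)))
    slopes[0, :, ib["lDelta"]] = -0.20
    slopes[0, :, ib["Theta"]] = -0.05
    return SyntheticConfig(
        n_animals_per_strain=n_animals_per_strain,
        step_s=step_s,
        duration_s=duration_s,
        dose_slope_effects=slopes,
        noise_sd=noise_sd,
        spike_rate=0.002,
        outlier_curve_rate=0.0,
        seed=seed,
    )
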