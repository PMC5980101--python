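"""Spectral band-power extraction for multichannel EEG.

The quantitative-EEG convention used throughout the package splits the
spectrum into nine sub-bands (Total, lDelta, Delta, Theta, Alpha, Beta,
Gamma, High, vHigh) and tracks the power in each band as a time series
sampled on a fixed step (250 ms by default).  Band intervals are half-open
``[f_low, f_high)`` and may overlap (lDelta and Delta share 1-1.5 Hz).

The estimator is a per-step rectangular-window periodogram: each
non-overlapping window of ``step_s`` seconds is transformed once and the
one-sided power spectral density is integrated over the band's bins.  With
``detrend=False`` this satisfies Parseval's identity, so the Total band
power of a window equals the window's mean squared amplitude (up to the
excluded Nyquist bin).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import periodogram

__all__ = [
    "BandDefinition",
    "BandPowerDataset",
    "PAPER_BANDS",
    "BAND_ORDER",
    "LOW_BANDS",
    "compute_band_power",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency interval ``[f_low, f_high)`` in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (0 <= self.f_low < self.f_high):
            raise ValueError(
                f"band {self.name!r}: need 0 <= f_low < f_high, "
                f"got [{self.f_low}, {self.f_high})"
            )


#: The nine standard sub-bands, in canonical order.
PAPER_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("Total", 0.0, 250.0),
    BandDefinition("lDelta", 0.1, 1.5),
    BandDefinition("Delta", 1.0, 4.0),
    BandDefinition("Theta", 4.0, 8.0),
    BandDefinition("Alpha", 8.0, 12.0),
    BandDefinition("Beta", 12.0, 30.0),
    BandDefinition("Gamma", 30.0, 55.0),
    BandDefinition("High", 70.0, 170.0),
    BandDefinition("vHigh", 190.0, 250.0),
)

BAND_ORDER: tuple[str, ...] = tuple(b.name for b in PAPER_BANDS)

#: The low-frequency bands used as biomarker candidates (symbols m, d, th, a, b).
LOW_BANDS: tuple[str, ...] = ("lDelta", "Delta", "Theta", "Alpha", "Beta")


@dataclass
class BandPowerDataset:
    """Band-power array indexed ``[band, time, channel, day, animal, strain]``.

    ``injection_index`` is the time-axis sample at which the agent was
    injected (records of all days are aligned so this is a single index;
    under the default alignment it falls 9 minutes after record start).
    """

    power: np.ndarray
    step_s: float
    injection_index: int
    band_defs: tuple[BandDefinition, ...] = PAPER_BANDS
    strains: tuple[str, ...] = ("SHR", "WKY", "WIS")
    days: tuple[str, ...] = ("D0", "D1", "D2", "D3", "D4", "D5", "D6", "D7")
    channels: tuple[str, ...] = ("LF", "RF", "LP", "RP", "RO")
    animals: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        if self.power.ndim != 6:
            raise ValueError("power must be 6-dimensional [band,time,channel,day,animal,strain]")
        if not self.animals:
            self.animals = tuple(f"A{i}" for i in range(self.power.shape[4]))
        self.validate()

    def validate(self) -> None:
        nb, _, nc, nd, na, ns = self.power.shape
        expect = (len(self.band_defs), nc, nd, na, ns)
        got = (nb, len(self.channels), len(self.days), len(self.animals), len(self.strains))
        if (nb, *expect[1:]) != got:
            raise ValueError(f"axis lengths {self.power.shape} inconsistent with labels {got}")
        if np.isnan(self.power).any():
            raise ValueError("power contains NaNs")
        if (self.power < 0).any():
            idx = tuple(int(i[0]) for i in np.nonzero(self.power < 0))
            raise ValueError(f"negative power at [band,time,channel,day,animal,strain]={idx}")
        if not (0 <= self.injection_index < self.power.shape[1]):
            raise ValueError("injection_index outside the time axis")

    # -- convenience ---------------------------------------------------
    @property
    def band_names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.band_defs)

    def band_index(self, name: str) -> int:
        try:
            return self.band_names.index(name)
        except ValueError:
            raise KeyError(f"unknown band {name!r}; have {self.band_names}") from None

    @property
    def n_time(self) -> int:
        return self.power.shape[1]

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_time) * self.step_s

    def curves(self, band: str, strain: str, day: str) -> np.ndarray:
        """All (channel x animal) curves of one (strain, day, band) group.

        Returns an array of shape (n_channels * n_animals, n_time); channel
        is the fastest-varying curve index.
        """
        b = self.band_index(band)
        s = self.strains.index(strain)
        d = self.days.index(day)
        block = self.power[b, :, :, d, :, s]  # (time, channel, animal)
        return block.transpose(2, 1, 0).reshape(-1, self.n_time)


def compute_band_power(
    eeg: np.ndarray,
    sampling_rate_hz: float,
    band_defs: tuple[BandDefinition, ...] = PAPER_BANDS,
    step_s: float = 0.25,
) -> np.ndarray:
    """Per-band spectral power in non-overlapping ``step_s`` windows.

    Parameters
    ----------
    eeg
        Signal array, shape ``(n_samples,)`` or ``(n_channels, n_samples)``.
    sampling_rate_hz
        Sampling rate; must be at least twice the highest requested band edge.
    band_defs
        Bands to integrate over (half-open intervals).
    step_s
        Window length in seconds; the output time axis has
        ``floor(n_samples / (step_s * fs))`` points.

    Returns
    -------
    ndarray of shape ``(n_bands, n_steps, n_channels)``.
    """
    eeg = np.asarray(eeg, dtype=float)
    if eeg.ndim == 1:
        eeg = eeg[None, :]
    if eeg.ndim != 2:
        raise ValueError("eeg must be 1-D or (n_channels, n_samples)")
    if np.isnan(eeg).any():
        raise ValueError("eeg contains NaNs")
    fs = float(sampling_rate_hz)
    for b in band_defs:
        if b.f_high > fs / 2:
            raise ValueError(
                f"band {b.name!r} upper edge {b.f_high} Hz exceeds Nyquist {fs / 2} Hz"
            )
    spw = int(round(step_s * fs))
    n_ch, n_samp = eeg.shape
    n_steps = n_samp // spw
    if n_steps < 1:
        raise ValueError("signal shorter than one step window")

    segs = eeg[:, : n_steps * spw].reshape(n_ch, n_steps, spw)
    freqs, psd = periodogram(segs, fs=fs, window="boxcar", detrend=False, axis=-1)
    df = freqs[1] - freqs[0] if len(freqs) > 1 else 1.0

    out = np.empty((len(band_defs), n_steps, n_ch))
    for i, b in enumerate(band_defs):
        sel = (freqs >= b.f_low) & (freqs < b.f_high)
        out[i] = (psd[..., sel].sum(axis=-1) * df).T
    return out
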