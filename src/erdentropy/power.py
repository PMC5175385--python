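"""Single-taper FFT power on a 1-Hz grid and baseline-relative percent change.

Power is estimated per trial and channel with a Hann-tapered periodogram in
one-sided density scaling, P(f) = 2 |X_w(f)|^2 / (fs * sum w^2): white noise
gives a flat, unbiased density, and a unit-amplitude sinusoid at a bin
center of a 1-s epoch yields the same value at any sampling rate.  The
default analysis grid runs from 8 to 25 Hz inclusive in 1-Hz steps (18
bins).  Movement power is converted to percent change relative to the
segment-averaged baseline power,

    Pow_rel = 100 * (Pow_move - Pow_baseline) / Pow_baseline,

computed per trial and then averaged across trials per participant.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import periodogram

from .simulate import EpochSet

__all__ = [
    "default_grid",
    "PowerSpectra",
    "BaselineSpectrum",
    "RelativePowerSpectrum",
    "epoch_power",
    "baseline_power",
    "relative_power",
    "average_trials",
    "band_mean",
]


def default_grid() -> np.ndarray:
    """The 8-25 Hz analysis grid in 1-Hz steps: 18 bins, both ends inclusive."""
    return np.arange(8.0, 26.0, 1.0)


def _check_grid(freqs: np.ndarray) -> np.ndarray:
    freqs = np.asarray(freqs, dtype=float)
    if freqs.ndim != 1 or freqs.size < 1:
        raise ValueError("frequency grid must be a non-empty 1-D array")
    if np.any(np.diff(freqs) <= 0):
        raise ValueError("frequency grid must be strictly increasing")
    return freqs


@dataclass
class PowerSpectra:
    """Per-trial, per-channel power at the analysis bins.

    ``values`` has shape (n_trials, n_channels, n_bins), nonnegative.
    """

    values: np.ndarray
    freqs: np.ndarray
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.freqs = _check_grid(self.freqs)
        if self.values.ndim != 3 or self.values.shape[2] != self.freqs.size:
            raise ValueError("values must be (trials, channels, bins)")
        if np.any(self.values < 0):
            raise ValueError("power values must be nonnegative")


@dataclass
class BaselineSpectrum:
    """Channel x bin baseline power, averaged across all baseline sub-windows."""

    values: np.ndarray
    freqs: np.ndarray
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.freqs = _check_grid(self.freqs)
        if self.values.ndim != 2 or self.values.shape[1] != self.freqs.size:
            raise ValueError("values must be (channels, bins)")
        if np.any(self.values <= 0):
            raise ValueError(
                "baseline power must be strictly positive in every bin "
                "(it is the denominator of the percent-change ratio)"
            )


@dataclass
class RelativePowerSpectrum:
    """Percent power change relative to baseline.

    ``level='trial'`` holds (trials, channels, bins); ``level='participant'``
    holds the trial average with shape (channels, bins).
    """

    values: np.ndarray
    freqs: np.ndarray
    channels: tuple[str, ...]
    level: str = "trial"

    def __post_init__(self) -> None:
        self.freqs = _check_grid(self.freqs)
        expected_ndim = {"trial": 3, "participant": 2}
        if self.level not in expected_ndim:
            raise ValueError("level must be 'trial' or 'participant'")
        if self.values.ndim != expected_ndim[self.level]:
            raise ValueError(
                f"level={self.level!r} expects {expected_ndim[self.level]}-D values"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("relative power contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        """Participant-level spectrum as a channels x bins DataFrame."""
        if self.level != "participant":
            raise ValueError("to_frame requires a participant-level spectrum")
        return pd.DataFrame(self.values, index=list(self.channels), columns=self.freqs)

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "channel"
        df.to_csv(path, sep="\t", float_format="%.6g")


def _taper_power(data: np.ndarray, fs: float, freqs: np.ndarray) -> np.ndarray:
    """Hann-tapered one-sided periodogram restricted to ``freqs``.

    ``data`` is (..., n_samples); requested bins must sit on the DFT grid
    of the window length.
    """
    n = data.shape[-1]
    resolution = fs / n
    bins = freqs / resolution
    rounded = np.round(bins)
    if np.max(np.abs(bins - rounded)) > 1e-6:
        off = freqs[np.abs(bins - rounded) > 1e-6]
        raise ValueError(
            f"requested frequencies {off.tolist()} do not sit on the DFT grid "
            f"(resolution {resolution:g} Hz for {n / fs:g}-s windows)"
        )
    f_all, p_all = periodogram(
        data, fs=fs, window="hann", detrend=False, scaling="density", axis=-1
    )
    idx = rounded.astype(int)
    if idx.max() >= f_all.size:
        raise ValueError("requested frequency exceeds the Nyquist frequency")
    return p_all[..., idx]


def epoch_power(epochs: EpochSet, freqs: np.ndarray | None = None) -> PowerSpectra:
    """Per-trial Hann-taper FFT power at the requested bins.

    The epoch must be long enough that the DFT resolution reaches the grid
    (1-s epochs for the default 1-Hz grid) and at least two cycles of the
    lowest bin must fit in the window.
    """
    freqs = _check_grid(default_grid() if freqs is None else freqs)
    duration = epochs.duration_s
    if duration * freqs[0] < 2:
        raise ValueError(
            f"epoch of {duration:g} s holds fewer than 2 cycles of the lowest "
            f"requested bin ({freqs[0]:g} Hz)"
        )
    values = _taper_power(epochs.data, epochs.fs, freqs)
    return PowerSpectra(values=values, freqs=freqs, channels=epochs.montage.labels)


def baseline_power(
    baseline: EpochSet, freqs: np.ndarray | None = None, window_s: float = 1.0
) -> BaselineSpectrum:
    """Baseline power averaged over 1-s sub-windows of every segment.

    Each baseline segment (2 s by convention) is split into non-overlapping
    ``window_s`` sub-windows so the frequency grid matches
    :func:`epoch_power` exactly; power is then averaged across all
    sub-windows of all segments.
    """
    freqs = _check_grid(default_grid() if freqs is None else freqs)
    n_win = round(window_s * baseline.fs)
    n_samples = baseline.data.shape[2]
    if n_samples < n_win:
        raise ValueError(
            f"baseline segments of {n_samples / baseline.fs:g} s are shorter than "
            f"the {window_s:g}-s analysis window"
        )
    n_sub = n_samples // n_win
    trimmed = baseline.data[:, :, : n_sub * n_win]
    n_seg, n_ch = trimmed.shape[:2]
    windows = trimmed.reshape(n_seg, n_ch, n_sub, n_win)
    power = _taper_power(windows, baseline.fs, freqs)  # (seg, ch, sub, bins)
    mean = power.mean(axis=(0, 2))
    if np.any(mean <= 0):
        bad = np.argwhere(mean <= 0)
        raise ValueError(
            f"estimated baseline power is zero at (channel, bin) {bad.tolist()}; "
            "percent change is undefined"
        )
    return BaselineSpectrum(values=mean, freqs=freqs, channels=baseline.montage.labels)


def relative_power(move: PowerSpectra, base: BaselineSpectrum) -> RelativePowerSpectrum:
    """Percent power change per trial: 100 * (move - baseline) / baseline."""
    if move.freqs.shape != base.freqs.shape or np.any(move.freqs != base.freqs):
        raise ValueError("movement and baseline spectra use different frequency grids")
    if move.channels != base.channels:
        raise ValueError("movement and baseline spectra use different channel orders")
    rel = 100.0 * (move.values - base.values[None]) / base.values[None]
    return RelativePowerSpectrum(
        values=rel, freqs=move.freqs, channels=move.channels, level="trial"
    )


def average_trials(rel: RelativePowerSpectrum) -> RelativePowerSpectrum:
    """Average percent change across trials, yielding one spectrum per participant."""
    if rel.level != "trial":
        raise ValueError("average_trials expects a trial-level spectrum")
    if rel.values.shape[0] == 0:
        raise ValueError("cannot average an empty trial set")
    return RelativePowerSpectrum(
        values=rel.values.mean(axis=0),
        freqs=rel.freqs,
        channels=rel.channels,
        level="participant",
    )


def band_mean(rel: RelativePowerSpectrum, band: tuple[float, float]) -> np.ndarray:
    """Mean relative power over the bins in [f_lo, f_hi] inclusive, per channel.

    For a participant-level spectrum returns shape (n_channels,); for a
    trial-level spectrum, (n_trials, n_channels).
    """
    f_lo, f_hi = band
    if f_lo > f_hi:
        raise ValueError("band must satisfy f_lo <= f_hi")
    in_band = (rel.freqs >= f_lo - 1e-9) & (rel.freqs <= f_hi + 1e-9)
    if not np.any(in_band):
        raise ValueError(
            f"band {band} contains no bins of the grid "
            f"[{rel.freqs[0]:g}, {rel.freqs[-1]:g}] Hz"
        )
    if not (rel.freqs[0] <= f_lo and f_hi <= rel.freqs[-1]):
        raise ValueError(f"band {band} extends outside the analysis grid")
    return rel.values[..., in_band].mean(axis=-1)
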