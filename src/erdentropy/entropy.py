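"""Normalized spectral entropy of the relative-power spectrum.

The band-restricted relative-power spectrum is turned into a probability
vector by magnitude normalization,

    p_i = |Pow_rel(i)| / sum_j |Pow_rel(j)|,

and its Shannon entropy is scaled by 1/ln(N) so that H lies in [0, 1]:

    H = -(1 / ln N) * sum_i p_i ln p_i,       0 * ln 0 := 0.

H ~ 1 indicates a flat, broadband spectrum (power change spread evenly
across bins); H ~ 0 a peaked, narrowband one (power change concentrated in
a single bin).  One H is computed per channel from the trial-averaged
(participant-level) spectrum; the bands of interest are the full 8-25 Hz
grid (N = 18) and the 13-19 Hz sub-band (N = 7).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .power import RelativePowerSpectrum

__all__ = ["EntropyMap", "normalize_spectrum", "spectral_entropy", "entropy_map"]


@dataclass
class EntropyMap:
    """Per-channel spectral entropy in a stated band."""

    H: np.ndarray                      # (n_channels,), each in [0, 1]
    band: tuple[float, float]
    n_bins: int
    channels: tuple[str, ...]
    p: np.ndarray | None = None        # optional (n_channels, n_bins) masses

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("entropy needs at least 2 bins")
        if np.any(self.H < -1e-12) or np.any(self.H > 1 + 1e-12):
            raise ValueError("entropy out of [0, 1]")
        self.H = np.clip(self.H, 0.0, 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel": list(self.channels),
                "band": [f"{self.band[0]:g}-{self.band[1]:g}"] * len(self.channels),
                "H": self.H,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def normalize_spectrum(rel_values: np.ndarray) -> np.ndarray:
    """Magnitude-normalize a relative-power vector into a probability vector.

    Signs are discarded: a -50% change carries the same spectral mass as a
    +50% change.  Raises if every bin is zero (the distribution, and hence
    the entropy, is undefined).
    """
    v = np.abs(np.asarray(rel_values, dtype=float))
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need a 1-D vector of at least 2 bins")
    if not np.all(np.isfinite(v)):
        raise ValueError("spectrum contains non-finite values")
    total = v.sum()
    if total == 0:
        raise ValueError("entropy undefined for null spectrum (all bins zero)")
    return v / total


def spectral_entropy(rel_values: np.ndarray) -> float:
    """Normalized Shannon entropy of a relative-power vector, in [0, 1]."""
    p = normalize_spectrum(rel_values)
    nz = p[p > 0]
    h = -np.sum(nz * np.log(nz)) / np.log(p.size)
    return float(np.clip(h, 0.0, 1.0)) + 0.0  # +0.0 normalizes -0.0


def entropy_map(
    rel: RelativePowerSpectrum, band: tuple[float, float] = (8.0, 25.0)
) -> EntropyMap:
    """Per-channel spectral entropy of a participant-level spectrum in ``band``.

    N in the 1/ln(N) normalization is the number of grid bins inside the
    band, endpoints inclusive (18 for 8-25 Hz, 7 for 13-19 Hz on the
    default grid).
    """
    if rel.level != "participant":
        raise ValueError(
            "entropy is computed on the trial-averaged participant-level "
            "spectrum; average trials first"
        )
    f_lo, f_hi = band
    in_band = (rel.freqs >= f_lo - 1e-9) & (rel.freqs <= f_hi + 1e-9)
    n_bins = int(in_band.sum())
    if n_bins < 2:
        raise ValueError(f"band {band} covers {n_bins} grid bin(s); need >= 2")
    sub = rel.values[:, in_band]
    masses = np.stack([normalize_spectrum(row) for row in sub])
    H = np.array([spectral_entropy(row) for row in sub])
    return EntropyMap(H=H, band=band, n_bins=n_bins, channels=rel.channels, p=masses)
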