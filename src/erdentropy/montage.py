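"""Sensor montages for the 10-10 electrode placement system.

Two presets are provided: a full 63-channel layout matching a standard
10-10 EEG cap, and a reduced 16-channel layout for fast desk-scale runs.
Both include the left (contralateral-to-right-hand) sensorimotor region
of interest FC3/C3/CP3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Montage", "build_montage", "MONTAGE_PRESETS"]

#: Default left-sensorimotor region of interest (right-hand movements).
DEFAULT_ROI = ("FC3", "C3", "CP3")

# Standard 63-channel 10-10 cap (actiCAP-style layout, Cz recorded).
_FULL63 = [
    "Fp1", "Fp2",
    "AF7", "AF3", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT9", "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8", "FT10",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
]

# Reduced cap: contralateral SM (FC3/C3/CP3), ipsilateral SM (FC4/C4/CP4),
# frontal, midline and occipital coverage.
_TOY16 = [
    "Fp1", "Fp2",
    "F3", "Fz", "F4",
    "FC3", "FC4",
    "C3", "Cz", "C4",
    "CP3", "CP4",
    "P3", "Pz", "P4",
    "Oz",
]

MONTAGE_PRESETS = {"full63": _FULL63, "toy16": _TOY16}


@dataclass(frozen=True)
class Montage:
    """An ordered set of scalp channels with schematic 2-D positions.

    Parameters
    ----------
    labels : tuple of str
        Unique channel names in fixed order; this order defines the channel
        axis of every epoch array downstream.
    layout : ndarray, shape (n_channels, 2)
        2-D head-schematic coordinates (arbitrary units) for topographic
        reporting.
    roi_contralateral_sm : tuple of str
        Channels covering the left sensorimotor cortex, used for the
        region-of-interest per-bin analysis.
    """

    labels: tuple[str, ...]
    layout: np.ndarray = field(repr=False)
    roi_contralateral_sm: tuple[str, ...] = DEFAULT_ROI

    def __post_init__(self) -> None:
        if len(self.labels) == 0:
            raise ValueError("montage must have at least one channel")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("montage labels must be unique")
        if self.layout.shape != (len(self.labels), 2):
            raise ValueError(
                f"layout must be (n_channels, 2); got {self.layout.shape} "
                f"for {len(self.labels)} labels"
            )
        missing = set(self.roi_contralateral_sm) - set(self.labels)
        if missing:
            raise ValueError(f"ROI channels not in montage: {sorted(missing)}")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        """Position of ``label`` on the channel axis."""
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None

    def indices(self, labels) -> np.ndarray:
        return np.array([self.index(c) for c in labels], dtype=int)


def _standard_positions(labels: list[str]) -> np.ndarray:
    """2-D positions from the MNE standard 10-05 montage (azimuthal projection)."""
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        try:  # montage renamed in newer MNE releases
            std = mne.channels.make_standard_montage("colin27_1005")
        except ValueError:
            std = mne.channels.make_standard_montage("standard_1005")
    pos3d = std.get_positions()["ch_pos"]
    out = np.empty((len(labels), 2))
    for i, name in enumerate(labels):
        x, y, z = pos3d[name]
        # simple stereographic-like flattening: scale xy by polar angle
        r = np.hypot(x, y)
        theta = np.arctan2(r, z)
        scale = theta / r if r > 1e-9 else 0.0
        out[i] = (x * scale, y * scale)
    return out


def build_montage(preset: str = "toy16") -> Montage:
    """Build a named montage preset.

    Parameters
    ----------
    preset : {"full63", "toy16"}
        ``full63`` is the standard 63-channel 10-10 cap; ``toy16`` is a
        16-channel reduced cap for fast tests and examples.

    Returns
    -------
    Montage

    Raises
    ------
    ValueError
        If ``preset`` is not a known name.
    """
    if preset not in MONTAGE_PRESETS:
        raise ValueError(
            f"unknown montage preset {preset!r}; valid presets: "
            f"{sorted(MONTAGE_PRESETS)}"
        )
    labels = MONTAGE_PRESETS[preset]
    return Montage(labels=tuple(labels), layout=_standard_positions(labels))
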