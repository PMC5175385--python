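"""EDF export/import for epoch sets.

Writing uses a small built-in EDF writer (16-bit, one data record per
epoch); reading goes through MNE's EDF reader.  EDF stores samples as
16-bit integers scaled between per-signal physical extrema, so a
write/read round trip is lossy at the level of the quantization step
(physical range / 2^16).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from .montage import DEFAULT_ROI, Montage
from .simulate import EpochSet

__all__ = ["export_edf", "import_edf"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _fixed(value: str, width: int) -> bytes:
    b = value.encode("ascii", errors="replace")
    if len(b) > width:
        b = b[:width]
    return b.ljust(width)


def _fmt_float(x: float, width: int = 8) -> str:
    for fmt in (f"%.{width - 2}g", "%.4g", "%.3g", "%.2g"):
        s = fmt % x
        if len(s) <= width:
            return s
    return ("%g" % x)[:width]


def export_edf(epochs: EpochSet, path: str | Path) -> None:
    """Write an EpochSet to an EDF file, one data record per epoch.

    Channels become EDF signals; the record duration equals the epoch
    duration.  Per-signal physical extrema are taken from the data, so
    amplitudes survive the round trip to within one 16-bit quantization
    step.
    """
    path = Path(path)
    data = epochs.data
    n_epochs, n_ch, n_samp = data.shape
    duration = n_samp / epochs.fs

    phys_min = data.min(axis=(0, 2))
    phys_max = data.max(axis=(0, 2))
    # avoid a zero physical range (flat signal)
    flat = phys_max - phys_min <= 0
    phys_max = np.where(flat, phys_min + 1.0, phys_max)

    gain = (_DIG_MAX - _DIG_MIN) / (phys_max - phys_min)
    digital = np.clip(
        np.round((data - phys_min[None, :, None]) * gain[None, :, None]) + _DIG_MIN,
        _DIG_MIN,
        _DIG_MAX,
    ).astype("<i2")

    header_bytes = 256 + 256 * n_ch
    head = b"".join(
        [
            _fixed("0", 8),
            _fixed(f"X X X {epochs.participant_id or 'X'}", 80),
            _fixed(f"Startdate X X X X {epochs.state}", 80),
            _fixed("01.01.00", 8),
            _fixed("00.00.00", 8),
            _fixed(str(header_bytes), 8),
            _fixed("", 44),
            _fixed(str(n_epochs), 8),
            _fixed(_fmt_float(duration), 8),
            _fixed(str(n_ch), 4),
        ]
    )
    labels = [str(c) for c in epochs.montage.labels]
    sig = b"".join(
        [
            b"".join(_fixed(lab, 16) for lab in labels),
            b"".join(_fixed("", 80) for _ in labels),
            b"".join(_fixed("uV", 8) for _ in labels),
            b"".join(_fixed(_fmt_float(v), 8) for v in phys_min),
            b"".join(_fixed(_fmt_float(v), 8) for v in phys_max),
            b"".join(_fixed(str(_DIG_MIN), 8) for _ in labels),
            b"".join(_fixed(str(_DIG_MAX), 8) for _ in labels),
            b"".join(_fixed("", 80) for _ in labels),
            b"".join(_fixed(str(n_samp), 8) for _ in labels),
            b"".join(_fixed("", 32) for _ in labels),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(head + sig)
        # records: epoch-major, signal-major within record
        fh.write(np.ascontiguousarray(digital).tobytes())


def _fallback_layout(labels: list[str]) -> np.ndarray:
    angles = np.linspace(0, 2 * np.pi, len(labels), endpoint=False)
    return np.column_stack([np.cos(angles), np.sin(angles)])


def _montage_from_labels(labels: list[str]) -> Montage:
    from .montage import _standard_positions

    try:
        layout = _standard_positions(labels)
    except KeyError:
        layout = _fallback_layout(labels)
    roi = tuple(c for c in DEFAULT_ROI if c in labels)
    if len(roi) < len(DEFAULT_ROI):
        warnings.warn(
            "imported recording lacks the FC3/C3/CP3 sensorimotor ROI; "
            "ROI-based analyses are disabled",
            UserWarning,
            stacklevel=3,
        )
    return Montage(labels=tuple(labels), layout=layout, roi_contralateral_sm=roi)


def import_edf(
    path: str | Path,
    state: str = "movement",
    epoch_len_s: float | None = None,
    expected_fs: float | None = None,
) -> EpochSet:
    """Read an EDF file and segment it into equal-length epochs.

    The continuous recording is cut into non-overlapping windows of
    ``epoch_len_s`` (default: 1 s for movement, 2 s for baseline, the
    study's segmentation conventions).  If ``expected_fs`` is given and the
    file's sampling rate differs, an error is raised.  A missing FC3/C3/CP3
    region of interest produces a warning and an empty ROI.
    """
    import mne

    if state not in ("movement", "baseline"):
        raise ValueError("state must be 'movement' or 'baseline'")
    if epoch_len_s is None:
        epoch_len_s = 1.0 if state == "movement" else 2.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    if expected_fs is not None and abs(fs - expected_fs) > 1e-6:
        raise ValueError(f"EDF sampling rate {fs:g} Hz != expected {expected_fs:g} Hz")
    n_win = round(epoch_len_s * fs)
    signal = raw.get_data()  # (channels, samples), in Volts for EEG channels
    n_epochs = signal.shape[1] // n_win
    if n_epochs == 0:
        raise ValueError(
            f"recording shorter than one {epoch_len_s:g}-s epoch at {fs:g} Hz"
        )
    # MNE returns EEG channels in Volts; our epoch arrays are in µV units
    signal = signal * 1e6
    trimmed = signal[:, : n_epochs * n_win]
    data = trimmed.reshape(signal.shape[0], n_epochs, n_win).transpose(1, 0, 2)
    montage = _montage_from_labels(list(raw.ch_names))
    return EpochSet(
        data=np.ascontiguousarray(data),
        fs=fs,
        montage=montage,
        state=state,
    )
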