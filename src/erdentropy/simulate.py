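"""Synthetic multichannel EEG with movement-related desynchronization.

Generates seeded, artifact-free recordings whose spectral content is under
exact analytic control, so the downstream power/entropy/statistics stages
can be validated without any real data.  The signal model is a stationary
Gaussian process synthesized in the frequency domain: each epoch's rFFT
coefficients are drawn as independent complex normals scaled so that the
expected one-sided power spectral density equals

    S(ch, f) = background(f) + sum_k bump_k(f) * (1 - d_k 1[movement]) * 1[ch in k]

where ``background`` is 1/f^beta colored noise and each oscillatory
component ``k`` contributes a spectral bump (Gaussian or flat) on its
affected channels.  During movement the oscillatory power is scaled by
(1 - d), i.e. amplitude by sqrt(1 - d), which makes the configured depth
``d`` exactly the expected fractional power decrease at the component bin.

Two group presets emulate the study conditions: young participants show
deep, narrowband power decreases near 10 and 20 Hz confined to the left
sensorimotor channels; elderly participants show a shallower but broadband
(8-25 Hz) decrease over a wider set of channels including frontal and
ipsilateral sensorimotor sites.  Task structure only modulates the young
preset (the elderly response is task-invariant).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .montage import DEFAULT_ROI, Montage, build_montage

__all__ = [
    "OscComponent",
    "ModulationProfile",
    "SimConfig",
    "EpochSet",
    "Participant",
    "StudyDataset",
    "young_profile",
    "elderly_profile",
    "default_profiles",
    "expected_epoch_power",
    "simulate_epochs",
    "simulate_study",
    "reject_epochs_by_amplitude",
    "save_study",
    "load_study",
]

GROUPS = ("elderly", "young")
DEFAULT_TASKS = ("finger_sequence", "pinch_grip", "whole_hand_grip")

# Channel sets used by the group presets.
_SM_CONTRA = DEFAULT_ROI                      # FC3, C3, CP3
_SM_IPSI = ("FC4", "C4", "CP4")
_FRONTAL = ("Fp1", "Fp2", "F3", "Fz", "F4")
_WIDE_ELDERLY = _SM_CONTRA + _SM_IPSI + _FRONTAL + ("Cz",)


@dataclass(frozen=True)
class OscComponent:
    """One oscillatory component of the signal model.

    Parameters
    ----------
    center_hz : float
        Center frequency of the spectral bump.
    bandwidth_hz : float
        Full width at half maximum for ``shape="gaussian"``; full width of
        the flat top for ``shape="boxcar"``.
    amplitude : float
        Peak one-sided PSD of the component at baseline (power units/Hz).
    channels : tuple of str
        Channels carrying the component.
    depth : float
        Movement-related desynchronization depth d in [0, 1): baseline
        component PSD is multiplied by (1 - d) during movement.
    shape : {"gaussian", "boxcar"}
    """

    center_hz: float
    bandwidth_hz: float
    amplitude: float
    channels: tuple[str, ...]          # ("*",) targets every montage channel
    depth: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if not (0.0 <= self.depth < 1.0):
            raise ValueError(
                f"desynchronization depth must satisfy 0 <= d < 1, got {self.depth}"
            )
        if self.shape not in ("gaussian", "boxcar"):
            raise ValueError(f"unknown component shape {self.shape!r}")
        if self.amplitude < 0 or self.bandwidth_hz <= 0:
            raise ValueError("amplitude must be >= 0 and bandwidth > 0")

    def psd(self, freqs: np.ndarray, state: str) -> np.ndarray:
        """One-sided PSD contribution of this component at ``freqs``."""
        if self.shape == "gaussian":
            sigma = self.bandwidth_hz / (2.0 * np.sqrt(2.0 * np.log(2.0)))
            env = np.exp(-0.5 * ((freqs - self.center_hz) / sigma) ** 2)
        else:  # boxcar
            half = self.bandwidth_hz / 2.0
            env = (
                (freqs >= self.center_hz - half) & (freqs <= self.center_hz + half)
            ).astype(float)
        scale = (1.0 - self.depth) if state == "movement" else 1.0
        return self.amplitude * scale * env


@dataclass(frozen=True)
class ModulationProfile:
    """Per-channel, per-frequency desynchronization profile of one condition."""

    components: tuple[OscComponent, ...]
    noise_scale: float = 1.0

    def scaled_depths(self, factor: float) -> "ModulationProfile":
        """Return a copy with every component depth multiplied by ``factor``.

        Depths are truncated to [0, 0.95] to keep movement power positive.
        """
        comps = tuple(
            replace(c, depth=float(np.clip(c.depth * factor, 0.0, 0.95)))
            for c in self.components
        )
        return replace(self, components=comps)

    def target_psd(
        self, montage: Montage, freqs: np.ndarray, state: str, noise_exponent: float
    ) -> np.ndarray:
        """Expected one-sided PSD, shape (n_channels, n_freqs).

        The background term is noise_scale^2 / f^beta (zero at f = 0).
        """
        n_ch = montage.n_channels
        psd = np.zeros((n_ch, freqs.size))
        with np.errstate(divide="ignore"):
            bg = np.where(freqs > 0, self.noise_scale**2 / freqs**noise_exponent, 0.0)
        psd += bg[None, :]
        for comp in self.components:
            if comp.channels == ("*",):
                idx = np.arange(n_ch)
            else:
                idx = montage.indices(comp.channels)
            psd[idx] += comp.psd(freqs, state)[None, :]
        return psd


# Non-modulated broadband oscillatory floor on every channel.  Real EEG has
# substantial band power everywhere; without this floor, component tails
# dominate the weak 1/f background and narrowband responses look broadband.
_SPECTRAL_FLOOR = OscComponent(16.5, 17.0, 2.0, ("*",), 0.0, shape="boxcar")
# Non-modulated posterior resting alpha.
_POSTERIOR_ALPHA = OscComponent(10.0, 3.0, 10.0, ("Oz",), 0.0)


def young_profile(task: str | None = None) -> ModulationProfile:
    """Narrowband preset: deep alpha/beta decreases on left sensorimotor channels.

    The young response is task-dependent: the overlearned finger sequence
    drives deep, sharply tuned 10/20 Hz desynchronization, while the two
    grip tasks produce a shallower and spectrally broader beta response.
    """
    if task in (None, "finger_sequence"):
        beta = OscComponent(20.0, 1.5, 12.0, _SM_CONTRA, 0.65)
        alpha_d = 0.75
    else:  # pinch / whole-hand grip: broader, band-centered low-beta response
        beta = OscComponent(16.5, 6.0, 12.0, _SM_CONTRA, 0.5)
        alpha_d = 0.55
    return ModulationProfile(
        components=(
            OscComponent(10.0, 1.5, 24.0, _SM_CONTRA, alpha_d),
            beta,
            _SPECTRAL_FLOOR,
            _POSTERIOR_ALPHA,
        ),
        noise_scale=1.0,
    )


def elderly_profile(task: str | None = None) -> ModulationProfile:
    """Broadband preset: shallow flat 8-25 Hz decrease over a wide channel set."""
    del task  # elderly response is task-invariant
    return ModulationProfile(
        components=(
            OscComponent(16.5, 17.0, 14.0, _WIDE_ELDERLY, 0.35, shape="boxcar"),
            _SPECTRAL_FLOOR,
            _POSTERIOR_ALPHA,
        ),
        noise_scale=1.0,
    )


def default_profiles(group: str, task: str | None = None) -> ModulationProfile:
    """Group/task preset lookup used by :func:`simulate_study` defaults."""
    if group == "young":
        return young_profile(task)
    if group == "elderly":
        return elderly_profile(task)
    raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")


@dataclass(frozen=True)
class SimConfig:
    """Study-level simulation parameters.

    Defaults reflect a grip-task-scale study: 16 participants per group,
    three motor tasks, 60 one-second movement epochs per task, a pooled
    2.5-minute baseline cut into 2-second segments, 1000 Hz sampling and
    1/f background noise.
    """

    n_per_group: int = 16
    tasks: tuple[str, ...] = DEFAULT_TASKS
    trials_per_task: int = 60
    fs: float = 1000.0
    epoch_len_s: float = 1.0
    baseline_len_s: float = 2.0
    n_baseline_segments: int = 75
    noise_exponent: float = 1.0
    between_subject_sd: float = 0.15
    seed: int = 0
    montage_preset: str = "toy16"
    common_average: bool = True
    max_analysis_hz: float = 25.0

    def __post_init__(self) -> None:
        if self.n_per_group < 1 or self.trials_per_task < 1:
            raise ValueError("n_per_group and trials_per_task must be >= 1")
        if min(self.epoch_len_s, self.baseline_len_s) <= 0 or self.fs <= 0:
            raise ValueError("durations and sampling rate must be positive")
        n = self.fs * self.epoch_len_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("fs * epoch_len_s must be an integer sample count")
        if n < 2 * self.max_analysis_hz:
            raise ValueError(
                "epoch too short for the requested analysis band: need "
                f"fs*epoch_len_s >= {2 * self.max_analysis_hz}"
            )


@dataclass
class EpochSet:
    """A stack of equal-length epochs from one participant and condition.

    ``data`` has shape (n_epochs, n_channels, n_samples); the channel axis
    follows ``montage.labels``.
    """

    data: np.ndarray
    fs: float
    montage: Montage
    state: str
    participant_id: str = ""
    group: str = ""
    task: str = ""

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("EpochSet data must be (epochs, channels, samples)")
        if self.data.shape[1] != self.montage.n_channels:
            raise ValueError(
                f"channel axis {self.data.shape[1]} does not match montage "
                f"({self.montage.n_channels} channels)"
            )
        if self.state not in ("movement", "baseline"):
            raise ValueError("state must be 'movement' or 'baseline'")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EpochSet contains non-finite values")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.data.shape[2] / self.fs


@dataclass
class Participant:
    participant_id: str
    group: str
    movement: dict[str, EpochSet]      # task -> movement epochs
    baseline: EpochSet


@dataclass
class StudyDataset:
    participants: list[Participant]
    config: SimConfig
    montage: Montage

    def __post_init__(self) -> None:
        for p in self.participants:
            if p.group not in GROUPS:
                raise ValueError(f"group label {p.group!r} not in {GROUPS}")
            if not p.movement:
                raise ValueError(f"participant {p.participant_id} has no movement data")


def expected_epoch_power(
    profile: ModulationProfile,
    montage: Montage,
    freqs: np.ndarray,
    state: str,
    fs: float,
    duration_s: float,
    noise_exponent: float = 1.0,
    common_average: bool = True,
    window_s: float | None = None,
) -> np.ndarray:
    """Exact expectation of the Hann-taper power estimate on simulated epochs.

    Because channels are synthesized independently with a known one-sided
    PSD, the expected Hann periodogram is available in closed form: the
    common average reference mixes channel PSDs as
    (1-1/M)^2 S_c + (1/M^2) sum_{j!=c} S_j, and the taper smears the target
    across bins.  When the analysis window equals the synthesis length
    (``window_s`` omitted) the smearing is the periodic-Hann kernel
    (1/6, 2/3, 1/6) on the shared DFT grid; for a shorter window (baseline
    segments analyzed in 1-s sub-windows) the full quadratic-form kernel
    between the two grids is evaluated.  Returns (n_channels, len(freqs)).
    """
    n_synth = round(duration_s * fs)
    grid = np.fft.rfftfreq(n_synth, d=1.0 / fs)
    psd = profile.target_psd(montage, grid, state, noise_exponent)
    # synthesis zeroes DC and Nyquist coefficients
    psd[:, 0] = 0.0
    if n_synth % 2 == 0:
        psd[:, -1] = 0.0
    if common_average:
        m = montage.n_channels
        total = psd.sum(axis=0, keepdims=True)
        psd = (1.0 - 1.0 / m) ** 2 * psd + (total - psd) / m**2

    freqs = np.asarray(freqs, dtype=float)
    if window_s is None or round(window_s * fs) == n_synth:
        smoothed = (
            2.0 / 3.0 * psd
            + 1.0 / 6.0 * np.roll(psd, 1, axis=1)
            + 1.0 / 6.0 * np.roll(psd, -1, axis=1)
        )
        resolution = fs / n_synth
        idx = np.round(freqs / resolution).astype(int)
        if np.max(np.abs(freqs - idx * resolution)) > 1e-6:
            raise ValueError("requested frequencies do not sit on the DFT grid")
        return smoothed[:, idx]

    # General path: window of n_win samples cut from an n_synth-sample
    # realization.  E P(k) = sum_m S_m (|G+_m(k)|^2 + |G-_m(k)|^2) / (N2 * sum w^2)
    # with G+-_m(k) the windowed-DFT response to the synthesis exponentials.
    n_win = round(window_s * fs)
    resolution = fs / n_win
    idx = np.round(freqs / resolution).astype(int)
    if np.max(np.abs(freqs - idx * resolution)) > 1e-6:
        raise ValueError("requested frequencies do not sit on the window DFT grid")
    n = np.arange(n_win)
    w = 0.5 - 0.5 * np.cos(2.0 * np.pi * n / n_win)
    m = np.arange(grid.size)
    basis = w[:, None] * np.exp(2j * np.pi * n[:, None] * m[None, :] / n_synth)
    F = np.fft.fft(basis, axis=0)          # F[k, m] = G+_m(k)
    gp2 = np.abs(F[idx, :]) ** 2
    gm2 = np.abs(F[(-idx) % n_win, :]) ** 2
    kernel = (gp2 + gm2) / (n_synth * np.sum(w**2))
    return psd @ kernel.T


def _synth_psd_epochs(
    psd: np.ndarray, n_epochs: int, n_samples: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw epochs of a Gaussian process with one-sided PSD ``psd``.

    ``psd`` has shape (n_channels, n_rfft_bins).  rFFT coefficients are
    complex normal with E|X_k|^2 = S_k * fs * N / 2, which makes the
    expected periodogram (density scaling) equal S.  DC and Nyquist are
    set to zero (the analysis band never touches them).
    """
    n_bins = n_samples // 2 + 1
    n_ch = psd.shape[0]
    scale = np.sqrt(np.maximum(psd, 0.0) * fs * n_samples / 4.0)
    re = rng.standard_normal((n_epochs, n_ch, n_bins))
    im = rng.standard_normal((n_epochs, n_ch, n_bins))
    coeffs = scale[None] * (re + 1j * im)
    coeffs[..., 0] = 0.0
    if n_samples % 2 == 0:
        coeffs[..., -1] = 0.0
    return np.fft.irfft(coeffs, n=n_samples, axis=-1)


def simulate_epochs(
    profile: ModulationProfile,
    montage: Montage,
    state: str,
    n_epochs: int,
    duration_s: float,
    fs: float,
    noise_exponent: float = 1.0,
    seed: int | np.random.SeedSequence = 0,
    common_average: bool = True,
) -> EpochSet:
    """Simulate one stack of movement epochs or baseline segments.

    Each epoch is an independent realization of 1/f^beta background plus
    the profile's oscillatory components; during movement the component
    PSD is scaled by (1 - depth).  Identical inputs reproduce identical
    output bit for bit.

    Parameters
    ----------
    state : {"movement", "baseline"}
    seed : int or numpy SeedSequence
        Source of randomness; an integer is wrapped in a SeedSequence.
    common_average : bool
        Apply a common average reference as the final step (default), as
        done to the recordings the analysis stage expects.
    """
    n_samples = round(duration_s * fs)
    if abs(n_samples - duration_s * fs) > 1e-9:
        raise ValueError("duration_s * fs must be an integer sample count")
    if state not in ("movement", "baseline"):
        raise ValueError("state must be 'movement' or 'baseline'")
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    psd = profile.target_psd(montage, freqs, state, noise_exponent)
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(seq)
    data = _synth_psd_epochs(psd, n_epochs, n_samples, fs, rng)
    if common_average:
        data = data - data.mean(axis=1, keepdims=True)
    return EpochSet(data=data, fs=fs, montage=montage, state=state)


def _participant_seed(master: int, index: int, purpose: str) -> np.random.SeedSequence:
    """Deterministic sub-seed: master seed + participant counter + stream tag.

    The spawn key encodes the participant index and a small integer per
    purpose ('jitter', 'baseline', or a task index), so regeneration of any
    participant is independent of generation order.
    """
    tags = {"jitter": 0, "baseline": 1}
    tag = tags.get(purpose)
    if tag is None:
        tag = 2 + int(purpose)
    return np.random.SeedSequence(entropy=master, spawn_key=(index, tag))


def simulate_study(
    config: SimConfig,
    profiles=default_profiles,
) -> StudyDataset:
    """Simulate a full two-group, multi-task study.

    Per-participant desynchronization depths are jittered multiplicatively
    (``1 + between_subject_sd * z``, truncated so d stays in [0, 0.95]);
    sub-seeds are derived deterministically from ``config.seed`` so the
    dataset is reproducible bit for bit.

    Parameters
    ----------
    profiles : callable(group, task) -> ModulationProfile
        Condition presets; defaults to the young/elderly study presets.
    """
    montage = build_montage(config.montage_preset)
    participants: list[Participant] = []
    counter = 0
    for group in GROUPS:
        for i in range(config.n_per_group):
            pid = f"{group[0]}{i + 1:02d}"
            jit_rng = np.random.default_rng(_participant_seed(config.seed, counter, "jitter"))
            factor = 1.0 + config.between_subject_sd * jit_rng.standard_normal()
            factor = max(factor, 0.0)
            movement: dict[str, EpochSet] = {}
            for t_idx, task in enumerate(config.tasks):
                prof = profiles(group, task).scaled_depths(factor)
                es = simulate_epochs(
                    prof,
                    montage,
                    "movement",
                    config.trials_per_task,
                    config.epoch_len_s,
                    config.fs,
                    config.noise_exponent,
                    seed=_participant_seed(config.seed, counter, str(t_idx)),
                    common_average=config.common_average,
                )
                es.participant_id, es.group, es.task = pid, group, task
                movement[task] = es
            base_prof = profiles(group, None).scaled_depths(factor)
            baseline = simulate_epochs(
                base_prof,
                montage,
                "baseline",
                config.n_baseline_segments,
                config.baseline_len_s,
                config.fs,
                config.noise_exponent,
                seed=_participant_seed(config.seed, counter, "baseline"),
                common_average=config.common_average,
            )
            baseline.participant_id, baseline.group = pid, group
            participants.append(Participant(pid, group, movement, baseline))
            counter += 1
    return StudyDataset(participants=participants, config=config, montage=montage)


def reject_epochs_by_amplitude(epochs: EpochSet, threshold: float) -> EpochSet:
    """Drop epochs whose peak absolute amplitude exceeds ``threshold``.

    Synthetic data is artifact-free, so this is off by default everywhere;
    it exists for imported recordings.
    """
    keep = np.abs(epochs.data).max(axis=(1, 2)) <= threshold
    if not keep.any():
        raise ValueError("amplitude threshold rejected every epoch")
    out = EpochSet(
        data=epochs.data[keep],
        fs=epochs.fs,
        montage=epochs.montage,
        state=epochs.state,
        participant_id=epochs.participant_id,
        group=epochs.group,
        task=epochs.task,
    )
    return out


# ---------------------------------------------------------------------------
# Disk round-trip: one .npy per EpochSet plus a JSON sidecar.

def _write_epochset(es: EpochSet, path: Path) -> None:
    np.save(path.with_suffix(".npy"), es.data)
    meta = {
        "fs": es.fs,
        "labels": list(es.montage.labels),
        "roi": list(es.montage.roi_contralateral_sm),
        "state": es.state,
        "participant_id": es.participant_id,
        "group": es.group,
        "task": es.task,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def _read_epochset(path: Path, montage: Montage) -> EpochSet:
    meta = json.loads(path.with_suffix(".json").read_text())
    if list(montage.labels) != meta["labels"]:
        raise ValueError(f"channel labels in {path} do not match the study montage")
    return EpochSet(
        data=np.load(path.with_suffix(".npy")),
        fs=meta["fs"],
        montage=montage,
        state=meta["state"],
        participant_id=meta["participant_id"],
        group=meta["group"],
        task=meta["task"],
    )


def save_study(study: StudyDataset, directory: str | Path) -> None:
    """Write a StudyDataset as a directory of array files with JSON sidecars."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(study.config).items()
        },
        "participants": [],
    }
    for p in study.participants:
        entry = {"id": p.participant_id, "group": p.group, "tasks": list(p.movement)}
        _write_epochset(p.baseline, directory / f"{p.participant_id}_baseline")
        for task, es in p.movement.items():
            _write_epochset(es, directory / f"{p.participant_id}_{task}")
        manifest["participants"].append(entry)
    (directory / "study.json").write_text(json.dumps(manifest, indent=1))


def load_study(directory: str | Path) -> StudyDataset:
    """Read a StudyDataset written by :func:`save_study`."""
    directory = Path(directory)
    manifest = json.loads((directory / "study.json").read_text())
    cfg_dict = dict(manifest["config"])
    cfg_dict["tasks"] = tuple(cfg_dict["tasks"])
    config = SimConfig(**cfg_dict)
    montage = build_montage(config.montage_preset)
    participants = []
    for entry in manifest["participants"]:
        pid = entry["id"]
        baseline = _read_epochset(directory / f"{pid}_baseline", montage)
        movement = {
            task: _read_epochset(directory / f"{pid}_{task}", montage)
            for task in entry["tasks"]
        }
        participants.append(Participant(pid, entry["group"], movement, baseline))
    return StudyDataset(participants=participants, config=config, montage=montage)
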