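"""End-to-end orchestration: simulate -> power -> entropy -> statistics.

``run_pipeline`` drives the full sensor-level analysis on a simulated
study and writes every result as TSV plus a JSON run manifest; identical
configurations reproduce identical output bytes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .entropy import entropy_map
from .power import average_trials, band_mean, baseline_power, epoch_power, relative_power
from .simulate import SimConfig, StudyDataset, simulate_study
from .stats import (
    binwise_roi_test,
    channelwise_group_test,
    group_effect_map,
    metric_table,
    posthoc_task_contrasts,
)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "load_config",
    "participant_spectra",
    "build_metric_tables",
    "run_pipeline",
]

logger = logging.getLogger("erdentropy")

#: Which two-group test each metric gets in the per-task channel maps:
#: relative power is treated as normally distributed (Student t), entropy
#: as non-normal (Wilcoxon rank-sum).
METRIC_TESTS = {"relative_power": "student_t", "entropy": "wilcoxon"}


class PipelineError(RuntimeError):
    """An analysis stage failed; the message names the stage and entity."""


@dataclass(frozen=True)
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    bands: tuple[tuple[float, float], ...] = ((8.0, 25.0), (13.0, 19.0))
    alpha: float = 0.05
    inference: str = "lrt"
    posthoc_metrics: tuple[str, ...] = ("entropy",)
    write_plots: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        for lo, hi in self.bands:
            if not (8.0 <= lo <= hi <= 25.0):
                raise ValueError(f"band ({lo}, {hi}) outside the 8-25 Hz grid")


def load_config(path: str | Path, seed: int | None = None) -> PipelineConfig:
    """Read a pipeline configuration from YAML or JSON.

    The file holds a mapping with optional keys ``sim`` (SimConfig fields),
    ``bands``, ``alpha``, ``inference``, ``posthoc_metrics``,
    ``write_plots``.  ``seed`` overrides the simulation seed.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    sim_kwargs = dict(raw.get("sim", {}))
    if "tasks" in sim_kwargs:
        sim_kwargs["tasks"] = tuple(sim_kwargs["tasks"])
    if seed is not None:
        sim_kwargs["seed"] = seed
    kwargs: dict = {"sim": SimConfig(**sim_kwargs)}
    if "bands" in raw:
        kwargs["bands"] = tuple(tuple(float(f) for f in b) for b in raw["bands"])
    for key in ("alpha", "inference"):
        if key in raw:
            kwargs[key] = raw[key]
    if "posthoc_metrics" in raw:
        kwargs["posthoc_metrics"] = tuple(raw["posthoc_metrics"])
    if "write_plots" in raw:
        kwargs["write_plots"] = bool(raw["write_plots"])
    return PipelineConfig(**kwargs)


def _stage(name: str):
    """Decorator: re-raise stage failures with the stage name attached."""

    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as err:
                logger.error("stage %s failed: %s", name, err)
                raise PipelineError(f"stage {name!r} failed: {err}") from err

        return inner

    return wrap


@_stage("spectra")
def participant_spectra(study: StudyDataset):
    """Participant-level relative-power spectra for every task.

    Returns ``{(participant_id, task): RelativePowerSpectrum}`` where each
    spectrum is the trial average of per-trial percent power change against
    that participant's segment-averaged baseline.
    """
    out = {}
    for p in study.participants:
        base = baseline_power(p.baseline)
        for task, epochs in p.movement.items():
            rel = relative_power(epoch_power(epochs), base)
            out[(p.participant_id, task)] = average_trials(rel)
    return out


@_stage("metrics")
def build_metric_tables(study: StudyDataset, spectra, bands):
    """Long-format metric tables per band, plus the per-bin ROI table.

    For each band: per channel, the band-mean relative power and the
    spectral entropy of the band-restricted spectrum.  The ROI bin table
    holds per-bin relative power at the left-sensorimotor channels.
    """
    groups = {p.participant_id: p.group for p in study.participants}
    tables = {}
    for band in bands:
        rows = []
        for (pid, task), rel in spectra.items():
            bm = band_mean(rel, band)
            ent = entropy_map(rel, band)
            for ci, ch in enumerate(rel.channels):
                rows.append((pid, groups[pid], task, ch, "relative_power", bm[ci]))
                rows.append((pid, groups[pid], task, ch, "entropy", ent.H[ci]))
        tables[band] = metric_table(rows)

    roi = study.montage.roi_contralateral_sm
    bin_rows = []
    for (pid, task), rel in spectra.items():
        for ch in roi:
            ci = rel.channels.index(ch)
            for fi, f in enumerate(rel.freqs):
                bin_rows.append(
                    {
                        "participant_id": pid,
                        "group": groups[pid],
                        "task": task,
                        "channel": ch,
                        "freq": float(f),
                        "value": rel.values[ci, fi],
                    }
                )
    bin_table = pd.DataFrame(bin_rows)
    return tables, bin_table


def _band_tag(band) -> str:
    return f"{band[0]:g}-{band[1]:g}Hz"


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["sim"]["tasks"] = list(d["sim"]["tasks"])
    d["bands"] = [list(b) for b in d["bands"]]
    d["posthoc_metrics"] = list(d["posthoc_metrics"])
    return d


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the whole analysis and write TSV tables plus a JSON manifest.

    Writes, per band: participant-level relative-power spectra, entropy
    values, per-task channel-wise group maps for both metrics, the per-bin
    ROI test per task, the mixed-model group-effect map with estimated
    marginal means, and post-hoc task contrasts per group.  Returns the
    in-memory results keyed like the files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("simulating study (%d participants/group)", config.sim.n_per_group)

    try:
        study = simulate_study(config.sim)
    except Exception as err:
        raise PipelineError(f"stage 'simulate' failed: {err}") from err

    spectra = participant_spectra(study)
    tables, bin_table = build_metric_tables(study, spectra, config.bands)

    results: dict = {"tables": tables, "bin_table": bin_table, "spectra": spectra}
    spec_dir = out / "spectra"
    spec_dir.mkdir(exist_ok=True)
    for (pid, task), rel in sorted(spectra.items()):
        rel.to_tsv(spec_dir / f"{pid}_{task}_relpower.tsv")

    roi_ok = len(study.montage.roi_contralateral_sm) > 0
    for band in config.bands:
        tag = _band_tag(band)
        table = tables[band]
        table.to_csv(out / f"metrics_{tag}.tsv", sep="\t", index=False, float_format="%.6g")
        for metric, test in METRIC_TESTS.items():
            for task in config.sim.tasks:
                try:
                    cmap = channelwise_group_test(
                        table, metric, task, test=test, alpha=config.alpha
                    )
                except Exception as err:
                    raise PipelineError(
                        f"stage 'channelwise' failed for metric={metric}, "
                        f"task={task}, band={tag}: {err}"
                    ) from err
                cmap.to_tsv(out / f"channelwise_{metric}_{task}_{tag}.tsv")
                results[f"channelwise_{metric}_{task}_{tag}"] = cmap
            try:
                gmap, fits = group_effect_map(
                    table, metric, alpha=config.alpha, inference=config.inference
                )
            except Exception as err:
                raise PipelineError(
                    f"stage 'mixed_model' failed for metric={metric}, band={tag}: {err}"
                ) from err
            gmap.to_tsv(out / f"group_effect_{metric}_{tag}.tsv")
            emm = pd.concat(
                [f.emmeans.assign(channel=ch) for ch, f in fits.items()],
                ignore_index=True,
            )
            emm.to_csv(
                out / f"emmeans_{metric}_{tag}.tsv",
                sep="\t",
                index=False,
                float_format="%.6g",
            )
            results[f"group_effect_{metric}_{tag}"] = gmap
            results[f"emmeans_{metric}_{tag}"] = emm
        for metric in config.posthoc_metrics:
            for grp in ("elderly", "young"):
                try:
                    con = posthoc_task_contrasts(table, metric, grp, alpha=config.alpha)
                except Exception as err:
                    raise PipelineError(
                        f"stage 'posthoc' failed for metric={metric}, "
                        f"group={grp}, band={tag}: {err}"
                    ) from err
                con.to_csv(
                    out / f"posthoc_{metric}_{grp}_{tag}.tsv",
                    sep="\t",
                    index=False,
                    float_format="%.6g",
                )
                results[f"posthoc_{metric}_{grp}_{tag}"] = con

    if roi_ok:
        for task in config.sim.tasks:
            try:
                roi_res = binwise_roi_test(
                    bin_table,
                    study.montage.roi_contralateral_sm,
                    task=task,
                    alpha=config.alpha,
                )
            except Exception as err:
                raise PipelineError(
                    f"stage 'binwise_roi' failed for task={task}: {err}"
                ) from err
            roi_res.to_csv(
                out / f"binwise_roi_{task}.tsv",
                sep="\t",
                index=False,
                float_format="%.6g",
            )
            results[f"binwise_roi_{task}"] = roi_res
    else:
        logger.warning("montage lacks the sensorimotor ROI; skipping per-bin tests")

    if config.write_plots:
        from .plotting import topomap_figure

        for band in config.bands:
            tag = _band_tag(band)
            for metric in METRIC_TESTS:
                key = f"group_effect_{metric}_{tag}"
                topomap_figure(
                    study.montage,
                    results[key],
                    title=f"{metric} group effect, {tag}",
                    path=out / f"topo_{metric}_{tag}.png",
                )

    cfg = _config_dict(config)
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.sim.seed,
        "versions": _versions(),
        "outputs": sorted(str(p.relative_to(out)) for p in out.rglob("*.tsv")),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    results["manifest"] = manifest
    return results


def _versions() -> dict:
    import scipy
    import statsmodels

    from . import __version__

    return {
        "erdentropy": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
    }
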