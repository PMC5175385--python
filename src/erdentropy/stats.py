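"""Channel-wise group inference: two-sample tests, FDR, and mixed models.

The inferential layer mirrors a standard sensor-level EEG group analysis:

* per-channel two-group comparisons of participant-level metrics
  (pooled-variance Student t for relative power, Wilcoxon rank-sum for
  entropy), corrected across channels by Benjamini-Hochberg FDR;
* per-frequency-bin comparisons over a sensorimotor region of interest,
  corrected across the 18 bins;
* per-channel linear mixed models pooling tasks, ``value ~ group + task``
  with a participant random intercept (REML estimates; the group effect is
  tested by a likelihood-ratio test on ML refits);
* post-hoc pairwise task contrasts within each group from the
  group x task interaction model, via estimated marginal (least-square)
  means, FDR-corrected within each group's contrast family.

The long-format metric table is a pandas DataFrame with columns
``participant_id, group, task, channel, metric, value``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "ChannelStatMap",
    "MixedModelFit",
    "students_t_unpaired",
    "wilcoxon_rank_sum",
    "fdr_bh",
    "metric_table",
    "channelwise_group_test",
    "binwise_roi_test",
    "fit_random_intercept_model",
    "group_effect_map",
    "posthoc_task_contrasts",
]

METRIC_COLUMNS = ["participant_id", "group", "task", "channel", "metric", "value"]

#: Sample size at or below which the Wilcoxon p-value is exact (enumeration).
EXACT_WILCOXON_MAX_N = 12


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_x: int
    n_y: int
    df: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class ChannelStatMap:
    """Per-channel statistic with raw and FDR-adjusted p-values."""

    channels: tuple[str, ...]
    statistic: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    significant: np.ndarray
    alpha: float
    method: str

    def __post_init__(self) -> None:
        if np.any(self.p_adj + 1e-12 < self.p_raw):
            raise ValueError("adjusted p-values must be >= raw p-values")
        if not np.array_equal(self.significant, self.p_adj < self.alpha):
            raise ValueError("significance mask inconsistent with adjusted p and alpha")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel": list(self.channels),
                "statistic": self.statistic,
                "p_raw": self.p_raw,
                "p_fdr": self.p_adj,
                "significant": self.significant,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def students_t_unpaired(x, y) -> TestResult:
    """Two-sample pooled-variance (Student) t-test, two-sided.

    Requires at least two observations per group and nonzero pooled
    variance; degrees of freedom are n_x + n_y - 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    sx2 = x.var(ddof=1)
    sy2 = y.var(ddof=1)
    pooled = ((x.size - 1) * sx2 + (y.size - 1) * sy2) / (x.size + y.size - 2)
    if pooled <= 0:
        raise ValueError("zero pooled variance: t statistic undefined")
    res = sps.ttest_ind(x, y, equal_var=True)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="student_t",
        n_x=x.size,
        n_y=y.size,
        df=float(x.size + y.size - 2),
    )


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum test with midranks for ties.

    For combined sample sizes up to 12 the p-value is exact, from complete
    enumeration of the rank assignments; above that a normal approximation
    with tie and continuity correction is used.  The reported statistic is
    the rank sum W of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    nx, ny = x.size, y.size
    n = nx + ny
    ranks = _midranks(np.concatenate([x, y]))
    w = ranks[:nx].sum()
    if n <= EXACT_WILCOXON_MAX_N:
        sums = np.fromiter(
            (sum(c) for c in itertools.combinations(ranks, nx)),
            dtype=float,
        )
        tol = 1e-9
        p_lo = np.mean(sums <= w + tol)
        p_hi = np.mean(sums >= w - tol)
        p = min(1.0, 2.0 * min(p_lo, p_hi))
    else:
        mu = nx * (n + 1) / 2.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
        var = nx * ny / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (w - mu - np.sign(w - mu) * 0.5) / np.sqrt(var)
            p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return TestResult(
        statistic=float(w), p_value=float(p), method="wilcoxon", n_x=nx, n_y=ny
    )


def fdr_bh(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR correction.

    Returns ``(p_adjusted, reject)`` where ``p_adjusted[i]`` is
    min over j >= rank(i) of p_(j) * m / j capped at 1, and
    ``reject = p_adjusted < alpha``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("need a non-empty 1-D vector of p-values")
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, p_adj < alpha


def metric_table(rows) -> pd.DataFrame:
    """Assemble and validate a long-format metric table.

    One row per (participant, task, channel, metric); duplicate keys are an
    error since downstream models assume one observation per cell.
    """
    df = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    dup = df.duplicated(subset=["participant_id", "task", "channel", "metric"])
    if dup.any():
        raise ValueError("duplicate (participant, task, channel, metric) rows")
    bad = set(df["group"]) - {"elderly", "young"}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    return df


def _select(table: pd.DataFrame, metric: str, task: str | None) -> pd.DataFrame:
    sub = table[table["metric"] == metric]
    if task is not None:
        sub = sub[sub["task"] == task]
    if sub.empty:
        raise ValueError(f"no rows for metric={metric!r}, task={task!r}")
    return sub


_TESTS = {"student_t": students_t_unpaired, "wilcoxon": wilcoxon_rank_sum}


def channelwise_group_test(
    table: pd.DataFrame,
    metric: str,
    task: str | None = None,
    test: str = "student_t",
    alpha: float = 0.05,
) -> ChannelStatMap:
    """Elderly-vs-young test per channel, FDR-corrected across channels.

    ``task=None`` averages each participant's values across tasks first.
    """
    if test not in _TESTS:
        raise ValueError(f"unknown test {test!r}; choose from {sorted(_TESTS)}")
    sub = _select(table, metric, task)
    if task is None:
        sub = (
            sub.groupby(["participant_id", "group", "channel"], as_index=False)["value"]
            .mean()
        )
    channels = list(dict.fromkeys(sub["channel"]))
    stats_, pvals = [], []
    for ch in channels:
        rows = sub[sub["channel"] == ch]
        x = rows.loc[rows["group"] == "elderly", "value"].to_numpy()
        y = rows.loc[rows["group"] == "young", "value"].to_numpy()
        if x.size < 2 or y.size < 2:
            raise ValueError(f"both groups need >= 2 participants at channel {ch}")
        res = _TESTS[test](x, y)
        stats_.append(res.statistic)
        pvals.append(res.p_value)
    p_raw = np.array(pvals)
    p_adj, reject = fdr_bh(p_raw, alpha)
    return ChannelStatMap(
        channels=tuple(channels),
        statistic=np.array(stats_),
        p_raw=p_raw,
        p_adj=p_adj,
        significant=reject,
        alpha=alpha,
        method=test,
    )


def binwise_roi_test(
    bin_table: pd.DataFrame,
    roi: tuple[str, ...],
    task: str | None = None,
    test: str = "student_t",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-frequency-bin group test of ROI-averaged relative power.

    ``bin_table`` is long-format with columns participant_id, group, task,
    channel, freq, value.  Per participant and bin, values are averaged
    over the ROI channels; the chosen two-group test is applied per bin and
    corrected across bins by FDR.  Returns a DataFrame with one row per bin.
    """
    missing = set(roi) - set(bin_table["channel"])
    if missing:
        raise ValueError(f"ROI channels absent from table: {sorted(missing)}")
    sub = bin_table[bin_table["channel"].isin(roi)]
    if task is not None:
        sub = sub[sub["task"] == task]
        if sub.empty:
            raise ValueError(f"no rows for task {task!r}")
    per_part = (
        sub.groupby(["participant_id", "group", "freq"], as_index=False)["value"].mean()
    )
    freqs = np.sort(per_part["freq"].unique())
    rows = []
    for f in freqs:
        at_f = per_part[per_part["freq"] == f]
        x = at_f.loc[at_f["group"] == "elderly", "value"].to_numpy()
        y = at_f.loc[at_f["group"] == "young", "value"].to_numpy()
        res = _TESTS[test](x, y)
        rows.append({"freq": f, "statistic": res.statistic, "p_raw": res.p_value})
    out = pd.DataFrame(rows)
    out["p_fdr"], out["significant"] = fdr_bh(out["p_raw"].to_numpy(), alpha)
    return out


@dataclass
class MixedModelFit:
    """One channel's random-intercept model fit."""

    channel: str
    fixed_effects: pd.Series
    fe_cov: pd.DataFrame = field(repr=False)
    participant_var: float
    residual_var: float
    group_p_value: float
    emmeans: pd.DataFrame          # estimated marginal means per group x task
    converged: bool
    loglike_full_ml: float
    loglike_reduced_ml: float

    def __post_init__(self) -> None:
        if self.participant_var < 0 or self.residual_var < 0:
            raise ValueError("variance components must be nonnegative")


def _design(sub: pd.DataFrame, include_interaction: bool):
    """Treatment-coded design matrix for group + task (+ interaction).

    References: group='young' (so the group coefficient is elderly - young),
    first task in sorted order.
    """
    tasks = sorted(sub["task"].unique())
    cols = {"Intercept": np.ones(len(sub))}
    g = (sub["group"] == "elderly").to_numpy(dtype=float)
    cols["group[elderly]"] = g
    for t in tasks[1:]:
        cols[f"task[{t}]"] = (sub["task"] == t).to_numpy(dtype=float)
    if include_interaction:
        for t in tasks[1:]:
            cols[f"group[elderly]:task[{t}]"] = g * (sub["task"] == t).to_numpy(float)
    X = pd.DataFrame(cols, index=sub.index)
    return X, tasks


def _fit_mixedlm(endog, exog, groups, reml: bool):
    """MixedLM fit with optimizer fallbacks.

    A boundary solution (participant variance ~ 0) can leave the profiled
    Hessian singular under the default optimizer; Powell and Nelder-Mead
    usually recover it.  Only if every optimizer fails is the error
    surfaced, with the last diagnostic attached.
    """
    last_err: Exception | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(endog, exog, groups=groups)
        for method in (["lbfgs", "bfgs", "cg"], "powell", "nm"):
            try:
                return model.fit(reml=reml, method=method)
            except Exception as err:  # noqa: BLE001 - retried, then surfaced
                last_err = err
    raise RuntimeError(f"mixed model failed to fit: {last_err}") from last_err


def fit_random_intercept_model(
    table: pd.DataFrame,
    metric: str,
    channel: str,
    include_interaction: bool = False,
    inference: str = "lrt",
) -> MixedModelFit:
    """Fit ``value ~ group + task (+ group:task)`` with participant intercepts.

    Estimates come from a REML fit.  The group-effect p-value defaults to a
    likelihood-ratio test between ML refits of the model with and without
    all group terms (chi-squared reference, df = number of group terms);
    ``inference='wald'`` uses the REML Wald z-test on the group main effect
    instead.  Singular fits (zero participant variance) are reported, not
    hidden; true optimizer failures raise with diagnostics.
    """
    sub = table[(table["metric"] == metric) & (table["channel"] == channel)]
    if sub.empty:
        raise ValueError(f"no rows for metric={metric!r} at channel={channel!r}")
    for grp in ("elderly", "young"):
        if sub.loc[sub["group"] == grp, "participant_id"].nunique() < 2:
            raise ValueError(f"need >= 2 participants in group {grp!r}")
    X, tasks = _design(sub, include_interaction)
    y = sub["value"].to_numpy(dtype=float)
    groups = sub["participant_id"].to_numpy()

    fit = _fit_mixedlm(y, X, groups, reml=True)
    group_cols = [c for c in X.columns if c.startswith("group[")]
    if inference == "lrt":
        full = _fit_mixedlm(y, X, groups, reml=False)
        reduced = _fit_mixedlm(y, X.drop(columns=group_cols), groups, reml=False)
        lr = 2.0 * (full.llf - reduced.llf)
        p_group = float(sps.chi2.sf(max(lr, 0.0), df=len(group_cols)))
        ll_full, ll_red = float(full.llf), float(reduced.llf)
    elif inference == "wald":
        p_group = float(fit.pvalues["group[elderly]"])
        ll_full = ll_red = float("nan")
    else:
        raise ValueError("inference must be 'lrt' or 'wald'")

    fe = fit.fe_params
    fe_cov = pd.DataFrame(
        np.asarray(fit.cov_params())[: len(fe), : len(fe)],
        index=fe.index,
        columns=fe.index,
    )
    emm_rows = []
    for grp in ("elderly", "young"):
        for t in tasks:
            vec = _emm_vector(fe.index, grp, t)
            emm_rows.append(
                {
                    "group": grp,
                    "task": t,
                    "emmean": float(vec @ fe.to_numpy()),
                    "se": float(np.sqrt(vec @ fe_cov.to_numpy() @ vec)),
                }
            )
    return MixedModelFit(
        channel=channel,
        fixed_effects=fe,
        fe_cov=fe_cov,
        participant_var=float(np.asarray(fit.cov_re).squeeze()),
        residual_var=float(fit.scale),
        group_p_value=p_group,
        emmeans=pd.DataFrame(emm_rows),
        converged=bool(getattr(fit, "converged", True)),
        loglike_full_ml=ll_full,
        loglike_reduced_ml=ll_red,
    )


def _emm_vector(coef_names, group: str, task: str) -> np.ndarray:
    """Fixed-effect contrast vector for the (group, task) cell mean."""
    vec = np.zeros(len(coef_names))
    for i, name in enumerate(coef_names):
        if name == "Intercept":
            vec[i] = 1.0
        elif name == "group[elderly]":
            vec[i] = 1.0 if group == "elderly" else 0.0
        elif name.startswith("task["):
            vec[i] = 1.0 if name == f"task[{task}]" else 0.0
        elif ":" in name:
            vec[i] = 1.0 if (group == "elderly" and name.endswith(f"task[{task}]")) else 0.0
    return vec


def group_effect_map(
    table: pd.DataFrame,
    metric: str,
    alpha: float = 0.05,
    inference: str = "lrt",
) -> tuple[ChannelStatMap, dict[str, MixedModelFit]]:
    """Mixed-model group effect per channel, FDR-corrected across channels.

    Returns the channel map plus the per-channel fits (for marginal means
    and variance components).
    """
    channels = list(dict.fromkeys(table.loc[table["metric"] == metric, "channel"]))
    if not channels:
        raise ValueError(f"no rows for metric {metric!r}")
    fits: dict[str, MixedModelFit] = {}
    stats_, pvals = [], []
    for ch in channels:
        f = fit_random_intercept_model(table, metric, ch, inference=inference)
        fits[ch] = f
        stats_.append(float(f.fixed_effects.get("group[elderly]", np.nan)))
        pvals.append(f.group_p_value)
    p_adj, reject = fdr_bh(np.array(pvals), alpha)
    cmap = ChannelStatMap(
        channels=tuple(channels),
        statistic=np.array(stats_),
        p_raw=np.array(pvals),
        p_adj=p_adj,
        significant=reject,
        alpha=alpha,
        method="mixed_lrt" if inference == "lrt" else "mixed_wald",
    )
    return cmap, fits


def posthoc_task_contrasts(
    table: pd.DataFrame,
    metric: str,
    group: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise task contrasts of least-square means within one group.

    Fits the group x task interaction model per channel, forms all pairwise
    task differences of the estimated marginal means for ``group``, with
    standard errors from the fixed-effect covariance and normal-reference
    two-sided p-values, FDR-corrected over the whole contrast family
    (channels x task pairs).
    """
    sub = table[table["metric"] == metric]
    tasks = sorted(sub["task"].unique())
    if len(tasks) < 2:
        raise ValueError("post-hoc task contrasts need at least 2 tasks")
    channels = list(dict.fromkeys(sub["channel"]))
    rows = []
    for ch in channels:
        f = fit_random_intercept_model(table, metric, ch, include_interaction=True)
        names = f.fixed_effects.index
        beta = f.fixed_effects.to_numpy()
        cov = f.fe_cov.to_numpy()
        for t1, t2 in itertools.combinations(tasks, 2):
            c = _emm_vector(names, group, t1) - _emm_vector(names, group, t2)
            est = float(c @ beta)
            se = float(np.sqrt(c @ cov @ c))
            z = est / se if se > 0 else 0.0
            rows.append(
                {
                    "channel": ch,
                    "group": group,
                    "contrast": f"{t1} - {t2}",
                    "estimate": est,
                    "se": se,
                    "z": z,
                    "p_raw": float(min(1.0, 2.0 * sps.norm.sf(abs(z)))),
                }
            )
    out = pd.DataFrame(rows)
    out["p_fdr"], out["significant"] = fdr_bh(out["p_raw"].to_numpy(), alpha)
    return out
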