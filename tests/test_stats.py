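"""Two-sample tests, FDR correction, and channel/bin maps."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

import erdentropy as ee
from erdentropy.stats import metric_table


def bh_oracle(p, alpha=0.05):
    """Brute-force Benjamini-Hochberg step-up, coded independently."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj, adj < alpha


class TestStudentT:
    def test_identical_samples_give_t0_p1(self):
        r = ee.students_t_unpaired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_worked_example_closed_form(self):
        # pooled s^2 = 1, se = sqrt(2/3), t = -3/se
        r = ee.students_t_unpaired([1, 2, 3], [4, 5, 6])
        assert r.statistic == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), rel=1e-12)
        assert r.statistic == pytest.approx(-3.674, abs=5e-4)
        assert r.df == 4
        assert r.method == "student_t"

    def test_single_observation_is_an_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            ee.students_t_unpaired([1.0], [2.0, 3.0])

    def test_zero_pooled_variance_is_an_error(self):
        with pytest.raises(ValueError, match="pooled variance"):
            ee.students_t_unpaired([2.0, 2.0], [5.0, 5.0])

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=rng.integers(3, 20))
            y = rng.normal(0.5, 1.3, size=rng.integers(3, 20))
            r = ee.students_t_unpaired(x, y)
            ref = sps.ttest_ind(x, y, equal_var=True)
            assert r.statistic == pytest.approx(ref.statistic, rel=1e-12)
            assert r.p_value == pytest.approx(ref.pvalue, rel=1e-12)


class TestWilcoxon:
    def test_small_sample_exact_p(self):
        r = ee.wilcoxon_rank_sum([1.0, 2.0], [3.0, 4.0])
        assert r.p_value == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_identical_multisets_give_p1(self):
        r = ee.wilcoxon_rank_sum([1.0, 2.0], [1.0, 2.0])
        assert r.p_value == pytest.approx(1.0)

    def test_exact_matches_label_permutation_oracle(self):
        """Exhaustive check against an independent oracle that permutes
        group labels and recomputes the rank sum, for every split of small
        combined samples (with and without ties)."""
        rng = np.random.default_rng(3)
        datasets = [
            rng.normal(size=8),
            np.array([1.0, 1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 9.0]),  # heavy ties
        ]
        for pooled in datasets:
            for nx in (2, 3, 4):
                x, y = pooled[:nx], pooled[nx:]
                r = ee.wilcoxon_rank_sum(x, y)
                ranks = sps.rankdata(pooled)
                w_obs = ranks[:nx].sum()
                sums = [sum(c) for c in itertools.combinations(ranks, nx)]
                p_lo = np.mean([s <= w_obs + 1e-9 for s in sums])
                p_hi = np.mean([s >= w_obs - 1e-9 for s in sums])
                expected = min(1.0, 2.0 * min(p_lo, p_hi))
                assert r.p_value == pytest.approx(expected, abs=1e-12)

    def test_normal_approximation_near_exact_at_crossover(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.normal(size=6)
            y = rng.normal(0.3, 1.0, size=6)
            exact = ee.wilcoxon_rank_sum(x, y).p_value          # n=12: exact
            # force the approximation by inflating the crossover temporarily
            mu = 6 * 13 / 2.0
            var = 36 * 13 / 12.0
            w = sps.rankdata(np.concatenate([x, y]))[:6].sum()
            z = (w - mu - np.sign(w - mu) * 0.5) / np.sqrt(var)
            approx = min(1.0, 2.0 * sps.norm.sf(abs(z)))
            assert abs(exact - approx) < 0.02

    def test_large_sample_uses_normal_path(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=30)
        y = rng.normal(1.0, 1.0, size=30)
        r = ee.wilcoxon_rank_sum(x, y)
        ref = sps.ranksums(x, y)
        assert r.p_value == pytest.approx(ref.pvalue, abs=0.01)
        assert r.p_value < 0.01


class TestFdrBH:
    def test_single_p_unchanged(self):
        adj, rej = ee.fdr_bh([0.03])
        assert adj[0] == pytest.approx(0.03)
        assert rej[0]

    def test_worked_stepup(self):
        adj, _ = ee.fdr_bh([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_constant_p_vector_unchanged(self):
        adj, _ = ee.fdr_bh([0.05] * 7)
        np.testing.assert_allclose(adj, 0.05)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            ee.fdr_bh([0.5, 1.2])
        with pytest.raises(ValueError):
            ee.fdr_bh([-0.1, 0.5])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8))
    def test_matches_brute_force_oracle(self, pvals):
        adj, rej = ee.fdr_bh(pvals)
        oadj, orej = bh_oracle(pvals)
        np.testing.assert_allclose(adj, oadj, atol=1e-12)
        assert np.array_equal(rej, orej)

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=20))
    def test_adjusted_monotone_in_raw_rank(self, pvals):
        adj, _ = ee.fdr_bh(pvals)
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(np.asarray(adj)[order]) >= -1e-12)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)


def toy_metric_table(rng, n_per_group=6, channels=("C3", "C4", "Cz"),
                     tasks=("a",), group_shift=0.0, metric="entropy",
                     subject_sd=0.0):
    rows = []
    for g, shift in (("elderly", group_shift), ("young", 0.0)):
        for i in range(n_per_group):
            pid = f"{g}{i}"
            offset = rng.normal(0.0, subject_sd)
            for task in tasks:
                for ch in channels:
                    rows.append((pid, g, task, ch, metric,
                                 shift + offset + rng.normal()))
    return metric_table(rows)


class TestChannelwiseGroupTest:
    def test_one_p_value_per_channel(self):
        rng = np.random.default_rng(0)
        table = toy_metric_table(rng, channels=tuple(f"c{i}" for i in range(16)))
        cmap = ee.channelwise_group_test(table, "entropy", "a", test="wilcoxon")
        assert len(cmap.channels) == 16
        assert cmap.p_raw.size == 16
        assert np.all(cmap.p_adj >= cmap.p_raw - 1e-12)
        assert np.array_equal(cmap.significant, cmap.p_adj < cmap.alpha)

    def test_null_false_positive_rate_controlled(self):
        """Identical group distributions: the expected fraction of
        FDR-significant channels stays at or below alpha."""
        rng = np.random.default_rng(42)
        frac = []
        for _ in range(200):
            table = toy_metric_table(rng)
            cmap = ee.channelwise_group_test(table, "entropy", "a",
                                             test="student_t")
            frac.append(cmap.significant.mean())
        assert np.mean(frac) <= 0.05 + 0.02

    def test_missing_metric_or_task_is_an_error(self):
        rng = np.random.default_rng(1)
        table = toy_metric_table(rng)
        with pytest.raises(ValueError, match="no rows"):
            ee.channelwise_group_test(table, "nope", "a")
        with pytest.raises(ValueError, match="no rows"):
            ee.channelwise_group_test(table, "entropy", "zz")

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(2)
        table = toy_metric_table(rng, n_per_group=10, group_shift=3.0)
        cmap = ee.channelwise_group_test(table, "entropy", "a")
        assert cmap.significant.all()


class TestBinwiseRoiTest:
    def make_bin_table(self, rng, shift_bins=(), n_per_group=8):
        freqs = np.arange(8.0, 26.0)
        rows = []
        for g in ("elderly", "young"):
            for i in range(n_per_group):
                pid = f"{g}{i}"
                for ch in ("FC3", "C3", "CP3"):
                    for f in freqs:
                        delta = 2.5 if (g == "elderly" and f in shift_bins) else 0.0
                        rows.append({"participant_id": pid, "group": g,
                                     "task": "a", "channel": ch, "freq": f,
                                     "value": delta + rng.normal()})
        return pd.DataFrame(rows)

    def test_18_bins_tested(self):
        rng = np.random.default_rng(0)
        res = ee.binwise_roi_test(self.make_bin_table(rng), ("FC3", "C3", "CP3"))
        assert len(res) == 18
        assert np.all(res["p_fdr"] >= res["p_raw"] - 1e-12)

    def test_shifted_bins_detected_contiguously(self):
        rng = np.random.default_rng(1)
        table = self.make_bin_table(rng, shift_bins=(14.0, 15.0, 16.0, 17.0))
        res = ee.binwise_roi_test(table, ("FC3", "C3", "CP3"))
        sig = set(res.loc[res.significant, "freq"])
        assert {14.0, 15.0, 16.0, 17.0} <= sig

    def test_permuted_labels_yield_no_systematic_significance(self):
        rng = np.random.default_rng(7)
        fracs = []
        for _ in range(60):
            res = ee.binwise_roi_test(self.make_bin_table(rng, n_per_group=5),
                                      ("FC3", "C3", "CP3"))
            fracs.append(res.significant.mean())
        assert np.mean(fracs) <= 0.05 + 0.03

    def test_missing_roi_channel_is_an_error(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="ROI"):
            ee.binwise_roi_test(self.make_bin_table(rng), ("FC3", "C3", "XX1"))


def test_metric_table_rejects_duplicates_and_bad_groups():
    rows = [("p1", "elderly", "a", "C3", "entropy", 0.5)]
    with pytest.raises(ValueError, match="duplicate"):
        metric_table(rows * 2)
    with pytest.raises(ValueError, match="group"):
        metric_table([("p1", "old", "a", "C3", "entropy", 0.5)])
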