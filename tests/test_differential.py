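"""Depth estimation, Poisson score statistic, p- and q-values."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from phosphoflow.differential import (
    DepthEstimate,
    DiffConfig,
    estimate_depths,
    p_values,
    paired_contrasts,
    q_values,
    run_contrast,
    score_statistics,
    to_counts,
)
from phosphoflow.model import Contrast, make_matrix
from phosphoflow.simulate import SimulationParams, simulate_design, simulate_reporter_data


def _homogeneous_counts(col_sums, n_features=25):
    """Features sharing the columns' proportions exactly (Poisson null mean)."""
    props = np.asarray(col_sums, dtype=float) / np.sum(col_sums)
    per_feature = np.sum(col_sums) / n_features
    data = np.tile(props * per_feature, (n_features, 1))
    return pd.DataFrame(data, index=[f"f{i}" for i in range(n_features)],
                        columns=[f"s{i}" for i in range(len(col_sums))])


class TestEstimateDepths:
    def test_homogeneous_features_give_column_proportions(self):
        counts = _homogeneous_counts([300, 100])
        est = estimate_depths(counts)
        assert est.d["s0"] == pytest.approx(0.75, abs=1e-12)
        assert est.d["s1"] == pytest.approx(0.25, abs=1e-12)
        assert est.d.sum() == pytest.approx(1.0, abs=1e-12)

    def test_converges_quickly_on_exact_null(self):
        counts = _homogeneous_counts([100, 100, 100, 100])
        est = estimate_depths(counts)
        assert est.n_iterations <= 2
        assert np.allclose(est.d, 0.25)

    def test_few_features_fall_back_with_warning(self):
        counts = _homogeneous_counts([300, 100], n_features=5)
        with pytest.warns(UserWarning, match="fewer than 20"):
            est = estimate_depths(counts)
        assert est.d["s0"] == pytest.approx(0.75)
        assert est.n_iterations == 0

    def test_robust_to_strongly_differential_features(self, rng):
        """With 10% planted differential features, trimmed depths beat naive
        column sums (smaller max error vs planted depths), most seeds."""
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            true_d = np.array([0.1, 0.15, 0.2, 0.25, 0.3])
            base = r.uniform(200, 2000, size=300)
            lam = np.outer(base, true_d) * 5
            diff = r.choice(300, 30, replace=False)
            lam[diff[:15], :2] *= 8  # strong effects concentrated in two samples
            lam[diff[15:], 2:] *= 8
            counts = pd.DataFrame(r.poisson(lam), columns=list("abcde"))
            est = estimate_depths(counts)
            naive = counts.sum(axis=0) / counts.to_numpy().sum()
            err_est = np.abs(est.d.to_numpy() - true_d).max()
            err_naive = np.abs(naive.to_numpy() - true_d).max()
            wins += err_est < err_naive
        assert wins >= int(0.8 * n_seeds)

    def test_all_zero_rows_dropped(self):
        counts = _homogeneous_counts([100, 100])
        counts.iloc[0] = 0.0
        est = estimate_depths(counts)
        assert "f0" not in est.gof.index


class TestScoreStatistic:
    @staticmethod
    def _depths(vals, names):
        d = pd.Series(vals, index=names)
        return DepthEstimate(d=d, gof=pd.Series(dtype=float), kept_features=set(), n_iterations=0)

    def test_balanced_null_is_zero(self):
        counts = pd.DataFrame({"a1": [5.0], "a2": [5.0], "b1": [5.0], "b2": [5.0]}, index=["f"])
        depths = self._depths([0.25] * 4, ["a1", "a2", "b1", "b2"])
        c = Contrast("c", ["a1", "a2"], ["b1", "b2"])
        t, lfc = score_statistics(counts, depths, c)
        assert t["f"] == pytest.approx(0.0, abs=1e-12)
        assert lfc["f"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_calculated_value(self):
        # class sums 15 vs 5, equal depth halves -> expected 10/10 -> T = 5
        counts = pd.DataFrame({"a1": [7.0], "a2": [8.0], "b1": [2.0], "b2": [3.0]}, index=["f"])
        depths = self._depths([0.25] * 4, ["a1", "a2", "b1", "b2"])
        c = Contrast("c", ["a1", "a2"], ["b1", "b2"])
        t, lfc = score_statistics(counts, depths, c)
        assert t["f"] == pytest.approx(5.0)
        assert lfc["f"] == pytest.approx(np.log2(3.0))

    def test_empty_feature_convention(self):
        counts = pd.DataFrame({"a1": [0.0], "a2": [0.0], "b1": [0.0], "b2": [0.0]}, index=["f"])
        depths = self._depths([0.25] * 4, ["a1", "a2", "b1", "b2"])
        c = Contrast("c", ["a1", "a2"], ["b1", "b2"])
        t, lfc = score_statistics(counts, depths, c)
        assert t["f"] == 0.0 and lfc["f"] == 0.0

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_label_swap_symmetry(self, seed):
        r = np.random.default_rng(seed)
        counts = pd.DataFrame(r.poisson(50.0, size=(10, 6)).astype(float),
                              columns=[f"s{i}" for i in range(6)],
                              index=[f"f{i}" for i in range(10)])
        d = r.dirichlet(np.ones(6))
        depths = self._depths(d, counts.columns)
        a, b = ["s0", "s1", "s2"], ["s3", "s4", "s5"]
        t1, l1 = score_statistics(counts, depths, Contrast("c", a, b))
        t2, l2 = score_statistics(counts, depths, Contrast("c", b, a))
        assert np.allclose(t1, t2, rtol=1e-12)
        finite = np.isfinite(l1)
        assert np.allclose(l1[finite], -l2[finite], rtol=1e-12)


class TestPValues:
    def test_chisq_null_point(self):
        p = p_values(pd.Series({"f": 0.0}), method="chisq")
        assert p["f"] == pytest.approx(1.0)

    def test_chisq_five_percent_quantile(self):
        # 3.841458820694124 is the 95th percentile of chi-square(1)
        p = p_values(pd.Series({"f": 3.841458820694124}), method="chisq")
        assert p["f"] == pytest.approx(0.05, abs=1e-9)

    def test_permutation_matches_chisq_roughly(self):
        r = np.random.default_rng(0)
        counts = pd.DataFrame(r.poisson(200.0, size=(200, 6)).astype(float),
                              columns=[f"s{i}" for i in range(6)],
                              index=[f"f{i}" for i in range(200)])
        depths = estimate_depths(counts)
        c = Contrast("c", ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        t, _ = score_statistics(counts, depths, c)
        p_perm = p_values(t, method="permutation", counts=counts, depths=depths,
                          contrast=c, n_permutations=200, seed=1)
        p_chi = p_values(t, method="chisq")
        # same ranking, similar scale
        assert stats.spearmanr(p_perm, p_chi).statistic > 0.97
        assert abs((p_perm < 0.1).mean() - (p_chi < 0.1).mean()) < 0.05

    def test_permutation_deterministic_given_seed(self):
        r = np.random.default_rng(3)
        counts = pd.DataFrame(r.poisson(100.0, size=(30, 4)).astype(float),
                              columns=list("abcd"), index=[f"f{i}" for i in range(30)])
        depths = estimate_depths(counts)
        c = Contrast("c", ["a", "b"], ["c", "d"])
        t, _ = score_statistics(counts, depths, c)
        kw = dict(method="permutation", counts=counts, depths=depths, contrast=c,
                  n_permutations=120, seed=9)
        assert p_values(t, **kw).equals(p_values(t, **kw))


class TestQValues:
    def test_bh_hand_example(self):
        p = pd.Series([0.01, 0.02, 0.03, 0.04], index=list("abcd"))
        q = q_values(p)
        assert np.allclose(q, 0.04)

    def test_all_ones(self):
        q = q_values(pd.Series([1.0, 1.0, 1.0]))
        assert (q == 1.0).all()

    def test_single_feature(self):
        q = q_values(pd.Series([0.2], index=["f"]))
        assert q["f"] == pytest.approx(0.2)

    def test_monotone_in_p(self):
        r = np.random.default_rng(5)
        p = pd.Series(r.uniform(size=100))
        q = q_values(p)
        order = p.sort_values().index
        assert (q[order].diff().dropna() >= -1e-15).all()

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_reordering_invariance(self, seed):
        r = np.random.default_rng(seed)
        p = pd.Series(r.uniform(size=30), index=[f"f{i}" for i in range(30)])
        q1 = q_values(p)
        perm = r.permutation(p.index)
        q2 = q_values(p[perm])
        assert np.allclose(q1[perm].to_numpy(), q2.to_numpy())


class TestRunContrast:
    def test_incomplete_features_excluded(self):
        design = simulate_design(3)
        m, _ = simulate_reporter_data(design, SimulationParams(n_features=50, seed=6))
        m.values.iloc[0, 0] = np.nan  # channel 1 of plex1 belongs to a WT sample
        contrast = paired_contrasts(design)[0]
        res, excl = run_contrast(m, design, contrast, DiffConfig(target_median_count=None))
        feature = m.feature_ids[0]
        if feature in set(excl["feature_id"]):
            assert excl.set_index("feature_id").loc[feature, "reason"] == "incomplete"
            assert feature not in set(res["feature_id"])

    def test_low_count_features_excluded(self):
        design = simulate_design(3)
        m, _ = simulate_reporter_data(design, SimulationParams(n_features=50, seed=6))
        m.values.iloc[1, :] = 0.1
        contrast = paired_contrasts(design)[0]
        res, excl = run_contrast(m, design, contrast, DiffConfig(target_median_count=None))
        feature = m.feature_ids[1]
        assert excl.set_index("feature_id").loc[feature, "reason"] == "low_count"

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            Contrast("bad", ["a", "b"], ["b", "c"])

    def test_counts_rescaled_to_target_median(self):
        vals = pd.DataFrame(np.full((10, 4), 50000.0))
        counts = to_counts(vals, target_median_count=500.0)
        assert counts.to_numpy().max() == 500.0
        unscaled = to_counts(vals, target_median_count=None)
        assert unscaled.to_numpy().max() == 50000.0

    def test_contrast_with_all_excluded_returns_empty(self):
        design = simulate_design(3)
        m, _ = simulate_reporter_data(design, SimulationParams(n_features=5, seed=6))
        m.values.iloc[:, 0] = np.nan
        contrast = paired_contrasts(design)[0]
        res, excl = run_contrast(m, design, contrast)
        assert len(res) + len(excl) >= 5
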