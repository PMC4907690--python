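"""Forced choice, ROC, group tests, FDR, bootstrap thresholding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import painsig as ps
from painsig.errors import (DegenerateDataError, InvalidConfigError,
                            ZeroVarianceError)
from painsig.inference import (bh_fdr, binomial_interval, bootstrap_threshold,
                               conjunction_mask, forced_choice, huber_location,
                               paired_t, robust_group_test, roc_curve,
                               within_subject_sem)
from painsig.train import TrainerConfig, lasso_pcr_fit

finite = st.floats(-100, 100, allow_nan=False)


class TestForcedChoice:
    def test_all_correct(self):
        a = np.arange(28) + 1.0
        res = forced_choice(a, a - 1.0)
        assert res.accuracy == 1.0
        assert res.p_value < 1e-4

    def test_all_ties_give_half(self):
        a = np.ones(10)
        res = forced_choice(a, a)
        assert res.accuracy == 0.5
        assert res.p_value == 1.0

    def test_20_of_28_against_binomial_oracle(self):
        a = np.r_[np.ones(20), np.zeros(8)]
        b = np.zeros(28) + 0.5
        res = forced_choice(a, b)
        assert res.accuracy == pytest.approx(20 / 28)
        # exact two-sided binomial tail-sum oracle
        pmf = stats.binom.pmf(np.arange(29), 28, 0.5)
        oracle = pmf[pmf <= pmf[20] * (1 + 1e-12)].sum()
        assert res.p_value == pytest.approx(oracle, rel=1e-10)

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.tuples(finite, finite), min_size=1, max_size=10))
    def test_accuracy_matches_pair_enumeration(self, pairs):
        a = np.array([p[0] for p in pairs])
        b = np.array([p[1] for p in pairs])
        res = forced_choice(a, b)
        oracle = np.mean([1.0 if x > y else 0.5 if x == y else 0.0
                          for x, y in pairs])
        assert res.accuracy == pytest.approx(oracle)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidConfigError):
            forced_choice(np.ones(3), np.ones(4))


class TestROC:
    def test_perfect_separation(self):
        _, auc = roc_curve([3.0, 4.0], [1.0, 2.0])
        assert auc == 1.0

    def test_identical_distributions(self):
        _, auc = roc_curve([1.0, 2.0], [1.0, 2.0])
        assert auc == 0.5

    def test_hand_example(self):
        # pairs: 3>1, 3>2, 2>1 correct; 2=2 tie → (3 + 0.5)/4
        points, auc = roc_curve([3.0, 2.0], [1.0, 2.0])
        assert auc == pytest.approx(3.5 / 4)
        assert points[0].tolist() == [0.0, 0.0]
        assert points[-1].tolist() == [1.0, 1.0]

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(finite, min_size=1, max_size=8),
           st.lists(finite, min_size=1, max_size=8))
    def test_auc_matches_exhaustive_enumeration(self, pos, neg):
        _, auc = roc_curve(pos, neg)
        wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
                   for p in pos for n in neg)
        assert auc == pytest.approx(wins / (len(pos) * len(neg)))


class TestGroupTests:
    def test_paired_t_hand_value(self):
        t, df, p = paired_t(np.array([2.0, 3.0, 4.0]), np.array([1.0, 1.0, 1.0]))
        assert df == 2
        assert t == pytest.approx(2.0 / (1.0 / np.sqrt(3)), rel=1e-6)

    def test_zero_variance_is_error_not_p0(self):
        with pytest.raises(ZeroVarianceError):
            paired_t(np.ones(5), np.ones(5))
        with pytest.raises(ZeroVarianceError):
            robust_group_test(np.full(5, 2.0))

    def test_robust_equals_mean_on_clean_data(self):
        # light-tailed sample: no residual exceeds c·scale, so Huber
        # weighting is inactive and the estimate reduces to the mean
        x = np.array([-1.0, -1.0, -0.2, 0.0, 0.2, 1.0, 1.0]) + 3.0
        mu, t, df, p = robust_group_test(x)
        assert mu == pytest.approx(x.mean(), abs=1e-6)
        t_cls, p_cls = stats.ttest_1samp(x, 0.0)[:2]
        assert t == pytest.approx(t_cls, rel=1e-4)
        assert p == pytest.approx(p_cls, rel=1e-3)

    def test_robust_downweights_outlier(self):
        x = np.r_[np.full(9, 1.0) + np.linspace(-0.05, 0.05, 9), 50.0]
        mu, *_ = robust_group_test(x)
        assert abs(mu - 1.0) < 0.5  # the plain mean would be ≈ 5.9

    def test_matches_statsmodels_rlm_oracle(self, rng):
        import statsmodels.api as sm

        x = rng.normal(1.0, 1.0, 40)
        x[:4] += 8.0
        mu, t, df, p = robust_group_test(x)
        rlm = sm.RLM(x, np.ones_like(x),
                     M=sm.robust.norms.HuberT(t=1.345)).fit()
        assert mu == pytest.approx(float(rlm.params[0]), abs=1e-6)
        # SE conventions differ slightly between sandwich variants
        se = mu / t
        assert se == pytest.approx(float(rlm.bse[0]), rel=0.05)

    def test_vectorized_matches_scalar(self, rng):
        X = rng.normal(size=(20, 6))
        X[0, 3] += 15
        mu_vec, se_vec, _ = huber_location(X)
        for j in range(6):
            mu, se, _ = huber_location(X[:, j])
            assert mu_vec[j] == pytest.approx(mu)
            assert se_vec[j] == pytest.approx(se)


class TestWithinSubjectSEM:
    def test_identical_rows_zero(self):
        tab = pd.DataFrame([[1.0, 2.0, 3.0]] * 5, columns=list("abc"))
        assert np.allclose(within_subject_sem(tab), 0.0)

    def test_subject_offsets_removed(self):
        base = np.array([1.0, 2.0, 3.0])
        tab = pd.DataFrame([base + o for o in (0.0, 5.0, -2.0, 9.0)],
                           columns=list("abc"))
        assert np.allclose(within_subject_sem(tab), 0.0, atol=1e-12)

    def test_hand_centering_oracle(self):
        tab = pd.DataFrame([[1.0, 2.0], [3.0, 5.0]], columns=list("ab"))
        grand = 11.0 / 4
        centered = np.array([[1 - 1.5, 2 - 1.5], [3 - 4.0, 5 - 4.0]]) + grand
        sems = centered.std(axis=0, ddof=1) / np.sqrt(2) * np.sqrt(2 / 1)
        out = within_subject_sem(tab)
        assert np.allclose(out.to_numpy(), sems)

    def test_missing_cells_rejected(self):
        tab = pd.DataFrame([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(InvalidConfigError):
            within_subject_sem(tab)


def _bh_oracle(p, q):
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


class TestFDR:
    def test_no_rejections(self):
        thr, rej = bh_fdr(np.full(10, 0.9), 0.05)
        assert thr == 0.0 and not rej.any()

    def test_single_small_p_rejected(self):
        thr, rej = bh_fdr(np.array([0.01]), 0.05)
        assert rej.all() and thr == 0.01

    def test_step_up_example(self):
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.9])
        thr, rej = bh_fdr(p, 0.05)
        assert rej.sum() == 4
        assert thr == 0.04

    @settings(derandomize=True, max_examples=1000)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30),
           st.sampled_from([0.01, 0.05, 0.1]))
    def test_matches_independent_step_up(self, p, q):
        _, rej = bh_fdr(np.array(p), q)
        assert np.array_equal(rej, _bh_oracle(p, q))


class TestBootstrap:
    @pytest.fixture(scope="class")
    def boot(self, small_sim):
        ds = small_sim.dataset.select(modality="somatic")
        cfg = TrainerConfig(lasso_lambda=0.05, seed=0)
        fit = lambda X, y, m: lasso_pcr_fit(X, y, m, cfg)
        return ds, fit

    def test_deterministic_under_seed(self, boot):
        ds, fit = boot
        a = bootstrap_threshold(ds, fit, B=100, q=0.05, seed=3)
        b = bootstrap_threshold(ds, fit, B=100, q=0.05, seed=3)
        assert np.array_equal(a.surviving, b.surviving)
        assert np.array_equal(a.z, b.z)

    def test_survivors_within_bh_threshold(self, boot):
        ds, fit = boot
        m = bootstrap_threshold(ds, fit, B=100, q=0.05, seed=3)
        tested = ~m.excluded
        assert m.surviving[~tested].sum() == 0
        if m.surviving.any():
            assert m.p[m.surviving].max() <= m.fdr_threshold + 1e-15

    def test_zero_sd_voxel_excluded(self, small_sim):
        ds = small_sim.dataset.select(modality="somatic")
        X = ds.X.copy()
        X[:, 0] = 0.0  # dead voxel: weight is identically zero
        dead = ps.StudyDataset(ds.mask, X, ds.info)
        cfg = TrainerConfig(lasso_lambda=0.05, seed=0)
        m = bootstrap_threshold(
            dead, lambda X_, y, msk: lasso_pcr_fit(X_, y, msk, cfg),
            B=100, q=0.05, seed=3)
        assert m.excluded[0]
        assert not m.surviving[0]

    def test_too_small_B_rejected(self, boot):
        ds, fit = boot
        with pytest.raises(InvalidConfigError):
            bootstrap_threshold(ds, fit, B=50)


class TestConjunction:
    def test_intersection_of_known_voxels(self, rng):
        a = np.zeros((5, 5, 5), bool)
        b = np.zeros((5, 5, 5), bool)
        a[:3] = True
        b[2:4] = True
        out = conjunction_mask(a, b)
        assert out.sum() == 25
        assert np.array_equal(out, a & b)

    def test_identical_masks(self, rng):
        a = rng.random((4, 4, 4)) > 0.5
        assert np.array_equal(conjunction_mask(a, a), a)

    def test_disjoint_warns_not_errs(self):
        a = np.zeros((3, 3, 3), bool); a[0] = True
        b = np.zeros((3, 3, 3), bool); b[2] = True
        with pytest.warns(UserWarning):
            out = conjunction_mask(a, b)
        assert not out.any()


class TestBinomialInterval:
    def test_band_contains_half(self):
        lo, hi = binomial_interval(28)
        assert lo < 0.5 < hi
        # exact central band endpoints for n=28
        assert lo == stats.binom.ppf(0.025, 28, 0.5) / 28
        assert hi == stats.binom.ppf(0.975, 28, 0.5) / 28
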