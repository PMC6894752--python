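"""Granger engine: smoothing, stationarity, order selection, VAR, F statistics."""

import numpy as np
import pytest

from socialfreeze.granger import (
    GcInput,
    check_stationarity,
    fit_var,
    gc_f,
    pairwise_gc,
    pooled_gc,
    select_order,
    smooth_series,
)


def ln2_system(n, seed):
    """X2(t) = X1(t-1) + eps: population F(X1->X2) = ln 2, F(X2->X1) = 0."""
    rng = np.random.default_rng(seed)
    x1 = rng.normal(size=n)
    x2 = np.empty(n)
    x2[0] = rng.normal()
    x2[1:] = x1[:-1] + rng.normal(size=n - 1)
    return x1, x2


class TestSmoothing:
    def test_constant_series_preserved(self):
        out = smooth_series(np.full(500, 0.7), window_s=300)
        assert out == pytest.approx(0.7)

    def test_impulse_response_is_normalized_symmetric_kernel(self):
        x = np.zeros(501)
        x[250] = 1.0
        out = smooth_series(x, window_s=300, sigma=1.5)
        assert out.sum() == pytest.approx(1.0)
        assert out[249] == pytest.approx(out[251])
        assert out.argmax() == 250

    def test_step_response_is_monotone(self):
        x = np.concatenate([np.zeros(250), np.ones(250)])
        out = smooth_series(x, window_s=300)
        assert (np.diff(out) >= -1e-12).all()

    def test_kernel_longer_than_series_rejected(self):
        with pytest.raises(ValueError, match="window"):
            smooth_series(np.zeros(100), window_s=300)


class TestStationarity:
    def test_white_noise_passes(self, rng):
        v = check_stationarity(rng.normal(size=1000))
        assert v.passed and not v.degenerate

    def test_random_walk_warns(self, rng):
        v = check_stationarity(np.cumsum(rng.normal(size=1000)))
        assert not v.passed and not v.degenerate

    def test_constant_series_flagged_degenerate(self):
        v = check_stationarity(np.full(1000, 0.3))
        assert v.degenerate


class TestOrderSelection:
    def test_var2_order_recovered_in_majority_of_seeds(self):
        A1 = np.array([[0.4, 0.1], [0.0, 0.3]])
        A2 = np.array([[0.2, 0.0], [0.15, 0.1]])
        hits = 0
        for s in range(50):
            r = np.random.default_rng(1000 + s)
            X = np.zeros((2000, 2))
            for t in range(2, 2000):
                X[t] = A1 @ X[t - 1] + A2 @ X[t - 2] + r.normal(size=2)
            hits += select_order(X, max_order=8) == 2
        assert hits > 25

    def test_white_noise_prefers_smallest_order(self):
        picks = []
        for s in range(20):
            r = np.random.default_rng(2000 + s)
            picks.append(select_order(r.normal(size=(1500, 2)), max_order=6))
        assert np.bincount(picks).argmax() == 1

    def test_forced_single_order(self, rng):
        assert select_order(rng.normal(size=(500, 2)), max_order=1) == 1


class TestVarFit:
    def test_exact_linear_system_interpolated(self):
        X = np.zeros((200, 2))
        X[0] = [1.0, -1.0]
        A = np.array([[0.9, 0.0], [0.2, 0.8]])
        for t in range(1, 200):
            X[t] = A @ X[t - 1]
        fit = fit_var(X, 1)
        assert np.abs(fit.resid_cov).max() < 1e-20

    def test_var1_coefficients_recovered(self):
        A = np.array([[0.5, 0.0], [0.3, 0.4]])
        r = np.random.default_rng(3)
        X = np.zeros((5000, 2))
        for t in range(1, 5000):
            X[t] = A @ X[t - 1] + r.normal(size=2)
        fit = fit_var(X, 1)
        assert np.abs(fit.coef - A).max() < 0.05

    def test_variable_permutation_permutes_coefficient_blocks(self, rng):
        X = rng.normal(size=(400, 2)).cumsum(axis=0) * 0.01 + rng.normal(size=(400, 2))
        f_ab = fit_var(X, 2)
        f_ba = fit_var(X[:, ::-1], 2)
        # equation for variable 0 in one ordering is equation 1 in the other,
        # with lag blocks swapped pairwise
        perm = [1, 0, 3, 2]
        assert np.allclose(f_ab.coef, f_ba.coef[::-1][:, perm])

    def test_residual_covariance_psd_and_lengths(self, rng):
        X = rng.normal(size=(300, 3))
        fit = fit_var(X, 4)
        assert fit.resid.shape == (296, 3)
        eigs = np.linalg.eigvalsh(fit.resid_cov)
        assert eigs.min() > -1e-12


class TestGcF:
    def test_identical_models_give_zero(self, rng):
        X = rng.normal(size=(500, 2))
        fit = fit_var(X, 2)
        assert gc_f(fit, fit) == 0.0

    def test_nonnested_comparison_rejected(self, rng):
        X = rng.normal(size=(500, 2))
        small = fit_var(X, 1)
        # different effective samples -> refused
        with pytest.raises(ValueError):
            gc_f(small, fit_var(X, 2))

    def test_closed_form_ln2_value(self):
        Fs = np.array([pairwise_gc(GcInput(*ln2_system(8000, s)), m=1).F_x1_to_x2 for s in range(6)])
        se = Fs.std(ddof=1) / np.sqrt(len(Fs))
        assert abs(Fs.mean() - np.log(2)) < 4 * se + 0.01


class TestPairwise:
    def test_independent_series_give_near_zero_f_both_ways(self, rng):
        res = pairwise_gc(GcInput(rng.normal(size=4000), rng.normal(size=4000)), m=3)
        assert res.F_x1_to_x2 < 0.01 and res.F_x2_to_x1 < 0.01
        assert res.F_x1_to_x2 >= 0 and res.F_x2_to_x1 >= 0

    def test_directionality_of_ln2_system(self):
        res = pairwise_gc(GcInput(*ln2_system(20000, 17)), m=1)
        assert res.p_x1_to_x2 < 0.01
        assert res.p_x2_to_x1 > 0.05
        assert res.F_x2_to_x1 < 0.005

    def test_rescaling_series_leaves_f_invariant(self):
        x1, x2 = ln2_system(3000, 5)
        base = pairwise_gc(GcInput(x1, x2), m=2)
        scaled = pairwise_gc(GcInput(3.7 * x1, 0.2 * x2), m=2)
        assert abs(base.F_x1_to_x2 - scaled.F_x1_to_x2) < 1e-8
        assert abs(base.F_x2_to_x1 - scaled.F_x2_to_x1) < 1e-8

    def test_full_mediation_by_x3_kills_conditional_gc(self):
        # x1 -> x3 -> x2: conditioning on x3 removes x1's predictive power
        rng = np.random.default_rng(11)
        n = 8000
        x1 = rng.normal(size=n)
        x3 = np.zeros(n)
        x2 = np.zeros(n)
        x3[1:] = x1[:-1] + 0.1 * rng.normal(size=n - 1)
        x2[1:] = x3[:-1] + rng.normal(size=n - 1)
        unconditional = pairwise_gc(GcInput(x1, x2), m=2)
        conditional = pairwise_gc(GcInput(x1, x2, x3), m=2, condition_on_x3=True)
        assert unconditional.F_x1_to_x2 > 0.1
        assert conditional.F_x1_to_x2 < 0.01
        assert conditional.conditioned_on_x3

    def test_missing_x3_rejected_when_conditioning(self, rng):
        with pytest.raises(ValueError, match="x3"):
            pairwise_gc(GcInput(rng.normal(size=100), rng.normal(size=100)), m=2, condition_on_x3=True)


class TestPooled:
    def test_duplicating_one_dyad_preserves_f(self):
        x1, x2 = ln2_system(1500, 23)
        single = pooled_gc([GcInput(x1, x2)], m=2)
        dupl = pooled_gc([GcInput(x1, x2)] * 5, m=2)
        assert dupl.F_x1_to_x2 == pytest.approx(single.F_x1_to_x2, abs=1e-10)
        assert dupl.F_x2_to_x1 == pytest.approx(single.F_x2_to_x1, abs=1e-10)

    def test_single_dyad_pooling_matches_pairwise(self):
        x1, x2 = ln2_system(1500, 29)
        pooled = pooled_gc([GcInput(x1, x2)], m=3)
        pair = pairwise_gc(GcInput(x1, x2), m=3)
        assert pooled.F_x1_to_x2 == pytest.approx(pair.F_x1_to_x2)
        assert pooled.F_x2_to_x1 == pytest.approx(pair.F_x2_to_x1)

    def test_null_f_shrinks_as_dyads_accumulate(self):
        def null_f(k, seed):
            r = np.random.default_rng(seed)
            dyads = [GcInput(r.normal(size=710), r.normal(size=710)) for _ in range(k)]
            return pooled_gc(dyads, m=5).F_x1_to_x2

        few = np.median([null_f(1, s) for s in range(10)])
        many = np.median([null_f(8, 100 + s) for s in range(10)])
        assert many < few

    def test_inconsistent_lengths_rejected(self, rng):
        dyads = [
            GcInput(rng.normal(size=500), rng.normal(size=500)),
            GcInput(rng.normal(size=400), rng.normal(size=400)),
        ]
        with pytest.raises(ValueError, match="lengths"):
            pooled_gc(dyads, m=2)
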