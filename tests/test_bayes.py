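"""Bayesian coupling models: design building, sampling, LOO, ranking."""

import warnings

import numpy as np
import pandas as pd
import pytest

from socialfreeze.bayes import (
    Factor,
    FitResult,
    LooResult,
    ModelSpec,
    SamplerConfig,
    TermSpec,
    build_design,
    credible_interval,
    fit_model,
    psis_loo,
    rank_models,
)
from socialfreeze.bayes import _logmeanexp, _pointwise_loglik
from socialfreeze.models import indiv_dem_winning
from socialfreeze.synthetic import CohortDesign, gen_epoch_dataset

LIGHT = SamplerConfig(warmup=500, draws=750, seed=99)


def _fake_fit(spec, draw_map, nchain=2, ndraw=400, seed=0):
    """FitResult stub with prescribed posterior draw distributions."""
    rng = np.random.default_rng(seed)
    draws = {}
    for name, (mean, sd) in draw_map.items():
        draws[name] = mean + sd * rng.standard_normal((nchain, ndraw))
    cols = [n for n in draw_map if not n.startswith("sigma")]
    names = list(draw_map)
    return FitResult(
        param_names=names,
        draws=draws,
        rhat={n: 1.0 for n in names},
        converged=True,
        spec=spec,
        config=SamplerConfig(),
        column_names=cols,
    )


def _fake_loo(elpd, se, n=10):
    return LooResult(elpd_loo=elpd, se=se, pointwise=np.full(n, elpd / n), pareto_k=np.zeros(n))


class TestBuildDesign:
    def test_winning_model_term_evaluation(self, one_dyad_table):
        X, y = build_design(one_dyad_table, indiv_dem_winning())
        assert X.loc[0].tolist() == [0.0, 0.0]  # baseline row
        assert X.loc[1].tolist() == [1.0, 0.5]  # shock row gates the coupling
        assert y.tolist() == [0.02, 0.7]

    def test_complement_factor_is_one_minus_variable(self, one_dyad_table):
        spec = ModelSpec(
            "noshock",
            "freezing_obs",
            (TermSpec("strain_obs*noshock_dem", (Factor("strain_obs"), Factor("shock_dem", complement=True))),),
        )
        X, _ = build_design(one_dyad_table, spec)
        assert X.loc[0, "strain_obs*noshock_dem"] == 1.0
        assert X.loc[1, "strain_obs*noshock_dem"] == 0.0

    def test_per_week_split_isolates_the_dyads_group(self, one_dyad_table):
        spec = ModelSpec(
            "split",
            "freezing_dem",
            (
                TermSpec(
                    "freezing_obs*shock_dem",
                    (Factor("freezing_obs"), Factor("shock_dem")),
                    split_by="weeks",
                    split_levels=(0, 1, 3, 5),
                ),
            ),
        )
        X, _ = build_design(one_dyad_table, spec)
        shock_row = X.loc[1]
        assert shock_row["freezing_obs*shock_dem[weeks=3]"] == 0.5
        assert shock_row["freezing_obs*shock_dem[weeks=0]"] == 0.0
        assert shock_row["freezing_obs*shock_dem[weeks=5]"] == 0.0

    def test_missing_variable_rejected(self, one_dyad_table):
        spec = ModelSpec("bad", "freezing_dem", (TermSpec("x", (Factor("not_a_column"),)),))
        with pytest.raises(KeyError, match="not_a_column"):
            build_design(one_dyad_table, spec)

    def test_all_zero_column_warns(self, one_dyad_table):
        table = one_dyad_table.assign(freezing_obs=[0.0, 0.0])
        with pytest.warns(UserWarning, match="degenerate"):
            build_design(table, indiv_dem_winning())


class TestFitModel:
    def test_uninformative_design_returns_truncated_prior(self):
        # all-baseline data: the gated terms are identically zero, so the
        # posterior must match the (nearly flat) bounded prior
        table = pd.DataFrame(
            {
                "freezing_dem": np.full(20, 0.05),
                "freezing_obs": np.zeros(20),
                "shock_dem": np.zeros(20),
            }
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            X, y = build_design(table, indiv_dem_winning())
            fit = fit_model(X, y, indiv_dem_winning(), LIGHT)
        for name, (lo, hi) in (("shock_dem", (-1, 1)), ("freezing_obs*shock_dem", (-1.5, 1.5))):
            d = fit.flat(name)
            assert d.min() >= lo and d.max() <= hi
            assert abs(d.mean()) < 0.1
            # N(0,2) truncated to the bounds is nearly uniform
            expected_sd = (hi - lo) / np.sqrt(12)
            assert d.std() == pytest.approx(expected_sd, rel=0.15)

    def test_posterior_means_match_least_squares_oracle(self, rng):
        n = 400
        obs = rng.uniform(0, 1, n)
        shock = (np.arange(n) % 2).astype(float)
        X = pd.DataFrame({"shock_dem": shock, "freezing_obs*shock_dem": obs * shock})
        beta_true = np.array([0.45, 0.35])
        y = X.to_numpy() @ beta_true + 0.05 * rng.standard_normal(n)
        fit = fit_model(X, y, indiv_dem_winning(), LIGHT)
        ols = np.linalg.lstsq(X.to_numpy(), y, rcond=None)[0]
        for i, name in enumerate(X.columns):
            assert fit.flat(name).mean() == pytest.approx(ols[i], abs=0.02)

    def test_draws_respect_bounds_and_rhat_recorded(self):
        df = gen_epoch_dataset(CohortDesign(n_dyads=16, seed=4))
        X, y = build_design(df, indiv_dem_winning())
        fit = fit_model(X, y, indiv_dem_winning(), LIGHT)
        for name in fit.param_names:
            assert name in fit.rhat and np.isfinite(fit.rhat[name])
        b = fit.spec.column_bounds()
        for col, (lo, hi) in b.items():
            assert fit.flat(col).min() >= lo and fit.flat(col).max() <= hi
        assert fit.flat(fit.param_names[-1]).min() > 0  # residual SD positive

    def test_fixed_seed_reproducible(self):
        df = gen_epoch_dataset(CohortDesign(n_dyads=8, seed=4))
        X, y = build_design(df, indiv_dem_winning())
        f1 = fit_model(X, y, indiv_dem_winning(), LIGHT)
        f2 = fit_model(X, y, indiv_dem_winning(), LIGHT)
        assert np.array_equal(f1.flat("shock_dem"), f2.flat("shock_dem"))


@pytest.fixture(scope="module")
def fitted():
    df = gen_epoch_dataset(CohortDesign(n_dyads=16, seed=12))
    X, y = build_design(df, indiv_dem_winning())
    fit = fit_model(X, y, indiv_dem_winning(), LIGHT)
    return fit, X, y


class TestPsisLoo:
    def test_pointwise_contributions_sum_to_total(self, fitted):
        fit, X, y = fitted
        loo = psis_loo(fit, X, y)
        assert loo.pointwise.sum() == pytest.approx(loo.elpd_loo, abs=1e-6)
        assert loo.se >= 0

    def test_identical_models_score_identically_within_mc_error(self, fitted):
        fit, X, y = fitted
        a = psis_loo(fit, X, y)
        fit_b = fit_model(X, y, fit.spec, SamplerConfig(warmup=500, draws=750, seed=7))
        b = psis_loo(fit_b, X, y)
        assert abs(a.elpd_loo - b.elpd_loo) < 0.5

    def test_exact_leave_one_out_refits_agree_with_psis(self):
        # brute-force oracle on a 10-row dataset: refit without each point
        # and score it by its posterior predictive density
        rng = np.random.default_rng(6)
        obs = rng.uniform(0, 1, 5)
        X = pd.DataFrame(
            {
                "shock_dem": np.r_[np.zeros(5), np.ones(5)],
                "freezing_obs*shock_dem": np.r_[np.zeros(5), obs],
            }
        )
        y = X.to_numpy() @ [0.47, 0.37] + 0.1 * rng.standard_normal(10)
        spec = indiv_dem_winning()
        fit = fit_model(X, y, spec, LIGHT)
        loo = psis_loo(fit, X, y)
        exact = np.empty(10)
        for i in range(10):
            keep = np.arange(10) != i
            sub = fit_model(X[keep], y[keep], spec, SamplerConfig(warmup=500, draws=750, seed=50 + i))
            ll = _pointwise_loglik(sub, X.to_numpy()[[i]], y[[i]])
            exact[i] = _logmeanexp(ll.reshape(-1))
        assert np.abs(exact - loo.pointwise).max() < 0.1


class TestRanking:
    def spec_pair(self):
        full = indiv_dem_winning()
        simple = ModelSpec("simple", "freezing_dem", (TermSpec("shock_dem", (Factor("shock_dem"),)),))
        return full, simple

    def test_single_model_wins_trivially(self):
        full, _ = self.spec_pair()
        fit = _fake_fit(full, {"shock_dem": (0.5, 0.05), "freezing_obs*shock_dem": (0.3, 0.05), "sigma_dem": (0.1, 0.01)})
        table = rank_models([_fake_loo(40.0, 10.0)], [fit])
        assert table.winner == full.name

    def test_large_gap_wins_outright(self):
        # scores as in the published demonstrator table: -27.2 vs 41.5, SE 15.2
        full, simple = self.spec_pair()
        fit_full = _fake_fit(full, {"shock_dem": (0.47, 0.05), "freezing_obs*shock_dem": (0.37, 0.08), "sigma_dem": (0.12, 0.01)})
        fit_simple = _fake_fit(simple, {"shock_dem": (0.6, 0.05), "sigma_dem": (0.2, 0.02)})
        table = rank_models([_fake_loo(41.5, 15.2), _fake_loo(-27.2, 1.9)], [fit_full, fit_simple])
        assert table.winner == full.name
        # worst model first, best last
        assert table.table.model.tolist() == [simple.name, full.name]

    def test_within_one_se_extra_parameter_crossing_zero_prefers_simpler(self):
        full, simple = self.spec_pair()
        fit_full = _fake_fit(full, {"shock_dem": (0.5, 0.05), "freezing_obs*shock_dem": (0.01, 0.2), "sigma_dem": (0.12, 0.01)})
        fit_simple = _fake_fit(simple, {"shock_dem": (0.52, 0.05), "sigma_dem": (0.12, 0.01)})
        table = rank_models([_fake_loo(42.0, 15.0), _fake_loo(41.0, 14.0)], [fit_full, fit_simple])
        assert table.winner == simple.name
        assert any("include 0" in n for n in table.notes)

    def test_within_one_se_overlapping_split_prefers_unsplit(self):
        split_term = TermSpec(
            "freezing_obs*shock_dem",
            (Factor("freezing_obs"), Factor("shock_dem")),
            split_by="same_strain",
            split_levels=(1, 0),
        )
        split_spec = ModelSpec("split", "freezing_dem", (TermSpec("shock_dem", (Factor("shock_dem"),)), split_term))
        plain = indiv_dem_winning()
        fit_split = _fake_fit(
            split_spec,
            {
                "shock_dem": (0.3, 0.03),
                "freezing_obs*shock_dem[same_strain=1]": (0.46, 0.06),
                "freezing_obs*shock_dem[same_strain=0]": (0.35, 0.06),
                "sigma_dem": (0.09, 0.01),
            },
        )
        fit_plain = _fake_fit(plain, {"shock_dem": (0.3, 0.03), "freezing_obs*shock_dem": (0.40, 0.06), "sigma_dem": (0.09, 0.01)})
        table = rank_models([_fake_loo(110.0, 13.1), _fake_loo(108.8, 13.0)], [fit_split, fit_plain])
        assert table.winner == plain.name
        assert any("overlap" in n for n in table.notes)

    def test_mismatched_row_sets_rejected(self):
        full, simple = self.spec_pair()
        fit_full = _fake_fit(full, {"shock_dem": (0.5, 0.05), "freezing_obs*shock_dem": (0.3, 0.05), "sigma_dem": (0.1, 0.01)})
        fit_simple = _fake_fit(simple, {"shock_dem": (0.5, 0.05), "sigma_dem": (0.1, 0.01)})
        with pytest.raises(ValueError, match="row sets"):
            rank_models([_fake_loo(10, 2, n=10), _fake_loo(9, 2, n=12)], [fit_full, fit_simple])


def test_model_spec_yaml_round_trip(tmp_path):
    from socialfreeze.models import load_model_spec, save_model_spec, strain_familiarity_dem_models

    spec = strain_familiarity_dem_models()[-1]  # includes a split coupling term
    path = tmp_path / "spec.yaml"
    save_model_spec(spec, path)
    assert load_model_spec(path) == spec


class TestCredibleInterval:
    def test_symmetric_gaussian_draws(self):
        spec = indiv_dem_winning()
        fit = _fake_fit(spec, {"shock_dem": (0.5, 0.1), "freezing_obs*shock_dem": (0.3, 0.05), "sigma_dem": (0.1, 0.01)}, ndraw=20000)
        lo, hi = credible_interval(fit, "shock_dem", 95)
        assert lo == pytest.approx(0.304, abs=0.01)
        assert hi == pytest.approx(0.696, abs=0.01)

    def test_full_level_returns_range_and_constant_draws_zero_width(self):
        spec = indiv_dem_winning()
        fit = _fake_fit(spec, {"shock_dem": (0.5, 0.0), "freezing_obs*shock_dem": (0.3, 0.1), "sigma_dem": (0.1, 0.01)})
        assert credible_interval(fit, "shock_dem", 95) == (0.5, 0.5)
        d = fit.flat("freezing_obs*shock_dem")
        assert credible_interval(fit, "freezing_obs*shock_dem", 100) == (d.min(), d.max())

    def test_unknown_parameter_rejected(self):
        spec = indiv_dem_winning()
        fit = _fake_fit(spec, {"shock_dem": (0.5, 0.1), "freezing_obs*shock_dem": (0.3, 0.05), "sigma_dem": (0.1, 0.01)})
        with pytest.raises(KeyError):
            credible_interval(fit, "nope", 95)
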