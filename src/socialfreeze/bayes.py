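"""Bayesian linear coupling models for epoch-level dyad freezing.

Each model explains one animal's freezing proportion (two rows per dyad: a
baseline and a shock epoch) as a linear combination of products of epoch
covariates — most importantly partner-coupling terms such as
``Freezing_obs * Shock_dem``, which gate the partner's freezing by the
presence of shocks.  The likelihood is an unbounded Normal on the proportion
scale; coefficients get flat-ish Normal(0, 2) priors restricted to a bounded
interval ([-1, 1] by default, [-1.5, 1.5] for partner-coupling terms), and
the residual SD a half-Normal(0, 2) prior.

Posterior sampling uses an affine-invariant ensemble sampler (emcee), with
walkers treated as chains for the Rhat convergence diagnostic.  Models are
scored by PSIS-LOO (expected log pointwise predictive density, ``elpd_loo``)
and ranked; when the best model sits within one SE of a runner-up, the
winner is pruned by credibility-interval rules: a parameter stays only if
its 90% interval excludes 0, and a group-split (modulator) version is
preferred only if the 95% intervals of the split parameters do not overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

with warnings.catch_warnings():
    warnings.simplefilter("ignore", FutureWarning)
    import arviz as az
import emcee

__all__ = [
    "Factor",
    "TermSpec",
    "ModelSpec",
    "SamplerConfig",
    "FitResult",
    "LooResult",
    "ComparisonTable",
    "build_design",
    "fit_model",
    "psis_loo",
    "rank_models",
    "credible_interval",
]

DEFAULT_BOUNDS = (-1.0, 1.0)
COUPLING_BOUNDS = (-1.5, 1.5)
PRIOR_SD = 2.0
SIGMA_PRIOR_SD = 2.0
RHAT_THRESHOLD = 1.01


@dataclass(frozen=True)
class Factor:
    """One multiplicative factor: a data variable, optionally complemented
    (``1 - x``, e.g. NoShock = 1 - Shock)."""

    var: str
    complement: bool = False

    def label(self) -> str:
        return f"no_{self.var}" if self.complement else self.var


@dataclass(frozen=True)
class TermSpec:
    """A product term, optionally split into one column per group level."""

    name: str
    factors: tuple[Factor, ...]
    split_by: str | None = None
    split_levels: tuple | None = None
    bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.factors:
            raise ValueError(f"term {self.name!r} needs at least one factor")

    def column_names(self) -> list[str]:
        if self.split_by is None:
            return [self.name]
        return [f"{self.name}[{self.split_by}={lvl}]" for lvl in self.split_levels]


@dataclass(frozen=True)
class ModelSpec:
    """A declared linear model for one freezing target."""

    name: str
    target: str  # 'freezing_obs' or 'freezing_dem'
    terms: tuple[TermSpec, ...]
    bounds: tuple[float, float] = DEFAULT_BOUNDS
    prior_sd: float = PRIOR_SD

    def __post_init__(self) -> None:
        if self.target not in ("freezing_obs", "freezing_dem"):
            raise ValueError(f"unknown target {self.target!r}")
        names = [t.name for t in self.terms]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate terms in model {self.name!r}")
        lo, hi = self.bounds
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < 0 < hi):
            raise ValueError("coefficient bounds must be finite and contain 0")

    def column_bounds(self) -> dict[str, tuple[float, float]]:
        out = {}
        for t in self.terms:
            b = t.bounds if t.bounds is not None else self.bounds
            for col in t.column_names():
                out[col] = b
        return out


@dataclass
class SamplerConfig:
    """Ensemble-sampler settings.

    ``chains`` independent walker ensembles are run; each ensemble is one
    chain for the Rhat diagnostic, with its walkers' thinned trajectories
    pooled as that chain's draws.
    """

    chains: int = 4
    nwalkers: int = 10         # walkers per ensemble
    warmup: int = 1000
    draws: int = 1000          # post-warmup steps per walker
    thin: int = 5
    seed: int = 0
    rhat_threshold: float = RHAT_THRESHOLD


@dataclass
class FitResult:
    """Posterior draws (chain x draw per parameter) plus diagnostics."""

    param_names: list[str]
    draws: dict[str, np.ndarray]
    rhat: dict[str, float]
    converged: bool
    spec: ModelSpec
    config: SamplerConfig
    column_names: list[str]

    @property
    def n_draws(self) -> int:
        first = next(iter(self.draws.values()))
        return first.size

    def flat(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)


@dataclass
class LooResult:
    elpd_loo: float
    se: float
    pointwise: np.ndarray
    pareto_k: np.ndarray
    n_refit: int = 0

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("SE must be >= 0")


@dataclass
class ComparisonTable:
    table: pd.DataFrame          # ordered worst -> best (ascending elpd)
    winner: str
    notes: list[str] = field(default_factory=list)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _variable(df: pd.DataFrame, factor: Factor) -> np.ndarray:
    if factor.var in ("intercept", "const", "1"):
        x = np.ones(len(df))
    else:
        if factor.var not in df.columns:
            raise KeyError(f"model variable {factor.var!r} not found in the data table")
        x = df[factor.var].to_numpy(dtype=float)
    return 1.0 - x if factor.complement else x


def build_design(data: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Evaluate the model's terms into a design matrix and response vector.

    Product terms multiply their factors elementwise; complemented factors
    use ``1 - x``; split terms contribute one column per group level, zero
    outside that group.
    """
    if spec.target not in data.columns:
        raise KeyError(f"target {spec.target!r} not found in the data table")
    cols: dict[str, np.ndarray] = {}
    for term in spec.terms:
        base = np.ones(len(data))
        for f in term.factors:
            base = base * _variable(data, f)
        if term.split_by is None:
            cols[term.name] = base
        else:
            if term.split_by not in data.columns:
                raise KeyError(f"split variable {term.split_by!r} not in the data table")
            g = data[term.split_by].to_numpy()
            for lvl, col in zip(term.split_levels, term.column_names()):
                cols[col] = base * (g == lvl)
    X = pd.DataFrame(cols, index=data.index)
    degenerate = [c for c in X.columns if not np.any(X[c].to_numpy())]
    if degenerate:
        warnings.warn(f"degenerate design: all-zero columns {degenerate}")
    y = data[spec.target].to_numpy(dtype=float)
    return X, y


def _log_posterior_factory(X, y, lo, hi, prior_sd, sigma_prior_sd):
    n = y.size

    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        beta = theta[:, :-1]
        sigma = theta[:, -1]
        lp = np.full(theta.shape[0], -np.inf)
        ok = (sigma > 0) & np.all((beta >= lo) & (beta <= hi), axis=1)
        if not ok.any():
            return lp
        b = beta[ok]
        s = sigma[ok]
        resid = y[None, :] - b @ X.T
        loglik = -0.5 * n * np.log(2 * np.pi * s**2) - np.sum(resid**2, axis=1) / (2 * s**2)
        logprior = -0.5 * np.sum((b / prior_sd) ** 2, axis=1) - 0.5 * (s / sigma_prior_sd) ** 2
        lp[ok] = loglik + logprior
        return lp

    return log_prob


def fit_model(
    design: pd.DataFrame | np.ndarray,
    response: np.ndarray,
    spec: ModelSpec,
    config: SamplerConfig | None = None,
) -> FitResult:
    """Sample the posterior of the bounded linear model.

    Parameters are the term coefficients plus the residual SD (named
    ``sigma_dem`` or ``sigma_obs`` after the target).  Non-convergence (any
    Rhat above the threshold) flags the result; it is never silent.
    """
    config = config or SamplerConfig()
    if isinstance(design, pd.DataFrame):
        colnames = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        colnames = [f"beta{i}" for i in range(X.shape[1])]
    y = np.asarray(response, dtype=float)
    if X.shape[0] != y.size:
        raise ValueError("design and response have mismatched row counts")
    ndim = X.shape[1] + 1
    bounds_map = spec.column_bounds() if colnames and colnames[0] in spec.column_bounds() else {}
    lo = np.array([bounds_map.get(c, spec.bounds)[0] for c in colnames])
    hi = np.array([bounds_map.get(c, spec.bounds)[1] for c in colnames])
    sigma_name = "sigma_dem" if spec.target == "freezing_dem" else "sigma_obs"
    param_names = colnames + [sigma_name]

    log_prob = _log_posterior_factory(X, y, lo, hi, spec.prior_sd, SIGMA_PRIOR_SD)
    nwalkers = max(config.nwalkers, 2 * ndim + 2)
    nwalkers += nwalkers % 2

    # start near the ridge-regularised least-squares solution, inside bounds
    if X.shape[1] > 0 and np.any(X):
        XtX = X.T @ X + 1e-8 * np.eye(X.shape[1])
        beta0 = np.linalg.solve(XtX, X.T @ y)
    else:
        beta0 = np.zeros(X.shape[1])
    beta0 = np.clip(beta0, lo + 0.05 * (hi - lo), hi - 0.05 * (hi - lo))
    resid0 = y - X @ beta0 if X.shape[1] else y
    sigma0 = max(float(np.std(resid0)), 0.02)
    center = np.concatenate([beta0, [sigma0]])

    chain_draws = []
    for chain_idx in range(config.chains):
        chain_seed = (config.seed * 1000003 + chain_idx) % (2**32)
        rng = np.random.default_rng(chain_seed)
        p0 = center[None, :] + 0.02 * rng.standard_normal((nwalkers, ndim))
        p0[:, :-1] = np.clip(p0[:, :-1], lo + 1e-6, hi - 1e-6)
        p0[:, -1] = np.abs(p0[:, -1]) + 1e-3
        sampler = emcee.EnsembleSampler(nwalkers, ndim, log_prob, vectorize=True)
        sampler.random_state = np.random.RandomState(chain_seed).get_state()
        state = sampler.run_mcmc(p0, config.warmup, progress=False)
        sampler.reset()
        sampler.run_mcmc(state, config.draws, progress=False)
        c = sampler.get_chain(thin=config.thin)      # (steps, walkers, ndim)
        chain_draws.append(c.reshape(-1, ndim))      # step-major flatten
    chain = np.stack(chain_draws)                    # (chains, draws, ndim)

    draws = {name: chain[:, :, i] for i, name in enumerate(param_names)}
    idata = az.from_dict(posterior=draws)
    rhat_ds = az.rhat(idata)
    rhat = {name: float(rhat_ds[name].values) for name in param_names}
    converged = all(np.isfinite(v) and v <= config.rhat_threshold for v in rhat.values())
    if not converged:
        warnings.warn(
            f"model {spec.name!r}: Rhat above {config.rhat_threshold} for "
            f"{[k for k, v in rhat.items() if not (v <= config.rhat_threshold)]}"
        )
    return FitResult(
        param_names=param_names,
        draws=draws,
        rhat=rhat,
        converged=converged,
        spec=spec,
        config=config,
        column_names=colnames,
    )


def _pointwise_loglik(fit: FitResult, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """(chain, draw, obs) pointwise Normal log likelihood."""
    sigma_name = fit.param_names[-1]
    beta = np.stack([fit.draws[c] for c in fit.column_names], axis=-1)  # (c, d, p)
    sigma = fit.draws[sigma_name]  # (c, d)
    mu = beta @ X.T if X.shape[1] else np.zeros(beta.shape[:2] + (y.size,))
    resid = y[None, None, :] - mu
    return (
        -0.5 * np.log(2 * np.pi * sigma[..., None] ** 2)
        - resid**2 / (2 * sigma[..., None] ** 2)
    )


def _logmeanexp(a: np.ndarray) -> float:
    m = np.max(a)
    return float(m + np.log(np.mean(np.exp(a - m))))


def psis_loo(
    fit: FitResult,
    design: pd.DataFrame | np.ndarray,
    response: np.ndarray,
    refit_threshold: float = 0.7,
    max_refits: int = 10,
) -> LooResult:
    """Pointwise out-of-sample predictive density via PSIS-LOO.

    Points whose Pareto tail diagnostic exceeds ``refit_threshold`` are
    re-scored by an exact leave-one-out refit (up to ``max_refits`` of them;
    beyond that a warning is emitted and the smoothed estimate kept).
    """
    X = design.to_numpy(dtype=float) if isinstance(design, pd.DataFrame) else np.asarray(design, float)
    y = np.asarray(response, dtype=float)
    ll = _pointwise_loglik(fit, X, y)
    if fit.n_draws < 100:
        raise ValueError("too few posterior draws for Pareto tail fitting")
    idata = az.from_dict(posterior=fit.draws, log_likelihood={"y": ll})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = az.loo(idata, pointwise=True)
    pointwise = np.asarray(res.loo_i.values, dtype=float)
    pareto_k = np.asarray(res.pareto_k.values, dtype=float)

    bad = np.flatnonzero(pareto_k > refit_threshold)
    n_refit = 0
    if bad.size > max_refits:
        warnings.warn(
            f"{bad.size} points exceed pareto-k {refit_threshold}; refitting only {max_refits}"
        )
        bad = bad[:max_refits]
    for i in bad:
        keep = np.ones(y.size, dtype=bool)
        keep[i] = False
        sub_design = X[keep]
        sub_fit = fit_model(
            pd.DataFrame(sub_design, columns=fit.column_names),
            y[keep],
            fit.spec,
            replace(fit.config, seed=fit.config.seed + 1000 + int(i)),
        )
        ll_i = _pointwise_loglik(sub_fit, X[[i]], y[[i]])
        pointwise[i] = _logmeanexp(ll_i.reshape(-1))
        n_refit += 1

    elpd = float(np.sum(pointwise))
    se = float(np.sqrt(y.size * np.var(pointwise)))
    return LooResult(elpd_loo=elpd, se=se, pointwise=pointwise, pareto_k=pareto_k, n_refit=n_refit)


def credible_interval(fit: FitResult, parameter: str, level: float = 95.0) -> tuple[float, float]:
    """Central posterior quantile interval at ``level`` percent."""
    if parameter not in fit.draws:
        raise KeyError(f"parameter {parameter!r} not in fit ({fit.param_names})")
    x = fit.flat(parameter)
    if level >= 100:
        return float(x.min()), float(x.max())
    alpha = (100.0 - level) / 200.0
    return float(np.quantile(x, alpha)), float(np.quantile(x, 1 - alpha))


def _term_cols(spec: ModelSpec) -> dict[str, list[str]]:
    return {t.name: t.column_names() for t in spec.terms}


def _find_split_relation(a: ModelSpec, b: ModelSpec):
    """If spec ``a`` equals ``b`` except one term of ``a`` is a group-split
    of a plain term of ``b``, return (split term in a, plain term in b)."""
    only_a = [t for t in a.terms if t not in b.terms]
    only_b = [t for t in b.terms if t not in a.terms]
    if len(only_a) == 1 and len(only_b) == 1:
        ta, tb = only_a[0], only_b[0]
        if ta.split_by is not None and tb.split_by is None and set(ta.factors) == set(tb.factors):
            return ta, tb
    return None


def rank_models(
    loos: list[LooResult],
    fits: list[FitResult],
    ci_inclusion_level: float = 90.0,
    ci_modulator_level: float = 95.0,
) -> ComparisonTable:
    """Rank models by elpd_loo (ascending, worst first) and pick the winner.

    The top model wins outright when its elpd lead over every runner-up
    exceeds its own SE.  Otherwise runners-up within one SE are compared
    pairwise against the top: a nested simpler model replaces it when the
    extra parameters' inclusion-level intervals all include 0, and a
    group-split (modulator) model is preferred over its plain counterpart
    only when the split parameters' intervals do not overlap.
    """
    if len(loos) != len(fits) or not loos:
        raise ValueError("need one LooResult per FitResult, at least one model")
    npoints = {loo.pointwise.size for loo in loos}
    if len(npoints) > 1:
        raise ValueError(f"models scored on different row sets: {sorted(npoints)}")
    names = [f.spec.name for f in fits]
    if len(set(names)) != len(names):
        raise ValueError("duplicate model names")
    order = np.argsort([loo.elpd_loo for loo in loos])
    table = pd.DataFrame(
        {
            "model": [names[i] for i in order],
            "elpd_loo": [loos[i].elpd_loo for i in order],
            "se": [loos[i].se for i in order],
            "n_params": [len(fits[i].param_names) - 1 for i in order],
            "converged": [fits[i].converged for i in order],
        }
    )
    notes: list[str] = []
    top_i = int(order[-1])
    winner = names[top_i]
    top_loo, top_fit = loos[top_i], fits[top_i]

    for j in order[:-1][::-1]:  # runners-up, best first
        j = int(j)
        gap = top_loo.elpd_loo - loos[j].elpd_loo
        if gap > top_loo.se:
            break
        runner_fit = fits[j]
        notes.append(f"{runner_fit.spec.name} within 1 SE of {top_fit.spec.name} (gap {gap:.2f})")
        # modulator rule: split vs plain versions of the same term
        rel = _find_split_relation(top_fit.spec, runner_fit.spec)
        if rel is not None:
            split_term, _ = rel
            cis = [
                credible_interval(top_fit, c, ci_modulator_level)
                for c in split_term.column_names()
            ]
            overlap = any(
                a[0] <= b[1] and b[0] <= a[1]
                for i, a in enumerate(cis)
                for b in cis[i + 1 :]
            )
            if overlap:
                winner = runner_fit.spec.name
                notes.append(
                    f"modulator {split_term.name!r} split intervals overlap; "
                    f"prefer plain {winner}"
                )
                break
            continue
        # nested rule: runner simpler, top's extra parameters cross 0?
        top_cols = set(top_fit.column_names)
        run_cols = set(runner_fit.column_names)
        if run_cols < top_cols:
            extra = sorted(top_cols - run_cols)
            crossing = [
                c
                for c in extra
                if credible_interval(top_fit, c, ci_inclusion_level)[0] <= 0
                <= credible_interval(top_fit, c, ci_inclusion_level)[1]
            ]
            if crossing and len(crossing) == len(extra):
                winner = runner_fit.spec.name
                notes.append(
                    f"extra parameters {crossing} include 0 at {ci_inclusion_level}%; "
                    f"prefer simpler {winner}"
                )
                break
    return ComparisonTable(table=table, winner=winner, notes=notes)


def coefficient_summary(fit: FitResult, level: float = 95.0) -> pd.DataFrame:
    """Posterior mean and central interval per parameter (table layout)."""
    rows = []
    for name in fit.param_names:
        lo, hi = credible_interval(fit, name, level)
        rows.append(
            {
                "parameter": name,
                "mean": float(fit.flat(name).mean()),
                f"ci{level:g}_low": lo,
                f"ci{level:g}_high": hi,
                "rhat": fit.rhat[name],
            }
        )
    return pd.DataFrame(rows)
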