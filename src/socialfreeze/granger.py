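"""Bidirectional (optionally conditional) Granger causality on freezing series.

The second-by-second binary freezing series of the two animals (demonstrator
``x1``, observer ``x2``) are smoothed with a narrow Gaussian kernel and
modelled with vector autoregressions.  The Granger statistic in a given
direction is the log ratio of the residual variance of the reduced model
(target's own history, plus any conditioning covariate) to that of the full
model (adding the source's history),

    F(x1 -> x2) = ln( var(eps_reduced) / var(eps_full) ),

which is non-negative for nested least squares and has a natural
information-rate interpretation.  Significance uses the likelihood-ratio
null ``(n_eff - k_full) * F ~ chi2(m)`` — one degree of freedom per zeroed
lag coefficient, with the residual-dof multiplier that keeps the test
calibrated at epoch-length samples.  A binary jump indicator can be
conditioned on by
letting its lags enter both the full and the reduced model.

Dyads can be analysed one at a time or pooled: pooling stacks the per-dyad
lagged design matrices block-wise so that no lag window ever crosses a dyad
boundary, and fits a single model over all blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.tsa.stattools import adfuller

from .ethogram import FreezingSeries

__all__ = [
    "GcInput",
    "VarFit",
    "GcResult",
    "StationarityVerdict",
    "smooth_series",
    "check_stationarity",
    "select_order",
    "fit_var",
    "gc_f",
    "pairwise_gc",
    "pooled_gc",
]


@dataclass
class GcInput:
    """Preprocessed series for one dyad: x1/x2 (and optional covariate x3)."""

    x1: np.ndarray
    x2: np.ndarray
    x3: np.ndarray | None = None
    dyad_id: str = ""

    def __post_init__(self) -> None:
        self.x1 = np.asarray(self.x1, dtype=float)
        self.x2 = np.asarray(self.x2, dtype=float)
        if self.x1.shape != self.x2.shape or self.x1.ndim != 1:
            raise ValueError("x1 and x2 must be 1-D series of equal length")
        if self.x3 is not None:
            self.x3 = np.asarray(self.x3, dtype=float)
            if self.x3.shape != self.x1.shape:
                raise ValueError("x3 must match x1/x2 in length")
        for name in ("x1", "x2", "x3"):
            v = getattr(self, name)
            if v is not None and not np.isfinite(v).all():
                raise ValueError(f"{name} contains non-finite values")

    @property
    def n(self) -> int:
        return self.x1.size


@dataclass
class VarFit:
    """Least-squares VAR fit: Y[t] = sum_i A(i) Y[t-i] (+ intercept)."""

    order: int
    coef: np.ndarray          # (k, k*m [+1]) per-equation coefficient rows
    resid: np.ndarray         # (n_eff, k)
    resid_cov: np.ndarray     # (k, k), normalised by n_eff
    n_eff: int
    intercept: bool


@dataclass
class GcResult:
    F_x1_to_x2: float
    F_x2_to_x1: float
    p_x1_to_x2: float
    p_x2_to_x1: float
    order: int
    mode: str
    n_eff: int
    conditioned_on_x3: bool = False


@dataclass
class StationarityVerdict:
    statistic: float
    pvalue: float
    passed: bool
    degenerate: bool = False


def smooth_series(
    series, window_s: int = 300, sigma: float = 1.5
) -> np.ndarray:
    """Gaussian smoothing: normalized kernel of SD ``sigma`` samples,
    truncated to ``window_s`` samples, reflected edges, length preserved."""
    values = series.values if isinstance(series, FreezingSeries) else np.asarray(series, float)
    values = values.astype(float)
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if window_s > values.size:
        raise ValueError(f"kernel window ({window_s}) longer than series ({values.size})")
    radius = max(1, window_s // 2)
    taps = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (taps / sigma) ** 2)
    kernel /= kernel.sum()
    pad = min(radius, values.size - 1)
    padded = np.pad(values, radius, mode="reflect") if pad == radius else np.pad(
        values, radius, mode="symmetric"
    )
    return np.convolve(padded, kernel, mode="valid")


def check_stationarity(series, max_order: int = 21) -> StationarityVerdict:
    """Augmented Dickey-Fuller unit-root screen.

    Non-rejection yields a warning verdict (``passed=False``), not an error:
    short behavioral epochs are screened, never discarded automatically.
    """
    values = series.values if isinstance(series, FreezingSeries) else np.asarray(series, float)
    if values.size <= 3 * max_order:
        raise ValueError("series too short for the stationarity screen")
    if np.ptp(values) == 0:
        return StationarityVerdict(np.nan, np.nan, passed=False, degenerate=True)
    stat, pvalue, *_ = adfuller(values, autolag="AIC")
    return StationarityVerdict(float(stat), float(pvalue), passed=pvalue < 0.05)


def _lag_matrix(X: np.ndarray, m: int, rows: slice | None = None) -> np.ndarray:
    """Stack lags 1..m of the (n, k) matrix X into an (n - m, k*m) design."""
    n = X.shape[0]
    cols = [X[m - i : n - i] for i in range(1, m + 1)]
    Z = np.hstack(cols)
    return Z


def fit_var(X: np.ndarray, m: int, intercept: bool = False) -> VarFit:
    """Least-squares VAR(m) on the columns of the (n, k) series matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if m < 1:
        raise ValueError("order m must be >= 1")
    if n <= m * k + 1:
        raise ValueError(f"series too short (n={n}) for VAR({m}) in {k} variables")
    Z = _lag_matrix(X, m)
    if intercept:
        Z = np.hstack([Z, np.ones((Z.shape[0], 1))])
    Y = X[m:]
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        raise np.linalg.LinAlgError(
            f"rank-deficient lag matrix (rank {rank} < {Z.shape[1]} columns)"
        )
    B, *_ = np.linalg.lstsq(Z, Y, rcond=None)
    E = Y - Z @ B
    n_eff = E.shape[0]
    cov = E.T @ E / n_eff
    return VarFit(order=m, coef=B.T, resid=E, resid_cov=cov, n_eff=n_eff, intercept=intercept)


def select_order(X: np.ndarray, max_order: int, intercept: bool = False) -> int:
    """AIC order selection on a common effective sample (rows max_order..n).

    AIC(m) = n_eff * ln det(Sigma(m)) + 2 * k_params, with Sigma the residual
    covariance of the VAR(m) fitted on rows max_order..n.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    if max_order >= n / 3:
        raise ValueError("max_order must be < n/3")
    best_m, best_aic = None, np.inf
    Y = X[max_order:]
    n_eff = Y.shape[0]
    full_Z = _lag_matrix(X, max_order)
    for m in range(1, max_order + 1):
        Z = full_Z[:, : k * m]
        if intercept:
            Z = np.hstack([Z, np.ones((n_eff, 1))])
        try:
            B, *_ = np.linalg.lstsq(Z, Y, rcond=None)
        except np.linalg.LinAlgError:
            continue
        E = Y - Z @ B
        cov = E.T @ E / n_eff
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0:
            continue
        k_params = Z.shape[1] * k
        aic = n_eff * logdet + 2 * k_params
        if aic < best_aic:
            best_m, best_aic = m, aic
    if best_m is None:
        raise np.linalg.LinAlgError("singular fits at every candidate order")
    return best_m


def gc_f(full: VarFit, reduced: VarFit, target: int = 0) -> float:
    """Granger F = ln(var(eps_reduced) / var(eps_full)) for one target
    equation (determinant ratio if ``target`` selects several equations)."""
    if full.n_eff != reduced.n_eff:
        raise ValueError("full and reduced fits use different effective samples")
    if reduced.coef.shape[1] > full.coef.shape[1]:
        raise ValueError("reduced model must be nested in the full model")
    idx = np.atleast_1d(target)
    if idx.size == 1:
        i = int(idx[0])
        v_full = full.resid_cov[i, i]
        v_red = reduced.resid_cov[i, i]
        if v_full <= 0:
            raise ZeroDivisionError("degenerate full-model residual variance")
        return float(np.log(v_red / v_full))
    sf, ldf = np.linalg.slogdet(full.resid_cov[np.ix_(idx, idx)])
    sr, ldr = np.linalg.slogdet(reduced.resid_cov[np.ix_(idx, idx)])
    if sf <= 0 or sr <= 0:
        raise ZeroDivisionError("degenerate residual covariance")
    return float(ldr - ldf)


def _direction_f(X_target, X_source, X_cond, m, intercept):
    """One-directional conditional GC via explicit full/reduced regressions.

    The target's own lags (and the covariate's, if any) are in both models;
    the source's lags only in the full model.  Effective sample rows m..n.
    """
    n = X_target.size
    y = X_target[m:]
    own = _lag_matrix(X_target[:, None], m)
    src = _lag_matrix(X_source[:, None], m)
    parts_red = [own]
    if X_cond is not None:
        parts_red.append(_lag_matrix(X_cond[:, None], m))
    if intercept:
        parts_red.append(np.ones((n - m, 1)))
    Z_red = np.hstack(parts_red)
    Z_full = np.hstack([Z_red, src])
    b_red, *_ = np.linalg.lstsq(Z_red, y, rcond=None)
    b_full, *_ = np.linalg.lstsq(Z_full, y, rcond=None)
    rss_red = float(np.sum((y - Z_red @ b_red) ** 2))
    rss_full = float(np.sum((y - Z_full @ b_full) ** 2))
    n_eff = y.size
    if rss_full <= 0:
        # perfectly interpolated target: causality statistic undefined/infinite
        return np.inf, 0.0, n_eff
    F = np.log(rss_red / rss_full)
    F = max(F, 0.0) if F > -1e-10 else F
    # likelihood-ratio null with the usual residual-dof multiplier, which
    # keeps the test calibrated at behavioral-epoch sample sizes
    p = float(stats.chi2.sf((n_eff - Z_full.shape[1]) * F, df=m))
    return float(F), p, n_eff


def pairwise_gc(
    gc_input: GcInput,
    m: int | str = "auto",
    condition_on_x3: bool = False,
    max_order: int = 30,
    intercept: bool = False,
    demean: bool = True,
) -> GcResult:
    """Bidirectional (conditional) Granger causality for one dyad at a single
    shared order ``m`` (AIC-selected when ``m='auto'``).

    Each series is demeaned first by default: freezing series are far from
    zero-mean, and without centering (or an intercept) the partner's lags
    act as extra estimates of the target's mean, inflating F even for
    independent series.
    """
    x1, x2 = gc_input.x1, gc_input.x2
    x3 = gc_input.x3 if (condition_on_x3 and gc_input.x3 is not None) else None
    if condition_on_x3 and gc_input.x3 is None:
        raise ValueError("condition_on_x3 requested but no x3 covariate provided")
    if demean:
        x1 = x1 - x1.mean()
        x2 = x2 - x2.mean()
        x3 = x3 - x3.mean() if x3 is not None else None
    if m == "auto":
        cols = [x1, x2] + ([x3] if x3 is not None else [])
        m = select_order(np.column_stack(cols), max_order=max_order, intercept=intercept)
    m = int(m)
    F12, p12, n_eff = _direction_f(x2, x1, x3, m, intercept)
    F21, p21, _ = _direction_f(x1, x2, x3, m, intercept)
    return GcResult(
        F_x1_to_x2=F12,
        F_x2_to_x1=F21,
        p_x1_to_x2=p12,
        p_x2_to_x1=p21,
        order=m,
        mode="per-dyad",
        n_eff=n_eff,
        conditioned_on_x3=x3 is not None,
    )


def _pooled_direction_f(dyads, src_attr, tgt_attr, m, condition, intercept):
    """Stacked block-lagged full/reduced regressions across dyads."""
    ys, Zr, Zf = [], [], []
    for d in dyads:
        y_series = getattr(d, tgt_attr)
        x_series = getattr(d, src_attr)
        n = y_series.size
        y = y_series[m:]
        own = _lag_matrix(y_series[:, None], m)
        src = _lag_matrix(x_series[:, None], m)
        parts = [own]
        if condition:
            parts.append(_lag_matrix(d.x3[:, None], m))
        if intercept:
            parts.append(np.ones((n - m, 1)))
        red = np.hstack(parts)
        ys.append(y)
        Zr.append(red)
        Zf.append(np.hstack([red, src]))
    y = np.concatenate(ys)
    Z_red = np.vstack(Zr)
    Z_full = np.vstack(Zf)
    b_red, *_ = np.linalg.lstsq(Z_red, y, rcond=None)
    b_full, *_ = np.linalg.lstsq(Z_full, y, rcond=None)
    rss_red = float(np.sum((y - Z_red @ b_red) ** 2))
    rss_full = float(np.sum((y - Z_full @ b_full) ** 2))
    n_eff = y.size
    if rss_full <= 0:
        return np.inf, 0.0, n_eff
    F = np.log(rss_red / rss_full)
    F = max(F, 0.0) if F > -1e-10 else F
    p = float(stats.chi2.sf((n_eff - Z_full.shape[1]) * F, df=m))
    return float(F), p, n_eff


def pooled_gc(
    dyads: list[GcInput],
    m: int | str = "auto",
    condition_on_x3: bool = False,
    max_order: int = 30,
    intercept: bool = False,
    demean: bool = True,
) -> GcResult:
    """One Granger model over all dyads (block-wise lag construction).

    Lag windows never cross dyad boundaries: each dyad contributes its own
    lagged block and the blocks are stacked into a single regression.  The
    order is AIC-selected on the pooled sample when ``m='auto'``.  Series
    are demeaned per dyad and per variable by default (see
    :func:`pairwise_gc`), which also removes between-dyad level differences
    that would otherwise masquerade as temporal coupling.
    """
    if not dyads:
        raise ValueError("no dyads to pool")
    lengths = {d.n for d in dyads}
    if len(lengths) > 1:
        raise ValueError(f"inconsistent dyad lengths: {sorted(lengths)}")
    condition = condition_on_x3
    if condition and any(d.x3 is None for d in dyads):
        raise ValueError("condition_on_x3 requested but some dyads lack x3")
    if demean:
        dyads = [
            GcInput(
                d.x1 - d.x1.mean(),
                d.x2 - d.x2.mean(),
                d.x3 - d.x3.mean() if d.x3 is not None else None,
                dyad_id=d.dyad_id,
            )
            for d in dyads
        ]
    if m == "auto":
        m = _pooled_select_order(dyads, max_order, condition, intercept)
    m = int(m)
    F12, p12, n_eff = _pooled_direction_f(dyads, "x1", "x2", m, condition, intercept)
    F21, p21, _ = _pooled_direction_f(dyads, "x2", "x1", m, condition, intercept)
    return GcResult(
        F_x1_to_x2=F12,
        F_x2_to_x1=F21,
        p_x1_to_x2=p12,
        p_x2_to_x1=p21,
        order=m,
        mode="pooled",
        n_eff=n_eff,
        conditioned_on_x3=condition,
    )


def _pooled_select_order(dyads, max_order, condition, intercept):
    """AIC over the stacked bivariate (or trivariate) VAR, blocks never
    crossing dyad boundaries, common effective sample rows max_order..n."""
    k = 3 if condition else 2
    Ys, Zs = [], []
    for d in dyads:
        cols = [d.x1, d.x2] + ([d.x3] if condition else [])
        X = np.column_stack(cols)
        Ys.append(X[max_order:])
        Zs.append(_lag_matrix(X, max_order))
    Y = np.vstack(Ys)
    Zfull = np.vstack(Zs)
    n_eff = Y.shape[0]
    best_m, best_aic = None, np.inf
    for m in range(1, max_order + 1):
        Z = Zfull[:, : k * m]
        if intercept:
            Z = np.hstack([Z, np.ones((n_eff, 1))])
        B, *_ = np.linalg.lstsq(Z, Y, rcond=None)
        E = Y - Z @ B
        sign, logdet = np.linalg.slogdet(E.T @ E / n_eff)
        if sign <= 0:
            continue
        aic = n_eff * logdet + 2 * Z.shape[1] * k
        if aic < best_aic:
            best_m, best_aic = m, aic
    if best_m is None:
        raise np.linalg.LinAlgError("singular pooled fits at every candidate order")
    return best_m
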