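"""Signal-detection simulation of socially informed danger detection.

Two threshold agents watch a periodic boxcar danger cue through independent
Gaussian sensory noise and decide, sample by sample, whether to freeze.  In
the *social* variant each agent additionally weighs the partner's freezing
decision from the previous sample by a coupling factor ``b``; with a noise
ratio ``r > 1`` animal 1 receives ``r`` times noisier input and pays
proportionally more attention to the partner (weight ``b``) while the
better-informed animal 2 down-weights it to ``b / r``.

Detection performance is scored with ROC analysis: the decision threshold
``c`` is swept over ``[-5*sigma, +5*sigma]``, each threshold is an
independent simulation with fresh noise, and the hit rate (freezing while
the cue is on) is traded off against the false-alarm rate (freezing while it
is off).  The area under the ROC curve (AUC) summarises accuracy, and the
benefit of coupling is expressed as the performance gain
``(AUC_social - AUC_individual) / (AUC_individual - 0.5)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DangerSignal",
    "SimParams",
    "AgentTrace",
    "GainGrid",
    "gen_danger",
    "simulate_individual",
    "simulate_coupled",
    "roc_auc",
    "performance_gain",
    "grid_sweep",
]


@dataclass(frozen=True)
class DangerSignal:
    """Deterministic on/off danger cue, on-first."""

    values: np.ndarray
    on_len: int
    off_len: int
    cycles: int

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.values.size


@dataclass
class SimParams:
    """Configuration for a ROC sweep / gain-grid simulation.

    sigma is the sensory noise SD of the reference (less noisy) animal;
    with noise ratio r >= 1 animal 1 experiences ``r * sigma``.
    """

    sigma: float = 1.0
    b: float = 0.0
    r: float = 1.0
    threshold_grid: int = 101
    reps: int = 20
    seed: int | None = None
    redraw_noise: bool = True
    f_init: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.b < 0:
            raise ValueError("coupling b must be >= 0")
        if self.r < 1:
            raise ValueError("noise ratio r must be >= 1 (animal1 is the noisier one)")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.threshold_grid < 2:
            raise ValueError("threshold grid needs at least 2 points")


@dataclass(frozen=True)
class AgentTrace:
    """Internal signal and freezing decisions of one simulated animal."""

    x: np.ndarray
    f: np.ndarray
    role: str


@dataclass
class GainGrid:
    """Median performance-gain and AUC surfaces over a (sigma, b) grid."""

    sigma_grid: np.ndarray
    b_grid: np.ndarray
    r: float
    median_gain: dict[str, np.ndarray] = field(default_factory=dict)
    median_auc_social: dict[str, np.ndarray] = field(default_factory=dict)
    median_auc_individual: dict[str, np.ndarray] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (sigma, b, focal) cell."""
        rows = []
        for focal in self.median_gain:
            for i, s in enumerate(self.sigma_grid):
                for j, b in enumerate(self.b_grid):
                    rows.append(
                        {
                            "sigma": s,
                            "b": b,
                            "r": self.r,
                            "focal": focal,
                            "median_gain": self.median_gain[focal][i, j],
                            "median_auc_social": self.median_auc_social[focal][i, j],
                            "median_auc_individual": self.median_auc_individual[focal][i, j],
                        }
                    )
        return pd.DataFrame(rows)


def gen_danger(on_len: int = 100, off_len: int = 100, cycles: int = 5) -> DangerSignal:
    """Boxcar danger cue: ``on_len`` ones then ``off_len`` zeros, repeated."""
    if on_len <= 0 or off_len <= 0 or cycles <= 0:
        raise ValueError("on_len, off_len and cycles must all be positive")
    cycle = np.concatenate([np.ones(on_len), np.zeros(off_len)])
    values = np.tile(cycle, cycles)
    return DangerSignal(values=values, on_len=on_len, off_len=off_len, cycles=cycles)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_individual(
    d: DangerSignal, sigma: float, c: float, seed=None, noise: np.ndarray | None = None
) -> AgentTrace:
    """One uncoupled agent: x = d + N(0, sigma); freeze iff x > c."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if noise is None:
        noise = _as_rng(seed).normal(0.0, 1.0, d.values.size)
    x = d.values + sigma * noise
    return AgentTrace(x=x, f=(x > c).astype(np.int8), role="animal1")


def _coupled_recursion(d, e1, e2, b, r, c, f_init):
    """Sequential coupled update, vectorised across a threshold axis.

    ``e1``/``e2`` are noise arrays of shape (n,) or (n, k); ``c`` is a scalar
    or a length-k threshold vector.  Animal 1 carries the extra noise factor
    ``r`` and coupling weight ``b``; animal 2 uses weight ``b / r``.
    """
    dv = d.values
    n = dv.size
    e1 = np.atleast_2d(e1.T).T  # (n, k)
    e2 = np.atleast_2d(e2.T).T
    k = e1.shape[1]
    c = np.broadcast_to(np.asarray(c, dtype=float), (k,))
    x1 = np.empty((n, k))
    x2 = np.empty((n, k))
    f1 = np.empty((n, k), dtype=np.int8)
    f2 = np.empty((n, k), dtype=np.int8)
    f1_prev = np.full(k, f_init, dtype=float)
    f2_prev = np.full(k, f_init, dtype=float)
    for t in range(n):
        x1[t] = dv[t] + r * e1[t] + b * (f2_prev - 0.5)
        x2[t] = dv[t] + e2[t] + (b / r) * (f1_prev - 0.5)
        f1[t] = x1[t] > c
        f2[t] = x2[t] > c
        f1_prev = f1[t].astype(float)
        f2_prev = f2[t].astype(float)
    return x1, x2, f1, f2


def simulate_coupled(
    d: DangerSignal,
    sigma1: float,
    sigma2: float,
    b: float,
    c: float,
    r: float = 1.0,
    seed=None,
    f_init: int = 0,
) -> tuple[AgentTrace, AgentTrace]:
    """Two mutually coupled threshold agents.

    x1(t) = d(t) + r*n1(t) + b*(f2[t-1] - 0.5),     n1 ~ N(0, sigma1)
    x2(t) = d(t) +   n2(t) + (b/r)*(f1[t-1] - 0.5), n2 ~ N(0, sigma2)

    Noise streams are independent across animals; partner decisions enter
    with a one-sample delay, seeded with ``f_init`` before t = 0.
    """
    if sigma1 < 0 or sigma2 < 0:
        raise ValueError("sigma must be >= 0")
    if r < 1:
        raise ValueError("noise ratio r must be >= 1 (animal1 is the noisier one)")
    rng = _as_rng(seed)
    n = d.values.size
    e1 = sigma1 * rng.normal(0.0, 1.0, n)
    e2 = sigma2 * rng.normal(0.0, 1.0, n)
    x1, x2, f1, f2 = _coupled_recursion(d, e1, e2, b, r, c, f_init)
    return (
        AgentTrace(x=x1[:, 0], f=f1[:, 0], role="animal1"),
        AgentTrace(x=x2[:, 0], f=f2[:, 0], role="animal2"),
    )


def _hit_fa(f: np.ndarray, dv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hit and false-alarm rates per threshold column."""
    on = dv == 1
    hits = f[on].mean(axis=0)
    fas = f[~on].mean(axis=0)
    return hits, fas


def _trapezoid_auc(fa: np.ndarray, hit: np.ndarray) -> float:
    """Trapezoid AUC over ROC points sorted along the curve, with the
    (0,0) and (1,1) anchors appended."""
    order = np.lexsort((hit, fa))
    fa = np.concatenate([[0.0], fa[order], [1.0]])
    hit = np.concatenate([[0.0], hit[order], [1.0]])
    return float(np.trapezoid(hit, fa))


def roc_auc(
    d: DangerSignal,
    params: SimParams,
    mode: str = "individual",
    focal: str = "animal1",
    seed=None,
) -> float:
    """AUC of one simulated ROC sweep.

    The threshold is swept over an evenly spaced grid on
    ``[-5*sigma_focal, +5*sigma_focal]``; by default each threshold is an
    independent simulation with fresh noise (``params.redraw_noise``).
    """
    if mode not in ("individual", "coupled"):
        raise ValueError(f"unknown mode {mode!r}")
    if focal not in ("animal1", "animal2"):
        raise ValueError(f"unknown focal {focal!r}")
    if params.sigma <= 0:
        raise ValueError("sigma must be > 0 for a meaningful threshold sweep")
    rng = _as_rng(params.seed if seed is None else seed)
    dv = d.values
    n = dv.size
    k = params.threshold_grid
    sigma_focal = params.sigma * (params.r if focal == "animal1" else 1.0)
    cs = np.linspace(-5 * sigma_focal, 5 * sigma_focal, k)
    ncols = k if params.redraw_noise else 1

    if mode == "individual":
        noise = rng.normal(0.0, 1.0, (n, ncols))
        # the focal animal sees its own effective noise level
        x = dv[:, None] + sigma_focal * noise
        f = (x > cs[None, :]).astype(np.int8)
    else:
        e1 = params.sigma * rng.normal(0.0, 1.0, (n, ncols))
        e2 = params.sigma * rng.normal(0.0, 1.0, (n, ncols))
        if params.redraw_noise:
            _, _, f1, f2 = _coupled_recursion(d, e1, e2, params.b, params.r, cs, params.f_init)
        else:
            f1 = np.empty((n, k), dtype=np.int8)
            f2 = np.empty((n, k), dtype=np.int8)
            for j, c in enumerate(cs):
                _, _, a, bb = _coupled_recursion(
                    d, e1[:, 0], e2[:, 0], params.b, params.r, c, params.f_init
                )
                f1[:, j] = a[:, 0]
                f2[:, j] = bb[:, 0]
        f = f1 if focal == "animal1" else f2

    hits, fas = _hit_fa(f, dv)
    return _trapezoid_auc(fas, hits)


def performance_gain(auc_social: float, auc_individual: float) -> float:
    """(AUC_social - AUC_individual) / (AUC_individual - 0.5).

    Expresses how much further from chance performance moved by using the
    partner's freezing.  Undefined (NaN, with a warning) when the individual
    AUC sits exactly at chance.
    """
    denom = auc_individual - 0.5
    if denom == 0:
        warnings.warn("individual AUC at chance level; performance gain undefined")
        return float("nan")
    return (auc_social - auc_individual) / denom


def grid_sweep(
    sigma_grid,
    b_grid,
    r: float = 1.0,
    reps: int = 20,
    seed=None,
    threshold_grid: int = 101,
    d: DangerSignal | None = None,
) -> GainGrid:
    """Median performance gain over a (sigma, b) grid, per focal animal.

    Every cell runs ``reps`` independent (individual, social) AUC pairs and
    stores the median gain and median AUCs; with ``r > 1`` the two animals
    differ, so both focal grids are reported.
    """
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    b_grid = np.asarray(b_grid, dtype=float)
    if sigma_grid.size == 0 or b_grid.size == 0:
        raise ValueError("sigma_grid and b_grid must be nonempty")
    if np.any(sigma_grid <= 0):
        raise ValueError("sigma grid must be strictly positive")
    if d is None:
        d = gen_danger()
    rng = _as_rng(seed)
    focals = ("animal1", "animal2")
    grid = GainGrid(sigma_grid=sigma_grid, b_grid=b_grid, r=r)
    shape = (sigma_grid.size, b_grid.size)
    for focal in focals:
        grid.median_gain[focal] = np.empty(shape)
        grid.median_auc_social[focal] = np.empty(shape)
        grid.median_auc_individual[focal] = np.empty(shape)
    for i, sigma in enumerate(sigma_grid):
        for j, b in enumerate(b_grid):
            gains = {f: np.empty(reps) for f in focals}
            auc_soc = {f: np.empty(reps) for f in focals}
            auc_ind = {f: np.empty(reps) for f in focals}
            for rep in range(reps):
                p_ind = SimParams(sigma=sigma, b=0.0, r=r, threshold_grid=threshold_grid)
                p_soc = SimParams(sigma=sigma, b=b, r=r, threshold_grid=threshold_grid)
                for f in focals:
                    ai = roc_auc(d, p_ind, mode="individual", focal=f, seed=rng)
                    asoc = roc_auc(d, p_soc, mode="coupled", focal=f, seed=rng)
                    auc_ind[f][rep] = ai
                    auc_soc[f][rep] = asoc
                    gains[f][rep] = performance_gain(asoc, ai)
            for f in focals:
                grid.median_gain[f][i, j] = np.median(gains[f])
                grid.median_auc_social[f][i, j] = np.median(auc_soc[f])
                grid.median_auc_individual[f][i, j] = np.median(auc_ind[f])
    return grid
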