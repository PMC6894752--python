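"""Synthetic dyad data with the statistical structure the analyses assume.

Two generative layers are produced, mirroring the two timescales of the
analyses:

* **Epoch level** — per dyad, one baseline and one shock row of freezing
  proportions drawn from linear coupling models with Gaussian noise, clamped
  to [0, 1].  Coupling terms are gated by the shock indicator.  When only
  the demonstrator couples to the observer the rows are drawn sequentially
  (observer first); when both targets carry a partner-coupling term the
  2x2 linear system is solved per dyad so that both stated coupling
  coefficients enter the data-generating process.
* **Second-by-second** — coupled binary freezing series driven by a
  shock-locked boxcar danger signal (the threshold-agent recursion of the
  detection simulator reused as a generative process).  Real scored
  freezing has no known per-second generative model; this layer is a
  stand-in with the right coarse structure (shock-locked drive, lag-1
  partner coupling, >=3-s bouts after cleaning), not a fit to real data.

``gen_cohort_bundle`` writes a complete on-disk study (per-dyad event CSVs,
an epoch table, metadata and a config manifest) that round-trips through the
ethogram reader.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .dangersim import DangerSignal, _coupled_recursion
from .ethogram import (
    DEFAULT_EPOCH_LEN_S,
    FreezingSeries,
    extract_epochs,
    freezing_percent,
    series_to_bouts,
)

__all__ = [
    "CohortDesign",
    "GenerativeParams",
    "gen_epoch_dataset",
    "gen_dyad_series",
    "gen_cohort_bundle",
    "DEFAULT_SHOCK_TIMES_S",
]

WEEK_LEVELS = (0, 1, 3, 5)
STRAINS = ("LE", "SD")
# five shocks from ~720 s, ISI within the study's 120-180 s range
DEFAULT_SHOCK_TIMES_S = (720, 870, 1020, 1170, 1320)
DEFAULT_DURATION_S = 1440
DEFAULT_DANGER_WINDOW_S = 60


@dataclass(frozen=True)
class CohortDesign:
    """Group structure of a synthetic cohort."""

    n_dyads: int = 32
    weeks_together: tuple = WEEK_LEVELS
    strain_obs: tuple = ("LE",)
    strain_dem: tuple = ("LE",)
    preexposed: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dyads < 1:
            raise ValueError("n_dyads must be >= 1")
        if any(w not in WEEK_LEVELS for w in self.weeks_together):
            raise ValueError(f"weeks_together levels must be among {WEEK_LEVELS}")
        for s in (*self.strain_obs, *self.strain_dem):
            if s not in STRAINS:
                raise ValueError(f"strains must be among {STRAINS}")

    def dyad_table(self) -> pd.DataFrame:
        """Deterministic covariate assignment, cycling through the levels."""
        rows = []
        for i in range(self.n_dyads):
            so = self.strain_obs[i % len(self.strain_obs)]
            sd = self.strain_dem[i % len(self.strain_dem)]
            rows.append(
                {
                    "dyad_id": f"dyad{i:03d}",
                    "weeks": self.weeks_together[i % len(self.weeks_together)],
                    "strain_obs": so,
                    "strain_dem": sd,
                    "same_strain": int(so == sd),
                    "preexposed": int(self.preexposed),
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class GenerativeParams:
    """Coefficients of a generating linear model on the proportion scale.

    ``terms`` maps variable products to coefficients.  Recognised keys:
    ``intercept``, ``shock_dem``, products joined with ``*`` over
    {shock_dem, freezing_obs, freezing_dem, strain_dem, strain_obs,
    preexposure_obs}.  Partner-coupling terms (those containing the other
    animal's freezing) are gated by ``shock_dem`` exactly as in the models.
    """

    terms: dict = field(default_factory=dict)
    residual_sd: float = 0.12

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        if not all(np.isfinite(v) for v in self.terms.values()):
            raise ValueError("coefficients must be finite")

    def coupling_coef(self, partner_var: str) -> float:
        """Summed coefficient on the partner's freezing (shock-gated)."""
        total = 0.0
        for key, coef in self.terms.items():
            if partner_var in key.split("*"):
                total += coef
        return total


def default_demonstrator_params() -> GenerativeParams:
    """Winning demonstrator model: 0.47*Shock + 0.37*Freezing_obs*Shock."""
    return GenerativeParams(
        terms={"shock_dem": 0.47, "freezing_obs*shock_dem": 0.37}, residual_sd=0.12
    )


def default_observer_params(coupled: bool = False) -> GenerativeParams:
    """Observer generator.

    Uncoupled (default): shock-epoch mean 0.55 with between-dyad SD 0.25 —
    a spread comparable to the wide observer freezing distributions seen
    during shock epochs — and baseline mean 0.
    Coupled: the winning observer model 0.85*Freezing_dem*Shock.
    """
    if coupled:
        return GenerativeParams(
            terms={"freezing_dem*shock_dem": 0.85}, residual_sd=0.19
        )
    return GenerativeParams(terms={"shock_dem": 0.55}, residual_sd=0.25)


def _linear_predictor(terms: dict, row: dict, skip_partner: str | None = None) -> float:
    """Evaluate the generating terms on one epoch row.

    ``skip_partner`` drops terms containing that variable (used when the
    partner value enters through the solved simultaneous system instead).
    """
    mu = 0.0
    for key, coef in terms.items():
        if key == "intercept":
            mu += coef
            continue
        factors = key.split("*")
        if skip_partner is not None and skip_partner in factors:
            continue
        val = 1.0
        for f in factors:
            val *= row[f]
        mu += coef * val
    return mu


def gen_epoch_dataset(
    design: CohortDesign,
    params_dem: GenerativeParams | None = None,
    params_obs: GenerativeParams | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Two epoch rows (baseline, shock) per dyad of clamped-Normal freezing.

    The observer draw comes first; if the observer terms do not reference
    ``freezing_dem`` the demonstrator is then drawn conditionally on it.
    If both targets couple to each other, the bivariate linear system is
    solved so each stated coupling coefficient genuinely generates the data.
    """
    params_dem = params_dem or default_demonstrator_params()
    params_obs = params_obs or default_observer_params()
    rng = rng if rng is not None else np.random.default_rng(design.seed)
    dyads = design.dyad_table()
    a = params_obs.coupling_coef("freezing_dem")  # dem -> obs
    b = params_dem.coupling_coef("freezing_obs")  # obs -> dem
    rows = []
    for rec in dyads.to_dict("records"):
        row = {
            "strain_obs": 1.0 if rec["strain_obs"] == "LE" else 0.0,
            "strain_dem": 1.0 if rec["strain_dem"] == "LE" else 0.0,
            "preexposure_obs": float(rec["preexposed"]),
            "weeks": float(rec["weeks"]),
            "same_strain": float(rec["same_strain"]),
        }
        for epoch, shock in (("baseline", 0.0), ("shock", 1.0)):
            row["shock_dem"] = shock
            e_o = rng.normal(0.0, params_obs.residual_sd)
            e_d = rng.normal(0.0, params_dem.residual_sd)
            mu_o = _linear_predictor(params_obs.terms, row, skip_partner="freezing_dem")
            if a != 0.0:
                # simultaneous system: obs = mu_o + a*s*dem + e_o,
                #                      dem = mu_d + b*s*obs + e_d
                mu_d = _linear_predictor(params_dem.terms, row, skip_partner="freezing_obs")
                det = 1.0 - a * b * shock * shock
                if abs(det) < 1e-9:
                    raise ValueError("coupling loop a*b too close to 1; system singular")
                dem = (mu_d + e_d + b * shock * (mu_o + e_o)) / det
                obs = mu_o + e_o + a * shock * dem
            else:
                # the analyses see the clamped observer value, so the
                # demonstrator is generated from the clamped value too
                obs = float(np.clip(mu_o + e_o, 0.0, 1.0))
                row["freezing_obs"] = obs
                dem = _linear_predictor(params_dem.terms, row) + e_d
            obs = float(np.clip(obs, 0.0, 1.0))
            dem = float(np.clip(dem, 0.0, 1.0))
            rows.append(
                {
                    "dyad_id": rec["dyad_id"],
                    "epoch": epoch,
                    "freezing_obs": obs,
                    "freezing_dem": dem,
                    "shock_dem": shock,
                    "weeks": rec["weeks"],
                    "strain_obs": row["strain_obs"],
                    "strain_dem": row["strain_dem"],
                    "same_strain": rec["same_strain"],
                    "preexposure_obs": row["preexposure_obs"],
                }
            )
    return pd.DataFrame(rows)


def _danger_track(shock_times_s, duration_s: int, window_s: int) -> np.ndarray:
    d = np.zeros(duration_s)
    for s in shock_times_s:
        if not 0 <= s < duration_s:
            raise ValueError(f"shock time {s}s outside the {duration_s}s recording")
        d[int(s) : min(int(s) + window_s, duration_s)] = 1.0
    return d


def gen_dyad_series(
    shock_times_s,
    duration_s: int = DEFAULT_DURATION_S,
    sigma_obs: float = 1.0,
    sigma_dem: float = 1.0,
    b: float = 1.0,
    seed=None,
    danger_window_s: int = DEFAULT_DANGER_WINDOW_S,
    threshold: float = 0.5,
) -> tuple[FreezingSeries, FreezingSeries]:
    """Second-by-second coupled binary freezing (demonstrator, observer).

    Both animals see the shock-locked boxcar danger signal (1 inside a
    ``danger_window_s`` window after each shock) through their own Gaussian
    noise and weigh the partner's previous-second freezing by ``b``.
    """
    if sigma_obs <= 0 or sigma_dem <= 0:
        raise ValueError("noise SDs must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = _danger_track(shock_times_s, duration_s, danger_window_s)
    sig = DangerSignal(values=d, on_len=danger_window_s, off_len=0, cycles=len(shock_times_s))
    e_dem = sigma_dem * rng.normal(0.0, 1.0, duration_s)
    e_obs = sigma_obs * rng.normal(0.0, 1.0, duration_s)
    _, _, f_dem, f_obs = _coupled_recursion(sig, e_dem, e_obs, b, 1.0, threshold, 0)
    return (
        FreezingSeries(values=f_dem[:, 0], subject_id="dem"),
        FreezingSeries(values=f_obs[:, 0], subject_id="obs"),
    )


def _drop_short_runs(values: np.ndarray, min_len: int = 3) -> np.ndarray:
    """Zero out freezing runs shorter than the scoring cutoff, so the series
    looks like scored data (no bout shorter than min_len seconds)."""
    v = values.copy()
    edges = np.flatnonzero(np.diff(np.concatenate([[0], v, [0]])))
    for a, bnd in zip(edges[::2], edges[1::2]):
        if bnd - a < min_len:
            v[a:bnd] = 0
    return v


def gen_cohort_bundle(
    design: CohortDesign,
    out_dir,
    params_dem: GenerativeParams | None = None,
    params_obs: GenerativeParams | None = None,
    shock_times_s=DEFAULT_SHOCK_TIMES_S,
    duration_s: int = DEFAULT_DURATION_S,
    series_sigma: float = 1.0,
    series_b: float = 1.0,
    epoch_len_s: int = DEFAULT_EPOCH_LEN_S,
) -> dict:
    """Write a complete synthetic study to ``out_dir``.

    Contents: ``events/<dyad>_<role>.csv`` scored-bout logs reconstructed
    from generated per-second series (runs shorter than 3 s removed first,
    as a human scorer would never log them), ``epochs.csv`` from the
    epoch-level generator, ``metadata.csv`` and ``config.json``.
    Returns a manifest dict of the written paths.
    """
    out = Path(out_dir)
    try:
        (out / "events").mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"cannot create bundle directory {out}: {exc}") from exc
    rng = np.random.default_rng(design.seed)
    epochs = gen_epoch_dataset(design, params_dem, params_obs, rng=rng)
    meta = design.dyad_table()
    event_files = {}
    series_pct = []
    for rec in meta.to_dict("records"):
        dem, obs = gen_dyad_series(
            shock_times_s,
            duration_s,
            sigma_obs=series_sigma,
            sigma_dem=series_sigma,
            b=series_b,
            seed=rng,
        )
        for role, series in (("dem", dem), ("obs", obs)):
            series = FreezingSeries(
                _drop_short_runs(series.values), subject_id=f"{rec['dyad_id']}_{role}"
            )
            bouts = series_to_bouts(series)
            path = out / "events" / f"{rec['dyad_id']}_{role}.csv"
            pd.DataFrame(
                [
                    {"subject": e.subject_id, "behavior": "freezing", "start": e.start, "stop": e.stop}
                    for e in bouts
                ],
                columns=["subject", "behavior", "start", "stop"],
            ).to_csv(path, index=False)
            event_files[f"{rec['dyad_id']}_{role}"] = str(path)
            base_w, shock_w = extract_epochs(series, shock_times_s[0], epoch_len_s)
            series_pct.append(
                {
                    "dyad_id": rec["dyad_id"],
                    "role": role,
                    "baseline_pct": freezing_percent(series, base_w),
                    "shock_pct": freezing_percent(series, shock_w),
                }
            )
    epochs_path = out / "epochs.csv"
    epochs.to_csv(epochs_path, index=False)
    meta_path = out / "metadata.csv"
    meta.to_csv(meta_path, index=False)
    pd.DataFrame(series_pct).to_csv(out / "series_epoch_percents.csv", index=False)
    config = {
        "design": asdict(design),
        "shock_times_s": list(shock_times_s),
        "duration_s": duration_s,
        "series_sigma": series_sigma,
        "series_b": series_b,
        "epoch_len_s": epoch_len_s,
        "params_dem": asdict(params_dem or default_demonstrator_params()),
        "params_obs": asdict(params_obs or default_observer_params()),
    }
    (out / "config.json").write_text(json.dumps(config, indent=2, sort_keys=True))
    return {
        "events": event_files,
        "epochs": str(epochs_path),
        "metadata": str(meta_path),
        "config": str(out / "config.json"),
        "series_epoch_percents": str(out / "series_epoch_percents.csv"),
    }
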