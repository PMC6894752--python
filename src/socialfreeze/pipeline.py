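"""Pipeline wiring: synthesize -> score -> fit/compare -> granger -> simulate.

A :class:`RunConfig` names the stages to run, the output directory and one
master seed; every stage derives its own substream from that seed, and every
run writes a ``manifest.json`` carrying the seed, a hash of the config and
the stage output paths, so a run is reproducible from its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bayes, granger, models, synthetic
from .dangersim import grid_sweep
from .ethogram import (
    events_to_series,
    extract_epochs,
    freezing_percent,
    read_events_csv,
)

__all__ = ["RunConfig", "run_pipeline", "report", "load_config"]

log = logging.getLogger("socialfreeze")

ALL_STAGES = ("synth", "score", "fit", "compare", "granger", "simulate")


@dataclass
class RunConfig:
    stages: tuple = ALL_STAGES
    out_dir: str = "socialfreeze_run"
    seed: int = 0
    n_dyads: int = 32
    # epoch-level generator: winning-model couplings in both directions
    coupling_dem_to_obs: float = 0.85
    coupling_obs_to_dem: float = 0.37
    shock_coef: float = 0.47
    residual_sd_dem: float = 0.12
    residual_sd_obs: float = 0.19
    # per-second generator
    series_b: float = 1.0
    series_sigma: float = 1.0
    shock_times_s: tuple = synthetic.DEFAULT_SHOCK_TIMES_S
    duration_s: int = synthetic.DEFAULT_DURATION_S
    # granger
    gc_max_order: int = 25
    gc_epoch: str = "shock"
    # bayes
    sampler: bayes.SamplerConfig = field(default_factory=bayes.SamplerConfig)
    # simulator
    sim_sigma_grid: tuple = (0.5, 1.0, 2.0)
    sim_b_grid: tuple = (0.0, 0.5, 1.0, 1.5)
    sim_r: float = 1.0
    sim_reps: int = 20
    events_dir: str | None = None  # read pre-existing event logs instead of synth
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = asdict(self)
        payload["sampler"] = asdict(self.sampler)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """RunConfig from a YAML (or JSON) file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    sampler = data.pop("sampler", None)
    cfg = RunConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in data.items()})
    if sampler:
        cfg.sampler = bayes.SamplerConfig(**sampler)
    return cfg


def _stage_seed(config: RunConfig, stage: str) -> int:
    h = hashlib.sha256(f"{config.seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _generating_params(config: RunConfig):
    params_dem = synthetic.GenerativeParams(
        terms={
            "shock_dem": config.shock_coef,
            "freezing_obs*shock_dem": config.coupling_obs_to_dem,
        },
        residual_sd=config.residual_sd_dem,
    )
    if config.coupling_dem_to_obs != 0:
        params_obs = synthetic.GenerativeParams(
            terms={"freezing_dem*shock_dem": config.coupling_dem_to_obs},
            residual_sd=config.residual_sd_obs,
        )
    else:
        params_obs = synthetic.default_observer_params()
    return params_dem, params_obs


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order; returns the manifest."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    stages = [s for s in ALL_STAGES if s in config.stages]

    design = synthetic.CohortDesign(n_dyads=config.n_dyads, seed=_stage_seed(config, "synth"))
    params_dem, params_obs = _generating_params(config)

    bundle = None
    if "synth" in stages:
        log.info("synth: generating %d dyads", config.n_dyads)
        bundle = synthetic.gen_cohort_bundle(
            design,
            out / "synth",
            params_dem=params_dem,
            params_obs=params_obs,
            shock_times_s=config.shock_times_s,
            duration_s=config.duration_s,
            series_sigma=config.series_sigma,
            series_b=config.series_b,
        )
        manifest["stages"]["synth"] = bundle

    events_dir = Path(config.events_dir) if config.events_dir else out / "synth" / "events"

    if "score" in stages:
        if not events_dir.is_dir():
            raise FileNotFoundError(
                f"stage 'score' needs event logs; directory not found: {events_dir}"
            )
        summaries = []
        for path in sorted(events_dir.glob("*.csv")):
            events = read_events_csv(path, behavior="freezing")
            series = events_to_series(events, config.duration_s, subject_id=path.stem)
            base_w, shock_w = extract_epochs(series, config.shock_times_s[0])
            summaries.append(
                {
                    "subject": path.stem,
                    "baseline_pct": freezing_percent(series, base_w),
                    "shock_pct": freezing_percent(series, shock_w),
                }
            )
        score_path = out / "epoch_scores.csv"
        pd.DataFrame(summaries).to_csv(score_path, index=False)
        manifest["stages"]["score"] = {"epoch_scores": str(score_path)}

    fits: dict = {}
    loos: dict = {}
    epochs_df = None
    if "fit" in stages or "compare" in stages:
        epochs_path = (Path(bundle["epochs"]) if bundle else out / "synth" / "epochs.csv")
        if not epochs_path.exists():
            raise FileNotFoundError(
                f"stage 'fit' needs the epoch table; file not found: {epochs_path}"
            )
        epochs_df = pd.read_csv(epochs_path)

    if "fit" in stages:
        seed0 = _stage_seed(config, "fit")
        candidates = {
            "freezing_dem": [models.indiv_dem_shock_only(), models.indiv_dem_winning()],
            "freezing_obs": [models.indiv_obs_intercept(), models.indiv_obs_winning()],
        }
        fit_rows = []
        for ti, (target, specs) in enumerate(sorted(candidates.items())):
            for k, spec in enumerate(specs):
                X, y = bayes.build_design(epochs_df, spec)
                cfg = bayes.SamplerConfig(
                    **{**asdict(config.sampler), "seed": seed0 + 37 * k + 101 * ti}
                )
                fit = bayes.fit_model(X, y, spec, cfg)
                loo = bayes.psis_loo(fit, X, y)
                fits.setdefault(target, []).append(fit)
                loos.setdefault(target, []).append(loo)
                summ = bayes.coefficient_summary(fit)
                summ.insert(0, "model", spec.name)
                summ.insert(1, "target", target)
                fit_rows.append(summ)
        fit_path = out / "fits.csv"
        pd.concat(fit_rows).to_csv(fit_path, index=False)
        manifest["stages"]["fit"] = {"fits": str(fit_path)}

    if "compare" in stages:
        if not fits:
            raise RuntimeError("stage 'compare' needs stage 'fit' in the same run")
        comparison = {}
        for target in fits:
            table = bayes.rank_models(loos[target], fits[target])
            cmp_path = out / f"comparison_{target}.csv"
            table.to_csv(cmp_path)
            comparison[target] = {
                "winner": table.winner,
                "table": str(cmp_path),
                "notes": table.notes,
                "winner_terms": [
                    t.name
                    for f in fits[target]
                    if f.spec.name == table.winner
                    for t in f.spec.terms
                ],
            }
        manifest["stages"]["compare"] = comparison

    if "granger" in stages:
        if not events_dir.is_dir():
            raise FileNotFoundError(
                f"stage 'granger' needs event logs; directory not found: {events_dir}"
            )
        inputs = []
        stems = sorted({p.stem.rsplit("_", 1)[0] for p in events_dir.glob("*.csv")})
        for dyad in stems:
            series = {}
            for role in ("dem", "obs"):
                path = events_dir / f"{dyad}_{role}.csv"
                events = read_events_csv(path, behavior="freezing")
                series[role] = events_to_series(events, config.duration_s, subject_id=path.stem)
            base_w, shock_w = extract_epochs(series["dem"], config.shock_times_s[0])
            window = shock_w if config.gc_epoch == "shock" else base_w
            x1 = granger.smooth_series(series["dem"].values[window.slice()])
            x2 = granger.smooth_series(series["obs"].values[window.slice()])
            if np.ptp(x1) == 0 or np.ptp(x2) == 0:
                # not enough freezing variation in this epoch to model
                log.warning("granger: excluding dyad %s (constant smoothed series)", dyad)
                continue
            inputs.append(granger.GcInput(x1, x2, dyad_id=dyad))
        if not inputs:
            raise RuntimeError("granger: no dyad with usable (non-constant) series")
        pooled = granger.pooled_gc(inputs, m="auto", max_order=config.gc_max_order)
        # dyadwise estimates at the order chosen on the pooled sample
        dyad_rows = []
        for d in inputs:
            res = granger.pairwise_gc(d, m=pooled.order)
            dyad_rows.append(
                {
                    "dyad_id": d.dyad_id,
                    "order": res.order,
                    "F_dem_to_obs": res.F_x1_to_x2,
                    "p_dem_to_obs": res.p_x1_to_x2,
                    "F_obs_to_dem": res.F_x2_to_x1,
                    "p_obs_to_dem": res.p_x2_to_x1,
                }
            )
        dyad_path = out / "granger_dyads.csv"
        pd.DataFrame(dyad_rows).to_csv(dyad_path, index=False)
        gc_payload = {
            "epoch": config.gc_epoch,
            "order": pooled.order,
            "F_dem_to_obs": pooled.F_x1_to_x2,
            "p_dem_to_obs": pooled.p_x1_to_x2,
            "F_obs_to_dem": pooled.F_x2_to_x1,
            "p_obs_to_dem": pooled.p_x2_to_x1,
            "n_eff": pooled.n_eff,
            "n_dyads": len(inputs),
        }
        gc_path = out / "granger_pooled.json"
        gc_path.write_text(json.dumps(gc_payload, indent=2))
        manifest["stages"]["granger"] = {
            "pooled": gc_payload,
            "path": str(gc_path),
            "per_dyad": str(dyad_path),
            "n_excluded": len(stems) - len(inputs),
        }

    if "simulate" in stages:
        grid = grid_sweep(
            config.sim_sigma_grid,
            config.sim_b_grid,
            r=config.sim_r,
            reps=config.sim_reps,
            seed=_stage_seed(config, "simulate"),
        )
        grid_path = out / "gain_grid.csv"
        grid.to_frame().to_csv(grid_path, index=False)
        manifest["stages"]["simulate"] = {"gain_grid": str(grid_path)}

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["manifest_path"] = str(manifest_path)
    return manifest


def report(manifest: dict | str) -> str:
    """Human-readable markdown summary of a completed run."""
    if isinstance(manifest, (str, Path)):
        manifest = json.loads(Path(manifest).read_text())
    lines = ["# socialfreeze run report", ""]
    lines.append(f"- seed: {manifest['seed']}")
    lines.append(f"- config hash: {manifest['config_hash']}")
    stages = manifest.get("stages", {})
    if not stages:
        lines.append("")
        lines.append("**warning: empty run — no stages completed (partial report)**")
        return "\n".join(lines)
    expected = set(ALL_STAGES)
    missing = expected - set(stages)
    if missing:
        lines.append(f"- **partial run** (missing stages: {', '.join(sorted(missing))})")
    if "compare" in stages:
        lines.append("")
        lines.append("## Winning models")
        for target, info in stages["compare"].items():
            lines.append(f"- {target}: **{info['winner']}** (terms: {', '.join(info['winner_terms'])})")
    if "fit" in stages:
        lines.append("")
        lines.append("## Coupling-parameter credible intervals")
        fits = pd.read_csv(stages["fit"]["fits"])
        coupling = fits[fits["parameter"].str.contains(r"freezing_(?:obs|dem)\*", regex=True)]
        for _, r in coupling.iterrows():
            lines.append(
                f"- {r['target']} / {r['model']} / {r['parameter']}: "
                f"{r['mean']:.3f} ({r['ci95_low']:.3f} to {r['ci95_high']:.3f})"
            )
    if "granger" in stages:
        g = stages["granger"]["pooled"]
        lines.append("")
        lines.append("## Pooled Granger causality")
        lines.append(
            f"- epoch {g['epoch']}, order {g['order']}: "
            f"dem->obs F={g['F_dem_to_obs']:.4f} (p={g['p_dem_to_obs']:.2g}), "
            f"obs->dem F={g['F_obs_to_dem']:.4f} (p={g['p_obs_to_dem']:.2g})"
        )
    if "simulate" in stages:
        grid = pd.read_csv(stages["simulate"]["gain_grid"])
        lines.append("")
        lines.append("## Simulated detection gains (median over reps)")
        best = grid.loc[grid["median_gain"].idxmax()]
        lines.append(
            f"- best cell: sigma={best['sigma']}, b={best['b']}, focal={best['focal']}: "
            f"gain {best['median_gain']:.3f}"
        )
    return "\n".join(lines)
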