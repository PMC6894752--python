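"""Canned model specifications for the epoch-level coupling analyses.

One :class:`~socialfreeze.bayes.ModelSpec` per candidate model in the two
familiarity studies (individual familiarity: 8 demonstrator + 4 observer
models; strain familiarity: 12 + 12) and the preexposure study (4 + 4).
Naming follows the study's numbering so comparison tables line up with the
published layout.  Partner-coupling terms — any term containing the other
animal's freezing — carry the relaxed [-1.5, 1.5] coefficient bounds; all
other coefficients keep the default [-1, 1].

The specs are plain data; load custom ones from YAML/JSON with
:func:`load_model_spec`.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .bayes import COUPLING_BOUNDS, Factor, ModelSpec, TermSpec

__all__ = [
    "individual_familiarity_dem_models",
    "individual_familiarity_obs_models",
    "strain_familiarity_dem_models",
    "strain_familiarity_obs_models",
    "preexposure_dem_models",
    "preexposure_obs_models",
    "load_model_spec",
    "save_model_spec",
]

WEEK_LEVELS = (0, 1, 3, 5)


def _t(name: str, *factors, split_by=None, split_levels=None, coupling=False) -> TermSpec:
    fs = tuple(Factor(v[3:], complement=True) if v.startswith("no_") else Factor(v) for v in factors)
    return TermSpec(
        name,
        fs,
        split_by=split_by,
        split_levels=split_levels,
        bounds=COUPLING_BOUNDS if coupling else None,
    )


def _intercept(name: str = "intercept") -> TermSpec:
    return _t(name, "intercept")


# -- shared term builders ---------------------------------------------------

def _shock() -> TermSpec:
    return _t("shock_dem", "shock_dem")


def _obs_coupling() -> TermSpec:
    return _t("freezing_obs*shock_dem", "freezing_obs", "shock_dem", coupling=True)


def _dem_coupling() -> TermSpec:
    return _t("freezing_dem*shock_dem", "freezing_dem", "shock_dem", coupling=True)


def _weeks_obs_coupling() -> TermSpec:
    return _t("weeks*freezing_obs*shock_dem", "weeks", "freezing_obs", "shock_dem", coupling=True)


def _weeks_dem_coupling() -> TermSpec:
    return _t("weeks*freezing_dem*shock_dem", "weeks", "freezing_dem", "shock_dem", coupling=True)


def _perweek_obs_coupling() -> TermSpec:
    return _t(
        "freezing_obs*shock_dem",
        "freezing_obs",
        "shock_dem",
        split_by="weeks",
        split_levels=WEEK_LEVELS,
        coupling=True,
    )


def _perweek_dem_coupling() -> TermSpec:
    return _t(
        "freezing_dem*shock_dem",
        "freezing_dem",
        "shock_dem",
        split_by="weeks",
        split_levels=WEEK_LEVELS,
        coupling=True,
    )


def _strain_dem_terms() -> list[TermSpec]:
    return [
        _t("strain_dem*shock_dem", "strain_dem", "shock_dem"),
        _t("strain_dem*noshock_dem", "strain_dem", "no_shock_dem"),
    ]


def _strain_obs_terms() -> list[TermSpec]:
    return [
        _t("strain_obs*shock_dem", "strain_obs", "shock_dem"),
        _t("strain_obs*noshock_dem", "strain_obs", "no_shock_dem"),
    ]


def _preexposure_obs_terms() -> list[TermSpec]:
    return [
        _t("preexposure_obs*shock_dem", "preexposure_obs", "shock_dem"),
        _t("preexposure_obs*noshock_dem", "preexposure_obs", "no_shock_dem"),
    ]


def _samediff_obs_coupling() -> TermSpec:
    return _t(
        "freezing_obs*shock_dem",
        "freezing_obs",
        "shock_dem",
        split_by="same_strain",
        split_levels=(1, 0),
        coupling=True,
    )


def _samediff_dem_coupling() -> TermSpec:
    return _t(
        "freezing_dem*shock_dem",
        "freezing_dem",
        "shock_dem",
        split_by="same_strain",
        split_levels=(1, 0),
        coupling=True,
    )


def _spec(name, target, terms) -> ModelSpec:
    return ModelSpec(name, target, tuple(terms))


# -- individual familiarity study -------------------------------------------

def indiv_dem_winning() -> ModelSpec:
    """Demonstrator model 6: Shock + Freezing_obs x Shock."""
    return _spec("indiv_dem_m6", "freezing_dem", [_shock(), _obs_coupling()])


def indiv_dem_shock_only() -> ModelSpec:
    return _spec("indiv_dem_m5", "freezing_dem", [_shock()])


def indiv_obs_winning() -> ModelSpec:
    """Observer model 2: Freezing_dem x Shock."""
    return _spec("indiv_obs_m2", "freezing_obs", [_dem_coupling()])


def indiv_obs_intercept() -> ModelSpec:
    return _spec("indiv_obs_m1", "freezing_obs", [_intercept()])


def individual_familiarity_dem_models() -> list[ModelSpec]:
    return [
        _spec("indiv_dem_m1", "freezing_dem", [_intercept()]),
        _spec("indiv_dem_m2", "freezing_dem", [_obs_coupling()]),
        _spec("indiv_dem_m3", "freezing_dem", [_perweek_obs_coupling()]),
        _spec("indiv_dem_m4", "freezing_dem", [_weeks_obs_coupling()]),
        indiv_dem_shock_only(),
        indiv_dem_winning(),
        _spec("indiv_dem_m7", "freezing_dem", [_shock(), _perweek_obs_coupling()]),
        _spec("indiv_dem_m8", "freezing_dem", [_shock(), _weeks_obs_coupling()]),
    ]


def individual_familiarity_obs_models() -> list[ModelSpec]:
    return [
        indiv_obs_intercept(),
        indiv_obs_winning(),
        _spec("indiv_obs_m3", "freezing_obs", [_perweek_dem_coupling()]),
        _spec("indiv_obs_m4", "freezing_obs", [_weeks_dem_coupling()]),
    ]


# -- strain familiarity study ------------------------------------------------

def strain_familiarity_dem_models() -> list[ModelSpec]:
    return [
        _spec("strain_dem_m1", "freezing_dem", [_intercept()]),
        _spec("strain_dem_m2", "freezing_dem", [_obs_coupling()]),
        _spec("strain_dem_m3", "freezing_dem", [_samediff_obs_coupling()]),
        _spec("strain_dem_m4", "freezing_dem", [_shock()]),
        _spec("strain_dem_m5", "freezing_dem", [_shock(), _obs_coupling()]),
        _spec("strain_dem_m6", "freezing_dem", [_shock(), _samediff_obs_coupling()]),
        _spec("strain_dem_m7", "freezing_dem", _strain_dem_terms()),
        _spec("strain_dem_m8", "freezing_dem", [*_strain_dem_terms(), _obs_coupling()]),
        _spec("strain_dem_m9", "freezing_dem", [*_strain_dem_terms(), _samediff_obs_coupling()]),
        _spec("strain_dem_m10", "freezing_dem", [_shock(), *_strain_dem_terms()]),
        _spec("strain_dem_m11", "freezing_dem", [_shock(), *_strain_dem_terms(), _obs_coupling()]),
        _spec(
            "strain_dem_m12",
            "freezing_dem",
            [_shock(), *_strain_dem_terms(), _samediff_obs_coupling()],
        ),
    ]


def strain_familiarity_obs_models() -> list[ModelSpec]:
    return [
        _spec("strain_obs_m1", "freezing_obs", [_intercept()]),
        _spec("strain_obs_m2", "freezing_obs", [_dem_coupling()]),
        _spec("strain_obs_m3", "freezing_obs", [_samediff_dem_coupling()]),
        _spec("strain_obs_m4", "freezing_obs", _preexposure_obs_terms()),
        _spec("strain_obs_m5", "freezing_obs", [*_preexposure_obs_terms(), _dem_coupling()]),
        _spec("strain_obs_m6", "freezing_obs", [*_preexposure_obs_terms(), _samediff_dem_coupling()]),
        _spec("strain_obs_m7", "freezing_obs", _strain_obs_terms()),
        _spec("strain_obs_m8", "freezing_obs", [*_strain_obs_terms(), _dem_coupling()]),
        _spec("strain_obs_m9", "freezing_obs", [*_strain_obs_terms(), _samediff_dem_coupling()]),
        _spec("strain_obs_m10", "freezing_obs", [*_strain_obs_terms(), *_preexposure_obs_terms()]),
        _spec(
            "strain_obs_m11",
            "freezing_obs",
            [*_strain_obs_terms(), *_preexposure_obs_terms(), _dem_coupling()],
        ),
        _spec(
            "strain_obs_m12",
            "freezing_obs",
            [*_strain_obs_terms(), *_preexposure_obs_terms(), _samediff_dem_coupling()],
        ),
    ]


# -- preexposure study --------------------------------------------------------
# 'preexposed' is the binary group label (preexposed vs not) for these models

def _pregroup_obs_coupling() -> TermSpec:
    return _t(
        "freezing_obs*shock_dem",
        "freezing_obs",
        "shock_dem",
        split_by="preexposure_obs",
        split_levels=(1, 0),
        coupling=True,
    )


def _pregroup_dem_coupling() -> TermSpec:
    return _t(
        "freezing_dem*shock_dem",
        "freezing_dem",
        "shock_dem",
        split_by="preexposure_obs",
        split_levels=(1, 0),
        coupling=True,
    )


def preexposure_dem_models() -> list[ModelSpec]:
    return [
        _spec("pre_dem_m1", "freezing_dem", [_obs_coupling()]),
        _spec("pre_dem_m2", "freezing_dem", [_shock(), _obs_coupling()]),
        _spec("pre_dem_m3", "freezing_dem", [_pregroup_obs_coupling()]),
        _spec("pre_dem_m4", "freezing_dem", [_shock(), _pregroup_obs_coupling()]),
    ]


def preexposure_obs_models() -> list[ModelSpec]:
    return [
        _spec("pre_obs_m1", "freezing_obs", [_dem_coupling()]),
        _spec("pre_obs_m2", "freezing_obs", [_t("preexposure_obs", "preexposure_obs"), _dem_coupling()]),
        _spec("pre_obs_m3", "freezing_obs", [_pregroup_dem_coupling()]),
        _spec(
            "pre_obs_m4",
            "freezing_obs",
            [_t("preexposure_obs", "preexposure_obs"), _pregroup_dem_coupling()],
        ),
    ]


# -- (de)serialisation --------------------------------------------------------

def save_model_spec(spec: ModelSpec, path) -> None:
    payload = {
        "name": spec.name,
        "target": spec.target,
        "bounds": list(spec.bounds),
        "prior_sd": spec.prior_sd,
        "terms": [
            {
                "name": t.name,
                "factors": [{"var": f.var, "complement": f.complement} for f in t.factors],
                "split_by": t.split_by,
                "split_levels": list(t.split_levels) if t.split_levels else None,
                "bounds": list(t.bounds) if t.bounds else None,
            }
            for t in spec.terms
        ],
    }
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=2))


def load_model_spec(path) -> ModelSpec:
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    terms = tuple(
        TermSpec(
            t["name"],
            tuple(Factor(f["var"], f.get("complement", False)) for f in t["factors"]),
            split_by=t.get("split_by"),
            split_levels=tuple(t["split_levels"]) if t.get("split_levels") else None,
            bounds=tuple(t["bounds"]) if t.get("bounds") else None,
        )
        for t in data["terms"]
    )
    return ModelSpec(
        data["name"],
        data["target"],
        terms,
        bounds=tuple(data.get("bounds", (-1.0, 1.0))),
        prior_sd=data.get("prior_sd", 2.0),
    )
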