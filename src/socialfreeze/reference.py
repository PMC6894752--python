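"""Published point estimates from the dyadic danger-transfer study.

These constants are *inputs*, not results: the winning-model coefficient
tables and model scores as printed, used to parameterise synthetic data,
to translate coupling coefficients into the simulator's coupling factor
``b = (partner-coupling coefficient) / (shock coefficient)``, and to line
comparison tables up with the published layout.
"""

from __future__ import annotations

__all__ = [
    "INDIV_DEM_WINNER",
    "INDIV_OBS_WINNER",
    "STRAIN_DEM_WINNER",
    "STRAIN_OBS_WINNER",
    "INDIV_DEM_ELPD",
    "coupling_factor_b",
]

# individual familiarity study, demonstrator target, winning model (model 6)
INDIV_DEM_WINNER = {
    "shock_dem": 0.47,
    "freezing_obs*shock_dem": 0.37,
    "sigma_dem": 0.12,
}

# individual familiarity study, observer target, winning model (model 2)
INDIV_OBS_WINNER = {
    "freezing_dem*shock_dem": 0.85,
    "sigma_obs": 0.19,
}

# strain familiarity study, demonstrator target, winning model (model 11)
STRAIN_DEM_WINNER = {
    "shock_dem": 0.30,
    "strain_dem*shock_dem": 0.10,
    "strain_dem*noshock_dem": 0.01,
    "freezing_obs*shock_dem": 0.40,
    "sigma_dem": 0.09,
}

# strain familiarity study, observer target, winning model (model 11)
STRAIN_OBS_WINNER = {
    "strain_obs*shock_dem": 0.04,
    "strain_obs*noshock_dem": 0.08,
    "preexposure_obs*shock_dem": 0.08,
    "preexposure_obs*noshock_dem": -0.01,
    "freezing_dem*shock_dem": 0.85,
    "sigma_obs": 0.13,
}

# elpd_loo (estimate, SE) per model, individual familiarity demonstrator table
INDIV_DEM_ELPD = {
    "indiv_dem_m1": (-27.2, 1.9),
    "indiv_dem_m4": (-23.0, 6.7),
    "indiv_dem_m3": (16.4, 10.3),
    "indiv_dem_m2": (20.5, 11.2),
    "indiv_dem_m5": (36.0, 16.4),
    "indiv_dem_m8": (36.1, 14.7),
    "indiv_dem_m7": (37.1, 13.5),
    "indiv_dem_m6": (41.5, 15.2),
}


def coupling_factor_b(winner: dict) -> float:
    """Simulator coupling factor implied by a winning demonstrator model:
    the ratio of the partner-coupling coefficient to the shock coefficient
    (the relative weight of social vs direct danger information)."""
    if "shock_dem" not in winner or "freezing_obs*shock_dem" not in winner:
        raise KeyError("winner table must contain shock and partner-coupling coefficients")
    return winner["freezing_obs*shock_dem"] / winner["shock_dem"]
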