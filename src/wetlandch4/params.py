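"""Central parameter file for the daily CH4 core.

The CH4 core is driven by a verbal process description (substrate supply from
root exudates, litter and labile soil organic matter; production limited by
soil temperature, texture and redox potential; emission split between plant
transport, ebullition and diffusion with pathway-specific oxidation).  Every
rate constant and functional-form coefficient used to make that description
numerical lives here, with literature-style defaults, so the model can be
re-tuned without touching code.  All values are overridable per run through
``ch4_params(**overrides)``.

Units are stated per key.  Pools are g C m-2; the dissolved store and the
saturation threshold are g CH4 m-2; fluxes are per day.
"""

from __future__ import annotations

CH4_DEFAULTS: dict[str, float] = {
    # temperature response of decomposition and methanogenesis
    "q10": 3.0,            # multiplicative rate change per 10 degC
    "t_ref": 30.0,         # degC, methanogen optimum reference
    # fraction of anaerobically decomposed carbon routed to CH4-C
    "y_ch4": 0.5,
    # redox control: full production at/below eh_full, zero at/above eh_zero
    "eh_min": -250.0,      # mV, floor under sustained flooding
    "eh_max": 300.0,       # mV, ceiling in drained soil
    "eh_full": -150.0,     # mV
    "eh_zero": -100.0,     # mV
    "eh_rate_down": 20.0,  # mV d-1 decline while standing water is present
    "eh_rate_up": 2.0,     # mV d-1 cm-1 recovery scaled by water-table deficit
    # soil texture index: SI = si_a + si_b * (sand% / 10)
    "si_a": 0.325,
    "si_b": 0.0225,
    # carbon content of plant dry matter
    "carbon_frac": 0.45,
    # first-order decomposition rates (d-1) at t_ref
    "k_litter": 0.01,
    "k_som": 1.0e-3,
    # labile fraction of soil organic matter and its carbon content
    "f_labile": 0.02,
    "som_carbon_frac": 0.58,
    "soil_depth_cm": 30.0,
    # emission pathways
    "k_diff": 0.08,            # d-1, diffusive loss from the dissolved store
    "c_sat": 1.5,              # g CH4 m-2, ebullition threshold under flooding
    "plant_transport_base": 0.55,  # scaled by aerenchyma factor and season
    "ox_plant": 0.5,           # fraction oxidized in transit through plants
    "ox_diff_flooded": 0.2,
    "ox_diff_drained": 0.9,
    # 5-day trailing window for the air->soil temperature smoother
    "t_soil_window": 5,
}

# Vegetation-specific traits for the two dominant Sanjiang marsh communities.
# k_e: fraction of ANPP carbon exuded by roots over the growing season.
# litter_input_frac: fraction of ANPP entering the litter pool at season end.
# transport_capacity: dimensionless aerenchyma factor (sedges > grasses).
VEG_TRAITS: dict[str, dict[str, float]] = {
    "deyeuxia": {
        "k_e": 0.25,
        "litter_input_frac": 0.45,
        "transport_capacity": 0.9,
    },
    "carex": {
        "k_e": 0.35,
        "litter_input_frac": 0.45,
        "transport_capacity": 1.2,
    },
}


def ch4_params(**overrides: float) -> dict[str, float]:
    """Return the default CH4 parameter set with keyword overrides applied.

    Unknown keys are rejected so typos cannot silently fall back to defaults.
    """
    bad = set(overrides) - set(CH4_DEFAULTS)
    if bad:
        raise KeyError(f"unknown CH4 parameter(s): {sorted(bad)}")
    out = dict(CH4_DEFAULTS)
    out.update(overrides)
    return out
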