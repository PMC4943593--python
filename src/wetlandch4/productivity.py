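"""Empirical annual ANPP driver.

The CH4 core needs annual above-ground net primary productivity (ANPP, g dry
matter m-2 yr-1) per cell.  Rather than coupling a full terrestrial
ecosystem model, this module provides a three-coefficient response surface

    ANPP = anpp0 * (1 + b_co2 * ln(CO2/CO2_ref))
                 * (1 + b_t * dT + b_p * dP_frac),   floored at 0

around a site baseline anpp0, capturing CO2 fertilisation (logarithmic),
warming and precipitation effects.  The coefficients are calibrated by
least squares against published decadal ANPP increments under the RCP
scenarios; any externally supplied per-year ANPP file can replace the
response surface entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = ["AnppModel", "npp_to_anpp", "anpp_response",
           "calibrate_anpp_coefficients"]

# baseline ANPP: midpoint of the 260-700 g m-2 range observed across the
# plain's marsh communities
DEFAULT_ANPP0 = 480.0


@dataclass(frozen=True)
class AnppModel:
    anpp0: float = DEFAULT_ANPP0   # g m-2 yr-1 at baseline conditions
    beta_co2: float = 0.0          # per ln(CO2 ratio)
    beta_t: float = 0.0            # per degC anomaly
    beta_p: float = 0.0            # per fractional precipitation anomaly
    ag_fraction: float = 0.5       # above-ground fraction of total NPP

    def __post_init__(self) -> None:
        if self.anpp0 <= 0:
            raise ValueError("anpp0 must be > 0")
        if not 0.0 < self.ag_fraction <= 1.0:
            raise ValueError("ag_fraction must be in (0, 1]")

    def replace(self, **kw) -> "AnppModel":
        return replace(self, **kw)


def npp_to_anpp(npp, ag_fraction: float):
    """Above-ground share of total NPP."""
    if not 0.0 < ag_fraction <= 1.0:
        raise ValueError("ag_fraction must be in (0, 1]")
    npp = np.asarray(npp, dtype=float)
    if np.any(npp < 0):
        raise ValueError("npp must be >= 0")
    return ag_fraction * npp


def anpp_response(model: AnppModel, dT, dP_frac, co2, co2_ref):
    """Annual ANPP (g m-2 yr-1) under the given anomalies, floored at zero."""
    co2 = np.asarray(co2, dtype=float)
    if np.any(co2 <= 0) or co2_ref <= 0:
        raise ValueError("CO2 concentrations must be > 0")
    fert = 1.0 + model.beta_co2 * np.log(co2 / co2_ref)
    clim = 1.0 + model.beta_t * np.asarray(dT, dtype=float) \
        + model.beta_p * np.asarray(dP_frac, dtype=float)
    return np.maximum(model.anpp0 * fert * clim, 0.0)


def calibrate_anpp_coefficients(trajectories: pd.DataFrame,
                                targets: pd.DataFrame,
                                anpp0: float = DEFAULT_ANPP0,
                                ag_fraction: float = 0.5) -> AnppModel:
    """Least-squares fit of (beta_co2, beta_t, beta_p) to decadal increments.

    trajectories: per (scenario, decade_start) the driver anomalies dT,
    dP_frac, co2 and co2_ref (e.g. from scenario_forge.scenario_trajectory).
    targets: per (scenario, decade_start) the ANPP increment vs the
    baseline decade, column dANPP_g_m2.  The design must span at least
    three decade rows and two scenarios and be well-conditioned (collinear
    single-scenario drivers are rejected).
    """
    merged = trajectories.merge(targets, on=["scenario", "decade_start"])
    if len(merged) < 3 or merged["scenario"].nunique() < 2:
        raise ValueError("need >= 3 target decades spanning >= 2 scenarios")

    L = np.log(merged["co2"].to_numpy() / merged["co2_ref"].to_numpy())
    dT = merged["dT"].to_numpy(dtype=float)
    dP = merged["dP_frac"].to_numpy(dtype=float)
    y = merged["dANPP_g_m2"].to_numpy(dtype=float)

    design = np.column_stack([L, dT, dP])
    if not np.any(np.abs(design) > 1e-12):
        raise ValueError("degenerate design: all driver anomalies are zero")
    sv = np.linalg.svd(design, compute_uv=False)
    if sv[0] == 0 or sv[-1] / sv[0] < 1e-8:
        raise ValueError("ill-conditioned design: drivers are collinear")

    def residual(beta):
        bc, bt, bp = beta
        model = (1.0 + bc * L) * (1.0 + bt * dT + bp * dP)
        return anpp0 * model - anpp0 - y

    fit = optimize.least_squares(residual, x0=[0.3, 0.02, 0.2],
                                 method="lm", max_nfev=10000)
    bc, bt, bp = fit.x
    return AnppModel(anpp0=anpp0, beta_co2=bc, beta_t=bt, beta_p=bp,
                     ag_fraction=ag_fraction)
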