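"""Daily substrate-based CH4 production, oxidation and emission model.

State per site/cell: a litter carbon pool, a labile soil-organic-carbon
pool, soil redox potential Eh, and a dissolved CH4 store.  Each day:

1. Soil temperature is a 5-day trailing mean of air temperature, clamped
   at 0 degC through the frozen season.
2. Eh falls at a fixed rate while standing water is present and recovers
   in proportion to the water-table deficit when drained, bounded in
   [-250, +300] mV.
3. Methanogenic substrate is the sum of root exudates (a fixed fraction of
   ANPP carbon released along a logistic-derivative seasonal allocation
   curve), first-order litter decomposition and first-order labile-SOM
   decomposition, the latter two with Q10 temperature scaling.
4. Production converts half of the decomposed carbon to CH4-C, modulated
   by a Q10 temperature factor (reference 30 degC), a linear Eh ramp
   (full below -150 mV, zero above -100 mV) and a sand-texture index.
5. The produced CH4 (as mass, 16/12 x CH4-C) enters the dissolved store
   and leaves via plant transport (partially oxidized in transit),
   ebullition of the excess above saturation when flooded (unoxidized),
   and diffusion (heavily oxidized when drained).  The daily mass balance
   production = emission + oxidation + store change is exact.

Redox dynamics see the true signed water table, while the transport and
ebullition pathways see the standing depth max(WT, 0): once a marsh has
been flooded for a while the emission becomes insensitive to how deep the
standing water is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import CH4_DEFAULTS, VEG_TRAITS, ch4_params

__all__ = [
    "SoilProfile", "VegetationTraits", "MethaneState",
    "growth_allocation", "soil_temperature", "update_eh",
    "substrate_supply", "production_rate", "partition_and_oxidize",
    "simulate_ch4_daily", "annual_flux", "vegetation_traits",
]

CH4_MASS_PER_C = 16.0 / 12.0

# growing season: May 1 - Sep 30 (153 days)
SEASON_START = (5, 1)
SEASON_END = (9, 30)
SEASON_LENGTH = 153


@dataclass(frozen=True)
class SoilProfile:
    sand: float          # % mass
    som: float           # g kg-1 soil organic matter
    bulk_density: float  # g cm-3

    def __post_init__(self) -> None:
        if not 0.0 <= self.sand <= 100.0:
            raise ValueError("sand must be in [0, 100] %")
        if self.som < 0:
            raise ValueError("som must be >= 0")
        if self.bulk_density <= 0:
            raise ValueError("bulk_density must be > 0")


@dataclass(frozen=True)
class VegetationTraits:
    label: str
    k_e: float                 # fraction of ANPP-C exuded over the season
    litter_input_frac: float   # fraction of ANPP entering litter at season end
    transport_capacity: float  # dimensionless aerenchyma factor

    def __post_init__(self) -> None:
        if not 0.0 <= self.k_e <= 1.0:
            raise ValueError("k_e must be in [0, 1]")
        if not 0.0 <= self.litter_input_frac <= 1.0:
            raise ValueError("litter_input_frac must be in [0, 1]")
        if self.transport_capacity < 0:
            raise ValueError("transport_capacity must be >= 0")


def vegetation_traits(label: str) -> VegetationTraits:
    if label not in VEG_TRAITS:
        raise ValueError(
            f"unknown vegetation {label!r}; expected one of {sorted(VEG_TRAITS)}")
    return VegetationTraits(label=label, **VEG_TRAITS[label])


@dataclass
class MethaneState:
    """Evolving state of the CH4 core (all pools g C or g CH4 per m2)."""

    litter_pool: float = 0.0
    labile_som_pool: float = 0.0
    eh: float = 0.0              # mV
    dissolved_ch4: float = 0.0   # g CH4 m-2
    flooded_days: int = 0


# --- seasonal allocation curve ----------------------------------------------

def _season_curve() -> np.ndarray:
    """Normalized daily allocation over the 153-day growing season.

    Logistic growth-derivative shape (bell-like, peak mid season), scaled
    so the daily weights sum to exactly 1.
    """
    dos = np.arange(SEASON_LENGTH, dtype=float)
    x = (dos - (SEASON_LENGTH - 1) / 2.0) / 18.0
    g = np.exp(-x) / (1.0 + np.exp(-x)) ** 2
    return g / g.sum()


_SEASON_G = _season_curve()
_SEASON_G_PEAK = float(_SEASON_G.max())


def day_of_season(date: pd.Timestamp) -> int:
    """Days since May 1 (0-based), or -1 outside the growing season."""
    start = pd.Timestamp(date.year, *SEASON_START)
    end = pd.Timestamp(date.year, *SEASON_END)
    if date < start or date > end:
        return -1
    return int((date - start).days)


def growth_allocation(date: pd.Timestamp) -> float:
    """g(t): fraction of seasonal exudation allocated to this day."""
    dos = day_of_season(date)
    return 0.0 if dos < 0 else float(_SEASON_G[dos])


# --- daily process steps ----------------------------------------------------

def soil_temperature(air_t_history) -> float:
    """Soil temperature proxy: trailing mean of recent air temperature,
    clamped at 0 degC (frozen soil does not track sub-zero air)."""
    hist = np.asarray(air_t_history, dtype=float)
    if hist.size == 0:
        raise ValueError("need at least one day of air-temperature history")
    window = int(CH4_DEFAULTS["t_soil_window"])
    return max(float(hist[-window:].mean()), 0.0)


def soil_temperature_series(air_t: pd.Series) -> np.ndarray:
    """Vectorised trailing-mean soil temperature for a whole series."""
    window = int(CH4_DEFAULTS["t_soil_window"])
    return air_t.rolling(window, min_periods=1).mean().clip(lower=0.0).to_numpy()


def update_eh(state: MethaneState, wt: float,
              params: dict[str, float] | None = None) -> float:
    """Advance soil redox potential one day given the signed water table."""
    p = params or CH4_DEFAULTS
    if wt >= 0.0:
        eh = max(state.eh - p["eh_rate_down"], p["eh_min"])
    else:
        eh = min(state.eh + p["eh_rate_up"] * abs(wt), p["eh_max"])
    return eh


def _q10_factor(t_soil: float, p: dict[str, float]) -> float:
    return p["q10"] ** ((t_soil - p["t_ref"]) / 10.0)


def substrate_supply(traits: VegetationTraits, anpp: float,
                     date: pd.Timestamp, state: MethaneState,
                     t_soil: float,
                     params: dict[str, float] | None = None) -> float:
    """Daily methanogenic substrate (g C m-2 d-1); mutates the pools.

    Exudate input follows the seasonal allocation curve; litter and labile
    SOM decompose first-order with Q10 scaling and are decremented by their
    contributions.  On the last day of the growing season the litter pool
    is replenished from that year's ANPP.
    """
    if anpp < 0:
        raise ValueError("anpp must be >= 0")
    p = params or CH4_DEFAULTS
    s_ex = traits.k_e * p["carbon_frac"] * anpp * growth_allocation(date)
    ft = _q10_factor(t_soil, p)
    s_litter = min(p["k_litter"] * ft, 1.0) * state.litter_pool
    s_som = min(p["k_som"] * ft, 1.0) * state.labile_som_pool
    state.litter_pool -= s_litter
    state.labile_som_pool -= s_som
    if (date.month, date.day) == SEASON_END:
        state.litter_pool += traits.litter_input_frac * p["carbon_frac"] * anpp
    return s_ex + s_litter + s_som


def texture_index(soil: SoilProfile,
                  params: dict[str, float] | None = None) -> float:
    """Sand index SI = si_a + si_b * sand%: methanogenesis is faster in
    coarser-textured soil (the index argument is the sand percentage)."""
    p = params or CH4_DEFAULTS
    return p["si_a"] + p["si_b"] * soil.sand


def _eh_factor(eh: float, p: dict[str, float]) -> float:
    if eh <= p["eh_full"]:
        return 1.0
    if eh >= p["eh_zero"]:
        return 0.0
    return (p["eh_zero"] - eh) / (p["eh_zero"] - p["eh_full"])


def production_rate(s_total: float, t_soil: float, eh: float,
                    soil: SoilProfile,
                    params: dict[str, float] | None = None) -> float:
    """CH4-C production (g C m-2 d-1) from substrate and limiters."""
    p = params or CH4_DEFAULTS
    if not all(np.isfinite([s_total, t_soil, eh])):
        raise ValueError("inputs must be finite")
    return (p["y_ch4"] * s_total * _q10_factor(t_soil, p)
            * _eh_factor(eh, p) * texture_index(soil, p))


def partition_and_oxidize(p_ch4c: float, state: MethaneState,
                          standing_wt: float, traits: VegetationTraits,
                          g_norm: float,
                          params: dict[str, float] | None = None):
    """Route one day's production through the three emission pathways.

    p_ch4c is CH4-C; it enters the dissolved store as CH4 mass.  Plant
    transport removes min(1, base * aerenchyma * seasonal factor) of the
    store with half oxidized in transit; ebullition exports the excess
    above saturation unoxidized when standing water is present; diffusion
    removes a fixed fraction of the remainder, mostly oxidized when the
    soil is drained.  Returns (emission, oxidized, dict of pathway fluxes);
    mutates the dissolved store.  Mass balance is exact by construction.
    """
    if p_ch4c < 0:
        raise ValueError("production must be >= 0")
    p = params or CH4_DEFAULTS
    prod_mass = CH4_MASS_PER_C * p_ch4c
    store = state.dissolved_ch4 + prod_mass

    f_p = min(1.0, p["plant_transport_base"] * traits.transport_capacity * g_norm)
    transported = f_p * store
    store -= transported
    plant_emit = (1.0 - p["ox_plant"]) * transported
    oxidized = p["ox_plant"] * transported

    ebullition = 0.0
    if standing_wt >= 0.0 and store > p["c_sat"]:
        ebullition = store - p["c_sat"]
        store -= ebullition

    diffused = p["k_diff"] * store
    store -= diffused
    ox_frac = p["ox_diff_flooded"] if standing_wt >= 0.0 else p["ox_diff_drained"]
    diff_emit = (1.0 - ox_frac) * diffused
    oxidized += ox_frac * diffused

    state.dissolved_ch4 = store
    emission = plant_emit + ebullition + diff_emit
    pathways = {"plant": plant_emit, "ebullition": ebullition,
                "diffusion": diff_emit}
    return emission, oxidized, pathways


# --- orchestration ----------------------------------------------------------

def _initial_state(soil: SoilProfile, traits: VegetationTraits,
                   anpp0: float, p: dict[str, float]) -> MethaneState:
    # labile SOM-C: labile fraction of the SOM stock in the active layer
    soil_mass_kg_m2 = soil.bulk_density * 1000.0 * p["soil_depth_cm"] / 100.0
    som_c = soil.som * soil_mass_kg_m2 * p["som_carbon_frac"]
    labile = p["f_labile"] * som_c
    # one season's litter carried over from the previous year
    litter = traits.litter_input_frac * p["carbon_frac"] * anpp0
    return MethaneState(litter_pool=litter, labile_som_pool=labile,
                        eh=0.0, dissolved_ch4=0.0)


def simulate_ch4_daily(climate: pd.DataFrame,
                       wt_series: pd.DataFrame,
                       anpp_by_year: dict[int, float] | pd.Series,
                       soil: SoilProfile,
                       traits: VegetationTraits,
                       params: dict[str, float] | None = None,
                       initial_state: MethaneState | None = None) -> pd.DataFrame:
    """Run the CH4 core day by day over aligned climate and water-table series.

    Returns a frame with date, flux (g CH4 m-2 d-1), production and
    oxidation (same units), the pathway components, the dissolved store,
    eh, soil temperature and the forcing water table.  Annual totals are
    available via :func:`annual_flux`.
    """
    p = params or ch4_params()
    dates = pd.DatetimeIndex(climate["date"])
    wt_dates = pd.DatetimeIndex(wt_series["date"])
    if len(dates) != len(wt_dates) or not (dates == wt_dates).all():
        raise ValueError("climate and water-table series are misaligned")
    anpp = dict(anpp_by_year)
    missing = set(dates.year.unique()) - set(int(y) for y in anpp)
    if missing:
        raise ValueError(f"missing ANPP for years {sorted(missing)}")

    t_soil = soil_temperature_series(climate["t_mean"])
    wt = np.asarray(wt_series["wt"], dtype=float)
    years = dates.year.to_numpy()

    state = initial_state or _initial_state(
        soil, traits, anpp[int(years[0])], p)

    n = len(dates)
    out = {k: np.zeros(n) for k in
           ("flux", "production", "oxidized", "plant", "ebullition",
            "diffusion", "store", "eh", "t_soil")}
    for i in range(n):
        date = dates[i]
        state.eh = update_eh(state, wt[i], p)
        if wt[i] >= 0:
            state.flooded_days += 1
        else:
            state.flooded_days = 0
        s_total = substrate_supply(traits, anpp[int(years[i])], date,
                                   state, t_soil[i], p)
        prod_c = production_rate(s_total, t_soil[i], state.eh, soil, p)
        dos = day_of_season(date)
        g_norm = 0.0 if dos < 0 else float(_SEASON_G[dos]) / _SEASON_G_PEAK
        emission, oxidized, paths = partition_and_oxidize(
            prod_c, state, max(wt[i], 0.0), traits, g_norm, p)
        out["flux"][i] = emission
        out["production"][i] = CH4_MASS_PER_C * prod_c
        out["oxidized"][i] = oxidized
        out["plant"][i] = paths["plant"]
        out["ebullition"][i] = paths["ebullition"]
        out["diffusion"][i] = paths["diffusion"]
        out["store"][i] = state.dissolved_ch4
        out["eh"][i] = state.eh
        out["t_soil"][i] = t_soil[i]

    frame = pd.DataFrame({"date": dates, "wt": wt, **out})
    return frame


def annual_flux(series: pd.DataFrame, year: int) -> float:
    """Calendar-year total CH4 emission (g CH4 m-2 yr-1)."""
    mask = pd.DatetimeIndex(series["date"]).year == year
    if not mask.any():
        raise ValueError(f"year {year} not present in the series")
    return float(series.loc[mask, "flux"].sum())


def annual_flux_series(series: pd.DataFrame) -> pd.Series:
    """All calendar-year totals, indexed by year."""
    years = pd.DatetimeIndex(series["date"]).year
    return series.groupby(years)["flux"].sum().rename("annual_flux")
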