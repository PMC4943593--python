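"""Regional aggregation, wetland-area scenarios and CO2-equivalent budgets.

Per-cell annual fluxes (g CH4 m-2 yr-1) are combined with the wetland area
mask into area-weighted means and regional totals (Tg yr-1); the
restoration scenario scales emissions by the planned area expansion
(+25 % by 2100, applied as a single end-state factor on the uniformly
distributed restored area); totals convert to CO2-equivalents with a
100-year GWP of 25 by default.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "area_weighted_mean", "regional_emission", "apply_restoration",
    "to_co2_eq", "decadal_anomaly_table", "subregion_percent_change",
]

G_PER_M2_KM2_TO_TG = 1e6 * 1e-12  # g m-2 x km2 -> Tg
DEFAULT_RESTORATION_FRACTION = 0.25
DEFAULT_GWP = 25.0
BASELINE_DECADE = (2001, 2010)


def area_weighted_mean(values, areas) -> float:
    """Sum(v*a)/Sum(a) over cells."""
    values = np.asarray(values, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if values.shape != areas.shape:
        raise ValueError("values and areas must have equal length")
    total = areas.sum()
    if total <= 0:
        raise ValueError("total area must be > 0")
    return float((values * areas).sum() / total)


def regional_emission(flux_g_m2, area_km2) -> float:
    """Regional total (Tg yr-1) from per-cell fluxes and wetland areas."""
    flux = np.asarray(flux_g_m2, dtype=float)
    area = np.asarray(area_km2, dtype=float)
    if flux.shape != area.shape:
        raise ValueError("flux and area must have equal length")
    if np.any(area < 0):
        raise ValueError("areas must be >= 0")
    return float((flux * area).sum() * G_PER_M2_KM2_TO_TG)


def apply_restoration(emission_tg: float,
                      fraction: float = DEFAULT_RESTORATION_FRACTION) -> float:
    """Scale a regional emission by the wetland-area expansion fraction."""
    if fraction < -1.0:
        raise ValueError("fraction must be >= -1")
    return emission_tg * (1.0 + fraction)


def to_co2_eq(emission_tg_ch4: float, gwp: float = DEFAULT_GWP) -> float:
    """Convert Tg CH4 to Tg CO2-equivalent."""
    if gwp <= 0:
        raise ValueError("gwp must be > 0")
    return emission_tg_ch4 * gwp


def decadal_anomaly_table(annual: pd.DataFrame,
                          baseline: tuple[int, int] = BASELINE_DECADE
                          ) -> pd.DataFrame:
    """Decade-mean anomalies of annual series vs the baseline decade.

    annual: frame indexed by year, one column per variable.  Returns one
    row per decade from 2011-2020 onward (within the data), columns
    mirroring the input plus decade bounds.  Decades with no data are
    skipped with a warning.
    """
    years = annual.index.to_numpy()
    base_mask = (years >= baseline[0]) & (years <= baseline[1])
    if not base_mask.any():
        raise ValueError("baseline years absent from the annual series")
    base_mean = annual.loc[base_mask].mean()

    rows = []
    last = int(years.max())
    for start in range(baseline[1] + 1, last + 1, 10):
        end = start + 9
        mask = (years >= start) & (years <= end)
        if not mask.any():
            warnings.warn(f"decade {start}-{end} missing from the series")
            continue
        row = (annual.loc[mask].mean() - base_mean).to_dict()
        rows.append({"decade_start": start, "decade_end": end, **row})
    return pd.DataFrame(rows)


def subregion_percent_change(cell_annual: pd.DataFrame,
                             areas: pd.Series,
                             labels: pd.Series,
                             baseline: tuple[int, int] = BASELINE_DECADE,
                             horizon: tuple[int, int] = (2091, 2100)
                             ) -> pd.Series:
    """Percent change of area-weighted flux per subregion.

    cell_annual: years x cells frame of annual fluxes; areas and labels
    are indexed by the same cell ids.  Returns 100 * (horizon mean -
    baseline mean) / baseline mean per label; subregions with zero
    baseline flux are reported as NaN with a warning.
    """
    cells = cell_annual.columns
    if set(cells) - set(labels.index) or set(cells) - set(areas.index):
        raise ValueError("every cell must have an area and a subregion label")
    years = cell_annual.index.to_numpy()
    bmask = (years >= baseline[0]) & (years <= baseline[1])
    hmask = (years >= horizon[0]) & (years <= horizon[1])
    if not bmask.any() or not hmask.any():
        raise ValueError("baseline or horizon years absent")

    out = {}
    for label in sorted(labels.unique()):
        ids = [c for c in cells if labels[c] == label]
        a = areas[ids].to_numpy()
        base = area_weighted_mean(
            cell_annual.loc[bmask, ids].mean(axis=0).to_numpy(), a)
        hor = area_weighted_mean(
            cell_annual.loc[hmask, ids].mean(axis=0).to_numpy(), a)
        if base == 0:
            warnings.warn(f"zero baseline flux in subregion {label}")
            out[label] = np.nan
        else:
            out[label] = 100.0 * (hor - base) / base
    return pd.Series(out, name="pct_change")
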