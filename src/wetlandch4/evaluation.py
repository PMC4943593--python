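"""Validation statistics and calibration test harness.

Observed-versus-simulated regression (slope, R2, p, RMSE), linear trends of
annual series expressed per decade, and a Monte-Carlo parameter-recovery
experiment for the water-table calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["RegressionResult", "regression_metrics", "linear_trend",
           "recovery_experiment"]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    n: int
    p_value: float
    rmse: float
    degenerate: bool = False


def regression_metrics(observed, simulated,
                       swap_axes: bool = False) -> RegressionResult:
    """OLS of observed on simulated (or swapped), with fit diagnostics.

    The default axis convention regresses the observations on the model;
    swap_axes reverses it.  A constant predictor leaves the slope
    undefined and is reported as degenerate rather than raising.
    """
    obs = np.asarray(observed, dtype=float)
    sim = np.asarray(simulated, dtype=float)
    if obs.shape != sim.shape or obs.ndim != 1:
        raise ValueError("observed and simulated must be equal-length 1-D")
    if len(obs) < 3:
        raise ValueError("need at least 3 points")
    if not (np.all(np.isfinite(obs)) and np.all(np.isfinite(sim))):
        raise ValueError("inputs must be finite")
    x, y = (obs, sim) if swap_axes else (sim, obs)
    if np.ptp(x) == 0:
        return RegressionResult(np.nan, np.nan, 0.0, len(obs), np.nan,
                                float(np.sqrt(np.mean((y - y.mean()) ** 2))),
                                degenerate=True)
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue ** 2),
        n=len(obs),
        p_value=float(fit.pvalue),
        rmse=float(np.sqrt(np.mean(resid ** 2))),
    )


def linear_trend(annual: pd.Series) -> tuple[float, float]:
    """Fitted linear trend of an annual series, per decade, with p-value.

    annual is indexed by year; the slope is the per-year OLS coefficient
    times 10, the p-value the two-sided t-test on the slope.
    """
    if len(annual) < 10:
        raise ValueError("need at least 10 annual values for a trend")
    years = np.asarray(annual.index, dtype=float)
    fit = stats.linregress(years, np.asarray(annual, dtype=float))
    return float(fit.slope * 10.0), float(fit.pvalue)


def recovery_experiment(truth, noise_sd: float, n_reps: int, seed: int = 0,
                        climate: pd.DataFrame | None = None,
                        bounds: dict | None = None) -> pd.DataFrame:
    """Calibration self-test: plant known parameters, recover them n_reps times.

    For each replicate, water-table pseudo-observations are generated from
    the planted truth with the given noise, the calibration is run, and
    the recovered (alpha0, a1, a2) are recorded.  The returned frame
    carries one row per replicate plus ``attrs['summary']`` with
    per-parameter bias and RMSE.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    from .hydrology import calibrate_ehm
    from .scenario_forge import (SCENARIOS, generate_climate_series,
                                 generate_synthetic_observations)

    if climate is None:
        spec = SCENARIOS["baseline"].replace(years=(2001, 2002), seed=seed)
        climate = generate_climate_series(spec)

    rows = []
    for rep in range(n_reps):
        obs = generate_synthetic_observations(
            truth, climate, noise_sd, seed=seed + 1000 * (rep + 1))
        obs = obs.rename(columns={"wt_obs": "wt_obs"})
        fitted, rmse = calibrate_ehm(obs, climate, bounds=bounds,
                                     seed=seed + rep, base_params=truth)
        rows.append({"rep": rep, "alpha0": fitted.alpha0, "a1": fitted.a1,
                     "a2": fitted.a2, "rmse": rmse})
    frame = pd.DataFrame(rows)
    summary = {}
    for name in ("alpha0", "a1", "a2"):
        true_val = getattr(truth, name)
        err = frame[name] - true_val
        summary[name] = {"truth": true_val,
                         "bias": float(err.mean()),
                         "rmse": float(np.sqrt((err ** 2).mean()))}
    frame.attrs["summary"] = summary
    return frame
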