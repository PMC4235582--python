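"""Home-range-scale functional response of gravel road use.

Availability per data set is the share of the home range's land area inside
a 30 m corridor along gravel roads; use is the share of hourly positions
within 30 m of a gravel road (both in percent, matching the scale on which
the published intercept/slope are plausible). Proportional use implies a
linear relationship with slope 1 and intercept 0, tested per reproductive
status with ordinary least squares after backward elimination of the
candidate covariates (home-range size, median Julian date, sex); the
availability term itself is never eliminated since the slope test is the
point of the model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .geoprimitives import ConvexPolygon, buffered_network_land_fraction, distances_to_network, mcp
from .stats_core import FitResult, backward_eliminate, fit_ols
from .synthetic_data import Landscape
from .trajectory import ROAD_THRESHOLD

AVAIL_TERM = "availability_pct"


def compute_fr_record(
    hourly: pd.DataFrame,
    landscape: Landscape,
    home_range: ConvexPolygon | None = None,
    width: float = ROAD_THRESHOLD,
) -> dict:
    """Availability and use percentages for one data set.

    Availability = % of the home range's non-water land area within
    ``width`` m of a gravel road; use = % of hourly fixes within ``width`` m
    of a gravel road. The home range defaults to the 100% MCP of the fixes.
    """
    if len(hourly) == 0:
        raise ValueError("no fixes for this data set")
    pts = hourly[["x", "y"]].to_numpy()
    hr = home_range if home_range is not None else mcp(pts)
    gravel = landscape.roads.subset("gravel")
    if gravel.is_empty():
        availability = 0.0
        use = 0.0
    else:
        availability = 100.0 * buffered_network_land_fraction(
            gravel, hr, landscape.grid, width
        )
        d = distances_to_network(pts, landscape.roads, "gravel")
        use = 100.0 * float(np.mean(d <= width))
    rec = {
        "availability_pct": availability,
        "use_pct": use,
        "home_range_km2": hr.area_km2,
        "median_julian": float(np.median(hourly["timestamp"].dt.dayofyear)),
        "n_fixes": int(len(hourly)),
    }
    return rec


def fit_functional_response(
    records: pd.DataFrame, status: str, alpha: float = 0.05
) -> dict:
    """OLS of use on availability for one status group, with the slope-vs-1
    and intercept-vs-0 t-tests.

    Returns the final :class:`FitResult` plus the two tests (t statistic and
    two-sided P on n - p residual degrees of freedom) and R2.
    """
    grp = records.loc[records["reproduction"] == status].reset_index(drop=True)
    if len(grp) < 5:
        raise ValueError(f"only {len(grp)} records for status {status!r}; need >= 5")
    terms = [AVAIL_TERM, "home_range_km2", "median_julian"]
    if "sex" in grp.columns and grp["sex"].nunique() > 1:
        terms.append("C(sex)")

    def fit_fn(ts):
        return fit_ols(grp, "use_pct", ts)

    final, trace = backward_eliminate(fit_fn, terms, alpha=alpha, protected=(AVAIL_TERM,))
    b = float(final.params[AVAIL_TERM])
    se_b = float(final.se[AVAIL_TERM])
    df_resid = final.meta["df_resid"]
    t_slope = (b - 1.0) / se_b
    p_slope = 2 * stats.t.sf(abs(t_slope), df_resid)
    b0 = float(final.params.get("Intercept", 0.0))
    se0 = float(final.se.get("Intercept", np.nan))
    t_int = b0 / se0 if se0 > 0 else np.nan
    p_int = 2 * stats.t.sf(abs(t_int), df_resid) if np.isfinite(t_int) else np.nan
    return {
        "fit": final,
        "slope": b,
        "slope_se": se_b,
        "slope_p": float(final.pvalues[AVAIL_TERM]),
        "intercept": b0,
        "intercept_se": se0,
        "t_slope_vs_1": float(t_slope),
        "p_slope_vs_1": float(p_slope),
        "t_intercept_vs_0": float(t_int),
        "p_intercept_vs_0": float(p_int),
        "r2": final.meta["r2"],
        "n": len(grp),
        "trace": trace,
    }
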