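"""Travel-speed analysis.

A linear mixed model of step speed (km/h) with the 3-state road variable in
interaction with reproductive status and time of day, sex as a candidate
covariate, data-set-in-territory nested random intercepts, stepwise backward
elimination at alpha = 0.05, and Nakagawa marginal/conditional R2. Reference
levels: Road = on, Reproduction = nonbreeding, Time of day = Day.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats_core import FitResult, backward_eliminate, fit_lmm, nakagawa_r2

ROAD = "C(road, Treatment('on'))"
REPRO = "C(reproduction, Treatment('nonbreeding'))"
TOD = "C(time_of_day, Treatment('Day'))"
SEX = "C(sex)"

FULL_TERMS = [
    ROAD,
    REPRO,
    TOD,
    SEX,
    f"{ROAD}:{REPRO}",
    f"{ROAD}:{TOD}",
    f"{REPRO}:{TOD}",
]


def speed_records(
    steps: pd.DataFrame, dataset_meta: pd.DataFrame
) -> pd.DataFrame:
    """Join speed steps with per-dataset reproduction status and sex.

    ``dataset_meta`` needs columns dataset_id, reproduction
    ('breeding'/'nonbreeding') and sex.
    """
    rec = steps.merge(dataset_meta, on="dataset_id", how="left")
    cols = [
        "speed_kmh", "road", "reproduction", "time_of_day", "sex",
        "dataset_id", "territory_id",
    ]
    return rec[cols].dropna().reset_index(drop=True)


def fit_speed_model(
    records: pd.DataFrame, alpha: float = 0.05
) -> tuple[FitResult, tuple[float, float], list]:
    """Backward-eliminated LMM of travel speed; returns fit, (R2m, R2c), trace."""
    for col, label in (("road", "Road"), ("reproduction", "Reproduction"),
                       ("time_of_day", "Time of day")):
        if records[col].nunique() < 2:
            raise ValueError(f"design error: factor {label} has a single level")
    if records["territory_id"].nunique() < 2:
        raise ValueError("need at least 2 territories")

    terms = [t for t in FULL_TERMS if not (t == SEX and records["sex"].nunique() < 2)]

    def fit_fn(ts):
        return fit_lmm(records, "speed_kmh", ts)

    final, trace = backward_eliminate(fit_fn, terms, alpha=alpha)
    return final, nakagawa_r2(final), trace


def predicted_speed(fit: FitResult, road: str, reproduction: str, time_of_day: str) -> float:
    """Fixed-effect predicted mean speed for one factor combination."""
    grid = pd.DataFrame(
        {
            "road": [road],
            "reproduction": [reproduction],
            "time_of_day": [time_of_day],
            "sex": ["F"],
        }
    )
    # rebuild design on a frame carrying all levels so contrasts match
    ref = pd.DataFrame(
        {
            "road": ["on", "partly", "off"] * 4,
            "reproduction": (["nonbreeding"] * 3 + ["breeding"] * 3) * 2,
            "time_of_day": ["Day"] * 6 + ["Night"] * 6,
            "sex": ["F", "M"] * 6,
        }
    )
    from .stats_core import build_design

    frame = pd.concat([grid, ref], ignore_index=True)
    X, _ = build_design(frame, fit.terms)
    X = X[[c for c in X.columns if c in fit.params.index]]
    eta = X.to_numpy() @ fit.params.reindex(X.columns).to_numpy()
    return float(eta[0])


def summarize_speeds(records: pd.DataFrame) -> pd.DataFrame:
    """Per-road-state n, mean and SD of speed, with the on/off ratio attached."""
    rows = []
    for state in ("on", "partly", "off"):
        grp = records.loc[records["road"] == state, "speed_kmh"]
        if len(grp) == 0:
            import warnings

            warnings.warn(f"no steps in road state {state!r}; omitted")
            continue
        rows.append(
            {
                "road": state,
                "n": int(len(grp)),
                "mean_kmh": float(grp.mean()),
                "sd_kmh": float(grp.std(ddof=1)) if len(grp) > 1 else 0.0,
            }
        )
    out = pd.DataFrame(rows)
    means = dict(zip(out["road"], out["mean_kmh"]))
    if "on" in means and "off" in means and means["off"] > 0:
        out.attrs["on_off_ratio"] = means["on"] / means["off"]
    return out
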