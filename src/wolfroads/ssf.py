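"""Site-scale step selection functions (SSFs).

Each real hourly step is matched to 10 random steps drawn from the empirical
step-length and turning-angle distributions of its step category (SS / SC /
CS / CC, sampled independently); the 11 steps form a stratum. End points are
annotated with distances to the nearest gravel road, main road and house
(km), the land-cover class (steps ending in water are reassigned the nearest
terrestrial class), and 30 m on-road indicators. Conditional logistic
models with territory-clustered robust SEs are fitted for all steps and for
each time-of-day x behavior subset, and validated leave-one-territory-out
with a one-sided paired Wilcoxon test on within-stratum ranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import rankdata

from .geoprimitives import distances_to_network, landcover_at_many
from .stats_core import (
    FitResult,
    UnidentifiableError,
    backward_eliminate,
    build_design,
    fit_conditional_logistic,
    pearson_screen,
    wilcoxon_signed_rank,
)
from .synthetic_data import Landscape
from .trajectory import ROAD_THRESHOLD

CATEGORIES = ("SS", "SC", "CS", "CC")
DISTANCE_COVARIATES = ["gravel_km", "main_km", "house_km"]
HABITAT_DUMMIES = ["mire", "open"]


@dataclass
class EmpiricalStepDistribution:
    """Raw per-category samples of step length (m) and turning angle (rad)."""

    category: str
    lengths: np.ndarray
    angles: np.ndarray
    borrowed: bool = False


def build_distributions(
    steps: pd.DataFrame, min_per_category: int = 30
) -> dict[str, EmpiricalStepDistribution]:
    """Per-category empirical distributions from the real steps.

    Raw samples are kept (no binning). Steps without a defined turning angle
    donate their length only. Categories below the floor borrow the pooled
    sample, with a warning.
    """
    if len(steps) == 0:
        raise ValueError("no steps available")
    pooled_len = steps["length"].to_numpy()
    pooled_ang = steps["turning_angle"].dropna().to_numpy()
    out = {}
    for cat in CATEGORIES:
        sub = steps.loc[steps["category"] == cat]
        lengths = sub["length"].to_numpy()
        angles = sub["turning_angle"].dropna().to_numpy()
        if len(sub) < min_per_category or len(angles) == 0:
            warnings.warn(
                f"category {cat}: {len(sub)} steps < floor {min_per_category}; "
                "borrowing the pooled distribution"
            )
            out[cat] = EmpiricalStepDistribution(cat, pooled_len, pooled_ang, borrowed=True)
        else:
            out[cat] = EmpiricalStepDistribution(cat, lengths, angles)
    return out


def generate_random_steps(
    start: np.ndarray,
    prev_bearing: float,
    dist: EmpiricalStepDistribution,
    n: int,
    rng: np.random.Generator,
    extent: tuple[float, float, float, float],
    max_attempts: int = 100,
) -> np.ndarray | None:
    """Draw ``n`` random end points for one real step.

    Length and turning angle are sampled independently from the category's
    raw samples; the end point is the start displaced by the drawn length at
    bearing (previous bearing + drawn angle). Without a previous bearing the
    drawn angles are used as absolute bearings. End points outside the
    landscape are redrawn up to ``max_attempts`` times each; returns None
    (stratum dropped) on failure.
    """
    x0, y0, x1, y1 = extent
    base = 0.0 if np.isnan(prev_bearing) else prev_bearing
    pts = np.empty((n, 2))
    for i in range(n):
        for attempt in range(max_attempts):
            L = float(rng.choice(dist.lengths))
            if np.isnan(prev_bearing):
                ang = float(rng.uniform(-np.pi, np.pi)) if len(dist.angles) == 0 else float(rng.choice(dist.angles))
                bearing = base + ang if len(dist.angles) else ang
            else:
                bearing = base + float(rng.choice(dist.angles))
            ex = start[0] + L * np.cos(bearing)
            ey = start[1] + L * np.sin(bearing)
            if x0 <= ex < x1 and y0 <= ey < y1:
                pts[i] = (ex, ey)
                break
        else:
            return None
    return pts


def annotate_endpoints(points: np.ndarray, landscape: Landscape) -> pd.DataFrame:
    """End-point covariates: distances (km), habitat, 30 m road indicators."""
    pts = np.asarray(points, dtype=float)
    d_gravel = distances_to_network(pts, landscape.roads, "gravel")
    d_main = distances_to_network(pts, landscape.roads, "main")
    if len(landscape.houses) > 0:
        d_house, _ = landscape.house_tree().query(pts)
    else:
        d_house = np.full(len(pts), np.nan)
    habitat = landcover_at_many(pts, landscape.grid, terrestrial_fallback=True)
    return pd.DataFrame(
        {
            "gravel_km": d_gravel / 1000.0,
            "main_km": d_main / 1000.0,
            "house_km": d_house / 1000.0,
            "habitat": habitat,
            "on_gravel": (d_gravel <= ROAD_THRESHOLD).astype(int),
            "on_main": (d_main <= ROAD_THRESHOLD).astype(int),
        }
    )


def build_strata(
    steps: pd.DataFrame,
    dists: dict[str, EmpiricalStepDistribution],
    landscapes: dict[str, Landscape],
    n_random: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Assemble 1:``n_random`` matched strata with annotated end points.

    ``landscapes`` maps territory_id to its landscape. Each retained real
    step contributes one stratum of 11 rows (y = 1 for the real end point).
    Quadratic distance covariates (``*_sq``) are centered on the table-wide
    mean before squaring.
    """
    rng = np.random.default_rng(seed)
    frames = []
    dropped = 0
    steps = steps.reset_index(drop=True)
    for tid, grp in steps.groupby("territory_id", sort=True):
        land = landscapes[tid]
        extent = land.extent
        pts_all, meta = [], []
        for idx, row in grp.iterrows():
            start = np.array([row["x0"], row["y0"]])
            prev = row.get("prev_bearing", np.nan)
            prev = prev if np.isfinite(prev) else np.nan
            endpoints = generate_random_steps(
                start, prev, dists[row["category"]], n_random, rng, extent
            )
            if endpoints is None:
                dropped += 1
                continue
            real_end = np.array([[row["x1"], row["y1"]]])
            block = np.vstack([real_end, endpoints])
            pts_all.append(block)
            meta.append(
                {
                    "stratum_id": f"{row['dataset_id']}_{idx}",
                    "territory_id": tid,
                    "dataset_id": row["dataset_id"],
                    "time_of_day": row["time_of_day"],
                    "behavior": row["behavior"],
                    "category": row["category"],
                }
            )
        if not pts_all:
            continue
        pts = np.vstack(pts_all)
        # clamp numerical spill just outside the grid (real ends can sit on it)
        x0, y0, x1, y1 = extent
        pts[:, 0] = np.clip(pts[:, 0], x0, x1 - 1e-6)
        pts[:, 1] = np.clip(pts[:, 1], y0, y1 - 1e-6)
        cov = annotate_endpoints(pts, land)
        k = n_random + 1
        rep = pd.DataFrame(meta).loc[np.repeat(np.arange(len(meta)), k)].reset_index(drop=True)
        rep["y"] = np.tile(np.r_[1, np.zeros(n_random, dtype=int)], len(meta))
        frames.append(pd.concat([rep, cov.reset_index(drop=True)], axis=1))
    if not frames:
        raise ValueError("no strata could be built")
    strata = pd.concat(frames, ignore_index=True)
    for c in DISTANCE_COVARIATES:
        strata[f"{c}_sq"] = (strata[c] - strata[c].mean()) ** 2
    strata["mire"] = (strata["habitat"] == "Mire").astype(int)
    strata["open"] = (strata["habitat"] == "Open").astype(int)
    strata.attrs["n_dropped_strata"] = dropped
    strata.attrs["seed"] = seed
    return strata


def _subset(strata: pd.DataFrame, time_of_day=None, behavior=None) -> pd.DataFrame:
    out = strata
    if time_of_day is not None:
        out = out.loc[out["time_of_day"] == time_of_day]
    if behavior is not None:
        out = out.loc[out["behavior"] == behavior]
    return out.reset_index(drop=True)


def fit_ssf(
    strata: pd.DataFrame,
    spec: str = "road_use",
    alpha: float = 0.05,
    r_max: float = 0.6,
) -> FitResult:
    """Fit one SSF on (a subset of) the strata.

    ``spec='road_use'``: on-gravel and on-main indicators only (no
    elimination); flagged unstable when the subset has no real steps on one
    road type (the likelihood then separates and the coefficient runs to a
    large negative value). ``spec='distance'``: distances + centered
    quadratics + land-cover contrasts vs Forest, screened at |r| < r_max and
    backward-eliminated at ``alpha`` on robust Wald P-values.
    """
    if spec == "road_use":
        # an indicator with no within-stratum variation (e.g. no step at all
        # on a main road in this subset) is inestimable; drop and flag it
        terms, dropped = [], []
        for ind in ("on_gravel", "on_main"):
            grp = strata.groupby("stratum_id")[ind]
            if (grp.transform("max") - grp.transform("min")).abs().max() > 0:
                terms.append(ind)
            else:
                dropped.append(ind)
        if not terms:
            raise UnidentifiableError("no road indicator varies within any stratum")
        fit = fit_conditional_logistic(strata, terms)
        if dropped:
            fit.flags["inestimable"] = dropped
        real = strata.loc[strata["y"] == 1]
        fit.meta["n_real_on_gravel"] = int(real["on_gravel"].sum())
        fit.meta["n_real_on_main"] = int(real["on_main"].sum())
        rand = strata.loc[strata["y"] == 0]
        fit.meta["n_random_on_gravel"] = int(rand["on_gravel"].sum())
        fit.meta["n_random_on_main"] = int(rand["on_main"].sum())
        if fit.flags.get("separation") or any(
            fit.meta[f"n_real_{t}"] == 0 for t in terms
        ):
            fit.flags["unstable"] = True
        return fit
    if spec != "distance":
        raise ValueError(f"unknown SSF spec {spec!r}")

    candidates = [c for c in DISTANCE_COVARIATES + HABITAT_DUMMIES if strata[c].notna().all()]
    kept, dropped_pairs = pearson_screen(strata, candidates, r_max=r_max, priority=candidates)
    terms = []
    for c in kept:
        terms.append(c)
        if c in DISTANCE_COVARIATES:
            terms.append(f"{c}_sq")

    def fit_fn(ts):
        return fit_conditional_logistic(strata, ts)

    final, trace = backward_eliminate(fit_fn, terms, alpha=alpha)
    final.meta["screen_dropped"] = dropped_pairs
    final.meta["elimination_trace"] = trace
    return final


def fit_ssf_suite(strata: pd.DataFrame, spec: str = "road_use", alpha: float = 0.05):
    """SSFs for all steps and each time-of-day x behavior combination."""
    out = {"all": fit_ssf(strata, spec, alpha=alpha)}
    for tod in ("Day", "Night"):
        for beh in ("Kill", "Rest", "Travel"):
            sub = _subset(strata, tod, beh)
            key = f"{tod.lower()}_{beh.lower()}"
            if sub.empty or sub["stratum_id"].nunique() < 2:
                out[key] = None
                continue
            try:
                out[key] = fit_ssf(sub, spec, alpha=alpha)
            except Exception as exc:  # noqa: BLE001 - a subset may be degenerate
                warnings.warn(f"SSF subset {key} failed: {exc}")
                out[key] = None
    return out


def crossvalidate_ssf(
    strata: pd.DataFrame,
    terms: list[str],
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Leave-one-territory-out rank validation of a fitted SSF term set.

    Coefficients are re-estimated on all other territories, the held-out
    strata are scored and ranked 1-11 within stratum (mid-ranks for ties),
    one random row is sampled per stratum, and a one-sided paired Wilcoxon
    tests whether real ranks exceed the sampled random ranks. The model is
    accepted iff P <= alpha.
    """
    territories = sorted(strata["territory_id"].unique())
    if len(territories) < 3:
        raise ValueError("need at least 3 territories for leave-one-out validation")
    rng = np.random.default_rng(seed)
    real_ranks, rand_ranks = [], []
    for tid in territories:
        train = strata.loc[strata["territory_id"] != tid]
        test = strata.loc[strata["territory_id"] == tid]
        if test.empty:
            continue
        if terms:
            fit = fit_conditional_logistic(train, terms)
            X, _ = build_design(test, terms, drop_intercept=True)
            eta = X.to_numpy() @ fit.params.reindex(X.columns).to_numpy()
        else:
            eta = np.zeros(len(test))
        test = test.assign(_eta=eta)
        for _, grp in test.groupby("stratum_id", sort=True):
            ranks = rankdata(grp["_eta"].to_numpy(), method="average")
            yv = grp["y"].to_numpy()
            real_ranks.append(float(ranks[yv == 1][0]))
            pick = rng.integers(0, int(np.sum(yv == 0)))
            rand_ranks.append(float(ranks[yv == 0][pick]))
    diffs = np.asarray(real_ranks) - np.asarray(rand_ranks)
    try:
        V, P = wilcoxon_signed_rank(diffs, alternative="greater")
    except ValueError:
        V, P = float("nan"), 1.0
    return {
        "V": V,
        "P": P,
        "accepted": bool(P <= alpha),
        "n_strata": len(diffs),
        "mean_real_rank": float(np.mean(real_ranks)) if real_ranks else float("nan"),
    }
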