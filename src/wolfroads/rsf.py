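"""Patch-scale resource selection functions (RSFs).

Used patches are circles of radius 1.78 km (nominal 10 km2; exactly
9.95 km2) centered on every single position and on the first position in
time of each cluster; availability is 100 random patch centers per data set
drawn uniformly inside the 100% MCP home range. Patches carry gravel/main
road densities (km/km2), house density (per km2) and land-cover fractions.
Selection is modelled with random-intercept logistic regression (data set
nested in territory) separately for the six reproductive status x behavior
combinations, screened at |r| < 0.6, backward-eliminated at alpha = 0.05,
and validated by repeated 10-fold cross-validation with a binned Spearman
rank correlation, rejecting models with mean r < 0.6.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geoprimitives import (
    ConvexPolygon,
    line_length_in_circle,
    mcp,
    points_in_circle_count,
)
from .stats_core import (
    FitResult,
    backward_eliminate,
    build_design,
    fit_logistic_rim,
    pearson_screen,
    spearman,
)
from .synthetic_data import Landscape

PATCH_RADIUS = 1780.0  # m; pi * r^2 = 9.95 km2
RSF_COVARIATES = ["gravel_density", "main_density", "house_density", "mire"]
# collinearity-screen priority: house density first among the human-
# infrastructure covariates (houses and main roads are spatially coupled;
# the patch-scale human-disturbance signal is carried by houses)
RSF_SCREEN_PRIORITY = ["gravel_density", "house_density", "main_density", "mire"]
QUADRATIC_FOR = {"gravel_density", "mire"}  # the candidate quadratic terms
SPEARMAN_ACCEPT = 0.6


@dataclass
class BoyceCV:
    """Binned-Spearman cross-validation summary."""

    per_rep: list = field(default_factory=list)
    mean_r: float = float("nan")
    accepted: bool = False
    threshold: float = SPEARMAN_ACCEPT


# ---------------------------------------------------------------------------
# Patch construction
# ---------------------------------------------------------------------------

_BEHAVIOR_FROM_CLUSTER = {"bed": "Rest"}


def used_patches(labelled: pd.DataFrame, clusters: pd.DataFrame) -> pd.DataFrame:
    """Used patch centers of one data set: every single position plus the
    earliest member fix of each cluster.

    Behavior labels: singles -> Travel; kill-flagged clusters -> Kill; bed
    clusters -> Rest; den/rendezvous and untyped clusters get no behavior
    label (they count as used positions but enter no behavior-specific
    model).
    """
    singles = labelled.loc[labelled["is_single"]]
    rows = [
        pd.DataFrame(
            {
                "x": singles["x"].to_numpy(),
                "y": singles["y"].to_numpy(),
                "behavior": "Travel",
            }
        )
    ]
    if len(clusters):
        first = (
            labelled.loc[~labelled["is_single"]]
            .sort_values("timestamp")
            .groupby("cluster", sort=True)
            .first()
            .reset_index()
        )
        first = first.merge(clusters[["cluster", "kind", "is_kill"]], on="cluster")
        beh = np.where(
            first["is_kill"],
            "Kill",
            first["kind"].map(_BEHAVIOR_FROM_CLUSTER).fillna(""),
        )
        rows.append(pd.DataFrame({"x": first["x"], "y": first["y"], "behavior": beh}))
    out = pd.concat(rows, ignore_index=True)
    out["behavior"] = out["behavior"].replace("", np.nan)
    out["used"] = 1
    return out


def available_patches(
    home_range: ConvexPolygon, n: int = 100, seed: int = 0
) -> pd.DataFrame:
    """``n`` patch centers uniform inside the MCP (rejection sampling)."""
    rng = np.random.default_rng(seed)
    v = home_range.vertices
    xmin, ymin = v.min(axis=0)
    xmax, ymax = v.max(axis=0)
    pts = np.empty((n, 2))
    got = 0
    while got < n:
        cand = rng.uniform([xmin, ymin], [xmax, ymax], size=(4 * (n - got), 2))
        inside = home_range.contains_many(cand)
        take = cand[inside][: n - got]
        pts[got : got + len(take)] = take
        got += len(take)
    return pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1], "behavior": np.nan, "used": 0})


def annotate_patches(
    patches: pd.DataFrame, landscape: Landscape, radius: float = PATCH_RADIUS
) -> pd.DataFrame:
    """Road/house densities and land-cover fractions for each patch circle.

    Land-cover fractions are over grid cells whose centers fall inside the
    circle; patches whose circle contains no grid cell center are dropped
    with a warning.
    """
    area_km2 = np.pi * radius**2 / 1e6
    centers, codes = landscape.grid.cell_centers()
    from scipy.spatial import cKDTree

    cell_tree = cKDTree(centers)
    gravel_net = landscape.roads.subset("gravel")
    main_net = landscape.roads.subset("main")
    rows = []
    kept_idx = []
    for i, (x, y) in enumerate(zip(patches["x"], patches["y"])):
        c = (float(x), float(y))
        idx = cell_tree.query_ball_point(c, radius)
        if len(idx) == 0:
            warnings.warn("patch fully outside land-cover grid; dropped")
            continue
        sub = codes[idx]
        rows.append(
            {
                "gravel_density": line_length_in_circle(gravel_net, c, radius)
                / area_km2,
                "main_density": line_length_in_circle(main_net, c, radius)
                / area_km2,
                "house_density": points_in_circle_count(landscape.houses, c, radius)
                / area_km2,
                "forest": float(np.mean(sub == 0)),
                "mire": float(np.mean(sub == 1)),
                "water": float(np.mean(sub == 2)),
                "open": float(np.mean(sub == 3)),
            }
        )
        kept_idx.append(i)
    ann = pd.DataFrame(rows)
    out = pd.concat(
        [patches.iloc[kept_idx].reset_index(drop=True), ann.reset_index(drop=True)],
        axis=1,
    )
    out.attrs["patch_area_km2"] = area_km2
    return out


def build_patch_table(
    per_dataset: dict[str, tuple[pd.DataFrame, pd.DataFrame]],
    landscapes: dict[str, Landscape],
    dataset_meta: pd.DataFrame,
    n_available: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Used + available annotated patches for every data set.

    ``per_dataset`` maps dataset_id to (labelled hourly fixes, clusters)
    from :func:`wolfroads.trajectory.cluster_fixes`; ``dataset_meta`` carries
    dataset_id, territory_id, reproduction.
    """
    meta = dataset_meta.set_index("dataset_id")
    frames = []
    rng = np.random.default_rng(seed)
    for did, (labelled, clusters) in sorted(per_dataset.items()):
        tid = meta.loc[did, "territory_id"]
        land = landscapes[tid]
        used = used_patches(labelled, clusters)
        hr = mcp(labelled[["x", "y"]].to_numpy())
        avail = available_patches(hr, n=n_available, seed=int(rng.integers(2**31)))
        both = pd.concat([used, avail], ignore_index=True)
        ann = annotate_patches(both, land)
        ann["dataset_id"] = did
        ann["territory_id"] = tid
        ann["reproduction"] = meta.loc[did, "reproduction"]
        ann["home_range_km2"] = hr.area_km2
        frames.append(ann)
    table = pd.concat(frames, ignore_index=True)
    # centered quadratic candidates
    for c in QUADRATIC_FOR:
        table[f"{c}_sq"] = (table[c] - table[c].mean()) ** 2
    return table


# ---------------------------------------------------------------------------
# Model fitting and cross-validation
# ---------------------------------------------------------------------------


def _model_frame(records: pd.DataFrame, status: str, behavior: str) -> pd.DataFrame:
    grp = records.loc[records["reproduction"] == status]
    used = grp.loc[(grp["used"] == 1) & (grp["behavior"] == behavior)]
    avail = grp.loc[grp["used"] == 0]
    return pd.concat([used, avail], ignore_index=True)


def fit_rsf(
    records: pd.DataFrame,
    status: str,
    behavior: str,
    alpha: float = 0.05,
    r_max: float = 0.6,
    min_used: int = 30,
) -> FitResult | None:
    """Backward-eliminated random-intercept logistic RSF for one
    status x behavior combination; None (with a warning) below ``min_used``
    used patches."""
    df = _model_frame(records, status, behavior)
    n_used = int(df["used"].sum())
    if n_used < min_used:
        warnings.warn(
            f"{status}/{behavior}: only {n_used} used patches (<{min_used}); fit skipped"
        )
        return None
    usable = [c for c in RSF_COVARIATES if df[c].var() > 1e-12]
    priority = [c for c in RSF_SCREEN_PRIORITY if c in usable]
    kept, dropped_pairs = pearson_screen(df, usable, r_max=r_max, priority=priority)
    terms = []
    for c in kept:
        terms.append(c)
        if c in QUADRATIC_FOR:
            terms.append(f"{c}_sq")

    def fit_fn(ts):
        return fit_logistic_rim(df, "used", ts)

    final, trace = backward_eliminate(fit_fn, terms, alpha=alpha)
    final.meta["n_used"] = n_used
    final.meta["screen_dropped"] = dropped_pairs
    final.meta["elimination_trace"] = trace
    final.meta["status"] = status
    final.meta["behavior"] = behavior
    return final


def fit_rsf_suite(records: pd.DataFrame, alpha: float = 0.05) -> dict:
    out = {}
    for status in ("breeding", "nonbreeding"):
        for behavior in ("Kill", "Rest", "Travel"):
            out[f"{status}_{behavior.lower()}"] = fit_rsf(
                records, status, behavior, alpha=alpha
            )
    return out


def crossvalidate_rsf(
    records: pd.DataFrame,
    status: str,
    behavior: str,
    terms: list[str],
    k: int = 10,
    bins: int = 10,
    reps: int = 100,
    seed: int = 0,
) -> BoyceCV:
    """Repeated k-fold binned-Spearman validation of a final RSF.

    Per repetition: random k-fold partition; each validation fold is scored
    with coefficients refitted on the training folds, sorted by score, cut
    into ``bins`` equal-sized bins, and the Spearman correlation between bin
    rank and the bin's used-patch fraction is recorded. The model is
    accepted iff the mean correlation is >= 0.6.
    """
    df = _model_frame(records, status, behavior).reset_index(drop=True)
    rng = np.random.default_rng(seed)
    n = len(df)
    rep_means = []
    for _ in range(reps):
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        rs = []
        for fold in folds:
            test = df.iloc[fold]
            train = df.drop(index=fold)
            if terms:
                try:
                    fit = fit_logistic_rim(train, "used", terms)
                except Exception:  # noqa: BLE001 - a fold can degenerate
                    continue
                X, _ = build_design(test, terms)
                eta = fit.predict_linear(X)
            else:
                eta = np.zeros(len(test))
            order = np.argsort(eta, kind="stable")
            used_sorted = test["used"].to_numpy()[order]
            bin_parts = np.array_split(used_sorted, bins)
            freq = np.array([p.mean() if len(p) else np.nan for p in bin_parts])
            ok = np.isfinite(freq)
            if ok.sum() < 3 or np.all(freq[ok] == freq[ok][0]):
                rs.append(0.0)
                continue
            rs.append(spearman(np.arange(1, bins + 1)[ok], freq[ok]))
        if rs:
            rep_means.append(float(np.mean(rs)))
    mean_r = float(np.mean(rep_means)) if rep_means else float("nan")
    return BoyceCV(
        per_rep=rep_means,
        mean_r=mean_r,
        accepted=bool(np.isfinite(mean_r) and mean_r >= SPEARMAN_ACCEPT),
    )
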