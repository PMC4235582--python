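"""From raw GPS fixes to derived movement objects.

Implements the cluster/single decomposition (100 m position buffers dissolved
into clusters, i.e. single-linkage components at a 200 m pairwise threshold,
including temporal revisits), cluster typing (den/rendezvous vs bed by hourly
position count), travel-speed steps (35 min / 200 m filters on half-hourly
data), hourly step-selection steps with SS/SC/CS/CC categories, the 3-state
road variable at a 30 m threshold, and the Day/Night clock split.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .geoprimitives import RoadNetwork, distances_to_network

LINK_DISTANCE = 200.0      # m; 100 m buffers overlap iff centers <= 200 m apart
ROAD_THRESHOLD = 30.0      # m; GPS inaccuracy scale
SPEED_MAX_DT = 35.0        # min
SPEED_MIN_LENGTH = 200.0   # m
SSF_MIN_LENGTH = 200.0     # m
DEN_MIN_HOURLY = 44        # den/rendezvous clusters: >= 44 hourly positions
BED_MAX_HOURLY = 36        # bed clusters: <= 36 hourly positions


# ---------------------------------------------------------------------------
# Fix preparation and clustering
# ---------------------------------------------------------------------------


def thin_hourly(fixes: pd.DataFrame, tol_min: float = 5.0) -> pd.DataFrame:
    """Keep fixes on the hour (minute 0 +/- tol); half-hourly data thinned."""
    minutes = fixes["timestamp"].dt.minute.to_numpy().astype(float)
    keep = np.minimum(minutes, 60.0 - minutes) <= tol_min
    return fixes.loc[keep].reset_index(drop=True)


def link_clusters(points: np.ndarray, link_distance: float = LINK_DISTANCE) -> np.ndarray:
    """Single-linkage components at a pairwise distance threshold (inclusive).

    Equivalent to dissolving overlapping 100 m buffers: fixes whose closed
    disks touch (centers <= 200 m apart) join the same cluster, through
    chains and regardless of time order. Returns an integer component label
    per point; size-1 components are singles.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n == 0:
        return np.empty(0, dtype=int)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(link_distance, output_type="ndarray")
    if len(pairs) == 0:
        return np.arange(n)
    graph = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(graph, directed=False)
    return labels


def star_score(centroid: np.ndarray, departures: np.ndarray) -> float:
    """Mean resultant length of bearings from a cluster centroid to the
    positions reached by steps leaving the cluster; 0 if none."""
    if len(departures) == 0:
        return 0.0
    d = np.asarray(departures, dtype=float) - np.asarray(centroid, dtype=float)
    ang = np.arctan2(d[:, 1], d[:, 0])
    return float(np.hypot(np.mean(np.cos(ang)), np.mean(np.sin(ang))))


def classify_cluster(
    n_hourly: int,
    star: float = 0.0,
    min_den_hourly: int = DEN_MIN_HOURLY,
    max_bed_hourly: int = BED_MAX_HOURLY,
    star_threshold: float = 0.0,
) -> str:
    """Type a cluster: ``den_rdv`` (>=44 hourly positions and star score at
    least the threshold), ``bed`` (<=36), else ``unassigned`` (37-43,
    excluded downstream)."""
    if n_hourly >= min_den_hourly and star >= star_threshold:
        return "den_rdv"
    if n_hourly <= max_bed_hourly:
        return "bed"
    return "unassigned"


def cluster_fixes(
    hourly: pd.DataFrame,
    kill_flags: pd.Series | np.ndarray | None = None,
    link_distance: float = LINK_DISTANCE,
    star_threshold: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster hourly fixes of one data set and type the clusters.

    Returns ``(fixes_with_labels, clusters)``: the input frame with added
    ``cluster`` (component id), ``is_single``, and ``position_class`` columns
    (``single`` or the cluster kind), plus a per-cluster table with member
    counts, centroid, kind, and kill flag (from the optional per-fix flag
    column; field kill verification is outside this pipeline's scope).
    """
    fx = hourly.reset_index(drop=True).copy()
    pts = fx[["x", "y"]].to_numpy()
    labels = link_clusters(pts, link_distance)
    fx["cluster"] = labels
    sizes = fx.groupby("cluster")["x"].transform("size")
    fx["is_single"] = sizes == 1

    kills = (
        np.asarray(kill_flags, dtype=bool)
        if kill_flags is not None
        else np.zeros(len(fx), dtype=bool)
    )

    rows = []
    for cid, grp in fx.groupby("cluster"):
        if len(grp) == 1:
            continue
        centroid = grp[["x", "y"]].to_numpy().mean(axis=0)
        # departures: the next fix in time after each member, when outside
        idx = grp.index.to_numpy()
        nxt = idx + 1
        nxt = nxt[nxt < len(fx)]
        outside = nxt[~np.isin(nxt, idx)]
        departures = fx.loc[outside, ["x", "y"]].to_numpy()
        sc = star_score(centroid, departures)
        kind = classify_cluster(len(grp), sc, star_threshold=star_threshold)
        rows.append(
            {
                "cluster": cid,
                "n_hourly": len(grp),
                "cx": centroid[0],
                "cy": centroid[1],
                "star_score": sc,
                "kind": kind,
                "is_kill": bool(kills[grp.index].any()),
                "t_first": grp["timestamp"].min(),
            }
        )
    clusters = pd.DataFrame(
        rows,
        columns=[
            "cluster", "n_hourly", "cx", "cy", "star_score", "kind", "is_kill", "t_first",
        ],
    )

    kind_map = dict(zip(clusters["cluster"], clusters["kind"]))
    kill_map = dict(zip(clusters["cluster"], clusters["is_kill"]))
    fx["position_class"] = [
        "single" if s else kind_map[c] for s, c in zip(fx["is_single"], fx["cluster"])
    ]
    fx["in_kill_cluster"] = [
        (not s) and kill_map.get(c, False) for s, c in zip(fx["is_single"], fx["cluster"])
    ]
    return fx, clusters


# ---------------------------------------------------------------------------
# Steps
# ---------------------------------------------------------------------------


def time_of_day(ts) -> str:
    """Day 08:00-19:59, Night 20:00-07:59 (human-activity split)."""
    hour = ts.hour if hasattr(ts, "hour") else pd.Timestamp(ts).hour
    return "Day" if 8 <= hour < 20 else "Night"


def _times_of_day(ts: pd.Series) -> np.ndarray:
    hours = ts.dt.hour.to_numpy()
    return np.where((hours >= 8) & (hours < 20), "Day", "Night")


def road_state(
    d_start: float, d_end: float, threshold: float = ROAD_THRESHOLD
) -> str:
    """3-state road variable: ``on`` (both endpoints <= threshold from a
    road), ``partly`` (one endpoint), ``off`` (neither)."""
    on0, on1 = d_start <= threshold, d_end <= threshold
    if on0 and on1:
        return "on"
    if on0 or on1:
        return "partly"
    return "off"


def _consecutive_steps(fx: pd.DataFrame) -> pd.DataFrame:
    """Raw consecutive-fix steps of one data set (sorted by time)."""
    fx = fx.sort_values("timestamp").reset_index(drop=True)
    a, b = fx.iloc[:-1], fx.iloc[1:]
    dx = b["x"].to_numpy() - a["x"].to_numpy()
    dy = b["y"].to_numpy() - a["y"].to_numpy()
    steps = pd.DataFrame(
        {
            "t_start": a["timestamp"].to_numpy(),
            "t_end": b["timestamp"].to_numpy(),
            "x0": a["x"].to_numpy(),
            "y0": a["y"].to_numpy(),
            "x1": b["x"].to_numpy(),
            "y1": b["y"].to_numpy(),
            "dt_min": (b["timestamp"].to_numpy() - a["timestamp"].to_numpy())
            / np.timedelta64(60, "s"),
            "length": np.hypot(dx, dy),
            "bearing": np.arctan2(dy, dx),
        }
    )
    for col in ("territory_id", "dataset_id"):
        if col in fx.columns:
            steps[col] = fx[col].iloc[0]
    return steps


def build_speed_steps(
    fixes: pd.DataFrame,
    roads: RoadNetwork | None = None,
    max_dt: float = SPEED_MAX_DT,
    min_length: float = SPEED_MIN_LENGTH,
    threshold: float = ROAD_THRESHOLD,
) -> pd.DataFrame:
    """Travel-speed steps from half-hourly data sets only.

    Consecutive fixes at most ``max_dt`` minutes apart and at least
    ``min_length`` m long; speed in km/h. If a road network is given, each
    step gets the 3-state road variable at the 30 m threshold.
    """
    if "schedule" in fixes.columns:
        fixes = fixes.loc[fixes["schedule"] == "half-hourly"]
    out = []
    for _, grp in fixes.groupby("dataset_id", sort=True):
        steps = _consecutive_steps(grp)
        steps = steps.loc[
            (steps["dt_min"] <= max_dt) & (steps["length"] >= min_length)
        ].copy()
        out.append(steps)
    if not out:
        return pd.DataFrame()
    steps = pd.concat(out, ignore_index=True)
    steps["speed_kmh"] = (steps["length"] / 1000.0) / (steps["dt_min"] / 60.0)
    steps["time_of_day"] = _times_of_day(steps["t_end"])
    if roads is not None:
        steps["road"] = road_states_for_steps(steps, roads, threshold)
    return steps


def road_states_for_steps(
    steps: pd.DataFrame, roads: RoadNetwork, threshold: float = ROAD_THRESHOLD
) -> np.ndarray:
    d0 = distances_to_network(steps[["x0", "y0"]].to_numpy(), roads)
    d1 = distances_to_network(steps[["x1", "y1"]].to_numpy(), roads)
    on0, on1 = d0 <= threshold, d1 <= threshold
    return np.where(on0 & on1, "on", np.where(on0 | on1, "partly", "off"))


_BEHAVIOR = {"bed": "Rest", "single": "Travel"}


def build_ssf_steps(
    labelled: pd.DataFrame,
    min_length: float = SSF_MIN_LENGTH,
    max_dt: float = 65.0,
) -> pd.DataFrame:
    """Hourly steps with SS/SC/CS/CC categories for the step selection models.

    Input is the labelled hourly frame from :func:`cluster_fixes` (one data
    set or several; grouped by ``dataset_id``). Steps of at least
    ``min_length`` m between consecutive hourly fixes are kept; steps to or
    from den/rendezvous clusters are excluded (spatial autocorrelation), as
    are steps touching the untyped 37-43-position clusters. The turning angle
    is measured against the previous consecutive step's bearing and is NaN
    for a data set's first step or after a schedule gap; the behavior at the
    end point is Kill (kill-flagged cluster), Rest (bed cluster) or Travel
    (single position).
    """
    out = []
    for _, grp in labelled.groupby("dataset_id", sort=True):
        grp = grp.sort_values("timestamp").reset_index(drop=True)
        steps = _consecutive_steps(grp)
        n = len(steps)
        if n == 0:
            continue
        cls = grp["position_class"].to_numpy()
        kill = grp["in_kill_cluster"].to_numpy()
        steps["start_class"] = cls[:-1]
        steps["end_class"] = cls[1:]
        steps["end_in_kill"] = kill[1:]

        consecutive = steps["dt_min"].to_numpy() <= max_dt
        prev_bearing = np.r_[np.nan, steps["bearing"].to_numpy()[:-1]]
        prev_ok = np.r_[False, consecutive[:-1]]
        turn = steps["bearing"].to_numpy() - prev_bearing
        turn = (turn + np.pi) % (2 * np.pi) - np.pi
        turn[~prev_ok] = np.nan
        steps["turning_angle"] = turn
        steps["prev_bearing"] = np.where(prev_ok, prev_bearing, np.nan)

        keep = (
            consecutive
            & (steps["length"].to_numpy() >= min_length)
            & (steps["start_class"] != "den_rdv")
            & (steps["end_class"] != "den_rdv")
            & (steps["start_class"] != "unassigned")
            & (steps["end_class"] != "unassigned")
        )
        steps = steps.loc[keep].copy()
        out.append(steps)
    if not out:
        return pd.DataFrame()
    steps = pd.concat(out, ignore_index=True)
    s_single = (steps["start_class"] == "single").map({True: "S", False: "C"})
    e_single = (steps["end_class"] == "single").map({True: "S", False: "C"})
    steps["category"] = s_single + e_single
    steps["behavior"] = np.where(
        steps["end_in_kill"],
        "Kill",
        steps["end_class"].map(_BEHAVIOR).fillna("Rest"),
    )
    steps["time_of_day"] = _times_of_day(steps["t_end"])
    return steps
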