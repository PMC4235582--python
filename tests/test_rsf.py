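"""Patch selection: patch construction, annotation oracles, fits, CV."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wolfroads.geoprimitives import ConvexPolygon, mcp
from wolfroads.rsf import (
    PATCH_RADIUS,
    annotate_patches,
    available_patches,
    crossvalidate_rsf,
    fit_rsf,
    used_patches,
)
from wolfroads.trajectory import cluster_fixes


class TestUsedPatches:
    def test_singles_plus_clusters(self):
        xs = [0.0, 50.0, 10000.0, 20000.0, 30000.0, 40000.0, 50000.0]
        df = pd.DataFrame(
            {
                "dataset_id": "d",
                "timestamp": pd.date_range("2004-06-15", periods=len(xs), freq="1h"),
                "x": xs,
                "y": 0.0,
            }
        )
        labelled, clusters = cluster_fixes(df)
        used = used_patches(labelled, clusters)
        assert len(used) == 5 + 1  # 5 singles + 1 cluster
        assert (used["used"] == 1).all()

    def test_cluster_center_is_earliest_fix(self):
        df = pd.DataFrame(
            {
                "dataset_id": "d",
                "timestamp": pd.to_datetime(
                    ["2004-06-15 02:00", "2004-06-15 01:00", "2004-06-15 03:00"]
                ),
                "x": [10.0, 0.0, 20.0],
                "y": 0.0,
            }
        )
        labelled, clusters = cluster_fixes(df)
        used = used_patches(labelled, clusters)
        assert len(used) == 1
        assert used["x"].iloc[0] == 0.0  # the 01:00 fix

    def test_behavior_mapping(self):
        xs = [0.0, 50.0, 9000.0, 9050.0, 20000.0]
        df = pd.DataFrame(
            {
                "dataset_id": "d",
                "timestamp": pd.date_range("2004-06-15", periods=5, freq="1h"),
                "x": xs,
                "y": 0.0,
            }
        )
        labelled, clusters = cluster_fixes(df, kill_flags=[True, False, False, False, False])
        used = used_patches(labelled, clusters)
        beh = used.sort_values("x")["behavior"].tolist()
        assert beh == ["Kill", "Rest", "Travel"]


class TestAvailablePatches:
    square = ConvexPolygon(
        np.array([[0.0, 0.0], [20000.0, 0.0], [20000.0, 20000.0], [0.0, 20000.0]])
    )

    def test_exactly_n_inside(self):
        out = available_patches(self.square, n=100, seed=0)
        assert len(out) == 100
        assert self.square.contains_many(out[["x", "y"]].to_numpy()).all()

    def test_tiny_mcp_still_inside(self):
        tri = ConvexPolygon(np.array([[0.0, 0.0], [100.0, 0.0], [50.0, 80.0]]))
        out = available_patches(tri, n=50, seed=1)
        assert tri.contains_many(out[["x", "y"]].to_numpy()).all()

    def test_centers_uniform_chisquare(self):
        rejections = 0
        for seed in range(20):
            out = available_patches(self.square, n=200, seed=seed)
            qx = (out["x"] > 10000.0).astype(int)
            qy = (out["y"] > 10000.0).astype(int)
            counts = pd.crosstab(qx, qy).to_numpy().ravel()
            chi2 = np.sum((counts - 50.0) ** 2 / 50.0)
            if stats.chi2.sf(chi2, df=3) < 0.05:
                rejections += 1
        assert rejections <= 1  # uniform in >=95% of seeded replicates

    def test_deterministic_under_seed(self):
        a = available_patches(self.square, n=30, seed=5)
        b = available_patches(self.square, n=30, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestAnnotatePatches:
    def test_chord_through_center_density(self, landscape):
        from wolfroads.geoprimitives import RoadNetwork
        from wolfroads.synthetic_data import Landscape, LandscapeConfig

        net = RoadNetwork(
            [np.array([[0.0, 10000.0], [20000.0, 10000.0]])], ["gravel"]
        )
        land = Landscape(net, np.empty((0, 2)), landscape.grid, landscape.config)
        patches = pd.DataFrame({"x": [10000.0], "y": [10000.0], "behavior": np.nan, "used": 0})
        ann = annotate_patches(patches, land)
        r_km = PATCH_RADIUS / 1000.0
        expected = 2 * r_km / (np.pi * r_km**2)
        assert ann["gravel_density"].iloc[0] == pytest.approx(expected, rel=1e-6)
        assert expected == pytest.approx(0.358, abs=0.002)
        assert ann["house_density"].iloc[0] == 0.0

    def test_densities_match_monte_carlo_oracle(self, landscape, rng):
        x0, y0, x1, y1 = landscape.extent
        patches = pd.DataFrame(
            {
                "x": rng.uniform(x0 + PATCH_RADIUS, x1 - PATCH_RADIUS, 5),
                "y": rng.uniform(y0 + PATCH_RADIUS, y1 - PATCH_RADIUS, 5),
                "behavior": np.nan,
                "used": 0,
            }
        )
        ann = annotate_patches(patches, landscape)
        area_km2 = np.pi * PATCH_RADIUS**2 / 1e6
        gravel = landscape.roads.subset("gravel")
        segs = gravel.segments()
        lens = np.hypot(*(segs[:, 1] - segs[:, 0]).T)
        total = lens.sum()
        pick = rng.choice(len(segs), size=15 * 10**5, p=lens / total)
        t = rng.random(len(pick))
        pts = segs[pick, 0] + t[:, None] * (segs[pick, 1] - segs[pick, 0])
        for i in range(len(patches)):
            c = patches[["x", "y"]].iloc[i].to_numpy()
            inside = np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1]) <= PATCH_RADIUS
            oracle = inside.mean() * total / 1000.0 / area_km2
            if inside.sum() >= 2 * 10**4:  # enough hits for the MC tolerance
                assert ann["gravel_density"].iloc[i] == pytest.approx(oracle, rel=0.02)

    def test_patch_outside_grid_dropped(self, landscape):
        patches = pd.DataFrame(
            {"x": [1e7], "y": [1e7], "behavior": np.nan, "used": 0}
        )
        with pytest.warns(UserWarning, match="dropped"):
            ann = annotate_patches(patches, landscape)
        assert len(ann) == 0

    def test_landcover_fractions_sum_to_one(self, landscape, rng):
        x0, y0, x1, y1 = landscape.extent
        patches = pd.DataFrame(
            {
                "x": rng.uniform(x0 + PATCH_RADIUS, x1 - PATCH_RADIUS, 10),
                "y": rng.uniform(y0 + PATCH_RADIUS, y1 - PATCH_RADIUS, 10),
                "behavior": np.nan,
                "used": 0,
            }
        )
        ann = annotate_patches(patches, landscape)
        total = ann[["forest", "mire", "water", "open"]].sum(axis=1)
        assert np.allclose(total, 1.0)


def simulate_patch_records(
    rng, n_dsets=10, n_used=60, n_avail=100, beta_house=-0.07, n_houses_scale=8.0
):
    """Used/available patches with selection acting on house density."""
    rows = []
    for d in range(n_dsets):
        tid = f"t{d % 5}"
        bt = rng.normal(0, 0.1)
        house = rng.gamma(2.0, n_houses_scale / 2.0, n_avail * 4)
        gravel = rng.gamma(3.0, 0.3, n_avail * 4)
        mire = rng.beta(2.0, 12.0, n_avail * 4)
        eta = beta_house * house + bt
        w = np.exp(eta - eta.max())
        pick = rng.choice(n_avail * 4, size=n_used, replace=True, p=w / w.sum())
        used = pd.DataFrame(
            {
                "used": 1,
                "behavior": "Travel",
                "house_density": house[pick],
                "gravel_density": gravel[pick],
                "main_density": 0.2,
                "mire": mire[pick],
            }
        )
        akeep = rng.choice(n_avail * 4, size=n_avail, replace=False)
        avail = pd.DataFrame(
            {
                "used": 0,
                "behavior": np.nan,
                "house_density": house[akeep],
                "gravel_density": gravel[akeep],
                "main_density": 0.2,
                "mire": mire[akeep],
            }
        )
        for frame in (used, avail):
            frame["dataset_id"] = f"{tid}d{d}"
            frame["territory_id"] = tid
            frame["reproduction"] = "breeding"
        rows += [used, avail]
    df = pd.concat(rows, ignore_index=True)
    df["gravel_density_sq"] = (df["gravel_density"] - df["gravel_density"].mean()) ** 2
    df["mire_sq"] = (df["mire"] - df["mire"].mean()) ** 2
    return df


class TestFitRSF:
    def test_house_density_coefficient_recovered(self, rng):
        df = simulate_patch_records(rng, n_dsets=10, n_used=150, n_avail=350)
        assert len(df) >= 5000
        fit = fit_rsf(df, "breeding", "Travel")
        assert "house_density" in fit.params.index
        assert abs(fit.params["house_density"] + 0.07) < 3 * fit.se["house_density"]

    def test_constant_covariate_dropped(self, rng):
        df = simulate_patch_records(rng, n_dsets=6)
        fit = fit_rsf(df, "breeding", "Travel")
        assert "main_density" not in fit.params.index  # zero variance

    def test_too_few_used_skipped(self, rng):
        df = simulate_patch_records(rng, n_dsets=4, n_used=5)
        with pytest.warns(UserWarning, match="skipped"):
            assert fit_rsf(df, "breeding", "Travel") is None

    def test_house_avoidance_produces_negative_terms(self):
        # end-to-end: simulated house avoidance surfaces as negative fitted
        # house/infrastructure coefficients for rest and travel patches
        from wolfroads.pipeline import RunConfig, cluster_stage, dataset_metadata
        from wolfroads.rsf import build_patch_table
        from wolfroads.synthetic_data import (
            LandscapeConfig,
            WolfConfig,
            make_study,
        )

        study = make_study(
            n_territories=3,
            n_datasets=6,
            landscape_cfg=LandscapeConfig(extent_km=(20.0, 20.0)),
            wolf_cfg=WolfConfig(study_days=16, house_avoidance_strength=0.5),
            seed=31,
        )
        from wolfroads.rsf import _model_frame
        from wolfroads.stats_core import fit_logistic_rim

        meta = dataset_metadata(study)
        clustered = cluster_stage(study, RunConfig())
        table = build_patch_table(clustered, study.landscapes, meta, seed=5)
        # used patches sit in emptier neighborhoods than available ones
        means = table.groupby("used")["house_density"].mean()
        assert means[1] < means[0]
        betas = []
        for status in ("breeding", "nonbreeding"):
            for beh in ("Rest", "Travel"):
                df = _model_frame(table, status, beh)
                if df["used"].sum() < 30:
                    continue
                fit = fit_logistic_rim(df, "used", ["house_density"])
                betas.append(fit.params["house_density"])
        assert betas and all(b < 0 for b in betas)


class TestCrossvalidateRSF:
    def test_separable_model_r_near_one(self, rng):
        # a covariate that orders used above available almost perfectly:
        # bin frequencies rise strictly, so the rank correlation approaches 1
        rows = []
        for d in range(6):
            signal = rng.normal(0, 1, 400)
            used = (rng.random(400) < 1 / (1 + np.exp(-3 * signal))).astype(int)
            rows.append(
                pd.DataFrame(
                    {
                        "used": used,
                        "behavior": np.where(used == 1, "Travel", None),
                        "signal": signal,
                        "dataset_id": f"d{d}",
                        "territory_id": f"t{d % 3}",
                        "reproduction": "breeding",
                    }
                )
            )
        df = pd.concat(rows, ignore_index=True)
        cv = crossvalidate_rsf(df, "breeding", "Travel", ["signal"], reps=3, seed=1)
        assert cv.mean_r > 0.9
        assert cv.accepted

    def test_noise_model_rejected(self, rng):
        rejections = 0
        for seed in range(10):
            df = simulate_patch_records(rng, n_dsets=6, beta_house=0.0)
            df["noise"] = rng.normal(0, 1, len(df))
            cv = crossvalidate_rsf(df, "breeding", "Travel", ["noise"], reps=2, seed=seed)
            if abs(cv.mean_r) < 0.3:
                rejections += 1
            assert not cv.accepted or cv.mean_r < 0.65
        assert rejections >= 9

    def test_acceptance_threshold_boundary(self):
        from wolfroads.rsf import BoyceCV, SPEARMAN_ACCEPT

        assert SPEARMAN_ACCEPT == 0.6
        low = BoyceCV(per_rep=[0.59], mean_r=0.59, accepted=0.59 >= SPEARMAN_ACCEPT)
        high = BoyceCV(per_rep=[0.60], mean_r=0.60, accepted=0.60 >= SPEARMAN_ACCEPT)
        assert not low.accepted
        assert high.accepted
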