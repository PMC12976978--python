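"""Clustering, hull sizing and the precision size-bias model."""

import math

import numpy as np
import pandas as pd
import pytest

from evquant import (
    SyntheticConfig,
    assign_cross_channel_labels,
    cluster_localisations,
    hull_diameter,
    measure_particle_diameter,
    predicted_observed_diameter,
    render_localisations,
)
from evquant.clustering import detect_particles
from evquant.synthetic import GroundTruthEV, LocalisationTable


def _table(points, channels=None, fov=0):
    points = np.asarray(points, dtype=float)
    if channels is None:
        channels = ["panEV"] * len(points)
    return LocalisationTable(
        data=pd.DataFrame(
            {
                "x_nm": points[:, 0] if len(points) else [],
                "y_nm": points[:, 1] if len(points) else [],
                "frame": np.zeros(len(points), dtype=int),
                "channel": channels,
            }
        ),
        fov_index=fov,
    )


class TestDBSCANClustering:
    def test_single_tight_blob(self, rng):
        pts = rng.normal(0, 3, size=(10, 2)) + 500
        clusters = cluster_localisations(_table(pts), eps=50, min_samples=5)
        assert len(clusters) == 1
        assert clusters[0].n_loc == 10

    def test_too_few_points_is_noise(self):
        pts = np.tile([100.0, 100.0], (4, 1))
        assert cluster_localisations(_table(pts), eps=50, min_samples=5) == []

    def test_two_distant_blobs(self, rng):
        a = rng.normal(0, 3, size=(10, 2))
        b = rng.normal(0, 3, size=(10, 2)) + [1000.0, 0.0]
        clusters = cluster_localisations(_table(np.vstack([a, b])), eps=50, min_samples=5)
        assert [c.n_loc for c in clusters] == [10, 10]

    def test_empty_table_gives_empty_list(self):
        assert cluster_localisations(_table(np.empty((0, 2)))) == []

    def test_cargo_never_forms_clusters(self, rng):
        pts = rng.normal(0, 3, size=(20, 2)) + 500
        clusters = cluster_localisations(_table(pts, channels=["cargo"] * 20))
        assert clusters == []

    def test_matches_bruteforce_connected_components(self, rng):
        # with min_samples=1, DBSCAN is exactly eps-connectivity
        for trial in range(5):
            pts = rng.uniform(0, 2000, size=(rng.integers(20, 200), 2))
            eps = 80.0
            clusters = cluster_localisations(_table(pts), eps=eps, min_samples=1)
            # brute force union-find over the pairwise distance graph
            n = len(pts)
            parent = list(range(n))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            for i in range(n):
                for j in range(i + 1, n):
                    if d[i, j] <= eps:
                        parent[find(i)] = find(j)
            expected = {}
            for i in range(n):
                expected.setdefault(find(i), set()).add(i)
            got = {frozenset(c.member_indices.tolist()) for c in clusters}
            assert got == {frozenset(s) for s in expected.values()}


class TestHullDiameter:
    def test_square_equivalent_diameter(self):
        corners = [(0, 0), (0, 100), (100, 0), (100, 100)]
        area, diam = hull_diameter(corners)
        assert area == pytest.approx(10_000.0)
        assert diam == pytest.approx(2 * math.sqrt(10_000 / math.pi), rel=1e-9)
        assert diam == pytest.approx(112.84, abs=0.01)

    def test_single_point(self):
        assert hull_diameter([(5.0, 5.0)]) == (0.0, 0.0)

    def test_collinear_points_use_max_extent(self):
        area, diam = hull_diameter([(0, 0), (40, 0), (80, 0)])
        assert area == 0.0
        assert diam == pytest.approx(80.0)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            hull_diameter(np.empty((0, 2)))

    def test_translation_and_rotation_invariance(self, rng):
        pts = rng.uniform(0, 200, size=(40, 2))
        area0, diam0 = hull_diameter(pts)
        theta = 0.7
        rot = np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        moved = pts @ rot.T + np.array([1e5, -3e4])
        area1, diam1 = hull_diameter(moved)
        assert area1 == pytest.approx(area0, rel=1e-6)
        assert diam1 == pytest.approx(diam0, rel=1e-6)


class TestMeasureParticleDiameter:
    def test_uses_pan_ev_members_only(self):
        pts = [(0, 0), (0, 100), (100, 0), (100, 100), (500, 500), (520, 520)]
        channels = ["panEV"] * 4 + ["TT"] * 2
        table = _table(pts, channels)
        (cluster,) = cluster_localisations(table, eps=1000, min_samples=3)
        diam = measure_particle_diameter(cluster, table)
        assert diam == pytest.approx(112.84, abs=0.01)
        assert not cluster.fallback

    def test_coincident_pan_ev_members_flagged_degenerate(self):
        pts = [(50, 50)] * 6
        table = _table(pts)
        (cluster,) = cluster_localisations(table, eps=10, min_samples=3)
        assert measure_particle_diameter(cluster, table) == 0.0
        assert cluster.degenerate

    def test_tt_only_cluster_uses_fallback(self, rng):
        pts = rng.normal(0, 20, size=(8, 2)) + 300
        table = _table(pts, channels=["TT"] * 8)
        (cluster,) = cluster_localisations(table, eps=200, min_samples=3)
        diam = measure_particle_diameter(cluster, table)
        assert cluster.fallback
        assert diam > 0


class TestAssignCrossChannelLabels:
    def _two_cluster_table(self):
        a = [(0.0, 0.0), (10.0, 0.0), (0.0, 10.0), (10.0, 10.0)]
        b = [(1000.0, 0.0), (1010.0, 0.0), (1000.0, 10.0), (1010.0, 10.0)]
        cargo = [(15.0, 0.0), (500.0, 500.0), (505.0, 5.0)]
        pts = a + b + cargo
        channels = ["panEV"] * 8 + ["cargo"] * 3
        return _table(pts, channels)

    def test_nearby_cargo_credited_distant_not(self):
        table = self._two_cluster_table()
        clusters = cluster_localisations(table, eps=50, min_samples=3)
        assign_cross_channel_labels(clusters, table, assign_radius=30)
        # cargo at (15,0) is 5 nm from cluster 0's member; the others are far
        assert clusters[0].channel_counts["cargo"] == 1
        assert clusters[1].channel_counts["cargo"] == 0

    def test_members_count_toward_their_own_cluster(self):
        table = self._two_cluster_table()
        clusters = cluster_localisations(table, eps=50, min_samples=3)
        assign_cross_channel_labels(clusters, table, assign_radius=30)
        assert clusters[0].channel_counts["panEV"] == 4
        assert clusters[1].channel_counts["panEV"] == 4

    def test_equidistant_point_goes_to_lower_cluster_index(self):
        # two 3-point clusters; a cargo point exactly midway between members
        pts = [(0.0, 0.0), (0.0, 5.0), (0.0, -5.0),
               (40.0, 0.0), (40.0, 5.0), (40.0, -5.0),
               (20.0, 0.0)]
        channels = ["panEV"] * 6 + ["cargo"]
        table = _table(pts, channels)
        clusters = cluster_localisations(table, eps=10, min_samples=3)
        assign_cross_channel_labels(clusters, table, assign_radius=30)
        assert clusters[0].channel_counts["cargo"] == 1
        assert clusters[1].channel_counts["cargo"] == 0


class TestBiasModel:
    @pytest.mark.parametrize(
        "r,sigma,expected_bias",
        [(25.0, 20.0, 14.0), (75.0, 20.0, 5.2), (25.0, 15.0, 8.3)],
    )
    def test_printed_bias_values(self, r, sigma, expected_bias):
        d_obs, bias = predicted_observed_diameter(r, sigma)
        assert d_obs == pytest.approx(2 * math.sqrt(r**2 + sigma**2), rel=1e-12)
        assert bias == pytest.approx(expected_bias, abs=0.05)

    def test_zero_precision_gives_zero_bias(self):
        for r in (10.0, 50.0, 200.0):
            _, bias = predicted_observed_diameter(r, 0.0)
            assert bias == 0.0

    def test_bias_monotone_in_sigma(self):
        sigmas = np.linspace(0, 40, 50)
        _, bias = predicted_observed_diameter(np.full_like(sigmas, 60.0), sigmas)
        assert np.all(np.diff(bias) >= 0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            predicted_observed_diameter(-1.0, 10.0)
        with pytest.raises(ValueError):
            predicted_observed_diameter(10.0, -1.0)


class TestGeometryClosure:
    def test_member_rms_radius_matches_broadening_model(self, rng):
        # the RMS radial spread of a clustered rim closes the loop on
        # d_observed = 2 sqrt(R^2 + sigma^2)
        R, sigma = 50.0, 20.0
        cfg = SyntheticConfig(
            rate_panEV=4000, rate_TT=0, sigma_loc=sigma, background_density=0, seed=0
        )
        ev = GroundTruthEV((5000.0, 5000.0), 2 * R, False, False, 0)
        table = render_localisations([ev], cfg, rng=rng)
        (cluster,) = cluster_localisations(table, eps=60, min_samples=3)
        pts = table.coordinates(["panEV"])[cluster.member_indices]
        centroid = pts.mean(axis=0)
        rms = np.sqrt(np.mean(np.sum((pts - centroid) ** 2, axis=1)))
        d_pred, _ = predicted_observed_diameter(R, sigma)
        assert 2 * rms == pytest.approx(d_pred, rel=0.02)

    def test_hull_of_well_sampled_noisy_rim_overestimates(self, rng):
        # known estimator property: the convex hull tracks the extreme points
        # of the noise, so at high localisation counts it exceeds the
        # RMS-broadening prediction
        R, sigma = 50.0, 20.0
        diams = []
        for _ in range(40):
            cfg = SyntheticConfig(
                rate_panEV=60, rate_TT=0, sigma_loc=sigma, background_density=0, seed=1
            )
            ev = GroundTruthEV((5000.0, 5000.0), 2 * R, False, False, 0)
            table = render_localisations([ev], cfg, rng=rng)
            clusters = detect_particles(table, eps=100, min_samples=3)
            diams.append(clusters[0].diameter)
        d_pred, _ = predicted_observed_diameter(R, sigma)
        assert np.mean(diams) > d_pred
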