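import warnings

import numpy as np
import pytest

from conftest import brute_force_dbscan
from somatrack.detection import DetectionCloud, NucleusSizePrior
from somatrack.registration import (
    RegisteredCloud,
    RegisteredFrame,
    SimilarityTransform,
    TransformChain,
    register_sequence,
)
from somatrack.tracking import (
    Cluster,
    DBSCANParams,
    PROVENANCE_CODES,
    cluster_detections,
    estimate_dbscan_params,
    finalize_trajectory,
    split_merged,
    track,
)

PRIOR = NucleusSizePrior(3.0)


def _identity_cloud(per_frame_points):
    """RegisteredCloud whose registered coordinates equal the originals."""
    frames = [
        RegisteredFrame(t, np.atleast_2d(p).astype(float), np.atleast_2d(p).astype(float),
                        np.atleast_2d(p).astype(float), np.ones(np.atleast_2d(p).shape[0]))
        for t, p in enumerate(per_frame_points)
    ]
    T = len(frames)
    chain = TransformChain(T // 2, {}, [SimilarityTransform.identity() for _ in range(T)])
    return RegisteredCloud(frames, chain)


def _blob_cloud(centers, T, sigma=0.2, seed=0):
    """T frames of jittered copies of fixed cluster centres."""
    rng = np.random.default_rng(seed)
    return _identity_cloud(
        [np.asarray(centers) + rng.normal(0, sigma, (len(centers), 3)) for _ in range(T)]
    )


class TestParamEstimation:
    def test_tight_clusters_separated(self):
        centers = np.array([[0, 0, 0], [0, 10, 0], [10, 0, 0], [8, 8, 8]], dtype=float)
        cloud = _blob_cloud(centers, T=20)
        params = estimate_dbscan_params(cloud, PRIOR)
        assert params.eps < 5.0  # below inter-cluster spacing
        assert 2 <= params.min_pts <= 20
        clusters = cluster_detections(cloud, params)
        assert len(clusters) == len(centers)

    def test_uniform_cloud_yields_mostly_noise(self):
        rng = np.random.default_rng(1)
        cloud = _identity_cloud([rng.uniform(0, 100, (30, 3)) for _ in range(10)])
        params = estimate_dbscan_params(cloud, PRIOR)
        clusters = cluster_detections(cloud, params)
        clustered = sum(len(c) for c in clusters)
        assert clustered < 0.5 * 300


class TestClusterDetections:
    def test_blobs_found_and_scatter_noise(self):
        rng = np.random.default_rng(2)
        blob_centers = np.array([[0, 0, 0], [20, 0, 0], [0, 20, 0]], dtype=float)
        pts = np.concatenate(
            [c + rng.normal(0, 0.3, (120, 3)) for c in blob_centers]
            + [rng.uniform(40, 100, (20, 3))]
        )
        frames = np.zeros(len(pts), dtype=int)
        cloud = _identity_cloud([pts])
        clusters = cluster_detections(cloud, DBSCANParams(eps=1.5, min_pts=10))
        assert len(clusters) == 3
        in_clusters = sum(len(c) for c in clusters)
        assert in_clusters <= 360 + 5  # at least 15 of 20 scattered points are noise

    def test_isolated_point_is_noise(self):
        cloud = _identity_cloud([np.array([[0.0, 0.0, 0.0]])])
        clusters = cluster_detections(cloud, DBSCANParams(eps=1.0, min_pts=2))
        assert clusters == []

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force_dbscan(self, seed):
        rng = np.random.default_rng(seed)
        pts = np.concatenate(
            [rng.normal(0, 1, (80, 3)), rng.normal(15, 1, (80, 3)), rng.uniform(-20, 40, (40, 3))]
        )
        cloud = _identity_cloud([pts])
        eps, min_pts = 2.0, 8
        clusters = cluster_detections(cloud, DBSCANParams(eps, min_pts))
        ref_labels = brute_force_dbscan(pts, eps, min_pts)
        got = {frozenset(map(int, c.point_ids)) for c in clusters}
        expected = {
            frozenset(np.flatnonzero(ref_labels == cid).tolist())
            for cid in set(ref_labels) - {-1}
        }
        assert got == expected


class TestSplitMerged:
    def test_single_detection_per_frame_unchanged(self):
        coords = np.tile([1.0, 2.0, 3.0], (10, 1))
        c = Cluster(0, coords, np.arange(10), np.arange(10))
        out = split_merged(c)
        assert len(out) == 1 and out[0] is c

    def test_two_merged_somata_split(self):
        rng = np.random.default_rng(3)
        T = 30
        a = np.array([0.0, 0.0, 0.0]) + rng.normal(0, 0.2, (T, 3))
        b = np.array([0.0, 2.5, 0.0]) + rng.normal(0, 0.2, (T, 3))
        coords = np.concatenate([a, b])
        frames = np.concatenate([np.arange(T), np.arange(T)])
        c = Cluster(0, coords, frames, np.arange(2 * T))
        out = split_merged(c, rng=0)
        assert len(out) == 2
        sizes = sorted(len(o) for o in out)
        assert sizes[0] >= T - 5

    def test_occasional_duplicates_keep_cluster_whole(self):
        # median per-frame count stays 1 despite a few double detections
        coords = np.tile([0.0, 0.0, 0.0], (12, 1))
        frames = np.array([0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 3, 7])
        c = Cluster(0, coords, frames, np.arange(12))
        out = split_merged(c)
        assert len(out) == 1


class TestFinalizeTrajectory:
    def test_missing_frame_is_linear_midpoint(self):
        T = 5
        pts = [np.array([[0.0, 0.0, float(t)]]) for t in range(T)]
        pts[2] = np.empty((0, 3))
        cloud = _identity_cloud(pts)
        coords = np.concatenate([p for p in pts if len(p)])
        frames = np.array([0, 1, 3, 4])
        c = Cluster(0, coords, frames, np.arange(4))
        orig, reg, prov = finalize_trajectory(c, T, cloud)
        np.testing.assert_allclose(orig[2], [0, 0, 2.0])
        assert prov[2] == PROVENANCE_CODES["interpolated"]

    def test_three_frame_gap_interpolated_at_quarters(self):
        T = 6
        a, b = np.array([0.0, 0.0, 0.0]), np.array([0.0, 0.0, 4.0])
        pts = [a[None], np.empty((0, 3)), np.empty((0, 3)), np.empty((0, 3)), b[None], b[None]]
        cloud = _identity_cloud(pts)
        c = Cluster(0, np.stack([a, b, b]), np.array([0, 4, 5]), np.arange(3))
        orig, _, prov = finalize_trajectory(c, T, cloud)
        np.testing.assert_allclose(orig[1], [0, 0, 1.0])
        np.testing.assert_allclose(orig[2], [0, 0, 2.0])
        np.testing.assert_allclose(orig[3], [0, 0, 3.0])

    def test_duplicate_resolved_to_nearest_centroid(self):
        T = 3
        good = np.array([0.0, 0.0, 0.0])
        dup_near, dup_far = np.array([0.0, 0.0, 0.2]), np.array([0.0, 0.0, 1.5])
        pts = [good[None], np.stack([dup_near, dup_far]), good[None]]
        cloud = _identity_cloud(pts)
        coords = np.concatenate(pts)
        c = Cluster(0, coords, np.array([0, 1, 1, 2]), np.arange(4))
        orig, _, prov = finalize_trajectory(c, T, cloud)
        np.testing.assert_allclose(orig[1], dup_near)
        assert prov[1] == PROVENANCE_CODES["deduplicated"]

    def test_sparse_cluster_discarded(self):
        pts = [np.array([[0.0, 0.0, 0.0]]), np.array([[0.0, 0.0, 0.0]])] + [
            np.empty((0, 3)) for _ in range(8)
        ]
        cloud = _identity_cloud(pts)
        c = Cluster(0, np.zeros((2, 3)), np.array([0, 1]), np.arange(2))
        assert finalize_trajectory(c, 10, cloud) is None

    def test_ends_copy_nearest_detection(self):
        T = 5
        pts = [np.empty((0, 3)), np.array([[1.0, 1.0, 1.0]]),
               np.array([[1.0, 1.0, 2.0]]), np.array([[1.0, 1.0, 3.0]]), np.empty((0, 3))]
        cloud = _identity_cloud(pts)
        c = Cluster(0, np.concatenate(pts[1:4]), np.array([1, 2, 3]), np.arange(3))
        orig, _, _ = finalize_trajectory(c, T, cloud)
        np.testing.assert_allclose(orig[0], [1, 1, 1])
        np.testing.assert_allclose(orig[4], [1, 1, 3])


class TestTrack:
    def test_motionless_noiseless_detections_recovered_exactly(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(10, 50, (30, 3))
        cloud = _identity_cloud([pts for _ in range(12)])
        traj = track(cloud, PRIOR, rng=0)
        assert traj.n_somata == 30
        got = traj.positions[:, 0, :]
        order = np.lexsort(got.T)
        ref_order = np.lexsort(pts.T)
        np.testing.assert_allclose(got[order], pts[ref_order], atol=1e-9)
        assert (traj.provenance == PROVENANCE_CODES["detected"]).all()

    def test_noise_only_cloud_yields_empty_set(self):
        rng = np.random.default_rng(5)
        cloud = _identity_cloud([rng.uniform(0, 200, (40, 3)) for _ in range(10)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            traj = track(cloud, PRIOR, rng=0)
        assert traj.n_somata <= 2

    def test_every_trajectory_covers_every_frame_and_no_sharing(self, bench_truth):
        from somatrack.synthetic import inject_detection_noise

        _, truth = bench_truth
        clouds = inject_detection_noise(truth, 0.1, 0.05, 0.3, rng=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reg = register_sequence(clouds, rng=7)
            traj = track(reg, PRIOR, rng=11)
        assert traj.positions.shape[1] == truth.n_frames
        assert np.isfinite(traj.positions).all()
        assert traj.n_somata >= 0.9 * truth.n_nuclei
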