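import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_nearest_seed
from somatrack.errors import AlignmentImpossibleError
from somatrack.io_core import AcquisitionGeometry, StimulusWindow
from somatrack.signal import (
    align_batches,
    default_stimulus_windows,
    extract_raw,
    fly_quality_control,
    glow_control_filter,
    normalize,
    responder_set_jaccard,
    select_responsive,
    voronoi_partition,
)

GEOM = AcquisitionGeometry(0.5, 1.0, 0.9, 8, (12, 12))


class TestVoronoi:
    def test_single_seed_unbounded_radius_labels_everything(self):
        labels = voronoi_partition(np.array([[2.0, 3.0, 3.0]]), GEOM.stack_shape, GEOM, np.inf)
        assert (labels == 0).all()

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force_nearest_seed(self, seed):
        rng = np.random.default_rng(seed)
        seeds = rng.uniform(0, 5, (4, 3))
        max_radius = 2.5
        labels = voronoi_partition(seeds, GEOM.stack_shape, GEOM, max_radius)
        expected = brute_force_nearest_seed(GEOM.stack_shape, GEOM.voxel_size, seeds, max_radius)
        np.testing.assert_array_equal(labels, expected)

    def test_equidistant_voxel_goes_to_lowest_id(self):
        # two seeds symmetric about the x = 6 voxel column
        seeds = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 5.0]])
        labels = voronoi_partition(seeds, GEOM.stack_shape, GEOM, np.inf)
        assert labels[0, 0, 6] == 0  # voxel at x = 3.0 µm is equidistant

    def test_regions_never_intersect_and_stay_within_radius(self):
        rng = np.random.default_rng(3)
        seeds = rng.uniform(0, 5, (6, 3))
        max_radius = 1.2
        labels = voronoi_partition(seeds, GEOM.stack_shape, GEOM, max_radius)
        for i in range(6):
            vox = np.argwhere(labels == i)
            if len(vox) == 0:
                continue
            d = np.linalg.norm(vox * GEOM.voxel_size - seeds[i], axis=1)
            assert (d <= max_radius + 1e-9).all()


class TestExtractRaw:
    def test_uniform_calcium_channel_gives_constant_traces(self, tiny_simulation):
        from somatrack.io_core import Sequence, VolumeStack
        from somatrack.tracking import TrajectorySet

        cfg, seq, truth = tiny_simulation
        g = seq.geometry
        frames = []
        for t in range(seq.n_frames):
            flat = VolumeStack(np.full(g.stack_shape, 42.0), g, t, "calcium")
            frames.append((seq.frames[t][0], flat))
        flat_seq = Sequence(frames, seq.stimulus_windows)
        traj = TrajectorySet(
            truth.centers_um.copy(),
            np.zeros((truth.n_nuclei, truth.n_frames), dtype=np.int8),
            np.arange(truth.n_nuclei),
        )
        F = extract_raw(traj, flat_seq, max_radius=2.0)
        np.testing.assert_allclose(F, 42.0)

    def test_only_active_soma_shows_the_transient(self, tiny_simulation):
        from somatrack.tracking import TrajectorySet

        cfg, seq, truth = tiny_simulation
        traj = TrajectorySet(
            truth.centers_um.copy(),
            np.zeros((truth.n_nuclei, truth.n_frames), dtype=np.int8),
            np.arange(truth.n_nuclei),
        )
        F = extract_raw(traj, seq, max_radius=1.5 * 1.5)
        # responsive somata's raw fluorescence follows their true activity;
        # non-responsive somata show no comparable in-window rise
        for i in np.flatnonzero(truth.responsive):
            r = np.corrcoef(F[i], truth.activity[i])[0, 1]
            assert r > 0.5



class TestNormalize:
    def test_constant_trace_normalizes_to_zero(self):
        F = np.full((3, 40), 250.0)
        traces = normalize(F)
        np.testing.assert_allclose(traces.normalized, 0.0, atol=1e-12)
        assert traces.valid.all()

    def test_bump_produces_positive_peak(self):
        F = np.full((1, 60), 100.0)
        F[0, 30:40] = 120.0
        traces = normalize(F)
        assert traces.normalized[0, 30:40].max() > 0.05

    def test_nyquist_alternation_attenuated_tenfold(self):
        F = 100.0 + 10.0 * (-1.0) ** np.arange(50)[None, :]
        traces = normalize(F)
        # away from the filtfilt edge transient the alternation is suppressed
        assert np.abs(traces.smoothed[:, 5:-5] - 100.0).max() < 1.0  # >= 10x

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(scale=st.floats(0.01, 100.0), seed=st.integers(0, 1000))
    def test_scale_invariance_of_dff(self, scale, seed):
        rng = np.random.default_rng(seed)
        F = rng.uniform(50, 150, (2, 40))
        a = normalize(F).normalized
        b = normalize(scale * F).normalized
        np.testing.assert_allclose(a, b, rtol=1e-9, atol=1e-12)


class TestSelectResponsive:
    def _traces(self, normalized):
        from somatrack.signal import TraceMatrix

        normalized = np.atleast_2d(normalized)
        n, T = normalized.shape
        ones = np.ones_like(normalized)
        return TraceMatrix(ones, ones, ones, normalized, np.ones(n, dtype=bool))

    def test_peak_inside_window_is_responsive(self):
        norm = np.zeros((1, 30))
        norm[0, 12] = 0.25
        resp = select_responsive(self._traces(norm), StimulusWindow("odor_A", 10, 16))
        assert resp[0]

    def test_peak_outside_window_is_not_responsive(self):
        norm = np.zeros((1, 30))
        norm[0, 25] = 0.25
        norm[0, 12] = 0.08
        resp = select_responsive(self._traces(norm), StimulusWindow("odor_A", 10, 16))
        assert not resp[0]

    def test_threshold_is_strict(self):
        norm = np.zeros((2, 30))
        norm[0, 12] = 0.1  # exactly at threshold: not responsive
        norm[1, 12] = 0.1 + 1e-9
        resp = select_responsive(self._traces(norm), StimulusWindow("odor_A", 10, 16))
        assert not resp[0]
        assert resp[1]


class TestGlowControl:
    def test_middle_dimmest_of_three_collinear_removed_first(self):
        pos = np.array([[0, 0, 0.0], [0, 0, 4.5], [0, 0, 9.0]])  # spacing 1.5x soma size of 3 µm
        peaks = np.array([1.0, 0.2, 0.9])
        kept = glow_control_filter(pos, peaks, min_sep=6.0)
        assert list(kept) == [0, 2]

    def test_already_separated_is_identity(self):
        pos = np.array([[0, 0, 0.0], [0, 0, 10.0], [0, 10.0, 0]])
        kept = glow_control_filter(pos, np.array([1.0, 2.0, 3.0]), min_sep=6.0)
        assert list(kept) == [0, 1, 2]

    def test_coincident_somata_keep_the_brighter(self):
        pos = np.zeros((2, 3))
        kept = glow_control_filter(pos, np.array([0.5, 0.9]), min_sep=6.0)
        assert list(kept) == [1]

    def test_retained_set_is_order_independent(self):
        rng = np.random.default_rng(4)
        pos = rng.uniform(0, 20, (25, 3))
        peaks = rng.uniform(0.1, 1.0, 25)
        kept = set(glow_control_filter(pos, peaks, min_sep=5.0))
        perm = rng.permutation(25)
        kept_perm = glow_control_filter(pos[perm], peaks[perm], min_sep=5.0)
        assert {int(perm[i]) for i in kept_perm} == kept

    def test_pairwise_separation_guaranteed(self):
        rng = np.random.default_rng(5)
        pos = rng.uniform(0, 15, (30, 3))
        kept = glow_control_filter(pos, rng.uniform(0, 1, 30), min_sep=6.0)
        sub = pos[kept]
        d = np.linalg.norm(sub[:, None] - sub[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        assert (d >= 6.0).all()


class TestBatchAlignment:
    def test_ratio_of_percentiles(self):
        rng = np.random.default_rng(6)
        a = rng.uniform(0, 2.0, 200)
        b = 2.0 * a  # P99 doubled
        factors = align_batches([a, b])
        assert factors[0] == pytest.approx(1.0)
        assert factors[1] == pytest.approx(0.5)

    def test_identical_batches_all_unit(self):
        rng = np.random.default_rng(7)
        a = rng.uniform(0, 3.0, 100)
        factors = align_batches([a, a.copy(), a.copy()])
        np.testing.assert_allclose(factors, 1.0)

    def test_correction_equalizes_p99_exactly(self):
        rng = np.random.default_rng(8)
        batches = [rng.uniform(0, s, 150) for s in (1.0, 2.5, 4.0)]
        factors = align_batches(batches)
        p99 = [np.percentile(b * f, 99) for b, f in zip(batches, factors)]
        np.testing.assert_allclose(p99, p99[0])

    def test_zero_percentile_impossible(self):
        with pytest.raises(AlignmentImpossibleError):
            align_batches([np.ones(30), np.zeros(30)])


class TestResponderJaccard:
    def test_half_overlap(self):
        assert responder_set_jaccard({1, 2, 3}, {2, 3, 4}) == pytest.approx(0.5)

    def test_identical_and_disjoint(self):
        assert responder_set_jaccard({1, 2}, {1, 2}) == 1.0
        assert responder_set_jaccard({1}, {2}) == 0.0

    def test_both_empty_is_zero_with_warning(self):
        with pytest.warns(RuntimeWarning):
            assert responder_set_jaccard(set(), set()) == 0.0


class TestFlyQualityControl:
    def _traces(self, normalized):
        from somatrack.signal import TraceMatrix

        n = normalized.shape[0]
        ones = np.ones_like(normalized)
        return TraceMatrix(ones, ones, ones, normalized, np.ones(n, dtype=bool))

    WINDOWS = [StimulusWindow("air", 20, 26), StimulusWindow("odor_A", 50, 58)]

    def test_odor_locked_responders_pass(self):
        norm = np.zeros((50, 80))
        norm[:30, 52] = 0.4  # 30 clean odor responders
        ok, reasons = fly_quality_control(self._traces(norm), self.WINDOWS)
        assert ok and reasons == []

    def test_zero_responders_fail(self):
        norm = np.zeros((50, 80))
        ok, reasons = fly_quality_control(self._traces(norm), self.WINDOWS)
        assert not ok
        assert any("responsive" in r for r in reasons)

    def test_nonspecific_activity_fails(self):
        rng = np.random.default_rng(9)
        norm = rng.uniform(0.15, 0.5, (50, 80))  # "responding" everywhere
        ok, reasons = fly_quality_control(self._traces(norm), self.WINDOWS)
        assert not ok


def test_default_stimulus_windows_match_protocol_timing():
    windows = default_stimulus_windows(120, 0.9)
    labels = {w.label: w for w in windows}
    # air pulse at 45-50 s, octanol at 85-90 s, 0.9 s frames, +5 frames decay
    assert labels["air"].start == 50
    assert labels["odor_A"].start == 94
    assert labels["odor_A"].end <= 120
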