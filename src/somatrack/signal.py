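"""Per-soma calcium signal extraction, normalization and responder calling.

The raw GCaMP fluorescence of each tracked soma is averaged over a discrete
3D Voronoi region around its position (recomputed per frame, truncated at a
maximum radius so regions stay local).  Traces are low-pass filtered
(Butterworth, 20% of Nyquist, zero phase), normalized as ΔF/F = (F - F0)/F0
against a moving-average baseline of radius 10 frames, and somata whose
normalized trace peaks above 0.1 inside a stimulus window are called
responsive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .errors import AlignmentImpossibleError
from .io_core import AcquisitionGeometry, Sequence, StimulusWindow
from .tracking import TrajectorySet

__all__ = [
    "TraceMatrix",
    "default_stimulus_windows",
    "voronoi_partition",
    "extract_raw",
    "normalize",
    "select_responsive",
    "glow_control_filter",
    "align_batches",
    "responder_set_jaccard",
    "fly_quality_control",
]

logger = logging.getLogger(__name__)


@dataclass
class TraceMatrix:
    """Raw, baseline and normalized soma x frame fluorescence."""

    raw: np.ndarray  # (n, T)
    smoothed: np.ndarray
    baseline: np.ndarray  # F0
    normalized: np.ndarray  # (F_smoothed - F0) / F0
    valid: np.ndarray  # (n,) bool; False when F0 was non-positive

    @property
    def n_somata(self) -> int:
        return self.raw.shape[0]

    @property
    def n_frames(self) -> int:
        return self.raw.shape[1]


def default_stimulus_windows(
    n_frames: int = 120,
    frame_period: float = 0.9,
    decay_extension: int = 5,
) -> list[StimulusWindow]:
    """Stimulus windows of the 120-frame retrieval protocol.

    Odor delivery: 45 s airflow, 5 s air-control pulse, 35 s airflow, 5 s
    octanol pulse (0.9 s per frame).  Windows are extended by
    ``decay_extension`` frames past stimulus offset to capture the slow
    indicator decay.
    """
    events = [("air", 45.0, 50.0), ("odor_A", 85.0, 90.0)]
    windows = []
    for label, t0, t1 in events:
        start = int(np.floor(t0 / frame_period))
        end = int(np.ceil(t1 / frame_period)) + decay_extension
        if start < n_frames:
            windows.append(StimulusWindow(label, start, min(end, n_frames)))
    return windows


def voronoi_partition(
    positions_um: np.ndarray,
    stack_shape: tuple[int, int, int],
    geometry: AcquisitionGeometry,
    max_radius: float,
) -> np.ndarray:
    """Discrete 3D Voronoi labelling of a voxel grid, truncated at max_radius.

    Every voxel within ``max_radius`` (µm) of its nearest seed gets that
    seed's index; farther voxels get -1.  Equidistant voxels break ties
    toward the lowest seed index.
    """
    seeds = np.atleast_2d(np.asarray(positions_um, dtype=float))
    if seeds.shape[0] < 1:
        raise ValueError("at least one seed required")
    voxel = geometry.voxel_size
    grids = np.meshgrid(
        np.arange(stack_shape[0]) * voxel[0],
        np.arange(stack_shape[1]) * voxel[1],
        np.arange(stack_shape[2]) * voxel[2],
        indexing="ij",
    )
    pts = np.stack([g.ravel() for g in grids], axis=1)
    tree = cKDTree(seeds)
    k = min(2, seeds.shape[0])
    d, idx = tree.query(pts, k=k)
    if k == 2:
        best_d, best_i = d[:, 0], idx[:, 0].copy()
        # deterministic tie-break: lowest seed id wins
        tie = np.isclose(d[:, 0], d[:, 1], rtol=0.0, atol=1e-9) & (idx[:, 1] < idx[:, 0])
        best_i[tie] = idx[:, 1][tie]
    else:
        best_d, best_i = d, idx
    labels = np.where(best_d <= max_radius, best_i, -1)
    return labels.reshape(stack_shape).astype(np.int32)


def extract_raw(
    traj: TrajectorySet,
    seq: Sequence,
    max_radius: float,
) -> np.ndarray:
    """Mean calcium intensity in each soma's Voronoi region, per frame.

    The partition is recomputed per frame from that frame's positions.  A
    soma whose region was entirely captured by neighbours falls back to the
    intensity at its seed voxel (with a warning).
    """
    if traj.n_frames != seq.n_frames:
        raise ValueError("trajectory and sequence frame counts differ")
    geometry = seq.geometry
    shape = geometry.stack_shape
    F = np.zeros((traj.n_somata, traj.n_frames))
    for t in range(seq.n_frames):
        calcium = seq.frames[t][1].data
        labels = voronoi_partition(traj.positions[:, t, :], shape, geometry, max_radius)
        sums = np.bincount(
            labels.ravel()[labels.ravel() >= 0],
            weights=calcium.ravel()[labels.ravel() >= 0],
            minlength=traj.n_somata,
        )
        counts = np.bincount(labels.ravel()[labels.ravel() >= 0], minlength=traj.n_somata)
        for i in range(traj.n_somata):
            if counts[i] > 0:
                F[i, t] = sums[i] / counts[i]
            else:
                vox = np.clip(
                    np.round(traj.positions[i, t, :] / geometry.voxel_size).astype(int),
                    0,
                    np.array(shape) - 1,
                )
                F[i, t] = calcium[tuple(vox)]
                logger.warning("soma %d frame %d: empty Voronoi region; seed voxel used", i, t)
    return F


def normalize(
    F: np.ndarray,
    window_radius: int = 10,
    cutoff_frac: float = 0.2,
    f0_floor_frac: float = 1e-6,
) -> TraceMatrix:
    """Smooth and normalize raw traces to ΔF/F.

    Per soma: order-2 Butterworth low-pass at ``cutoff_frac`` of the Nyquist
    frequency, applied forward-backward (zero phase); F0 is the moving
    average of the smoothed trace over frames [t - r, t + r] truncated at
    the sequence bounds; normalized = (F_smoothed - F0)/F0.  F0 is floored
    at ``f0_floor_frac`` x the global median of F; somata whose F0 was
    non-positive before flooring are flagged invalid.
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    n, T = F.shape
    if T < 2 * window_radius + 1:
        raise ValueError(f"need >= {2 * window_radius + 1} frames, got {T}")
    b, a = butter(2, cutoff_frac)
    smoothed = filtfilt(b, a, F, axis=1)
    # truncated moving average of radius r around each frame
    kernel = np.ones(2 * window_radius + 1)
    ones = np.ones(T)
    denom = np.convolve(ones, kernel, mode="same")
    baseline = np.apply_along_axis(
        lambda row: np.convolve(row, kernel, mode="same") / denom, 1, smoothed
    )
    valid = baseline.min(axis=1) > 0
    floor = f0_floor_frac * max(float(np.median(F)), np.finfo(float).tiny)
    f0 = np.maximum(baseline, floor)
    normalized = (smoothed - f0) / f0
    return TraceMatrix(raw=F, smoothed=smoothed, baseline=f0, normalized=normalized, valid=valid)


def select_responsive(
    traces: TraceMatrix,
    window: StimulusWindow,
    threshold: float = 0.1,
) -> np.ndarray:
    """Somata whose normalized trace peaks strictly above threshold in-window."""
    if window.end > traces.n_frames:
        raise ValueError("stimulus window outside trace matrix")
    peak = traces.normalized[:, window.start : window.end].max(axis=1)
    return (peak > threshold) & traces.valid


def glow_control_filter(
    positions_um: np.ndarray,
    peak_intensities: np.ndarray,
    min_sep: float,
) -> np.ndarray:
    """Iteratively remove the dimmest member of every too-close pair.

    Returns the retained soma indices (sorted); all pairwise distances among
    the retained somata are >= ``min_sep``.  The removal order — globally
    dimmest violating soma first, ties toward the lower index — makes the
    result independent of input ordering.
    """
    positions_um = np.atleast_2d(np.asarray(positions_um, dtype=float))
    peaks = np.asarray(peak_intensities, dtype=float).ravel()
    n = positions_um.shape[0]
    if peaks.shape[0] != n:
        raise ValueError("positions and peaks must align")
    if min_sep <= 0:
        raise ValueError("min_sep must be positive")
    alive = np.ones(n, dtype=bool)
    dist = cdist(positions_um, positions_um)
    np.fill_diagonal(dist, np.inf)
    while True:
        sub = np.flatnonzero(alive)
        viol = (dist[np.ix_(sub, sub)] < min_sep).any(axis=1)
        if not viol.any():
            break
        cand = sub[viol]
        order = np.lexsort((cand, peaks[cand]))
        alive[cand[order[0]]] = False
    return np.flatnonzero(alive)


def align_batches(
    peak_sets: list[np.ndarray],
    reference: int = 0,
    min_peaks: int = 20,
) -> np.ndarray:
    """Multiplicative batch correction aligning 99th percentiles.

    factor_b = P99(reference batch) / P99(batch b); applying factor_b to all
    traces of batch b equalizes the reference-condition response scale
    across batches.
    """
    p99 = []
    for i, peaks in enumerate(peak_sets):
        peaks = np.asarray(peaks, dtype=float).ravel()
        if peaks.size < min_peaks:
            raise ValueError(f"batch {i}: need >= {min_peaks} peaks, got {peaks.size}")
        p99.append(float(np.percentile(peaks, 99)))
    ref = p99[reference]
    factors = []
    for i, p in enumerate(p99):
        if p <= 0:
            raise AlignmentImpossibleError(f"batch {i}: zero 99th percentile")
        factors.append(ref / p)
    return np.array(factors)


def responder_set_jaccard(responsive_a: set, responsive_b: set) -> float:
    """|A ∩ B| / |A ∪ B| between two responder sets; both empty -> 0."""
    a, b = set(responsive_a), set(responsive_b)
    union = a | b
    if not union:
        warnings.warn("both responder sets empty; Jaccard defined as 0", RuntimeWarning)
        return 0.0
    return len(a & b) / len(union)


def fly_quality_control(
    traces: TraceMatrix,
    windows: list[StimulusWindow],
    threshold: float = 0.1,
    min_responders: int = 5,
    baseline_fraction_factor: float = 0.5,
) -> tuple[bool, list[str]]:
    """Automated odor-response quality control for one fly.

    Fails when (a) fewer than ``min_responders`` somata respond in the first
    odor window, or (b) the fraction of somata "responding" during the
    pre-stimulus baseline frames exceeds ``baseline_fraction_factor`` times
    the odor-window responsive fraction (non-specific activity).
    """
    odor_windows = [w for w in windows if w.label != "air"]
    if not odor_windows:
        raise ValueError("no odor window provided")
    first = min(odor_windows, key=lambda w: w.start)
    responsive = select_responsive(traces, first, threshold)
    reasons = []
    if responsive.sum() < min_responders:
        reasons.append(
            f"only {int(responsive.sum())} responsive somata in window "
            f"{first.label!r} (< {min_responders})"
        )
    baseline_end = min(w.start for w in windows)
    if baseline_end > 0 and traces.n_somata > 0:
        pseudo = StimulusWindow("baseline", 0, baseline_end)
        base_frac = select_responsive(traces, pseudo, threshold).mean()
        odor_frac = responsive.mean()
        if base_frac > baseline_fraction_factor * odor_frac:
            reasons.append(
                f"baseline responsive fraction {base_frac:.3f} exceeds "
                f"{baseline_fraction_factor} x odor fraction {odor_frac:.3f}"
            )
    return (len(reasons) == 0, reasons)
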