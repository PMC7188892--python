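"""Quantitative evaluation of detection and tracking, and annotation I/O.

Detection scoring: a detection is a true positive when it falls inside a
sphere of 1.5x the nucleus radius around a ground-truth position; each
sphere yields at most one TP (extra in-sphere detections count as FP),
out-of-sphere detections are FP, empty spheres FN.  There is no true
negative.  Accuracy is the Jaccard index TP/(TP + FP + FN).

Tracking scoring: complete trajectories are assigned one-to-one to their
closest ground-truth tracks by mean-over-time distance; a trajectory within
3x the nucleus size is a TP, otherwise FP; unmatched truth tracks are FN.
"""

from __future__ import annotations

import logging
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .errors import AnnotationParseError, UndefinedScoreError
from .io_core import AcquisitionGeometry

__all__ = [
    "MatchResult",
    "match_detections",
    "jaccard",
    "evaluate_tracking",
    "read_annotations",
    "write_annotations_csv",
]

logger = logging.getLogger(__name__)


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int]] = field(default_factory=list)  # (detection, truth)
    distances: list[float] = field(default_factory=list)

    @property
    def counts(self) -> tuple[int, int, int]:
        return (self.tp, self.fp, self.fn)


def _greedy_match(dist: np.ndarray, max_dist: float) -> list[tuple[int, int]]:
    """One-to-one nearest-first matching of pairs with distance <= max_dist."""
    pairs = []
    if dist.size == 0:
        return pairs
    di, ti = np.nonzero(dist <= max_dist)
    order = np.argsort(dist[di, ti], kind="stable")
    used_d = np.zeros(dist.shape[0], dtype=bool)
    used_t = np.zeros(dist.shape[1], dtype=bool)
    for k in order:
        d, t = di[k], ti[k]
        if used_d[d] or used_t[t]:
            continue
        used_d[d] = used_t[t] = True
        pairs.append((int(d), int(t)))
    return pairs


def _optimal_match(dist: np.ndarray, max_dist: float) -> list[tuple[int, int]]:
    """Assignment-optimal alternative to greedy matching."""
    if dist.size == 0:
        return []
    big = 10.0 * max(max_dist, dist.max() if np.isfinite(dist).any() else 1.0)
    cost = np.where(dist <= max_dist, dist, big)
    ri, ci = linear_sum_assignment(cost)
    return [(int(d), int(t)) for d, t in zip(ri, ci) if dist[d, t] <= max_dist]


def match_detections(
    detections: np.ndarray,
    truth: np.ndarray,
    nucleus_radius: float,
    radius_factor: float = 1.5,
    method: str = "greedy",
) -> MatchResult:
    """Score detections against ground-truth centres.

    Matching is one-to-one within spheres of ``radius_factor`` x
    ``nucleus_radius``; nearest pairs are matched first (``method="greedy"``,
    the default) or globally optimally (``method="optimal"``).
    """
    if nucleus_radius <= 0:
        raise ValueError("nucleus_radius must be positive")
    detections = np.atleast_2d(np.asarray(detections, dtype=float))
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    if detections.size == 0:
        detections = detections.reshape(0, 3)
    if truth.size == 0:
        truth = truth.reshape(0, 3)
    max_dist = radius_factor * nucleus_radius
    dist = cdist(detections, truth) if detections.size and truth.size else np.empty(
        (detections.shape[0], truth.shape[0])
    )
    matcher = {"greedy": _greedy_match, "optimal": _optimal_match}[method]
    pairs = matcher(dist, max_dist)
    tp = len(pairs)
    fp = detections.shape[0] - tp
    fn = truth.shape[0] - tp
    return MatchResult(tp, fp, fn, pairs, [float(dist[d, t]) for d, t in pairs])


def jaccard(match: MatchResult) -> float:
    """Detection accuracy TP / (TP + FP + FN); one for a perfect match."""
    total = match.tp + match.fp + match.fn
    if total == 0:
        raise UndefinedScoreError("Jaccard undefined on all-zero counts")
    return match.tp / total


def evaluate_tracking(
    trajectories: np.ndarray,
    truth_tracks: np.ndarray,
    nucleus_size: float,
    method: str = "greedy",
) -> MatchResult:
    """Score complete trajectories against ground-truth tracks.

    ``trajectories`` is (n_traj, T, 3) and ``truth_tracks`` (n_true, T, 3);
    the per-pair score is the distance averaged over time, the acceptance
    bound 3x ``nucleus_size`` (the nucleus diameter, generous mostly for
    axial imprecision).
    """
    trajectories = np.asarray(trajectories, dtype=float)
    truth_tracks = np.asarray(truth_tracks, dtype=float)
    if trajectories.size == 0:
        return MatchResult(0, 0, truth_tracks.shape[0])
    if truth_tracks.size == 0:
        return MatchResult(0, trajectories.shape[0], 0)
    if trajectories.shape[1] != truth_tracks.shape[1]:
        raise ValueError("trajectories and truth must cover the same frames")
    diff = trajectories[:, None, :, :] - truth_tracks[None, :, :, :]
    mean_dist = np.sqrt((diff**2).sum(axis=3)).mean(axis=2)
    matcher = {"greedy": _greedy_match, "optimal": _optimal_match}[method]
    pairs = matcher(mean_dist, 3.0 * nucleus_size)
    tp = len(pairs)
    fp = trajectories.shape[0] - tp
    fn = truth_tracks.shape[0] - tp
    return MatchResult(tp, fp, fn, pairs, [float(mean_dist[d, t]) for d, t in pairs])


def read_annotations(path, geometry: AcquisitionGeometry):
    """Read manual annotations (Cell-Counter XML or the package CSV dialect).

    Returns a dict marker_type -> (n, 3) array of physical (z, y, x) µm
    coordinates.  Cell-Counter coordinates are pixel/slice indices with
    1-based slices, converted with the supplied geometry.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        required = {"z_um", "y_um", "x_um"}
        if not required <= set(df.columns):
            raise AnnotationParseError(f"CSV missing columns {sorted(required - set(df.columns))}")
        if "type" not in df.columns:
            df["type"] = 1
        out = {}
        for mtype, grp in df.groupby("type"):
            out[mtype] = grp[["z_um", "y_um", "x_um"]].to_numpy(dtype=float)
        if not out:
            warnings.warn(f"{path}: no markers found", RuntimeWarning)
        return out
    try:
        tree = ET.parse(str(path))
    except ET.ParseError as exc:
        line, col = exc.position
        raise AnnotationParseError(f"{path}: malformed XML at line {line}, column {col}") from exc
    root = tree.getroot()
    out: dict = {}
    for type_node in root.iter("Marker_Type"):
        type_el = type_node.find("Type")
        mtype = int(type_el.text) if type_el is not None and type_el.text else 1
        pts = []
        for marker in type_node.iter("Marker"):
            try:
                x = float(marker.findtext("MarkerX"))
                y = float(marker.findtext("MarkerY"))
                z = float(marker.findtext("MarkerZ"))
            except (TypeError, ValueError) as exc:
                raise AnnotationParseError(f"{path}: marker with missing coordinate") from exc
            pts.append(
                [
                    (z - 1.0) * geometry.z_step,  # ImageJ slices are 1-based
                    y * geometry.pixel_size_xy,
                    x * geometry.pixel_size_xy,
                ]
            )
        if pts:
            out[mtype] = np.asarray(pts, dtype=float)
    if not out:
        warnings.warn(f"{path}: no markers found", RuntimeWarning)
    return out


def write_annotations_csv(points_by_type: dict, path) -> None:
    """Write the CSV annotation dialect (columns type, z_um, y_um, x_um)."""
    rows = []
    for mtype, pts in points_by_type.items():
        for z, y, x in np.atleast_2d(pts):
            rows.append({"type": mtype, "z_um": z, "y_um": y, "x_um": x})
    pd.DataFrame(rows, columns=["type", "z_um", "y_um", "x_um"]).to_csv(path, index=False)
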