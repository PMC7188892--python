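"""Trajectory reconstruction from the registered 3D+time cloud.

After registration, every soma's detections across time pile up into a
compact spatial cluster.  DBSCAN on the registered (z, y, x) coordinates —
deliberately ignoring time — identifies those piles and discards isolated
spurious detections as noise.  Clusters that captured n > 1 somata (about
n*T members) are split by k-means; per-frame duplicates are resolved to the
detection nearest the cluster centroid, missing frames are filled by linear
interpolation in time, and the completed paths are mapped back to the
original coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import DBSCAN, KMeans
from sklearn.neighbors import NearestNeighbors

from .detection import NucleusSizePrior
from .registration import RegisteredCloud

__all__ = [
    "DBSCANParams",
    "Cluster",
    "TrajectorySet",
    "PROVENANCE_CODES",
    "estimate_dbscan_params",
    "cluster_detections",
    "split_merged",
    "finalize_trajectory",
    "track",
]

logger = logging.getLogger(__name__)

#: provenance of each trajectory position
PROVENANCE_CODES = {"detected": 0, "interpolated": 1, "deduplicated": 2}
PROVENANCE_NAMES = {v: k for k, v in PROVENANCE_CODES.items()}


@dataclass(frozen=True)
class DBSCANParams:
    eps: float  # µm
    min_pts: int

    def __post_init__(self):
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.min_pts < 2:
            raise ValueError("min_pts must be >= 2")


@dataclass
class Cluster:
    """Member detections of one DBSCAN cluster (indices into the stacked cloud)."""

    cluster_id: int
    coords: np.ndarray  # (n, 3) registered µm
    frames: np.ndarray  # (n,) frame index per member
    point_ids: np.ndarray  # (n,) indices into the stacked registered cloud

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    @property
    def median_per_frame_count(self) -> float:
        _, counts = np.unique(self.frames, return_counts=True)
        return float(np.median(counts))


@dataclass
class TrajectorySet:
    """Complete per-soma paths over all frames, in original coordinates."""

    positions: np.ndarray  # (n_somata, T, 3) µm
    provenance: np.ndarray  # (n_somata, T) int8, see PROVENANCE_CODES
    soma_ids: np.ndarray  # (n_somata,)
    registered_positions: np.ndarray | None = None  # same shape, reference space

    def __post_init__(self):
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must be (n, T, 3)")
        if self.provenance.shape != self.positions.shape[:2]:
            raise ValueError("provenance shape mismatch")

    @property
    def n_somata(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]


def estimate_dbscan_params(
    cloud: RegisteredCloud,
    prior: NucleusSizePrior,
    support_fraction: float = 0.5,
) -> DBSCANParams:
    """Estimate DBSCAN parameters from the registered cloud itself.

    min_pts demands that a soma be detected in at least ``support_fraction``
    of the frames; eps is read at the knee (maximum deviation from the
    chord) of the sorted min_pts-NN distance curve, capped at the nucleus
    radius so distinct adjacent somata are never bridged.
    """
    coords, frames = cloud.stacked("nonrigid")
    if coords.shape[0] == 0:
        raise ValueError("empty registered cloud")
    T = len(cloud.frames)
    min_pts = max(2, int(round(support_fraction * T)))
    k = min(min_pts, coords.shape[0] - 1)
    if k < 1:
        return DBSCANParams(eps=prior.radius, min_pts=min_pts)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    dists, _ = nn.kneighbors(coords)
    curve = np.sort(dists[:, -1])
    n = curve.size
    if n < 3:
        eps = float(curve[-1])
    else:
        # knee: farthest point below the chord joining the curve's endpoints
        t = np.linspace(0.0, 1.0, n)
        chord = curve[0] + t * (curve[-1] - curve[0])
        eps = float(curve[int(np.argmax(chord - curve))])
    eps = min(max(eps, 1e-6), prior.radius)
    return DBSCANParams(eps=eps, min_pts=min_pts)


def cluster_detections(cloud: RegisteredCloud, params: DBSCANParams) -> list[Cluster]:
    """DBSCAN on registered spatial coordinates only; noise is dropped."""
    coords, frames = cloud.stacked("nonrigid")
    if coords.shape[0] == 0:
        return []
    labels = DBSCAN(eps=params.eps, min_samples=params.min_pts).fit_predict(coords)
    clusters = []
    for cid in np.unique(labels):
        if cid == -1:
            continue
        sel = np.flatnonzero(labels == cid)
        clusters.append(Cluster(int(cid), coords[sel], frames[sel], sel))
    return clusters


def split_merged(
    cluster: Cluster,
    rng: np.random.Generator | int = 0,
) -> list[Cluster]:
    """Split a cluster that merged n somata into n clusters by k-means.

    n is the median number of detections per frame (over frames where the
    cluster has at least one detection), rounded to the nearest integer
    (banker's rounding); n <= 1 leaves the cluster unchanged.
    """
    if len(cluster) == 0:
        return [cluster]
    n = int(np.round(cluster.median_per_frame_count))
    if n <= 1:
        return [cluster]
    seed = rng if isinstance(rng, (int, np.integer)) else int(rng.integers(2**31 - 1))
    n = min(n, len(cluster))
    km = KMeans(n_clusters=n, n_init=10, random_state=int(seed)).fit(cluster.coords)
    out = []
    for j in range(n):
        sel = np.flatnonzero(km.labels_ == j)
        if sel.size == 0:
            continue
        out.append(
            Cluster(cluster.cluster_id, cluster.coords[sel], cluster.frames[sel], cluster.point_ids[sel])
        )
    return out


def _frame_point_lookup(cloud: RegisteredCloud):
    """Map stacked point index -> (frame position in list, row within frame)."""
    offsets = []
    start = 0
    for f in cloud.frames:
        offsets.append(start)
        start += len(f)
    offsets = np.array(offsets + [start])

    def lookup(point_id: int) -> tuple[int, int]:
        fi = int(np.searchsorted(offsets, point_id, side="right") - 1)
        return fi, int(point_id - offsets[fi])

    return lookup


def finalize_trajectory(
    cluster: Cluster,
    T: int,
    cloud: RegisteredCloud,
    min_support: int = 3,
):
    """Turn one (post-split) cluster into a complete per-frame trajectory.

    Per frame: multiple detections keep only the one nearest the cluster
    centroid (position flagged ``deduplicated``); missing frames are linearly
    interpolated in registered space between the nearest detected frames
    (copied at the sequence ends) and mapped back to original coordinates by
    inverting the frame's similarity transform after removing the frame's
    CPD displacement (nearest-detection lookup).  Detected positions keep
    their stored original coordinates exactly.

    Returns ``None`` (cluster discarded) when detections cover fewer than
    ``min_support`` distinct frames.
    """
    if np.unique(cluster.frames).size < min_support:
        logger.info("cluster %d: support < %d frames; discarded", cluster.cluster_id, min_support)
        return None
    lookup = _frame_point_lookup(cloud)
    centroid = cluster.centroid
    reg_pos = np.full((T, 3), np.nan)
    orig_pos = np.full((T, 3), np.nan)
    prov = np.full(T, PROVENANCE_CODES["interpolated"], dtype=np.int8)
    for t in range(T):
        sel = np.flatnonzero(cluster.frames == t)
        if sel.size == 0:
            continue
        if sel.size == 1:
            best = sel[0]
            prov[t] = PROVENANCE_CODES["detected"]
        else:
            d = np.linalg.norm(cluster.coords[sel] - centroid, axis=1)
            best = sel[int(np.argmin(d))]
            prov[t] = PROVENANCE_CODES["deduplicated"]
            logger.debug("cluster %d frame %d: %d duplicates dropped", cluster.cluster_id, t, sel.size - 1)
        reg_pos[t] = cluster.coords[best]
        fi, row = lookup(int(cluster.point_ids[best]))
        orig_pos[t] = cloud.frames[fi].original[row]
    detected = np.flatnonzero(prov != PROVENANCE_CODES["interpolated"])
    # fill gaps in registered space by linear interpolation in time
    for axis in range(3):
        reg_pos[:, axis] = np.interp(np.arange(T), detected, reg_pos[detected, axis])
    # map interpolated positions back to original coordinates
    frame_by_index = {f.frame: f for f in cloud.frames}
    for t in range(T):
        if prov[t] != PROVENANCE_CODES["interpolated"]:
            continue
        f = frame_by_index.get(t)
        p = reg_pos[t]
        if f is not None and len(f) > 0:
            d = np.linalg.norm(f.nonrigid - p, axis=1)
            disp = f.displacement[int(np.argmin(d))]
        else:
            disp = np.zeros(3)
        rigid = p - disp
        orig_pos[t] = cloud.chain.from_reference(t, rigid)[0]
    return orig_pos, reg_pos, prov


def track(
    cloud: RegisteredCloud,
    prior: NucleusSizePrior,
    params: DBSCANParams | None = None,
    min_support: int = 3,
    support_fraction: float = 0.5,
    rng: np.random.Generator | int = 0,
) -> TrajectorySet:
    """Full step 4: estimate parameters, cluster, split, finalize.

    Every returned trajectory covers every frame; an empty result (all
    clusters rejected) is returned with a warning, not an error.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    T = len(cloud.frames)
    if params is None:
        params = estimate_dbscan_params(cloud, prior, support_fraction)
    clusters = cluster_detections(cloud, params)
    split: list[Cluster] = []
    for c in clusters:
        split.extend(split_merged(c, rng))
    orig, reg, prov, ids = [], [], [], []
    for i, c in enumerate(split):
        result = finalize_trajectory(c, T, cloud, min_support)
        if result is None:
            continue
        o, r, p = result
        orig.append(o)
        reg.append(r)
        prov.append(p)
        ids.append(len(ids))
    if not orig:
        logger.warning("tracking produced zero trajectories")
        return TrajectorySet(
            np.empty((0, T, 3)), np.empty((0, T), dtype=np.int8), np.empty((0,), dtype=int),
            registered_positions=np.empty((0, T, 3)),
        )
    return TrajectorySet(
        np.stack(orig),
        np.stack(prov),
        np.arange(len(orig)),
        registered_positions=np.stack(reg),
    )
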