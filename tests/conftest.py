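import dataclasses
import warnings

import numpy as np
import pytest

from somatrack.io_core import AcquisitionGeometry, PAPER_GEOMETRY
from somatrack.synthetic import (
    SimulationConfig,
    simulate_ground_truth,
    simulate_sequence,
)


@pytest.fixture(scope="session")
def paper_geometry():
    return PAPER_GEOMETRY


@pytest.fixture(scope="session")
def tiny_geometry():
    """Reduced field of view at the standard voxel pitch (fast rendering)."""
    return AcquisitionGeometry(
        pixel_size_xy=0.16125, z_step=1.5, frame_period=0.9, n_planes=10, plane_shape=(32, 32)
    )


@pytest.fixture(scope="session")
def tiny_simulation(tiny_geometry):
    """A small rendered two-channel sequence with ground truth."""
    cfg = SimulationConfig(
        n_nuclei=8,
        geometry=tiny_geometry,
        n_frames=10,
        fraction_responsive=0.5,
        motion_amplitude=0.3,  # the 5 µm field of view tolerates little drift
        stimulus_windows=(("air", 1, 3), ("odor_A", 5, 8)),
        seed=11,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        seq, truth = simulate_sequence(cfg)
    return cfg, seq, truth


@pytest.fixture(scope="session")
def bench_truth():
    """Point-cloud tracking benchmark: 200 nuclei, 40 frames, default motion."""
    cfg = SimulationConfig(n_nuclei=200, n_frames=40, seed=3)
    truth, windows = simulate_ground_truth(cfg)
    return cfg, truth


# ---------------------------------------------------------------------------
# independent brute-force oracles used by several test modules

def brute_force_local_maxima(data: np.ndarray):
    """Naive 26-neighbourhood maxima with plateau grouping.

    A voxel is a candidate when it is >= all 26 neighbours (borders
    excluded); equal-valued adjacent candidates form one plateau, reported at
    its centroid, and only plateaus strictly above every surrounding
    non-candidate voxel count.
    """
    nz, ny, nx = data.shape
    cand = np.zeros(data.shape, dtype=bool)
    for z in range(1, nz - 1):
        for y in range(1, ny - 1):
            for x in range(1, nx - 1):
                v = data[z, y, x]
                neigh = data[z - 1 : z + 2, y - 1 : y + 2, x - 1 : x + 2]
                if v >= neigh.max():
                    cand[z, y, x] = True
    # group adjacent candidates (necessarily equal-valued) by BFS
    seen = np.zeros_like(cand)
    out = []
    offs = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    for z, y, x in np.argwhere(cand):
        if seen[z, y, x]:
            continue
        stack = [(z, y, x)]
        seen[z, y, x] = True
        comp = []
        while stack:
            cz, cy, cx = stack.pop()
            comp.append((cz, cy, cx))
            for dz, dy, dx in offs:
                n = (cz + dz, cy + dy, cx + dx)
                if (
                    0 <= n[0] < nz and 0 <= n[1] < ny and 0 <= n[2] < nx
                    and cand[n] and not seen[n]
                ):
                    seen[n] = True
                    stack.append(n)
        val = data[comp[0]]
        dominates = True
        for cz, cy, cx in comp:
            for dz, dy, dx in offs:
                n = (cz + dz, cy + dy, cx + dx)
                if 0 <= n[0] < nz and 0 <= n[1] < ny and 0 <= n[2] < nx:
                    if not cand[n] and data[n] >= val:
                        dominates = False
                else:
                    pass
            if not dominates:
                break
        if dominates:
            out.append((np.mean([c for c in comp], axis=0), val))
    if not out:
        return np.empty((0, 3)), np.empty((0,))
    coords = np.array([c for c, _ in out])
    vals = np.array([v for _, v in out])
    return coords, vals


def brute_force_dbscan(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Textbook DBSCAN; returns labels with -1 for noise."""
    n = points.shape[0]
    dist = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    neighbors = [np.flatnonzero(dist[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_pts for nb in neighbors])
    labels = np.full(n, -1)
    cid = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        labels[i] = cid
        queue = list(neighbors[i])
        while queue:
            j = queue.pop()
            if labels[j] == -1:
                labels[j] = cid
                if core[j]:
                    queue.extend(neighbors[j])
        cid += 1
    return labels


def brute_force_nearest_seed(shape, voxel_size, seeds, max_radius):
    """Per-voxel nearest-seed labelling with lowest-index tie-break."""
    labels = np.full(shape, -1, dtype=int)
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                p = np.array([z, y, x]) * voxel_size
                d = np.sqrt(((seeds - p) ** 2).sum(axis=1))
                i = int(np.argmin(d))  # argmin takes the lowest index on ties
                if d[i] <= max_radius:
                    labels[z, y, x] = i
    return labels
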