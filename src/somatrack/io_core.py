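"""Image sequence I/O, acquisition geometry, and corrupted-frame repair.

Volumes are held in (z, y, x) order with 0-based indices; physical
coordinates in micrometres are obtained as index times the axial/lateral
sampling step.  All point sets downstream of this module carry physical
coordinates, so the ~10x axial:lateral sampling anisotropy lives in the
units rather than in the indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import tifffile
import yaml

from .errors import ChannelCountError, SequenceFormatError, UnrecoverableSequenceError

__all__ = [
    "AcquisitionGeometry",
    "VolumeStack",
    "StimulusWindow",
    "Sequence",
    "PAPER_GEOMETRY",
    "read_sequence",
    "write_sequence",
    "detect_corrupted_frames",
    "repair_frames",
]


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Physical sampling of one acquisition.

    Attributes
    ----------
    pixel_size_xy : float
        Lateral pixel size in µm/pixel.
    z_step : float
        Axial distance between consecutive 2D planes in µm.
    frame_period : float
        Time between consecutive 3D stacks in seconds.
    n_planes : int
        Number of 2D planes per 3D stack.
    plane_shape : tuple of int
        (rows, cols) of each 2D plane.
    """

    pixel_size_xy: float
    z_step: float
    frame_period: float
    n_planes: int
    plane_shape: tuple[int, int]

    def __post_init__(self):
        if not (
            self.pixel_size_xy > 0
            and self.z_step > 0
            and self.frame_period > 0
            and self.n_planes > 0
            and all(s > 0 for s in self.plane_shape)
        ):
            raise ValueError("all geometry fields must be strictly positive")

    @property
    def anisotropy_ratio(self) -> float:
        return self.z_step / self.pixel_size_xy

    @property
    def stack_shape(self) -> tuple[int, int, int]:
        return (self.n_planes, *self.plane_shape)

    @property
    def voxel_size(self) -> np.ndarray:
        """(z, y, x) sampling steps in µm."""
        return np.array([self.z_step, self.pixel_size_xy, self.pixel_size_xy])

    @property
    def extent_um(self) -> np.ndarray:
        """Physical span of the stack along (z, y, x) in µm."""
        return (np.array(self.stack_shape) - 1) * self.voxel_size + self.voxel_size


#: Geometry of the spinning-disk mushroom-body acquisitions: 45 planes of
#: 256x512 px at 0.16125 µm/px, 1.5 µm z-step, one stack every 0.9 s.
PAPER_GEOMETRY = AcquisitionGeometry(
    pixel_size_xy=0.16125,
    z_step=1.5,
    frame_period=0.9,
    n_planes=45,
    plane_shape=(256, 512),
)

CHANNEL_NAMES = ("nuclei", "calcium")


@dataclass
class VolumeStack:
    """One 3D intensity grid at one time point."""

    data: np.ndarray  # (z, y, x), non-negative
    geometry: AcquisitionGeometry
    time_index: int = 0
    channel: str = "nuclei"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("VolumeStack data must be 3D (z, y, x)")
        if self.data.shape != self.geometry.stack_shape:
            raise ValueError(
                f"data shape {self.data.shape} inconsistent with geometry "
                f"{self.geometry.stack_shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("VolumeStack intensities must be finite")

    def voxel_to_um(self, idx: np.ndarray) -> np.ndarray:
        """Convert (z, y, x) voxel indices to physical µm coordinates."""
        return np.asarray(idx, dtype=float) * self.geometry.voxel_size

    def um_to_voxel(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) / self.geometry.voxel_size


@dataclass(frozen=True)
class StimulusWindow:
    """Half-open frame interval [start, end) during which a stimulus acts."""

    label: str
    start: int
    end: int

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError("stimulus window must satisfy 0 <= start < end")


@dataclass
class Sequence:
    """Ordered two-channel 3D+time sequence."""

    frames: list[tuple[VolumeStack, VolumeStack]]  # (nuclei, calcium) per frame
    stimulus_windows: list[StimulusWindow] = field(default_factory=list)

    def __post_init__(self):
        if len(self.frames) < 1:
            raise ValueError("Sequence needs at least one frame")
        geom = self.frames[0][0].geometry
        for nuc, cal in self.frames:
            if nuc.geometry != geom or cal.geometry != geom:
                raise ValueError("all frames must share one geometry")
        for w in self.stimulus_windows:
            if w.end > len(self.frames):
                raise ValueError(f"stimulus window {w.label} outside sequence")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def geometry(self) -> AcquisitionGeometry:
        return self.frames[0][0].geometry

    def channel(self, name: str) -> list[VolumeStack]:
        i = CHANNEL_NAMES.index(name)
        return [f[i] for f in self.frames]


def _axis_positions(axis_order: str) -> dict[str, int]:
    axis_order = axis_order.upper()
    required = set("XYZTC")
    declared = set(axis_order)
    if "C" not in declared:
        raise ChannelCountError(f"no channel axis in axis order {axis_order!r}")
    for ax in sorted(required - declared):
        raise SequenceFormatError(f"missing axis {ax!r} in axis order {axis_order!r}")
    for ax in sorted(declared - required):
        raise SequenceFormatError(f"unsupported axis {ax!r} in axis order {axis_order!r}")
    if len(axis_order) != 5:
        raise SequenceFormatError(f"duplicate axes in axis order {axis_order!r}")
    # Convention: the axis string lists axes from fastest- to slowest-varying,
    # so the numpy array laid out on disk has shape reversed(axis_order).
    return {ax: i for i, ax in enumerate(reversed(axis_order))}


def write_sequence(seq: Sequence, path, axis_order: str = "XYZTC") -> None:
    """Write a two-channel sequence as a 5D 16-bit multi-page TIFF.

    A YAML sidecar ``<path>.meta.yaml`` stores the geometry and stimulus
    windows.
    """
    pos = _axis_positions(axis_order)
    g = seq.geometry
    shape = [0] * 5
    shape[pos["T"]] = seq.n_frames
    shape[pos["C"]] = 2
    shape[pos["Z"]] = g.n_planes
    shape[pos["Y"]] = g.plane_shape[0]
    shape[pos["X"]] = g.plane_shape[1]
    arr = np.zeros(shape, dtype=np.uint16)
    idx = [slice(None)] * 5
    for t, (nuc, cal) in enumerate(seq.frames):
        idx[pos["T"]] = t
        for c, stack in enumerate((nuc, cal)):
            idx[pos["C"]] = c
            view = np.moveaxis(
                arr[tuple(idx)],
                # remaining axes among Z,Y,X keep their relative order
                _remaining_order(pos),
                (0, 1, 2),
            )
            view[...] = np.clip(np.round(stack.data), 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(str(path), arr)
    meta = {
        "axis_order": axis_order,
        "pixel_size_xy": float(g.pixel_size_xy),
        "z_step": float(g.z_step),
        "frame_period": float(g.frame_period),
        "n_planes": int(g.n_planes),
        "plane_shape": [int(s) for s in g.plane_shape],
        "stimulus_windows": [
            {"label": w.label, "start": int(w.start), "end": int(w.end)}
            for w in seq.stimulus_windows
        ],
    }
    with open(f"{path}.meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)


def _remaining_order(pos: dict[str, int]) -> tuple[int, int, int]:
    spatial = sorted(("Z", "Y", "X"), key=lambda ax: pos[ax])
    rank = {ax: i for i, ax in enumerate(spatial)}
    return (rank["Z"], rank["Y"], rank["X"])


def read_sequence(path, axis_order: str | None = None) -> Sequence:
    """Read a 5D XYZTC TIFF (bit-exact) plus its YAML geometry sidecar."""
    meta_path = f"{path}.meta.yaml"
    try:
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh)
    except FileNotFoundError:
        raise SequenceFormatError(f"missing geometry sidecar {meta_path}")
    if axis_order is None:
        axis_order = meta.get("axis_order", "XYZTC")
    pos = _axis_positions(axis_order)
    arr = tifffile.imread(str(path))
    if arr.ndim != 5:
        raise SequenceFormatError(
            f"expected a 5D array for axes {axis_order!r}, got {arr.ndim}D"
        )
    if arr.shape[pos["C"]] != 2:
        raise ChannelCountError(
            f"expected 2 channels, found {arr.shape[pos['C']]} on axis C"
        )
    geometry = AcquisitionGeometry(
        pixel_size_xy=float(meta["pixel_size_xy"]),
        z_step=float(meta["z_step"]),
        frame_period=float(meta["frame_period"]),
        n_planes=int(meta["n_planes"]),
        plane_shape=tuple(int(s) for s in meta["plane_shape"]),
    )
    idx = [slice(None)] * 5
    frames = []
    for t in range(arr.shape[pos["T"]]):
        idx[pos["T"]] = t
        pair = []
        for c, name in enumerate(CHANNEL_NAMES):
            idx[pos["C"]] = c
            vol = np.moveaxis(arr[tuple(idx)], _remaining_order(pos), (0, 1, 2))
            pair.append(
                VolumeStack(np.ascontiguousarray(vol), geometry, time_index=t, channel=name)
            )
        frames.append(tuple(pair))
    windows = [
        StimulusWindow(w["label"], int(w["start"]), int(w["end"]))
        for w in meta.get("stimulus_windows", [])
    ]
    return Sequence(frames, windows)


def detect_corrupted_frames(seq: Sequence, z_max: float = 5.0) -> list[int]:
    """Flag frames whose nuclei-channel median intensity is a robust outlier.

    A sporadic acquisition artifact occasionally wipes out or saturates whole
    stacks; such frames show a per-frame median far from the sequence-wide
    median.  A frame is flagged when its robust z-score (median/MAD, MAD
    scaled by 0.6745 to be sigma-consistent) exceeds ``z_max``.  At most 20%
    of frames are ever flagged (the worst offenders first).
    """
    medians = np.array([float(np.median(nuc.data)) for nuc, _ in seq.frames])
    center = np.median(medians)
    mad = np.median(np.abs(medians - center))
    scale = mad / 0.6745
    if scale <= 0:
        # over half the frames share the exact same median: only a gross
        # deviation from it can be an artifact
        scale = max(1e-9, 1e-9 * max(abs(center), 1.0))
    z = np.abs(medians - center) / scale
    flagged = np.flatnonzero(z > z_max)
    cap = int(0.2 * len(medians))
    if len(flagged) > cap:
        order = np.argsort(z[flagged])[::-1]
        flagged = np.sort(flagged[order[:cap]])
    return [int(i) for i in flagged]


def repair_frames(seq: Sequence, bad: list[int]) -> Sequence:
    """Replace corrupted frames by per-voxel linear interpolation in time.

    The two nearest good frames bracket each bad frame; at the sequence ends
    the nearest good frame is copied.  Good frames are passed through
    untouched (same arrays).
    """
    T = seq.n_frames
    bad_set = {int(b) for b in bad}
    if not bad_set:
        return seq
    if not all(0 <= b < T for b in bad_set):
        raise ValueError("bad frame index out of range")
    good = [t for t in range(T) if t not in bad_set]
    if not good:
        raise UnrecoverableSequenceError("all frames are corrupted")
    good_arr = np.array(good)

    new_frames: list[tuple[VolumeStack, VolumeStack]] = []
    for t in range(T):
        if t not in bad_set:
            new_frames.append(seq.frames[t])
            continue
        lo = good_arr[good_arr < t]
        hi = good_arr[good_arr > t]
        pair = []
        for c in range(2):
            if len(lo) == 0:
                data = seq.frames[hi[0]][c].data.copy()
            elif len(hi) == 0:
                data = seq.frames[lo[-1]][c].data.copy()
            else:
                a, b = int(lo[-1]), int(hi[0])
                w = (t - a) / (b - a)
                data = (1 - w) * seq.frames[a][c].data.astype(float) + w * seq.frames[b][
                    c
                ].data.astype(float)
            src = seq.frames[t][c]
            pair.append(replace(src, data=data))
        new_frames.append(tuple(pair))
    return Sequence(new_frames, list(seq.stimulus_windows))
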