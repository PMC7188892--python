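"""Ground-truthed synthetic two-channel acquisitions.

Emulates the mushroom-body recordings: ~2,000 nuclei packed into an
ellipsoidal tissue foreground, rendered as PSF-blurred solid spheres on a
fine isotropic grid, axially subsampled to the acquisition anisotropy, with
additive Gaussian noise.  Motion combines a global similarity jitter (slow
drift plus rare erratic shifts of the whole preparation) with a smooth
low-frequency deformation field, so neighbouring somata move coherently and
inter-neighbour distances stay nearly constant.  A responsive subset of
nuclei carries calcium transients (instant rise, exponential decay) locked
to the stimulus windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from sklearn.cluster import KMeans

from .detection import DetectionCloud
from .errors import DegenerateTemplateError, InfeasiblePlacementError
from .io_core import (
    AcquisitionGeometry,
    PAPER_GEOMETRY,
    Sequence,
    StimulusWindow,
    VolumeStack,
)
from .signal import default_stimulus_windows

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "make_foreground",
    "place_nuclei",
    "render_stack",
    "simulate_ground_truth",
    "simulate_sequence",
    "ground_truth_clouds",
    "inject_detection_noise",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the emulated acquisition.

    Defaults reproduce the full-scale recording: 2,000 Kenyon-cell nuclei of
    ~3 µm diameter in the standard 45 x 256 x 512 geometry, 120 frames at
    0.9 s.  PSF sigmas are in µm with a 3x axial elongation; noise_sigma is
    the additive Gaussian noise on a ~1,000 a.u. nucleus brightness.
    """

    n_nuclei: int = 2000
    geometry: AcquisitionGeometry = PAPER_GEOMETRY
    nucleus_diameter: float = 3.0  # µm
    psf_sigma_lateral: float = 0.2  # µm
    psf_sigma_axial: float = 0.6  # µm (3x lateral by default)
    noise_sigma: float = 30.0  # a.u.
    nucleus_brightness: float = 1000.0  # a.u., log-normal per-nucleus spread 0.3
    calcium_brightness: float = 600.0  # a.u. baseline of the calcium channel
    n_frames: int = 120
    motion_amplitude: float = 1.0  # scales drift, shifts and deformation
    drift_step: float = 0.08  # µm random-walk step per frame
    rotation_step: float = 0.002  # rad random-walk step per frame
    erratic_rate: float = 2.0  # expected erratic whole-volume shifts per sequence
    erratic_shift: float = 2.0  # µm amplitude of an erratic shift
    deformation_amplitude: float = 0.3  # µm peak of each sinusoidal mode
    deformation_modes: int = 3
    fraction_responsive: float = 0.2
    transient_peak_dff: float = 0.5  # mean peak ΔF/F of a transient
    transient_tau: float = 2.0  # s decay time constant
    foreground_fraction: float = 0.4
    stimulus_windows: tuple | None = None  # ((label, start, end), ...); None = standard protocol
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        """Build a config from plain (YAML-loaded) values."""
        kw = dict(raw)
        if isinstance(kw.get("geometry"), dict):
            geo = dict(kw["geometry"])
            geo["plane_shape"] = tuple(geo["plane_shape"])
            kw["geometry"] = AcquisitionGeometry(**geo)
        if kw.get("stimulus_windows") is not None:
            kw["stimulus_windows"] = tuple(tuple(w) for w in kw["stimulus_windows"])
        return cls(**kw)

    def __post_init__(self):
        if not 0.0 <= self.fraction_responsive <= 1.0:
            raise ValueError("fraction_responsive must be in [0, 1]")
        for name in (
            "n_nuclei", "nucleus_diameter", "psf_sigma_lateral", "psf_sigma_axial",
            "nucleus_brightness", "calcium_brightness", "n_frames", "transient_tau",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GroundTruth:
    """True per-frame nucleus centres and activity."""

    centers_um: np.ndarray  # (n, T, 3)
    responsive: np.ndarray  # (n,) bool
    onset_frames: np.ndarray  # (n, n_windows) int, -1 for non-responsive
    activity: np.ndarray  # (n, T) multiplicative calcium brightness factor

    @property
    def n_nuclei(self) -> int:
        return self.centers_um.shape[0]

    @property
    def n_frames(self) -> int:
        return self.centers_um.shape[1]


def make_foreground(
    template: VolumeStack | None,
    shape: tuple[int, int, int] | None = None,
    fraction: float = 0.4,
) -> np.ndarray:
    """Binary tissue foreground mask.

    With a template stack, Otsu's global threshold delineates the tissue and
    the largest connected component is kept.  Without one, a centred
    ellipsoid occupying ~``fraction`` of the volume stands in.
    """
    if template is not None:
        data = template.data
        if np.ptp(data) == 0:
            raise DegenerateTemplateError("constant template has no foreground")
        mask = data > threshold_otsu(data)
        if not mask.any():
            raise DegenerateTemplateError("Otsu threshold yields an empty mask")
        labels, n = ndimage.label(mask)
        if n > 1:
            sizes = ndimage.sum_labels(mask, labels, np.arange(1, n + 1))
            mask = labels == (1 + int(np.argmax(sizes)))
        return mask
    if shape is None:
        raise ValueError("shape required when no template is given")
    # ellipsoid volume fraction = (pi/6) * fz*fy*fx with f the diameter
    # fraction per axis; equal fractions give f = (6*fraction/pi)^(1/3)
    f = (6.0 * fraction / np.pi) ** (1.0 / 3.0)
    zz, yy, xx = np.meshgrid(
        *[(np.arange(s) - (s - 1) / 2.0) / (f * s / 2.0) for s in shape], indexing="ij"
    )
    return zz**2 + yy**2 + xx**2 <= 1.0


def place_nuclei(
    mask: np.ndarray,
    n: int,
    geometry: AcquisitionGeometry,
    rng: np.random.Generator | int = 0,
    n_samples: int = 50000,
) -> np.ndarray:
    """Evenly spaced nucleus centres inside the foreground, via k-means.

    Voxels of the mask are sampled uniformly (in physical µm coordinates so
    spacing honours the axial step) and clustered with k-means, k = n; the
    centroids, snapped back inside the mask, are the centres.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    vox = np.argwhere(mask)
    if vox.shape[0] < n:
        raise InfeasiblePlacementError(f"{n} nuclei requested but mask has {vox.shape[0]} voxels")
    take = min(n_samples, vox.shape[0])
    sample = vox[rng.choice(vox.shape[0], size=take, replace=False)]
    pts = sample * geometry.voxel_size
    km = KMeans(n_clusters=n, n_init=1, random_state=int(rng.integers(2**31 - 1))).fit(pts)
    centers = km.cluster_centers_
    # snap any centroid that left the mask back onto the nearest mask voxel
    vox_idx = np.round(centers / geometry.voxel_size).astype(int)
    vox_idx = np.clip(vox_idx, 0, np.array(mask.shape) - 1)
    outside = ~mask[tuple(vox_idx.T)]
    if outside.any():
        mask_pts = vox * geometry.voxel_size
        for i in np.flatnonzero(outside):
            j = int(np.argmin(((mask_pts - centers[i]) ** 2).sum(axis=1)))
            centers[i] = mask_pts[j]
    return centers


def _axial_factor(geometry: AcquisitionGeometry) -> int:
    return max(1, int(round(geometry.z_step / geometry.pixel_size_xy)))


def render_stack(
    centers_um: np.ndarray,
    config: SimulationConfig,
    brightness: np.ndarray | None = None,
    rng: np.random.Generator | int = 0,
    channel: str = "nuclei",
    time_index: int = 0,
) -> VolumeStack:
    """Render one channel: spheres -> PSF blur -> axial subsampling -> noise.

    Solid spheres of the nucleus radius are drawn at the centres on a fine
    isotropic grid (lateral pixel pitch), convolved with the anisotropic
    Gaussian PSF, subsampled axially by the anisotropy factor, and corrupted
    with i.i.d. Gaussian noise (clamped at zero).
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    g = config.geometry
    centers_um = np.atleast_2d(np.asarray(centers_um, dtype=float))
    n = centers_um.shape[0]
    if brightness is None:
        brightness = np.full(n, config.nucleus_brightness)
    factor = _axial_factor(g)
    px = g.pixel_size_xy
    fine_nz = (g.n_planes - 1) * factor + 1
    fine = np.zeros((fine_nz, *g.plane_shape), dtype=np.float32)
    radius = config.nucleus_diameter / 2.0
    r_vox = radius / px
    fine_steps = np.array([g.z_step / factor, px, px])
    for c, amp in zip(centers_um, brightness):
        cv = c / fine_steps
        lo = np.maximum(np.floor(cv - r_vox).astype(int), 0)
        hi = np.minimum(np.ceil(cv + r_vox).astype(int) + 1, fine.shape)
        if np.any(lo >= hi):
            continue
        zz, yy, xx = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
        inside = (zz - cv[0]) ** 2 + (yy - cv[1]) ** 2 + (xx - cv[2]) ** 2 <= r_vox**2
        region = fine[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        np.maximum(region, inside * amp, out=region)
    sigma_vox = (config.psf_sigma_axial / (g.z_step / factor),
                 config.psf_sigma_lateral / px,
                 config.psf_sigma_lateral / px)
    ndimage.gaussian_filter(fine, sigma=sigma_vox, output=fine, mode="reflect")
    coarse = fine[::factor]
    noisy = coarse + rng.normal(0.0, config.noise_sigma, size=coarse.shape).astype(np.float32)
    np.clip(noisy, 0.0, None, out=noisy)
    return VolumeStack(noisy, g, time_index=time_index, channel=channel)


def _motion_fields(config: SimulationConfig, rng: np.random.Generator):
    """Precompute the global similarity jitter and deformation modes."""
    T = config.n_frames
    amp = config.motion_amplitude
    trans = np.cumsum(rng.normal(0.0, amp * config.drift_step, size=(T, 3)), axis=0)
    n_err = rng.poisson(config.erratic_rate)
    for _ in range(n_err):
        t0 = int(rng.integers(1, T)) if T > 1 else 0
        shift = rng.normal(0.0, amp * config.erratic_shift, size=3)
        trans[t0:] += shift
    angles = np.cumsum(rng.normal(0.0, amp * config.rotation_step, size=T))
    extent = config.geometry.extent_um
    modes = []
    for _ in range(config.deformation_modes):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        wave = rng.normal(size=3)
        wave /= np.linalg.norm(wave)
        wavelength = float(rng.uniform(0.8, 1.5)) * float(np.max(extent))
        phase = float(rng.uniform(0, 2 * np.pi))
        omega = float(rng.uniform(0.2, 1.0)) * 2 * np.pi / T
        a = amp * config.deformation_amplitude
        modes.append((direction, wave, wavelength, phase, omega, a))
    return trans, angles, modes


def _apply_motion(base: np.ndarray, t: int, trans, angles, modes, center: np.ndarray) -> np.ndarray:
    pts = base.copy()
    for direction, wave, wavelength, phase, omega, a in modes:
        arg = 2 * np.pi * (base @ wave) / wavelength + phase + omega * t
        pts = pts + a * np.sin(arg)[:, None] * direction
    theta = angles[t]
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])  # small rotation about z-axis of the stage
    pts = (pts - center) @ rot.T + center + trans[t]
    return pts


def simulate_ground_truth(config: SimulationConfig) -> tuple[GroundTruth, list[StimulusWindow]]:
    """Simulate nucleus placement, motion and calcium activity (no images).

    All centres move jointly under the global similarity jitter plus a sum
    of large-wavelength sinusoidal deformation modes (spatially smooth, so
    the displacement field is tissue-coherent).  Responsive nuclei receive a
    calcium transient (instant rise, exponential decay with
    ``transient_tau``) at the start of each non-air stimulus window.
    """
    rng = np.random.default_rng(config.seed)
    g = config.geometry
    mask = make_foreground(None, g.stack_shape, config.foreground_fraction)
    base = place_nuclei(mask, config.n_nuclei, g, rng)
    center = base.mean(axis=0)
    trans, angles, modes = _motion_fields(config, rng)
    T = config.n_frames
    centers = np.empty((config.n_nuclei, T, 3))
    for t in range(T):
        centers[:, t, :] = _apply_motion(base, t, trans, angles, modes, center)

    if config.stimulus_windows is not None:
        windows = [StimulusWindow(l, int(a), int(b)) for l, a, b in config.stimulus_windows]
    else:
        windows = default_stimulus_windows(T, g.frame_period)
    odor_windows = [w for w in windows if w.label != "air"]
    n_resp = int(round(config.fraction_responsive * config.n_nuclei))
    responsive = np.zeros(config.n_nuclei, dtype=bool)
    responsive[rng.choice(config.n_nuclei, size=n_resp, replace=False)] = True

    activity = np.ones((config.n_nuclei, T))
    onsets = np.full((config.n_nuclei, max(1, len(odor_windows))), -1, dtype=int)
    tau_frames = config.transient_tau / g.frame_period
    frames_idx = np.arange(T)
    for wi, w in enumerate(odor_windows):
        for i in np.flatnonzero(responsive):
            onset = w.start + int(rng.integers(0, max(1, min(3, w.end - w.start))))
            peak = rng.lognormal(np.log(config.transient_peak_dff), 0.3)
            decay = peak * np.exp(-(frames_idx - onset) / tau_frames)
            decay[frames_idx < onset] = 0.0
            activity[i] += decay
            onsets[i, wi] = onset
    return GroundTruth(centers, responsive, onsets, activity), windows


def simulate_sequence(config: SimulationConfig) -> tuple[Sequence, GroundTruth]:
    """Full dynamic two-channel simulation: ground truth plus rendered images."""
    truth, windows = simulate_ground_truth(config)
    rng = np.random.default_rng(config.seed + 1)  # rendering noise stream
    T = config.n_frames
    nuc_brightness = rng.lognormal(np.log(config.nucleus_brightness), 0.3, size=config.n_nuclei)
    cal_brightness = rng.lognormal(np.log(config.calcium_brightness), 0.3, size=config.n_nuclei)
    frames = []
    for t in range(T):
        nuc = render_stack(truth.centers_um[:, t, :], config, nuc_brightness, rng, "nuclei", t)
        cal = render_stack(
            truth.centers_um[:, t, :], config, cal_brightness * truth.activity[:, t], rng, "calcium", t
        )
        frames.append((nuc, cal))
    seq = Sequence(frames, windows)
    return seq, truth


def ground_truth_clouds(truth: GroundTruth) -> list[DetectionCloud]:
    """Exact detection clouds straight from the ground truth."""
    return [
        DetectionCloud(t, truth.centers_um[:, t, :].copy(), np.ones(truth.n_nuclei))
        for t in range(truth.n_frames)
    ]


def inject_detection_noise(
    truth: GroundTruth,
    miss_rate: float = 0.0,
    spur_rate: float = 0.0,
    jitter_sigma: float = 0.0,
    rng: np.random.Generator | int = 0,
    bounds_um: np.ndarray | None = None,
) -> list[DetectionCloud]:
    """Degrade ground-truth centres into realistic detection clouds.

    Per frame: each true point is dropped with probability ``miss_rate``,
    the survivors are jittered with isotropic Gaussian noise, and
    Poisson(spur_rate x n) spurious points are added uniformly inside the
    cloud's bounding box (or ``bounds_um``).
    """
    if not (0 <= miss_rate < 1 and 0 <= spur_rate < 1):
        raise ValueError("rates must be in [0, 1)")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    n, T = truth.n_nuclei, truth.n_frames
    if bounds_um is None:
        all_pts = truth.centers_um.reshape(-1, 3)
        bounds_um = np.stack([all_pts.min(axis=0), all_pts.max(axis=0)])
    clouds = []
    for t in range(T):
        pts = truth.centers_um[:, t, :]
        keep = rng.random(n) >= miss_rate
        kept = pts[keep]
        if jitter_sigma > 0:
            kept = kept + rng.normal(0.0, jitter_sigma, size=kept.shape)
        n_spur = rng.poisson(spur_rate * n)
        spur = rng.uniform(bounds_um[0], bounds_um[1], size=(n_spur, 3))
        coords = np.vstack([kept, spur]) if n_spur else kept
        clouds.append(DetectionCloud(t, coords, np.ones(coords.shape[0])))
    return clouds
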