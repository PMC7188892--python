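"""Multiscale 3D nucleus detection.

Each interpolated nuclei-channel stack is convolved with a bank of 10
isotropic Gaussian filters whose widths bracket the average nucleus
diameter (the sole tuning parameter of the step).  Per scale, 3D local
maxima (26-neighbourhood) are split into background and nucleus maxima by a
two-component Gaussian mixture on their intensities.  Foreground maxima
from all scales are painted with their original intensity into an empty
grid, which is then merged by a Gaussian convolution matched to the nucleus
size; the local maxima of that merged grid are the final detections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.mixture import GaussianMixture

from .errors import GMMDegenerateError, UnmeasurableProfileError
from .io_core import VolumeStack

__all__ = [
    "FWHM_PER_SIGMA",
    "NucleusSizePrior",
    "DetectionCloud",
    "estimate_nucleus_size",
    "build_filter_bank",
    "local_maxima_3d",
    "gmm_intensity_split",
    "detect_nuclei",
]

logger = logging.getLogger(__name__)

#: FWHM of a Gaussian of unit standard deviation: 2*sqrt(2*ln 2).
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class NucleusSizePrior:
    """Average nucleus diameter in µm (FWHM of the intensity profile)."""

    diameter: float

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValueError("nucleus diameter must be positive")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def sigma(self) -> float:
        """Gaussian sigma whose FWHM equals the nucleus diameter."""
        return self.diameter / FWHM_PER_SIGMA


@dataclass
class DetectionCloud:
    """Candidate nucleus centres of one frame, in physical µm coordinates."""

    frame: int
    coords_um: np.ndarray  # (n, 3) as (z, y, x)
    intensities: np.ndarray  # (n,)

    def __post_init__(self):
        self.coords_um = np.atleast_2d(np.asarray(self.coords_um, dtype=float))
        if self.coords_um.size == 0:
            self.coords_um = np.empty((0, 3))
        self.intensities = np.asarray(self.intensities, dtype=float).ravel()
        if self.coords_um.shape[0] != self.intensities.shape[0]:
            raise ValueError("coords and intensities must align")

    def __len__(self) -> int:
        return self.coords_um.shape[0]


def _profile_fwhm(profile: np.ndarray, center: int, spacing: float) -> float | None:
    """FWHM (in µm) of a background-subtracted 1D profile peaked near center.

    Returns None when the profile never crosses half maximum on either side
    within the sampled window.
    """
    prof = profile.astype(float) - profile.min()
    peak = prof[center]
    if peak <= 0:
        return None
    half = peak / 2.0

    def cross(direction: int) -> float | None:
        i = center
        while 0 <= i + direction < len(prof):
            j = i + direction
            if prof[j] < half:
                # linear sub-sample interpolation between i and j
                frac = (prof[i] - half) / (prof[i] - prof[j])
                return (abs(i - center) + frac) * spacing
            i = j
        return None

    left = cross(-1)
    right = cross(+1)
    if left is None or right is None:
        return None
    return left + right


def estimate_nucleus_size(stack: VolumeStack, sample_points: np.ndarray) -> NucleusSizePrior:
    """Estimate the average nucleus diameter from isolated bright spots.

    For each sample point (voxel indices, z/y/x), the FWHM of the 1D
    intensity profile through the point is measured along x and along y and
    averaged.  Points whose profile never drops below half maximum are
    skipped; if all fail an :class:`UnmeasurableProfileError` is raised.
    """
    sample_points = np.atleast_2d(np.asarray(sample_points, dtype=int))
    if sample_points.shape[0] < 1:
        raise ValueError("at least one sample point is required")
    px = stack.geometry.pixel_size_xy
    fwhms = []
    for z, y, x in sample_points:
        per_point = []
        fx = _profile_fwhm(stack.data[z, y, :], int(x), px)
        fy = _profile_fwhm(stack.data[z, :, x], int(y), px)
        for f in (fx, fy):
            if f is not None:
                per_point.append(f)
        if per_point:
            fwhms.append(float(np.mean(per_point)))
    if not fwhms:
        raise UnmeasurableProfileError(
            "no sampled profile crossed half maximum; cannot estimate nucleus size"
        )
    return NucleusSizePrior(diameter=float(np.mean(fwhms)))


def build_filter_bank(prior: NucleusSizePrior, n_filters: int = 10) -> np.ndarray:
    """Gaussian sigmas (µm) log-spaced over [0.5, 1.5] x the nominal sigma.

    The nominal sigma converts the diameter through the FWHM relation
    sigma = diameter / 2.3548.  A single-filter bank is the nominal sigma.
    """
    if n_filters < 1:
        raise ValueError("n_filters must be >= 1")
    if n_filters == 1:
        return np.array([prior.sigma])
    return prior.sigma * np.geomspace(0.5, 1.5, n_filters)


def local_maxima_3d(filtered: VolumeStack | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """3D local maxima over a 3x3x3 neighbourhood, borders excluded.

    A connected plateau of equal-valued voxels that dominates its surround
    yields a single maximum at the plateau centroid (ties must not multiply
    detections).  Returns (coords, values) with coords as float voxel
    indices (z, y, x).
    """
    data = filtered.data if isinstance(filtered, VolumeStack) else np.asarray(filtered)
    if data.ndim != 3:
        raise ValueError("expected a 3D array")
    data = data.astype(float, copy=False)
    footprint = np.ones((3, 3, 3), dtype=bool)
    is_max = data == ndimage.maximum_filter(data, footprint=footprint, mode="reflect")
    interior = np.zeros_like(is_max)
    interior[1:-1, 1:-1, 1:-1] = True
    is_max &= interior
    if np.ptp(data) > 0:
        # a plateau at the global minimum can never strictly dominate its
        # surround; dropping it early keeps labelling cheap
        is_max &= data > data.min()
    if not is_max.any():
        return np.empty((0, 3)), np.empty((0,))
    # adjacent candidate voxels necessarily share the same value, so connected
    # components of the candidate mask are equal-valued plateaus
    labels, n = ndimage.label(is_max, structure=footprint)
    ids = np.arange(1, n + 1)
    # a plateau counts as a maximum only if every surrounding (non-candidate)
    # voxel is strictly below it
    outer = ndimage.maximum_filter(
        np.where(is_max, -np.inf, data), footprint=footprint, mode="constant", cval=-np.inf
    )
    tied = is_max & (outer >= data)
    keep = np.ones(n + 1, dtype=bool)
    keep[np.unique(labels[tied])] = False
    ids = ids[keep[ids]]
    if ids.size == 0:
        return np.empty((0, 3)), np.empty((0,))
    coords = np.array(ndimage.center_of_mass(is_max, labels, ids))
    vals = ndimage.labeled_comprehension(data, labels, ids, np.max, float, 0.0)
    return coords, np.asarray(vals, dtype=float)


def gmm_intensity_split(
    intensities: np.ndarray,
    rng: np.random.Generator | int = 0,
    min_rel_sep: float = 0.5,
) -> float:
    """Threshold separating background from nucleus maxima intensities.

    Fits a two-component 1D Gaussian mixture by EM (k-means++ init, 3
    restarts) and returns the intensity at which the posterior
    responsibility flips from the dim to the bright component; values
    strictly above the threshold are foreground.

    Raises :class:`GMMDegenerateError` when the fit is degenerate: component
    means closer than one pooled standard deviation, or closer than
    ``min_rel_sep`` x the dim mean.  The relative condition rejects
    signal-free stacks, where EM happily halves the narrow unimodal
    distribution of background maxima into two components that are well
    separated on the noise scale but nearly identical on the intensity
    scale a nucleus would reach.
    """
    x = np.asarray(intensities, dtype=float).ravel()
    if x.size < 10:
        raise ValueError("need at least 10 intensity values")
    if np.ptp(x) == 0:
        raise GMMDegenerateError("all intensities identical")
    seed = rng if isinstance(rng, (int, np.integer)) else int(rng.integers(2**31 - 1))
    gm = GaussianMixture(
        n_components=2,
        n_init=3,
        init_params="k-means++",
        tol=1e-6,
        max_iter=200,
        random_state=int(seed),
    ).fit(x[:, None])
    means = gm.means_.ravel()
    sigmas = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    lo, hi = np.argsort(means)
    pooled = np.sqrt(weights @ (sigmas**2))
    sep = abs(means[hi] - means[lo])
    if sep < pooled:
        raise GMMDegenerateError(
            f"component means {means[lo]:.3g}, {means[hi]:.3g} within one pooled sigma"
        )
    if sep < min_rel_sep * abs(means[lo]):
        raise GMMDegenerateError(
            f"component separation {sep:.3g} below {min_rel_sep:.0%} of the "
            f"background mean {means[lo]:.3g}"
        )
    grid = np.linspace(means[lo], means[hi], 2049)
    post = gm.predict_proba(grid[:, None])[:, hi]
    flip = np.searchsorted(post > 0.5, True)
    if flip == 0 or flip >= len(grid):
        raise GMMDegenerateError("posterior never flips between the means")
    return float(grid[flip])


def detect_nuclei(
    stack: VolumeStack,
    prior: NucleusSizePrior,
    n_filters: int = 10,
    rng: np.random.Generator | int = 0,
) -> DetectionCloud:
    """Detect nucleus centres in one interpolated nuclei-channel stack.

    Pipeline per scale: Gaussian convolution, 26-neighbourhood maxima,
    GMM intensity split, keep foreground maxima.  Kept maxima from all
    scales are painted with the *original* stack intensity into an empty
    grid, which is merged by a Gaussian convolution at the nominal nucleus
    sigma; the final detections are the local maxima of the merged grid,
    returned in physical µm coordinates.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    data = stack.data.astype(np.float32)
    voxel = stack.geometry.voxel_size
    accum = np.zeros_like(data)
    painted = 0
    for sigma_um in build_filter_bank(prior, n_filters):
        sigma_vox = sigma_um / voxel
        filt = ndimage.gaussian_filter(data, sigma=sigma_vox, mode="reflect")
        coords, vals = local_maxima_3d(filt)
        if len(vals) < 10:
            continue
        try:
            thr = gmm_intensity_split(vals, rng)
        except GMMDegenerateError as exc:
            logger.info("scale %.3g µm: degenerate intensity mixture (%s); skipped", sigma_um, exc)
            continue
        keep = vals > thr
        for c in coords[keep]:
            iz, iy, ix = np.round(c).astype(int)
            accum[iz, iy, ix] = max(accum[iz, iy, ix], data[iz, iy, ix])
            painted += 1
    if painted == 0:
        return DetectionCloud(stack.time_index, np.empty((0, 3)), np.empty((0,)))
    merged = ndimage.gaussian_filter(accum, sigma=prior.sigma / voxel, mode="reflect")
    coords, _ = local_maxima_3d(merged)
    vals_merged = merged[tuple(np.round(coords).astype(int).T)]
    keep = vals_merged > 0
    coords = coords[keep]
    ivox = np.round(coords).astype(int)
    intens = data[tuple(ivox.T)]
    return DetectionCloud(stack.time_index, coords * voxel, intens)
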