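"""Point-cloud registration of per-frame detections to a reference frame.

Stage one (rigid): consecutive frames are aligned pairwise by a similarity
transform (rotation, isotropic scale, translation — no shear) fitted by the
closed-form absolute-orientation solution to Hungarian-coupled random
subsets; the pairwise transforms are chained so every frame maps onto the
mid-sequence reference frame.  Stage two (non-rigid): each rigidly aligned
frame is refined directly against the reference cloud with the Coherent
Point Drift algorithm, whose motion-coherence prior preserves the
topological structure of the tissue — neighbouring somata move together.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .detection import DetectionCloud, NucleusSizePrior
from .errors import DegenerateGeometryError, EmptyFrameError

__all__ = [
    "SimilarityTransform",
    "TransformChain",
    "CPDParams",
    "RegisteredFrame",
    "RegisteredCloud",
    "couple_subsets",
    "fit_similarity",
    "fit_similarity_robust",
    "build_chain",
    "cpd_refine",
    "register_sequence",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimilarityTransform:
    """Homogeneous 4x4 transform with upper-left block s*R, det(R) = +1."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("expected a 4x4 homogeneous matrix")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(np.eye(4))

    @classmethod
    def from_parts(cls, rotation: np.ndarray, scale: float, translation: np.ndarray):
        m = np.eye(4)
        m[:3, :3] = scale * np.asarray(rotation, dtype=float)
        m[:3, 3] = np.asarray(translation, dtype=float)
        return cls(m)

    @property
    def scale(self) -> float:
        return float(np.cbrt(np.linalg.det(self.matrix[:3, :3])))

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3] / self.scale

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """self after other: (self ∘ other)(x) = self(other(x))."""
        return SimilarityTransform(self.matrix @ other.matrix)

    def inverse(self) -> "SimilarityTransform":
        return SimilarityTransform(np.linalg.inv(self.matrix))


@dataclass
class TransformChain:
    """Pairwise optimal transforms and their compositions onto the reference.

    ``pairwise[t]`` maps frame t to its chain neighbour (t+1 before the
    reference, t-1 after it); ``composed[t]`` maps frame t directly onto the
    reference frame.  The reference composes to the identity.
    """

    reference: int
    pairwise: dict[int, SimilarityTransform]
    composed: list[SimilarityTransform]

    def to_reference(self, t: int, points: np.ndarray) -> np.ndarray:
        return self.composed[t].apply(points)

    def from_reference(self, t: int, points: np.ndarray) -> np.ndarray:
        return self.composed[t].inverse().apply(points)


@dataclass(frozen=True)
class CPDParams:
    """Non-rigid Coherent Point Drift settings.

    beta is the Gaussian motion-coherence kernel width in µm (the scale over
    which somata are forced to move together); lamb trades data fit against
    smoothness; w is the outlier weight of the mixture (the default 0 lets the
    softmax itself down-weight far points: a nonzero w inflates the uniform
    component at moderate variance and stalls the drift long before
    convergence).
    """

    beta: float = 6.0
    lamb: float = 3.0
    w: float = 0.0
    tol: float = 1e-5
    max_iter: int = 150

    @classmethod
    def for_prior(cls, prior: NucleusSizePrior, **kw) -> "CPDParams":
        """Kernel width of two nucleus diameters, the package default."""
        return cls(beta=2.0 * prior.diameter, **kw)


@dataclass
class RegisteredFrame:
    """One frame's detections at the three registration stages."""

    frame: int
    original: np.ndarray  # (n, 3) µm, as detected
    rigid: np.ndarray  # after the chained similarity transform
    nonrigid: np.ndarray  # after CPD refinement
    intensities: np.ndarray

    @property
    def displacement(self) -> np.ndarray:
        """CPD displacement field sampled at the rigid positions."""
        return self.nonrigid - self.rigid

    def __len__(self) -> int:
        return self.original.shape[0]


@dataclass
class RegisteredCloud:
    frames: list[RegisteredFrame]
    chain: TransformChain

    @property
    def reference(self) -> int:
        return self.chain.reference

    def stacked(self, stage: str = "nonrigid") -> tuple[np.ndarray, np.ndarray]:
        """All points of one stage as (coords (n,3), frame index (n,))."""
        coords = [getattr(f, stage) for f in self.frames]
        frames = [np.full(len(f), f.frame) for f in self.frames]
        return (
            np.concatenate(coords) if coords else np.empty((0, 3)),
            np.concatenate(frames).astype(int) if frames else np.empty((0,), int),
        )


def couple_subsets(
    s_t: np.ndarray,
    s_t1: np.ndarray,
    m: int = 100,
    rng: np.random.Generator | int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Optimally couple random equal-size subsets of two point sets.

    Draws one random subset of size m from each set (m lowered to the
    smaller cardinality when needed) and solves the assignment problem
    minimising total squared Euclidean distance (Hungarian algorithm).
    Returns the coupled pairs as two (m, 3) arrays.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    s_t = np.atleast_2d(np.asarray(s_t, dtype=float))
    s_t1 = np.atleast_2d(np.asarray(s_t1, dtype=float))
    if s_t.shape[0] == 0 or s_t1.shape[0] == 0:
        raise EmptyFrameError("cannot couple an empty point set")
    m = min(m, s_t.shape[0], s_t1.shape[0])
    a = s_t[rng.choice(s_t.shape[0], size=m, replace=False)]
    b = s_t1[rng.choice(s_t1.shape[0], size=m, replace=False)]
    cost = cdist(a, b, "sqeuclidean")
    ri, ci = linear_sum_assignment(cost)
    return a[ri], b[ci]


def fit_similarity(x: np.ndarray, y: np.ndarray) -> SimilarityTransform:
    """Least-squares similarity transform mapping points x onto points y.

    Closed-form absolute-orientation (Umeyama) solution minimising
    sum ||A x_i - y_i||^2 over rotation, isotropic scale and translation.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape != y.shape or x.shape[1] != 3:
        raise ValueError("expected matching (n, 3) point arrays")
    if x.shape[0] < 4:
        raise DegenerateGeometryError("need >= 4 point pairs for a 3D similarity")
    mx, my = x.mean(axis=0), y.mean(axis=0)
    xc, yc = x - mx, y - my
    cov = yc.T @ xc / x.shape[0]
    u, s, vt = np.linalg.svd(cov)
    if s[-1] < 1e-12 * max(s[0], 1e-300) or s[0] == 0:
        raise DegenerateGeometryError("point configuration is collinear or coplanar")
    d = np.sign(np.linalg.det(u @ vt))
    diag = np.diag([1.0, 1.0, d])
    rot = u @ diag @ vt
    var_x = (xc**2).sum() / x.shape[0]
    scale = float(np.trace(np.diag(s) @ diag) / var_x)
    trans = my - scale * rot @ mx
    return SimilarityTransform.from_parts(rot, scale, trans)


def fit_similarity_robust(
    x: np.ndarray,
    y: np.ndarray,
    trim_dist: float = 3.0,
    n_iter: int = 3,
    start_translation: np.ndarray = (0.0, 0.0, 0.0),
) -> SimilarityTransform:
    """Trimmed similarity fit for Hungarian-coupled random subsets.

    Random subsets of two dense clouds share only part of their points, so
    the optimal coupling mixes true correspondences (pair distance of the
    order of the inter-frame motion) with mismatches at the nucleus packing
    distance.  The mismatches are removed before the least-squares fit:
    pairs are pre-aligned by ``start_translation`` (e.g. zero for small
    motions or the component-wise median displacement, which is robust to
    the mismatch majority), pairs with residual above ``trim_dist`` µm are
    dropped, and the closed-form fit / re-trim cycle is iterated.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    start = SimilarityTransform.from_parts(np.eye(3), 1.0, np.asarray(start_translation, dtype=float))
    transform = start
    # shrink the trim radius as the fit sharpens, down to a floor that still
    # keeps genuinely corresponding (jittered) pairs
    radii = np.maximum(trim_dist / 2.0 ** np.arange(n_iter), trim_dist / 3.0)
    for radius in radii:
        resid = np.linalg.norm(transform.apply(x) - y, axis=1)
        keep = resid < radius
        if keep.sum() < 4:
            break
        try:
            transform = fit_similarity(x[keep], y[keep])
        except DegenerateGeometryError:
            break
    return transform


def _best_pair_transform(
    s_t: np.ndarray,
    s_t1: np.ndarray,
    m: int,
    rng: np.random.Generator,
    trim_dist: float,
) -> SimilarityTransform:
    """Fit frame-to-frame transform and validate it on the full clouds.

    The trimmed fit can occasionally lock onto a self-consistent but wrong
    set of mismatched pairs; the candidate transforms (identity, median
    translation of the coupled pairs, trimmed similarity) are therefore
    scored by the mean nearest-neighbour distance of the fully transformed
    cloud to the target cloud — the very quantity the registration is meant
    to minimise — and the best one wins.
    """
    a, b = couple_subsets(s_t, s_t1, m, rng)
    median_shift = np.median(b - a, axis=0)
    candidates = [
        SimilarityTransform.identity(),
        SimilarityTransform.from_parts(np.eye(3), 1.0, median_shift),
        fit_similarity_robust(a, b, trim_dist=trim_dist),
        fit_similarity_robust(a, b, trim_dist=trim_dist, start_translation=median_shift),
    ]
    tree = cKDTree(s_t1)
    scores = [float(tree.query(c.apply(s_t), k=1)[0].mean()) for c in candidates]
    return candidates[int(np.argmin(scores))]


def build_chain(
    clouds: list[DetectionCloud],
    m: int = 100,
    rng: np.random.Generator | int = 0,
    trim_dist: float = 3.0,
) -> TransformChain:
    """Chain pairwise similarity transforms onto the mid-sequence frame.

    Frames before the reference (floor(T/2)) are registered forward
    (t -> t+1), frames after it backward (t -> t-1); compositions map every
    frame onto the reference.  Frames without detections are bridged by
    interpolating the composed transforms of their neighbours.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    T = len(clouds)
    if T < 1:
        raise ValueError("need at least one frame")
    ref = T // 2
    nonempty = [t for t in range(T) if len(clouds[t]) > 0]
    if not nonempty:
        raise EmptyFrameError("no frame has any detection")

    def pair_transform(t_from: int, t_to: int) -> SimilarityTransform:
        return _best_pair_transform(
            clouds[t_from].coords_um, clouds[t_to].coords_um, m, rng, trim_dist
        )

    pairwise: dict[int, SimilarityTransform] = {}
    composed: list[SimilarityTransform | None] = [None] * T
    composed[ref] = SimilarityTransform.identity()

    # forward half: t -> t+1 -> ... -> ref
    current = SimilarityTransform.identity()
    for t in range(ref - 1, -1, -1):
        if len(clouds[t]) == 0 or len(clouds[t + 1]) == 0:
            pairwise[t] = SimilarityTransform.identity()
        else:
            try:
                pairwise[t] = pair_transform(t, t + 1)
            except EmptyFrameError as exc:
                raise EmptyFrameError(f"frame {t}: {exc}") from exc
        current = current.compose(pairwise[t]) if t == ref - 1 else composed[t + 1].compose(pairwise[t])
        composed[t] = current
    # backward half: t -> t-1 -> ... -> ref
    for t in range(ref + 1, T):
        if len(clouds[t]) == 0 or len(clouds[t - 1]) == 0:
            pairwise[t] = SimilarityTransform.identity()
        else:
            pairwise[t] = pair_transform(t, t - 1)
        composed[t] = composed[t - 1].compose(pairwise[t])

    # frames without detections inherit an interpolation of neighbour maps
    for t in range(T):
        if len(clouds[t]) == 0:
            composed[t] = _interpolate_transform(composed, nonempty, t)
    return TransformChain(reference=ref, pairwise=pairwise, composed=list(composed))


def _interpolate_transform(
    composed: list[SimilarityTransform],
    nonempty: list[int],
    t: int,
) -> SimilarityTransform:
    lo = [u for u in nonempty if u < t]
    hi = [u for u in nonempty if u > t]
    if not lo:
        return composed[hi[0]]
    if not hi:
        return composed[lo[-1]]
    a, b = lo[-1], hi[0]
    w = (t - a) / (b - a)
    # element-wise blend; motions between neighbouring frames are small
    return SimilarityTransform((1 - w) * composed[a].matrix + w * composed[b].matrix)


def _gaussian_kernel(y: np.ndarray, beta: float) -> np.ndarray:
    return np.exp(-cdist(y, y, "sqeuclidean") / (2.0 * beta**2))


def cpd_refine(
    cloud_t: np.ndarray,
    reference: np.ndarray,
    params: CPDParams = CPDParams(),
) -> np.ndarray:
    """Non-rigid Coherent Point Drift of one frame onto the reference cloud.

    The moving points are treated as Gaussian-mixture centroids drifting
    toward the reference; displacements are expanded on a Gaussian kernel of
    width ``beta`` so the field is smooth and nearby somata move coherently.
    Returns the displaced copy of ``cloud_t`` (point count unchanged).  On
    non-convergence the best iterate is returned with a warning.
    """
    y0 = np.atleast_2d(np.asarray(cloud_t, dtype=float))
    x = np.atleast_2d(np.asarray(reference, dtype=float))
    if y0.shape[0] == 0 or x.shape[0] == 0:
        raise EmptyFrameError("CPD needs non-empty point sets")
    m, n, d = y0.shape[0], x.shape[0], 3
    g = _gaussian_kernel(y0, params.beta)
    w_coef = np.zeros((m, d))
    y = y0.copy()
    sigma2 = cdist(y0, x, "sqeuclidean").sum() / (d * m * n)
    prev_q = np.inf
    converged = False
    for _ in range(params.max_iter):
        # E-step: responsibilities with uniform outlier component
        sq = cdist(y, x, "sqeuclidean")
        p = np.exp(-sq / (2.0 * sigma2))
        c = (
            (2.0 * np.pi * sigma2) ** (d / 2.0)
            * params.w
            / (1.0 - params.w)
            * m
            / n
        )
        den = p.sum(axis=0) + c
        den[den == 0] = np.finfo(float).tiny
        p /= den
        p1 = p.sum(axis=1)
        pt1 = p.sum(axis=0)
        np_total = p1.sum()
        if np_total <= 0:
            break
        # M-step: solve (diag(P1) G + lambda sigma2 I) W = P X - diag(P1) Y0
        lhs = p1[:, None] * g + params.lamb * sigma2 * np.eye(m)
        rhs = p @ x - p1[:, None] * y0
        w_coef = np.linalg.solve(lhs, rhs)
        y = y0 + g @ w_coef
        xpx = (pt1 * (x**2).sum(axis=1)).sum()
        ypy = (p1 * (y**2).sum(axis=1)).sum()
        trpxy = ((p @ x) * y).sum()
        sigma2 = max((xpx - 2 * trpxy + ypy) / (np_total * d), 1e-12)
        q = np_total * d / 2.0 * np.log(sigma2)
        if abs(prev_q - q) < params.tol * max(1.0, abs(prev_q)):
            converged = True
            break
        prev_q = q
    if not converged:
        warnings.warn("CPD did not converge; returning best iterate", RuntimeWarning)
    return y


def _mean_nn_distance(a: np.ndarray, b: np.ndarray) -> float:
    tree = cKDTree(b)
    d, _ = tree.query(a, k=1)
    return float(np.mean(d))


def register_sequence(
    clouds: list[DetectionCloud],
    m: int = 100,
    cpd_params: CPDParams = CPDParams(),
    rng: np.random.Generator | int = 0,
    trim_dist: float = 3.0,
) -> RegisteredCloud:
    """Rigid chain then CPD refinement of every frame onto the reference.

    Per frame the mean nearest-neighbour distance to the reference cloud is
    guaranteed non-increasing from the rigid to the non-rigid stage: if CPD
    worsens a frame (rare, noisy frames) its rigid positions are kept.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    T = len(clouds)
    if T == 1:
        f = RegisteredFrame(
            clouds[0].frame,
            clouds[0].coords_um.copy(),
            clouds[0].coords_um.copy(),
            clouds[0].coords_um.copy(),
            clouds[0].intensities.copy(),
        )
        chain = TransformChain(0, {}, [SimilarityTransform.identity()])
        return RegisteredCloud([f], chain)
    chain = build_chain(clouds, m=m, rng=rng, trim_dist=trim_dist)
    ref = chain.reference
    ref_rigid = chain.to_reference(ref, clouds[ref].coords_um)
    frames: list[RegisteredFrame] = []
    for t, cloud in enumerate(clouds):
        if len(cloud) == 0:
            frames.append(
                RegisteredFrame(cloud.frame, np.empty((0, 3)), np.empty((0, 3)), np.empty((0, 3)), np.empty((0,)))
            )
            continue
        rigid = chain.to_reference(t, cloud.coords_um)
        if t == ref:
            nonrigid = rigid.copy()
        else:
            nonrigid = cpd_refine(rigid, ref_rigid, cpd_params)
            if _mean_nn_distance(nonrigid, ref_rigid) > _mean_nn_distance(rigid, ref_rigid):
                logger.warning("frame %d: CPD increased NN distance; rigid kept", t)
                nonrigid = rigid.copy()
        frames.append(
            RegisteredFrame(cloud.frame, cloud.coords_um.copy(), rigid, nonrigid, cloud.intensities.copy())
        )
    return RegisteredCloud(frames, chain)
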