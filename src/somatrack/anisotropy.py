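"""Axial anisotropy correction.

The axial plane spacing of the acquisitions is ~10x the lateral pixel size.
The first step of the pipeline fills the void between consecutive planes
with cubic-spline-interpolated planes so that voxels become near-cubic,
which makes the isotropic 3D convolutions of the detection step meaningful.
This does not deconvolve the axially elongated PSF; it only equalises the
sampling.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import InsufficientPlanesError
from .io_core import AcquisitionGeometry, VolumeStack

__all__ = ["default_insert_count", "interpolate_axial"]


def default_insert_count(geometry: AcquisitionGeometry) -> int:
    """Number of planes to insert between consecutive planes for cubic voxels.

    ceil(z_step / pixel_size) - 1, so that the interpolated axial step is the
    largest step not exceeding the lateral pixel size.  For the standard
    acquisition (1.5 µm step, 0.16125 µm pixels) this is 9.
    """
    ratio = geometry.z_step / geometry.pixel_size_xy
    return max(0, math.ceil(ratio - 1e-9) - 1)


def interpolate_axial(stack: VolumeStack, n_insert: int) -> VolumeStack:
    """Insert ``n_insert`` cubic-spline planes between consecutive planes.

    Each (y, x) column is interpolated independently along z with a natural
    cubic spline.  Original planes are preserved exactly at indices
    ``k * (n_insert + 1)``; spline undershoot is clamped to zero.
    """
    if stack.data.shape[0] < 4:
        raise InsufficientPlanesError(
            f"cubic-spline interpolation needs >= 4 planes, got {stack.data.shape[0]}"
        )
    if n_insert < 0:
        raise ValueError("n_insert must be >= 0")
    n = stack.data.shape[0]
    if n_insert == 0:
        return stack
    step = n_insert + 1
    n_out = n + (n - 1) * n_insert
    knots = np.arange(n, dtype=float)
    spline = CubicSpline(knots, stack.data.astype(float), axis=0, bc_type="natural")
    fine_z = np.arange(n_out, dtype=float) / step
    out = spline(fine_z)
    np.clip(out, 0.0, None, out=out)
    out[::step] = stack.data  # knots are exact by construction
    geometry = replace(
        stack.geometry,
        n_planes=n_out,
        z_step=stack.geometry.z_step / step,
    )
    return VolumeStack(out, geometry, time_index=stack.time_index, channel=stack.channel)
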