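"""Voxel geometry: quaternion <-> affine conversion and conformance defaults.

NIfTI encodes the voxel-to-world mapping either as a quaternion plus scales
and offsets (the qform) or as a direct 3x4 matrix (the sform).  The qform
can represent only rotations (no shear); handedness is carried by the
``qfac`` sign stored in ``pixdim[0]``.  Unlocalized data (simulated data, or
data whose only localization is coil sensitivity) uses a default voxel
extent of 10 m with the transform code set to unknown.

Conventions: 0-based voxel indices, world coordinates in millimeters at
voxel centers.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from nibabel import quaternions as nq

from .errors import NonRigidAffineError, QuaternionError

#: Default spatial extent for unlocalized data: 10 m, stored in mm.
UNLOCALIZED_EXTENT_MM = 10_000.0

#: NIfTI transform codes carried as Geometry.frame_code.
XFORM_UNKNOWN = 0
XFORM_SCANNER_ANAT = 1
XFORM_TEMPLATE = 4

_QUAT_NORM_TOL = 1e-6
_SHEAR_TOL = 1e-5


@dataclass(frozen=True)
class Geometry:
    """A 4x4 voxel-to-world affine (mm) plus its NIfTI transform code."""

    affine: np.ndarray
    frame_code: int = XFORM_UNKNOWN

    def __post_init__(self) -> None:
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        object.__setattr__(self, "affine", affine)
        if self.frame_code > 0 and abs(np.linalg.det(affine[:3, :3])) == 0.0:
            raise ValueError("singular affine with a meaningful frame code")


class QuaternionParams(NamedTuple):
    """qform parameters as stored in the NIfTI header."""

    b: float
    c: float
    d: float
    qfac: float
    pixdim: tuple[float, float, float]
    offsets: tuple[float, float, float]


def affine_from_quaternion(
    b: float,
    c: float,
    d: float,
    qfac: float,
    pixdim: tuple[float, float, float],
    offsets: tuple[float, float, float],
    frame_code: int = XFORM_SCANNER_ANAT,
) -> Geometry:
    """Build the voxel-to-world affine from stored qform parameters.

    The scalar quaternion component is reconstructed as
    ``a = sqrt(max(0, 1 - b^2 - c^2 - d^2))``; the rotation matrix follows
    the NIfTI-1 reference formula, columns are scaled by the voxel sizes and
    the third column is multiplied by ``qfac`` (+1 or -1).
    """
    norm2 = b * b + c * c + d * d
    if norm2 > 1.0 + _QUAT_NORM_TOL:
        raise QuaternionError(f"quaternion norm^2 = {norm2:.9f} exceeds 1")
    if qfac not in (-1.0, 1.0, -1, 1):
        raise QuaternionError(f"qfac must be +1 or -1, got {qfac!r}")
    a = np.sqrt(max(0.0, 1.0 - norm2))
    rotation = nq.quat2mat((a, b, c, d))
    scales = np.array([pixdim[0], pixdim[1], pixdim[2] * qfac], dtype=float)
    affine = np.eye(4)
    affine[:3, :3] = rotation * scales  # column-wise scaling
    affine[:3, 3] = offsets
    return Geometry(affine=affine, frame_code=frame_code)


def quaternion_from_affine(geometry: Geometry) -> QuaternionParams:
    """Decompose a shear-free affine into qform parameters.

    The sign of the determinant of the rotation-scale block becomes
    ``qfac``; the quaternion is returned with non-negative scalar part.
    Raises :class:`NonRigidAffineError` when the block contains shear (the
    qform cannot encode it).
    """
    affine = np.asarray(geometry.affine, dtype=float)
    rzs = affine[:3, :3]
    scales = np.linalg.norm(rzs, axis=0)
    if np.any(scales == 0):
        raise NonRigidAffineError("affine has a zero-length column")
    rotation = rzs / scales
    qfac = 1.0
    if np.linalg.det(rotation) < 0:
        qfac = -1.0
        rotation = rotation.copy()
        rotation[:, 2] *= -1
    if not np.allclose(rotation.T @ rotation, np.eye(3), atol=_SHEAR_TOL):
        raise NonRigidAffineError("affine contains shear; qform cannot encode it")
    a, b, c, d = nq.mat2quat(rotation)  # nibabel returns w >= 0
    if a < 0:  # defensive: enforce the sign convention regardless
        b, c, d = -b, -c, -d
    return QuaternionParams(
        b=float(b),
        c=float(c),
        d=float(d),
        qfac=qfac,
        pixdim=tuple(float(s) for s in scales),
        offsets=tuple(float(t) for t in affine[:3, 3]),
    )


def default_unlocalized_geometry() -> Geometry:
    """Geometry for data with no real-world position.

    Voxel extent defaults to 10 m (10000 mm per axis) and the frame code is
    0 (transform unknown); this marks a dimension as unlocalized or of
    poorly defined extent.
    """
    affine = np.diag([UNLOCALIZED_EXTENT_MM] * 3 + [1.0])
    return Geometry(affine=affine, frame_code=XFORM_UNKNOWN)


def spatial_extent_m(geometry: Geometry) -> tuple[float, float, float]:
    """Voxel extent along each axis in meters (header stores millimeters)."""
    scales = np.linalg.norm(np.asarray(geometry.affine)[:3, :3], axis=0)
    return tuple(float(s) / 1000.0 for s in scales)


def check_contiguity(
    origins: np.ndarray,
    voxel_size: tuple[float, float, float],
    rel_tol: float = 1e-3,
) -> bool:
    """True iff per-voxel origins form a dense grid at the voxel spacing.

    ``origins`` is an (M, 3) array of voxel positions on an axis-aligned
    lattice.  The placement is contiguous when, along every axis, the
    distinct coordinates are evenly spaced by exactly the voxel size (so no
    gaps between voxels or slices) and every lattice site is occupied.
    Multi-slab acquisitions with gaps fail this check and must be stored as
    separate files.
    """
    origins = np.atleast_2d(np.asarray(origins, dtype=float))
    if origins.shape[1] != 3:
        raise ValueError("origins must be an (M, 3) array")
    if origins.shape[0] == 1:
        return True
    counts = []
    for axis in range(3):
        step = float(voxel_size[axis])
        coords = np.unique(np.round(origins[:, axis] / (step * rel_tol)) * step * rel_tol)
        counts.append(len(coords))
        if len(coords) > 1:
            spacings = np.diff(np.sort(coords))
            if not np.allclose(spacings, step, rtol=rel_tol, atol=step * rel_tol):
                return False
    if int(np.prod(counts)) != origins.shape[0]:
        return False
    # every lattice site occupied exactly once
    return len({tuple(np.round(row, 6)) for row in origins}) == origins.shape[0]
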