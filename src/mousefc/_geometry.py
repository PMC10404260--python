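"""Rigid/affine transform construction and trilinear resampling.

All transforms are expressed in world (mm) coordinates and converted to
voxel space through the image affine before resampling, so anisotropic
voxels (0.25 x 0.25 x 0.5 mm here) are handled correctly.
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage


def rotation_matrix(rotations_deg) -> np.ndarray:
    """3x3 rotation from Euler angles about x, y, z (applied in that order)."""
    rx, ry, rz = np.deg2rad(np.asarray(rotations_deg, dtype=float))
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    mx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    my = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    mz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return mz @ my @ mx


def rigid_world_matrix(translations_mm, rotations_deg, center_mm=None) -> np.ndarray:
    """4x4 world-space rigid transform rotating about ``center_mm``."""
    m = np.eye(4)
    r = rotation_matrix(rotations_deg)
    t = np.asarray(translations_mm, dtype=float)
    c = np.zeros(3) if center_mm is None else np.asarray(center_mm, dtype=float)
    m[:3, :3] = r
    m[:3, 3] = t + c - r @ c
    return m


def affine_world_matrix(params12) -> np.ndarray:
    """4x4 from 12 parameters: 3 translations, 3 rotations (deg), 3 scales, 3 shears."""
    p = np.asarray(params12, dtype=float)
    t, r, s, h = p[0:3], p[3:6], p[6:9], p[9:12]
    scale = np.diag(s)
    shear = np.array([[1, h[0], h[1]], [0, 1, h[2]], [0, 0, 1]])
    m = np.eye(4)
    m[:3, :3] = rotation_matrix(r) @ scale @ shear
    m[:3, 3] = t
    return m


def resample(volume: np.ndarray, world_matrix: np.ndarray, affine: np.ndarray,
             out_affine: np.ndarray | None = None, out_shape=None,
             order: int = 1, cval: float = 0.0) -> np.ndarray:
    """Resample ``volume`` under a world-space transform (trilinear by default).

    The output grid defaults to the input grid.  A point y on the output
    grid is filled with the intensity at ``world_matrix^-1 @ y`` of the
    input, i.e. ``world_matrix`` maps input world coords to output world
    coords (a "forward" transform of the object).
    """
    if out_affine is None:
        out_affine = affine
    if out_shape is None:
        out_shape = volume.shape
    # voxel(out) -> world(out) -> world(in) -> voxel(in)
    vox_map = np.linalg.inv(affine) @ np.linalg.inv(world_matrix) @ out_affine
    return ndimage.affine_transform(
        volume, vox_map[:3, :3], offset=vox_map[:3, 3],
        output_shape=tuple(out_shape), order=order, cval=cval, mode="constant",
    )


def center_of_volume_mm(shape, affine) -> np.ndarray:
    """World coordinates of the grid center (rotation pivot for registration)."""
    c_vox = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    return (affine @ np.append(c_vox, 1.0))[:3]
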