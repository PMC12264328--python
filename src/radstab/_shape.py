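"""3-D shape descriptors of a binary mask on an anisotropic voxel grid.

Mesh-based quantities (volume, surface area) come from a marching-cubes
surface; the maximum 2-D diameters are computed from boundary voxel
centres within each slice/column/row plane, and the axis lengths from a
principal-component analysis of the physical voxel coordinates
(length = 4 * sqrt(eigenvalue), i.e. the full axis of the ellipsoid with
matching second moments).
"""

from __future__ import annotations

from typing import Dict

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import marching_cubes, mesh_surface_area

SHAPE_NAMES = (
    "MeshVolume",
    "VoxelVolume",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "Sphericity",
    "Maximum3DDiameter",
    "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow",
    "MajorAxisLength",
    "MinorAxisLength",
    "LeastAxisLength",
    "Elongation",
    "Flatness",
)


def _max_pairwise(points: np.ndarray) -> float:
    """Largest pairwise Euclidean distance; convex hull prunes large sets."""
    if len(points) < 2:
        return 0.0
    pts = np.asarray(points, dtype=float)
    if len(pts) > 400:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (coplanar/collinear): brute force below
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    v0 = verts[faces[:, 0]]
    v1 = verts[faces[:, 1]]
    v2 = verts[faces[:, 2]]
    return float(abs(np.sum(np.einsum("ij,ij->i", v0, np.cross(v1, v2)))) / 6.0)


def shape_features(mask: np.ndarray, spacing) -> Dict[str, float]:
    """All 14 shape descriptors; ``spacing`` is (x, y, z) mm for a mask
    indexed (slices=z, rows=y, cols=x)."""
    mask = np.asarray(mask).astype(bool)
    sx, sy, sz = spacing
    vox = np.array([sz, sy, sx])  # per-axis size in array order
    out: Dict[str, float] = {n: float("nan") for n in SHAPE_NAMES}
    n_vox = int(mask.sum())
    if n_vox == 0:
        return out
    out["VoxelVolume"] = n_vox * float(np.prod(vox))

    padded = np.pad(mask, 1).astype(float)
    try:
        verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=tuple(vox))
    except (ValueError, RuntimeError):
        verts = faces = None
    if verts is not None and len(faces):
        vol = _mesh_volume(verts, faces)
        area = float(mesh_surface_area(verts, faces))
        out["MeshVolume"] = vol
        out["SurfaceArea"] = area
        if vol > 0 and area > 0:
            out["SurfaceVolumeRatio"] = area / vol
            out["Sphericity"] = (36.0 * np.pi * vol**2) ** (1.0 / 3.0) / area
        out["Maximum3DDiameter"] = _max_pairwise(verts)

    boundary = mask & ~ndimage.binary_erosion(mask)
    coords = np.argwhere(boundary).astype(float) * vox  # physical (z, y, x)
    idx = np.argwhere(boundary)
    for name, plane_axis, keep in (
        ("Maximum2DDiameterSlice", 0, (1, 2)),  # in-plane (y, x), per slice
        ("Maximum2DDiameterColumn", 1, (0, 2)),  # (z, x), per row-plane
        ("Maximum2DDiameterRow", 2, (0, 1)),  # (z, y), per column-plane
    ):
        best = 0.0
        for plane in np.unique(idx[:, plane_axis]):
            pts = coords[idx[:, plane_axis] == plane][:, keep]
            best = max(best, _max_pairwise(pts))
        out[name] = best

    all_coords = np.argwhere(mask).astype(float) * vox
    if len(all_coords) > 1:
        eig = np.sort(np.linalg.eigvalsh(np.cov(all_coords.T)))[::-1]
        eig = np.clip(eig, 0.0, None)
        out["MajorAxisLength"] = 4.0 * float(np.sqrt(eig[0]))
        out["MinorAxisLength"] = 4.0 * float(np.sqrt(eig[1]))
        out["LeastAxisLength"] = 4.0 * float(np.sqrt(eig[2]))
        if eig[0] > 0:
            out["Elongation"] = float(np.sqrt(eig[1] / eig[0]))
            out["Flatness"] = float(np.sqrt(eig[2] / eig[0]))
    return out
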