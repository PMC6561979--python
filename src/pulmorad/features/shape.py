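"""Size and shape descriptors (category C1).

All lengths are in millimeters computed from voxel-center coordinates
(0-based indices scaled by spacing); features with a ``_pxl`` suffix are in
voxel units.  Conventions for degenerate masks are documented per feature.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import cdist


class EmptyMaskError(ValueError):
    pass


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Boolean array of mask voxels with at least one 6-neighbor outside."""
    struct = ndimage.generate_binary_structure(3, 1)
    eroded = ndimage.binary_erosion(mask, structure=struct, border_value=0)
    return mask & ~eroded


def _hull_points(points: np.ndarray) -> np.ndarray:
    """Convex-hull vertices, falling back to all points for degenerate sets."""
    if len(points) < 5:
        return points
    try:
        hull = ConvexHull(points)
        return points[hull.vertices]
    except QhullError:
        return points


def _max_pair(points: np.ndarray) -> tuple[float, np.ndarray]:
    """Maximum pairwise distance and its direction (unit vector)."""
    if len(points) == 1:
        return 0.0, np.array([1.0, 0.0, 0.0])
    d = cdist(points, points)
    i, j = np.unravel_index(int(np.argmax(d)), d.shape)
    vec = points[j] - points[i]
    norm = np.linalg.norm(vec)
    return float(d[i, j]), (vec / norm if norm > 0 else np.array([1.0, 0.0, 0.0]))


def _principal_axes(coords_mm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (desc) and eigenvectors (columns) of the coord covariance."""
    centered = coords_mm - coords_mm.mean(axis=0)
    cov = centered.T @ centered / len(coords_mm)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return evals[order], evecs[:, order]


def extract_size_shape(vol: np.ndarray, mask: np.ndarray,
                       spacing_mm=(1.0, 1.0, 1.0)) -> dict[str, float]:
    """Compute the C1 size/shape feature map for one volume+mask pair.

    A single-voxel mask uses the voxel-diagonal convention for diameters.
    ``rectangular_fit`` measures oriented-bounding-box extents between
    extreme voxel centers and is capped at 1.
    """
    if not mask.any():
        raise EmptyMaskError("mask has no voxels")
    spacing = np.asarray(spacing_mm, dtype=float)
    voxvol = float(np.prod(spacing))
    idx = np.argwhere(mask)
    coords = idx * spacing
    n_vox = len(idx)
    volume_mm3 = n_vox * voxvol

    surf = surface_voxels(mask)
    surf_pts = np.argwhere(surf) * spacing
    border_len = int(surf.sum())

    if n_vox == 1:
        diag = float(np.linalg.norm(spacing))
        long_d = short_ax = diag
        u = np.array([1.0, 0.0, 0.0])
    else:
        pts = _hull_points(surf_pts)
        long_d, u = _max_pair(pts)
        proj = pts - np.outer(pts @ u, u)
        short_ax, _ = _max_pair(_hull_points(proj))
        if long_d == 0:
            long_d = short_ax = float(np.linalg.norm(spacing))

    evals, evecs = _principal_axes(coords)
    proj_pc = (coords - coords.mean(axis=0)) @ evecs
    extents_mm = proj_pc.max(axis=0) - proj_pc.min(axis=0)
    mean_spacing = float(spacing.mean())
    extents_pxl = extents_mm / mean_spacing + 1.0  # cell-based voxel extents
    length_pxl, width_pxl, thickness_pxl = np.sort(extents_pxl)[::-1]

    # oriented bounding box from center extents, capped at unity
    obb_extents = np.maximum(extents_mm, mean_spacing * 1e-9)
    obb_vol = float(np.prod(np.where(obb_extents > 0, obb_extents, mean_spacing)))
    rectangular_fit = min(1.0, volume_mm3 / obb_vol) if obb_vol > 0 else 1.0

    sphere_vol = np.pi / 6.0 * long_d**3
    density = volume_mm3 / sphere_vol if sphere_vol > 0 else 1.0

    elliptic_fit = _elliptic_fit(mask, coords, evals, evecs, spacing)

    return {
        "volume_mm3": float(volume_mm3),
        "volume_pxl": float(n_vox),
        "longest_diameter_mm": float(long_d),
        "short_axis_mm": float(short_ax),
        "shortax_longdia": float(short_ax * long_d),
        "length_pxl": float(length_pxl),
        "thickness_pxl": float(thickness_pxl),
        "length_by_width": float(length_pxl / width_pxl) if width_pxl > 0 else 1.0,
        "border_length_pxl": float(border_len),
        "density": float(density),
        "elliptic_fit": float(elliptic_fit),
        "rectangular_fit": float(rectangular_fit),
    }


def _elliptic_fit(mask: np.ndarray, coords: np.ndarray, evals: np.ndarray,
                  evecs: np.ndarray, spacing: np.ndarray) -> float:
    """Jaccard overlap between the mask and its moment-matched ellipsoid.

    The ellipsoid shares the mask's centroid and principal axes with
    semi-axes sqrt(5 * eigenvalue), the uniform-ellipsoid moment relation.
    """
    center = coords.mean(axis=0)
    semi = np.sqrt(np.maximum(evals, 1e-12) * 5.0)
    lo = np.maximum(np.floor((center - semi.max()) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((center + semi.max()) / spacing).astype(int) + 1,
                    np.asarray(mask.shape))
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    grids = np.meshgrid(*[np.arange(a, b) * s for (a, b), s in
                          zip(zip(lo, hi), spacing)], indexing="ij")
    rel = np.stack([g - c for g, c in zip(grids, center)])
    body = np.einsum("ij,jxyz->ixyz", evecs.T, rel)
    inside = ((body / semi[:, None, None, None]) ** 2).sum(axis=0) <= 1.0
    sub = mask[sl]
    inter = float(np.logical_and(sub, inside).sum())
    union = float(sub.sum() + inside.sum() - inter)
    # voxels of the mask outside the crop window belong to the union only
    union += float(mask.sum() - sub.sum())
    return inter / union if union > 0 else 1.0
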