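"""Histogram and location descriptors (category C2).

Histogram features summarize the within-mask HU distribution; location
features describe the nodule's relation to the surrounding lung and its
internal airspace content.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, stats

from .shape import EmptyMaskError, surface_voxels

#: HU below which surrounding tissue is considered aerated lung
LUNG_HU = -500.0
#: HU below which a mask voxel counts as airspace
AIRSPACE_HU = -910.0


def extract_histogram(vol: np.ndarray, mask: np.ndarray,
                      n_bins: int = 32) -> dict[str, float]:
    """First-order statistics of the within-mask HU distribution.

    ``hist_energy`` is sum(p^2) and ``hist_entropy`` is -sum(p log2 p) over
    an ``n_bins`` histogram spanning the observed HU range.  A constant
    region has SD 0, energy 1 and entropy 0; skewness/kurtosis are 0 by
    convention there.
    """
    if not mask.any():
        raise EmptyMaskError("mask has no voxels")
    x = np.asarray(vol, dtype=float)[mask]
    sd = float(x.std())
    if sd > 0:
        skew = float(stats.skew(x))
        kurt = float(stats.kurtosis(x))
        counts, _ = np.histogram(x, bins=n_bins, range=(x.min(), x.max()))
    else:
        skew = kurt = 0.0
        counts = np.array([x.size])
    p = counts[counts > 0] / x.size
    return {
        "mean_hu": float(x.mean()),
        "sd_hu": sd,
        "skewness": skew,
        "kurtosis": kurt,
        "hist_energy": float(np.sum(p**2)),
        "hist_entropy": float(-np.sum(p * np.log2(p))),
    }


def extract_location(vol: np.ndarray, mask: np.ndarray,
                     spacing_mm=(1.0, 1.0, 1.0),
                     lung_hu: float = LUNG_HU,
                     airspace_hu: float = AIRSPACE_HU) -> dict[str, float]:
    """Location and airspace descriptors.

    - ``border_to_lung``: fraction of surface voxels with at least one
      outside 6-neighbor below ``lung_hu`` (isolated nodule in parenchyma
      scores 1).
    - ``relative_vol_airspaces``: fraction of mask voxels below
      ``airspace_hu``.
    - ``avg/sd_vol_airspaces``: mean/SD of 26-connected airspace component
      volumes in mm^3 (0 when there is no airspace).
    - ``min_dist_cog_to_border``: distance (mm) from the mask centroid to
      the nearest surface voxel center.
    - ``main_direction``: angle in degrees between the longest principal
      axis and the axial (first-two-axes) plane, in [0, 90].
    """
    if not mask.any():
        raise EmptyMaskError("mask has no voxels")
    spacing = np.asarray(spacing_mm, dtype=float)
    voxvol = float(np.prod(spacing))
    hu = np.asarray(vol, dtype=float)

    surf = surface_voxels(mask)
    surf_idx = np.argwhere(surf)
    lung_like = (hu < lung_hu) & ~mask
    struct6 = ndimage.generate_binary_structure(3, 1)
    near_lung = ndimage.binary_dilation(lung_like, structure=struct6)
    lungish = int((surf & near_lung).sum())
    border_to_lung = lungish / len(surf_idx) if len(surf_idx) else 0.0

    air = mask & (hu < airspace_hu)
    rel_air = float(air.sum()) / float(mask.sum())
    if air.any():
        struct = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
        lbl, n_comp = ndimage.label(air, structure=struct)
        sizes = np.bincount(lbl.ravel())[1:] * voxvol
        avg_air = float(sizes.mean())
        sd_air = float(sizes.std())
    else:
        avg_air = sd_air = 0.0

    coords = np.argwhere(mask) * spacing
    cog = coords.mean(axis=0)
    surf_mm = surf_idx * spacing
    min_dist = float(np.min(np.linalg.norm(surf_mm - cog, axis=1)))

    centered = coords - cog
    cov = centered.T @ centered / len(coords)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, int(np.argmax(evals))]
    norm = np.linalg.norm(axis)
    main_dir = float(np.degrees(np.arcsin(abs(axis[2]) / norm))) if norm > 0 else 0.0

    return {
        "border_to_lung": float(border_to_lung),
        "relative_vol_airspaces": rel_air,
        "avg_vol_airspaces": avg_air,
        "sd_vol_airspaces": sd_air,
        "min_dist_cog_to_border": min_dist,
        "main_direction": main_dir,
    }
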