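"""Radiomic feature extraction: a category-tagged open panel.

The panel covers three broad descriptor categories used in pulmonary-nodule
radiomics:

- **C1** — size and shape (volume, diameters, fits);
- **C2** — regional texture and location (HU histogram, gray-level
  co-occurrence, run lengths, airspace/border descriptors);
- **C3** — fine texture in transformed domains (3D Laws filter bank,
  wavelet sub-band statistics).

Texture families are computed on a 1 mm isotropic resampling of the
volume (trilinear; nearest-neighbor for the mask) restricted to the
nodule's bounding box; size features use the native grid in mm.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .shape import EmptyMaskError, extract_size_shape
from .intensity import extract_histogram, extract_location
from .texture import (DIRECTIONS_3D, MaskTooSmallError, extract_cooccurrence,
                      extract_runlength, glcm_matrix, glrlm_matrix, quantize)
from .energy import (extract_laws, extract_wavelet, laws_kernel_factors,
                     laws_kernel_names, LAWS_1D, LAWS_ORDER, WAVELET_SUBBANDS)

__all__ = [
    "EmptyMaskError", "MaskTooSmallError", "ExtractionSettings",
    "FeatureDescriptor", "extract_all", "extract_cohort", "extract_size_shape",
    "extract_histogram", "extract_location", "extract_cooccurrence",
    "extract_runlength", "extract_laws", "extract_wavelet", "panel_descriptors",
    "descriptor_frame", "DIRECTIONS_3D", "glcm_matrix", "glrlm_matrix",
    "quantize", "laws_kernel_factors", "laws_kernel_names", "LAWS_1D",
    "LAWS_ORDER", "WAVELET_SUBBANDS",
]

_FAMILY_CATEGORY = {
    "size": "C1", "shape": "C1",
    "histogram": "C2", "cooccurrence": "C2", "runlength": "C2", "location": "C2",
    "laws": "C3", "wavelet": "C3",
}


@dataclass(frozen=True)
class FeatureDescriptor:
    """Name, category (C1/C2/C3) and family of one panel feature."""

    name: str
    category: str
    family: str

    def __post_init__(self) -> None:
        if _FAMILY_CATEGORY.get(self.family) != self.category:
            raise ValueError(
                f"family {self.family!r} is inconsistent with {self.category!r}")


@dataclass(frozen=True)
class ExtractionSettings:
    """Panel-wide extraction settings (fixed per cohort).

    ``hu_clip`` bounds HU before texture extraction to suppress
    calcification outliers; ``resample_iso_mm`` is the isotropic texture
    grid; ``bbox_margin`` voxels of context are kept around the nodule.
    """

    n_bins: int = 32
    n_levels: int = 32
    glcm_distance: int = 1
    hu_clip: tuple[float, float] = (-1024.0, 400.0)
    laws_erosion: int = 2
    wavelet: str = "db4"
    wavelet_levels: int = 2
    lung_hu: float = -500.0
    airspace_hu: float = -910.0
    resample_iso_mm: float = 1.0
    bbox_margin: int = 6

    def settings_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=list)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


_SIZE_FEATURES = ("volume_mm3", "volume_pxl", "longest_diameter_mm",
                  "short_axis_mm", "shortax_longdia", "length_pxl",
                  "thickness_pxl", "length_by_width", "border_length_pxl")
_SHAPE_FEATURES = ("density", "elliptic_fit", "rectangular_fit")
_HIST_FEATURES = ("mean_hu", "sd_hu", "skewness", "kurtosis", "hist_energy",
                  "hist_entropy")
_COOC_FEATURES = ("avg_cooc_homogeneity", "avg_cooc_contrast",
                  "avg_cooc_energy", "avg_cooc_entropy",
                  "avg_cooc_correlation")
_RUN_FEATURES = ("avg_SRE", "avg_LRE", "avg_GLN", "avg_RLN", "avg_RP")
_LOC_FEATURES = ("border_to_lung", "relative_vol_airspaces",
                 "avg_vol_airspaces", "sd_vol_airspaces",
                 "min_dist_cog_to_border", "main_direction")


def panel_descriptors(settings: ExtractionSettings | None = None
                      ) -> list[FeatureDescriptor]:
    """Descriptors of the full panel, in output column order."""
    settings = settings or ExtractionSettings()
    out = [FeatureDescriptor(n, "C1", "size") for n in _SIZE_FEATURES]
    out += [FeatureDescriptor(n, "C1", "shape") for n in _SHAPE_FEATURES]
    out += [FeatureDescriptor(n, "C2", "histogram") for n in _HIST_FEATURES]
    out += [FeatureDescriptor(n, "C2", "cooccurrence") for n in _COOC_FEATURES]
    out += [FeatureDescriptor(n, "C2", "runlength") for n in _RUN_FEATURES]
    out += [FeatureDescriptor(n, "C2", "location") for n in _LOC_FEATURES]
    out += [FeatureDescriptor(n, "C3", "laws") for n in laws_kernel_names()]
    for level in range(1, settings.wavelet_levels + 1):
        for key in WAVELET_SUBBANDS:
            out.append(FeatureDescriptor(f"wave_P1_L{level}_{key}", "C3",
                                         "wavelet"))
            out.append(FeatureDescriptor(f"wave_P2_L{level}_{key}", "C3",
                                         "wavelet"))
    return out


def descriptor_frame(settings: ExtractionSettings | None = None) -> pd.DataFrame:
    """Panel descriptors as a DataFrame indexed by feature name."""
    descs = panel_descriptors(settings)
    return pd.DataFrame({"category": [d.category for d in descs],
                         "family": [d.family for d in descs]},
                        index=[d.name for d in descs])


def _resample_iso(vol: np.ndarray, mask: np.ndarray, spacing: np.ndarray,
                  iso: float) -> tuple[np.ndarray, np.ndarray]:
    if np.allclose(spacing, iso):
        return vol, mask
    zoom = spacing / iso
    v = ndimage.zoom(np.asarray(vol, float), zoom, order=1)
    m = ndimage.zoom(mask.astype(np.uint8), zoom, order=0).astype(bool)
    if not m.any():  # nearest-neighbor can drop a tiny mask entirely
        m = ndimage.zoom(mask.astype(float), zoom, order=1) >= 0.5
    return v, m


def _crop_bbox(vol: np.ndarray, mask: np.ndarray, margin: int
               ) -> tuple[np.ndarray, np.ndarray]:
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, np.asarray(mask.shape))
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return vol[sl], mask[sl]


def extract_all(vol: np.ndarray, mask: np.ndarray,
                spacing_mm=(1.0, 1.0, 1.0),
                settings: ExtractionSettings | None = None) -> dict[str, float]:
    """Extract the full feature panel for one volume+mask pair.

    Returns an ordered feature-name -> value map matching
    :func:`panel_descriptors`.  Size/shape features are computed on the
    native grid; texture families on the clipped, isotropically resampled
    bounding-box crop.
    """
    settings = settings or ExtractionSettings()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("mask has no voxels")
    spacing = np.asarray(spacing_mm, dtype=float)

    row: dict[str, float] = {}
    row.update(extract_size_shape(vol, mask, spacing))

    v_iso, m_iso = _resample_iso(vol, mask, spacing, settings.resample_iso_mm)
    v_iso, m_iso = _crop_bbox(v_iso, m_iso, settings.bbox_margin)
    v_tex = np.clip(v_iso, *settings.hu_clip)

    row.update(extract_histogram(v_tex, m_iso, settings.n_bins))
    if m_iso.sum() >= 2:
        row.update(extract_cooccurrence(v_tex, m_iso, settings.n_levels,
                                        settings.glcm_distance))
    else:  # degenerate single-voxel nodule: no pair exists
        row.update({k: 0.0 for k in _COOC_FEATURES})
        row["avg_cooc_homogeneity"] = 1.0
        row["avg_cooc_energy"] = 1.0
        row["avg_cooc_correlation"] = 1.0
    row.update(extract_runlength(v_tex, m_iso, settings.n_levels))
    row.update(extract_location(v_tex, m_iso,
                                (settings.resample_iso_mm,) * 3,
                                settings.lung_hu, settings.airspace_hu))
    row.update(extract_laws(v_tex, m_iso, settings.laws_erosion))
    row.update(extract_wavelet(v_tex, m_iso, settings.wavelet_levels,
                               settings.wavelet))

    ordered = {d.name: row[d.name] for d in panel_descriptors(settings)}
    bad = [k for k, v in ordered.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite feature values: {bad}")
    return ordered


def extract_cohort(volumes, settings: ExtractionSettings | None = None,
                   subject_ids=None) -> pd.DataFrame:
    """Feature table (subjects x features) for a sequence of volumes.

    ``volumes`` yields SyntheticVolume-like objects with ``hu_grid``,
    ``mask`` and ``spacing_mm`` attributes.
    """
    settings = settings or ExtractionSettings()
    rows, ids = [], []
    for i, vol in enumerate(volumes):
        rows.append(extract_all(vol.hu_grid, vol.mask, vol.spacing_mm, settings))
        ids.append(subject_ids[i] if subject_ids is not None else f"S{i:04d}")
    table = pd.DataFrame(rows, index=ids)
    table.attrs["settings_hash"] = settings.settings_hash()
    return table
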