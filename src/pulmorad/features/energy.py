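"""Laws texture-energy and wavelet sub-band descriptors (category C3).

These families probe fine-scale intra-nodular texture in transformed
domains: separable 3D Laws filter banks (125 kernels from the five 1D
level/edge/spot/ripple/wave filters) and a 2-level separable Daubechies-4
wavelet decomposition.
"""

from __future__ import annotations

import logging

import numpy as np
import pywt
from scipy import ndimage

from .shape import EmptyMaskError

log = logging.getLogger(__name__)

#: the five 1D Laws filters, L1-normalized
LAWS_1D = {
    "L5": np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0,
    "E5": np.array([-1.0, -2.0, 0.0, 2.0, 1.0]) / 6.0,
    "S5": np.array([-1.0, 0.0, 2.0, 0.0, -1.0]) / 4.0,
    "R5": np.array([1.0, -4.0, 6.0, -4.0, 1.0]) / 16.0,
    "W5": np.array([-1.0, 2.0, 0.0, -2.0, 1.0]) / 6.0,
}
LAWS_ORDER = ("L5", "E5", "S5", "R5", "W5")

#: detail sub-band keys of a separable 3D DWT, sorted
WAVELET_SUBBANDS = ("aad", "ada", "add", "daa", "dad", "dda", "ddd")


def laws_kernel_names() -> list[str]:
    """Names laws_001..laws_125 in lexicographic (axis0, axis1, axis2) order."""
    return [f"laws_{i + 1:03d}" for i in range(125)]


def laws_kernel_factors(index: int) -> tuple[str, str, str]:
    """1D factor names (axis 0, 1, 2) of kernel ``laws_<index+1>``."""
    i, rem = divmod(index, 25)
    j, k = divmod(rem, 5)
    return LAWS_ORDER[i], LAWS_ORDER[j], LAWS_ORDER[k]


def extract_laws(vol: np.ndarray, mask: np.ndarray,
                 erosion: int = 2) -> dict[str, float]:
    """Mean absolute response of each of the 125 3D Laws kernels in the mask.

    The mask is eroded by ``erosion`` voxels (6-connectivity) to avoid
    boundary effects, falling back to the full mask if erosion empties it.
    Separable filtering uses reflect boundary handling, so every kernel
    with a zero-sum factor responds 0 on constant input.
    """
    if not mask.any():
        raise EmptyMaskError("mask has no voxels")
    core = mask
    if erosion > 0:
        struct = ndimage.generate_binary_structure(3, 1)
        eroded = ndimage.binary_erosion(mask, structure=struct,
                                        iterations=erosion, border_value=0)
        if eroded.any():
            core = eroded
    v = np.asarray(vol, dtype=float)
    # factorized cascade: 5 responses along axis 0, 25 along 0+1, 125 full
    stage0 = {n: ndimage.correlate1d(v, k, axis=0, mode="reflect")
              for n, k in LAWS_1D.items()}
    out: dict[str, float] = {}
    idx = 0
    for n0 in LAWS_ORDER:
        for n1 in LAWS_ORDER:
            stage1 = ndimage.correlate1d(stage0[n0], LAWS_1D[n1], axis=1,
                                         mode="reflect")
            for n2 in LAWS_ORDER:
                resp = ndimage.correlate1d(stage1, LAWS_1D[n2], axis=2,
                                           mode="reflect")
                idx += 1
                out[f"laws_{idx:03d}"] = float(np.mean(np.abs(resp[core])))
    return out


def _downsample_mask(mask: np.ndarray, times: int) -> np.ndarray:
    """Any-pooling of the mask by factors of 2 (sub-band footprint)."""
    m = mask
    for _ in range(times):
        shape = tuple(-(-s // 2) * 2 for s in m.shape)
        padded = np.zeros(shape, dtype=bool)
        padded[tuple(slice(0, s) for s in m.shape)] = m
        m = padded.reshape(shape[0] // 2, 2, shape[1] // 2, 2,
                           shape[2] // 2, 2).any(axis=(1, 3, 5))
    return m


def extract_wavelet(vol: np.ndarray, mask: np.ndarray, levels: int = 2,
                    wavelet: str = "db4") -> dict[str, float]:
    """Within-mask statistics of 3D wavelet detail coefficients.

    A separable orthogonal decomposition (``db4`` by default, periodized)
    is taken to ``levels`` levels; for each of the 7 detail sub-bands per
    level, P1 = mean absolute coefficient and P2 = sum of squared
    coefficients over the mask's sub-band footprint.  If the footprint is
    empty at some level (tiny nodule) the affected features are 0 and a
    warning is logged.
    """
    if not mask.any():
        raise EmptyMaskError("mask has no voxels")
    v = np.asarray(vol, dtype=float)
    import warnings
    with warnings.catch_warnings():
        # small crops trigger a benign boundary-effect warning
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedecn(v, wavelet=wavelet, mode="periodization",
                               level=levels)
    out: dict[str, float] = {}
    # coeffs[0] is the final approximation; coeffs[1] is the deepest level
    for depth, detail in enumerate(coeffs[1:], start=1):
        level = levels - depth + 1  # pywt lists deepest level first
        fp = _downsample_mask(mask, level)
        for key in WAVELET_SUBBANDS:
            c = detail[key]
            foot = fp[tuple(slice(0, s) for s in c.shape)]
            if foot.any():
                sel = c[foot]
                p1 = float(np.mean(np.abs(sel)))
                p2 = float(np.sum(sel**2))
            else:
                log.warning("empty wavelet footprint at level %d; emitting 0",
                            level)
                p1 = p2 = 0.0
            out[f"wave_P1_L{level}_{key}"] = p1
            out[f"wave_P2_L{level}_{key}"] = p2
    return out
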