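"""Gray-level co-occurrence and run-length descriptors (category C2).

Both families quantize the within-mask HU range to ``n_levels`` gray levels
and aggregate over the 13 unique 3D direction offsets at unit voxel
distance, averaging the per-direction feature values (the ``avg_`` prefix).
Only voxel pairs/runs lying entirely inside the mask contribute.
"""

from __future__ import annotations

import numpy as np

from .shape import EmptyMaskError

#: the 13 unique direction offsets of the 26-neighborhood (antipodes merged)
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)


class MaskTooSmallError(ValueError):
    pass


def quantize(vol: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Quantize within-mask HU to integer levels 0..n_levels-1 (-1 outside)."""
    q = np.full(vol.shape, -1, dtype=np.int32)
    x = np.asarray(vol, dtype=float)[mask]
    mn, mx = float(x.min()), float(x.max())
    if mx > mn:
        lv = np.floor((x - mn) / (mx - mn) * n_levels).astype(np.int32)
        np.clip(lv, 0, n_levels - 1, out=lv)
    else:
        lv = np.zeros(x.size, dtype=np.int32)
    q[mask] = lv
    return q


def _pair_slices(shape, d):
    sl1, sl2 = [], []
    for n, step in zip(shape, d):
        if step >= 0:
            sl1.append(slice(0, n - step))
            sl2.append(slice(step, n))
        else:
            sl1.append(slice(-step, n))
            sl2.append(slice(0, n + step))
    return tuple(sl1), tuple(sl2)


def glcm_matrix(q: np.ndarray, n_levels: int, direction, distance: int = 1
                ) -> np.ndarray:
    """Symmetric normalized GLCM for one direction offset.

    Returns an ``n_levels`` x ``n_levels`` matrix summing to 1, or a zero
    matrix when the direction admits no in-mask pair.
    """
    d = tuple(distance * c for c in direction)
    sl1, sl2 = _pair_slices(q.shape, d)
    a, b = q[sl1], q[sl2]
    ok = (a >= 0) & (b >= 0)
    if not ok.any():
        return np.zeros((n_levels, n_levels))
    av, bv = a[ok].astype(np.int64), b[ok].astype(np.int64)
    counts = np.bincount(av * n_levels + bv, minlength=n_levels * n_levels)
    m = counts.reshape(n_levels, n_levels).astype(float)
    m = m + m.T  # symmetric accumulation
    return m / m.sum()


def _glcm_features(p: np.ndarray) -> dict[str, float]:
    n = p.shape[0]
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    diff = np.abs(i - j)
    homogeneity = float(np.sum(p / (1.0 + diff)))
    contrast = float(np.sum((i - j) ** 2 * p))
    energy = float(np.sum(p**2))
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    pi = p.sum(axis=1)
    mu_i = float(np.sum(np.arange(n) * pi))
    var_i = float(np.sum((np.arange(n) - mu_i) ** 2 * pi))
    if var_i > 0:
        corr = float(np.sum((i - mu_i) * (j - mu_i) * p) / var_i)
    else:
        corr = 1.0  # degenerate single-level matrix: perfectly concordant
    return {"avg_cooc_homogeneity": homogeneity, "avg_cooc_contrast": contrast,
            "avg_cooc_energy": energy, "avg_cooc_entropy": entropy,
            "avg_cooc_correlation": corr}


def extract_cooccurrence(vol: np.ndarray, mask: np.ndarray, n_levels: int = 32,
                         distance: int = 1,
                         directions=DIRECTIONS_3D) -> dict[str, float]:
    """Direction-averaged Haralick features from in-mask GLCMs."""
    if mask.sum() < 2:
        raise MaskTooSmallError("need at least 2 mask voxels for co-occurrence")
    q = quantize(vol, mask, n_levels)
    acc: list[dict[str, float]] = []
    for d in directions:
        m = glcm_matrix(q, n_levels, d, distance)
        if m.sum() > 0:
            acc.append(_glcm_features(m))
    if not acc:
        raise MaskTooSmallError("no in-mask voxel pair in any direction")
    return {k: float(np.mean([f[k] for f in acc])) for k in acc[0]}


# ---------------------------------------------------------------------------
# run lengths


def _shift2d(arr: np.ndarray, s1: int, s2: int, fill) -> np.ndarray:
    """out[y, x] = arr[y - s1, x - s2], out-of-bounds filled."""
    out = np.full_like(arr, fill)
    n1, n2 = arr.shape
    src1 = slice(max(0, -s1), min(n1, n1 - s1))
    dst1 = slice(max(0, s1), min(n1, n1 + s1))
    src2 = slice(max(0, -s2), min(n2, n2 - s2))
    dst2 = slice(max(0, s2), min(n2, n2 + s2))
    out[dst1, dst2] = arr[src1, src2]
    return out


def glrlm_matrix(q: np.ndarray, n_levels: int, direction) -> np.ndarray:
    """Gray-level run-length matrix R[level, length-1] for one direction.

    Runs are maximal collinear sequences of equal quantized level lying
    inside the mask; voxels outside the mask break runs.
    """
    d = np.asarray(direction)
    primary = int(np.flatnonzero(d)[0])
    if d[primary] < 0:
        d = -d
    # permute so the primary axis is axis 0
    order = [primary] + [ax for ax in range(3) if ax != primary]
    qp = np.transpose(q, order)
    e1, e2 = int(d[order[1]]), int(d[order[2]])

    n0 = qp.shape[0]
    maxlen = sum(qp.shape)
    valid = qp >= 0
    lengths = np.zeros(qp.shape, dtype=np.int32)
    ends = np.zeros(qp.shape, dtype=bool)

    lengths[0] = valid[0].astype(np.int32)
    for i in range(1, n0):
        prev_len = _shift2d(lengths[i - 1], e1, e2, 0)
        prev_q = _shift2d(qp[i - 1], e1, e2, -2)
        cont = valid[i] & (prev_q == qp[i])
        lengths[i] = np.where(cont, prev_len + 1, valid[i].astype(np.int32))
    for i in range(n0):
        if i + 1 < n0:
            nxt_q = _shift2d(qp[i + 1], -e1, -e2, -2)
        else:
            nxt_q = np.full(qp[i].shape, -2, dtype=qp.dtype)
        ends[i] = valid[i] & (nxt_q != qp[i])

    lv = qp[ends].astype(np.int64)
    ln = lengths[ends].astype(np.int64)
    counts = np.bincount(lv * maxlen + (ln - 1), minlength=n_levels * maxlen)
    return counts.reshape(n_levels, maxlen).astype(float)


def _glrlm_features(r: np.ndarray, n_voxels: int) -> dict[str, float]:
    nr = r.sum()
    lengths = np.arange(1, r.shape[1] + 1, dtype=float)
    row = r.sum(axis=1)
    col = r.sum(axis=0)
    return {
        "avg_SRE": float(np.sum(col / lengths**2) / nr),
        "avg_LRE": float(np.sum(col * lengths**2) / nr),
        "avg_GLN": float(np.sum(row**2) / nr),
        "avg_RLN": float(np.sum(col**2) / nr),
        "avg_RP": float(nr / n_voxels),
    }


def extract_runlength(vol: np.ndarray, mask: np.ndarray, n_levels: int = 32,
                      directions=DIRECTIONS_3D) -> dict[str, float]:
    """Direction-averaged run-length features from in-mask GLRLMs."""
    if not mask.any():
        raise EmptyMaskError("mask has no voxels")
    q = quantize(vol, mask, n_levels)
    n_vox = int(mask.sum())
    acc = []
    for d in directions:
        r = glrlm_matrix(q, n_levels, d)
        if r.sum() > 0:
            acc.append(_glrlm_features(r, n_vox))
    return {k: float(np.mean([f[k] for f in acc])) for k in acc[0]}
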