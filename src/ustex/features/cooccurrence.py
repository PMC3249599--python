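"""Gray-level and edge co-occurrence matrices with the Haralick feature set.

Co-occurrence is counted symmetrically (both displacement directions) over
pixel pairs that lie entirely inside the patch, then normalized to sum 1.
Angles follow the classic convention measured counter-clockwise from the
positive column axis with rows growing downward:

====== ===================
angle  unit offset (dr, dc)
====== ===================
0      (0, 1)
45     (-1, 1)
90     (-1, 0)
135    (-1, -1)
====== ===================
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .firstorder import quantize

_EPS = 1e-12

_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

ECM_LEVELS = 16


def glcm_matrix(
    patch_q: np.ndarray, distance: int, angle: int, levels: int = 32
) -> np.ndarray:
    """Normalized symmetric co-occurrence matrix of a quantized patch.

    ``distance`` scales the unit offset of ``angle`` (diagonal displacements
    move ``distance`` pixels along each axis).
    """
    if angle not in _ANGLE_OFFSETS:
        raise ValueError(f"angle must be one of {sorted(_ANGLE_OFFSETS)}")
    q = np.asarray(patch_q, dtype=np.int64)
    if q.min() < 0 or q.max() >= levels:
        raise ValueError("quantized patch values must lie in [0, levels)")
    dr, dc = _ANGLE_OFFSETS[angle]
    dr *= distance
    dc *= distance
    h, w = q.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = q[r0:r1, c0:c1]
    b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    counts = np.bincount(
        (a * levels + b).ravel(), minlength=levels * levels
    ).reshape(levels, levels)
    mat = (counts + counts.T).astype(np.float64)
    total = mat.sum()
    if total > 0:
        mat /= total
    return mat


def haralick_features(glcm: np.ndarray) -> np.ndarray:
    """The 13 classic Haralick features of a normalized co-occurrence matrix.

    Order: ASM, contrast, correlation, sum-of-squares variance, inverse
    difference moment, sum average, sum variance, sum entropy, entropy,
    difference variance, difference entropy, IMC1, IMC2.  Logarithms are
    base 2.  Degenerate conventions: zero marginal variance gives
    correlation 0; undefined information measures give 0.
    """
    P = np.asarray(glcm, dtype=np.float64)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("co-occurrence matrix must be square")
    if abs(P.sum() - 1.0) > 1e-6:
        raise ValueError("co-occurrence matrix must be normalized to sum 1")
    G = P.shape[0]
    lv = np.arange(G, dtype=np.float64)
    i = lv[:, None]
    j = lv[None, :]

    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float(np.sum(lv * px))
    mu_y = float(np.sum(lv * py))
    sig_x = float(np.sqrt(np.sum((lv - mu_x) ** 2 * px)))
    sig_y = float(np.sqrt(np.sum((lv - mu_y) ** 2 * py)))

    asm = float(np.sum(P * P))
    contrast = float(np.sum((i - j) ** 2 * P))
    if sig_x > _EPS and sig_y > _EPS:
        correlation = float((np.sum(i * j * P) - mu_x * mu_y) / (sig_x * sig_y))
    else:
        correlation = 0.0
    variance = float(np.sum((i - mu_x) ** 2 * P))
    idm = float(np.sum(P / (1.0 + (i - j) ** 2)))

    # marginal distributions of i+j and |i-j|
    sum_idx = (np.arange(G)[:, None] + np.arange(G)[None, :]).ravel()
    p_sum = np.bincount(sum_idx, weights=P.ravel(), minlength=2 * G - 1)
    k_sum = np.arange(2 * G - 1, dtype=np.float64)
    sum_average = float(np.sum(k_sum * p_sum))
    sum_variance = float(np.sum((k_sum - sum_average) ** 2 * p_sum))
    nz = p_sum[p_sum > 0]
    sum_entropy = float(-np.sum(nz * np.log2(nz)))

    diff_idx = np.abs(np.arange(G)[:, None] - np.arange(G)[None, :]).ravel()
    p_diff = np.bincount(diff_idx, weights=P.ravel(), minlength=G)
    k_diff = np.arange(G, dtype=np.float64)
    diff_average = float(np.sum(k_diff * p_diff))
    difference_variance = float(np.sum((k_diff - diff_average) ** 2 * p_diff))
    nz = p_diff[p_diff > 0]
    difference_entropy = float(-np.sum(nz * np.log2(nz)))

    nz = P[P > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    nzx = px[px > 0]
    hx = float(-np.sum(nzx * np.log2(nzx)))
    nzy = py[py > 0]
    hy = float(-np.sum(nzy * np.log2(nzy)))
    pxy = px[:, None] * py[None, :]
    mask = (P > 0) & (pxy > 0)
    hxy1 = float(-np.sum(P[mask] * np.log2(pxy[mask])))
    mask2 = pxy > 0
    hxy2 = float(-np.sum(pxy[mask2] * np.log2(pxy[mask2])))
    denom = max(hx, hy)
    imc1 = float((entropy - hxy1) / denom) if denom > _EPS else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    return np.array(
        [
            asm,
            contrast,
            correlation,
            variance,
            idm,
            sum_average,
            sum_variance,
            sum_entropy,
            entropy,
            difference_variance,
            difference_entropy,
            imc1,
            imc2,
        ]
    )


def sobel_magnitude(patch: np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude (reflect padding)."""
    g = np.asarray(patch, dtype=np.float64)
    gx = ndimage.sobel(g, axis=1, mode="reflect")
    gy = ndimage.sobel(g, axis=0, mode="reflect")
    return np.hypot(gx, gy)


def ecm_features(patch: np.ndarray, levels: int = ECM_LEVELS) -> np.ndarray:
    """Haralick features of the edge (gradient-magnitude) co-occurrence matrix.

    The Sobel magnitude is quantized to ``levels`` bins over
    ``[0, observed max]``; co-occurrence is taken at distance 1 averaged over
    the four angles.  A zero-gradient patch yields a single-cell matrix, on
    which the Haralick degenerate conventions apply.
    """
    mag = sobel_magnitude(patch)
    mmax = mag.max()
    if mmax > 0:
        q = np.minimum((mag * levels / mmax).astype(np.int64), levels - 1)
    else:
        q = np.zeros_like(mag, dtype=np.int64)
    mats = [glcm_matrix(q, 1, a, levels=levels) for a in (0, 45, 90, 135)]
    mean_mat = np.mean(mats, axis=0)
    return haralick_features(mean_mat)


def glcm_haralick_block(
    patch: np.ndarray,
    distances=(1, 2),
    angles=(0, 45, 90, 135),
    levels: int = 32,
) -> np.ndarray:
    """Haralick features for every (distance, angle) pair, concatenated."""
    q = quantize(patch, levels)
    out = []
    for d in distances:
        for a in angles:
            out.append(haralick_features(glcm_matrix(q, d, a, levels=levels)))
    return np.concatenate(out)
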