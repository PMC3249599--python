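"""Neighborhood gray tone difference matrix (Amadasun-King) features.

Centers are interior pixels only (the 3x3 neighbourhood must lie inside the
patch); the matrix entry for level ``i`` accumulates the absolute difference
between each center of level ``i`` and the mean of its 8 neighbours.  All
denominators are guarded by ``eps = 1e-12`` so every feature is finite on
degenerate input.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

_EPS = 1e-12


def ngtdm_table(patch_q: np.ndarray, levels: int = 32):
    """Return ``(s, n)``: per-level difference sums and center counts."""
    q = np.asarray(patch_q, dtype=np.float64)
    if q.min() < 0 or q.max() >= levels:
        raise ValueError("quantized patch values must lie in [0, levels)")
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    nbr_mean = ndimage.correlate(q, kernel, mode="constant") / 8.0
    center = q[1:-1, 1:-1].astype(np.int64)
    diff = np.abs(q[1:-1, 1:-1] - nbr_mean[1:-1, 1:-1])
    s = np.bincount(center.ravel(), weights=diff.ravel(), minlength=levels)
    n = np.bincount(center.ravel(), minlength=levels).astype(np.float64)
    return s, n


def ngtdm_features(patch_q: np.ndarray, levels: int = 32) -> np.ndarray:
    """Five Amadasun-King features: coarseness, contrast, busyness,
    complexity, strength."""
    s, n = ngtdm_table(patch_q, levels)
    N = n.sum()
    p = n / N
    lv = np.arange(levels, dtype=np.float64)
    present = p > 0
    ng = int(present.sum())

    coarseness = 1.0 / (_EPS + float(np.sum(p * s)))

    if ng > 1:
        pi = p[present]
        li = lv[present]
        dif2 = (li[:, None] - li[None, :]) ** 2
        contrast = float(
            np.sum(pi[:, None] * pi[None, :] * dif2) / (ng * (ng - 1))
        ) * float(s.sum() / N)
    else:
        contrast = 0.0

    ipi = lv[present] * p[present]
    denom = float(np.sum(np.abs(ipi[:, None] - ipi[None, :])))
    busyness = float(np.sum(p * s)) / denom if denom > _EPS else 0.0

    if ng > 0:
        pi = p[present]
        si = s[present]
        li = lv[present]
        num = np.abs(li[:, None] - li[None, :]) * (
            (pi[:, None] * si[:, None] + pi[None, :] * si[None, :])
        )
        complexity = float(np.sum(num / (N * (pi[:, None] + pi[None, :]))))
    else:
        complexity = 0.0

    if ng > 0:
        pi = p[present]
        li = lv[present]
        strength = float(
            np.sum((pi[:, None] + pi[None, :]) * (li[:, None] - li[None, :]) ** 2)
        ) / (_EPS + float(s.sum()))
    else:
        strength = 0.0

    return np.array([coarseness, contrast, busyness, complexity, strength])
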