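"""Texture feature coding: sign-pattern codes of local gray change.

Every interior pixel is coded from the signs of its gray difference to the
two opposite neighbours along each of the four scan directions
(horizontal, diagonal, vertical, anti-diagonal).  Differences within the
tolerance ``delta`` count as "no change".  Per direction the sign pair is
classified as

* 0 - no change (both signs zero),
* 1 - partial change (exactly one sign zero),
* 2 - monotone gradient (opposite nonzero signs),
* 3 - local extremum (equal nonzero signs),

and the pixel code is the sum of the four direction classes (0..12).  The
code histogram drives four summary features.
"""

from __future__ import annotations

import numpy as np

TFCM_DELTA = 2.0

_DIRECTIONS = ((0, 1), (1, 1), (1, 0), (1, -1))


def tfcm_codes(patch: np.ndarray, delta: float = TFCM_DELTA):
    """Return ``(codes, class_counts)`` for interior pixels.

    ``codes`` is the (side-2)x(side-2) array of per-pixel codes;
    ``class_counts`` is an (npixels, 4) array whose columns count, per
    pixel, how many directions fell in each class 0..3.
    """
    g = np.asarray(patch, dtype=np.float64)
    c = g[1:-1, 1:-1]
    codes = np.zeros_like(c, dtype=np.int64)
    per_class = np.zeros(c.shape + (4,), dtype=np.int64)
    for dr, dc in _DIRECTIONS:
        nb1 = g[1 - dr : g.shape[0] - 1 - dr, 1 - dc : g.shape[1] - 1 - dc]
        nb2 = g[1 + dr : g.shape[0] - 1 + dr, 1 + dc : g.shape[1] - 1 + dc]
        d1 = nb1 - c
        d2 = nb2 - c
        s1 = np.where(np.abs(d1) <= delta, 0, np.sign(d1)).astype(np.int64)
        s2 = np.where(np.abs(d2) <= delta, 0, np.sign(d2)).astype(np.int64)
        prod = s1 * s2
        cls = np.zeros_like(s1)
        cls[(s1 == 0) ^ (s2 == 0)] = 1
        cls[prod == -1] = 2
        cls[prod == 1] = 3
        codes += cls
        for k in range(4):
            per_class[..., k] += cls == k
    return codes, per_class


def tfcm_features(patch: np.ndarray, delta: float = TFCM_DELTA) -> np.ndarray:
    """Four texture-coding features: coarseness, homogeneity, mean
    convergence, and code variance.

    * coarseness - mean fraction of no-change directions per pixel;
    * homogeneity - fraction of pixels with no change in any direction;
    * mean convergence - mean fraction of extremum-type directions;
    * variance - population variance of the pixel codes.
    """
    codes, per_class = tfcm_codes(patch, delta)
    n_dir = len(_DIRECTIONS)
    coarseness = float(per_class[..., 0].mean() / n_dir)
    homogeneity = float(np.mean(codes == 0))
    convergence = float(per_class[..., 3].mean() / n_dir)
    variance = float(codes.astype(np.float64).var())
    return np.array([coarseness, homogeneity, convergence, variance])
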