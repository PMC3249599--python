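"""Fractal-dimension estimators: fBm increments, differential box counting,
and the morphological blanket method.

All three treat the gray-level patch as a surface ``z = I(x, y)`` and
estimate its roughness from log-log scaling laws.  Estimated dimensions are
clipped to the admissible surface range [2, 3].
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

_EPS = 1e-12

MRFD_LAGS = (1, 2, 4, 8)
DBC_GRID_SIZES = (2, 4, 8, 16, 32)
MORPH_SCALES = tuple(range(1, 9))
MORPH_TRIPLETS = ((0, 1, 2), (2, 3, 4), (5, 6, 7))


def _chebyshev_increment_means(patch: np.ndarray, lags=MRFD_LAGS) -> np.ndarray:
    """Mean absolute gray difference over all pixel pairs at each Chebyshev
    distance ``k`` (every offset with ``max(|dr|, |dc|) = k``)."""
    g = np.asarray(patch, dtype=np.float64)
    h, w = g.shape
    means = []
    for k in lags:
        total = 0.0
        count = 0
        # half the ring of offsets (4k of the 8k); each unordered pair once
        offsets = [(k, dc) for dc in range(-k, k + 1)]
        offsets.append((0, k))
        for dr in range(1, k):
            offsets.append((dr, k))
            offsets.append((dr, -k))
        for dr, dc in offsets:
            r0, r1 = max(0, -dr), min(h, h - dr)
            c0, c1 = max(0, -dc), min(w, w - dc)
            if r0 >= r1 or c0 >= c1:
                continue
            d = np.abs(g[r0:r1, c0:c1] - g[r0 + dr : r1 + dr, c0 + dc : c1 + dc])
            total += d.sum()
            count += d.size
        means.append(total / count if count else 0.0)
    return np.asarray(means)


def mrfd_features(patch: np.ndarray) -> np.ndarray:
    """Multiresolution fractal dimensions from the fBm increment model.

    For lags ``k in {1, 2, 4, 8}`` the mean absolute increment ``m(k)``
    scales as ``k^H`` for fractional Brownian surfaces with Hurst exponent
    ``H``; the fractal dimension is ``FD = 3 - H``.  Returns
    ``(FD_1, FD_2, FD_3, FD_global, intercept)``: local log-log slopes
    between consecutive lags, the least-squares global slope, and the fit
    intercept.  A flat patch (all increments zero) returns ``(2,2,2,2,0)``.
    """
    m = _chebyshev_increment_means(patch)
    if np.all(m < _EPS):
        return np.array([2.0, 2.0, 2.0, 2.0, 0.0])
    logm = np.log(np.maximum(m, _EPS))
    logk = np.log(np.asarray(MRFD_LAGS, dtype=np.float64))
    local = []
    for j in range(3):
        hj = (logm[j + 1] - logm[j]) / (logk[j + 1] - logk[j])
        local.append(float(np.clip(3.0 - hj, 2.0, 3.0)))
    slope, intercept = np.polyfit(logk, logm, 1)
    fd_global = float(np.clip(3.0 - slope, 2.0, 3.0))
    return np.array(local + [fd_global, float(intercept)])


def dbc_box_counts(patch: np.ndarray, grid_sizes=DBC_GRID_SIZES) -> np.ndarray:
    """Differential box counts ``N(s)`` for each grid size ``s``.

    The patch is tiled into ``s x s`` cells; with box height
    ``h = 256 * s / side`` the cell contributes
    ``ceil(max/h) - ceil(min/h) + 1`` boxes.
    """
    g = np.asarray(patch, dtype=np.float64)
    side = g.shape[0]
    if g.shape[0] != g.shape[1]:
        raise ValueError("patch must be square")
    counts = []
    for s in grid_sizes:
        if side % s:
            raise ValueError(f"grid size {s} does not divide patch side {side}")
        h = 256.0 * s / side
        blocks = g.reshape(side // s, s, side // s, s)
        bmax = blocks.max(axis=(1, 3))
        bmin = blocks.min(axis=(1, 3))
        n = np.ceil(bmax / h) - np.ceil(bmin / h) + 1
        counts.append(float(n.sum()))
    return np.asarray(counts)


def dbc_fd(patch: np.ndarray) -> float:
    """Differential box-counting fractal dimension: slope of
    ``log N(s)`` vs ``log(1/s)``, clipped to [2, 3]."""
    counts = dbc_box_counts(patch)
    x = np.log(1.0 / np.asarray(DBC_GRID_SIZES, dtype=np.float64))
    y = np.log(counts)
    slope = np.polyfit(x, y, 1)[0]
    return float(np.clip(slope, 2.0, 3.0))


_CROSS = ndimage.generate_binary_structure(2, 1)


def blanket_areas(patch: np.ndarray, scales=MORPH_SCALES) -> np.ndarray:
    """Blanket surface areas ``A(eps) = (V_dil - V_ero) / (2 eps)``.

    The upper/lower blankets are grown iteratively: at each scale the upper
    blanket rises by at least one gray unit and swallows its 4-neighbourhood
    maximum (dually for the lower blanket).
    """
    g = np.asarray(patch, dtype=np.float64)
    u = g.copy()
    v = g.copy()
    areas = []
    for eps in scales:
        u = np.maximum(u + 1.0, ndimage.grey_dilation(u, footprint=_CROSS))
        v = np.minimum(v - 1.0, ndimage.grey_erosion(v, footprint=_CROSS))
        areas.append(float((u.sum() - v.sum()) / (2.0 * eps)))
    return np.asarray(areas)


def morph_fd(patch: np.ndarray) -> np.ndarray:
    """Blanket-method fractal dimensions: ``FD = 2 - d log A / d log eps``.

    Returns the global slope over scales 1..8 plus local slopes fitted on
    the scale triplets (1,2,3), (3,4,5), (6,7,8), each clipped to [2, 3].
    """
    areas = blanket_areas(patch)
    loga = np.log(np.maximum(areas, _EPS))
    loge = np.log(np.asarray(MORPH_SCALES, dtype=np.float64))
    slope = np.polyfit(loge, loga, 1)[0]
    out = [float(np.clip(2.0 - slope, 2.0, 3.0))]
    for idx in MORPH_TRIPLETS:
        sl = np.polyfit(loge[list(idx)], loga[list(idx)], 1)[0]
        out.append(float(np.clip(2.0 - sl, 2.0, 3.0)))
    return np.asarray(out)


def synthesize_fbm_surface(
    size: int, hurst: float, rng: np.random.Generator
) -> np.ndarray:
    """Spectral synthesis of a fractional Brownian surface with Hurst
    exponent ``hurst``, mapped to gray levels [0, 255].

    Used to validate the fractal estimators: the surface has power spectrum
    ``|f|^-(2H + 2)`` and expected fractal dimension ``3 - H``.
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError("hurst must lie in (0, 1)")
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = np.inf  # kill DC
    amplitude = f ** (-(hurst + 1.0))
    phase = rng.uniform(0, 2 * np.pi, size=(size, size))
    spectrum = amplitude * np.exp(1j * phase)
    surf = np.fft.ifft2(spectrum).real
    surf -= surf.min()
    if surf.max() > 0:
        surf = surf / surf.max() * 255.0
    return surf
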