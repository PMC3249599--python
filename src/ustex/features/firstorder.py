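"""Gray-level quantization and first-order (histogram) statistics."""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def quantize(patch: np.ndarray, levels: int = 32) -> np.ndarray:
    """Uniformly bin gray levels: ``g' = floor(g * levels / 256)``."""
    if levels < 2:
        raise ValueError("levels must be >= 2")
    p = np.asarray(patch)
    return (p.astype(np.int64) * levels // 256).astype(np.int64)


def fos_features(patch: np.ndarray) -> np.ndarray:
    """Six first-order statistics of the 256-bin gray histogram.

    Returns ``(mean, std, skewness, kurtosis, energy, entropy)`` where
    ``energy = sum p^2`` and ``entropy = -sum p log2 p``.  Skewness and
    kurtosis use population moments and are defined as 0 when the standard
    deviation is 0.
    """
    p = np.asarray(patch).astype(np.int64).ravel()
    hist = np.bincount(p, minlength=256).astype(np.float64)
    prob = hist / hist.sum()
    g = np.arange(256, dtype=np.float64)
    mean = float(np.sum(g * prob))
    var = float(np.sum((g - mean) ** 2 * prob))
    std = float(np.sqrt(var))
    if std > _EPS:
        skew = float(np.sum((g - mean) ** 3 * prob) / std**3)
        kurt = float(np.sum((g - mean) ** 4 * prob) / std**4)
    else:
        skew = 0.0
        kurt = 0.0
    energy = float(np.sum(prob**2))
    nz = prob[prob > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    return np.array([mean, std, skew, kurt, energy, entropy])
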