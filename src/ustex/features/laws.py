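"""Laws texture energy measures.

The patch is first flattened by subtracting a 15x15 local mean (reflect
padding), then correlated with the 25 separable 5x5 masks formed as outer
products of the level/edge/spot/wave/ripple vectors.  The energy of each
mask is the mean absolute response over the valid (fully-covered) region.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

LAWS_VECTORS = {
    "L5": np.array([1.0, 4.0, 6.0, 4.0, 1.0]),
    "E5": np.array([-1.0, -2.0, 0.0, 2.0, 1.0]),
    "S5": np.array([-1.0, 0.0, 2.0, 0.0, -1.0]),
    "W5": np.array([-1.0, 2.0, 0.0, -2.0, 1.0]),
    "R5": np.array([1.0, -4.0, 6.0, -4.0, 1.0]),
}

LAWS_ORDER = tuple(
    (a, b) for a in ("L5", "E5", "S5", "W5", "R5") for b in ("L5", "E5", "S5", "W5", "R5")
)

MEAN_WINDOW = 15


def laws_features(patch: np.ndarray) -> np.ndarray:
    """25 Laws energies in fixed L5L5..R5R5 order (row vector x column
    vector; the first name filters along rows/vertical, the second along
    columns/horizontal)."""
    g = np.asarray(patch, dtype=np.float64)
    g = g - ndimage.uniform_filter(g, size=MEAN_WINDOW, mode="reflect")
    # separable pass: filter rows (axis 0) once per vector, reuse for pairs
    row_pass = {
        name: ndimage.correlate1d(g, vec, axis=0, mode="reflect")
        for name, vec in LAWS_VECTORS.items()
    }
    out = np.empty(len(LAWS_ORDER))
    for idx, (a, b) in enumerate(LAWS_ORDER):
        resp = ndimage.correlate1d(row_pass[a], LAWS_VECTORS[b], axis=1, mode="reflect")
        valid = resp[2:-2, 2:-2]
        out[idx] = np.abs(valid).mean()
    return out
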