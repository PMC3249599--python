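"""Full-suite extraction: one 64x64 ROI in, 234 named features out."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cooccurrence import ecm_features, glcm_haralick_block
from .firstorder import fos_features, quantize
from .fractal import dbc_fd, morph_fd, mrfd_features
from .laws import laws_features
from .ngtdm import ngtdm_features
from .registry import GLCM_LEVELS, FeatureRegistry, default_registry
from .spectral import fourier_features, gabor_features, phasecong_features
from .tfcm import tfcm_features


@dataclass
class FeatureVector:
    """Named feature values for one patient plus the class label."""

    patient_id: str
    values: np.ndarray
    label: str  # "F0" or "F4"

    def __post_init__(self):
        if self.label not in ("F0", "F4"):
            raise ValueError("label must be 'F0' or 'F4'")


def extract_all(
    patch: np.ndarray, registry: FeatureRegistry | None = None
) -> np.ndarray:
    """Compute every registry feature of a 64x64 gray patch, in order.

    The output is always finite: each family defines explicit conventions
    for degenerate (e.g. constant) input.
    """
    registry = registry or default_registry()
    p = np.asarray(patch)
    if p.shape != (64, 64):
        raise ValueError(f"expected a 64x64 patch, got {p.shape}")
    if p.min() < 0 or p.max() > 255:
        raise ValueError("gray levels must lie in [0, 255]")

    q = quantize(p, GLCM_LEVELS)
    blocks = {
        "fos": fos_features(p),
        "ngtdm": ngtdm_features(q, GLCM_LEVELS),
        "glcm": glcm_haralick_block(p, levels=GLCM_LEVELS),
        "mrfd": mrfd_features(p),
        "dbc": np.array([dbc_fd(p)]),
        "morph": morph_fd(p),
        "fourier": fourier_features(p),
        "gabor": gabor_features(p),
        "laws": laws_features(p),
        "ecm": ecm_features(p),
        "pc": phasecong_features(p),
        "tfcm": tfcm_features(p),
    }
    values = np.concatenate([blocks[fam] for fam in blocks])
    if len(values) != len(registry):
        raise RuntimeError(
            f"feature count mismatch: {len(values)} != {len(registry)}"
        )
    if not np.all(np.isfinite(values)):
        bad = [registry.names[i] for i in np.where(~np.isfinite(values))[0]]
        raise RuntimeError(f"non-finite features: {bad}")
    return values
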