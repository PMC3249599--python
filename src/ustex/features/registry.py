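"""The fixed 234-entry texture feature registry.

Twelve texture families describe each 64x64 ROI:

========================  =====  ==========================================
family                    count  parameters
========================  =====  ==========================================
first-order statistics        6  256-bin histogram moments
NGTDM (Amadasun-King)         5  32 gray levels, 3x3 neighbourhood
GLCM / Haralick             104  13 features x 2 distances x 4 angles, 32 levels
multiresolution fractal       5  fBm increments, lags 1/2/4/8
differential box counting     1  grids 2..32
morphological fractal         4  blanket method, scales 1..8
Fourier power spectrum       14  8 radial rings + 6 angular wedges
Gabor bank                   48  4 frequencies x 6 orientations, mean+std
Laws energy                  25  L5/E5/S5/W5/R5 outer products
edge co-occurrence           13  Haralick set on Sobel-magnitude GLCM
phase congruency              5  log-Gabor, 4 scales x 6 orientations
texture feature coding        4  sign coding, tolerance 2
========================  =====  ==========================================

The counts are a fixed reconstruction chosen to keep each cited method in
its standard form while totalling exactly 234; alternates are a one-line
edit here.  Registry order is stable and feature names are unique.
"""

from __future__ import annotations

from dataclasses import dataclass

HARALICK_NAMES = (
    "asm",
    "contrast",
    "correlation",
    "variance",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
)

GLCM_DISTANCES = (1, 2)
GLCM_ANGLES = (0, 45, 90, 135)
GLCM_LEVELS = 32

GABOR_FREQUENCIES = (0.05, 0.1, 0.2, 0.4)  # cycles / pixel
GABOR_ORIENTATIONS = (0, 30, 60, 90, 120, 150)  # degrees

LAWS_VECTOR_NAMES = ("L5", "E5", "S5", "W5", "R5")

FOURIER_N_RINGS = 8
FOURIER_N_WEDGES = 6


@dataclass(frozen=True)
class RegistryEntry:
    family: str
    name: str
    params: tuple = ()


def _build_entries() -> tuple[RegistryEntry, ...]:
    entries: list[RegistryEntry] = []

    for stat in ("mean", "std", "skewness", "kurtosis", "energy", "entropy"):
        entries.append(RegistryEntry("fos", f"fos_{stat}"))

    for stat in ("coarseness", "contrast", "busyness", "complexity", "strength"):
        entries.append(RegistryEntry("ngtdm", f"ngtdm_{stat}"))

    for d in GLCM_DISTANCES:
        for a in GLCM_ANGLES:
            for h in HARALICK_NAMES:
                entries.append(
                    RegistryEntry("glcm", f"glcm_d{d}_a{a}_{h}", (d, a))
                )

    for name in ("fd_lag1", "fd_lag2", "fd_lag3", "fd_global", "intercept"):
        entries.append(RegistryEntry("mrfd", f"mrfd_{name}"))

    entries.append(RegistryEntry("dbc", "dbc_fd"))

    for name in ("fd_global", "fd_eps123", "fd_eps345", "fd_eps678"):
        entries.append(RegistryEntry("morph", f"morph_{name}"))

    for i in range(FOURIER_N_RINGS):
        entries.append(RegistryEntry("fourier", f"fourier_ring{i}"))
    for i in range(FOURIER_N_WEDGES):
        entries.append(RegistryEntry("fourier", f"fourier_wedge{i}"))

    for f in GABOR_FREQUENCIES:
        for o in GABOR_ORIENTATIONS:
            for stat in ("mean", "std"):
                entries.append(
                    RegistryEntry("gabor", f"gabor_f{f:g}_o{o}_{stat}", (f, o))
                )

    for a in LAWS_VECTOR_NAMES:
        for b in LAWS_VECTOR_NAMES:
            entries.append(RegistryEntry("laws", f"laws_{a}{b}", (a, b)))

    for h in HARALICK_NAMES:
        entries.append(RegistryEntry("ecm", f"ecm_{h}"))

    for stat in ("mean", "std", "skewness", "kurtosis", "edge_density"):
        entries.append(RegistryEntry("pc", f"pc_{stat}"))

    for stat in ("coarseness", "homogeneity", "mean_convergence", "variance"):
        entries.append(RegistryEntry("tfcm", f"tfcm_{stat}"))

    return tuple(entries)


class FeatureRegistry:
    """Ordered, immutable list of feature names grouped by family."""

    def __init__(self, entries: tuple[RegistryEntry, ...] | None = None):
        self.entries = entries if entries is not None else _build_entries()
        self.names = tuple(e.name for e in self.entries)
        if len(set(self.names)) != len(self.names):
            raise ValueError("registry feature names must be unique")
        self.families: dict[str, tuple[str, ...]] = {}
        for e in self.entries:
            self.families.setdefault(e.family, ())
        for fam in self.families:
            self.families[fam] = tuple(e.name for e in self.entries if e.family == fam)

    def __len__(self) -> int:
        return len(self.entries)

    def index(self, name: str) -> int:
        return self.names.index(name)


_DEFAULT: FeatureRegistry | None = None


def default_registry() -> FeatureRegistry:
    """The shared default 234-feature registry (singleton)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = FeatureRegistry()
    return _DEFAULT
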