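"""Synthetic study-data generation.

Since the original patient images are not available, this module generates
everything the study measured: fan-shaped speckle frames whose second-order
texture statistics depend on the class (healthy F0 vs cirrhotic F4), a
labeled cohort with the study's class split and frames-per-patient
distribution, five simulated "experts" of graded skill placing one ROI per
patient per iteration, and stationary texture banks for the tile
classification harness.

The speckle model is the simplest one with controllable texture statistics:
a unit-mean correlated reflectivity field multiplied by independent
Rayleigh-distributed amplitude samples and log-compressed to 8 bits.  The
class effect lives in the reflectivity correlation length (and a weak
low-frequency inhomogeneity for F4), so it shows up in second-order texture
features rather than in first-order brightness.  Hypoechoic vessels, an
acoustic shadow ray and a bright capsule line are inserted as artifacts,
with a ground-truth artifact mask returned alongside each frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import truncnorm

from .autoroi import ArtifactDetectorConfig, detect_artifacts, establish_auto_roi
from .geometry import (
    DEFAULT_APERTURE_DEG,
    DEFAULT_DEPTH_CM,
    DEFAULT_FRAME_SHAPE,
    DEFAULT_PIXEL_SPACING_CM,
    DEFAULT_ROI_SIDE,
    DEFAULT_SOURCE_OFFSET_PX,
    RoiRecord,
    UltrasoundFrame,
    compute_fan_mask,
    make_roi_record,
)

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Cohort composition mirroring the study group: 125 patients split
    51 healthy (F0) / 74 cirrhotic (F4), with 12.97 +/- 6.06 right-lobe
    frames per patient (truncated to [2, 33])."""

    n_f0: int = 51
    n_f4: int = 74
    frames_mean: float = 12.97
    frames_sd: float = 6.06
    frames_min: int = 2
    frames_max: int = 33

    @property
    def n_patients(self) -> int:
        return self.n_f0 + self.n_f4


@dataclass(frozen=True)
class FrameGeometryConfig:
    """Shared acquisition geometry of all synthetic frames."""

    shape: tuple[int, int] = DEFAULT_FRAME_SHAPE
    pixel_spacing_cm: float = DEFAULT_PIXEL_SPACING_CM
    source_offset_px: float = DEFAULT_SOURCE_OFFSET_PX
    aperture_deg: float = DEFAULT_APERTURE_DEG
    depth_cm: float = DEFAULT_DEPTH_CM

    @property
    def source_xy(self) -> tuple[float, float]:
        return ((self.shape[1] - 1) / 2.0, -self.source_offset_px)

    @property
    def probe_radius_cm(self) -> float:
        return self.source_offset_px * self.pixel_spacing_cm


@dataclass(frozen=True)
class TextureParams:
    """Class-dependent speckle texture parameters."""

    corr_len_f0: float = 1.5  # class-mean reflectivity correlation length, px
    corr_len_f4: float = 4.0
    trait_sigma: float = 0.22  # per-patient lognormal spread of the trait
    reflect_contrast: float = 0.5
    inhomogeneity_amp: float = 0.1  # F4-only low-frequency modulation
    inhomogeneity_len: float = 40.0
    vessel_max: int = 3
    vessel_reflect: float = 0.05
    shadow_prob: float = 0.4
    shadow_reflect: float = 0.08
    capsule_gain: float = 4.5
    capsule_below_probe_cm: tuple[float, float] = (0.7, 1.4)
    log_offset: float = 135.0
    log_gain: float = 38.0
    # position-dependent image quality: away from the beam axis and beyond
    # the focal depth the point-spread function widens, blurring the
    # speckle texture (why ROI placement matters)
    position_blur_sigma: float = 2.0
    blur_theta_gain: float = 4.0
    blur_depth_gain: float = 0.2  # per cm beyond the reference depth
    blur_depth_ref_cm: float = 4.0
    # oblique insonification decorrelates the parenchymal speckle: off-axis
    # and deep regions carry a class-neutral texture instead of the
    # patient's class-informative one
    neutral_corr_len: float = 2.5
    signal_theta_gain: float = 5.0
    signal_depth_gain: float = 0.4  # per cm beyond the reference depth
    signal_depth_ref_cm: float = 6.0


@dataclass(frozen=True)
class ExpertProfile:
    """Simulated ROI-placement behaviour of one expert.

    Skill degrades with ``expert_id``: placement jitter and the probability
    of overlooking an artifact overlap are non-decreasing in the rank.
    ``expert_id = 5`` is the automatic accept/reject tool.
    """

    expert_id: int
    jitter_px: float = 0.0
    miss_prob: float = 0.0
    depth_bias_px: float = 0.0
    give_up_prob: float = 0.0
    frame_skip_prob: float = 0.35  # idiosyncratic per-image preference
    automatic: bool = False


def default_profiles() -> tuple[ExpertProfile, ...]:
    """The five study experts: two senior radiologists, an intern, a
    trained GP, and the automatic tool."""
    return (
        ExpertProfile(1, jitter_px=3.0, miss_prob=0.02, depth_bias_px=0.0, give_up_prob=0.02),
        ExpertProfile(2, jitter_px=8.0, miss_prob=0.10, depth_bias_px=4.0, give_up_prob=0.03),
        ExpertProfile(3, jitter_px=20.0, miss_prob=0.45, depth_bias_px=16.0, give_up_prob=0.02),
        ExpertProfile(4, jitter_px=32.0, miss_prob=0.70, depth_bias_px=28.0, give_up_prob=0.08),
        ExpertProfile(5, automatic=True),
    )


@dataclass
class PatientAnatomy:
    """Per-patient structures that persist across frames.

    Vessels and shadows are anatomical: they reappear (with small
    acquisition jitter) in every frame of the same patient.  A patient
    whose anatomy blocks the fixed on-axis position therefore blocks it in
    *all* frames — the mechanism behind patient dropout for the automatic
    tool.  ``corr_len_px`` is the patient's texture trait: the reflectivity
    correlation length drawn lognormally around the class mean, so that the
    two class distributions overlap at the patient level (the signal is
    weak, as in real fibrosis detection).
    """

    capsule_depth_cm: float
    vessels: tuple  # of (row, col, semi_axis_a, semi_axis_b, angle_rad)
    shadow: tuple | None  # (theta0_deg, rho0_cm)
    corr_len_px: float = 0.0  # 0 means "use the class mean"


def sample_anatomy(
    rng: np.random.Generator,
    geometry: "FrameGeometryConfig | None" = None,
    params: "TextureParams | None" = None,
    label: str = "F0",
) -> PatientAnatomy:
    """Draw one patient's persistent anatomy and texture trait."""
    geom = geometry or FrameGeometryConfig()
    tp = params or TextureParams()
    shared = _shared_geometry(geom)
    cap_depth = rng.uniform(*tp.capsule_below_probe_cm)
    rho_cap = geom.probe_radius_cm + cap_depth
    liver = shared.fan & (shared.rho > rho_cap + 0.3)
    rows, cols = np.where(liver)
    vessels = []
    n_vessels = int(rng.integers(0, tp.vessel_max + 1))
    for _ in range(n_vessels):
        if len(rows) == 0:
            break
        i = int(rng.integers(len(rows)))
        vessels.append(
            (
                int(rows[i]),
                int(cols[i]),
                float(rng.uniform(4, 12)),
                float(rng.uniform(4, 12)),
                float(rng.uniform(0, np.pi)),
            )
        )
    shadow = None
    if rng.random() < tp.shadow_prob:
        shadow = (
            float(rng.uniform(-geom.aperture_deg + 4, geom.aperture_deg - 4)),
            float(rng.uniform(rho_cap + 1.0, 8.0)),
        )
    base = tp.corr_len_f0 if label == "F0" else tp.corr_len_f4
    corr_len = float(base * np.exp(rng.normal(0.0, tp.trait_sigma)))
    return PatientAnatomy(
        capsule_depth_cm=float(cap_depth),
        vessels=tuple(vessels),
        shadow=shadow,
        corr_len_px=corr_len,
    )


@dataclass
class FrameSample:
    """A generated frame plus its ground truth."""

    frame: UltrasoundFrame
    artifact_gt: np.ndarray  # bool mask of inserted artifacts
    capsule_row: int


@dataclass
class Cohort:
    """Everything one synthetic study run produces."""

    labels: dict  # patient_id -> "F0" / "F4"
    frames: dict  # patient_id -> list[FrameSample]
    roi_sets: dict  # (expert_id, iteration) -> list[RoiRecord]
    exclusions: dict  # (expert_id, iteration) -> list[patient_id]
    patient_ids: tuple = ()


# ---------------------------------------------------------------------------
# Frame generation
# ---------------------------------------------------------------------------


class _SharedGeometry:
    """Per-geometry caches (fan mask, polar grids) reused by every frame."""

    def __init__(self, geom: FrameGeometryConfig):
        self.geom = geom
        h, w = geom.shape
        sx, sy = geom.source_xy
        yy, xx = np.mgrid[0:h, 0:w]
        dx = xx - sx
        dy = yy - sy
        self.rho = np.hypot(dx, dy) * geom.pixel_spacing_cm
        self.theta = np.degrees(np.arctan2(dx, dy))
        self.yy = yy
        self.xx = xx
        self.fan = compute_fan_mask(
            geom.source_xy,
            geom.aperture_deg,
            geom.depth_cm,
            geom.shape,
            geom.pixel_spacing_cm,
            geom.probe_radius_cm,
        )


_geom_cache: dict[FrameGeometryConfig, _SharedGeometry] = {}


def _shared_geometry(geom: FrameGeometryConfig) -> _SharedGeometry:
    if geom not in _geom_cache:
        _geom_cache[geom] = _SharedGeometry(geom)
    return _geom_cache[geom]


def _correlated_field(shape, corr_len, rng) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian random field with the given
    correlation length.  Long correlation lengths are synthesized at a
    coarse grid and upsampled (the result is smooth anyway)."""
    if corr_len > 8:
        step = int(corr_len // 4)
        small = (shape[0] // step + 2, shape[1] // step + 2)
        noise = rng.standard_normal(small)
        f = ndimage.gaussian_filter(noise, corr_len / step, mode="reflect")
        f = ndimage.zoom(f, step, order=1)[: shape[0], : shape[1]]
    else:
        noise = rng.standard_normal(shape)
        f = ndimage.gaussian_filter(noise, corr_len, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_frame(
    label: str,
    rng: np.random.Generator,
    geometry: FrameGeometryConfig | None = None,
    params: TextureParams | None = None,
    artifacts: bool = True,
    anatomy: PatientAnatomy | None = None,
) -> FrameSample:
    """Generate one fan-shaped speckle frame for class ``label``.

    ``anatomy`` carries the patient's persistent structures (vessels,
    shadow, capsule depth); when omitted a fresh anatomy is drawn, when
    supplied only small per-frame acquisition jitter is added.  Returns the
    frame, the ground-truth mask of the inserted artifacts and the on-axis
    capsule row.
    """
    if label not in ("F0", "F4"):
        raise ValueError("label must be 'F0' or 'F4'")
    geom = geometry or FrameGeometryConfig()
    tp = params or TextureParams()
    shared = _shared_geometry(geom)
    h, w = geom.shape
    spacing = geom.pixel_spacing_cm

    if anatomy is None:
        anatomy = sample_anatomy(rng, geom, tp, label)

    corr = anatomy.corr_len_px or (
        tp.corr_len_f0 if label == "F0" else tp.corr_len_f4
    )
    field = _correlated_field((h, w), corr, rng)
    if tp.signal_theta_gain > 0 or tp.signal_depth_gain > 0:
        mix = np.clip(
            tp.signal_theta_gain * np.abs(shared.theta) / geom.aperture_deg
            + tp.signal_depth_gain
            * np.maximum(0.0, shared.rho - tp.signal_depth_ref_cm),
            0.0,
            1.0,
        )
        neutral = _correlated_field((h, w), tp.neutral_corr_len, rng)
        norm = np.sqrt((1.0 - mix) ** 2 + mix**2)
        field = ((1.0 - mix) * field + mix * neutral) / norm
    refl = 1.0 + tp.reflect_contrast * field
    if label == "F4" and tp.inhomogeneity_amp > 0:
        low = _correlated_field((h, w), tp.inhomogeneity_len, rng)
        refl *= 1.0 + tp.inhomogeneity_amp * low
    refl = np.clip(refl, 0.05, None)

    gt = np.zeros((h, w), dtype=bool)

    # capsule: bright arc at a constant radius below the probe face
    cap_depth = anatomy.capsule_depth_cm + rng.normal(0, 0.02)
    rho_cap = geom.probe_radius_cm + cap_depth
    capsule_row = int(round(rho_cap / spacing - geom.source_offset_px))

    if artifacts:
        cap_band = np.abs(shared.rho - rho_cap) <= 1.5 * spacing
        refl[cap_band] *= tp.capsule_gain
        gt |= np.abs(shared.rho - rho_cap) <= 3.0 * spacing
        # hypoechoic vessels, jittered around their anatomical positions
        for row0, col0, a, b, ang in anatomy.vessels:
            cy = int(round(row0 + rng.normal(0, 2.0)))
            cx = int(round(col0 + rng.normal(0, 2.0)))
            ca, sa = np.cos(ang), np.sin(ang)
            r_ext = int(np.ceil(max(a, b))) + 1
            y0, y1 = max(0, cy - r_ext), min(h, cy + r_ext + 1)
            x0, x1 = max(0, cx - r_ext), min(w, cx + r_ext + 1)
            if y0 >= y1 or x0 >= x1:
                continue
            yy = shared.yy[y0:y1, x0:x1]
            xx = shared.xx[y0:y1, x0:x1]
            u = (xx - cx) * ca + (yy - cy) * sa
            v = -(xx - cx) * sa + (yy - cy) * ca
            inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
            refl[y0:y1, x0:x1][inside] *= tp.vessel_reflect
            gt[y0:y1, x0:x1] |= inside
        # acoustic shadow ray
        if anatomy.shadow is not None:
            t0 = anatomy.shadow[0] + rng.normal(0, 0.5)
            r0 = anatomy.shadow[1]
            ray = (np.abs(shared.theta - t0) <= 1.5) & (shared.rho >= r0)
            refl[ray] *= tp.shadow_reflect
            gt |= ray

    amplitude = refl * rng.rayleigh(scale=1.0, size=(h, w))
    img = tp.log_offset + tp.log_gain * np.log(amplitude + 1e-6)
    if tp.position_blur_sigma > 0:
        blurred = ndimage.gaussian_filter(img, tp.position_blur_sigma)
        weight = np.clip(
            tp.blur_theta_gain * np.abs(shared.theta) / geom.aperture_deg
            + tp.blur_depth_gain
            * np.maximum(0.0, shared.rho - tp.blur_depth_ref_cm),
            0.0,
            1.0,
        )
        img = (1.0 - weight) * img + weight * blurred
    img = np.clip(img, 0, 255)
    img[~shared.fan] = 0
    pixels = img.astype(np.uint8)

    frame = UltrasoundFrame(
        pixels=pixels,
        pixel_spacing_cm=spacing,
        source_xy=geom.source_xy,
        aperture_deg=geom.aperture_deg,
        depth_cm=geom.depth_cm,
        probe_radius_cm=geom.probe_radius_cm,
    )
    # inject the shared caches so thousands of frames share one geometry
    frame._fan_mask = shared.fan
    frame._polar = (shared.rho, shared.theta)
    gt &= shared.fan
    return FrameSample(frame=frame, artifact_gt=gt, capsule_row=capsule_row)


# ---------------------------------------------------------------------------
# Expert simulation
# ---------------------------------------------------------------------------

_MAX_ATTEMPTS_PER_FRAME = 20
ROI_BELOW_CAPSULE_CM = 1.0


def _window_valid(frame: UltrasoundFrame, cx: int, cy: int, side: int) -> bool:
    half = side // 2
    x0, x1, y0, y1 = cx - half, cx + half, cy - half, cy + half
    h, w = frame.pixels.shape
    if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
        return False
    return bool(frame.fan_mask[y0:y1, x0:x1].all())


def simulate_expert_roi(
    frames: list[FrameSample],
    profile: ExpertProfile,
    rng: np.random.Generator,
    patient_id: str = "",
    iteration: int = 1,
    side: int = DEFAULT_ROI_SIDE,
    frame_order: np.ndarray | None = None,
) -> RoiRecord | None:
    """Simulate one human expert establishing one ROI for one patient.

    The nominal target is on the fan axis with the window top 1 cm below
    the capsule; skill enters through Gaussian placement jitter, a depth
    bias, and the probability of overlooking an overlap with a ground-truth
    artifact (an overlap the expert notices is re-drawn, up to 20 attempts
    per frame).  Returns ``None`` if the expert gives up or no valid window
    is found on any frame.
    """
    if profile.automatic:
        raise ValueError("use establish_auto_roi for the automatic expert")
    if not frames:
        raise ValueError("need at least one frame")
    if rng.random() < profile.give_up_prob:
        return None
    order = (
        np.asarray(frame_order)
        if frame_order is not None
        else rng.permutation(len(frames))
    )
    gap_px = ROI_BELOW_CAPSULE_CM / frames[0].frame.pixel_spacing_cm
    # experts browse in the shared order but have idiosyncratic image
    # preferences: unappealing frames are passed over (revisited only if
    # nothing else worked), so different experts work on different frames
    order = list(order)
    preferred = [i for i in order if rng.random() >= profile.frame_skip_prob]
    skipped = [i for i in order if i not in preferred]
    for idx in preferred + skipped:
        fs = frames[idx]
        sx = fs.frame.source_xy[0]
        half = side // 2
        for attempt in range(_MAX_ATTEMPTS_PER_FRAME):
            # on a blocked target the expert deliberately searches farther
            # from the nominal position, so the spread grows per attempt
            sigma = profile.jitter_px + (2.5 * attempt if attempt else 0.0)
            dx = rng.normal(0, sigma) if sigma > 0 else 0.0
            dy = rng.normal(0, sigma) if sigma > 0 else 0.0
            cx = int(round(sx + dx))
            cy = int(
                round(
                    fs.capsule_row + gap_px + half + profile.depth_bias_px + dy
                )
            )
            if not _window_valid(fs.frame, cx, cy, side):
                continue
            overlap = bool(
                fs.artifact_gt[cy - half : cy + half, cx - half : cx + half].any()
            )
            if overlap and rng.random() >= profile.miss_prob:
                continue  # the expert notices the artifact and re-draws
            return make_roi_record(
                fs.frame,
                patient_id,
                profile.expert_id,
                iteration,
                (cx, cy),
                side,
                frame_index=int(idx),
            )
    return None


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _frame_counts(config: SyntheticCohortConfig, n: int, rng) -> np.ndarray:
    a = (config.frames_min - config.frames_mean) / config.frames_sd
    b = (config.frames_max - config.frames_mean) / config.frames_sd
    counts = truncnorm.rvs(
        a, b, loc=config.frames_mean, scale=config.frames_sd, size=n, random_state=rng
    )
    return np.clip(np.round(counts), config.frames_min, config.frames_max).astype(int)


def generate_cohort(
    config: SyntheticCohortConfig | None = None,
    profiles: tuple[ExpertProfile, ...] | None = None,
    geometry: FrameGeometryConfig | None = None,
    params: TextureParams | None = None,
    rng: np.random.Generator | None = None,
    iterations: int = 5,
    detector_config: ArtifactDetectorConfig | None = None,
) -> Cohort:
    """Generate a full synthetic study: frames, labels and one ROI set per
    (expert, iteration).

    Frames are generated once per patient (the experts re-read the same
    saved images).  Within one iteration every expert sees the patients and
    each patient's frames in the same randomized order; the order is
    redrawn between iterations.
    """
    config = config or SyntheticCohortConfig()
    profiles = profiles or default_profiles()
    geom = geometry or FrameGeometryConfig()
    rng = rng if rng is not None else np.random.default_rng()

    frame_rng, order_rng, expert_seed_rng = rng.spawn(3)

    patient_ids = tuple(f"P{i + 1:03d}" for i in range(config.n_patients))
    labels = {
        pid: ("F0" if i < config.n_f0 else "F4")
        for i, pid in enumerate(patient_ids)
    }
    counts = _frame_counts(config, config.n_patients, frame_rng)

    frames: dict[str, list[FrameSample]] = {}
    for pid, n_frames in zip(patient_ids, counts):
        anatomy = sample_anatomy(frame_rng, geom, params, labels[pid])
        frames[pid] = [
            generate_frame(labels[pid], frame_rng, geom, params, anatomy=anatomy)
            for _ in range(n_frames)
        ]

    # artifact detections for the automatic expert, one per frame
    auto_masks: dict[str, list] = {}
    has_auto = any(p.automatic for p in profiles)
    if has_auto:
        for pid in patient_ids:
            auto_masks[pid] = [
                detect_artifacts(fs.frame, detector_config) for fs in frames[pid]
            ]

    roi_sets: dict[tuple[int, int], list[RoiRecord]] = {}
    exclusions: dict[tuple[int, int], list[str]] = {}
    for z in range(1, iterations + 1):
        patient_order = order_rng.permutation(config.n_patients)
        frame_orders = {
            pid: order_rng.permutation(len(frames[pid])) for pid in patient_ids
        }
        for profile in profiles:
            e_rng = np.random.default_rng(
                [int(expert_seed_rng.integers(2**31)), profile.expert_id, z]
            )
            key = (profile.expert_id, z)
            roi_sets[key] = []
            exclusions[key] = []
            for pi in patient_order:
                pid = patient_ids[pi]
                if profile.automatic:
                    roi = establish_auto_roi(
                        [fs.frame for fs in frames[pid]],
                        e_rng,
                        patient_id=pid,
                        iteration=z,
                        artifact_masks=auto_masks[pid],
                        frame_order=frame_orders[pid],
                    )
                else:
                    roi = simulate_expert_roi(
                        frames[pid],
                        profile,
                        e_rng,
                        patient_id=pid,
                        iteration=z,
                        frame_order=frame_orders[pid],
                    )
                if roi is None:
                    exclusions[key].append(pid)
                else:
                    roi_sets[key].append(roi)

    return Cohort(
        labels=labels,
        frames=frames,
        roi_sets=roi_sets,
        exclusions=exclusions,
        patient_ids=patient_ids,
    )


# ---------------------------------------------------------------------------
# Texture banks
# ---------------------------------------------------------------------------


def generate_texture_bank(
    n_classes: int,
    rng: np.random.Generator,
    image_size: int = 640,
) -> list[np.ndarray]:
    """Generate ``n_classes`` distinct stationary 8-bit texture images.

    The class generators (cycled if ``n_classes > 5``): an oriented
    sinusoid, a blob field, a stripe field, fine filtered noise, and
    coarse filtered noise under a checkered modulation.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 texture classes")
    size = image_size
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)

    def sinusoid(r):
        a = np.radians(30.0)
        base = 127 + 60 * np.sin(2 * np.pi * (xx * np.cos(a) + yy * np.sin(a)) / 12.0)
        return base + 20 * r.standard_normal((size, size))

    def blobs(r):
        f = ndimage.gaussian_filter(r.standard_normal((size, size)), 5.0)
        img = np.where(f > 0, 170.0, 80.0)
        return ndimage.gaussian_filter(img, 1.5) + 15 * r.standard_normal((size, size))

    def stripes(r):
        base = np.where((xx // 8).astype(int) % 2 == 0, 165.0, 90.0)
        return base + 15 * r.standard_normal((size, size))

    def fine_noise(r):
        f = ndimage.gaussian_filter(r.standard_normal((size, size)), 1.0)
        return 127 + 40 * f / f.std()

    def coarse_checker(r):
        f = ndimage.gaussian_filter(r.standard_normal((size, size)), 6.0)
        checker = np.where(((xx // 32).astype(int) + (yy // 32).astype(int)) % 2 == 0, 1.2, 0.8)
        return 127 + 50 * (f / f.std()) * checker

    generators = [sinusoid, blobs, stripes, fine_noise, coarse_checker]
    images = []
    for c in range(n_classes):
        img = generators[c % len(generators)](rng)
        images.append(np.clip(img, 0, 255).astype(np.uint8))
    return images


def tile_nonoverlapping(image: np.ndarray, side: int = 64) -> np.ndarray:
    """Split an image into row-major non-overlapping ``side x side`` tiles.

    The image dimensions must be divisible by ``side``; the tile union
    reconstructs the image exactly.
    """
    img = np.asarray(image)
    h, w = img.shape
    if h % side or w % side:
        raise ValueError(f"image shape {img.shape} not divisible by side {side}")
    tiles = (
        img.reshape(h // side, side, w // side, side)
        .swapaxes(1, 2)
        .reshape(-1, side, side)
    )
    return tiles
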