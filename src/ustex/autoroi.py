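"""Automatic ROI establishment ("expert 5").

The tool detects artifacts and then tries to place a 64x64 window at a
*fixed* geometric position — on the fan axis, 1 cm below the liver capsule.
Frames of a patient are tested in random order; the first frame whose fixed
candidate window contains no artifact pixel yields the ROI.  If every frame
fails, the patient is excluded for this expert.

The artifact detector combines three rules (all thresholds configurable):

* hypoechoic blobs — in-fan pixels darker than ``hypo_frac`` times the
  in-fan median gray, morphologically closed and size-filtered;
* acoustic shadows — angular rays whose distal half is much darker than the
  proximal half;
* the capsule margin — everything above, and the first centimetre below,
  the brightest horizontal ridge in the upper third of the frame.

Out-of-fan pixels are always flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import (
    DEFAULT_ROI_SIDE,
    RoiBoundsError,
    RoiRecord,
    UltrasoundFrame,
    make_roi_record,
)


@dataclass(frozen=True)
class ArtifactDetectorConfig:
    hypo_frac: float = 0.4  # blob threshold as a fraction of in-fan median
    min_blob_px: int = 30
    shadow_ratio: float = 0.5  # distal mean < ratio * proximal mean
    shadow_ray_deg: float = 1.0
    capsule_margin_cm: float = 1.0
    capsule_prominence: float = 1.18  # ridge must beat the profile baseline


@dataclass
class ArtifactMask:
    """Boolean artifact grid plus the detected capsule row (``None`` when
    no prominent capsule ridge was found).

    ``focal`` holds only the localized artifacts (hypoechoic blobs and
    shadow rays); ``mask`` adds the capsule margin and out-of-fan pixels.
    """

    mask: np.ndarray
    capsule_row: int | None
    focal: np.ndarray | None = None


def detect_artifacts(
    frame: UltrasoundFrame, config: ArtifactDetectorConfig | None = None
) -> ArtifactMask:
    """Flag artifact pixels (blobs, shadows, capsule margin, out-of-fan)."""
    cfg = config or ArtifactDetectorConfig()
    fan = frame.fan_mask
    if not fan.any():
        raise ValueError("frame has an empty fan")
    px = frame.pixels.astype(np.float64)
    h, w = px.shape

    flagged = ~fan.copy()

    # (a) hypoechoic blobs
    median = np.median(px[fan])
    threshold = cfg.hypo_frac * median
    # strict comparison for normal frames; an all-black fan is fully flagged
    hypo = ((px <= threshold) if threshold == 0 else (px < threshold)) & fan
    hypo |= ndimage.binary_closing(hypo, structure=np.ones((3, 3), bool))
    labels_arr, n_lab = ndimage.label(hypo)
    if n_lab:
        sizes = np.bincount(labels_arr.ravel())
        keep = sizes >= cfg.min_blob_px
        keep[0] = False
        hypo = keep[labels_arr]
    flagged |= hypo & fan

    # (b) shadow rays: distal half much darker than proximal half
    rho, theta = frame.polar_grids()
    n_rays = max(1, int(np.ceil(2 * frame.aperture_deg / cfg.shadow_ray_deg)))
    ray_idx = np.clip(
        ((theta + frame.aperture_deg) / cfg.shadow_ray_deg).astype(np.int64),
        0,
        n_rays - 1,
    )
    for ray in range(n_rays):
        sel = (ray_idx == ray) & fan
        if sel.sum() < 20:
            continue
        r = rho[sel]
        v = px[sel]
        mid = (r.min() + r.max()) / 2.0
        prox = v[r < mid]
        dist = v[r >= mid]
        if len(prox) and len(dist) and dist.mean() < cfg.shadow_ratio * prox.mean():
            shadow_sel = sel & (rho >= mid)
            flagged |= shadow_sel

    # (c) capsule: the brightest ridge of the radial gray profile in the
    # proximal third of the fan; the capsule itself and the first
    # centimetre below it are off limits
    focal = flagged & fan  # blobs + shadows only
    capsule_rho = find_capsule_rho(frame, cfg.capsule_prominence)
    capsule_row: int | None = None
    if capsule_rho is not None:
        margin_tol = frame.pixel_spacing_cm  # one-pixel slack at the bound
        flagged = flagged | (rho < capsule_rho + cfg.capsule_margin_cm - margin_tol)
        capsule_row = int(
            round(capsule_rho / frame.pixel_spacing_cm + frame.source_xy[1])
        )

    return ArtifactMask(mask=flagged, capsule_row=capsule_row, focal=focal)


def find_capsule_rho(
    frame: UltrasoundFrame, prominence: float = 1.18
) -> float | None:
    """Radius (cm) of the strongest bright ridge of the in-fan radial gray
    profile, searched over the proximal third of the fan.

    The liver capsule is an arc at roughly constant distance from the
    probe, so it shows as a sharp peak of mean gray vs radius.  Returns
    ``None`` when no radial bin's mean exceeds ``prominence`` times the
    profile baseline (median) — i.e. no capsule is visible.
    """
    fan = frame.fan_mask
    if not fan.any():
        return None
    px = frame.pixels.astype(np.float64)
    rho, _ = frame.polar_grids()
    r = rho[fan]
    v = px[fan]
    spacing = frame.pixel_spacing_cm
    r_min, r_max = r.min(), r.max()
    limit = r_min + (r_max - r_min) / 3.0
    sel = r <= limit
    if sel.sum() < 50:
        return None
    bins = ((r[sel] - r_min) / spacing).astype(np.int64)
    n_bins = bins.max() + 1
    counts = np.bincount(bins, minlength=n_bins)
    sums = np.bincount(bins, weights=v[sel], minlength=n_bins)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    means = ndimage.uniform_filter1d(means, size=3)
    valid = counts >= 20
    if not valid.any():
        return None
    candidates = np.where(valid, means, -np.inf)
    peak = int(np.argmax(candidates))
    baseline = float(np.median(means[valid]))
    if baseline <= 0 or candidates[peak] < prominence * baseline:
        return None
    return float(r_min + peak * spacing)


def candidate_center(
    frame: UltrasoundFrame,
    capsule_row: int | None,
    side: int = DEFAULT_ROI_SIDE,
    below_capsule_cm: float = 1.0,
) -> tuple[int, int]:
    """Fixed candidate ROI center: on the fan axis, window top
    ``below_capsule_cm`` below the capsule row.  With no detected capsule
    the anchor falls back to the first in-fan row on the axis."""
    cx = int(round(frame.source_xy[0]))
    if capsule_row is None:
        col = np.clip(cx, 0, frame.pixels.shape[1] - 1)
        in_fan_rows = np.where(frame.fan_mask[:, col])[0]
        capsule_row = int(in_fan_rows[0]) if len(in_fan_rows) else 0
    gap_px = int(round(below_capsule_cm / frame.pixel_spacing_cm))
    cy = capsule_row + gap_px + side // 2
    return cx, cy


def window_is_clean(
    frame: UltrasoundFrame,
    artifact_mask: np.ndarray,
    center: tuple[int, int],
    side: int = DEFAULT_ROI_SIDE,
    safety_margin_px: int = 0,
) -> bool:
    """True iff the side x side window fits the image/fan and contains no
    flagged pixel.

    ``safety_margin_px`` additionally requires a flag-free guard band
    around the window (the automatic tool is deliberately cautious)."""
    cx, cy = center
    half = side // 2
    x0, x1, y0, y1 = cx - half, cx + half, cy - half, cy + half
    h, w = frame.pixels.shape
    if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
        return False
    if not frame.fan_mask[y0:y1, x0:x1].all():
        return False
    m = safety_margin_px
    gx0, gx1 = max(0, x0 - m), min(w, x1 + m)
    gy0, gy1 = max(0, y0 - m), min(h, y1 + m)
    return not artifact_mask[gy0:gy1, gx0:gx1].any()


def establish_auto_roi(
    frames: list[UltrasoundFrame],
    rng: np.random.Generator,
    patient_id: str = "",
    iteration: int = 1,
    side: int = DEFAULT_ROI_SIDE,
    config: ArtifactDetectorConfig | None = None,
    artifact_masks: list[ArtifactMask] | None = None,
    frame_order: np.ndarray | None = None,
    safety_margin_px: int = 8,
) -> RoiRecord | None:
    """Accept/reject automatic ROI placement for one patient.

    Frames are tested in random order (or the supplied ``frame_order``); the
    first whose fixed candidate window is artifact-free — with a
    ``safety_margin_px`` guard band kept clear of focal artifacts — yields
    the ROI with ``expert_id = 5``.  Returns ``None`` when no frame
    qualifies.  ``artifact_masks`` may carry precomputed detections (one
    per frame).
    """
    if not frames:
        raise ValueError("need at least one frame")
    if artifact_masks is None:
        artifact_masks = [detect_artifacts(f, config) for f in frames]
    order = (
        np.asarray(frame_order)
        if frame_order is not None
        else rng.permutation(len(frames))
    )
    for idx in order:
        frame = frames[idx]
        am = artifact_masks[idx]
        center = candidate_center(frame, am.capsule_row, side)
        focal = am.focal if am.focal is not None else am.mask
        if window_is_clean(frame, am.mask, center, side) and window_is_clean(
            frame, focal, center, side, safety_margin_px
        ):
            try:
                return make_roi_record(
                    frame, patient_id, 5, iteration, center, side, frame_index=int(idx)
                )
            except RoiBoundsError:  # pragma: no cover - guarded by window check
                continue
    return None
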