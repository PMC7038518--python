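"""Exposure/color normalization across snaps and extraction of the usable
(non-overlapped) region of each snap.

Neighboring snaps share a known overlap (40% angularly within a strip, the
frame-minus-step band vertically between strips).  Those shared regions are
the only cross-snap photometric anchor, so normalization runs before
cropping: a scalar gain per snap equalizes median overlap luminance along
the rotation chain, strips are then tied together through their vertical
overlap, and finally each snap is cropped to the central wedge it uniquely
covers (plus a small guard margin kept for stitching refinement).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .acquisition import AcquisitionPlan
from .synthetic import CameraModel, Snap

#: Rec. 601 luma weights.
_LUMA = np.array([0.299, 0.587, 0.114])

GAIN_BOUNDS = (0.5, 2.0)


class NormalizeError(ValueError):
    pass


def luminance(pixels: np.ndarray) -> np.ndarray:
    """Rec. 601 luminance; single-band images pass through."""
    if pixels.ndim == 2:
        return np.asarray(pixels, dtype=np.float64)
    return np.asarray(pixels, dtype=np.float64) @ _LUMA


def _angular_overlap_px(plan: AcquisitionPlan, camera: CameraModel) -> int:
    dtheta = 360.0 / plan.snaps_per_rotation
    return int(round((camera.fov_deg - dtheta) / camera.fov_deg
                     * camera.sensor_w_px))


def _vertical_overlap_px(plan: AcquisitionPlan, camera: CameraModel) -> int:
    return int(round((camera.frame_h_mm - plan.step_mm) / camera.frame_h_mm
                     * camera.sensor_h_px))


def exposure_normalize(
    snaps: list[Snap], plan: AcquisitionPlan, camera: CameraModel,
) -> tuple[list[Snap], dict[tuple[int, int], float]]:
    """Equalize per-snap exposure with scalar gains chained over overlaps.

    Within each strip the gain of snap i+1 matches its left-overlap median
    luminance to snap i's gained right overlap, anchored at angle 0; strips
    are chained to strip 0 through the median of their vertical overlap
    bands.  Gains are clipped to [0.5, 2].  With no overlap at all the
    routine falls back to matching every snap's global median (with a
    warning).

    Returns gain-applied snaps and the gain per (strip_idx, angle_idx).
    """
    ow = _angular_overlap_px(plan, camera)
    ov = _vertical_overlap_px(plan, camera)
    by_pos: dict[tuple[int, int], Snap] = {
        (s.strip_idx, s.angle_idx): s for s in snaps}
    if len(by_pos) != len(snaps):
        raise NormalizeError("duplicate (strip, angle) positions")
    strips = sorted({s.strip_idx for s in snaps})
    n = plan.snaps_per_rotation
    gains: dict[tuple[int, int], float] = {}

    if ow <= 0:
        warnings.warn("no angular overlap: falling back to global-median "
                      "exposure matching", stacklevel=2)
        ref = np.median(luminance(snaps[0].pixels))
        for s in snaps:
            g = ref / max(np.median(luminance(s.pixels)), 1e-6)
            gains[(s.strip_idx, s.angle_idx)] = float(np.clip(g, *GAIN_BOUNDS))
    else:
        for si in strips:
            gains[(si, 0)] = 1.0
            for a in range(n - 1):
                cur = by_pos[(si, a)]
                nxt = by_pos[(si, a + 1)]
                med_r = np.median(luminance(cur.pixels)[:, -ow:])
                med_l = np.median(luminance(nxt.pixels)[:, :ow])
                g = gains[(si, a)] * med_r / max(med_l, 1e-6)
                gains[(si, a + 1)] = float(np.clip(g, *GAIN_BOUNDS))
        # tie consecutive strips through the vertical overlap band
        strip_factor = {strips[0]: 1.0}
        for si, sj in zip(strips, strips[1:]):
            if ov <= 0:
                strip_factor[sj] = 1.0
                continue
            bot = np.median([
                np.median(luminance(by_pos[(si, a)].pixels)[-ov:, :]
                          * gains[(si, a)]) for a in range(n)])
            top = np.median([
                np.median(luminance(by_pos[(sj, a)].pixels)[:ov, :]
                          * gains[(sj, a)]) for a in range(n)])
            strip_factor[sj] = strip_factor[si] * bot / max(top, 1e-6)
        for (si, a) in list(gains):
            gains[(si, a)] = float(np.clip(gains[(si, a)] * strip_factor[si],
                                           *GAIN_BOUNDS))

    out = []
    for s in snaps:
        g = gains[(s.strip_idx, s.angle_idx)]
        px = np.clip(s.pixels.astype(np.float32) * g, 0, 1)
        out.append(Snap(pixels=px, strip_idx=s.strip_idx,
                        angle_idx=s.angle_idx, angle_deg=s.angle_deg,
                        depth_mm=s.depth_mm, band_nm=s.band_nm,
                        streak_mask=s.streak_mask))
    return out, gains


def color_correct(pixels: np.ndarray,
                  reference_gray: tuple[float, float, float] | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Gray-world channel balancing toward a reference gray ratio.

    Per-channel gains map the image's median channel values onto the
    reference ratio (default: the image's own mean of channel medians, i.e.
    plain gray-world).  Single-band images pass through with unit gain.

    Returns (corrected pixels, gains).
    """
    px = np.asarray(pixels)
    if px.ndim == 2:
        return px.copy(), np.array([1.0])
    med = np.median(px.reshape(-1, px.shape[-1]), axis=0)
    med = np.maximum(med, 1e-6)
    if reference_gray is None:
        target = np.full(3, med.mean())
    else:
        ref = np.asarray(reference_gray, dtype=np.float64)
        target = ref / ref.mean() * med.mean()
    gains = np.clip(target / med, *GAIN_BOUNDS)
    out = np.clip(px.astype(np.float32) * gains.astype(np.float32), 0, 1)
    return out, gains


@dataclass(frozen=True)
class CroppedSnap:
    """A snap reduced to its unique wedge, with guard margins and placement.

    ``pixels`` includes the guards; the core (unique) region starts at
    ``(guard_t, guard_l)`` inside it and measures ``core_h x core_w``.
    ``(pan_x0, pan_y0)`` is the core origin in panorama coordinates
    (columns from angle -angle_step/2, rows from depth -step/2).
    """

    pixels: np.ndarray
    strip_idx: int
    angle_idx: int
    core_w: int
    core_h: int
    guard_l: int
    guard_r: int
    guard_t: int
    guard_b: int
    pan_x0: int
    pan_y0: int

    def to_record(self) -> dict:
        return {"strip_idx": self.strip_idx, "angle_idx": self.angle_idx,
                "crop_offset": {
                    "pan_x0": self.pan_x0, "pan_y0": self.pan_y0,
                    "core_w": self.core_w, "core_h": self.core_h,
                    "guards": [self.guard_l, self.guard_r,
                               self.guard_t, self.guard_b]}}


def panorama_dims(plan: AcquisitionPlan, camera: CameraModel) -> tuple[int, int]:
    """(width, height) of the assembled panorama in pixels."""
    ppd = camera.sensor_w_px / camera.fov_deg
    s_v = camera.frame_h_mm / camera.sensor_h_px
    return (int(round(360.0 * ppd)),
            int(round(plan.n_strips * plan.step_mm / s_v)))


def crop_usable(snap: Snap, plan: AcquisitionPlan, camera: CameraModel,
                guard_px: int = 0) -> CroppedSnap:
    """Extract the snap's unique wedge: angle_step degrees by step_mm.

    Crop boundaries are computed in absolute panorama coordinates and
    rounded per boundary, so concatenated crop widths telescope to exactly
    the panorama width and rounding never accumulates.  ``guard_px`` extra
    pixels are retained on every side (clipped to the sensor) for seam
    refinement and feathering.
    """
    n = plan.snaps_per_rotation
    dtheta = 360.0 / n
    ppd = camera.sensor_w_px / camera.fov_deg
    s_v = camera.frame_h_mm / camera.sensor_h_px
    i, s = snap.angle_idx, snap.strip_idx
    if not 0 <= i < n:
        raise NormalizeError(f"angle_idx {i} outside plan")

    # absolute panorama column span of the core wedge
    x0 = int(round(i * dtheta * ppd))
    x1 = int(round((i + 1) * dtheta * ppd))
    y0 = int(round(s * plan.step_mm / s_v))
    y1 = int(round((s + 1) * plan.step_mm / s_v))
    core_w, core_h = x1 - x0, y1 - y0

    # sensor-space origin of the core region
    sx0 = int(round(x0 - (i * dtheta - (camera.fov_deg - dtheta) / 2.0) * ppd))
    sy0 = int(round(y0 - (s * plan.step_mm
                          - (camera.frame_h_mm - plan.step_mm) / 2.0) / s_v))
    h, w = snap.pixels.shape[:2]
    gl = min(guard_px, sx0)
    gr = min(guard_px, w - (sx0 + core_w))
    gt = min(guard_px, sy0)
    gb = min(guard_px, h - (sy0 + core_h))
    if sx0 < 0 or sy0 < 0 or sx0 + core_w > w or sy0 + core_h > h:
        raise NormalizeError("core wedge exceeds the sensor frame; "
                             "overlap smaller than requested crop")
    px = snap.pixels[sy0 - gt: sy0 + core_h + gb,
                     sx0 - gl: sx0 + core_w + gr]
    return CroppedSnap(pixels=px, strip_idx=s, angle_idx=i,
                       core_w=core_w, core_h=core_h,
                       guard_l=gl, guard_r=gr, guard_t=gt, guard_b=gb,
                       pan_x0=x0, pan_y0=y0)
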