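"""Assembly of cropped snaps into 360° strips and strips into the full-tube
panorama.

The locomotive's angular and vertical positioning is precise, so stitching
is geometry-first: every crop carries its dead-reckoned panorama placement,
and registration only *refines* that prior by a few pixels of translation,
scored by normalized cross-correlation over the guard-margin overlaps.
Around a closed 360° rotation the refined seam shifts must telescope back to
the start; any residual closure error is distributed uniformly across the
seams so the strip width is conserved exactly.  Overlapping guard margins
are blended with linear feathering.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass

import numpy as np

from .acquisition import AcquisitionPlan
from .normalize import CroppedSnap, panorama_dims
from .synthetic import CameraModel


class StitchError(ValueError):
    pass


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-mean normalized cross-correlation of two equal-shape images."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom < 1e-12:
        return 0.0
    return float(np.dot(a, b) / denom)


#: NCC advantage a candidate must earn per pixel of deviation from the
#: dead-reckoned prior.  The locomotive positions snaps to sub-pixel
#: precision, so a shift away from the prior needs real evidence.
PRIOR_PENALTY = 0.02


def register_pair(a: np.ndarray, b: np.ndarray,
                  prior_shift: tuple[int, int] = (0, 0),
                  search_px: int = 2,
                  prior_penalty: float = PRIOR_PENALTY,
                  ) -> tuple[tuple[int, int], float]:
    """Refine b's integer offset relative to a around a geometric prior.

    ``prior_shift`` is (dx, dy): the position of b's origin in a's pixel
    frame.  All shifts within a Chebyshev radius ``search_px`` of the prior
    are scored by NCC over the implied overlap, minus ``prior_penalty`` per
    pixel of Manhattan deviation from the prior; the best wins, ties
    resolved toward the prior.  A flat (zero-variance) overlap scores 0; if
    nothing scores above 0 the prior is returned with a warning.

    Returns ((dx, dy), raw NCC score of the winner).
    """
    pdx, pdy = int(prior_shift[0]), int(prior_shift[1])
    ha, wa = a.shape[:2]
    hb, wb = b.shape[:2]
    if search_px == 0:
        ax0, ax1 = max(0, pdx), min(wa, wb + pdx)
        ay0, ay1 = max(0, pdy), min(ha, hb + pdy)
        score = 0.0
        if ax1 - ax0 >= 2 and ay1 - ay0 >= 2:
            score = ncc(a[ay0:ay1, ax0:ax1],
                        b[ay0 - pdy:ay1 - pdy, ax0 - pdx:ax1 - pdx])
        return (pdx, pdy), score
    candidates = []
    for ddy in range(-search_px, search_px + 1):
        for ddx in range(-search_px, search_px + 1):
            candidates.append((abs(ddx) + abs(ddy), ddx, ddy))
    candidates.sort()
    best_shift, best_adj, best_raw = (pdx, pdy), -np.inf, 0.0
    for dist, ddx, ddy in candidates:
        dx, dy = pdx + ddx, pdy + ddy
        ax0, ax1 = max(0, dx), min(wa, wb + dx)
        ay0, ay1 = max(0, dy), min(ha, hb + dy)
        if ax1 - ax0 < 2 or ay1 - ay0 < 2:
            continue
        ra = a[ay0:ay1, ax0:ax1]
        rb = b[ay0 - dy:ay1 - dy, ax0 - dx:ax1 - dx]
        raw = ncc(ra, rb)
        adj = raw - prior_penalty * dist
        if adj > best_adj + 1e-12:
            best_shift, best_adj, best_raw = (dx, dy), adj, raw
    if not np.isfinite(best_adj) or best_raw <= 0.0:
        warnings.warn("flat or empty overlap: keeping geometric prior",
                      stacklevel=2)
        return (pdx, pdy), 0.0
    return best_shift, best_raw


@dataclass(frozen=True)
class StripPanorama:
    """One stitched 360° band, including retained vertical guard rows."""

    pixels: np.ndarray
    strip_idx: int
    depth_mm: float
    px_per_deg: float
    closure_residual_px: int
    row0_pan: int               # panorama row of pixels[0]
    core_y0: int                # panorama row where the unique band starts
    core_h: int
    seam_scores: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        expect = round(360.0 * self.px_per_deg)
        if abs(self.pixels.shape[1] - expect) > 1:
            raise StitchError("strip width disagrees with 360° x px_per_deg")


@dataclass(frozen=True)
class TubePanorama:
    """Full unwrapped tube image."""

    pixels: np.ndarray
    mm_per_px: float
    tube_len_mm: float
    provenance: str = ""
    seam_scores: tuple[float, ...] = ()


def _distribute_closure(deltas: list[int], residual: int) -> list[int]:
    """Spread a closure residual uniformly over the seams, exactly."""
    n = len(deltas)
    out = []
    for i, d in enumerate(deltas):
        take = round((i + 1) * residual / n) - round(i * residual / n)
        out.append(d - take)
    return out


def stitch_strip(crops: list[CroppedSnap], plan: AcquisitionPlan,
                 camera: CameraModel, search_px: int = 2) -> StripPanorama:
    """Assemble one strip's crops into a seamless 360° band.

    Crops are placed by their panorama priors, each seam refined by
    ``register_pair`` over the guard overlaps, the wraparound closure error
    distributed uniformly, and overlaps feather-blended.  The output width
    equals the nominal panorama width regardless of refinement.
    """
    if not crops:
        raise StitchError("no crops to stitch")
    n = plan.snaps_per_rotation
    by_idx = {c.angle_idx: c for c in crops}
    missing = [i for i in range(n) if i not in by_idx]
    if missing or len(crops) != n:
        raise StitchError(f"strip is missing angle_idx {missing}")
    ordered = [by_idx[i] for i in range(n)]
    W_pan, _ = panorama_dims(plan, camera)

    # seam refinement: deltas relative to the geometric prior
    ddxs, ddys, scores = [], [], []
    for i in range(n):
        a, b = ordered[i], ordered[(i + 1) % n]
        b_x0 = b.pan_x0 + (W_pan if i + 1 == n else 0)
        prior = (b_x0 - b.guard_l - (a.pan_x0 - a.guard_l),
                 (b.pan_y0 - b.guard_t) - (a.pan_y0 - a.guard_t))
        if search_px > 0 and (a.guard_r + b.guard_l) > 0:
            (dx, dy), score = register_pair(a.pixels, b.pixels, prior,
                                            search_px)
        else:
            (dx, dy), score = prior, 1.0
        ddxs.append(dx - prior[0])
        ddys.append(dy - prior[1])
        scores.append(score)
    residual = int(sum(ddxs))
    ddxs = _distribute_closure(ddxs, residual)

    # absolute placements (origin of each crop's pixel block)
    xs = [ordered[0].pan_x0 - ordered[0].guard_l]
    ys = [ordered[0].pan_y0 - ordered[0].guard_t]
    for i in range(n - 1):
        a, b = ordered[i], ordered[i + 1]
        prior_gap_x = (b.pan_x0 - b.guard_l) - (a.pan_x0 - a.guard_l)
        prior_gap_y = (b.pan_y0 - b.guard_t) - (a.pan_y0 - a.guard_t)
        xs.append(xs[i] + prior_gap_x + ddxs[i])
        ys.append(ys[i] + prior_gap_y + int(np.clip(ddys[i], -search_px,
                                                    search_px)))

    row_lo = min(ys)
    row_hi = max(y + c.pixels.shape[0] for y, c in zip(ys, ordered))
    H = row_hi - row_lo
    nch = 3 if ordered[0].pixels.ndim == 3 else 1
    acc = np.zeros((H, W_pan, nch), dtype=np.float64)
    wsum = np.zeros((H, W_pan), dtype=np.float64)
    for x0, y0, c in zip(xs, ys, ordered):
        px = c.pixels if c.pixels.ndim == 3 else c.pixels[..., None]
        h, w = px.shape[:2]
        wx = np.ones(w)
        if c.guard_l > 0:
            wx[:c.guard_l] = (np.arange(c.guard_l) + 1) / (c.guard_l + 1)
        if c.guard_r > 0:
            wx[w - c.guard_r:] = ((np.arange(c.guard_r) + 1)
                                  / (c.guard_r + 1))[::-1]
        wy = np.ones(h)
        if c.guard_t > 0:
            wy[:c.guard_t] = (np.arange(c.guard_t) + 1) / (c.guard_t + 1)
        if c.guard_b > 0:
            wy[h - c.guard_b:] = ((np.arange(c.guard_b) + 1)
                                  / (c.guard_b + 1))[::-1]
        wgt = np.outer(wy, wx)
        cols = (np.arange(x0, x0 + w))[None, :] % W_pan
        rows = np.arange(y0 - row_lo, y0 - row_lo + h)[:, None]
        acc[rows, cols, :] += (wgt[..., None] * px)
        wsum[rows, cols] += wgt
    out = np.where(wsum[..., None] > 0, acc / np.maximum(wsum[..., None],
                                                         1e-12), 0.0)
    out = out.astype(np.float32)
    if ordered[0].pixels.ndim == 2:
        out = out[..., 0]
    return StripPanorama(
        pixels=out, strip_idx=ordered[0].strip_idx,
        depth_mm=float(ordered[0].strip_idx * plan.step_mm),
        px_per_deg=W_pan / 360.0, closure_residual_px=residual,
        row0_pan=row_lo, core_y0=ordered[0].pan_y0,
        core_h=ordered[0].core_h, seam_scores=tuple(scores))


def _register_bands(a: StripPanorama, b: StripPanorama,
                    search_px: int) -> tuple[int, int, float]:
    """Refine (roll_dx, dy) of band b against band a over their overlap."""
    prior_dy = b.row0_pan - a.row0_pan
    best = (0, prior_dy, -np.inf, 0.0)
    for ddy in range(-search_px, search_px + 1):
        dy = prior_dy + ddy
        ay0, ay1 = max(0, dy), min(a.pixels.shape[0], b.pixels.shape[0] + dy)
        if ay1 - ay0 < 2:
            continue
        ra = a.pixels[ay0:ay1]
        for dx in range(-search_px, search_px + 1):
            rb = np.roll(b.pixels, dx, axis=1)[ay0 - dy:ay1 - dy]
            raw = ncc(ra, rb)
            adj = raw - PRIOR_PENALTY * (abs(dx) + abs(ddy))
            if adj > best[2] + 1e-12:
                best = (dx, dy, adj, raw)
    if not np.isfinite(best[2]) or best[3] <= 0:
        warnings.warn("flat inter-strip overlap: keeping geometric prior",
                      stacklevel=2)
        return 0, prior_dy, 0.0
    return best[0], best[1], best[3]


def stitch_panorama(strips: list[StripPanorama], plan: AcquisitionPlan,
                    camera: CameraModel, search_px: int = 2,
                    provenance: str = "") -> TubePanorama:
    """Stack strips by depth into the full-tube panorama.

    Each strip is registered against its predecessor over the vertical
    guard overlap (a per-strip horizontal roll corrects global angular
    drift, chained from strip 0), then composited with vertical feathering
    over the guard rows.
    """
    if not strips:
        raise StitchError("no strips to stitch")
    order = sorted(strips, key=lambda s: s.strip_idx)
    idxs = [s.strip_idx for s in order]
    if idxs != list(range(idxs[0], idxs[0] + len(order))):
        raise StitchError(f"non-contiguous strip indices {idxs}")
    W_pan, _ = panorama_dims(plan, camera)
    s_v = camera.frame_h_mm / camera.sensor_h_px
    y_off = int(round(idxs[0] * plan.step_mm / s_v))
    H_pan = int(round(len(order) * plan.step_mm / s_v))

    rolls, rows, scores = [0], [order[0].row0_pan], []
    for a, b in zip(order, order[1:]):
        if search_px > 0:
            dx, dy, sc = _register_bands(a, b, search_px)
        else:
            dx, dy, sc = 0, b.row0_pan - a.row0_pan, 1.0
        rolls.append(rolls[-1] + dx)
        rows.append(rows[-1] + (dy - (b.row0_pan - a.row0_pan))
                    + (b.row0_pan - a.row0_pan))
        scores.append(sc)

    nch = 3 if order[0].pixels.ndim == 3 else 1
    acc = np.zeros((H_pan, W_pan, nch), dtype=np.float64)
    wsum = np.zeros((H_pan, W_pan), dtype=np.float64)
    for s, roll, r0 in zip(order, rolls, rows):
        px = s.pixels if s.pixels.ndim == 3 else s.pixels[..., None]
        if roll % W_pan:
            px = np.roll(px, roll, axis=1)
        h = px.shape[0]
        gt = s.core_y0 - s.row0_pan
        gb = h - gt - s.core_h
        wy = np.ones(h)
        if gt > 0:
            wy[:gt] = (np.arange(gt) + 1) / (gt + 1)
        if gb > 0:
            wy[h - gb:] = ((np.arange(gb) + 1) / (gb + 1))[::-1]
        for rr in range(h):
            pr = r0 + rr - y_off
            if 0 <= pr < H_pan:
                acc[pr] += wy[rr] * px[rr]
                wsum[pr] += wy[rr]
    out = np.where(wsum[..., None] > 0,
                   acc / np.maximum(wsum[..., None], 1e-12), 0.0)
    out = out.astype(np.float32)
    if order[0].pixels.ndim == 2:
        out = out[..., 0]
    return TubePanorama(pixels=out,
                        mm_per_px=camera.frame_h_mm / camera.sensor_h_px,
                        tube_len_mm=len(order) * plan.step_mm,
                        provenance=provenance, seam_scores=tuple(scores))


def manifest_digest(records: list[dict]) -> str:
    """Stable SHA-256 digest of a manifest for provenance tracking."""
    blob = json.dumps(records, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
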