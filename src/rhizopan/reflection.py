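"""Specular-reflection detection and removal in HSV space.

Light-source reflections on the tube wall show up as bright streaks whose
hue is displaced from the soil/root background; inspected in the HSV plane
the artifact concentrates in the hue channel.  Detection thresholds a hue
band (with optional value/saturation gates), removal fills the flagged
pixels from their surroundings, and the result is converted back to RGB.

Hue is stored in [0, 1) and treated circularly: a detection band may wrap
through zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.color import hsv2rgb, rgb2hsv
from skimage.morphology import closing, disk


class ReflectionError(ValueError):
    """Unusable input for reflection handling (e.g., single-band image)."""


def _as_float(image: np.ndarray) -> tuple[np.ndarray, bool]:
    img = np.asarray(image)
    if np.issubdtype(img.dtype, np.integer):
        return img.astype(np.float64) / 255.0, True
    return img.astype(np.float64), False


def to_hsv(image: np.ndarray) -> np.ndarray:
    """RGB -> HSV with H in [0, 1), S and V in [0, 1]."""
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ReflectionError("to_hsv needs a 3-channel RGB image")
    img, _ = _as_float(image)
    return rgb2hsv(np.clip(img, 0, 1))


def from_hsv(hsv_image: np.ndarray) -> np.ndarray:
    """HSV -> RGB, float in [0, 1]."""
    return hsv2rgb(np.clip(np.asarray(hsv_image, dtype=np.float64), 0, 1))


def hue_in_band(h: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Circular band membership: the band may wrap through hue 0."""
    h = np.asarray(h)
    if lo <= hi:
        return (h >= lo) & (h <= hi)
    return (h >= lo) | (h <= hi)


@dataclass(frozen=True)
class ReflectionMask:
    """Detected artifact pixels plus the thresholds that produced them."""

    mask: np.ndarray
    coverage_frac: float
    threshold_used: dict

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage_frac <= 1.0:
            raise ReflectionError("coverage_frac out of [0, 1]")


def _auto_hue_band(hsv: np.ndarray, v_min: float,
                   n_bins: int = 72) -> tuple[float, float] | None:
    """Pick the artifact band as the isolated secondary hue-histogram mode.

    Restricted to bright pixels (V >= v_min) where reflections live; the
    dominant mode is the scene background, and a well-separated second mode
    is taken as the artifact.  Returns None when no secondary mode exists.
    """
    h = hsv[..., 0].ravel()
    bright = hsv[..., 2].ravel() >= v_min
    if bright.sum() < 20:
        bright = np.ones(h.shape, bool)
    hist, edges = np.histogram(h[bright], bins=n_bins, range=(0.0, 1.0))
    kernel = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
    kernel /= kernel.sum()
    smooth = np.convolve(np.concatenate([hist[-2:], hist, hist[:2]]),
                         kernel, mode="same")[2:-2]
    primary = int(np.argmax(smooth))

    def circ_dist(a: int, b: int) -> int:
        d = abs(a - b)
        return min(d, n_bins - d)

    best, best_val = None, 0.0
    for b in range(n_bins):
        if circ_dist(b, primary) < n_bins // 6:
            continue
        left, right = smooth[(b - 1) % n_bins], smooth[(b + 1) % n_bins]
        if smooth[b] >= left and smooth[b] >= right and smooth[b] > best_val:
            best, best_val = b, smooth[b]
    if best is None or best_val < 0.002 * max(bright.sum(), 1):
        return None
    # grow the band outward while the histogram stays above 5% of the mode
    floor = 0.05 * best_val
    lo = hi = best
    for _ in range(n_bins // 4):
        nxt = (lo - 1) % n_bins
        if smooth[nxt] < floor or circ_dist(nxt, primary) < 3:
            break
        lo = nxt
    for _ in range(n_bins // 4):
        nxt = (hi + 1) % n_bins
        if smooth[nxt] < floor or circ_dist(nxt, primary) < 3:
            break
        hi = nxt
    return (edges[lo], edges[hi] + (edges[1] - edges[0]))


def estimate_artifact_band(images: list[np.ndarray], v_min: float = 0.5,
                           ) -> tuple[float, float] | None:
    """Estimate the artifact hue band once from a whole scan.

    The light source — hence the artifact hue — is common to every snap of
    a session, so pooling hue/value samples across snaps is far more stable
    than per-snap histograms (a single frame may contain too few streak
    pixels to raise a secondary mode).  Returns (lo, hi) or None if no
    secondary hue mode emerges.
    """
    hs, vs = [], []
    for img in images:
        if img.ndim != 3:
            continue
        hsv = to_hsv(img)
        hs.append(hsv[..., 0].ravel())
        vs.append(hsv[..., 2].ravel())
    if not hs:
        raise ReflectionError("no RGB images to estimate a hue band from")
    pooled = np.zeros((len(np.concatenate(hs)), 1, 3))
    pooled[:, 0, 0] = np.concatenate(hs)
    pooled[:, 0, 2] = np.concatenate(vs)
    return _auto_hue_band(pooled, v_min)


def detect_reflections(image: np.ndarray, policy: str = "auto",
                       hue_band: tuple[float, float] | None = None,
                       v_min: float = 0.5, s_max: float | None = None,
                       closing_radius: int = 1) -> ReflectionMask:
    """Flag reflection pixels by hue-band thresholding.

    ``policy='auto'`` locates the artifact hue band from the hue histogram
    of bright pixels; ``policy='fixed'`` uses the supplied ``hue_band``
    (circular, may wrap through 0).  Optional gates require V >= v_min and
    S <= s_max.  A morphological closing consolidates fragmented streaks.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ReflectionError(
            "reflection detection needs an RGB image; for single-band "
            "imagery skip this stage")
    hsv = to_hsv(img)
    if policy == "fixed":
        if hue_band is None:
            raise ReflectionError("policy 'fixed' requires hue_band")
        band = tuple(hue_band)
    elif policy == "auto":
        band = _auto_hue_band(hsv, v_min)
        if band is None:
            empty = np.zeros(img.shape[:2], dtype=bool)
            return ReflectionMask(empty, 0.0,
                                  {"policy": "auto", "hue_band": None,
                                   "v_min": v_min, "s_max": s_max})
    else:
        raise ReflectionError(f"unknown policy {policy!r}")

    mask = hue_in_band(hsv[..., 0], band[0] % 1.0, band[1] % 1.0)
    mask &= hsv[..., 2] >= v_min
    if s_max is not None:
        mask &= hsv[..., 1] <= s_max
    if closing_radius > 0 and mask.any():
        mask = closing(mask, disk(closing_radius)).astype(bool)
    coverage = float(mask.mean())
    if coverage >= 1.0:
        warnings.warn("reflection mask covers the whole frame; "
                      "fill will have no valid donors", stacklevel=2)
    return ReflectionMask(mask, coverage,
                          {"policy": policy,
                           "hue_band": (band[0] % 1.0, band[1] % 1.0),
                           "v_min": v_min, "s_max": s_max})


def remove(image: np.ndarray, mask: np.ndarray | ReflectionMask,
           fill: str = "interpolate", smooth_iters: int = 4,
           donor_margin: int = 2) -> np.ndarray:
    """Replace masked pixels; all unmasked pixels pass through bit-identical.

    ``fill='interpolate'``: each masked pixel starts from its nearest donor,
    then a fixed number of diffusion passes smooth the patch into its
    surround.  Donors are taken from outside the mask *dilated* by
    ``donor_margin`` pixels, because the rim just outside a specular streak
    is usually itself contaminated; only pixels inside the original mask are
    ever written.  ``fill='clamp_hue'``: only the hue channel is replaced
    (median-filtered nearest-donor hue); saturation and value keep their
    observed values.
    """
    m = mask.mask if isinstance(mask, ReflectionMask) else np.asarray(mask)
    img = np.asarray(image)
    if m.shape != img.shape[:2]:
        raise ReflectionError("mask shape does not match image")
    out = img.copy()
    if not m.any():
        return out
    if m.all():
        return out  # no valid donors: leave untouched (caller was warned)

    contaminated = m
    if donor_margin > 0:
        grown = ndimage.binary_dilation(m, iterations=donor_margin)
        if not grown.all():
            contaminated = grown
    _, (iy, ix) = ndimage.distance_transform_edt(contaminated,
                                                 return_indices=True)
    work, was_int = _as_float(img)

    if fill == "interpolate":
        filled = work[iy, ix]
        c3 = filled.ndim == 3
        for _ in range(smooth_iters):
            blurred = np.stack(
                [ndimage.uniform_filter(filled[..., c], size=3)
                 for c in range(filled.shape[-1])], axis=-1) \
                if c3 else ndimage.uniform_filter(filled, 3)
            filled = np.where(contaminated[..., None] if c3 else contaminated,
                              blurred, filled)
        res = np.where(m[..., None] if work.ndim == 3 else m, filled, work)
    elif fill == "clamp_hue":
        if img.ndim != 3:
            raise ReflectionError("clamp_hue needs an RGB image")
        hsv = rgb2hsv(np.clip(work, 0, 1))
        donor_h = hsv[..., 0][iy, ix]
        donor_h = ndimage.median_filter(donor_h, size=5)
        hsv[..., 0] = np.where(m, donor_h, hsv[..., 0])
        res = hsv2rgb(hsv)
    else:
        raise ReflectionError(f"unknown fill policy {fill!r}")

    if was_int:
        res = np.clip(np.round(res * 255.0), 0, 255).astype(img.dtype)
    else:
        res = res.astype(img.dtype, copy=False)
    out[m] = res[m]
    return out
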