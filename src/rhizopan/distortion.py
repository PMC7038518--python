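"""Radial lens-distortion calibration and correction.

A wide-angle lens pointed at the curved interior of a minirhizotron tube
produces strong barrel-type geometric distortion.  Both effects are lumped
into a single measured radial profile: an even-order polynomial

    r_d = r_u * (1 + k1*rho^2 + k2*rho^4 + k3*rho^6),   rho = r_u / r_norm

mapping undistorted radius ``r_u`` to distorted radius ``r_d`` about a
distortion center ``(cx, cy)``.  The profile is calibrated once from a grid
target and the same corrective profile is applied to every field image.

The polynomial gives the *forward* map directly; the inverse (needed to
synthesize distorted imagery) is tabulated on a dense radius LUT and linearly
interpolated, which keeps both directions deterministic and testable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares

_LUT_KNOTS = 1024


class DistortionError(ValueError):
    """Non-physical profile or degenerate calibration geometry."""


@dataclass(frozen=True)
class DistortionProfile:
    """Radial polynomial distortion model: center, coefficients, scale."""

    cx: float
    cy: float
    k: tuple[float, float, float]
    r_norm: float
    rms_px: float | None = None

    def __post_init__(self) -> None:
        if self.r_norm <= 0:
            raise DistortionError("r_norm must be positive")
        if len(self.k) != 3:
            raise DistortionError("k must be (k1, k2, k3)")

    # -- radius maps --------------------------------------------------------
    def distort_radius(self, r_u: np.ndarray | float) -> np.ndarray | float:
        """Forward polynomial map r_u -> r_d."""
        r_u = np.asarray(r_u, dtype=np.float64)
        rho2 = (r_u / self.r_norm) ** 2
        k1, k2, k3 = self.k
        return r_u * (1.0 + rho2 * (k1 + rho2 * (k2 + rho2 * k3)))

    def undistort_radius(self, r_d: np.ndarray | float,
                         r_max: float | None = None) -> np.ndarray | float:
        """Inverse map r_d -> r_u via a dense monotone LUT."""
        r_max = 1.5 * self.r_norm if r_max is None else float(r_max)
        ru_grid = np.linspace(0.0, r_max, _LUT_KNOTS)
        rd_grid = self.distort_radius(ru_grid)
        if np.any(np.diff(rd_grid) <= 0):
            raise DistortionError("profile is not monotone on [0, r_max]")
        return np.interp(np.asarray(r_d, dtype=np.float64), rd_grid, ru_grid)

    def check_monotone(self, r_max: float) -> None:
        """Reject profiles whose r_u -> r_d map folds inside radius r_max."""
        ru = np.linspace(0.0, r_max, _LUT_KNOTS)
        if np.any(np.diff(self.distort_radius(ru)) <= 0):
            raise DistortionError(
                f"distortion profile non-monotone within r = {r_max:.1f} px")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {"cx": self.cx, "cy": self.cy, "k": list(self.k),
                "r_norm": self.r_norm, "rms_px": self.rms_px}

    @classmethod
    def from_dict(cls, d: dict) -> "DistortionProfile":
        return cls(cx=d["cx"], cy=d["cy"], k=tuple(d["k"]),
                   r_norm=d["r_norm"], rms_px=d.get("rms_px"))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "DistortionProfile":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def identity_profile(shape_hw: tuple[int, int]) -> DistortionProfile:
    """Zero-coefficient profile centered on an image of the given shape."""
    h, w = shape_hw
    return DistortionProfile(cx=(w - 1) / 2.0, cy=(h - 1) / 2.0,
                             k=(0.0, 0.0, 0.0),
                             r_norm=float(np.hypot(w, h) / 2.0))


# ---------------------------------------------------------------------------
# point maps
# ---------------------------------------------------------------------------

def forward_distort_points(points: np.ndarray,
                           profile: DistortionProfile) -> np.ndarray:
    """Apply r_u -> r_d to (N, 2) points given as (x, y) columns."""
    pts = np.asarray(points, dtype=np.float64)
    if not any(profile.k):
        return pts.copy()
    d = pts - np.array([profile.cx, profile.cy])
    r = np.hypot(d[:, 0], d[:, 1])
    rd = np.asarray(profile.distort_radius(r))
    scale = np.where(r > 0, rd / np.where(r > 0, r, 1.0), 1.0)
    return np.array([profile.cx, profile.cy]) + d * scale[:, None]


def undistort_points(points: np.ndarray,
                     profile: DistortionProfile) -> np.ndarray:
    """Numerically invert the radial map on (N, 2) (x, y) points."""
    pts = np.asarray(points, dtype=np.float64)
    if not any(profile.k):
        return pts.copy()
    d = pts - np.array([profile.cx, profile.cy])
    r = np.hypot(d[:, 0], d[:, 1])
    r_max_needed = max(float(r.max(initial=0.0)) * 1.2, profile.r_norm) * 1.5
    ru = np.asarray(profile.undistort_radius(r, r_max=r_max_needed))
    scale = np.where(r > 0, ru / np.where(r > 0, r, 1.0), 1.0)
    return np.array([profile.cx, profile.cy]) + d * scale[:, None]


# ---------------------------------------------------------------------------
# image warps
# ---------------------------------------------------------------------------

def _radial_resample(image: np.ndarray, profile: DistortionProfile,
                     source_radius, fill: float) -> np.ndarray:
    """Resample ``image`` so output radius r maps to source radius f(r)."""
    img = np.asarray(image)
    h, w = img.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    dx, dy = xx - profile.cx, yy - profile.cy
    r = np.hypot(dx, dy)
    r_src = np.asarray(source_radius(r))
    scale = np.where(r > 0, r_src / np.where(r > 0, r, 1.0), 1.0)
    sx = profile.cx + dx * scale
    sy = profile.cy + dy * scale
    coords = np.stack([sy.ravel(), sx.ravel()])

    def _one(band: np.ndarray) -> np.ndarray:
        out = ndimage.map_coordinates(band.astype(np.float64), coords,
                                      order=1, mode="constant", cval=fill)
        return out.reshape(h, w)

    if img.ndim == 2:
        res = _one(img)
    else:
        res = np.stack([_one(img[..., c]) for c in range(img.shape[-1])],
                       axis=-1)
    return res.astype(img.dtype) if np.issubdtype(img.dtype, np.integer) \
        else res.astype(img.dtype, copy=False)


def forward_distort(image: np.ndarray, profile: DistortionProfile,
                    fill: float = 0.0) -> np.ndarray:
    """Render the distorted view of an undistorted image.

    Output pixels live at distorted radii, so each is pulled from the
    undistorted source at the numerically inverted radius.
    """
    h, w = np.asarray(image).shape[:2]
    r_frame = float(np.hypot(max(profile.cx, w - 1 - profile.cx),
                             max(profile.cy, h - 1 - profile.cy)))
    profile.check_monotone(r_frame)
    r_max = max(r_frame * 1.2, profile.r_norm) * 1.5
    return _radial_resample(
        image, profile,
        lambda r: profile.undistort_radius(r, r_max=r_max), fill)


def correct(image: np.ndarray, profile: DistortionProfile,
            fill: float = 0.0) -> np.ndarray:
    """Undo the calibrated distortion on an image.

    Each output (undistorted) pixel samples the distorted input at the
    polynomial's forward radius; bilinear interpolation throughout.
    """
    h, w = np.asarray(image).shape[:2]
    r_frame = float(np.hypot(max(profile.cx, w - 1 - profile.cx),
                             max(profile.cy, h - 1 - profile.cy)))
    profile.check_monotone(r_frame)
    return _radial_resample(image, profile, profile.distort_radius, fill)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def _check_geometry(undistorted: np.ndarray, center: np.ndarray,
                    r_norm: float) -> None:
    pts = undistorted - undistorted.mean(axis=0)
    sv = np.linalg.svd(pts, compute_uv=False)
    if sv[-1] < 1e-6 * max(sv[0], 1.0):
        raise DistortionError("collinear calibration points: fit is degenerate")
    r = np.hypot(*(undistorted - center).T)
    distinct = np.unique(np.round(r / (0.02 * r_norm)))
    if distinct.size < 3:
        raise DistortionError(
            "calibration points span fewer than 3 distinct radii")


def calibrate(undistorted_points: np.ndarray, distorted_points: np.ndarray,
              r_norm: float | None = None,
              center0: tuple[float, float] | None = None) -> DistortionProfile:
    """Fit (k1, k2, k3, cx, cy) to point correspondences by least squares.

    ``undistorted_points`` are the ideal target positions (x, y);
    ``distorted_points`` their observed positions in the image.  Needs at
    least 12 pairs spanning at least 3 distinct radii.  The fitted profile
    records the RMS reprojection residual in pixels.
    """
    u = np.asarray(undistorted_points, dtype=np.float64)
    d = np.asarray(distorted_points, dtype=np.float64)
    if u.shape != d.shape or u.ndim != 2 or u.shape[1] != 2:
        raise DistortionError("point arrays must both be (N, 2)")
    if len(u) < 12:
        raise DistortionError("need at least 12 correspondences")
    c0 = np.asarray(center0 if center0 is not None else u.mean(axis=0),
                    dtype=np.float64)
    if r_norm is None:
        r_norm = float(np.hypot(*(u - c0).T).max())
    _check_geometry(u, c0, r_norm)

    def residuals(theta: np.ndarray) -> np.ndarray:
        k1, k2, k3, cx, cy = theta
        prof = DistortionProfile(cx=cx, cy=cy, k=(k1, k2, k3), r_norm=r_norm)
        return (forward_distort_points(u, prof) - d).ravel()

    x0 = np.array([0.0, 0.0, 0.0, c0[0], c0[1]])
    sol = least_squares(residuals, x0, method="lm", xtol=1e-15, ftol=1e-15,
                        gtol=1e-15, max_nfev=10000)
    k1, k2, k3, cx, cy = sol.x
    rms = float(np.sqrt(np.mean(np.sum(sol.fun.reshape(-1, 2) ** 2, axis=1))))
    prof = DistortionProfile(cx=float(cx), cy=float(cy),
                             k=(float(k1), float(k2), float(k3)),
                             r_norm=float(r_norm), rms_px=rms)
    r_frame = float(np.hypot(*(u - np.array([cx, cy])).T).max())
    prof.check_monotone(r_frame)
    return prof


# ---------------------------------------------------------------------------
# grid-target helpers (synthesize, detect, calibrate from an image)
# ---------------------------------------------------------------------------

def make_dot_grid(shape_hw: tuple[int, int], spacing: int = 40,
                  dot_radius: float = 3.0, margin: int = 24) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize a calibration target: bright Gaussian dots on black.

    Returns (image float in [0,1], ideal dot centers as (N, 2) x/y).
    """
    h, w = shape_hw
    xs = np.arange(margin, w - margin + 1, spacing, dtype=np.float64)
    ys = np.arange(margin, h - margin + 1, spacing, dtype=np.float64)
    centers = np.array([(x, y) for y in ys for x in xs])
    img = np.zeros((h, w), dtype=np.float64)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    for x, y in centers:
        img += np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * dot_radius ** 2))
    return np.clip(img, 0, 1), centers


def detect_dots(image: np.ndarray, threshold: float = 0.3) -> np.ndarray:
    """Centroids of bright blobs in a grid-target image, as (N, 2) x/y."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 3:
        img = img.mean(axis=-1)
    mask = img > threshold * img.max()
    labels, n = ndimage.label(mask)
    if n == 0:
        raise DistortionError("no dots detected in grid image")
    cms = ndimage.center_of_mass(img, labels, index=np.arange(1, n + 1))
    return np.array([(x, y) for y, x in cms])


def calibrate_grid(distorted_image: np.ndarray, ideal_centers: np.ndarray,
                   **kwargs) -> DistortionProfile:
    """Calibrate from a distorted image of a known dot grid.

    Detected blob centroids are matched to the nearest ideal lattice point
    (valid while distortion displaces dots by less than half the spacing).
    """
    detected = detect_dots(distorted_image)
    ideal = np.asarray(ideal_centers, dtype=np.float64)
    dists = np.linalg.norm(detected[:, None, :] - ideal[None, :, :], axis=-1)
    nearest = np.argmin(dists, axis=1)
    if len(np.unique(nearest)) < len(detected):
        raise DistortionError("ambiguous dot-to-lattice matching")
    return calibrate(ideal[nearest], detected, **kwargs)
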