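"""Synthetic cylindrical tube scenes and a degraded snap renderer.

Field imagery from a buried minirhizotron tube is not redistributable, so the
pipeline is exercised against simulated scenes with known ground truth: a
soil-textured cylinder interior (unwrapped to a plane: width maps to the
tube circumference, height to tube length) crossed by bright curvilinear
roots.  A camera model then renders individual snaps of angular windows,
degraded the way the field prototype's images were degraded — barrel
distortion from the wide-angle lens and tube curvature, specular reflection
streaks from the light source, per-snap exposure variation, vignetting and
sensor noise.

Geometry conventions: angle 0 at the tube top increasing clockwise viewed
from the open end; depth 0 at the top of the imaged window increasing
downward; image origin top-left, row-major.  All imagery is float32 in
[0, 1] in memory and 8-bit on disk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.color import hsv2rgb, rgb2hsv

from .acquisition import AcquisitionPlan
from .distortion import DistortionProfile, forward_distort

#: LED wavelengths (nm) available for multispectral acquisition.
MULTISPECTRAL_BANDS: tuple[int, ...] = (850, 700, 630, 610, 590, 555, 525,
                                        475, 465, 395)

_SOIL_RGB = np.array([0.42, 0.30, 0.20])      # moist loam against acrylic
_ROOT_RGB = np.array([0.88, 0.82, 0.68])      # young root, near-white
_SOIL_NOISE_AMP = 0.06


class SceneError(ValueError):
    """Invalid scene or render geometry."""


@dataclass(frozen=True)
class RootParams:
    """Controls the simulated root population on the tube wall."""

    n_roots: int = 6
    mean_width_mm: float = 1.2
    contrast: float = 0.5          # root brightness above soil, [0, 1] scale
    branching_prob: float = 0.25   # per-step probability of spawning a branch


@dataclass(frozen=True)
class ReflectionParams:
    """Specular streaks left by the light source on the tube surface."""

    n_streaks: int = 2
    width_px: float = 2.5     # ~0.7 mm FWHM: thin specular line on acrylic
    value_boost: float = 0.4
    saturation_drop: float = 0.6
    artifact_hue: float = 0.83     # violet: separable from soil/root hues
    hue_blend: float = 0.9


@dataclass(frozen=True)
class CameraModel:
    """Rendering camera: optics, sensor, and degradation strengths."""

    fov_deg: float = 60.0
    sensor_w_px: int = 120
    sensor_h_px: int = 101
    frame_h_mm: float = 28.0
    forward_distortion: DistortionProfile | None = None
    vignette_strength: float = 0.0
    exposure_jitter_sd: float = 0.0
    reflection: ReflectionParams | None = None
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.sensor_w_px <= 0 or self.sensor_h_px <= 0:
            raise SceneError("sensor dimensions must be positive")
        if self.noise_sd < 0:
            raise SceneError("noise_sd must be non-negative")


@dataclass(frozen=True)
class Snap:
    """One rendered frame plus its position metadata."""

    pixels: np.ndarray            # float32 [0,1], (H, W, 3) or (H, W)
    strip_idx: int
    angle_idx: int
    angle_deg: float
    depth_mm: float
    band_nm: int | str = "RGB"
    streak_mask: np.ndarray | None = None   # simulator truth, bool (H, W)

    def __post_init__(self) -> None:
        if not 0 <= self.angle_deg < 360:
            raise SceneError("angle_deg must lie in [0, 360)")


@dataclass(frozen=True)
class TubeScene:
    """Ground-truth unwrapped cylinder interior."""

    texture: np.ndarray           # float32 [0,1], (H, W, 3)
    mm_per_px: float
    tube_id_mm: float
    tube_len_mm: float
    seed: int
    root_params: RootParams
    band_gains: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        circ = math.pi * self.tube_id_mm
        if abs(self.texture.shape[1] * self.mm_per_px - circ) > self.mm_per_px:
            raise SceneError("texture width disagrees with tube circumference")
        if any(g <= 0 for g in self.band_gains.values()):
            raise SceneError("band gains must be positive")

    @property
    def width_px(self) -> int:
        return self.texture.shape[1]

    @property
    def height_px(self) -> int:
        return self.texture.shape[0]

    @property
    def px_per_deg(self) -> float:
        return self.width_px / 360.0


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------

def _soil_background(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    """Band-limited smooth noise tinted with a soil color.

    Filtering wraps in the angular (column) axis so the left edge continues
    the right edge seamlessly.
    """
    lum = rng.standard_normal((h, w))
    lum = ndimage.gaussian_filter(lum, sigma=2.5, mode=("reflect", "wrap"))
    lum /= max(lum.std(), 1e-9)
    clump = rng.standard_normal((h, w))
    clump = ndimage.gaussian_filter(clump, sigma=9.0, mode=("reflect", "wrap"))
    clump /= max(clump.std(), 1e-9)
    shade = 1.0 + _SOIL_NOISE_AMP * lum + _SOIL_NOISE_AMP * clump
    return np.clip(_SOIL_RGB[None, None, :] * shade[..., None], 0, 1)


def _draw_root(canvas: np.ndarray, rng: np.random.Generator,
               width_px: float, branching_prob: float,
               depth_frac: float = 1.0) -> None:
    """Accumulate one random-walk root polyline with Gaussian cross-section."""
    h, w = canvas.shape
    x = rng.uniform(0, w)
    y = rng.uniform(-0.1, 0.25) * h
    heading = rng.uniform(-0.45, 0.45)          # radians off vertical
    step = max(1.0, width_px)
    length = int(depth_frac * h / step * rng.uniform(0.7, 1.3)) + 4
    sigma = max(width_px / 2.355, 0.7)          # FWHM -> sigma
    half = int(math.ceil(3 * sigma))
    for _ in range(length):
        heading += rng.normal(0, 0.12)
        heading = float(np.clip(heading, -1.1, 1.1))
        x += step * math.sin(heading)
        y += step * math.cos(heading)
        if y >= h + half:
            break
        yi, xi = int(round(y)), int(round(x)) % w
        y0, y1 = max(0, yi - half), min(h, yi + half + 1)
        if y0 >= y1:
            continue
        yy = np.arange(y0, y1)[:, None] - y
        xx = (np.arange(xi - half, xi + half + 1)[None, :] - (x % w))
        xcols = np.arange(xi - half, xi + half + 1) % w
        blob = np.exp(-(yy ** 2 + xx ** 2) / (2 * sigma ** 2))
        canvas[y0:y1, xcols] = np.maximum(canvas[y0:y1, xcols], blob)
        if rng.random() < branching_prob * 0.1:
            sub = np.random.default_rng(rng.integers(2 ** 31))
            _draw_root_from(canvas, sub, x, y, width_px * 0.7,
                            branching_prob * 0.5)


def _draw_root_from(canvas: np.ndarray, rng: np.random.Generator,
                    x0: float, y0: float, width_px: float,
                    branching_prob: float) -> None:
    h, w = canvas.shape
    x, y = x0, y0
    heading = rng.uniform(-1.0, 1.0)
    step = max(1.0, width_px)
    sigma = max(width_px / 2.355, 0.6)
    half = int(math.ceil(3 * sigma))
    for _ in range(int(h / (2 * step)) + 2):
        heading += rng.normal(0, 0.15)
        x += step * math.sin(heading)
        y += step * math.cos(heading)
        if y >= h + half or y < -half:
            break
        yi, xi = int(round(y)), int(round(x)) % w
        ylo, yhi = max(0, yi - half), min(h, yi + half + 1)
        if ylo >= yhi:
            continue
        yy = np.arange(ylo, yhi)[:, None] - y
        xx = np.arange(xi - half, xi + half + 1)[None, :] - (x % w)
        xcols = np.arange(xi - half, xi + half + 1) % w
        blob = np.exp(-(yy ** 2 + xx ** 2) / (2 * sigma ** 2))
        canvas[ylo:yhi, xcols] = np.maximum(canvas[ylo:yhi, xcols], blob)


def generate_scene(tube_id_mm: float = 63.5, tube_len_mm: float = 100.0,
                   width_px: int = 720, root_params: RootParams = RootParams(),
                   band_gains: dict | None = None,
                   seed: int = 0) -> TubeScene:
    """Build a ground-truth tube interior, deterministic for a fixed seed.

    Each root is driven by its own child seed, so increasing ``n_roots``
    adds roots without re-rolling the ones already present.
    """
    if width_px <= 0 or tube_len_mm <= 0 or tube_id_mm <= 0:
        raise SceneError("scene dimensions must be positive")
    mm_per_px = math.pi * tube_id_mm / width_px
    h = int(round(tube_len_mm / mm_per_px))
    if h <= 0:
        raise SceneError("tube too short for the chosen resolution")
    soil_rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD1A7]))
    tex = _soil_background(h, width_px, soil_rng)
    root_map = np.zeros((h, width_px), dtype=np.float64)
    width_root_px = root_params.mean_width_mm / mm_per_px
    for i in range(root_params.n_roots):
        rng_i = np.random.default_rng(np.random.SeedSequence([seed, 1, i]))
        w_i = width_root_px * rng_i.uniform(0.7, 1.4)
        _draw_root(root_map, rng_i, w_i, root_params.branching_prob)
    alpha = (root_params.contrast * root_map)[..., None]
    tex = tex * (1 - alpha) + _ROOT_RGB[None, None, :] * alpha
    return TubeScene(texture=np.clip(tex, 0, 1).astype(np.float32),
                     mm_per_px=mm_per_px, tube_id_mm=tube_id_mm,
                     tube_len_mm=tube_len_mm, seed=seed,
                     root_params=root_params,
                     band_gains=dict(band_gains or {}))


def soil_reference_ceiling(scene: TubeScene) -> float:
    """Upper bound for soil-only pixels: soil max plus 3x the texture grain."""
    return float(_SOIL_RGB.max() * (1 + 2 * _SOIL_NOISE_AMP)
                 + 3 * _SOIL_NOISE_AMP)


# ---------------------------------------------------------------------------
# snap rendering
# ---------------------------------------------------------------------------

def _sample_window(scene: TubeScene, camera: CameraModel, angle_deg: float,
                   depth_mm: float) -> np.ndarray:
    """Bilinear resample of the (angle, depth) window onto the sensor grid.

    Columns wrap around the cylinder seam; rows clamp at the tube ends.
    """
    W = scene.width_px
    ppd = scene.px_per_deg
    sw, sh = camera.sensor_w_px, camera.sensor_h_px
    cols = np.arange(sw)
    # continuous scene x of each sensor-pixel center, then to index space
    u = (angle_deg - camera.fov_deg / 2.0) * ppd \
        + (cols + 0.5) * camera.fov_deg * ppd / sw
    xi = (u - 0.5) % W
    rows = np.arange(sh)
    v = (depth_mm - camera.frame_h_mm / 2.0
         + (rows + 0.5) * camera.frame_h_mm / sh) / scene.mm_per_px
    yi = np.clip(v - 0.5, 0, scene.height_px - 1)
    # pad one wrap column so bilinear across the seam sees pixel 0 again
    tex = np.concatenate([scene.texture, scene.texture[:, :2]], axis=1)
    yy, xx = np.meshgrid(yi, xi, indexing="ij")
    coords = np.stack([yy.ravel(), xx.ravel()])
    out = np.stack([
        ndimage.map_coordinates(tex[..., c].astype(np.float64), coords,
                                order=1, mode="nearest").reshape(sh, sw)
        for c in range(tex.shape[-1])], axis=-1)
    return out


def _streak_field(camera: CameraModel, rng: np.random.Generator) -> np.ndarray:
    """Super-Gaussian vertical streak profile field in [0, 1], (H, W)."""
    p = camera.reflection
    sh, sw = camera.sensor_h_px, camera.sensor_w_px
    prof = np.zeros((sh, sw))
    rows = np.arange(sh)[:, None]
    cols = np.arange(sw)[None, :]
    for _ in range(p.n_streaks):
        x0 = rng.uniform(0.1 * sw, 0.9 * sw)
        amp = rng.uniform(0.0, 2.0)
        phase = rng.uniform(0, 2 * math.pi)
        center = x0 + amp * np.sin(2 * math.pi * rows / sh + phase)
        d = np.abs(cols - center)
        prof = np.maximum(prof, np.exp(-(d / p.width_px) ** 8))
    return prof


def render_snap(scene: TubeScene, camera: CameraModel, angle_deg: float,
                depth_mm: float, strip_idx: int = 0, angle_idx: int = 0,
                band_nm: int | str = "RGB",
                rng: np.random.Generator | None = None) -> Snap:
    """Render one degraded snap of the scene.

    Degradations apply in acquisition order: barrel distortion, vignetting,
    a log-normal exposure gain, reflection streaks, additive Gaussian noise,
    then clipping to [0, 1].  The random stream draws the same variates
    whether or not a degradation's strength is zero, so two cameras differing
    only in strengths see identical streak geometry and gains.
    """
    if not 0.0 <= depth_mm <= scene.tube_len_mm:
        raise SceneError(f"depth {depth_mm} mm outside tube"
                         f" [0, {scene.tube_len_mm}]")
    rng = rng or np.random.default_rng(0)
    img = _sample_window(scene, camera, angle_deg % 360.0, depth_mm)
    if band_nm != "RGB":
        gain = scene.band_gains.get(band_nm, 1.0)
        img = np.clip(img.mean(axis=-1, keepdims=True) * gain, 0, 1)
        img = np.repeat(img, 3, axis=-1)   # keep 3-channel until the end

    if camera.forward_distortion is not None:
        img = forward_distort(img, camera.forward_distortion, fill=0.0)

    sh, sw = camera.sensor_h_px, camera.sensor_w_px
    if camera.vignette_strength > 0:
        yy, xx = np.mgrid[0:sh, 0:sw].astype(np.float64)
        r2 = ((xx - (sw - 1) / 2) ** 2 + (yy - (sh - 1) / 2) ** 2)
        r2 /= max(r2.max(), 1e-9)
        img = img * (1.0 - camera.vignette_strength * r2)[..., None]

    gain_z = rng.standard_normal()
    img = img * math.exp(camera.exposure_jitter_sd * gain_z)

    streak_mask = None
    if camera.reflection is not None and camera.reflection.n_streaks > 0:
        prof = _streak_field(camera, rng)
        p = camera.reflection
        hsv = rgb2hsv(np.clip(img, 0, 1))
        blend = p.hue_blend * prof
        hsv[..., 0] = hsv[..., 0] * (1 - blend) + p.artifact_hue * blend
        hsv[..., 1] = hsv[..., 1] * (1 - p.saturation_drop * prof)
        hsv[..., 2] = hsv[..., 2] + p.value_boost * prof
        img = hsv2rgb(np.clip(hsv, 0, 1))
        streak_mask = prof > 0.5

    noise = rng.standard_normal(img.shape)
    if camera.noise_sd > 0:
        img = img + camera.noise_sd * noise
    img = np.clip(img, 0, 1).astype(np.float32)
    if band_nm != "RGB":
        img = img.mean(axis=-1).astype(np.float32)
    return Snap(pixels=img, strip_idx=strip_idx, angle_idx=angle_idx,
                angle_deg=angle_deg % 360.0, depth_mm=depth_mm,
                band_nm=band_nm, streak_mask=streak_mask)


# ---------------------------------------------------------------------------
# full acquisition
# ---------------------------------------------------------------------------

def default_camera(scene: TubeScene, plan: AcquisitionPlan,
                   **degradations) -> CameraModel:
    """Camera whose sensor grid matches the scene's pixel pitch."""
    sw = int(round(plan.fov_deg / 360.0 * scene.width_px))
    sh = int(round(plan.frame_h_mm / scene.mm_per_px))
    return CameraModel(fov_deg=plan.fov_deg, sensor_w_px=sw, sensor_h_px=sh,
                       frame_h_mm=plan.frame_h_mm, **degradations)


def acquire(scene: TubeScene, plan: AcquisitionPlan, camera: CameraModel,
            seed: int = 0,
            bands: list | None = None) -> tuple[list[Snap], list[dict]]:
    """Scan the scene: equally spaced snaps per strip, strips down the tube.

    Snap order follows the locomotive: all angles of strip 0, step down,
    all angles of strip 1, and so on.  With ``bands`` set, every (strip,
    angle) position is re-imaged once per wavelength.  Deterministic for a
    fixed seed (each snap draws from its own child stream keyed by strip,
    angle and band).

    Returns the snaps and a manifest (one record per snap).
    """
    n = plan.snaps_per_rotation
    dtheta = 360.0 / n
    band_list = ["RGB"] if bands is None else list(bands)
    snaps: list[Snap] = []
    manifest: list[dict] = []
    for s in range(plan.n_strips):
        depth = s * plan.step_mm
        for a in range(n):
            for bi, band in enumerate(band_list):
                rng = np.random.default_rng(
                    np.random.SeedSequence([seed, 2, s, a, bi]))
                snap = render_snap(scene, camera, a * dtheta, depth,
                                   strip_idx=s, angle_idx=a, band_nm=band,
                                   rng=rng)
                snaps.append(snap)
                manifest.append({
                    "snap_id": f"s{s:03d}_a{a:02d}_{band}",
                    "strip_idx": s, "angle_idx": a,
                    "angle_deg": a * dtheta, "depth_mm": depth,
                    "band_nm": band,
                    "filename": f"s{s:03d}_a{a:02d}_{band}.png",
                })
    return snaps, manifest
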