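"""End-to-end reconstruction pipeline: correct -> clean -> normalize ->
crop -> stitch.

The stage order is fixed (geometric correction first so every later stage
sees undistorted geometry; exposure normalization before cropping because
the overlaps it needs are discarded by the crop).  Each stage can be
skipped by flag; a skipped pipeline still stitches the raw crops.  A run
produces the tube panorama plus a machine-readable report (per-stage
timings, seam scores, mask coverage, provenance digest).
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from .acquisition import AcquisitionPlan
from .distortion import DistortionProfile, correct
from .manifest import validate_records
from .normalize import color_correct, crop_usable, exposure_normalize
from .reflection import detect_reflections, estimate_artifact_band, remove
from .stitcher import (StripPanorama, TubePanorama, manifest_digest,
                       stitch_panorama, stitch_strip)
from .synthetic import CameraModel, Snap


class ConfigError(ValueError):
    pass


#: Allowed configuration tree: key -> (type or sub-tree).  Mirrors the
#: field prototype's values as defaults.
_CONFIG_SCHEMA: dict = {
    "plan": {"fov_deg": float, "angular_overlap_frac": float,
             "frame_w_mm": float, "frame_h_mm": float, "tube_id_mm": float,
             "tube_len_mm": float, "step_mm": float},
    "camera": {"sensor_w_px": int, "sensor_h_px": int},
    "stages": {"correct": bool, "clean": bool, "normalize": bool,
               "color_correct": bool, "crop": bool},
    "distortion_profile": (str, type(None)),
    "clean": {"policy": str, "hue_band": (list, type(None)),
              "v_min": float, "s_max": (float, type(None)),
              "closing_radius": int, "fill": str},
    "crop": {"guard_px": int},
    "stitch": {"search_px": int},
}

DEFAULT_CONFIG: dict = {
    "plan": {"fov_deg": 60.0, "angular_overlap_frac": 0.4,
             "frame_w_mm": 35.0, "frame_h_mm": 28.0, "tube_id_mm": 63.5,
             "tube_len_mm": 1000.0, "step_mm": 15.0},
    "camera": {"sensor_w_px": 120, "sensor_h_px": 101},
    "stages": {"correct": False, "clean": True, "normalize": True,
               "color_correct": False, "crop": True},
    "distortion_profile": None,
    "clean": {"policy": "auto", "hue_band": None, "v_min": 0.5,
              "s_max": None, "closing_radius": 1, "fill": "interpolate"},
    "crop": {"guard_px": 8},
    "stitch": {"search_px": 2},
}


def _validate_tree(cfg: dict, schema: dict, path: str = "") -> None:
    for key, val in cfg.items():
        if key not in schema:
            raise ConfigError(f"unknown config key {path + key!r}")
        want = schema[key]
        if isinstance(want, dict):
            if not isinstance(val, dict):
                raise ConfigError(f"{path + key!r} must be a mapping")
            _validate_tree(val, want, path + key + ".")
        else:
            kinds = want if isinstance(want, tuple) else (want,)
            if float in kinds:
                kinds = kinds + (int,)
            if not isinstance(val, kinds) or isinstance(val, bool) \
                    and bool not in kinds:
                raise ConfigError(
                    f"{path + key!r} has wrong type {type(val).__name__}")


def load_config(overrides: dict | None = None) -> dict:
    """Merge user overrides into the defaults, validating keys and types."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if overrides:
        _validate_tree(overrides, _CONFIG_SCHEMA)
        for key, val in overrides.items():
            if isinstance(val, dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def plan_from_config(cfg: dict) -> AcquisitionPlan:
    return AcquisitionPlan(**cfg["plan"])


def camera_from_config(cfg: dict) -> CameraModel:
    return CameraModel(fov_deg=cfg["plan"]["fov_deg"],
                       frame_h_mm=cfg["plan"]["frame_h_mm"],
                       sensor_w_px=cfg["camera"]["sensor_w_px"],
                       sensor_h_px=cfg["camera"]["sensor_h_px"])


@dataclass
class PipelineReport:
    """Machine-readable account of one pipeline run."""

    stage_timings_s: dict = field(default_factory=dict)
    mask_coverage: list = field(default_factory=list)
    gains: dict = field(default_factory=dict)
    strip_closure_px: list = field(default_factory=list)
    strip_seam_scores: list = field(default_factory=list)
    panorama_seam_scores: list = field(default_factory=list)
    provenance: str = ""
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def content_hash(self) -> str:
        """Digest of everything except wall-clock timings."""
        d = self.to_dict()
        d.pop("stage_timings_s")
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=float).encode()).hexdigest()


def run_pipeline(snaps: list[Snap], records: list[dict], config: dict | None,
                 profile: DistortionProfile | None = None,
                 ) -> tuple[TubePanorama, PipelineReport]:
    """Reconstruct the tube panorama from raw snaps.

    ``records`` is the acquisition manifest (validated, one entry per
    snap); ``config`` any subset of :data:`DEFAULT_CONFIG`.  When the
    correction stage is enabled a calibrated ``profile`` must be supplied.
    """
    cfg = load_config(config) if not _is_full(config) else config
    validate_records(records)
    plan = plan_from_config(cfg)
    camera = camera_from_config(cfg)
    report = PipelineReport(config=cfg, provenance=manifest_digest(records))
    stages = cfg["stages"]

    def timed(name, fn):
        t0 = time.perf_counter()
        res = fn()
        report.stage_timings_s[name] = time.perf_counter() - t0
        return res

    if stages["correct"]:
        if profile is None:
            raise ConfigError(
                "correction stage enabled but no distortion profile given; "
                "calibrate one or set stages.correct: false")
        snaps = timed("correct", lambda: [
            _replace_pixels(s, correct(s.pixels, profile)) for s in snaps])

    if stages["clean"]:
        def _clean():
            out = []
            cc = cfg["clean"]
            kw = dict(policy=cc["policy"], v_min=cc["v_min"],
                      s_max=cc["s_max"],
                      closing_radius=cc["closing_radius"])
            if cc["hue_band"] is not None:
                kw["policy"] = "fixed"
                kw["hue_band"] = tuple(cc["hue_band"])
            elif cc["policy"] == "auto":
                # the artifact hue is a property of the light source, not of
                # one frame: estimate the band once from the whole scan
                band = estimate_artifact_band(
                    [s.pixels for s in snaps if s.pixels.ndim == 3],
                    v_min=cc["v_min"])
                if band is not None:
                    kw["policy"] = "fixed"
                    kw["hue_band"] = band
            for s in snaps:
                if s.pixels.ndim != 3:
                    out.append(s)
                    report.mask_coverage.append(0.0)
                    continue
                m = detect_reflections(s.pixels, **kw)
                report.mask_coverage.append(m.coverage_frac)
                out.append(_replace_pixels(
                    s, remove(s.pixels, m, fill=cc["fill"])))
            return out
        snaps = timed("clean", _clean)

    if stages["normalize"]:
        def _norm():
            normed, gains = exposure_normalize(snaps, plan, camera)
            report.gains = {f"{k[0]}:{k[1]}": v for k, v in gains.items()}
            if stages["color_correct"]:
                normed = [_replace_pixels(s, color_correct(s.pixels)[0])
                          for s in normed]
            return normed
        snaps = timed("normalize", _norm)

    guard = cfg["crop"]["guard_px"] if stages["crop"] else 0
    crops = timed("crop", lambda: [
        crop_usable(s, plan, camera, guard_px=guard) for s in snaps])

    def _stitch():
        strips: list[StripPanorama] = []
        for si in sorted({c.strip_idx for c in crops}):
            strip = stitch_strip([c for c in crops if c.strip_idx == si],
                                 plan, camera,
                                 search_px=cfg["stitch"]["search_px"])
            report.strip_closure_px.append(strip.closure_residual_px)
            report.strip_seam_scores.append(list(strip.seam_scores))
            strips.append(strip)
        pano = stitch_panorama(strips, plan, camera,
                               search_px=cfg["stitch"]["search_px"],
                               provenance=report.provenance)
        report.panorama_seam_scores = list(pano.seam_scores)
        return pano
    pano = timed("stitch", _stitch)
    return pano, report


def _replace_pixels(s: Snap, pixels: np.ndarray) -> Snap:
    return Snap(pixels=np.asarray(pixels, dtype=np.float32),
                strip_idx=s.strip_idx, angle_idx=s.angle_idx,
                angle_deg=s.angle_deg, depth_mm=s.depth_mm,
                band_nm=s.band_nm, streak_mask=s.streak_mask)


def _is_full(cfg) -> bool:
    return isinstance(cfg, dict) and set(cfg) == set(DEFAULT_CONFIG)
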