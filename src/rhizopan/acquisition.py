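"""Acquisition planning and power-budget arithmetic for a rotating
minirhizotron tube camera.

The imaging head carries a wide-angle camera on a two-axis locomotive: it
rotates inside a transparent tube buried in soil, taking overlapping snaps
around 360°, then steps vertically and repeats.  Everything in this module is
closed-form: how many snaps a rotation needs for a given field of view and
angular overlap, how many 360° strips a tube of a given length needs, what one
imaging cycle costs in watt-hours, and how big a battery and solar panel must
be to run unattended.

Two numeric styles are supported throughout: exact double-precision
arithmetic (default) and a ``paper_rounding`` mode that rounds intermediates
the way an engineer sizing hardware on paper would (whole Wh for daily energy,
nearest-integer Wh/Ah/W for final sizes, nearest minute for transfer time).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


class PlanError(ValueError):
    """Raised for physically meaningless planner inputs."""


def _apply_rounding(x: float, rounding: str | None) -> float:
    if rounding is None:
        return x
    if rounding == "nearest":
        return float(round(x))
    if rounding == "ceil":
        return float(math.ceil(x))
    raise PlanError(f"unknown rounding mode {rounding!r}")


# ---------------------------------------------------------------------------
# coverage geometry
# ---------------------------------------------------------------------------

def snaps_per_rotation(fov_deg: float, overlap_frac: float) -> int:
    """Snaps needed for full 360° coverage with the requested angular overlap.

    Each snap contributes ``fov_deg * (1 - overlap_frac)`` degrees of new
    coverage, so ``ceil(360 / (fov * (1 - overlap)))`` snaps close the circle.
    A 60° lens needs 6 snaps with no overlap and 10 snaps at 40% overlap.
    """
    if not 0 < fov_deg <= 180:
        raise PlanError(f"fov_deg must be in (0, 180], got {fov_deg}")
    if not 0 <= overlap_frac < 1:
        raise PlanError(f"overlap_frac must be in [0, 1), got {overlap_frac}")
    effective = fov_deg * (1.0 - overlap_frac)
    # guard float droop on exact divisions (360 / 45 must give 8, not 9)
    n = 360.0 / effective
    return int(math.ceil(round(n, 9)))


def strips_for_length(tube_len_mm: float, step_mm: float) -> int:
    """Number of 360° strips for a tube length at a fixed vertical step.

    ``floor(tube_len / step)``: 1000 mm at 15 mm steps gives 66 strips.
    """
    if tube_len_mm <= 0 or step_mm <= 0:
        raise PlanError("tube length and step must be positive")
    return int(math.floor(round(tube_len_mm / step_mm, 9)))


def strip_overlap_fraction(frame_h_mm: float, step_mm: float) -> float:
    """Vertical overlap between consecutive strips: (frame_h - step)/frame_h."""
    if frame_h_mm <= 0 or step_mm <= 0:
        raise PlanError("frame height and step must be positive")
    if step_mm > frame_h_mm:
        raise PlanError("step larger than frame height leaves coverage gaps")
    return (frame_h_mm - step_mm) / frame_h_mm


def realized_angular_overlap(fov_deg: float, n_snaps: int) -> float:
    """Overlap actually achieved by n equally spaced snaps: 1 - 360/(n*fov)."""
    return 1.0 - 360.0 / (n_snaps * fov_deg)


def manual_coverage(
    frame_w_mm: float,
    frame_h_mm: float,
    tube_id_mm: float,
    tube_len_mm: float,
    vertical_count_override: int | None = None,
) -> tuple[int, int, int]:
    """Picture counts for manual (non-overlapped) full coverage of a tube.

    Angular count is the minimum number of ``frame_w_mm``-wide frames covering
    the circumference, ``ceil(pi * tube_id / frame_w)``; vertical count is
    ``round(tube_len / frame_h)`` unless overridden.  For a 1 m, 63.5 mm ID
    tube imaged in 34 x 24 mm frames with 40 vertical positions this is
    6 x 40 = 240 pictures.

    Returns ``(angular_count, vertical_count, total)``.
    """
    if min(frame_w_mm, frame_h_mm, tube_id_mm, tube_len_mm) <= 0:
        raise PlanError("all dimensions must be positive")
    angular = int(math.ceil(round(math.pi * tube_id_mm / frame_w_mm, 9)))
    if vertical_count_override is not None:
        vertical = int(vertical_count_override)
    else:
        vertical = int(round(tube_len_mm / frame_h_mm))
    return angular, vertical, angular * vertical


def manual_total(angular_count: int, vertical_count: int) -> int:
    """Product of explicitly supplied angular and vertical counts.

    Exists for overlapped manual plans whose two counts follow different
    rounding conventions and so cannot be derived from one rule.
    """
    if angular_count < 0 or vertical_count < 0:
        raise PlanError("counts must be non-negative")
    return angular_count * vertical_count


def manual_time_s(n_pictures: int, s_per_positioning: float = 20.0) -> float:
    """Operator time for manual imaging: pictures x seconds per positioning."""
    return n_pictures * s_per_positioning


@dataclass(frozen=True)
class AcquisitionPlan:
    """Scan geometry for one tube: lens, overlaps, step, and derived counts.

    Defaults are the field prototype's values: 60° lens at 40% angular
    overlap, 35 x 28 mm frame footprint, 63.5 mm ID tube, 15 mm vertical step.
    ``snaps_per_rotation`` and ``n_strips`` are derived when left at 0.
    """

    fov_deg: float = 60.0
    angular_overlap_frac: float = 0.4
    frame_w_mm: float = 35.0
    frame_h_mm: float = 28.0
    tube_id_mm: float = 63.5
    tube_len_mm: float = 1000.0
    step_mm: float = 15.0
    snaps_per_rotation: int = 0
    n_strips: int = 0

    def __post_init__(self) -> None:
        if self.snaps_per_rotation == 0:
            object.__setattr__(
                self, "snaps_per_rotation",
                snaps_per_rotation(self.fov_deg, self.angular_overlap_frac))
        if self.n_strips == 0:
            object.__setattr__(
                self, "n_strips",
                strips_for_length(self.tube_len_mm, self.step_mm))
        if self.snaps_per_rotation < math.ceil(360.0 / self.fov_deg):
            raise PlanError("snaps_per_rotation cannot cover 360°")
        if self.step_mm > self.frame_h_mm:
            raise PlanError("step_mm exceeds frame height: vertical gaps")
        if self.n_strips * self.step_mm > self.tube_len_mm + self.step_mm:
            raise PlanError("strip count overruns the tube length")

    @property
    def angle_step_deg(self) -> float:
        return 360.0 / self.snaps_per_rotation

    @property
    def strip_overlap(self) -> float:
        return strip_overlap_fraction(self.frame_h_mm, self.step_mm)

    def total_images(self) -> int:
        return total_images(self)

    def report(self) -> dict:
        """Planner summary as a plain dict (JSON-friendly)."""
        return {
            "fov_deg": self.fov_deg,
            "angular_overlap_frac": self.angular_overlap_frac,
            "realized_angular_overlap": realized_angular_overlap(
                self.fov_deg, self.snaps_per_rotation),
            "snaps_per_rotation": self.snaps_per_rotation,
            "angle_step_deg": self.angle_step_deg,
            "tube_id_mm": self.tube_id_mm,
            "tube_len_mm": self.tube_len_mm,
            "step_mm": self.step_mm,
            "n_strips": self.n_strips,
            "strip_overlap_frac": self.strip_overlap,
            "total_images": self.total_images(),
        }


def total_images(plan: AcquisitionPlan) -> int:
    """Images in a full scan: strips x snaps per rotation (66 x 10 = 660)."""
    return plan.n_strips * plan.snaps_per_rotation


def acquisition_time(plan: AcquisitionPlan, s_per_strip: float = 3.5,
                     s_per_step: float = 2.9) -> float:
    """Automated scan time: n_strips x rotation time + (n_strips - 1) steps.

    Defaults (3.5 s per 10-snap rotation, 2.9 s per 15 mm step) put a 66-strip
    tube at about 7 minutes.
    """
    if plan.n_strips < 1:
        raise PlanError("plan has no strips")
    return plan.n_strips * s_per_strip + (plan.n_strips - 1) * s_per_step


# ---------------------------------------------------------------------------
# energy budget
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComponentLoad:
    """One powered component's draw during an imaging cycle.

    ``peak_w`` may exceed or fall below ``power_w`` (a controller can average
    1.75 W against a 5 W peak); when omitted it defaults to ``power_w``.
    """

    name: str
    power_w: float
    active_s: float
    peak_w: float | None = None

    def __post_init__(self) -> None:
        if self.power_w < 0 or self.active_s < 0:
            raise PlanError(f"{self.name}: power and active time must be >= 0")

    @property
    def energy_wh(self) -> float:
        return self.power_w * self.active_s / 3600.0

    @property
    def peak(self) -> float:
        return self.power_w if self.peak_w is None else self.peak_w


#: Measured per-cycle loads of the field prototype (camera, two positioning
#: motors, LED light source, controller + single-board computer).
PROTOTYPE_LOADS: tuple[ComponentLoad, ...] = (
    ComponentLoad("camera", 1.2, 2178),
    ComponentLoad("motor-1", 3.0, 1980),
    ComponentLoad("motor-2", 5.0, 198),
    ComponentLoad("light source", 0.4, 2178),
    ComponentLoad("controller & SBC", 1.75, 7200, peak_w=5.0),
)


def energy_per_cycle(components: list[ComponentLoad] | tuple[ComponentLoad, ...]) -> float:
    """Total Wh for one imaging cycle: sum of power x active time / 3600."""
    return float(sum(c.energy_wh for c in components))


def peak_power(components: list[ComponentLoad] | tuple[ComponentLoad, ...]) -> float:
    """Worst-case instantaneous draw: sum of per-component peak watts."""
    return float(sum(c.peak for c in components))


def daily_energy(per_cycle_wh: float, images_per_day: int,
                 rounding: str | None = None) -> float:
    """Wh per day = per-cycle energy x imaging cycles per day."""
    if per_cycle_wh < 0 or images_per_day < 0:
        raise PlanError("energy and image count must be non-negative")
    return _apply_rounding(per_cycle_wh * images_per_day, rounding)


def system_daily_energy(daily_wh: float, conversion_eff: float,
                        rounding: str | None = None) -> float:
    """Daily Wh at the source after power-conversion losses."""
    if not 0 < conversion_eff <= 1:
        raise PlanError("conversion efficiency must be in (0, 1]")
    return _apply_rounding(daily_wh / conversion_eff, rounding)


def battery_wh(system_daily_wh: float, days_autonomy: float, dod: float,
               rounding: str | None = None) -> float:
    """Battery size: daily energy x days of autonomy / depth of discharge."""
    if not 0 < dod <= 1:
        raise PlanError("depth of discharge must be in (0, 1]")
    if days_autonomy <= 0 or system_daily_wh < 0:
        raise PlanError("autonomy must be positive, energy non-negative")
    return _apply_rounding(system_daily_wh * days_autonomy / dod, rounding)


def battery_ah(battery_capacity_wh: float, battery_v: float,
               rounding: str | None = None) -> float:
    """Amp-hours at the bus voltage.  ``rounding='ceil'`` guarantees the
    sized battery holds at least the requested Wh."""
    if battery_v <= 0:
        raise PlanError("battery voltage must be positive")
    return _apply_rounding(battery_capacity_wh / battery_v, rounding)


def panel_w(battery_capacity_wh: float, charge_eff: float, charge_h: float,
            rounding: str | None = None) -> float:
    """Solar panel watts to refill the battery in one day's charging window."""
    if not 0 < charge_eff <= 1:
        raise PlanError("charging efficiency must be in (0, 1]")
    if charge_h <= 0:
        raise PlanError("charge time must be positive")
    return _apply_rounding(battery_capacity_wh / (charge_eff * charge_h), rounding)


@dataclass(frozen=True)
class EnergyBudget:
    """Full power-system sizing problem for unattended field operation."""

    components: tuple[ComponentLoad, ...] = PROTOTYPE_LOADS
    images_per_day: int = 12
    conversion_eff: float = 0.8
    days_autonomy: float = 2.0
    dod: float = 0.8
    battery_v: float = 12.0
    charge_eff: float = 0.75
    charge_h: float = 8.0

    def __post_init__(self) -> None:
        for frac, name in ((self.conversion_eff, "conversion_eff"),
                           (self.dod, "dod"), (self.charge_eff, "charge_eff")):
            if not 0 < frac <= 1:
                raise PlanError(f"{name} must be in (0, 1], got {frac}")

    def report(self, paper_rounding: bool = False) -> dict:
        """Sizing chain from per-cycle Wh down to battery Ah and panel W.

        With ``paper_rounding`` the daily energy is rounded to whole Wh
        before conversion losses, battery sizing runs on the unrounded
        post-conversion value, and the final Wh/Ah/W are rounded to the
        nearest integer — the back-of-envelope chain a datasheet shows.
        """
        cycle = energy_per_cycle(self.components)
        daily = daily_energy(cycle, self.images_per_day)
        daily_out = daily_energy(cycle, self.images_per_day,
                                 rounding="nearest" if paper_rounding else None)
        system_daily = system_daily_energy(daily_out, self.conversion_eff)
        batt_wh = battery_wh(system_daily, self.days_autonomy, self.dod)
        r = "nearest" if paper_rounding else None
        return {
            "per_component_wh": {c.name: c.energy_wh for c in self.components},
            "energy_per_cycle_wh": cycle,
            "peak_power_w": peak_power(self.components),
            "daily_energy_wh": daily_out,
            "daily_energy_wh_exact": daily,
            "system_daily_energy_wh": _apply_rounding(system_daily, r),
            "battery_wh": _apply_rounding(batt_wh, r),
            "battery_ah": battery_ah(_apply_rounding(batt_wh, r), self.battery_v,
                                     rounding=r),
            "panel_w": panel_w(_apply_rounding(batt_wh, r), self.charge_eff,
                               self.charge_h, rounding=r),
            "paper_rounding": paper_rounding,
        }


# ---------------------------------------------------------------------------
# wireless transfer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransferSpec:
    """Bulk image transfer over a wireless link."""

    kb_per_image: float = 310.0
    n_images: int = 660
    link_mbps: float = 3.0
    overhead_frac: float = 0.10

    def __post_init__(self) -> None:
        if min(self.kb_per_image, self.n_images, self.link_mbps) <= 0:
            raise PlanError("transfer sizes and rate must be positive")
        if self.overhead_frac < 0:
            raise PlanError("overhead fraction must be non-negative")


def transfer_time(spec: TransferSpec, rounding: str | None = None) -> float:
    """Seconds to move a scan's images over the link.

    Total payload is rounded to whole megabytes first (the unit the link
    budget is quoted in); ``rounding='nearest'`` then snaps the result to the
    nearest whole minute.  660 images of 310 kB over 3 Mbps with 10% protocol
    overhead is 205 MB and about 10 minutes.
    """
    mb_total = round(spec.n_images * spec.kb_per_image / 1000.0)
    seconds = mb_total * 8.0 * (1.0 + spec.overhead_frac) / spec.link_mbps
    if rounding == "nearest":
        return float(round(seconds / 60.0) * 60)
    return seconds
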