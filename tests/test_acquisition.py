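"""Planner and power-budget arithmetic."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhizopan.acquisition import (PROTOTYPE_LOADS, AcquisitionPlan,
                                  ComponentLoad, EnergyBudget, PlanError,
                                  TransferSpec, acquisition_time, battery_ah,
                                  battery_wh, daily_energy, energy_per_cycle,
                                  manual_coverage, manual_time_s,
                                  manual_total, panel_w, peak_power,
                                  realized_angular_overlap,
                                  snaps_per_rotation, strip_overlap_fraction,
                                  strips_for_length, system_daily_energy,
                                  total_images, transfer_time)


@pytest.mark.parametrize("fov,overlap,expected", [
    (60, 0.4, 10),
    (60, 0.0, 6),
    (90, 0.5, 8),
])
def test_snaps_per_rotation(fov, overlap, expected):
    assert snaps_per_rotation(fov, overlap) == expected


@pytest.mark.parametrize("fov,overlap", [(0, 0.2), (-10, 0.2), (60, 1.0),
                                         (60, -0.1), (200, 0.0)])
def test_snaps_per_rotation_domain_errors(fov, overlap):
    with pytest.raises(PlanError):
        snaps_per_rotation(fov, overlap)


@pytest.mark.parametrize("length,step,expected", [
    (1000, 15, 66),
    (15, 15, 1),
    (320, 15, 21),
])
def test_strips_for_length(length, step, expected):
    assert strips_for_length(length, step) == expected


@pytest.mark.parametrize("kwargs,expected", [
    (dict(tube_len_mm=1000.0), 660),                       # 66 x 10
    (dict(tube_len_mm=320.0, snaps_per_rotation=11), 231),  # field trial
    (dict(tube_len_mm=10.0), 0),                            # degenerate
])
def test_total_images(kwargs, expected):
    assert total_images(AcquisitionPlan(**kwargs)) == expected


def test_manual_coverage_prototype_tube():
    angular, vertical, total = manual_coverage(34, 24, 63.5, 1000,
                                               vertical_count_override=40)
    assert (angular, vertical, total) == (6, 40, 240)
    # angular count is ceil(pi * 63.5 / 34) = ceil(5.867) = 6
    assert math.ceil(math.pi * 63.5 / 34) == 6


def test_manual_coverage_single_frame_circumference():
    angular, _, _ = manual_coverage(math.pi * 63.5, 24, 63.5, 24)
    assert angular == 1


def test_manual_overlapped_counts_are_explicit_inputs():
    # overlapped manual plan: counts follow no single rounding rule, so the
    # product takes both counts verbatim
    assert manual_total(58, 8) == 464
    assert manual_time_s(464, 20.0) == 9280.0


@pytest.mark.parametrize("frame_h,step,expected", [
    (28, 15, 13 / 28),
    (28, 28, 0.0),
    (28, 14, 0.5),
])
def test_strip_overlap_fraction(frame_h, step, expected):
    assert strip_overlap_fraction(frame_h, step) == pytest.approx(expected)


class TestEnergy:
    def test_per_component_and_cycle_total(self):
        wh = [c.energy_wh for c in PROTOTYPE_LOADS]
        assert wh == pytest.approx([0.726, 1.65, 0.275, 0.242, 3.5],
                                   abs=1e-9)
        assert energy_per_cycle(PROTOTYPE_LOADS) == pytest.approx(
            6.393, abs=1e-9)

    def test_trivial_cycles(self):
        assert energy_per_cycle([]) == 0.0
        assert energy_per_cycle([ComponentLoad("x", 1.0, 3600)]) == 1.0

    def test_peak_power_uses_component_peaks(self):
        assert peak_power(PROTOTYPE_LOADS) == pytest.approx(14.6)

    def test_exact_sizing_chain(self):
        daily = daily_energy(6.393, 12)
        assert daily == pytest.approx(76.716)
        assert system_daily_energy(77.0, 0.8) == pytest.approx(96.25)
        assert battery_wh(96.25, 2, 0.8) == pytest.approx(240.625)
        assert battery_ah(241.0, 12.0) == pytest.approx(20.0833, abs=1e-3)
        assert panel_w(241.0, 0.75, 8.0) == pytest.approx(40.1667, abs=1e-3)

    def test_paper_rounding_report(self):
        rep = EnergyBudget().report(paper_rounding=True)
        assert rep["daily_energy_wh"] == 77
        assert rep["system_daily_energy_wh"] == 96
        assert rep["battery_wh"] == 241
        assert rep["battery_ah"] == 20
        assert rep["panel_w"] == 40
        assert rep["peak_power_w"] == pytest.approx(14.6)

    def test_ceiling_rounding_guarantees_capacity(self):
        wh = battery_wh(96.25, 2, 0.8)
        ah = battery_ah(wh, 12.0, rounding="ceil")
        assert ah * 12.0 >= wh

    def test_invalid_fractions_rejected(self):
        with pytest.raises(PlanError):
            system_daily_energy(77, 0.0)
        with pytest.raises(PlanError):
            battery_wh(96, 2, 1.5)


class TestTransfer:
    def test_field_scan_transfer(self):
        spec = TransferSpec(kb_per_image=310, n_images=660, link_mbps=3,
                            overhead_frac=0.10)
        assert transfer_time(spec) == pytest.approx(601.33, abs=0.01)
        assert transfer_time(spec, rounding="nearest") == 600.0

    def test_small_batch(self):
        spec = TransferSpec(kb_per_image=310, n_images=100, link_mbps=3,
                            overhead_frac=0.10)
        assert transfer_time(spec) == pytest.approx(90.93, abs=0.01)

    def test_unit_megabyte(self):
        spec = TransferSpec(kb_per_image=1000, n_images=1, link_mbps=8,
                            overhead_frac=0.0)
        assert transfer_time(spec) == pytest.approx(1.0)


def test_acquisition_time_defaults_near_seven_minutes():
    plan = AcquisitionPlan(tube_len_mm=1000.0)
    t = acquisition_time(plan)
    assert 380 <= t <= 460          # "around 7 min" for the full tube
    one = AcquisitionPlan(tube_len_mm=15.0)
    assert acquisition_time(one, s_per_strip=3.5) == 3.5


@settings(deadline=None, max_examples=200)
@given(fov=st.floats(5, 180), overlap=st.floats(0, 0.95),
       dfov=st.floats(0, 20), doverlap=st.floats(0, 0.04))
def test_snap_count_monotonicity(fov, overlap, dfov, doverlap):
    """More FOV never needs more snaps; more overlap never needs fewer."""
    n = snaps_per_rotation(fov, overlap)
    assert snaps_per_rotation(min(fov + dfov, 180), overlap) <= n
    if overlap + doverlap < 1:
        assert snaps_per_rotation(fov, overlap + doverlap) >= n


@settings(deadline=None, max_examples=200)
@given(fov=st.floats(5, 180), overlap=st.floats(0, 0.95))
def test_realized_overlap_meets_request(fov, overlap):
    n = snaps_per_rotation(fov, overlap)
    assert realized_angular_overlap(fov, n) >= overlap - 1e-9
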