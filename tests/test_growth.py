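"""Oocyte growth: closed form, ODE fidelity path and threshold crossing."""

import math

import numpy as np
import pytest

from ogdm.growth import (
    BatchStatus,
    OocyteBatch,
    ProtocolError,
    VtgProtocol,
    batch_trajectory,
    grow_batch,
    maturation_time,
    oocyte_volume,
)


def test_volume_is_affine_in_absorbed_mass(params):
    assert oocyte_volume(0.0, params) == params.v_oog
    gain1 = oocyte_volume(1.0, params) - params.v_oog
    gain2 = oocyte_volume(2.0, params) - params.v_oog
    assert gain2 == pytest.approx(2 * gain1)
    with pytest.raises(ValueError):
        oocyte_volume(-0.1, params)


def test_unit_r_vtg_adds_molecular_mass_per_nmol(params):
    unit = params.with_overrides(r_vtg=1.0)
    assert oocyte_volume(1.0, unit) == pytest.approx(unit.v_oog + 0.156)


def test_maturation_time_inverse_in_concentration(params):
    assert maturation_time(0.05, params) == pytest.approx(2 * maturation_time(0.1, params))
    assert math.isinf(maturation_time(0.0, params))


def test_maturation_time_strictly_decreasing_in_rates(params):
    base = maturation_time(0.1, params)
    assert maturation_time(0.1, params.with_overrides(rho_vtg_ooc=params.rho_vtg_ooc * 2)) < base
    assert maturation_time(0.1, params.with_overrides(r_vtg=params.r_vtg * 2)) < base
    assert maturation_time(0.2, params) < base


def test_boundary_volume_gives_zero_maturation_time(params):
    degenerate = params.with_overrides(v_oog=params.v_threshold * (1 - 1e-12))
    assert maturation_time(0.1, degenerate) == pytest.approx(0.0, abs=1e-9)


@pytest.mark.parametrize("c_vtg", [0.01, 0.05, 0.1, 0.2, 0.3])
def test_ode_event_time_matches_closed_form(params, c_vtg):
    """Numerically integrated spawn time agrees with the analytic maturation
    time to relative error < 1e-6 (tight-tolerance ODE oracle)."""
    tight = params.with_overrides(ode_rtol=1e-12, ode_atol=1e-14)
    t_star = maturation_time(c_vtg, tight)
    batch = OocyteBatch(recruit_time=0.0, n_oogonia=10)
    grow_batch(batch, VtgProtocol.constant(c_vtg), t_star * 2, tight, method="ode")
    assert batch.status is BatchStatus.SPAWNED
    assert batch.spawn_time == pytest.approx(t_star, rel=1e-6)


def test_closed_form_spawn_time_equals_recruit_plus_maturation(params):
    c = 0.08
    batch = OocyteBatch(recruit_time=3.5, n_oogonia=40)
    grow_batch(batch, VtgProtocol.constant(c, start=0.0), 50.0, params)
    assert batch.spawn_time == pytest.approx(3.5 + maturation_time(c, params), rel=1e-12)


def test_zero_concentration_never_spawns(params):
    batch = OocyteBatch(recruit_time=0.0, n_oogonia=10)
    grow_batch(batch, VtgProtocol.constant(0.0), 1000.0, params)
    assert batch.status is BatchStatus.UNSPAWNED_AT_END
    assert batch.v_ooc == pytest.approx(params.v_oog)


def test_step_up_in_concentration_spawns_earlier_than_first_segment_alone(params):
    low, high = 0.02, 0.2
    protocol = VtgProtocol(((0.0, low), (5.0, high)))
    t_low_only = maturation_time(low, params)
    assert t_low_only > 5.0  # crossing occurs after the step
    batch = OocyteBatch(recruit_time=0.0, n_oogonia=10)
    grow_batch(batch, protocol, 100.0, params)
    assert batch.status is BatchStatus.SPAWNED
    assert batch.spawn_time < t_low_only


def test_piecewise_closed_form_matches_ode_path(params):
    """Closed-form and ODE integration agree to rel. error < 1e-6 on a
    multi-segment protocol, both in spawn time and in interim state."""
    tight = params.with_overrides(ode_rtol=1e-12, ode_atol=1e-14)
    protocol = VtgProtocol(((-10.0, 0.05), (0.0, 0.02), (4.0, 0.15)))
    a = OocyteBatch(recruit_time=-8.0, n_oogonia=5)
    b = OocyteBatch(recruit_time=-8.0, n_oogonia=5)
    grow_batch(a, protocol, 30.0, tight)
    grow_batch(b, protocol, 30.0, tight, method="ode")
    assert a.status is BatchStatus.SPAWNED and b.status is BatchStatus.SPAWNED
    assert a.spawn_time == pytest.approx(b.spawn_time, rel=1e-6)
    assert a.v_ooc == pytest.approx(b.v_ooc, rel=1e-6)


def test_volume_mass_consistency_at_all_reported_times(params):
    protocol = VtgProtocol(((0.0, 0.03), (6.0, 0.12)))
    for t_end in [1.0, 5.0, 6.0, 7.5, 100.0]:
        batch = OocyteBatch(recruit_time=0.0, n_oogonia=3)
        grow_batch(batch, protocol, t_end, params, final=False)
        expected = params.w_vtg * params.r_vtg * batch.m_vtg + params.v_oog
        assert abs(batch.v_ooc - expected) < 1e-12


def test_spawn_volume_hits_threshold_within_tolerance(params):
    for c in [0.02, 0.1, 0.25]:
        batch = OocyteBatch(recruit_time=0.0, n_oogonia=7)
        grow_batch(batch, VtgProtocol.constant(c), 1000.0, params)
        assert batch.v_ooc >= params.v_threshold - 1e-6
        assert batch.v_ooc == pytest.approx(params.v_threshold, rel=1e-9)


def test_crossing_exactly_at_window_end_counts_as_spawned(params):
    c = 0.1
    t_star = maturation_time(c, params)
    batch = OocyteBatch(recruit_time=0.0, n_oogonia=10)
    grow_batch(batch, VtgProtocol.constant(c), t_star, params)
    assert batch.status is BatchStatus.SPAWNED


def test_protocol_must_cover_the_growth_window(params):
    protocol = VtgProtocol.constant(0.1, start=0.0)
    batch = OocyteBatch(recruit_time=-5.0, n_oogonia=10)
    with pytest.raises(ProtocolError):
        grow_batch(batch, protocol, 10.0, params)


def test_protocol_validation():
    with pytest.raises(ProtocolError):
        VtgProtocol(((0.0, 0.1), (0.0, 0.2)))  # non-increasing starts
    with pytest.raises(ProtocolError):
        VtgProtocol(((0.0, -0.1),))  # negative concentration


def test_trajectory_dump_consistent_with_closed_form(params):
    protocol = VtgProtocol.constant(0.1)
    batch = OocyteBatch(recruit_time=0.0, n_oogonia=10)
    trajectory = batch_trajectory(batch, protocol, 50.0, params, n_points=50)
    times, masses, volumes = trajectory.T
    assert times[0] == 0.0
    assert volumes[0] == pytest.approx(params.v_oog)
    assert np.all(np.diff(volumes) > 0)
    # affine mass-volume relation holds along the whole trajectory
    assert np.allclose(volumes, params.w_vtg * params.r_vtg * masses + params.v_oog)
    # trajectory ends at the spawn crossing
    assert times[-1] == pytest.approx(maturation_time(0.1, params), rel=1e-9)
    assert volumes[-1] == pytest.approx(params.v_threshold, rel=1e-9)
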