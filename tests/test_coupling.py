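"""Synchronisation scheme and orchestrator tests."""

import math

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from emcosim.circuit import build_population
from emcosim.coupling import (CouplingConstants, adp_from_atp, run_coupled,
                              sanity_check, sync_atp, sync_schedule)
from emcosim.ephys import PumpParams

from conftest import small_test_spec
from test_metabolism import frozen_params

C = CouplingConstants()


# ---------------------------------------------------------------------------
# additive splitting
# ---------------------------------------------------------------------------


def test_sync_atp_identity_when_neither_side_moves():
    merged, adj = sync_atp(1.38, 1.38, 1.38)
    assert merged == 1.38 and adj == 0.0


def test_sync_atp_combines_decrement_and_increment():
    merged, _ = sync_atp(1.38, 1.30, 1.42)
    assert merged == pytest.approx(1.34, abs=1e-15)


def test_sync_atp_pure_production_passes_through():
    merged, _ = sync_atp(1.38, 1.38, 1.50)
    assert merged == pytest.approx(1.50, abs=1e-15)


def test_sync_atp_clamps_and_reports_adjustment():
    merged, adj = sync_atp(1.38, 0.01, 0.02)  # raw would be -1.35
    assert merged == C.atp_epsilon
    assert adj == pytest.approx(C.atp_epsilon - (-1.35))


@given(prev=st.floats(0.0, 1.44), e=st.floats(0.0, 1.44), m=st.floats(0.0, 1.44))
@settings(derandomize=True, max_examples=100)
def test_sync_atp_splitting_consistency(prev, e, m):
    """merged - prev == (ephys - prev) + (met - prev) before clamping."""
    merged, adj = sync_atp(prev, e, m)
    raw = merged - adj
    assert raw - prev == pytest.approx((e - prev) + (m - prev), abs=1e-12)


# ---------------------------------------------------------------------------
# adenylate kinase closure
# ---------------------------------------------------------------------------


def _ak_residual(adp, atp, c=C):
    """Equilibrium 2 ADP <-> ATP + AMP with constant q_AK: the closure must
    satisfy ADP^2 = q * ATP * AMP with AMP = A - ATP - ADP (the convention
    in which the closed form is the positive quadratic root)."""
    amp = c.a_tot - atp - adp
    return adp * adp - c.q_ak * atp * amp


def test_adp_zero_at_full_pool():
    assert adp_from_atp(C.a_tot) == pytest.approx(0.0, abs=1e-15)


def test_adp_at_physiological_atp():
    # closed form at ATP = 1.38, A = 1.44, q = 0.92
    assert adp_from_atp(1.38) == pytest.approx(0.0574045, abs=1e-6)
    # cross-check against a brute-force root of the equilibrium quadratic
    root = brentq(lambda adp: _ak_residual(adp, 1.38), 0.0, C.a_tot, xtol=1e-15)
    assert adp_from_atp(1.38) == pytest.approx(root, abs=1e-12)


def test_adp_matches_quadratic_root_at_half_pool():
    atp = C.a_tot / 2
    root = brentq(lambda adp: _ak_residual(adp, atp), 0.0, C.a_tot, xtol=1e-15)
    assert adp_from_atp(atp) == pytest.approx(root, abs=1e-12)


@given(atp=st.floats(0.01, 1.44))
@settings(derandomize=True, max_examples=200)
def test_adp_closure_satisfies_equilibrium_quadratic(atp):
    adp = adp_from_atp(atp)
    assert adp >= 0.0
    assert abs(_ak_residual(adp, atp)) < 1e-10


def test_adp_strictly_decreasing_in_atp_on_physiological_branch():
    # The AK closure is non-monotone globally (ADP -> 0 at both ends of the
    # pool); on the physiological high-energy branch it decreases strictly.
    grid = np.linspace(0.6, 1.44, 200)
    vals = adp_from_atp(grid)
    assert np.all(np.diff(vals) < 0)


def test_adp_domain_errors():
    with pytest.raises(ValueError):
        adp_from_atp(0.0)
    with pytest.raises(ValueError):
        adp_from_atp(1.45)


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------


def test_schedule_full_run_has_thirty_syncs():
    times = sync_schedule(3000.0, C)
    assert len(times) == 30
    assert times[0] == 100.0 and times[-1] == 3000.0


def test_schedule_single_interval():
    assert sync_schedule(100.0, C) == [100.0]


def test_smallest_common_multiple_of_simulator_steps_is_100ms():
    times = sync_schedule(200.0, CouplingConstants(), dt_met=100.0)
    assert times == [100.0, 200.0]


def test_incommensurate_steps_rejected():
    c = CouplingConstants(dt_ephys=0.025, dt_met=math.sqrt(2))
    with pytest.raises(ValueError, match="common"):
        sync_schedule(100.0, c, dt_met=math.sqrt(2))


def test_T_not_multiple_of_interval_rejected():
    with pytest.raises(ValueError, match="multiple"):
        sync_schedule(250.0, C)


# ---------------------------------------------------------------------------
# sanity checks
# ---------------------------------------------------------------------------


def test_sanity_check_within_bounds_is_empty():
    state = {"atp": 1.38, "na_i": 10.0, "k_i": 140.0}
    assert sanity_check(state, C.bounds) == []


def test_sanity_check_flags_negative_atp():
    out = sanity_check({"atp": -0.01}, C.bounds, neuron_id=3)
    assert len(out) == 1 and out[0].species == "atp" and out[0].neuron_id == 3


def test_sanity_check_flags_out_of_band_potassium():
    out = sanity_check({"k_i": 200.0}, {"k_i": (50.0, 180.0)})
    assert len(out) == 1 and out[0].species == "k_i"


# ---------------------------------------------------------------------------
# coupled runs
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def pop20():
    return build_population(small_test_spec(20))


def test_fixed_atp_mode_holds_reference_level(pop20):
    res = run_coupled(pop20[:5], 300.0, mode="fixed_atp", seed=4)
    assert np.all(res.traces["atp"] == 1.38)
    assert res.coupling is None
    assert np.all(res.energy["atp_consumed"] > 0)


def test_zero_metabolism_reproduces_ephys_only_trajectory(pop20):
    """With a metabolism whose RHS is identically zero, the merged ATP at
    every sync equals the electrophysiology-side value exactly."""
    pop = [replace(n, met_params=frozen_params()) for n in pop20[:5]]
    res = run_coupled(pop, 300.0, mode="coupled", seed=4)
    for rec in res.coupling:
        np.testing.assert_array_equal(rec.atp_met, rec.atp_prev)
        np.testing.assert_array_equal(rec.atp_merged, rec.atp_ephys)


def test_zero_consumption_reproduces_metabolism_only_trajectory(pop20):
    pop = [replace(n, eparams=replace(n.eparams,
                                      pump=PumpParams(v_max=0.0)))
           for n in pop20[:5]]
    res = run_coupled(pop, 300.0, mode="coupled", seed=4)
    assert np.all(res.energy["atp_consumed"] == 0.0)
    for rec in res.coupling:
        np.testing.assert_array_equal(rec.atp_ephys, rec.atp_prev)
        np.testing.assert_array_equal(rec.atp_merged, rec.atp_met)


def test_zero_both_sides_is_additive_fixed_point(pop20):
    pop = [replace(n, met_params=frozen_params(),
                   eparams=replace(n.eparams, pump=PumpParams(v_max=0.0)))
           for n in pop20[:3]]
    res = run_coupled(pop, 300.0, mode="coupled", seed=4)
    for rec in res.coupling:
        np.testing.assert_array_equal(rec.atp_merged, rec.atp_prev)


def test_coupling_records_satisfy_splitting_identity(pop20):
    res = run_coupled(pop20[:8], 400.0, mode="coupled", seed=4)
    assert len(res.coupling) == 4
    for rec in res.coupling:
        if rec.n_clamped == 0:
            np.testing.assert_allclose(
                rec.atp_merged,
                rec.atp_ephys + rec.atp_met - rec.atp_prev,
                rtol=0, atol=1e-15)


def test_worker_count_does_not_change_results(pop20):
    r1 = run_coupled(pop20[:6], 200.0, mode="coupled", seed=4, workers=1)
    r2 = run_coupled(pop20[:6], 200.0, mode="coupled", seed=4, workers=2)
    np.testing.assert_array_equal(r1.energy["final_atp"], r2.energy["final_atp"])
    np.testing.assert_array_equal(r1.energy["atp_produced"],
                                  r2.energy["atp_produced"])
    for s1, s2 in zip(r1.spikes, r2.spikes):
        np.testing.assert_array_equal(s1, s2)


def test_same_seed_reproduces_coupled_run(pop20):
    r1 = run_coupled(pop20[:4], 200.0, mode="coupled", seed=11)
    r2 = run_coupled(pop20[:4], 200.0, mode="coupled", seed=11)
    np.testing.assert_array_equal(r1.traces["v"], r2.traces["v"])
    np.testing.assert_array_equal(r1.energy["atp_produced"],
                                  r2.energy["atp_produced"])


def test_coupling_interval_halving_changes_final_atp_below_two_percent():
    pop = build_population(small_test_spec(20))
    r100 = run_coupled(pop, 1000.0, CouplingConstants(t_coupling=100.0,
                                                      dt_met=100.0),
                       mode="coupled", seed=4)
    r50 = run_coupled(pop, 1000.0, CouplingConstants(t_coupling=50.0,
                                                     dt_met=50.0),
                      mode="coupled", seed=4)
    m100 = r100.energy["final_atp"].mean()
    m50 = r50.energy["final_atp"].mean()
    assert abs(m50 - m100) / m100 < 0.02
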