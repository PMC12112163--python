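"""Membrane model and Na+/K+ pump tests."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.integrate import solve_ivp

from emcosim.circuit import ARCHETYPES
from emcosim.constants import RTF_MV
from emcosim.ephys import (EphysParams, PumpParams, ephys_step, gate_rates,
                           init_state, pump_cycle_rate, pump_flux,
                           run_ephys_segment, GATE_NAMES)
from emcosim.ephys import _ParamArrays, _StateArrays, run_batch_segment
from emcosim.stimulus import OUStimulusParams

PUMP = PumpParams()


# ---------------------------------------------------------------------------
# pump kinetics
# ---------------------------------------------------------------------------


def test_pump_zero_atp_shuts_all_fluxes_off():
    na_e, k_in, atp = pump_flux(-65.0, 12.0, 5.0, 0.0, PUMP)
    assert na_e == 0.0 and k_in == 0.0 and atp == 0.0


def test_pump_half_saturation_in_atp():
    # all other factors saturated: rate = v_max / 2
    sat = PumpParams(km_na=1e-9, km_k=1e-9, v_half=-1e6)
    rate = pump_cycle_rate(0.0, 1e6, 1e6, sat.km_atp, sat)
    assert rate == pytest.approx(sat.v_max / 2.0, rel=1e-6)


def test_pump_negative_concentration_names_field():
    with pytest.raises(ValueError, match="na_i"):
        pump_flux(-65.0, -1.0, 5.0, 1.38, PUMP)
    with pytest.raises(ValueError, match="atp"):
        pump_flux(-65.0, 10.0, 5.0, -0.1, PUMP)


@pytest.mark.parametrize("arg", ["na_i", "k_o", "atp"])
def test_pump_rate_monotone_in_substrates(arg):
    base = {"v": -65.0, "na_i": 10.0, "k_o": 5.0, "atp": 1.0}
    grid = np.linspace(0.01, 50.0 if arg != "atp" else 1.44, 40)
    rates = []
    for x in grid:
        kw = dict(base)
        kw[arg] = x
        rates.append(pump_cycle_rate(kw["v"], kw["na_i"], kw["k_o"], kw["atp"], PUMP))
    assert np.all(np.diff(rates) > 0)


def test_pump_stoichiometry_3_2_1():
    na_e, k_in, atp = pump_flux(-65.0, 12.0, 5.0, 1.38, PUMP)
    assert na_e == pytest.approx(3.0 * atp, rel=1e-15)
    assert k_in == pytest.approx(2.0 * atp, rel=1e-15)


def _pump_only_params():
    """All channels off; only the pump moves ions."""
    return EphysParams(g_leak=0.0, g_na=0.0, g_kd=0.0, g_m=0.0, g_na_leak=0.0,
                       tau_cl=1e9, tau_ca=1e9)


def test_pump_only_integration_preserves_stoichiometric_ratio():
    p = _pump_only_params()
    s = init_state(p)
    s.na_i = 12.0
    s0 = replace(s)
    r = run_ephys_segment(s, p, OUStimulusParams(), 10.0, 0.025,
                          np.random.default_rng(0))
    d_na = r.final_state.na_i - s0.na_i
    d_k = r.final_state.k_i - s0.k_i
    consumed = r.atp_consumed
    assert consumed > 0
    # 3 Na out : 2 K in : 1 ATP, exactly per unit volume
    assert d_na == pytest.approx(-3.0 * consumed, rel=1e-12)
    assert d_k == pytest.approx(2.0 * consumed, rel=1e-12)


# ---------------------------------------------------------------------------
# single fine steps
# ---------------------------------------------------------------------------


def test_step_without_fluxes_leaves_state_unchanged():
    p = EphysParams(g_leak=0.0, g_na=0.0, g_kd=0.0, g_m=0.0, g_na_leak=0.0,
                    pump=PumpParams(v_max=0.0), tau_cl=1e9, tau_ca=1e9)
    s = init_state(p, v0=-70.0)
    out = ephys_step(s, p, 0.0, 0.025)
    assert out.v == pytest.approx(s.v, abs=1e-12)
    assert out.na_i == s.na_i and out.k_i == s.k_i and out.atp == s.atp
    for g in GATE_NAMES:  # gates start at steady state for v0
        assert out.gates[g] == pytest.approx(s.gates[g], abs=1e-12)


def test_fixed_atp_mode_holds_level_while_tallying_consumption():
    p = EphysParams()
    s = init_state(p, atp=1.38)
    out = s
    for _ in range(200):
        out = ephys_step(out, p, 0.0, 0.025, fixed_atp=1.38)
    assert out.atp == 1.38
    assert out.atp_consumed_cum > 0


def _reference_trajectory(p, s0, i_stim_fn, t_end):
    """Adaptive-step integration of the same ODE system (independent of the
    fixed-step semi-implicit scheme)."""
    names = list(GATE_NAMES)

    def rhs(t, y):
        v = y[0]
        gates = y[1:8]
        na_i, k_i = y[8], y[9]
        atp = y[10]
        rates = gate_rates(np.array([v]), p.v_t, p.tau_max_m, p.tau_d2)
        dg = [(rates[g][0][0] - gates[j]) / rates[g][1][0]
              for j, g in enumerate(names)]
        m, h, n, pp, q, d1, d2 = gates
        ena = RTF_MV * np.log(p.na_o / na_i)
        ek = RTF_MV * np.log(p.k_o / k_i)
        g_na_tot = p.g_na * m**3 * h + p.g_na_leak
        g_k_tot = p.g_kd * n**4 + p.g_m * pp
        rate = pump_cycle_rate(v, na_i, p.k_o, atp, p.pump)
        pa = _ParamArrays([p])
        i_pump = rate * pa.flux_to_i[0]
        i_na = g_na_tot * (v - ena)
        i_k = g_k_tot * (v - ek)
        i_leak = p.g_leak * (v - p.e_leak)
        i_stim = i_stim_fn(t) * pa.nA_to_density[0]
        dv = (-(i_na + i_k + i_leak + i_pump) + i_stim) / p.cm
        dna = -i_na * pa.i_to_flux[0] - 3.0 * rate
        dk = -i_k * pa.i_to_flux[0] + 2.0 * rate
        datp = -rate
        return [dv] + dg + [dna, dk, datp]

    y0 = [s0.v] + [s0.gates[g] for g in names] + [s0.na_i, s0.k_i, s0.atp]
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="Radau", max_step=0.25,
                    rtol=1e-8, atol=1e-10, dense_output=True)
    return sol


def test_current_pulse_elicits_spike_with_sodium_influx():
    p = replace(ARCHETYPES["cNAC"].template, g_ca=0.0, g_kca=0.0, g_d=0.0)
    s0 = init_state(p, v0=-70.0)
    pulse = lambda t: 0.3 if 5.0 <= t < 6.0 else 0.0

    # fixed-step path
    s = replace(s0, gates=dict(s0.gates))
    vs, nas = [s.v], [s.na_i]
    for k in range(800):
        s = ephys_step(s, p, pulse(k * 0.025), 0.025)
        vs.append(s.v)
        nas.append(s.na_i)
    vs, nas = np.array(vs), np.array(nas)
    assert vs.max() > 0.0, "no action potential in the fixed-step scheme"
    up = np.argmax(vs)
    assert nas[up] > nas[0], "Na+ should accumulate during the upstroke"

    # independent adaptive-step oracle agrees on both facts
    sol = _reference_trajectory(p, s0, pulse, 20.0)
    v_ref = sol.y[0]
    na_ref = sol.y[8]
    assert v_ref.max() > 0.0
    assert na_ref[np.argmax(v_ref)] > na_ref[0]


# ---------------------------------------------------------------------------
# segments
# ---------------------------------------------------------------------------


def test_zero_duration_segment_is_identity():
    p = EphysParams()
    s = init_state(p)
    r = run_ephys_segment(s, p, OUStimulusParams(), 0.0, 0.025,
                          np.random.default_rng(0))
    assert r.final_state.v == s.v
    assert r.atp_consumed == 0.0
    assert r.spikes.size == 0


def test_duration_not_multiple_of_dt_rejected():
    p = EphysParams()
    with pytest.raises(ValueError, match="multiple"):
        run_ephys_segment(init_state(p), p, OUStimulusParams(), 10.01, 0.025,
                          np.random.default_rng(0))


def test_identical_seed_gives_bit_identical_traces():
    p = ARCHETYPES["cADpyr"].template
    stim = OUStimulusParams(mean=0.03, tau=3.0, amplitude=0.01)
    r1 = run_ephys_segment(init_state(p), p, stim, 200.0, 0.025,
                           np.random.default_rng(99))
    r2 = run_ephys_segment(init_state(p), p, stim, 200.0, 0.025,
                           np.random.default_rng(99))
    assert np.array_equal(r1.v, r2.v)
    assert np.array_equal(r1.na_i, r2.na_i)
    assert np.array_equal(r1.spikes, r2.spikes)


def test_quiescent_segment_consumes_atp():
    p = EphysParams()
    s = init_state(p, atp=1.38)
    settle = run_ephys_segment(s, p, OUStimulusParams(), 300.0, 0.025,
                               np.random.default_rng(0))
    s1 = settle.final_state
    r = run_ephys_segment(s1, p, OUStimulusParams(), 100.0, 0.025,
                          np.random.default_rng(0))
    atp = r.atp
    assert np.all(np.diff(atp) < 0), "ATP must strictly decrease at rest"
    # decrement rate agrees with the directly evaluated pump flux at the
    # settled quiescent state
    direct = pump_cycle_rate(s1.v, s1.na_i, 5.0, s1.atp, p.pump)
    measured = (s1.atp - r.final_state.atp) / 100.0
    assert measured == pytest.approx(direct, rel=0.02)


def test_compiled_kernel_matches_numpy_reference_path():
    p = ARCHETYPES["cSTUT"].template
    stim_mean, stim_tau, stim_amp = 0.03, 3.0, 0.01

    def run(use_kernel):
        pa = _ParamArrays([p] * 3)
        sa = _StateArrays([init_state(p) for _ in range(3)])
        rngs = [np.random.default_rng(i) for i in range(3)]
        out = run_batch_segment(
            sa, pa, np.full(3, stim_mean), np.full(3, stim_tau),
            np.full(3, stim_amp), 50.0, 0.025, rngs, use_kernel=use_kernel)
        return sa, out

    sa1, o1 = run(True)
    sa2, o2 = run(False)
    for f in ("v", "na_i", "k_i", "ca_i", "cl_i", "atp", "atp_consumed_cum"):
        np.testing.assert_allclose(getattr(sa1, f), getattr(sa2, f),
                                   rtol=0, atol=1e-12)
    np.testing.assert_allclose(sa1.gates, sa2.gates, rtol=0, atol=1e-12)
    for s1, s2 in zip(o1["spikes"], o2["spikes"]):
        np.testing.assert_allclose(s1, s2, atol=1e-9)


def test_time_step_halving_converges():
    """Halving dt leaves the spike count unchanged and moves final Na+ by
    less than 1% on a driven adapting cell."""
    p = ARCHETYPES["cADpyr"].template
    stim = OUStimulusParams(mean=0.09, tau=3.0, amplitude=0.0)
    r1 = run_ephys_segment(init_state(p), p, stim, 1500.0, 0.025,
                           np.random.default_rng(0), fixed_atp=1.38)
    r2 = run_ephys_segment(init_state(p), p, stim, 1500.0, 0.0125,
                           np.random.default_rng(0), fixed_atp=1.38)
    assert len(r1.spikes) == len(r2.spikes)
    assert r2.final_state.na_i == pytest.approx(r1.final_state.na_i, rel=0.01)
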