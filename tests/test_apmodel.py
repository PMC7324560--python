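import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aptrans import apmodel as ap
from aptrans._kernels import N_CURRENTS
from aptrans.biomarkers import compute_biomarkers


# ----------------------------------------------------------------- nernst


def test_nernst_symmetric_concentrations_give_zero():
    assert ap.nernst(1, 5.4, 5.4) == 0.0


def test_nernst_potassium_dog_value():
    # closed-form evaluation: (RT/F) ln(5.4/145) at 310 K
    assert ap.nernst(1, 145.0, 5.4, 310.0) == pytest.approx(-87.9, abs=0.05)


def test_nernst_valence_scaling():
    e1 = ap.nernst(1, 10.0, 140.0)
    e2 = ap.nernst(2, 10.0, 140.0)
    assert e2 == pytest.approx(e1 / 2)


@pytest.mark.parametrize("bad", [(1, 0.0, 5.4), (1, 5.4, -1.0), (0, 5.4, 5.4)])
def test_nernst_domain_errors(bad):
    z, ci, co = bad
    with pytest.raises(ValueError):
        ap.nernst(z, ci, co)


# ----------------------------------------------------------- T-type gates


def test_ttype_midpoints_exact():
    d_inf, _, _, _ = ap.ttype_gate_functions(-26.3)
    _, _, f_inf, _ = ap.ttype_gate_functions(-61.7)
    assert d_inf == 0.5
    assert f_inf == 0.5


def test_ttype_tau_d_at_midpoint():
    # printed formula at v = -26.3: 1 / (2 * 1.068)
    _, tau_d, _, _ = ap.ttype_gate_functions(-26.3)
    assert tau_d == pytest.approx(1.0 / (2 * 1.068), rel=1e-12)


@given(u=st.floats(0.0, 60.0))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_ttype_tau_d_symmetric_about_midpoint(u):
    _, lo, _, _ = ap.ttype_gate_functions(-26.3 - u)
    _, hi, _, _ = ap.ttype_gate_functions(-26.3 + u)
    assert lo == pytest.approx(hi, rel=1e-12)


@given(v=st.floats(-120.0, 60.0))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_gate_steady_states_bounded_taus_positive(v):
    from aptrans._kernels import gate_steady_tau

    inf, tau = gate_steady_tau(v)
    assert np.all(inf >= 0) and np.all(inf <= 1)
    assert np.all(tau > 0)


# ------------------------------------------------------- channel currents


def test_zero_conductance_zero_current(human):
    from dataclasses import replace

    p = replace(human, g_Kr=0.0)
    state = ap.resting_state(p, v0=-20.0)
    assert ap.channel_current("I_Kr", state, p) == 0.0


def test_zero_driving_force(human):
    e_k = human.equilibrium_potential("K")
    state = ap.resting_state(human, v0=e_k)
    assert ap.channel_current("I_Kr", state, human) == pytest.approx(0.0, abs=1e-12)
    assert ap.channel_current("I_to", state, human) == pytest.approx(0.0, abs=1e-12)


def test_block_factor_scales_linearly(human):
    state = ap.resting_state(human, v0=-20.0)
    full = ap.channel_current("I_CaL", state, human, 1.0)
    half = ap.channel_current("I_CaL", state, human, 0.5)
    assert half == pytest.approx(0.5 * full, rel=1e-12)


def test_unknown_channel_lists_valid_ids(human):
    state = ap.resting_state(human)
    with pytest.raises(KeyError, match="I_Kr"):
        ap.channel_current("I_herg", state, human)


# -------------------------------------------------------------------- rhs


def test_rhs_zero_model_is_static():
    zeros = {attr: 0.0 for attr in ap.CHANNEL_PARAM.values()}
    p = ap.SpeciesParams(species_name="null", **zeros)
    dv, _ = ap.rhs(ap.resting_state(p, v0=-50.0), p)
    assert dv == 0.0


def test_rhs_gates_at_steady_state_have_zero_derivative(human):
    state = ap.resting_state(human, v0=-63.0)
    _, dgates = ap.rhs(state, human)
    assert np.allclose(dgates, 0.0, atol=1e-14)


def test_rhs_equals_negative_current_sum_plus_stimulus(human):
    rng = np.random.default_rng(7)
    for _ in range(5):
        v = rng.uniform(-90, 40)
        gates = ap.GatingState(rng.uniform(0, 1, size=12))
        state = ap.CellState(v=v, gates=gates)
        stim = rng.uniform(0, 30)
        total = sum(ap.channel_current(ch, state, human) for ch in ap.CHANNELS)
        dv, _ = ap.rhs(state, human, stimulus=stim)
        assert dv == pytest.approx(-total + stim, abs=1e-12)


def test_rhs_rejects_nan_state(human):
    gates = ap.GatingState(np.full(12, 0.5))
    gates.values[3] = np.nan
    with pytest.raises(ValueError, match="hL"):
        ap.rhs(ap.CellState(v=-80.0, gates=gates), human)


# --------------------------------------------------------- species table


def test_human_table_values(human):
    assert human.g_Kr == 0.033
    assert human.g_CaL == 0.17
    assert human.g_Na == 5.0
    assert human.ion_concentrations["K"][0] == 120.0


def test_zebrafish_only_species_with_ttype():
    for name in ap.shipped_species():
        p = ap.species_defaults(name)
        if name == "zebrafish":
            assert p.g_CaT == 0.056
        else:
            assert p.g_CaT == 0.0


def test_dog_intracellular_potassium_raised():
    assert ap.species_defaults("dog").ion_concentrations["K"][0] == 145.0


def test_unknown_species_lists_shipped():
    with pytest.raises(KeyError, match="zebrafish"):
        ap.species_defaults("mouse")


# ------------------------------------------------------------ simulation


def test_zero_model_constant_trace():
    zeros = {attr: 0.0 for attr in ap.CHANNEL_PARAM.values()}
    p = ap.SpeciesParams(species_name="null", **zeros)
    proto = ap.StimulusProtocol(n_beats=1, stimulus_amplitude=0.0)
    trace = ap.simulate_paced(p, protocol=proto)
    assert np.allclose(trace.voltage, trace.voltage[0], atol=1e-9)


@pytest.mark.parametrize("name", ap.shipped_species())
def test_all_species_physiological_morphology(name):
    p = ap.species_defaults(name)
    trace = ap.simulate_paced(p, protocol=ap.StimulusProtocol(n_beats=40))
    bm = compute_biomarkers(trace)
    assert -92.0 <= bm.v_min <= -78.0, f"{name} resting potential {bm.v_min}"
    assert bm.v_max > 0.0, f"{name} peak {bm.v_max}"
    # beat-to-beat APD90 convergence at the recorded beat
    assert trace.metadata["apd90_delta_ms"] < 0.5


def test_human_steady_state_pacing_converged(human_steady_trace):
    assert human_steady_trace.metadata["apd90_delta_ms"] < 0.5
    assert "convergence_warning" not in human_steady_trace.metadata


def test_upstroke_sampling_resolution(human_steady_trace):
    t = human_steady_trace.time
    up = (t >= 5.0) & (t <= 15.0)  # upstroke window after the 5 ms stimulus
    assert np.max(np.diff(t[up])) <= 0.1


def test_solver_refinement_changes_apd_little(human, human_steady_biomarkers):
    fine = ap.SolverConfig(dt_min=0.001, dt_max=0.125, dv_max=0.1)
    trace = ap.simulate_paced(
        human, protocol=ap.StimulusProtocol(n_beats=100), solver=fine
    )
    bm = compute_biomarkers(trace)
    assert abs(bm.apd[50] - human_steady_biomarkers.apd[50]) < 0.1
    assert abs(bm.apd[90] - human_steady_biomarkers.apd[90]) < 0.2


def test_gates_remain_bounded_during_paced_beat(human):
    # final state after pacing carries the solver's end-of-run gate vector
    trace = ap.simulate_paced(human, protocol=ap.StimulusProtocol(n_beats=3))
    gates = np.array(trace.metadata["final_state"]["gates"])
    assert np.all(gates >= 0.0) and np.all(gates <= 1.0)


def test_scale_conductances_does_not_mutate(human):
    scaled = ap.scale_conductances(human, {"I_Kr": 1.2})
    assert scaled.g_Kr == pytest.approx(0.033 * 1.2)
    assert human.g_Kr == 0.033
    with pytest.raises(ValueError):
        ap.scale_conductances(human, {"I_Kr": 0.0})
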