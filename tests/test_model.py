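"""Clock-model unit and property tests: derivative structure, conservation,
integration accuracy and limit-cycle characterization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circanuc.model import (
    DEFAULT_PARAMS,
    STATE_NAMES,
    ParameterSet,
    Trajectory,
    clock_derivatives,
    limit_cycle_metrics,
    simulate_clock,
)


def test_zero_state_transcribes_at_maximal_rate():
    rates = clock_derivatives(np.zeros(8), DEFAULT_PARAMS)
    assert rates[0] == pytest.approx(DEFAULT_PARAMS.v_P)
    assert rates[1] == pytest.approx(DEFAULT_PARAMS.v_C)
    assert np.all(rates[2:] == 0.0)


@given(state=st.lists(st.floats(0.0, 50.0), min_size=8, max_size=8))
@settings(max_examples=50, deadline=None)
def test_protein_mass_conserved_without_synthesis_or_degradation(state):
    """With transcription, translation and all degradation off, each protein
    total (cytoplasmic + nuclear, monomer + complex) has zero net rate."""
    p = DEFAULT_PARAMS.replace(v_P=0, v_C=0, k_tlP=0, k_tlC=0,
                               d_MP=0, d_MC=0, d_Pc=0, d_Cc=0, d_Pn=0, d_Cn=0)
    r = dict(zip(STATE_NAMES, clock_derivatives(np.asarray(state), p)))
    total_P = r["P_c"] + r["P_n"] + r["PC_c"] + r["PC_n"]
    total_C = r["C_c"] + r["C_n"] + r["PC_c"] + r["PC_n"]
    assert total_P == pytest.approx(0.0, abs=1e-10)
    assert total_C == pytest.approx(0.0, abs=1e-10)


def test_negative_state_rejected_with_component_name():
    state = np.full(8, 0.1)
    state[4] = -0.01
    with pytest.raises(ValueError, match="PC_c"):
        clock_derivatives(state, DEFAULT_PARAMS)


def test_loss_terms_vanish_on_zero_substrate():
    """No species is consumed when absent: rates are non-negative wherever
    the state component is zero."""
    rng = np.random.default_rng(0)
    for _ in range(20):
        state = rng.uniform(0, 5, 8)
        zeroed = rng.integers(0, 8)
        state[zeroed] = 0.0
        rates = clock_derivatives(state, DEFAULT_PARAMS)
        assert rates[zeroed] >= -1e-12


def test_derivatives_match_finite_difference_of_integration():
    """Central finite difference of a short high-accuracy integration agrees
    with the analytic right-hand side."""
    y0 = np.full(8, 0.1)
    h = 1e-3
    traj = simulate_clock(DEFAULT_PARAMS, 2 * h, step=h, initial=y0, rtol=1e-12, atol=1e-14)
    fd = (traj.states[2] - traj.states[0]) / (2 * h)
    analytic = clock_derivatives(traj.states[1], DEFAULT_PARAMS)
    assert np.allclose(fd, analytic, rtol=1e-6, atol=1e-9)


def test_pure_decay_is_monotone_to_zero():
    p = DEFAULT_PARAMS.replace(v_P=0, v_C=0)
    traj = simulate_clock(p, 300.0, step=1.0)
    assert np.all(traj.states[-1] < 1e-6)
    per2 = traj.per2_nuc
    # after an initial redistribution phase, decay is monotone
    tail = per2[traj.time > 50]
    assert np.all(np.diff(tail) <= 1e-12)


def test_nonnegativity_along_trajectory(default_trajectory):
    assert default_trajectory.states.min() >= -1e-9


def test_converged_orbit_is_periodic(default_trajectory, default_metrics):
    """State at t and t + period agree within ~1e-3 relative after transient
    (one-period-later states are interpolated off the uniform grid)."""
    period = default_metrics.period
    t = default_trajectory.time
    for t0 in (600.0, 700.0, 800.0):
        i0 = np.searchsorted(t, t0)
        a = default_trajectory.states[i0]
        b = np.array([np.interp(t[i0] + period, t, default_trajectory.states[:, j])
                      for j in range(8)])
        assert np.allclose(a, b, rtol=2e-3, atol=1e-6)


def test_step_halving_converges():
    kw = dict(duration=300.0, initial=np.full(8, 0.1))
    coarse = simulate_clock(DEFAULT_PARAMS, step=0.2, **kw)
    fine = simulate_clock(DEFAULT_PARAMS, step=0.1, **kw)
    a = coarse.per2_nuc
    b = fine.per2_nuc[::2]
    scale = np.max(np.abs(b))
    assert np.max(np.abs(a - b)) / scale < 1e-4


def test_mass_conservation_along_trajectory():
    p = DEFAULT_PARAMS.replace(v_P=0, v_C=0, k_tlP=0, k_tlC=0,
                               d_MP=0, d_MC=0, d_Pc=0, d_Cc=0, d_Pn=0, d_Cn=0)
    traj = simulate_clock(p, 100.0, step=0.5, initial=np.array([0, 0, 1.0, 2.0, 0.5, 0.3, 0.2, 0.4]))
    total_P = traj["P_c"] + traj["P_n"] + traj["PC_c"] + traj["PC_n"]
    total_C = traj["C_c"] + traj["C_n"] + traj["PC_c"] + traj["PC_n"]
    assert np.allclose(total_P, total_P[0], rtol=1e-7)
    assert np.allclose(total_C, total_C[0], rtol=1e-7)


@given(pc_n=st.floats(0.01, 10.0), factor=st.floats(1.1, 5.0))
@settings(max_examples=50, deadline=None)
def test_repression_is_strictly_monotone(pc_n, factor):
    """More nuclear complex always means less transcription; at the
    threshold the rate is exactly half-maximal."""
    def transcription_rate(pc):
        state = np.zeros(8)
        state[5] = pc
        return clock_derivatives(state, DEFAULT_PARAMS)[0]

    assert transcription_rate(pc_n * factor) < transcription_rate(pc_n)
    assert transcription_rate(DEFAULT_PARAMS.K_rep) == pytest.approx(DEFAULT_PARAMS.v_P / 2)


def test_synthetic_cosine_metrics():
    """A pure 10 + 2 cos(2 pi t / 24) observable yields period 24.00 +/- 0.01
    and rAMP 0.4."""
    t = np.arange(0, 960.0, 0.1)
    states = np.zeros((t.size, 8))
    states[:, 6] = 10.0 + 2.0 * np.cos(2 * np.pi * t / 24.0)   # P_n carries the signal
    states[:, 7] = 10.0 + 2.0 * np.cos(2 * np.pi * t / 24.0)
    traj = Trajectory(time=t, states=states)
    m = limit_cycle_metrics(traj, transient=240.0)
    assert m.sustained
    assert m.period == pytest.approx(24.0, abs=0.01)
    assert m.ramp_per2 == pytest.approx(0.4, abs=1e-3)


def test_not_oscillating_flagged():
    t = np.arange(0, 400.0, 0.1)
    states = np.zeros((t.size, 8))
    states[:, 6] = 1.0
    m = limit_cycle_metrics(Trajectory(time=t, states=states), transient=240.0)
    assert not m.sustained


def test_parameter_validation():
    with pytest.raises(ValueError, match="K_rep"):
        DEFAULT_PARAMS.replace(K_rep=0.0)
    with pytest.raises(ValueError, match="h_rep"):
        DEFAULT_PARAMS.replace(h_rep=0.5)
    with pytest.raises(ValueError, match="v_P"):
        DEFAULT_PARAMS.replace(v_P=-1.0)
    with pytest.raises(ValueError, match="unknown"):
        ParameterSet.from_dict({**DEFAULT_PARAMS.to_dict(), "bogus": 1.0})


def test_default_regime_predictions(default_trajectory):
    """The default set encodes the predicted kinetic regimes: cytoplasmic
    association dominates dissociation, nuclear dissociation dominates
    association, and nuclear PER2 turns over faster than nuclear CRY1."""
    p = DEFAULT_PARAMS
    half = default_trajectory.time >= 480.0
    P_c = default_trajectory["P_c"][half].mean()
    C_c = default_trajectory["C_c"][half].mean()
    P_n = default_trajectory["P_n"][half].mean()
    C_n = default_trajectory["C_n"][half].mean()
    assert p.k_assC * np.sqrt(P_c * C_c) > p.k_disC
    assert p.k_disN > p.k_assN * np.sqrt(P_n * C_n)
    assert p.d_Pn > p.d_Cn
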