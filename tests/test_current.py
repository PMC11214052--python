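import numpy as np
import pytest

from acrcycles import (CurrentComponents, CurrentTrace, KineticScheme,
                       Transition, align_current, build_kinetic_matrix,
                       decompose_current, default_times, eigen_solve,
                       modify_current, required_fast_acceleration,
                       simulate_current, synthesize_current, time_evolution)
from acrcycles.current import ModificationFactors


def open_close_trace(k_open=2.5e4, k_close=500.0, n=300):
    s = KineticScheme(states=("K", "O", "R"),
                      transitions=(Transition("K", "O", k_open),
                                   Transition("O", "R", k_close)),
                      conductive={"O": True}, initial={"K": 1.0})
    sol = eigen_solve(build_kinetic_matrix(s), s.c0())
    evo = time_evolution(sol, default_times(n))
    return simulate_current(evo, s.conductive_mask()), evo, s


def test_decompose_recovers_scheme_rates():
    trace, _, _ = open_close_trace()
    comps = decompose_current(trace, n_components=2)
    assert comps.rise[1] == pytest.approx(1.0 / 2.5e4, rel=0.01)
    assert comps.fast_decay[1] == pytest.approx(1.0 / 500.0, rel=0.01)
    assert comps.rise[0] > 0


def test_decompose_flat_trace_zero_amplitudes():
    t = default_times(50)
    comps = decompose_current(CurrentTrace(times=t, current=np.zeros_like(t)))
    assert comps.rise[0] == 0.0
    assert comps.fast_decay[0] == 0.0
    assert comps.slow_decay[0] == 0.0


def test_decompose_two_decays_factor_ten_apart():
    t = default_times(300)
    comps_in = CurrentComponents(rise=(1.0, 4e-5), fast_decay=(0.7, 2e-3),
                                 slow_decay=(0.3, 2e-2))
    trace = synthesize_current(comps_in, t)
    out = decompose_current(trace, n_components=3)
    assert out.fast_decay[1] == pytest.approx(2e-3, rel=0.01)
    assert out.slow_decay[1] == pytest.approx(2e-2, rel=0.01)


def test_modify_identity_and_acceleration():
    t = default_times(300)
    comps = CurrentComponents(rise=(1.0, 4e-5), fast_decay=(0.7, 2e-3),
                              slow_decay=(0.3, 2e-2))
    same = modify_current(comps, ModificationFactors(), t)
    assert np.allclose(same.current, synthesize_current(comps, t).current)
    fast2 = modify_current(
        comps, ModificationFactors(amplitude={"fast_decay": 0.9},
                                   time={"fast_decay": 2.0}), t)
    refit = decompose_current(fast2, n_components=3)
    assert refit.fast_decay[1] == pytest.approx(1e-3, rel=0.01)
    assert refit.fast_decay[0] == pytest.approx(0.63, rel=0.01)


def test_modification_factor_validation():
    with pytest.raises(ValueError):
        ModificationFactors(amplitude={"bogus": 1.0})
    with pytest.raises(ValueError):
        ModificationFactors(time={"rise": 0.0})


def test_decompose_modify_decompose_idempotent():
    t = default_times(300)
    comps = CurrentComponents(rise=(1.0, 4e-5), fast_decay=(0.7, 2e-3),
                              slow_decay=(0.3, 2e-2))
    first = decompose_current(synthesize_current(comps, t), n_components=3)
    second = decompose_current(synthesize_current(first, t), n_components=3)
    for name in ("rise", "fast_decay", "slow_decay"):
        a1, tau1 = getattr(first, name)
        a2, tau2 = getattr(second, name)
        assert a2 == pytest.approx(a1, rel=1e-6)
        assert tau2 == pytest.approx(tau1, rel=1e-6)


def test_align_same_model_scale_one():
    trace, evo, s = open_close_trace()
    rep = align_current(trace, evo, s.conductive_mask())
    assert rep.scale == pytest.approx(1.0, rel=1e-9)
    assert rep.residual_rms < 1e-12


def test_align_scale_invariance():
    trace, evo, s = open_close_trace()
    doubled = CurrentTrace(times=trace.times, current=2.0 * trace.current)
    from acrcycles.kinetics import TimeEvolution
    evo2 = TimeEvolution(states=evo.states, times=evo.times,
                         concentrations=2.0 * evo.concentrations)
    r1 = align_current(trace, evo, s.conductive_mask())
    r2 = align_current(doubled, evo2, s.conductive_mask())
    assert r2.scale == pytest.approx(r1.scale, rel=1e-12)


def test_align_requires_conductive_state():
    trace, evo, s = open_close_trace()
    with pytest.raises(ValueError, match="no conductive state"):
        align_current(trace, evo, np.zeros(3, dtype=bool))


def test_align_negative_control_unrelated_trace():
    _, evo, s = open_close_trace()
    t = evo.times
    unrelated = CurrentTrace(times=t, current=np.exp(-t / 0.3))
    rep = align_current(unrelated, evo, s.conductive_mask())
    assert rep.normalized_residual > 0.1


def test_required_fast_acceleration_matched_profile_needs_none():
    t = default_times(300)
    y = 0.7 * np.exp(-t / 2e-3) + 0.3 * np.exp(-t / 2e-2)
    factor, residuals = required_fast_acceleration(2e-3, 2e-2, t, y)
    assert factor == pytest.approx(1.0, rel=0.05)
    # the factor grid is discrete, so the best residual is limited by the
    # grid resolution rather than machine precision
    assert residuals.min() < 0.01 * np.linalg.norm(y)
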