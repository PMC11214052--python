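import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from acrcycles import (KineticScheme, Transition, branch_rates,
                       build_kinetic_matrix, compute_b_spectra, default_basis,
                       default_times, eigen_solve, expm_solve, ode_solve,
                       time_evolution)


def chain(*rates):
    states = tuple(f"S{i}" for i in range(len(rates) + 1))
    trans = tuple(Transition(states[i], states[i + 1], r)
                  for i, r in enumerate(rates))
    return KineticScheme(states=states, transitions=trans,
                         initial={states[0]: 1.0})


def test_scheme_validation():
    with pytest.raises(ValueError, match="duplicate"):
        KineticScheme(states=("A", "A"), transitions=())
    with pytest.raises(ValueError, match="unknown state"):
        KineticScheme(states=("A", "B"),
                      transitions=(Transition("A", "C", 1.0),))
    with pytest.raises(ValueError, match="self-transition"):
        KineticScheme(states=("A",), transitions=(Transition("A", "A", 1.0),))
    with pytest.raises(ValueError, match="positive"):
        KineticScheme(states=("A", "B"),
                      transitions=(Transition("A", "B", 0.0),))
    with pytest.raises(ValueError, match="nonnegative"):
        KineticScheme(states=("A", "B"),
                      transitions=(Transition("A", "B", 1.0),),
                      initial={"A": -1.0})


def test_matrix_columns_sum_to_zero():
    s = chain(100.0, 10.0, 1.0)
    A = build_kinetic_matrix(s).A
    assert np.allclose(A.sum(axis=0), 0.0, atol=1e-12)


def test_eigen_solution_reconstructs_c0_and_conserves_mass():
    s = chain(1e5, 1e3, 10.0)
    sol = eigen_solve(build_kinetic_matrix(s), s.c0())
    assert np.allclose(sol.W.sum(axis=1), s.c0(), atol=1e-12)
    evo = time_evolution(sol, default_times(50))
    assert np.allclose(evo.concentrations.sum(axis=1), 1.0, atol=1e-10)
    assert np.all(evo.concentrations > -1e-12)


def test_chain_eigenvalues_equal_negated_rates():
    rates = (2e6, 3e4, 500.0, 10.0)
    s = chain(*rates)
    sol = eigen_solve(build_kinetic_matrix(s), s.c0())
    assert np.allclose(sorted(sol.eigenvalues), sorted([-r for r in rates] + [0.0]),
                       rtol=1e-12)


def test_eigen_expm_ode_agree_on_branched_scheme():
    s = KineticScheme(
        states=("A", "B", "C", "D"),
        transitions=(Transition("A", "B", 3e4), Transition("A", "C", 1e4),
                     Transition("B", "D", 250.0), Transition("C", "D", 40.0)),
        initial={"A": 1.0})
    A = build_kinetic_matrix(s)
    t = default_times(40)
    e = time_evolution(eigen_solve(A, s.c0()), t).concentrations
    x = expm_solve(A, s.c0(), t).concentrations
    o = ode_solve(A, s.c0(), t).concentrations
    assert np.max(np.abs(e - x)) < 1e-10
    assert np.max(np.abs(e - o)) < 1e-8


def test_complex_spectrum_rejected():
    # one-way loop has complex eigenvalues
    s = KineticScheme(
        states=("A", "B", "C"),
        transitions=(Transition("A", "B", 10.0), Transition("B", "C", 10.0),
                     Transition("C", "A", 10.0)),
        initial={"A": 1.0})
    with pytest.raises(ValueError, match="complex"):
        eigen_solve(build_kinetic_matrix(s), s.c0())


def test_parallel_cycles_shared_rate_is_one_degeneracy_group():
    c1 = chain(1e4, 10.0)
    c2 = chain(300.0, 10.0)
    combined = c1.combine(c2, suffixes=("_a", "_b"))
    sol = eigen_solve(build_kinetic_matrix(combined), combined.c0())
    groups = sol.degeneracy_groups
    # eigenvalues: -1e4, -300, -10 (x2 degenerate), 0 (x2)
    assert len(groups) == 4
    sizes = sorted(len(g) for g in groups)
    assert sizes == [1, 1, 2, 2]


def test_silent_transition_has_zero_b_spectrum_norm():
    """Isospectral K -> O: the -k eigencomponent is exactly silent."""
    basis = default_basis()
    s = KineticScheme(
        states=("K", "O"),
        transitions=(Transition("K", "O", 2.5e4),),
        conductive={"O": True}, initial={"K": 1.0})
    sol = eigen_solve(build_kinetic_matrix(s), s.c0())
    bs = compute_b_spectra(basis, sol, {"K": "K-like", "O": "K-like"})
    j = int(np.argmin(np.abs(bs.eigenvalues + 2.5e4)))
    silent_norm = np.linalg.norm(bs.spectra[:, j])
    total_norm = np.linalg.norm(bs.spectra)
    assert silent_norm < 1e-12 * total_norm


def test_silent_transition_downstream_leak_closed_form():
    """K -> O -> R with isospectral K, O but a distinct R: the opening
    eigencomponent is not exactly zero; it leaks the downstream spectral
    change with amplitude k_close / (k_open - k_close).  The pipeline's
    leakage refinement relies on this closed form."""
    basis = default_basis()
    k_open, k_close = 2.5e4, 500.0
    s = KineticScheme(
        states=("K", "O", "R"),
        transitions=(Transition("K", "O", k_open),
                     Transition("O", "R", k_close)),
        conductive={"O": True}, initial={"K": 1.0})
    sol = eigen_solve(build_kinetic_matrix(s), s.c0())
    bs = compute_b_spectra(basis, sol, {"K": "K-like", "O": "K-like",
                                        "R": "R"})
    j = int(np.argmin(np.abs(bs.eigenvalues + k_open)))
    leak = (basis.column("R") - basis.column("K-like")) * \
        k_close / (k_open - k_close)
    assert np.allclose(bs.spectra[:, j], leak, atol=1e-12)


def test_branch_rates_values_and_errors():
    out = branch_rates(500.0, [0.14, 0.185, 0.0925, 0.0925])
    assert out.shape == (4,)
    assert abs(out.sum() - 500.0) <= 2 * np.spacing(500.0)
    assert np.allclose(out / out.sum(),
                       np.array([0.14, 0.185, 0.0925, 0.0925]) / 0.51,
                       rtol=1e-12)
    with pytest.raises(ValueError):
        branch_rates(0.0, [0.5, 0.5])
    with pytest.raises(ValueError):
        branch_rates(10.0, [-0.1, 0.5])
    with pytest.raises(ValueError):
        branch_rates(10.0, [0.0, 0.0])


@given(st.lists(st.floats(min_value=1.0, max_value=1e7), min_size=1,
                max_size=5),
       st.floats(min_value=1.0, max_value=1e7))
def test_branch_rates_sum_property(fractions, k_app):
    out = branch_rates(k_app, fractions)
    assert abs(out.sum() - k_app) <= 4 * np.spacing(k_app)
    assert np.all(out >= 0)


@given(st.integers(min_value=2, max_value=6), st.integers(min_value=0,
                                                          max_value=2**31 - 1))
def test_random_chain_mass_conservation(n_steps, seed):
    rng = np.random.default_rng(seed)
    rates = 10.0 ** rng.uniform(0.5, 6.5, n_steps)
    # keep rates well-separated so the chain is numerically non-defective
    rates = np.sort(rates)[::-1]
    if np.any(np.abs(np.diff(np.log10(rates))) < 0.05):
        return
    s = chain(*rates)
    sol = eigen_solve(build_kinetic_matrix(s), s.c0())
    evo = time_evolution(sol, default_times(20))
    assert np.allclose(evo.concentrations.sum(axis=1), 1.0, atol=1e-8)


def test_scheme_json_round_trip():
    s = chain(123.456, 7.89)
    s2 = KineticScheme.from_json(s.to_json())
    assert s2 == s
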