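"""First-order kinetic schemes, their eigen-solutions and b-spectra.

A photocycle scheme is a labeled first-order reaction network.  With the
convention dc/dt = A c, the rate matrix A has A[i, j] = rate of j -> i for
i != j and column sums of zero (mass conservation).  The time evolution is
obtained by eigen-decomposition: c(t) = sum_k W[:, k] exp(lambda_k t), where
column k of W is eigenvector k scaled by the projection of the initial
populations.  Amplitude spectra of the exponential components (b-spectra) are
bs = E x W with E the matrix of intermediate-state spectra; eigenvector
columns belonging to degenerate eigenvalues (parallel cycles sharing a
lifetime) are combined before forming b-spectra.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .spectral import SpectralBasis

__all__ = [
    "Transition",
    "KineticScheme",
    "KineticMatrix",
    "EigenSolution",
    "TimeEvolution",
    "BSpectra",
    "build_kinetic_matrix",
    "eigen_solve",
    "expm_solve",
    "ode_solve",
    "time_evolution",
    "compute_b_spectra",
    "branch_rates",
    "default_times",
    "NearDegenerateWarning",
]

#: Eigenvalues whose relative difference is below this are one degenerate group.
DEGENERACY_RTOL = 1e-9
#: Relative differences between this and DEGENERACY_RTOL trigger a warning.
NEAR_DEGENERACY_RTOL = 1e-6


class NearDegenerateWarning(UserWarning):
    pass


@dataclass(frozen=True)
class Transition:
    from_state: str
    to_state: str
    rate: float  # s^-1


@dataclass(frozen=True)
class KineticScheme:
    """Labeled states with first-order transitions and initial populations."""

    states: tuple[str, ...]
    transitions: tuple[Transition, ...]
    conductive: dict[str, bool] = field(default_factory=dict)
    initial: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        states = tuple(self.states)
        if len(set(states)) != len(states):
            raise ValueError("duplicate state labels")
        trans = tuple(
            t if isinstance(t, Transition) else Transition(*t)
            for t in self.transitions
        )
        for t in trans:
            if t.from_state not in states or t.to_state not in states:
                raise ValueError(f"transition references unknown state: {t}")
            if t.from_state == t.to_state:
                raise ValueError(f"self-transition not allowed: {t}")
            if not (t.rate > 0):
                raise ValueError(f"rates must be positive: {t}")
        for s, v in self.initial.items():
            if s not in states:
                raise ValueError(f"initial population for unknown state {s!r}")
            if v < 0:
                raise ValueError("initial populations must be nonnegative")
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "transitions", trans)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def c0(self) -> np.ndarray:
        return np.array([self.initial.get(s, 0.0) for s in self.states])

    def conductive_mask(self) -> np.ndarray:
        return np.array([bool(self.conductive.get(s, False)) for s in self.states])

    def combine(self, other: "KineticScheme", suffixes=("", "")) -> "KineticScheme":
        """Disjoint union of two schemes (parallel cycles)."""
        s1 = [s + suffixes[0] for s in self.states]
        s2 = [s + suffixes[1] for s in other.states]
        if set(s1) & set(s2):
            raise ValueError("state label clash; use suffixes")
        trans = [Transition(t.from_state + suffixes[0], t.to_state + suffixes[0], t.rate)
                 for t in self.transitions]
        trans += [Transition(t.from_state + suffixes[1], t.to_state + suffixes[1], t.rate)
                  for t in other.transitions]
        cond = {s + suffixes[0]: v for s, v in self.conductive.items()}
        cond.update({s + suffixes[1]: v for s, v in other.conductive.items()})
        init = {s + suffixes[0]: v for s, v in self.initial.items()}
        init.update({s + suffixes[1]: v for s, v in other.initial.items()})
        return KineticScheme(tuple(s1 + s2), tuple(trans), cond, init)

    # -- JSON round trip (bit-exact rates via repr of float) ---------------
    def to_json(self) -> str:
        return json.dumps({
            "states": list(self.states),
            "transitions": [
                {"from": t.from_state, "to": t.to_state, "rate": t.rate}
                for t in self.transitions
            ],
            "conductive": self.conductive,
            "initial": self.initial,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "KineticScheme":
        d = json.loads(text)
        return cls(
            states=tuple(d["states"]),
            transitions=tuple(Transition(t["from"], t["to"], t["rate"])
                              for t in d["transitions"]),
            conductive=dict(d.get("conductive", {})),
            initial=dict(d.get("initial", {})),
        )


@dataclass(frozen=True)
class KineticMatrix:
    states: tuple[str, ...]
    A: np.ndarray  # s^-1, columns sum to 0

    def __post_init__(self):
        A = np.asarray(self.A, dtype=float)
        n = len(self.states)
        if A.shape != (n, n):
            raise ValueError("A must be square matching states")
        object.__setattr__(self, "A", A)


def build_kinetic_matrix(scheme: KineticScheme) -> KineticMatrix:
    """Assemble the rate matrix A for dc/dt = A c (columns sum to zero)."""
    n = scheme.n_states
    idx = {s: i for i, s in enumerate(scheme.states)}
    A = np.zeros((n, n))
    for t in scheme.transitions:
        j, i = idx[t.from_state], idx[t.to_state]
        A[i, j] += t.rate
        A[j, j] -= t.rate
    return KineticMatrix(states=scheme.states, A=A)


@dataclass(frozen=True)
class EigenSolution:
    """Eigen-decomposition of a kinetic matrix projected on c(0).

    ``W[:, k]`` is eigenvector k times the projection coefficient of the
    initial populations, so c(t) = sum_k W[:, k] exp(eigenvalues[k] * t).
    Eigenvalues are sorted fastest first (descending magnitude), zero last.
    """

    states: tuple[str, ...]
    eigenvalues: np.ndarray  # s^-1, real, <= 0
    W: np.ndarray  # n_states x n_states
    degeneracy_groups: tuple[tuple[int, ...], ...]
    c0: np.ndarray

    def group_eigenvalues(self) -> np.ndarray:
        return np.array([self.eigenvalues[g[0]] for g in self.degeneracy_groups])


def _degeneracy_groups(eigenvalues: np.ndarray, scale: float):
    """Group sorted eigenvalues whose relative difference is < DEGENERACY_RTOL."""
    groups: list[list[int]] = []
    for i, lam in enumerate(eigenvalues):
        placed = False
        for g in groups:
            ref = eigenvalues[g[0]]
            denom = max(abs(ref), abs(lam), 1e-300)
            rel = abs(lam - ref) / denom
            # treat numerically-zero eigenvalues as one group
            if abs(ref) < 1e-12 * scale and abs(lam) < 1e-12 * scale:
                rel = 0.0
            if rel < DEGENERACY_RTOL:
                g.append(i)
                placed = True
                break
            if DEGENERACY_RTOL <= rel < NEAR_DEGENERACY_RTOL:
                warnings.warn(
                    f"near-degenerate eigenvalues {ref:.6g} and {lam:.6g}",
                    NearDegenerateWarning,
                )
        if not placed:
            groups.append([i])
    return tuple(tuple(g) for g in groups)


def eigen_solve(matrix: KineticMatrix, c0) -> EigenSolution:
    """Diagonalize the kinetic matrix and project the initial condition.

    Raises if eigenvalues are complex (reversible loops are out of scope) or
    if the matrix is defective beyond tolerance.
    """
    A = matrix.A
    c0 = np.asarray(c0, dtype=float)
    if c0.shape != (A.shape[0],):
        raise ValueError("c0 length must match number of states")
    lam, V = np.linalg.eig(A)
    scale = max(np.max(np.abs(lam)), 1.0)
    if np.max(np.abs(lam.imag)) > 1e-9 * scale:
        raise ValueError(
            "complex eigenvalues encountered (reaction loop?); "
            "only tree/chain schemes with real spectra are supported"
        )
    lam = lam.real
    V = V.real
    # sort fastest first, zero eigenvalue(s) last
    order = np.argsort(-np.abs(lam), kind="stable")
    lam, V = lam[order], V[:, order]
    try:
        alpha = np.linalg.solve(V, c0)
    except np.linalg.LinAlgError as exc:
        raise ValueError("defective kinetic matrix: eigenvectors singular") from exc
    W = V * alpha[np.newaxis, :]
    recon = W.sum(axis=1)
    err = np.max(np.abs(recon - c0))
    if err > 1e-10 * max(1.0, np.max(np.abs(c0))):
        # locate the closest eigenvalue pair for the error message
        d = np.abs(lam[:, None] - lam[None, :])
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        raise ValueError(
            f"kinetic matrix defective beyond tolerance (c0 reconstruction "
            f"error {err:.3g}); near-degenerate pair: "
            f"{lam[i]:.6g}, {lam[j]:.6g} s^-1"
        )
    groups = _degeneracy_groups(lam, scale)
    return EigenSolution(states=matrix.states, eigenvalues=lam, W=W,
                         degeneracy_groups=groups, c0=c0)


@dataclass(frozen=True)
class TimeEvolution:
    states: tuple[str, ...]
    times: np.ndarray  # s
    concentrations: np.ndarray  # n_times x n_states


def default_times(n: int = 200, t_min: float = 1e-7, t_max: float = 1.0) -> np.ndarray:
    """Log-spaced time grid mirroring a 100 ns - 1 s observation window."""
    return np.geomspace(t_min, t_max, n)


def time_evolution(solution: EigenSolution, times) -> TimeEvolution:
    """Concentrations c(t) on a sorted positive time grid."""
    times = np.asarray(times, dtype=float)
    if np.any(times <= 0) or np.any(np.diff(times) < 0):
        raise ValueError("times must be positive and sorted")
    # guard exp underflow: lambda*t very negative -> 0
    ex = np.exp(np.outer(np.clip(solution.eigenvalues, -1e300, 0), times)
                .clip(min=-700))
    conc = (solution.W @ ex).T
    return TimeEvolution(states=solution.states, times=times, concentrations=conc)


def expm_solve(matrix: KineticMatrix, c0, times) -> TimeEvolution:
    """Propagate c(t) = expm(A t) c(0) with the scaling-and-squaring expm.

    Independent oracle for ``eigen_solve``/``time_evolution``: it makes no
    assumption about diagonalizability or real spectra.
    """
    from scipy.linalg import expm
    times = np.asarray(times, dtype=float)
    if np.any(times <= 0) or np.any(np.diff(times) < 0):
        raise ValueError("times must be positive and sorted")
    c0 = np.asarray(c0, dtype=float)
    conc = np.empty((times.size, len(matrix.states)))
    for i, t in enumerate(times):
        conc[i] = expm(matrix.A * t) @ c0
    return TimeEvolution(states=matrix.states, times=times, concentrations=conc)


def ode_solve(matrix: KineticMatrix, c0, times, rtol: float = 1e-10,
              atol: float = 1e-13) -> TimeEvolution:
    """Integrate dc/dt = A c with a stiff implicit solver (Radau).

    Second independent oracle; kinetic matrices spanning many decades in rate
    are stiff, so an implicit method with the exact Jacobian A is used.
    """
    from scipy.integrate import solve_ivp
    times = np.asarray(times, dtype=float)
    if np.any(times <= 0) or np.any(np.diff(times) < 0):
        raise ValueError("times must be positive and sorted")
    c0 = np.asarray(c0, dtype=float)
    A = matrix.A
    sol = solve_ivp(lambda t, c: A @ c, (0.0, times[-1]), c0, method="Radau",
                    t_eval=times, jac=lambda t, c: A, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"stiff ODE integration failed: {sol.message}")
    return TimeEvolution(states=matrix.states, times=times,
                         concentrations=sol.y.T)


@dataclass(frozen=True)
class BSpectra:
    """Amplitude spectra per degeneracy group, fastest group first."""

    eigenvalues: np.ndarray  # one representative per group
    spectra: np.ndarray  # n_wavelengths x n_groups

    @property
    def n_groups(self) -> int:
        return self.eigenvalues.size


def state_spectra_matrix(basis: SpectralBasis, states, state_to_form) -> np.ndarray:
    """n_wavelengths x n_states matrix of per-state spectra."""
    cols = []
    for s in states:
        if s not in state_to_form:
            raise ValueError(f"state {s!r} has no spectral form assigned")
        cols.append(basis.column(state_to_form[s]))
    return np.column_stack(cols)


def compute_b_spectra(basis: SpectralBasis, solution: EigenSolution,
                      state_to_form: dict[str, str]) -> BSpectra:
    """b-spectra bs = E x W, eigenvector columns combined per degeneracy group.

    The zero-eigenvalue group yields the final-state spectrum weighted by the
    recovered fraction.  A spectrally silent transition (isospectral source and
    product) yields a group spectrum of zero norm.
    """
    Es = state_spectra_matrix(basis, solution.states, state_to_form)
    full = Es @ solution.W
    spectra = np.column_stack([full[:, list(g)].sum(axis=1)
                               for g in solution.degeneracy_groups])
    return BSpectra(eigenvalues=solution.group_eigenvalues(), spectra=spectra)


def branch_rates(k_app: float, fractions) -> np.ndarray:
    """Microscopic rates of an irreversible branching step.

    The overall rate of a branching step equals the sum of the branch rates,
    and each branch rate is proportional to the fraction of product formed in
    it: k_i = k_app * fr_i / sum(fr).
    """
    if not (k_app > 0):
        raise ValueError("k_app must be positive")
    fr = np.asarray(fractions, dtype=float)
    if np.any(fr < 0):
        raise ValueError("fractions must be nonnegative")
    tot = fr.sum()
    if tot <= 0:
        raise ValueError("at least one fraction must be positive")
    return k_app * fr / tot
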