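"""Apparent kinetics and spectral composition from time-resolved data.

The analysis chain mirrors standard global analysis of flash-photolysis data:

1. SVD of the data matrix estimates the number of independent spectra.
2. A global multi-exponential fit (variable projection: lifetimes nonlinear,
   amplitude spectra linear) yields apparent lifetimes and b-spectra, plus a
   non-decaying spectrum for the final state.
3. The b-spectra are converted into sequential intermediate spectra via the
   coefficient matrix of an irreversible chain In1 -> In2 -> ... (Bateman
   solution), fastest rate assigned to the first transition.
4. Non-negative least squares against the spectral-form basis gives the
   composition matrix: the fraction of each spectral form in each sequential
   intermediate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, nnls

from .kinetics import (KineticScheme, Transition, build_kinetic_matrix,
                       eigen_solve)
from .spectral import SpectralBasis
from .synth import SyntheticDataset

__all__ = [
    "ApparentKinetics",
    "SequentialSpectra",
    "CompositionMatrix",
    "svd_rank",
    "global_exp_fit",
    "sequential_from_b",
    "deconvolve_composition",
    "amplitude_spectra_for_lifetimes",
]

SEQUENTIAL_NAMES = ("In1", "In2", "In3", "In4", "In5", "In6", "In7", "In8")


@dataclass(frozen=True)
class ApparentKinetics:
    """Apparent lifetimes (ascending) and amplitude b-spectra.

    ``b_spectra`` has one column per lifetime, fastest first, plus a final
    column for the non-decaying spectrum b_inf.
    """

    lifetimes: np.ndarray  # s, sorted ascending
    b_spectra: np.ndarray  # n_wavelengths x (n_exp + 1)
    fit_residual: float
    wavelengths: np.ndarray

    @property
    def rates(self) -> np.ndarray:
        return 1.0 / self.lifetimes

    @property
    def n_exp(self) -> int:
        return self.lifetimes.size

    def to_frame(self) -> pd.DataFrame:
        cols = [f"tau_{t:.4e}s" for t in self.lifetimes] + ["b_inf"]
        return pd.DataFrame(self.b_spectra, columns=cols,
                            index=pd.Index(self.wavelengths, name="wavelength_nm"))


@dataclass(frozen=True)
class SequentialSpectra:
    """Spectra of the sequential intermediates In1..In(n+1)."""

    spectra: np.ndarray  # n_wavelengths x (n_exp + 1)
    rates: np.ndarray  # chain rates, descending (k1 >= k2 >= ...)
    wavelengths: np.ndarray

    @property
    def names(self) -> tuple[str, ...]:
        return SEQUENTIAL_NAMES[: self.spectra.shape[1]]


@dataclass(frozen=True)
class CompositionMatrix:
    """Fractions of each spectral form in each sequential intermediate.

    Rows follow the basis form order (K-like, L-like, M, R); columns are
    In1..In(n+1).  With ``normalized`` the columns are population fractions.
    """

    fractions: np.ndarray  # n_forms x n_intermediates
    form_names: tuple[str, ...]
    column_names: tuple[str, ...]
    residuals: np.ndarray
    normalized: bool = True

    def entry(self, form: str, column: str) -> float:
        return float(self.fractions[self.form_names.index(form),
                                    self.column_names.index(column)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fractions, index=list(self.form_names),
                            columns=list(self.column_names))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def svd_rank(data, threshold: float = 1e-3,
             noise_sd: float | None = None) -> int:
    """Number of singular values above the signal/noise cutoff.

    With a known ``noise_sd`` the cutoff is the Marchenko-Pastur bulk edge of
    an i.i.d. Gaussian noise matrix, ``noise_sd * (sqrt(m) + sqrt(n))``;
    singular values above it carry signal.  Otherwise a relative cutoff of
    ``threshold`` times the largest singular value is used.  A
    ``SyntheticDataset`` supplies its own noise SD.
    """
    if noise_sd is None and isinstance(data, SyntheticDataset):
        noise_sd = data.noise_sd or None
    D = data.D if isinstance(data, SyntheticDataset) else np.asarray(data)
    if D.size == 0:
        raise ValueError("empty data matrix")
    s = np.linalg.svd(D, compute_uv=False)
    if s[0] == 0:
        return 0
    if noise_sd is not None and noise_sd > 0:
        cutoff = noise_sd * (np.sqrt(D.shape[0]) + np.sqrt(D.shape[1]))
        return int(np.sum(s > cutoff))
    return int(np.sum(s > threshold * s[0]))


def _design(times: np.ndarray, taus: np.ndarray) -> np.ndarray:
    X = np.exp(-(times[:, None] / taus[None, :]).clip(max=700))
    return np.column_stack([X, np.ones_like(times)])


def amplitude_spectra_for_lifetimes(dataset: SyntheticDataset, lifetimes) -> np.ndarray:
    """Linear solve for b-spectra at fixed lifetimes (plus b_inf column)."""
    taus = np.asarray(lifetimes, dtype=float)
    X = _design(dataset.times, taus)
    Bt, *_ = np.linalg.lstsq(X, dataset.D.T, rcond=None)
    return Bt.T


def global_exp_fit(dataset: SyntheticDataset, n_exp: int,
                   init_lifetimes=None, n_starts: int = 8, seed: int = 0,
                   min_separation: float = 1e-3,
                   max_nfev: int = 200,
                   fixed_lifetimes=None) -> ApparentKinetics:
    """Global multi-exponential fit by variable projection.

    Lifetimes are optimized in log space with deterministic multi-start; the
    b-spectra follow from a final linear solve.  Converged duplicate lifetimes
    (relative separation below ``min_separation``) are merged with a warning.

    ``fixed_lifetimes`` adds exponential components with known lifetimes whose
    amplitudes are fitted linearly but which are excluded from the reported
    lifetimes and b-spectra.  This absorbs components known from other
    measurements -- e.g. the small leakage of the spectrally silent
    channel-opening step, whose rate the current rise provides -- without
    biasing the free lifetimes.
    """
    if n_exp < 1:
        raise ValueError("n_exp must be >= 1")
    t, D = dataset.times, dataset.D
    fixed = (np.asarray(fixed_lifetimes, dtype=float)
             if fixed_lifetimes is not None else np.empty(0))
    if np.any(fixed <= 0):
        raise ValueError("fixed lifetimes must be positive")
    logt_lo, logt_hi = np.log10(t[0]), np.log10(t[-1])

    def residual(logtau):
        X = _design(t, np.concatenate([10.0 ** logtau, fixed]))
        Bt, *_ = np.linalg.lstsq(X, D.T, rcond=None)
        return (X @ Bt - D.T).ravel()

    starts = []
    if init_lifetimes is not None:
        starts.append(np.log10(np.asarray(init_lifetimes, dtype=float)))
    rng = np.random.default_rng(seed)
    starts.append(np.linspace(logt_lo + 0.3, logt_hi - 0.3, n_exp))
    while len(starts) < n_starts:
        starts.append(np.sort(rng.uniform(logt_lo, logt_hi, n_exp)))

    best = None
    for x0 in starts:
        try:
            sol = least_squares(residual, x0, method="trf",
                                bounds=(logt_lo - 2, logt_hi + 2),
                                max_nfev=max_nfev)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("global exponential fit failed to converge")

    taus = np.sort(10.0 ** best.x)
    # merge duplicates
    keep = [taus[0]]
    merged = False
    for tau in taus[1:]:
        if (tau - keep[-1]) / tau < min_separation:
            keep[-1] = np.sqrt(keep[-1] * tau)
            merged = True
        else:
            keep.append(tau)
    if merged:
        warnings.warn("duplicate converged lifetimes merged")
    taus = np.array(keep)
    X = _design(t, np.concatenate([taus, fixed]))
    Bt, *_ = np.linalg.lstsq(X, D.T, rcond=None)
    B_full = Bt.T
    resid = float(np.sqrt(np.mean((B_full @ X.T - D) ** 2)))
    # report free components plus b_inf; fixed-lifetime amplitudes are dropped
    B = np.column_stack([B_full[:, :taus.size], B_full[:, -1]])
    return ApparentKinetics(lifetimes=taus, b_spectra=B, fit_residual=resid,
                            wavelengths=dataset.grid.values)


def _chain_coefficients(rates_desc: np.ndarray) -> np.ndarray:
    """Coefficient matrix C of the irreversible chain In1 -> ... -> In(n+1).

    Row i gives the coefficients of state i over the exponential components
    (columns ordered fastest first, constant last), for unit initial In1:
    c_i(t) = sum_j C[i, j] exp(-k_j t)   (k for the last column is 0).
    """
    n = rates_desc.size
    states = SEQUENTIAL_NAMES[: n + 1]
    trans = tuple(Transition(states[i], states[i + 1], rates_desc[i])
                  for i in range(n))
    scheme = KineticScheme(states=tuple(states), transitions=trans,
                           initial={states[0]: 1.0})
    sol = eigen_solve(build_kinetic_matrix(scheme), scheme.c0())
    # columns of W are sorted fastest first, zero last, matching b-spectra order
    expected = np.concatenate([-rates_desc, [0.0]])
    if not np.allclose(sol.eigenvalues, expected, rtol=1e-9, atol=1e-12):
        raise ValueError("chain eigenvalues do not match requested rates")
    return sol.W


def sequential_from_b(kinetics: ApparentKinetics,
                      cond_limit: float = 1e12) -> SequentialSpectra:
    """Convert b-spectra into sequential intermediate spectra.

    Solves B = S C, where C is the Bateman coefficient matrix of the chain
    In1 -> ... -> In(n+1) with the fitted apparent rates assigned fastest
    first (k1 >= k2 >= ...).
    """
    rates = 1.0 / kinetics.lifetimes  # lifetimes ascending -> rates descending
    if np.any(np.diff(rates) >= 0):
        raise ValueError("chain rates must be strictly decreasing (k1 >= k2 >= ...)")
    C = _chain_coefficients(rates)
    cond = np.linalg.cond(C)
    if cond > cond_limit:
        raise ValueError(
            f"near-equal rates make the chain ill-conditioned (cond={cond:.3g})")
    S = np.linalg.solve(C.T, kinetics.b_spectra.T).T
    return SequentialSpectra(spectra=S, rates=rates,
                             wavelengths=kinetics.wavelengths)


def deconvolve_composition(seq: SequentialSpectra, basis: SpectralBasis,
                           normalize: bool = True,
                           cond_limit: float = 1e6) -> CompositionMatrix:
    """Per-intermediate non-negative least squares against the form basis."""
    if basis.condition_number > cond_limit:
        raise ValueError("basis condition number too high for deconvolution")
    n_cols = seq.spectra.shape[1]
    F = np.zeros((basis.n_forms, n_cols))
    resid = np.zeros(n_cols)
    for j in range(n_cols):
        w, r = nnls(basis.E, seq.spectra[:, j])
        F[:, j] = w
        resid[j] = r
    if normalize:
        sums = F.sum(axis=0)
        good = sums > 0
        F[:, good] = F[:, good] / sums[good]
    return CompositionMatrix(fractions=F, form_names=basis.form_names,
                             column_names=SEQUENTIAL_NAMES[:n_cols],
                             residuals=resid, normalized=normalize)
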