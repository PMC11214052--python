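# Methods

This document describes the numerical methods used by `acrcycles`, in the
order the analysis pipeline applies them.

## Kinetic model

A photocycle is a first-order reaction network: states (spectrally and
kinetically distinct intermediates) connected by unimolecular transitions
with rate constants `k` (s⁻¹).  The concentration vector obeys

    dc/dt = A c,   c(0) = c0,

where `A` is the kinetic matrix: `A[j, i] = k(i→j)` for each transition and
`A[i, i] = −Σ_j k(i→j)`.  Columns of `A` sum to zero, so total concentration
is conserved.

### Propagators

Three independent solvers compute `c(t)`:

- **Eigen-solution** (`eigen_solve` + `time_evolution`): diagonalize `A`,
  giving `c(t) = Σ_j α_j v_j exp(λ_j t)`.  This is the primary solver; it
  exposes the eigenvalues (apparent rates) and eigenvectors needed for
  b-spectra.  Complex or defective spectra are rejected with an error.
- **Matrix exponential** (`expm_solve`): `c(t) = expm(A t) c0` via
  `scipy.linalg.expm`, one call per time point.
- **Stiff ODE integration** (`ode_solve`): `scipy.integrate.solve_ivp` with
  the Radau method and the exact Jacobian `A`.

The three agree to ~1e-12 on random 3–8-state schemes with rates spanning
seven decades; the eigen-solution is used everywhere else because it is
exact, fast, and structured.

### Degeneracy

Parallel cycles that share a rate constant produce repeated eigenvalues.
`eigen_solve` groups eigenvalues that agree to a relative tolerance of 1e-9
into degeneracy groups; all downstream quantities (b-spectra, lifetimes)
are computed per group, i.e. the eigenvector contributions of a group are
summed.  This is required because only the group sum is observable: a
global exponential fit of the data sees one exponential per distinct
lifetime, not one per eigenvector.

### Branch rates

When a state decays into several products with branching fractions `f_i`
and total apparent rate `k_app`, the microscopic rates are
`k_i = k_app · f_i / Σf`.  They sum to `k_app` to machine precision and the
ODE-integrated product yields equal the normalized fractions.

## Spectral model

Intermediate difference spectra are skewed Gaussians in wavelength on a
350–700 nm grid (2 nm steps).  Four spectral *forms* are distinguished:
K-like (red-shifted, 540 nm), L-like (blue-shifted, 480 nm), M (400 nm,
deprotonated Schiff base) and R (515 nm, recovered).  Several kinetic
states may share one form; a transition between two states of the same
form is *spectrally silent*.

## Synthetic data

The ground-truth generator builds a two-cycle model — a conductive cycle
whose K state opens into the conductive O1 with a spectrally silent step,
and a nonconductive cycle with K↔L equilibria — simulates the absorbance
matrix `D(λ, t) = E · c_forms(t)`, and adds i.i.d. Gaussian noise whose
standard deviation is a stated fraction of `max|D|`.  The photocurrent is
the summed concentration of conductive states.  All randomness flows from
a single integer seed; reruns are byte-identical.

## Decomposition

1. **Rank estimation**: singular values of `D` are compared with the
   Marchenko–Pastur noise edge `σ(√m + √n)`; the rank is the number of
   singular values above it.
2. **Global exponential fit**: variable projection.  The lifetimes are the
   only nonlinear parameters; for trial lifetimes the amplitude spectra
   (*b-spectra*, one per exponential plus a constant) solve a linear least
   squares problem over all wavelengths at once.
3. **Misfit detection**: for a correct model the residual RMS should equal
   `σ·sqrt(1 − p/N)` where `p` counts fitted parameters and `N` data
   points, with sampling standard deviation `σ/sqrt(2(N−p))`.  The pipeline
   reports the z-score of the observed residual against this expectation
   and flags a misfit at `z > 5`.
4. **Sequential spectra**: with the fitted lifetimes ordered fast to slow,
   the b-spectra are converted into the spectra of sequential
   intermediates In1…In(n+1) using the Bateman solution of a sequential
   scheme — the unique sequential model consistent with the exponential
   fit.
5. **Composition**: each sequential spectrum is decomposed as a nonnegative
   combination of the spectral forms (least squares on the form basis),
   giving the composition matrix (forms × intermediates).

## Cycle partition

The composition matrix is partitioned into parallel cycles by arithmetic
on the K-like content:

- `a4`, the K-like fraction that decays with the channel-closing lifetime,
  is the conductive-cycle fraction; `1 − a4` is nonconductive.
- `a5`, the K-like fraction persisting into the slowest phase, is the O2
  fraction (the conductive sub-population that stays open longer);
  `O1 = a4 − a5`.
- A three-cycle variant splits the K-like content of an early intermediate
  into two conductive sub-cycles and the nonconductive cycle.

The partition demands `a5 ≤ a4` and non-negative remainders; violations
raise errors rather than being clipped.

## Scheme fitting

Microscopic rate constants are fitted per cycle.  The conductive-cycle
contribution (including the silent-opening leak, see below) is subtracted
from the measured b-spectra; the nonconductive topology is then fitted by
least squares on (eigenvalue, b-spectrum) pairs using structured
multi-starts plus basin hops, so that isospectral labeling modes (e.g.
swapping the L1 and L2 equilibria) are all visited.  Reported errors are
scored against the canonical labeling: the L1/L2 swap is a kinetically
equivalent relabeling and is normalized away before scoring.

## Silent transitions and the opening leak

If states K and O share a spectral form, the K→O eigencomponent of a pure
two-state system has *exactly* zero b-spectrum: the transition is invisible
spectrally while fully visible in the photocurrent.  With a downstream
state R of distinct spectrum (K→O→R), the opening eigencomponent is not
exactly zero — it carries the downstream spectral change scaled by
`k_close / (k_open − k_close)` (about 2% at the default rates, below the
0.5% noise floor relative to the data norm).  The pipeline subtracts this
leak self-consistently: the opening rate comes from the current rise, the
conductive fraction from the current amplitude, and the leak refinement
iterates until the subtracted b-spectra are stable.

## Current analysis

Photocurrents are decomposed into a rise and up to two decay exponentials
by variable projection.  `modify_current` rescales component amplitudes
and lifetimes; `align_current` finds the nonnegative scale matching a
measured trace to a model's conductive concentration;
`required_fast_acceleration` scans acceleration factors of the fast decay
component (nonnegative least squares per factor) and returns the factor
minimizing the residual — used to show that a current whose decays are
~10× apart cannot match a spectral profile whose two slowest lifetimes are
>100× apart without accelerating the fast component more than fivefold.

## Reproducibility

Every stochastic step draws from `numpy.random.default_rng(seed)` seeded
from the run configuration; the pipeline records per-stage wall times and
writes all artifacts as text (CSV/JSON).
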