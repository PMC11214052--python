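import numpy as np
import pytest

from acrcycles import (default_basis, default_times, deconvolve_composition,
                       global_exp_fit, sequential_from_b, svd_rank)
from acrcycles.decompose import (ApparentKinetics,
                                 amplitude_spectra_for_lifetimes)
from acrcycles.synth import wt_like_dataset


def two_exp_dataset(tau1=1e-4, tau2=1e-2, seed=0, noise_sd=0.0):
    """K -> L -> (final R) style two-exponential dataset."""
    basis = default_basis()
    t = default_times(150)
    k1, k2 = 1.0 / tau1, 1.0 / tau2
    cK = np.exp(-k1 * t)
    cL = k1 / (k2 - k1) * (np.exp(-k1 * t) - np.exp(-k2 * t))
    cR = 1.0 - cK - cL
    agg = np.zeros((4, t.size))
    agg[0], agg[1], agg[3] = cK, cL, cR
    D = basis.E @ agg
    if noise_sd > 0:
        D = D + noise_sd * np.random.default_rng(seed).standard_normal(D.shape)
    from acrcycles.synth import SyntheticDataset
    return SyntheticDataset(grid=basis.grid, times=t, D=D,
                            noise_sd=noise_sd, seed=seed)


def test_svd_rank_noiseless_and_noisy():
    assert svd_rank(wt_like_dataset(noise_frac=0.0)) == 4
    assert svd_rank(wt_like_dataset(seed=5, noise_frac=0.005)) == 4


def test_svd_rank_empty_rejected():
    with pytest.raises(ValueError):
        svd_rank(np.zeros((0, 0)))


def test_global_exp_fit_recovers_two_lifetimes():
    ds = two_exp_dataset()
    kin = global_exp_fit(ds, n_exp=2, seed=0)
    assert kin.lifetimes == pytest.approx([1e-4, 1e-2], rel=1e-6)
    assert kin.fit_residual < 1e-10
    assert kin.b_spectra.shape == (176, 3)


def test_global_exp_fit_validation():
    ds = two_exp_dataset()
    with pytest.raises(ValueError):
        global_exp_fit(ds, n_exp=0)
    with pytest.raises(ValueError):
        global_exp_fit(ds, n_exp=1, fixed_lifetimes=[-1.0])


def test_amplitude_spectra_linear_solve_matches_fit():
    ds = two_exp_dataset()
    kin = global_exp_fit(ds, n_exp=2, seed=0)
    B = amplitude_spectra_for_lifetimes(ds, kin.lifetimes)
    assert np.allclose(B, kin.b_spectra, atol=1e-9)


def test_sequential_round_trip():
    ds = two_exp_dataset()
    kin = global_exp_fit(ds, n_exp=2, seed=0)
    seq = sequential_from_b(kin)
    # In1 is the initial state: pure K-like spectrum
    basis = default_basis()
    assert np.allclose(seq.spectra[:, 0], basis.column("K-like"), atol=1e-6)
    comp = deconvolve_composition(seq, basis)
    assert comp.entry("K-like", "In1") == pytest.approx(1.0, abs=1e-6)
    assert comp.entry("L-like", "In2") == pytest.approx(1.0, abs=1e-4)
    assert comp.entry("R", "In3") == pytest.approx(1.0, abs=1e-6)
    # normalized columns
    assert np.allclose(comp.fractions.sum(axis=0), 1.0, atol=1e-9)


def test_sequential_requires_decreasing_rates():
    kin = ApparentKinetics(lifetimes=np.array([1e-3, 1e-3]),
                           b_spectra=np.zeros((5, 3)),
                           fit_residual=0.0, wavelengths=np.arange(5.0))
    with pytest.raises(ValueError):
        sequential_from_b(kin)


def test_misfit_residual_elevated():
    ds = two_exp_dataset(noise_sd=1e-3, seed=4)
    good = global_exp_fit(ds, n_exp=2, seed=0)
    bad = global_exp_fit(ds, n_exp=1, seed=0)
    assert good.fit_residual == pytest.approx(1e-3, rel=0.05)
    assert bad.fit_residual > 2.0 * good.fit_residual
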