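import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from acrcycles.spectral import (DEFAULT_FORM_PARAMS, RankDeficientBasisWarning,
                                WavelengthGrid, build_basis, default_basis,
                                default_grid, make_spectral_form,
                                nm_to_wavenumber, skewed_gaussian)


def test_default_grid_shape_and_monotonic():
    g = default_grid()
    assert g.n == 176
    assert g.values[0] == 350.0 and g.values[-1] == 700.0
    assert np.all(np.diff(g.values) > 0)
    assert np.all(np.diff(g.wavenumbers) < 0)


def test_grid_validation():
    with pytest.raises(ValueError):
        WavelengthGrid(np.array([500.0]))
    with pytest.raises(ValueError):
        WavelengthGrid(np.array([500.0, 400.0]))


def test_skewed_gaussian_peak_and_fwhm():
    nu = np.linspace(10000.0, 30000.0, 20001)
    peak, width, amp = 20000.0, 4000.0, 1.3
    y = skewed_gaussian(nu, peak, width, 0.0, amp)
    assert y.max() == pytest.approx(amp, rel=1e-9)
    assert nu[np.argmax(y)] == pytest.approx(peak, abs=1.0)
    half = nu[y >= amp / 2]
    assert half.max() - half.min() == pytest.approx(width, rel=1e-3)
    # nonzero skew keeps the maximum location and value
    ys = skewed_gaussian(nu, peak, width, 0.3, amp)
    assert ys.max() == pytest.approx(amp, rel=1e-9)
    assert nu[np.argmax(ys)] == pytest.approx(peak, abs=2.0)


@given(st.floats(min_value=-0.5, max_value=0.5),
       st.floats(min_value=1000.0, max_value=8000.0))
def test_skewed_gaussian_nonnegative(skew, width):
    nu = np.linspace(12000.0, 30000.0, 500)
    y = skewed_gaussian(nu, 19000.0, width, skew, 1.0)
    assert np.all(y >= 0)
    assert np.all(np.isfinite(y))


def test_make_spectral_form_validation():
    g = default_grid()
    with pytest.raises(ValueError, match="width"):
        make_spectral_form("X", 20000.0, -1.0, 0.0, 1.0, g)
    with pytest.raises(ValueError, match="amplitude"):
        make_spectral_form("X", 20000.0, 4000.0, 0.0, 0.0, g)
    with pytest.raises(ValueError, match="outside grid"):
        make_spectral_form("X", 5000.0, 4000.0, 0.0, 1.0, g)


def test_default_basis_structure():
    b = default_basis()
    assert b.form_names == ("K-like", "L-like", "M", "R")
    assert b.E.shape == (176, 4)
    assert np.all(b.E >= 0)
    assert np.isfinite(b.condition_number)
    # peaks in the configured order
    for name in b.form_names:
        peak_nm = DEFAULT_FORM_PARAMS[name]["peak_nm"]
        lam_max = b.grid.values[np.argmax(b.column(name))]
        assert lam_max == pytest.approx(peak_nm, abs=4.0)


def test_rank_deficient_basis_warns():
    g = default_grid()
    f = make_spectral_form("A", nm_to_wavenumber(540.0), 4200.0, 0.25, 1.0, g)
    f2 = make_spectral_form("B", nm_to_wavenumber(540.0), 4200.0, 0.25, 1.0, g)
    with pytest.warns(RankDeficientBasisWarning):
        build_basis([f, f2])


def test_build_basis_requires_shared_grid():
    g1, g2 = default_grid(), default_grid(360.0, 700.0)
    f1 = make_spectral_form("A", 20000.0, 4000.0, 0.0, 1.0, g1)
    f2 = make_spectral_form("B", 22000.0, 4000.0, 0.0, 1.0, g2)
    with pytest.raises(ValueError):
        build_basis([f1, f2])
    with pytest.raises(ValueError):
        build_basis([])
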