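"""Spectral forms and basis matrices for photocycle intermediate spectra.

Time-resolved difference spectra of channelrhodopsin photoreactions decompose
into a small number of independent *spectral forms* -- here a red-absorbing
K-like band, a blue-shifted L-like band, a deprotonated-Schiff-base M band
near 400 nm and a recovered R band.  Several kinetically distinct intermediate
states may share one form (isospectral states), which is why the basis matrix
``E`` and the state->form mapping are kept separate throughout the package.

Band shapes are modeled as skewed Gaussians on the energy (wavenumber) scale,
where retinal-protein absorption bands have their characteristic shape.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "SpectralForm",
    "SpectralBasis",
    "default_grid",
    "make_spectral_form",
    "build_basis",
    "default_basis",
    "DEFAULT_FORM_PARAMS",
    "RankDeficientBasisWarning",
]

#: Default band parameters for the four spectral forms.  The peaks follow the
#: qualitative red / blue-shifted / deprotonated / recovered ordering
#: (K-like ~540 nm, L-like ~480 nm, M ~400 nm, R ~515 nm); widths and skews
#: are representative of retinal-protein visible bands.  These are synthetic
#: stand-ins -- configuration, not measured values.
DEFAULT_FORM_PARAMS: dict[str, dict[str, float]] = {
    "K-like": {"peak_nm": 540.0, "width": 4200.0, "skew": 0.25, "amplitude": 1.0},
    "L-like": {"peak_nm": 480.0, "width": 4000.0, "skew": 0.25, "amplitude": 1.0},
    "M": {"peak_nm": 400.0, "width": 3600.0, "skew": 0.20, "amplitude": 0.9},
    "R": {"peak_nm": 515.0, "width": 3900.0, "skew": 0.25, "amplitude": 1.0},
}

FORM_ORDER = ("K-like", "L-like", "M", "R")


class RankDeficientBasisWarning(UserWarning):
    """Raised when a spectral basis is (near-)rank deficient."""


def nm_to_wavenumber(nm):
    """Convert wavelength (nm) to wavenumber (cm^-1)."""
    return 1.0e7 / np.asarray(nm, dtype=float)


def wavenumber_to_nm(wn):
    """Convert wavenumber (cm^-1) to wavelength (nm)."""
    return 1.0e7 / np.asarray(wn, dtype=float)


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength grid (nm) with wavenumber view."""

    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError("grid must be a 1-d array with at least 2 points")
        if not np.all(np.diff(vals) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        object.__setattr__(self, "values", vals)

    @property
    def wavenumbers(self) -> np.ndarray:
        """Wavenumbers (cm^-1); decreasing along the grid."""
        return nm_to_wavenumber(self.values)

    @property
    def n(self) -> int:
        return self.values.size

    def __eq__(self, other):
        return isinstance(other, WavelengthGrid) and np.array_equal(
            self.values, other.values
        )

    def __hash__(self):
        return hash(self.values.tobytes())


def default_grid(start: float = 350.0, stop: float = 700.0, step: float = 2.0) -> WavelengthGrid:
    """Default 350-700 nm grid at 2 nm spacing (176 points)."""
    return WavelengthGrid(np.arange(start, stop + 0.5 * step, step))


@dataclass(frozen=True)
class SpectralForm:
    """A single nonnegative, single-peaked absorption band on a grid."""

    name: str
    grid: WavelengthGrid
    absorbance: np.ndarray
    peak_wavenumber: float
    width: float
    skew: float

    def __post_init__(self):
        a = np.asarray(self.absorbance, dtype=float)
        if a.shape != (self.grid.n,):
            raise ValueError("absorbance length must match grid")
        if np.any(a < 0):
            raise ValueError("absorbance must be nonnegative")
        object.__setattr__(self, "absorbance", a)

    @property
    def peak_nm(self) -> float:
        return float(wavenumber_to_nm(self.peak_wavenumber))


def skewed_gaussian(wavenumbers: np.ndarray, peak: float, width: float,
                    skew: float, amplitude: float) -> np.ndarray:
    """Skewed-Gaussian (log-normal) band on the wavenumber scale.

    For ``skew == 0`` this is a Gaussian with FWHM ``width``; nonzero skew
    stretches one tail while keeping the maximum at ``peak`` with value
    ``amplitude``.
    """
    nu = np.asarray(wavenumbers, dtype=float)
    ln2 = np.log(2.0)
    if abs(skew) < 1e-12:
        return amplitude * np.exp(-4.0 * ln2 * ((nu - peak) / width) ** 2)
    arg = 1.0 + 2.0 * skew * (nu - peak) / width
    out = np.zeros_like(nu)
    ok = arg > 0
    out[ok] = amplitude * np.exp(-ln2 * (np.log(arg[ok]) / skew) ** 2)
    return out


def make_spectral_form(name: str, peak_wavenumber: float, width: float,
                       skew: float, amplitude: float,
                       grid: WavelengthGrid) -> SpectralForm:
    """Generate a single-peaked band in wavenumber space, sampled on ``grid``.

    Parameters
    ----------
    peak_wavenumber, width : cm^-1 (width is the FWHM of the unskewed band)
    skew : dimensionless asymmetry; 0 gives a symmetric Gaussian
    amplitude : peak absorbance, arbitrary units
    """
    if width <= 0:
        raise ValueError(f"width must be positive, got {width}")
    if amplitude <= 0:
        raise ValueError(f"amplitude must be positive, got {amplitude}")
    wn = grid.wavenumbers
    lo, hi = wn.min(), wn.max()
    if not (lo <= peak_wavenumber <= hi):
        raise ValueError(
            f"peak {peak_wavenumber:.0f} cm^-1 outside grid range "
            f"[{lo:.0f}, {hi:.0f}] cm^-1: basis unusable"
        )
    absorbance = skewed_gaussian(wn, peak_wavenumber, width, skew, amplitude)
    return SpectralForm(name=name, grid=grid, absorbance=absorbance,
                        peak_wavenumber=float(peak_wavenumber),
                        width=float(width), skew=float(skew))


@dataclass(frozen=True)
class SpectralBasis:
    """Matrix E of spectral forms (n_wavelengths x n_forms)."""

    grid: WavelengthGrid
    form_names: tuple[str, ...]
    E: np.ndarray
    condition_number: float = field(default=np.nan)

    def __post_init__(self):
        E = np.asarray(self.E, dtype=float)
        if E.shape != (self.grid.n, len(self.form_names)):
            raise ValueError("E shape must be (n_wavelengths, n_forms)")
        if np.any(E < 0):
            raise ValueError("basis entries must be nonnegative")
        object.__setattr__(self, "E", E)

    @property
    def n_forms(self) -> int:
        return len(self.form_names)

    def column(self, name: str) -> np.ndarray:
        return self.E[:, self.form_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.E, columns=list(self.form_names),
                            index=pd.Index(self.grid.values, name="wavelength_nm"))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def build_basis(forms: list[SpectralForm],
                cond_warn: float = 1e8) -> SpectralBasis:
    """Stack spectral forms into the basis matrix E (column order = input order).

    A warning carrying the condition number is emitted when the columns are
    (near-)linearly dependent.
    """
    if len(forms) < 1:
        raise ValueError("need at least one spectral form")
    grid = forms[0].grid
    for f in forms[1:]:
        if f.grid != grid:
            raise ValueError("all forms must share the same wavelength grid")
    E = np.column_stack([f.absorbance for f in forms])
    if E.shape[1] > 1:
        cond = float(np.linalg.cond(E))
    else:
        cond = 1.0
    if not np.isfinite(cond) or cond > cond_warn:
        warnings.warn(
            f"spectral basis is near rank-deficient (condition number {cond:.3g})",
            RankDeficientBasisWarning,
        )
    return SpectralBasis(grid=grid, form_names=tuple(f.name for f in forms),
                         E=E, condition_number=cond)


def default_basis(grid: WavelengthGrid | None = None,
                  params: dict | None = None) -> SpectralBasis:
    """Basis of the four default forms (K-like, L-like, M, R)."""
    grid = grid or default_grid()
    params = params or DEFAULT_FORM_PARAMS
    forms = []
    for name in FORM_ORDER:
        p = params[name]
        forms.append(make_spectral_form(
            name, nm_to_wavenumber(p["peak_nm"]), p["width"], p["skew"],
            p["amplitude"], grid))
    return build_basis(forms)


def basis_params_json(params: dict | None = None) -> str:
    """JSON sidecar with the band parameters used to build a basis."""
    return json.dumps(params or DEFAULT_FORM_PARAMS, indent=2)
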