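"""Synthetic time-resolved absorbance data from a parallel-cycle ground truth.

The generator emulates a flash-photolysis experiment on an anion
channelrhodopsin: difference-absorbance matrices D(lambda, t) on a 350-700 nm
grid over 100 ns - 1 s, produced by a known parallel-photocycle model, plus
the matching photocurrent trace.  The default ground truth is "WT-like": a
conductive cycle carrying 0.51 of the excited population (K -> O1 with a
spectrally silent opening step, O1 branching into O2 / N2 / M / R, slow
recovery) in parallel with a nonconductive cycle carrying 0.49
(L1 <-> K <-> L2 -> N1 -> branches), the two cycles sharing the early-ms and
late-ms apparent rates.  Five well-separated apparent lifetimes span ~0.5 us
to ~100 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

from .current import CurrentTrace
from .kinetics import (KineticScheme, TimeEvolution, Transition, branch_rates,
                       build_kinetic_matrix, default_times, eigen_solve,
                       time_evolution)
from .spectral import SpectralBasis, WavelengthGrid, default_basis

__all__ = [
    "GroundTruthModel",
    "SyntheticDataset",
    "DEFAULT_WT_LIKE",
    "wt_like_model",
    "simulate_absorbance",
    "simulate_current",
    "wt_like_dataset",
    "form_concentrations",
]

#: Ground-truth parameters of the default WT-like two-cycle model.  The
#: conductive/nonconductive split is 0.51/0.49; microscopic rates are chosen
#: to give five decade-separated apparent lifetimes (~0.5 us, ~6 us, ~90 us,
#: 2 ms, 100 ms); the channel-opening K->O1 step (spectrally silent) is
#: somewhat faster than the third apparent rate, as seen in the current rise.
#: The shared late states in In5 split 0.43 : 0.215 : 0.215 (L-like N2 : M :
#: early R) proportionally between the cycles.
DEFAULT_WT_LIKE: dict = {
    "conductive_fraction": 0.51,
    "o2_fraction": 0.14,
    "k_open": 2.5e4,           # s^-1, silent channel-opening step
    "k_app4": 500.0,           # s^-1, early-ms branching rate (both cycles)
    "k_app5": 10.0,            # s^-1, late-ms recovery rate (both cycles)
    # nonconductive equilibration L1 <-> K <-> L2 -> N1
    "k_K_L1": 1.2e6, "k_L1_K": 8.0e5,
    "k_K_L2": 9.0e4, "k_L2_K": 6.0e4,
    "k_L2_N1": 3.0e4,
    # fractions formed in the O1 branching step (conductive cycle):
    # O2, N2, M, early R
    "cycle1_branch": {"O2": 0.14, "N2": 0.185, "M": 0.0925, "R": 0.0925},
    # fractions formed in the N1 branching step (nonconductive cycle)
    "cycle2_branch": {"N2": 0.245, "M": 0.1225, "R": 0.1225},
}


@dataclass(frozen=True)
class GroundTruthModel:
    """Full forward model: parallel-cycle scheme, basis and state->form map."""

    scheme: KineticScheme
    basis: SpectralBasis
    state_to_form: dict[str, str]
    cycle_schemes: dict[str, KineticScheme]
    params: dict

    @property
    def grid(self) -> WavelengthGrid:
        return self.basis.grid


def _cycle1_scheme(p: dict) -> KineticScheme:
    br = p["cycle1_branch"]
    names = list(br)
    rates = branch_rates(p["k_app4"], [br[n] for n in names])
    trans = [Transition("K1", "O1", p["k_open"])]
    state_of = {"O2": "O2", "N2": "N2a", "M": "Ma", "R": "R1"}
    for name, rate in zip(names, rates):
        trans.append(Transition("O1", state_of[name], rate))
    for s in ("O2", "N2a", "Ma"):
        trans.append(Transition(s, "R1", p["k_app5"]))
    return KineticScheme(
        states=("K1", "O1", "O2", "N2a", "Ma", "R1"),
        transitions=tuple(trans),
        conductive={"O1": True, "O2": True},
        initial={"K1": p["conductive_fraction"]},
    )


def _cycle2_scheme(p: dict) -> KineticScheme:
    br = p["cycle2_branch"]
    names = list(br)
    rates = branch_rates(p["k_app4"], [br[n] for n in names])
    trans = [
        Transition("K2", "L1", p["k_K_L1"]),
        Transition("L1", "K2", p["k_L1_K"]),
        Transition("K2", "L2", p["k_K_L2"]),
        Transition("L2", "K2", p["k_L2_K"]),
        Transition("L2", "N1", p["k_L2_N1"]),
    ]
    state_of = {"N2": "N2b", "M": "Mb", "R": "R2"}
    for name, rate in zip(names, rates):
        trans.append(Transition("N1", state_of[name], rate))
    for s in ("N2b", "Mb"):
        trans.append(Transition(s, "R2", p["k_app5"]))
    return KineticScheme(
        states=("K2", "L1", "L2", "N1", "N2b", "Mb", "R2"),
        transitions=tuple(trans),
        conductive={},
        initial={"K2": 1.0 - p["conductive_fraction"]},
    )


WT_STATE_TO_FORM = {
    "K1": "K-like", "O1": "K-like", "O2": "K-like", "K2": "K-like",
    "L1": "L-like", "L2": "L-like", "N1": "L-like",
    "N2a": "L-like", "N2b": "L-like",
    "Ma": "M", "Mb": "M",
    "R1": "R", "R2": "R",
}


def wt_like_model(grid: WavelengthGrid | None = None,
                  params: dict | None = None) -> GroundTruthModel:
    """Default WT-like two-cycle ground truth (conductive 0.51 / 0.49)."""
    p = dict(DEFAULT_WT_LIKE)
    if params:
        p.update(params)
    c1 = _cycle1_scheme(p)
    c2 = _cycle2_scheme(p)
    scheme = c1.combine(c2)
    basis = default_basis(grid)
    return GroundTruthModel(scheme=scheme, basis=basis,
                            state_to_form=dict(WT_STATE_TO_FORM),
                            cycle_schemes={"cycle1": c1, "cycle2": c2},
                            params=p)


@dataclass(frozen=True)
class SyntheticDataset:
    """Difference-absorbance matrix with its generating model and noise spec."""

    grid: WavelengthGrid
    times: np.ndarray
    D: np.ndarray  # n_wavelengths x n_times
    noise_sd: float
    seed: int
    ground_truth: GroundTruthModel | None = None

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("grid/wavelength_nm", data=self.grid.values)
            f.create_dataset("times", data=self.times)
            f.create_dataset("D", data=self.D)
            meta = f.create_group("meta")
            meta.attrs["noise_sd"] = self.noise_sd
            meta.attrs["seed"] = self.seed
            if self.ground_truth is not None:
                meta.attrs["scheme_json"] = self.ground_truth.scheme.to_json()

    @classmethod
    def from_hdf5(cls, path) -> "SyntheticDataset":
        with h5py.File(path, "r") as f:
            grid = WavelengthGrid(f["grid/wavelength_nm"][...])
            return cls(grid=grid, times=f["times"][...], D=f["D"][...],
                       noise_sd=float(f["meta"].attrs["noise_sd"]),
                       seed=int(f["meta"].attrs["seed"]))

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.D, index=pd.Index(self.grid.values,
                                                 name="wavelength_nm"),
                          columns=[f"{t:.6e}" for t in self.times])
        df.to_csv(path)


def form_concentrations(model: GroundTruthModel, times) -> tuple[np.ndarray, TimeEvolution]:
    """Per-form aggregated concentrations (n_forms x n_times) and the evolution."""
    sol = eigen_solve(build_kinetic_matrix(model.scheme), model.scheme.c0())
    evo = time_evolution(sol, times)
    forms = model.basis.form_names
    agg = np.zeros((len(forms), len(evo.times)))
    for i, s in enumerate(model.scheme.states):
        agg[forms.index(model.state_to_form[s])] += evo.concentrations[:, i]
    return agg, evo


def simulate_absorbance(model: GroundTruthModel, times=None,
                        noise_sd: float = 0.0, seed: int = 0,
                        noise_sd_per_wavelength=None) -> SyntheticDataset:
    """Forward-simulate D = E x (form concentrations) + Gaussian noise.

    Parallel cycles enter additively through the combined scheme.  Noise is
    i.i.d. Gaussian by default; a per-wavelength SD vector makes it
    heteroscedastic.  Bit-exact reproducible from (model, noise level, seed).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    times = default_times() if times is None else np.asarray(times, dtype=float)
    agg, _ = form_concentrations(model, times)
    D = model.basis.E @ agg
    if noise_sd_per_wavelength is not None:
        sd = np.asarray(noise_sd_per_wavelength, dtype=float)[:, None]
        D = D + sd * np.random.default_rng(seed).standard_normal(D.shape)
        noise_sd = float(np.mean(sd))
    elif noise_sd > 0:
        D = D + noise_sd * np.random.default_rng(seed).standard_normal(D.shape)
    return SyntheticDataset(grid=model.grid, times=times, D=D,
                            noise_sd=float(noise_sd), seed=seed,
                            ground_truth=model)


def simulate_current(evolution: TimeEvolution, conductive_mask, scale: float = 1.0,
                     noise_sd: float = 0.0, seed: int = 0) -> CurrentTrace:
    """Current trace = scale x sum of conductive-state concentrations + noise."""
    mask = np.asarray(conductive_mask, dtype=bool)
    y = scale * evolution.concentrations[:, mask].sum(axis=1)
    if noise_sd > 0:
        y = y + noise_sd * np.random.default_rng(seed).standard_normal(y.shape)
    return CurrentTrace(times=evolution.times, current=y)


def wt_like_dataset(seed: int = 0, noise_frac: float = 0.005,
                    times=None, grid: WavelengthGrid | None = None,
                    params: dict | None = None) -> SyntheticDataset:
    """WT-like dataset with noise SD = ``noise_frac`` x max |noiseless signal|."""
    model = wt_like_model(grid=grid, params=params)
    times = default_times() if times is None else np.asarray(times, dtype=float)
    clean = simulate_absorbance(model, times, noise_sd=0.0, seed=seed)
    sd = noise_frac * float(np.max(np.abs(clean.D)))
    if sd == 0.0:
        return clean
    return simulate_absorbance(model, times, noise_sd=sd, seed=seed)
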