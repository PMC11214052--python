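"""Photocurrent traces: exponential decomposition, modification, alignment.

The flash-induced channel current of an anion channelrhodopsin rises with the
channel-opening step and decays in two phases carried by the fast- and
slow-decaying conductive states (O1 and O2).  Published current traces are
shape-only (absolute units are never comparable across experiments), so all
alignment against spectroscopically derived concentration profiles is done
through a single nonnegative scale factor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, nnls

from .kinetics import TimeEvolution

__all__ = [
    "CurrentTrace",
    "CurrentComponents",
    "ModificationFactors",
    "decompose_current",
    "modify_current",
    "synthesize_current",
    "align_current",
    "AlignmentReport",
    "required_fast_acceleration",
]


@dataclass(frozen=True)
class CurrentTrace:
    """Normalized photocurrent trace; ``components`` known for synthetic traces."""

    times: np.ndarray  # s
    current: np.ndarray
    components: "CurrentComponents | None" = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        i = np.asarray(self.current, dtype=float)
        if t.shape != i.shape or t.ndim != 1:
            raise ValueError("times and current must be matching 1-d arrays")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "current", i)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.times, "current": self.current}).to_csv(
            path, index=False)


@dataclass(frozen=True)
class CurrentComponents:
    """Exponential components of a current trace.

    Each component is (amplitude, lifetime); the rise amplitude is the (positive)
    magnitude of the rising term, stored with its own lifetime.
    """

    rise: tuple[float, float]
    fast_decay: tuple[float, float]
    slow_decay: tuple[float, float]
    baseline: float = 0.0
    reconstruction_error: float = np.nan

    def to_json(self) -> str:
        return json.dumps({
            "rise": {"amplitude": self.rise[0], "lifetime_s": self.rise[1]},
            "fast_decay": {"amplitude": self.fast_decay[0], "lifetime_s": self.fast_decay[1]},
            "slow_decay": {"amplitude": self.slow_decay[0], "lifetime_s": self.slow_decay[1]},
            "baseline": self.baseline,
            "reconstruction_error": self.reconstruction_error,
        }, indent=2)


@dataclass(frozen=True)
class ModificationFactors:
    """Per-component amplitude and time (acceleration) factors.

    An amplitude factor multiplies the component amplitude; a time factor of
    f accelerates the component, i.e. divides its lifetime by f.
    """

    amplitude: dict[str, float] = field(default_factory=dict)
    time: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for d in (self.amplitude, self.time):
            for k, v in d.items():
                if k not in ("rise", "fast_decay", "slow_decay"):
                    raise ValueError(f"unknown component {k!r}")
                if not (v > 0):
                    raise ValueError("factors must be positive")

    def to_json(self) -> str:
        return json.dumps({"amplitude": self.amplitude, "time": self.time}, indent=2)


def _exp_design(times: np.ndarray, taus: np.ndarray) -> np.ndarray:
    X = np.exp(-(times[:, None] / taus[None, :]).clip(max=700))
    return np.column_stack([X, np.ones_like(times)])


def _varpro_exp_fit(times: np.ndarray, y: np.ndarray, n_exp: int,
                    seed: int = 0, n_starts: int = 12):
    """Sum-of-exponentials fit with free-sign amplitudes (variable projection)."""
    logt_lo, logt_hi = np.log10(times[0]), np.log10(times[-1])

    def residual(logtau):
        X = _exp_design(times, 10.0 ** logtau)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        return X @ coef - y

    rng = np.random.default_rng(seed)
    best = None
    for k in range(n_starts):
        if k == 0:
            x0 = np.linspace(logt_lo + 0.5, logt_hi - 0.5, n_exp)
        else:
            x0 = np.sort(rng.uniform(logt_lo, logt_hi, n_exp))
        try:
            sol = least_squares(residual, x0, method="trf",
                                bounds=(logt_lo - 2, logt_hi + 2))
        except Exception:
            continue
        if best is None or sol.cost < best.cost - 1e-15 * max(best.cost, 1):
            best = sol
    if best is None:
        raise RuntimeError("current exponential fit failed to converge")
    taus = np.sort(10.0 ** best.x)
    X = _exp_design(times, taus)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    recon_err = float(np.sqrt(np.mean((X @ coef - y) ** 2)))
    return taus, coef[:-1], float(coef[-1]), recon_err


def decompose_current(trace: CurrentTrace, n_components: int = 3,
                      seed: int = 0) -> CurrentComponents:
    """Fit a sum of exponentials and classify rise / fast / slow components.

    Negative-amplitude terms are rise components (the fastest kept); positive
    terms sorted by lifetime give the fast and slow decays.
    """
    t, y = trace.times, trace.current
    if np.max(np.abs(y)) == 0:
        return CurrentComponents((0.0, np.nan), (0.0, np.nan), (0.0, np.nan),
                                 0.0, 0.0)
    taus, amps, baseline, err = _varpro_exp_fit(t, y, n_components, seed=seed)
    rise = (0.0, np.nan)
    decays = []
    for a, tau in zip(amps, taus):
        if a < 0:
            if rise[0] == 0.0 or tau < rise[1]:
                rise = (-a, tau)
        else:
            decays.append((a, tau))
    decays.sort(key=lambda p: p[1])
    # drop negligible decay terms so fast/slow classification is stable
    big = max((a for a, _ in decays), default=0.0)
    decays = [d for d in decays if d[0] > 1e-9 * max(big, 1e-300)] or [(0.0, np.nan)]
    fast = decays[0]
    slow = decays[-1] if len(decays) > 1 else (0.0, np.nan)
    return CurrentComponents(rise=rise, fast_decay=fast, slow_decay=slow,
                             baseline=baseline, reconstruction_error=err)


def synthesize_current(components: CurrentComponents, times) -> CurrentTrace:
    """Re-synthesize a trace from exponential components on a time grid."""
    t = np.asarray(times, dtype=float)
    y = np.full_like(t, components.baseline)
    a, tau = components.rise
    if a != 0 and np.isfinite(tau):
        y -= a * np.exp(-t / tau)
    for a, tau in (components.fast_decay, components.slow_decay):
        if a != 0 and np.isfinite(tau):
            y += a * np.exp(-t / tau)
    return CurrentTrace(times=t, current=y, components=components)


def modify_current(components: CurrentComponents, factors: ModificationFactors,
                   times) -> CurrentTrace:
    """Scale amplitudes and accelerate lifetimes per component, re-synthesize.

    A time factor f divides the component lifetime by f (factor > 1
    accelerates, < 1 slows down).
    """
    def mod(comp, name):
        a, tau = comp
        a *= factors.amplitude.get(name, 1.0)
        tau = tau / factors.time.get(name, 1.0)
        return (a, tau)

    new = CurrentComponents(
        rise=mod(components.rise, "rise"),
        fast_decay=mod(components.fast_decay, "fast_decay"),
        slow_decay=mod(components.slow_decay, "slow_decay"),
        baseline=components.baseline,
    )
    return synthesize_current(new, times)


@dataclass(frozen=True)
class AlignmentReport:
    scale: float
    residual_rms: float
    normalized_residual: float
    plateau_model: float
    plateau_current: float


def align_current(trace: CurrentTrace, evolution: TimeEvolution,
                  conductive_mask) -> AlignmentReport:
    """Align a current trace with the summed conductive-state concentrations.

    A single nonnegative scale minimizing the squared residual is fitted; the
    scale is invariant to multiplying both inputs by a common constant.
    """
    mask = np.asarray(conductive_mask, dtype=bool)
    if mask.shape != (len(evolution.states),):
        raise ValueError("conductive mask length must match states")
    if not mask.any():
        raise ValueError("no conductive state: nothing to align the current to")
    g_model = evolution.concentrations[:, mask].sum(axis=1)
    # interpolate the model onto the trace's time grid (log-time interpolation)
    g = np.interp(np.log(trace.times), np.log(evolution.times), g_model)
    denom = float(g @ g)
    scale = max(0.0, float(trace.current @ g) / denom) if denom > 0 else 0.0
    res = trace.current - scale * g
    rms = float(np.sqrt(np.mean(res ** 2)))
    norm = rms / max(float(np.sqrt(np.mean(trace.current ** 2))), 1e-300)
    return AlignmentReport(scale=scale, residual_rms=rms,
                           normalized_residual=norm,
                           plateau_model=float(g.max()),
                           plateau_current=float(trace.current.max()))


def required_fast_acceleration(fast_lifetime: float, slow_lifetime: float,
                               profile_times, profile,
                               factors=None) -> tuple[float, np.ndarray]:
    """Acceleration of the fast current component needed to match a profile.

    Scans time-scaling factors for the fast decay component (the slow one kept
    fixed), refitting nonnegative amplitudes at each factor, and returns the
    factor minimizing the residual together with the scanned residual curve.
    Used to demonstrate that a bi-exponential current whose components differ
    ~10x cannot follow a K-like profile whose two slowest decays differ >100x
    without an unrealistic acceleration of its fast component.
    """
    t = np.asarray(profile_times, dtype=float)
    y = np.asarray(profile, dtype=float)
    if factors is None:
        factors = np.geomspace(0.5, 100.0, 600)
    residuals = np.empty(len(factors))
    for i, f in enumerate(factors):
        X = np.column_stack([
            np.exp(-(t / (fast_lifetime / f)).clip(max=700)),
            np.exp(-(t / slow_lifetime).clip(max=700)),
        ])
        coef, rnorm = nnls(X, y)
        residuals[i] = rnorm
    best = int(np.argmin(residuals))
    return float(factors[best]), residuals
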