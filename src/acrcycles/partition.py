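"""Partitioning spectral forms between conductive and nonconductive cycles.

The channel current anchors the partition: the fraction of the red-absorbing
K-like spectral form that belongs to the conductive cycle equals the current
plateau, and equals the K-like content of the sequential intermediates In4 and
In5 (denoted a4 and a5).  The conductive Cycle1 then carries K (a4 through
In1-In3), the open-channel O state (a4 in In4, a5 in In5) and a4 of the
recovered R; the remaining 1 - a4 forms the nonconductive Cycle2
(K equilibrating with L1/L2, then N1).  The L-like, M and R content of In5
(b5, c5, d5) cannot be assigned to either cycle from the data alone -- these
are the shared states, and any split totaling a4 - a5 complements the
conductive cycle.

Splitting the O state between a fast-decaying O1 (a4 - a5) and a slow-decaying
O2 (a5) yields the three-cycle model (Cycle1a, Cycle1b = K -> O2 -> R,
Cycle2).  The S97E variant at low pH replaces the conductive O1 by a
nonconductive N'1 state with an L'-like spectrum, splitting the In3 K content
between three cycles.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from .decompose import CompositionMatrix

__all__ = [
    "CyclePartition",
    "ThreeCyclePartition",
    "S97ELowPHPartition",
    "partition_two_cycle",
    "split_three_cycle",
    "partition_s97e_lowpH",
    "enumerate_shared_allocations",
    "reassemble_composition",
]

#: Composition matrices are reported to two decimals; derived fractions more
#: negative than this indicate inconsistent data.
NEGATIVE_TOL = 0.02

R2_NOTE = ("Cycle2 recovered-R rendered as the nonconductive fraction 1 - a4 "
           "(the summary table prints a4 for this entry; the derivation text "
           "gives the nonconductive fraction).")


@dataclass(frozen=True)
class CyclePartition:
    """Two-cycle assignment of composition-matrix fractions (per Table rows)."""

    a: np.ndarray  # K-like row (a1..): a[0]=1 by normalization
    conductive_fraction: float  # a4
    # Cycle1: K in In1-In3, O in In4/In5, R in In6
    cycle1: dict[str, float]
    # Cycle2: K in In1-In3, L1+L2 in In2/In3, N1 and early M in In4, R in In6
    cycle2: dict[str, float]
    # Shared (In5): N2 (L-like), M, early R
    shared: dict[str, float]
    metadata: dict = field(default_factory=dict)

    @property
    def shared_total(self) -> float:
        return float(sum(self.shared.values()))

    def to_json(self) -> str:
        return json.dumps({
            "conductive_fraction": self.conductive_fraction,
            "cycle1": self.cycle1, "cycle2": self.cycle2,
            "shared": self.shared, "metadata": self.metadata,
        }, indent=2)


@dataclass(frozen=True)
class ThreeCyclePartition:
    """Cycle1 split into Cycle1a (O1 = a4 - a5) and Cycle1b (K -> O2 -> R)."""

    base: CyclePartition
    o1_fraction: float  # Cycle1a
    o2_fraction: float  # Cycle1b, shares no states with the other cycles

    def to_json(self) -> str:
        return json.dumps({
            "o1_fraction": self.o1_fraction,
            "o2_fraction": self.o2_fraction,
            "base": json.loads(self.base.to_json()),
        }, indent=2)


def _comp_entry(comp: CompositionMatrix, form: str, col: str) -> float:
    if col not in comp.column_names:
        return 0.0
    return comp.entry(form, col)


def partition_two_cycle(comp: CompositionMatrix,
                        conductive_a4: float | None = None,
                        conductive_a5: float | None = None,
                        tol: float = NEGATIVE_TOL) -> CyclePartition:
    """Partition a composition matrix into Cycle1 / Cycle2 / shared states.

    ``conductive_a4`` overrides the conductive K fraction (e.g. taken from the
    current plateau); by default it is the K-like content of In4, which the
    current alignments show to equal the conductive fraction.
    ``conductive_a5`` likewise overrides the slow open-state fraction (e.g.
    derived from the slow current-decay amplitude); default is the K-like
    content of In5.
    """
    a = np.array([_comp_entry(comp, "K-like", c)
                  for c in ("In1", "In2", "In3", "In4", "In5", "In6")])
    b = np.array([_comp_entry(comp, "L-like", c)
                  for c in ("In1", "In2", "In3", "In4", "In5", "In6")])
    c_ = np.array([_comp_entry(comp, "M", col)
                   for col in ("In1", "In2", "In3", "In4", "In5", "In6")])
    d = np.array([_comp_entry(comp, "R", col)
                  for col in ("In1", "In2", "In3", "In4", "In5", "In6")])
    a2, a3, a4, a5 = a[1], a[2], a[3], a[4]
    if conductive_a4 is not None:
        a4 = float(conductive_a4)
    if conductive_a5 is not None:
        a5 = float(conductive_a5)
    for name, val in (("a2 - a4", a2 - a4), ("a3 - a4", a3 - a4)):
        if val < -tol:
            raise ValueError(
                f"inconsistent composition: {name} = {val:.3f} < -{tol} "
                "(conductive fraction exceeds the available K-like form)")
    cycle1 = {
        "K_In1": a4, "K_In2": a4, "K_In3": a4,
        "O_In4": a4, "O_In5": a5, "R_In6": a4,
    }
    cycle2 = {
        "K_In1": 1.0 - a4, "K_In2": a2 - a4, "K_In3": a3 - a4,
        "L12_In2": b[1], "L12_In3": b[2],
        "N1_In4": b[3],
        "M_early_In3": c_[2], "M_early_In4": c_[3],
        "R_In6": 1.0 - a4,
    }
    shared = {"N2": b[4], "M": c_[4], "R_early": d[4]}
    if any(v < -tol for v in list(cycle1.values()) + list(cycle2.values())
           + list(shared.values())):
        raise ValueError("negative derived fraction beyond tolerance")
    return CyclePartition(a=a, conductive_fraction=a4, cycle1=cycle1,
                          cycle2=cycle2, shared=shared,
                          metadata={"note_R2": R2_NOTE, "a5": a5})


def split_three_cycle(partition: CyclePartition,
                      tol: float = NEGATIVE_TOL) -> ThreeCyclePartition:
    """Split the conductive cycle: O1 = a4 - a5 (Cycle1a), O2 = a5 (Cycle1b).

    The K -> O2 step of Cycle1b is assumed to have the same rate as K -> O1,
    and Cycle1b (K -> O2 -> R) shares no intermediates with the other cycles.
    """
    a4 = partition.conductive_fraction
    a5 = partition.cycle1["O_In5"]
    if a5 > a4 + tol:
        raise ValueError(f"a5 = {a5:.3f} exceeds a4 = {a4:.3f}: no valid split")
    return ThreeCyclePartition(base=partition, o1_fraction=a4 - a5,
                               o2_fraction=a5)


@dataclass(frozen=True)
class S97ELowPHPartition:
    """Three-cycle partition of the S97E low-pH kinetics.

    The In3 K content splits between a nonconductive Cycle1a
    (K -> N'1 -> N2 -> R, with N'1 carrying an L'-like spectrum), the
    conductive Cycle1b (K -> O2 -> R) and Cycle2, whose K stays spectrally
    silent through the In3 -> In4 transition.  There are no shared states.
    """

    cycle1a_fraction: float  # nonconductive, N'1 replaces the usual O1
    cycle1b_fraction: float  # conductive O2
    cycle2_fraction: float
    in3_k_total: float
    cycle1a_states: tuple[str, ...] = ("K", "N'1", "N2", "R")
    cycle1a_form_map: dict = field(default_factory=lambda: {
        "K": "K-like", "N'1": "L-prime", "N2": "L-like", "R": "R"})
    cycle1a_conductive: dict = field(default_factory=dict)
    cycle1b_states: tuple[str, ...] = ("K", "O2", "R")

    def to_json(self) -> str:
        return json.dumps({
            "cycle1a_fraction": self.cycle1a_fraction,
            "cycle1b_fraction": self.cycle1b_fraction,
            "cycle2_fraction": self.cycle2_fraction,
            "in3_k_total": self.in3_k_total,
        }, indent=2)


def partition_s97e_lowpH(comp: CompositionMatrix,
                         allocations: dict[str, float],
                         tol: float = 0.01) -> S97ELowPHPartition:
    """Split the In3 K-like fraction between three cycles (S97E, low pH)."""
    required = {"cycle1a", "cycle1b", "cycle2"}
    if set(allocations) != required:
        raise ValueError(f"allocations must have keys {sorted(required)}")
    a3 = _comp_entry(comp, "K-like", "In3")
    total = sum(allocations.values())
    if abs(total - a3) > tol:
        raise ValueError(
            f"allocations sum to {total:.3f}, but In3 K-like content is "
            f"{a3:.3f} (tolerance {tol})")
    return S97ELowPHPartition(
        cycle1a_fraction=float(allocations["cycle1a"]),
        cycle1b_fraction=float(allocations["cycle1b"]),
        cycle2_fraction=float(allocations["cycle2"]),
        in3_k_total=a3,
    )


def enumerate_shared_allocations(partition: CyclePartition, grid_step: float
                                 ) -> list[dict[str, float]]:
    """All lattice splits of the shared states complementing the fast O1 decay.

    Returns the Cycle1 portions of {N2, M, R_early} on a grid of step
    ``grid_step`` whose total equals a4 - a5 (the mass the conductive cycle
    loses in the early-ms branching besides O2); Cycle2 receives the
    remainder.  With zero shared mass the single empty allocation is returned.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    names = ("N2", "M", "R_early")
    totals = np.array([partition.shared[n] for n in names])
    target = partition.conductive_fraction - partition.cycle1["O_In5"]
    if totals.sum() <= 0:
        return [{n: 0.0 for n in names}]
    eps = 1e-9
    axes = [np.arange(0.0, tot + eps, grid_step) for tot in totals]
    out = []
    for combo in itertools.product(*axes):
        if abs(sum(combo) - target) < eps:
            out.append(dict(zip(names, (float(x) for x in combo))))
    return out


def reassemble_composition(partition: CyclePartition) -> np.ndarray:
    """Rebuild the 4 x 6 composition matrix from a partition (mass balance).

    Rows are (K-like, L-like, M, R); must reproduce the input composition
    exactly for every column.
    """
    c1, c2, sh = partition.cycle1, partition.cycle2, partition.shared
    K = np.array([c1["K_In1"] + c2["K_In1"], c1["K_In2"] + c2["K_In2"],
                  c1["K_In3"] + c2["K_In3"], c1["O_In4"], c1["O_In5"], 0.0])
    L = np.array([0.0, c2["L12_In2"], c2["L12_In3"], c2["N1_In4"],
                  sh["N2"], 0.0])
    M = np.array([0.0, 0.0, c2["M_early_In3"], c2["M_early_In4"], sh["M"], 0.0])
    R = np.array([0.0, 0.0, 0.0, 0.0, sh["R_early"],
                  c1["R_In6"] + c2["R_In6"]])
    return np.vstack([K, L, M, R])
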