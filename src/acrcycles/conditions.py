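"""Per-condition conductive anchor fractions for GtACR1 variants.

For each protein/pH condition the channel current (or, where currents are
unavailable, the K-like content of the sequential intermediates In4 and In5)
anchors two fractions: ``a4``, the total conductive K-like fraction, and
``a5``, its slow-decaying part (the O2 state).  The partition arithmetic then
follows: nonconductive fraction = 1 - a4, O1 = a4 - a5, O2 = a5.  The S97E
low-pH condition instead splits its In3 K-like content between three cycles
with no shared states.

These anchors are reference inputs of the worked-condition partitions, kept
as package data so the examples are reproducible without external files.
"""

from __future__ import annotations

import numpy as np

from .decompose import CompositionMatrix
from .partition import (S97ELowPHPartition, ThreeCyclePartition,
                        partition_s97e_lowpH, partition_two_cycle,
                        split_three_cycle)

__all__ = [
    "CONDITION_ANCHORS",
    "condition_composition",
    "condition_partition",
    "s97e_lowpH_condition_partition",
]

#: Anchor fractions per condition label.  Two-cycle conditions carry
#: (a4, a5); the S97E low-pH condition carries the three-way allocation of
#: its In3 K-like content instead.
CONDITION_ANCHORS: dict[str, dict] = {
    "wt_ph74": {"a4": 0.51, "a5": 0.14},
    "wt_ph55": {"a4": 0.38, "a5": 0.09},
    "wt_ph85": {"a4": 0.48, "a5": 0.06},
    "d234n_ph74": {"a4": 0.11, "a5": 0.06},
    "d234n_ph45": {"a4": 0.09, "a5": 0.02},
    "s97e_ph74": {"a4": 0.11, "a5": 0.03},
    "s97e_ph56": {
        "in3_k_allocations": {"cycle1a": 0.07, "cycle1b": 0.03,
                              "cycle2": 0.20},
    },
}


def condition_composition(label: str) -> CompositionMatrix:
    """Minimal normalized composition matrix realizing a condition's anchors.

    Only the K-like row carries the condition's information (a4 in In2-In4,
    a5 in In5); the complement is booked as L-like so every column is a valid
    population.  Sufficient input for the partition arithmetic, which uses
    the K-like row and the In5 column.
    """
    anch = CONDITION_ANCHORS[label]
    if "a4" not in anch:
        raise ValueError(f"condition {label!r} is not a two-cycle condition")
    a4, a5 = anch["a4"], anch["a5"]
    K = np.array([1.0, a4, a4, a4, a5, 0.0])
    L = np.array([0.0, 1 - a4, 1 - a4, 1 - a4, 1 - a5, 0.0])
    M = np.zeros(6)
    R = np.array([0.0, 0.0, 0.0, 0.0, 0.0, 1.0])
    return CompositionMatrix(
        fractions=np.vstack([K, L, M, R]),
        form_names=("K-like", "L-like", "M", "R"),
        column_names=("In1", "In2", "In3", "In4", "In5", "In6"),
        residuals=np.zeros(6))


def condition_partition(label: str) -> ThreeCyclePartition:
    """Two-cycle + O1/O2 partition of a condition from its anchor fractions."""
    return split_three_cycle(partition_two_cycle(condition_composition(label)))


def s97e_lowpH_condition_partition() -> S97ELowPHPartition:
    """Triple-cycle split of the S97E low-pH In3 K-like content."""
    alloc = CONDITION_ANCHORS["s97e_ph56"]["in3_k_allocations"]
    total = float(sum(alloc.values()))
    K = np.array([1.0, total, total, 0.0, 0.0, 0.0])
    L = np.array([0.0, 1 - total, 1 - total, 1.0, 1.0, 0.0])
    M = np.zeros(6)
    R = np.array([0.0, 0.0, 0.0, 0.0, 0.0, 1.0])
    comp = CompositionMatrix(
        fractions=np.vstack([K, L, M, R]),
        form_names=("K-like", "L-like", "M", "R"),
        column_names=("In1", "In2", "In3", "In4", "In5", "In6"),
        residuals=np.zeros(6))
    return partition_s97e_lowpH(comp, dict(alloc))
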