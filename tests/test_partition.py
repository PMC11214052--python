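import numpy as np
import pytest

from acrcycles import (CONDITION_ANCHORS, condition_composition,
                       condition_partition, enumerate_shared_allocations,
                       partition_s97e_lowpH, partition_two_cycle,
                       reassemble_composition, s97e_lowpH_condition_partition,
                       split_three_cycle)


def test_condition_partition_wt_ph74():
    three = condition_partition("wt_ph74")
    assert 1.0 - three.base.conductive_fraction == pytest.approx(0.49, abs=1e-12)
    assert three.o1_fraction == pytest.approx(0.37, abs=1e-12)
    assert three.o2_fraction == pytest.approx(0.14, abs=1e-12)


def test_condition_partition_mass_balance():
    for label, anch in CONDITION_ANCHORS.items():
        if "a4" not in anch:
            continue
        comp = condition_composition(label)
        part = partition_two_cycle(comp)
        rebuilt = reassemble_composition(part)
        assert np.allclose(rebuilt, comp.fractions, atol=1e-12), label
        three = split_three_cycle(part)
        assert three.o1_fraction + three.o2_fraction == pytest.approx(
            anch["a4"], abs=1e-12)


def test_partition_overrides():
    comp = condition_composition("wt_ph74")
    part = partition_two_cycle(comp, conductive_a4=0.50, conductive_a5=0.10)
    assert part.conductive_fraction == 0.50
    assert part.cycle1["O_In5"] == 0.10
    assert part.cycle2["K_In1"] == pytest.approx(0.50)


def test_partition_rejects_inconsistent_composition():
    comp = condition_composition("wt_ph74")
    with pytest.raises(ValueError, match="exceeds the available K-like"):
        partition_two_cycle(comp, conductive_a4=0.9)


def test_split_three_cycle_rejects_a5_above_a4():
    comp = condition_composition("wt_ph74")
    part = partition_two_cycle(comp, conductive_a4=0.2, conductive_a5=0.4)
    with pytest.raises(ValueError, match="exceeds"):
        split_three_cycle(part)


def test_enumerate_shared_allocations():
    comp = condition_composition("wt_ph74")
    part = partition_two_cycle(comp)
    allocs = enumerate_shared_allocations(part, grid_step=0.01)
    target = part.conductive_fraction - part.cycle1["O_In5"]
    assert len(allocs) > 0
    for a in allocs:
        assert sum(a.values()) == pytest.approx(target, abs=1e-8)
        for name, v in a.items():
            assert 0.0 <= v <= part.shared[name] + 1e-9
    with pytest.raises(ValueError):
        enumerate_shared_allocations(part, grid_step=0.0)


def test_s97e_lowpH_partition():
    p = s97e_lowpH_condition_partition()
    assert p.in3_k_total == pytest.approx(0.30, abs=1e-12)
    assert p.cycle1a_fraction == 0.07
    assert p.cycle1b_fraction == 0.03
    assert p.cycle2_fraction == 0.20
    # the nonconductive N'1 replaces the usual conductive O1
    assert p.cycle1a_form_map["N'1"] == "L-prime"
    assert p.cycle1a_conductive == {}


def test_s97e_partition_validation():
    from acrcycles.conditions import condition_composition as cc
    comp = cc("wt_ph74")
    with pytest.raises(ValueError, match="keys"):
        partition_s97e_lowpH(comp, {"cycle1a": 0.1})
    with pytest.raises(ValueError, match="sum"):
        partition_s97e_lowpH(comp, {"cycle1a": 0.3, "cycle1b": 0.3,
                                    "cycle2": 0.3})
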