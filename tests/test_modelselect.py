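"""Constraint generation, admissible rules, ensembles and selection."""

import numpy as np
import pytest

from chainlogic.bfcore import BooleanFunction, unate_directions
from chainlogic.bndyn import StochasticDynamics, attractors
from chainlogic.chainclass import Label, classify
from chainlogic.chaincount import enumerate_class
from chainlogic.modelselect import (
    EnsembleResult,
    NodeConstraint,
    SelectionCriteria,
    SignedNetwork,
    admissible_functions,
    ensemble,
    fixed_point_constraints,
    select_models,
)
from chainlogic.synthgen import random_model
from conftest import bf


def chain_net():
    return SignedNetwork.from_edges(
        [("A", "B", 1), ("B", "A", 1)], nodes=("A", "B")
    )


# ---------------------------------------------------------------------------
# fixed-point constraints


def test_single_activator_io_pairs():
    net = chain_net()
    fps = {
        "ON": {"A": 1, "B": 1},
        "OFF": {"A": 0, "B": 0},
    }
    cons = fixed_point_constraints(net, fps)
    assert cons["B"].io_pairs == {1: 1, 0: 0}
    assert not cons["B"].infeasible


def test_conflicting_requirements_flag_infeasible():
    net = SignedNetwork.from_edges([("A", "B", 1), ("B", "A", 1)])
    fps = {"S1": {"A": 1, "B": 1}, "S2": {"A": 1, "B": 0}}
    # B reads A=1 in both states but must output both 1 and 0
    cons = fixed_point_constraints(net, fps)
    assert cons["B"].infeasible
    assert admissible_functions(cons["B"]) == []


def test_untouched_rows_remain_free():
    net = SignedNetwork.from_edges(
        [("A", "C", 1), ("B", "C", 1), ("A", "A", 1), ("B", "B", 1)],
        nodes=("A", "B", "C"),
    )
    fps = {"S": {"A": 1, "B": 1, "C": 1}}
    cons = fixed_point_constraints(net, fps)
    assert cons["C"].io_pairs == {0b11: 1}  # rows 00, 01, 10 are free


def test_state_length_mismatch_rejected():
    net = chain_net()
    with pytest.raises(ValueError, match="misses"):
        fixed_point_constraints(net, {"S": {"A": 1}})


# ---------------------------------------------------------------------------
# admissible functions


def test_single_activator_chfu_is_identity_rule():
    c = NodeConstraint("B", 1, (1,), {1: 1, 0: 0}, "CHFU")
    fs = admissible_functions(c)
    assert len(fs) == 1
    assert fs[0] == BooleanFunction(1, "01")


def test_sign_conflicting_io_yields_nothing():
    c = NodeConstraint("B", 1, (1,), {1: 0}, "CHFU")
    assert admissible_functions(c) == []


def test_fallback_class_kicks_in():
    # a 2-input XOR-ish requirement admits no chain function; the NCF
    # fallback cannot help either, but a feasible example shows the switch
    c = NodeConstraint("B", 2, (1, 1), {0b11: 1, 0b00: 0}, "CHFU", "NCF")
    fs = admissible_functions(c)
    assert fs, "feasible constraint should admit functions"
    assert all(classify(f).label.is_chain() for f in fs)


@pytest.mark.parametrize("cls", ["CHF0", "CHF1", "CHFU", "NCF"])
@pytest.mark.parametrize("k", [2, 3, 4, 5])
def test_constructive_equals_oracle_filter(cls, k):
    """The constructive generator equals brute filtering of the enumerated
    class by unate signs and pinned rows."""
    rng = np.random.default_rng(k * 31 + len(cls))
    signs = tuple(int(s) for s in rng.choice([1, -1], size=k))
    n_pins = int(rng.integers(0, 3))
    rows = rng.choice(2**k, size=n_pins, replace=False)
    io = {int(r): int(rng.integers(0, 2)) for r in rows}
    c = NodeConstraint("X", k, signs, io, cls)
    got = {f.outputs.tobytes() for f in admissible_functions(c)}
    want = set()
    expect_dir = tuple("positive" if s == 1 else "negative" for s in signs)
    for f in enumerate_class(k, cls):
        if unate_directions(f) != expect_dir:
            continue
        if all(int(f.outputs[r]) == b for r, b in io.items()):
            want.add(f.outputs.tobytes())
    assert got == want


# ---------------------------------------------------------------------------
# ensembles


def test_ensemble_size_is_product_of_counts():
    counts = (1, 1, 1, 1, 1, 5, 1, 1, 12)
    per_node = {f"n{i}": list(range(c)) for i, c in enumerate(counts)}
    ens = EnsembleResult.__new__(EnsembleResult)
    object.__setattr__(ens, "network", None)
    object.__setattr__(ens, "per_node", per_node)
    assert ens.size == 60


def test_empty_choice_empties_the_ensemble():
    per_node = {"a": [1, 2], "b": []}
    ens = EnsembleResult.__new__(EnsembleResult)
    object.__setattr__(ens, "network", None)
    object.__setattr__(ens, "per_node", per_node)
    assert ens.size == 0


def test_ensemble_iterates_each_model_once():
    net = chain_net()
    fps = {"ON": {"A": 1, "B": 1}, "OFF": {"A": 0, "B": 0}}
    cons = fixed_point_constraints(net, fps, cls="NCF")
    per_node = {n: admissible_functions(c) for n, c in cons.items()}
    ens = ensemble(net, per_node)
    models = list(ens)
    assert len(models) == ens.size
    keys = {tuple(f.outputs.tobytes() for f in m.functions) for m in models}
    assert len(keys) == ens.size
    for i, m in enumerate(models):
        assert ens.index_of(m) == i


# ---------------------------------------------------------------------------
# selection


def _own_criteria(model, fps, basin=True):
    """Hierarchy/basin criteria computed from the model's own dynamics."""
    from chainlogic.bndyn import stability_analysis

    states = {
        name: model.bits_to_state([s[n] for n in model.nodes])
        for name, s in fps.items()
    }
    dyn = StochasticDynamics(eta=0.05)
    stab = stability_analysis(model, states, dyn, mode="exact")
    hier = []
    names = list(states)
    for i, u in enumerate(names):
        for v in names[i + 1 :]:
            verdict = stab.verdicts[(u, v)]
            if verdict == "u>v":
                hier.append((v, u))
            elif verdict == "v>u":
                hier.append((u, v))
    floor = None
    if basin:
        atts = attractors(model)
        fp_set = set(states.values())
        floor = sum(
            a.basin_size for a in atts if a.is_fixed_point and a.states[0] in fp_set
        )
    return SelectionCriteria(tuple(hier), basin_floor=floor, dynamics=dyn)


def test_generating_model_recovered_from_own_criteria():
    rng = np.random.default_rng(17)
    done = 0
    while done < 5:
        net, model, fps = random_model(5, 3, "CHFU", rng, min_fixed_points=2)
        cons = fixed_point_constraints(net, fps, cls="CHFU", fallback_cls="NCF")
        per_node = {n: admissible_functions(c) for n, c in cons.items()}
        ens = ensemble(net, per_node)
        if ens.size > 300:
            continue
        idx = ens.index_of(model)
        assert idx is not None, "generating model must satisfy its own constraints"
        crit = _own_criteria(model, fps)
        res = select_models(ens, fps, crit)
        assert idx in res.selected
        done += 1


def test_hierarchy_reversal_excludes_model():
    """In a two-model ensemble the model with the opposite stability
    ordering fails the hierarchy constraint."""
    net = SignedNetwork.from_edges(
        [("A", "A", 1), ("B", "B", 1), ("A", "B", 1), ("B", "A", 1)],
        nodes=("A", "B"),
    )
    # both models keep 00 and 11 fixed; they differ on the mixed rows and
    # hence on how much noise it takes to leave each fixed point
    and_rule = bf("x1 & x2", 2)
    or_rule = bf("x1 | x2", 2)
    m_and = {"A": and_rule, "B": and_rule}  # 11 fragile, 00 robust
    m_or = {"A": or_rule, "B": or_rule}  # 00 fragile, 11 robust
    per_node = {"A": [and_rule, or_rule], "B": [and_rule, or_rule]}
    ens = ensemble(net, per_node)
    fps = {"OFF": {"A": 0, "B": 0}, "ON": {"A": 1, "B": 1}}
    dyn = StochasticDynamics(eta=0.05)
    crit = SelectionCriteria((("ON", "OFF"),), dynamics=dyn)  # OFF more stable
    res = select_models(ens, fps, crit)
    sel_models = [ens.model(i) for i in res.selected]
    assert sel_models, "some model satisfies the hierarchy"
    for m in sel_models:
        assert m.functions[0] == and_rule  # AND favours the OFF state
    # the all-OR model reverses the hierarchy and is excluded
    or_idx = ens.index_of(ens._assemble(m_or))
    assert or_idx not in res.selected


def test_spurious_attractor_and_basin_floor_exclusion():
    net = SignedNetwork.from_edges(
        [("A", "A", 1), ("B", "B", 1)], nodes=("A", "B")
    )
    ident = BooleanFunction(1, "01")
    per_node = {"A": [ident], "B": [ident]}
    ens = ensemble(net, per_node)  # identity model: four fixed points
    fps = {"OFF": {"A": 0, "B": 0}, "ON": {"A": 1, "B": 1}}
    dyn = StochasticDynamics(eta=0.05)
    # 01 and 10 are spurious fixed points; biological basins sum to 2 < 4
    res = select_models(
        ens, fps, SelectionCriteria((), basin_floor=4, dynamics=dyn)
    )
    assert res.selected == ()
    res2 = select_models(
        ens, fps, SelectionCriteria((), require_no_spurious=True, dynamics=dyn)
    )
    assert res2.selected == ()
    res3 = select_models(
        ens, fps, SelectionCriteria((), basin_floor=2, dynamics=dyn)
    )
    assert res3.selected == (0,)
    assert res3.audit.loc[0, "n_spurious"] == 2


def test_single_violation_accounting():
    net = SignedNetwork.from_edges(
        [("A", "A", 1), ("B", "B", 1), ("A", "B", 1), ("B", "A", 1)],
        nodes=("A", "B"),
    )
    and_rule = bf("x1 & x2", 2)
    or_rule = bf("x1 | x2", 2)
    per_node = {"A": [and_rule, or_rule], "B": [and_rule, or_rule]}
    ens = ensemble(net, per_node)
    fps = {"OFF": {"A": 0, "B": 0}, "ON": {"A": 1, "B": 1}}
    crit = SelectionCriteria(
        (("ON", "OFF"), ("OFF", "ON")),  # contradictory on purpose
        dynamics=StochasticDynamics(eta=0.05),
    )
    res = select_models(ens, fps, crit)
    assert res.selected == ()
    # the decisive all-AND / all-OR models violate exactly one each
    assert res.n_single_hierarchy_violations >= 2
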