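"""Synchronous dynamics, attractors, the noisy one-step law, MFPT and RS."""

import numpy as np
import pytest

from chainlogic.bfcore import BooleanFunction
from chainlogic.bndyn import (
    BooleanModel,
    StochasticDynamics,
    attractors,
    mfpt,
    noisy_step,
    relative_stability,
    synchronous_step,
    transition_matrix,
    update_table,
)
from chainlogic.synthgen import random_model
from conftest import bf

IDENT = BooleanFunction(1, "01")
NEG = BooleanFunction(1, "10")


def two_node_swap():
    return BooleanModel(("A", "B"), ((1,), (0,)), (IDENT, IDENT))


def two_node_negated_swap():
    return BooleanModel(("A", "B"), ((1,), (0,)), (NEG, NEG))


def test_synchronous_step_examples():
    assert synchronous_step(two_node_swap(), 0b01) == 0b10
    assert synchronous_step(two_node_negated_swap(), 0b00) == 0b11
    ident2 = BooleanModel(("A", "B"), ((0,), (1,)), (IDENT, IDENT))
    for s in range(4):
        assert synchronous_step(ident2, s) == s


def test_arity_mismatch_rejected_at_construction():
    with pytest.raises(ValueError, match="arity"):
        BooleanModel(("A",), ((0,),), (bf("x1 & x2", 2),))


def test_attractors_negated_swap():
    atts = attractors(two_node_negated_swap())
    fixed = {a.states[0] for a in atts if a.is_fixed_point}
    cycles = [a for a in atts if not a.is_fixed_point]
    assert fixed == {0b01, 0b10}
    assert len(cycles) == 1 and set(cycles[0].states) == {0b00, 0b11}
    assert sorted(a.basin_size for a in atts) == [1, 1, 2]


def test_attractors_identity_model():
    ident2 = BooleanModel(("A", "B"), ((0,), (1,)), (IDENT, IDENT))
    atts = attractors(ident2)
    assert len(atts) == 4
    assert all(a.is_fixed_point and a.basin_size == 1 for a in atts)


def test_basins_partition_the_state_space():
    rng = np.random.default_rng(8)
    for _ in range(5):
        _, model, _ = random_model(6, 3, "CHFU", rng)
        atts = attractors(model)
        assert sum(a.basin_size for a in atts) == 2**model.N
        seen = set()
        for a in atts:
            assert not (set(a.states) & seen)
            seen |= set(a.states)


def test_noisy_step_reduces_to_deterministic_at_zero_noise():
    model = two_node_negated_swap()
    dyn = StochasticDynamics(eta=0.0)
    rng = np.random.default_rng(0)
    for s in range(4):
        assert noisy_step(model, s, dyn, rng) == synchronous_step(model, s)


def test_transition_matrix_columns_and_entries():
    model = two_node_negated_swap()
    T = transition_matrix(model, 0.05)
    assert np.allclose(T.sum(axis=0), 1.0)
    # single-bit flip probability and no-flip mass routed deterministically
    assert T[0b10, 0b00] == pytest.approx(0.05 * 0.95)
    det_img = synchronous_step(model, 0b00)
    assert T[det_img, 0b00] == pytest.approx(0.95**2 + 0.05**2)


def test_noisy_one_step_frequencies_match_matrix():
    """Empirical one-step law equals the T* column within 4 sigma."""
    model = two_node_negated_swap()
    eta = 0.1
    T = transition_matrix(model, eta)
    dyn = StochasticDynamics(eta=eta)
    rng = np.random.default_rng(123)
    n = 100_000
    start = 0b00
    counts = np.zeros(4)
    for _ in range(n):
        counts[noisy_step(model, start, dyn, rng)] += 1
    freq = counts / n
    for l in range(4):
        p = T[l, start]
        se = np.sqrt(p * (1 - p) / n)
        assert abs(freq[l] - p) < 4 * se + 1e-12, (l, freq[l], p)


def test_mfpt_identity_single_node_is_inverse_noise():
    ident = BooleanModel(("A",), ((0,),), (IDENT,))
    dyn = StochasticDynamics(eta=0.05, n_traj=3000)
    exact = mfpt(ident, 1, 0, dyn, mode="exact")
    assert exact.value == pytest.approx(20.0, rel=1e-9)
    sampled = mfpt(ident, 1, 0, dyn, mode="sampled", rng=np.random.default_rng(9))
    assert abs(sampled.value - 20.0) < 3 * sampled.se
    assert sampled.n_failures == 0


def test_mfpt_self_is_zero():
    ident = BooleanModel(("A",), ((0,),), (IDENT,))
    dyn = StochasticDynamics()
    assert mfpt(ident, 1, 1, dyn).value == 0.0


def test_sampled_mfpt_matches_exact_on_random_models():
    rng = np.random.default_rng(21)
    dyn = StochasticDynamics(eta=0.05, n_traj=3000)
    checked = 0
    while checked < 3:
        _, model, fps = random_model(5, 3, "CHFU", rng, min_fixed_points=2)
        states = sorted(
            model.bits_to_state([s[n] for n in model.nodes]) for s in fps.values()
        )
        u, v = states[0], states[1]
        exact = mfpt(model, u, v, dyn, mode="exact").value
        if exact > 5000:  # keep the sampling cheap
            continue
        sampled = mfpt(model, u, v, dyn, mode="sampled", rng=np.random.default_rng(checked))
        assert sampled.n_failures == 0
        assert abs(sampled.value - exact) < 3 * sampled.se + 1e-9, (exact, sampled)
        checked += 1


def test_sampled_mfpt_converges_with_more_trajectories():
    ident = BooleanModel(("A",), ((0,),), (IDENT,))
    errs = []
    for n_traj in (300, 3000, 30000):
        dyn = StochasticDynamics(eta=0.05, n_traj=n_traj)
        est = mfpt(ident, 1, 0, dyn, mode="sampled", rng=np.random.default_rng(5))
        errs.append((abs(est.value - 20.0), est.se))
    for err, se in errs:
        assert err < 3 * se
    assert errs[-1][1] < errs[0][1]  # standard error shrinks


def test_relative_stability_verdicts():
    rs, verdict = relative_stability(10.0, 20.0)
    assert rs == pytest.approx(0.05)
    assert verdict == "u>v"
    rs2, verdict2 = relative_stability(20.0, 10.0)
    assert rs2 == pytest.approx(-rs)
    assert verdict2 == "v>u"
    assert relative_stability(15.0, 15.0)[1] == "undecided"
    with pytest.raises(ValueError):
        relative_stability(-1.0, 5.0)


def test_sampled_ties_are_undecided():
    rs, verdict = relative_stability(100.0, 101.0, se_uv=5.0, se_vu=5.0)
    assert verdict == "undecided"


def test_hierarchy_insensitive_to_noise_level():
    """Exact-MFPT hierarchy verdicts agree across eta in [0.01, 0.05]."""
    rng = np.random.default_rng(31)
    _, model, fps = random_model(5, 3, "CHFU", rng, min_fixed_points=2)
    states = sorted(
        model.bits_to_state([s[n] for n in model.nodes]) for s in fps.values()
    )
    u, v = states[0], states[1]
    verdicts = []
    for eta in (0.01, 0.02, 0.05):
        dyn = StochasticDynamics(eta=eta)
        muv = mfpt(model, u, v, dyn, mode="exact").value
        mvu = mfpt(model, v, u, dyn, mode="exact").value
        verdicts.append(relative_stability(muv, mvu)[1])
    assert len(set(verdicts)) == 1
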