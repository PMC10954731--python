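"""Nested canalyzing decomposition, chain classes, layers, builders."""

import numpy as np
import pytest

from chainlogic.bfcore import BooleanFunction, truth_table_from_expression
from chainlogic.chainclass import (
    AND,
    OR,
    Label,
    build_function,
    canalyzing_pairs,
    classify,
    classify_exhaustive,
    form_to_expression,
    layers_from_bias,
    ncf_decompose,
)
from conftest import bf, from_rowlast_int


F1 = "x1 & x2 & x3 & (!x4 | !x5 | !x6)"


# ---------------------------------------------------------------------------
# canalyzing pairs and decomposition


@pytest.mark.parametrize(
    "expr, k, expected",
    [
        ("x1 & x2", 2, {(1, 0, 0), (2, 0, 0)}),
        ("(x1 & !x2) | (!x1 & x2)", 2, set()),
        ("x1 & (x2 | x3)", 3, {(1, 0, 0)}),
        ("x1 | x2", 2, {(1, 1, 1), (2, 1, 1)}),
    ],
)
def test_canalyzing_pairs(expr, k, expected):
    assert canalyzing_pairs(bf(expr, k)) == expected


def test_constants_have_no_canalyzing_pairs():
    assert canalyzing_pairs(BooleanFunction(2, "0000")) == set()


def test_decompose_two_layer_example():
    form = ncf_decompose(bf("x1 & x2 & (!x3 | x4)", 4))
    assert form.structure.layer_sizes == (2, 2)


def test_decompose_rejects_parity_and_dummy():
    assert ncf_decompose(bf("(x1 & !x2) | (!x1 & x2)", 2)) is None
    f = truth_table_from_expression("x1", ["x1", "x2"])
    assert ncf_decompose(f) is None


def test_decompose_peeling_by_hand():
    form = ncf_decompose(bf("x1 & (x2 | x3)", 3))
    assert form.sigma == (1, 2, 3)
    assert form.canalyzing_values == (0, 1, 1)
    assert form.canalyzed_outputs == (0, 1, 1)
    assert form.structure.layer_sizes == (1, 2)


def test_form_rebuilds_original_function():
    for expr, k in [(F1, 6), ("x1 & (x2 | x3)", 3), ("!x1 | (x2 & !x3)", 3)]:
        f = bf(expr, k)
        form = ncf_decompose(f)
        rebuilt = truth_table_from_expression(
            form_to_expression(form), [f"x{i}" for i in range(1, k + 1)]
        )
        assert rebuilt == f


# ---------------------------------------------------------------------------
# classification


@pytest.mark.parametrize(
    "expr, k, label",
    [
        (F1, 6, Label.CHF0),
        ("!x1 & (x2 | x3)", 3, Label.CHF1),
        ("x1 & (x2 | x3)", 3, Label.NCF_NON_CHFU),
        ("x1 & !x2", 2, Label.CHF_BOTH),
        ("(x1 & !x2) | (!x1 & x2)", 2, Label.NOT_NCF),
        ("x1", 1, Label.CHF_BOTH),
        ("!x1", 1, Label.CHF_BOTH),
    ],
)
def test_classify_examples(expr, k, label):
    assert classify(bf(expr, k)).label is label


def test_greedy_matches_peel_order_oracle_exhaustively_k_le_3():
    for k in (1, 2, 3):
        for tt in range(2 ** (2**k)):
            f = from_rowlast_int(k, tt)
            assert classify(f).label is classify_exhaustive(f).label, tt


def test_greedy_matches_peel_order_oracle_sampled_k45():
    rng = np.random.default_rng(42)
    for k in (4, 5):
        for tt in rng.integers(0, 2 ** (2**k), size=400):
            f = from_rowlast_int(k, int(tt))
            assert classify(f).label is classify_exhaustive(f).label
    # and on structured functions, where NCFs are not vanishingly rare
    for k in (4, 5):
        for P in range(1, 2**k, 2):
            f = build_function("CHF0", k, P)
            assert classify(f).label is classify_exhaustive(f).label


# ---------------------------------------------------------------------------
# layers from bias


def test_layers_examples():
    st = layers_from_bias(4, 5)
    assert st.operator_sequence == (AND, OR, AND)
    assert st.layer_sizes == (1, 1, 2)
    assert layers_from_bias(6, 7).layer_sizes == (3, 3)
    for k in (1, 3, 7):
        st = layers_from_bias(k, 1)
        assert st.layer_sizes == (k,)
        assert st.m_last == k


def test_layers_rejects_even_or_out_of_range_bias():
    with pytest.raises(ValueError, match="odd"):
        layers_from_bias(3, 4)
    with pytest.raises(ValueError, match="range"):
        layers_from_bias(3, 9)


def test_m_last_at_least_two_for_k_ge_2():
    for k in range(2, 10):
        for P in range(1, 2**k, 2):
            assert layers_from_bias(k, P).m_last >= 2


# ---------------------------------------------------------------------------
# constructive building


def test_build_reproduces_published_chain_variants():
    assert build_function("CHF0", 6, 7) == bf(F1, 6)
    assert build_function("CHF0", 6, 7, deviant=6) == bf(
        "x1 & x2 & x3 & (!x4 | !x5 | x6)", 6
    )
    assert build_function("CHF0", 2, 1) == bf("x1 & x2", 2)


def test_build_validation_errors():
    with pytest.raises(ValueError, match="last layer"):
        build_function("CHF0", 6, 7, deviant=1)
    with pytest.raises(ValueError, match="partition|sizes"):
        build_function("CHF0", 4, 5, [[1, 2], [3, 4]])
    with pytest.raises(ValueError, match="partition"):
        build_function("CHF0", 4, 3, [[1, 2], [3, 3]])


def test_built_chains_round_trip_to_their_class():
    for k in range(1, 6):
        for P in range(1, 2**k, 2):
            st = layers_from_bias(k, P)
            last = list(range(k - st.m_last + 1, k + 1))
            for dev in [None] + last:
                f0 = build_function("CHF0", k, P, deviant=dev)
                assert f0.bias == P
                lab = classify(f0).label
                assert lab in (Label.CHF0, Label.CHF_BOTH)
                f1 = build_function("CHF1", k, P, deviant=dev)
                assert classify(f1).label in (Label.CHF1, Label.CHF_BOTH)


def test_built_ncf_with_arbitrary_signs_is_ncf_with_that_bias():
    rng = np.random.default_rng(5)
    for k in (3, 4, 5):
        for P in range(1, 2**k, 2):
            signs = [bool(b) for b in rng.integers(0, 2, size=k)]
            f = build_function("NCF", k, P, signs=signs)
            assert f.bias == P
            assert classify(f).label is not Label.NOT_NCF


# ---------------------------------------------------------------------------
# structural invariants (enumerated, k <= 6 sets come from the session pool)


def test_every_enumerated_ncf_has_odd_bias_and_predicted_layers(class_sets):
    for k in (2, 3, 4, 5):
        for tt in class_sets(k, "NCF"):
            f = from_rowlast_int(k, tt)
            P = f.bias
            assert P % 2 == 1
            form = ncf_decompose(f)
            assert form is not None
            assert form.structure.layer_sizes == layers_from_bias(k, P).layer_sizes


def test_m_last_symmetric_under_complementation():
    for k in range(2, 12):
        for P in range(1, 2 ** (k - 1), 2):
            assert (
                layers_from_bias(k, P).m_last
                == layers_from_bias(k, 2**k - P).m_last
            )
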