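"""Nested canalyzing structure and chain-class membership.

A k-input function is *nested canalyzing* (NCF) when its inputs can be
peeled one at a time: each peeled input has a canalyzing value that fixes
the output, and the residual on the complementary value is again nested
canalyzing, down to a non-constant single-input residual.  Consecutive
peels that share a canalyzed output form a *layer*; the layer sizes
``m_1..m_last`` are a composition of k with ``m_last >= 2`` (for k >= 2)
and are determined by the pair (k, bias) alone: the first k-1 bits of the
k-bit binary form of the (odd) bias spell the AND/OR operator sequence of
the nested expression, and layer boundaries sit at operator flips.

Chain classes restrict the canalyzing values of the first k-1 peels:

* chain-0 (``CHF0``): every one of the first k-1 canalyzing values is 0,
  and the last input canalyzes in both values;
* chain-1 (``CHF1``): the dual class, with canalyzing values 1;
* generalized chain (``CHF_U``): their union.

For k <= 2 the two classes overlap (label ``CHF_BOTH``) and together
exhaust the NCFs; from k = 3 onwards they are disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from itertools import permutations
from typing import Optional, Sequence

import numpy as np

from .bfcore import (
    BooleanFunction,
    essential_inputs,
    restrict,
)

__all__ = [
    "AND",
    "OR",
    "Label",
    "LayerStructure",
    "NCFForm",
    "ClassLabel",
    "layers_from_bias",
    "canalyzing_pairs",
    "ncf_decompose",
    "classify",
    "build_function",
    "form_to_expression",
]

AND = "AND"
OR = "OR"


class Label(str, Enum):
    NOT_NCF = "NOT_NCF"
    CHF0 = "CHF0"
    CHF1 = "CHF1"
    CHF_BOTH = "CHF_BOTH"
    NCF_NON_CHFU = "NCF_NON_CHFU"

    def is_ncf(self) -> bool:
        return self is not Label.NOT_NCF

    def is_chain(self) -> bool:
        return self in (Label.CHF0, Label.CHF1, Label.CHF_BOTH)


@dataclass(frozen=True)
class LayerStructure:
    """Layer sizes and operator sequence of an NCF, fixed by (k, bias)."""

    k: int
    P: int
    operator_sequence: tuple  # length k-1 over {AND, OR}
    layer_sizes: tuple

    @property
    def layer_number(self) -> int:
        return len(self.layer_sizes)

    @property
    def m_last(self) -> int:
        return self.layer_sizes[-1]

    def layer_of_position(self, j: int) -> int:
        """0-based layer index containing 1-based position j of the peel order."""
        upto = 0
        for li, m in enumerate(self.layer_sizes):
            upto += m
            if j <= upto:
                return li
        raise ValueError(f"position {j} beyond k={self.k}")

    def layer_operator(self, li: int) -> str:
        """Operator joining the literals of layer li (AND for even-parity of
        the leading operator, alternating thereafter)."""
        if self.k == 1 or not self.operator_sequence:
            return AND
        # operators within a layer are constant; take the operator following
        # the first position of the layer (or the last operator overall for
        # a final layer of size m_last whose internal operators are the tail)
        start = sum(self.layer_sizes[:li]) + 1  # 1-based first position
        j = min(start, self.k - 1)
        return self.operator_sequence[j - 1]


def layers_from_bias(k: int, P: int) -> LayerStructure:
    """Layer sizes and AND/OR operator sequence for a k-input NCF of bias P.

    The k-bit binary form of the odd bias P has its first k-1 bits encode
    the operator sequence (0 = AND, 1 = OR); runs of equal operators are the
    layers, with the final run extended by one to absorb the last input.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not (1 <= P <= 2**k - 1):
        raise ValueError(f"bias P={P} out of range 1..{2**k - 1} for k={k}")
    if P % 2 == 0:
        raise ValueError(f"bias P={P} is even; nested canalyzing functions have odd bias")
    bits = [(P >> (k - 1 - j)) & 1 for j in range(k)]  # MSB first
    op_bits = bits[: k - 1]
    ops = tuple(OR if b else AND for b in op_bits)
    if k == 1:
        return LayerStructure(k, P, (), (1,))
    sizes = []
    run = 1
    for a, b in zip(op_bits, op_bits[1:]):
        if b == a:
            run += 1
        else:
            sizes.append(run)
            run = 1
    sizes.append(run + 1)  # last input joins the final operator run
    return LayerStructure(k, P, ops, tuple(sizes))


@dataclass(frozen=True)
class NCFForm:
    """A nested canalyzing decomposition of a specific function.

    ``sigma`` lists the original (1-based) input indices in peel order;
    ``canalyzing_values[i]`` / ``canalyzed_outputs[i]`` are the a_i / b_i of
    the i-th peel; ``literal_signs[i]`` is True when the literal at position
    i+1 of the nested expression is the plain variable (False: negated).
    """

    sigma: tuple
    canalyzing_values: tuple
    canalyzed_outputs: tuple
    literal_signs: tuple
    structure: LayerStructure

    @property
    def k(self) -> int:
        return len(self.sigma)


@dataclass(frozen=True)
class ClassLabel:
    label: Label
    form: Optional[NCFForm] = None


# ---------------------------------------------------------------------------


def canalyzing_pairs(f: BooleanFunction):
    """All (input i, canalyzing value a, canalyzed output b) triples.

    (i, a, b) qualifies when fixing x_i = a makes the function the constant
    b.  Constant functions are canalyzed by nothing and return the empty set.
    """
    out = set()
    if f.k == 0 or f.is_constant():
        return out
    ten = f.tensor()
    for i in range(1, f.k + 1):
        for a in (0, 1):
            half = np.take(ten, a, axis=i - 1)
            first = int(half.flat[0])
            if (half == first).all():
                out.add((i, a, first))
    return out


def _peel(f: BooleanFunction, allowed_values=(0, 1)):
    """Greedily peel canalyzing inputs restricted to ``allowed_values``.

    Returns (sigma, a_list, b_list, residual) peeling k-1 inputs, or None if
    peeling stalls or the function is constant along the way.  At each stage
    the lowest-index canalyzing input (by original numbering) is taken;
    within a layer all inputs canalyze simultaneously, so the greedy choice
    is safe (a brute-force peel-order oracle guards this in the test suite).
    """
    k = f.k
    if k == 0 or f.is_constant():
        return None
    remaining = list(range(1, k + 1))  # original indices, in order
    g = f
    sigma, avals, bvals = [], [], []
    while g.k > 1:
        ten = g.tensor()
        found = None
        for pos in range(1, g.k + 1):
            for a in allowed_values:
                half = np.take(ten, a, axis=pos - 1)
                first = int(half.flat[0])
                if (half == first).all():
                    found = (pos, a, first)
                    break
            if found:
                break
        if found is None:
            return None
        pos, a, b = found
        sigma.append(remaining.pop(pos - 1))
        avals.append(a)
        bvals.append(b)
        g = restrict(g, pos, 1 - a)
        if g.is_constant():
            return None
    # non-constant single-input residual required
    if g.outputs[0] == g.outputs[1]:
        return None
    sigma.append(remaining.pop())
    return sigma, avals, bvals, g


def _finish_form(f: BooleanFunction, sigma, avals, bvals, residual) -> NCFForm:
    k = f.k
    # last input canalyzes in both values; choose a_k so b_k extends the
    # previous layer's canalyzed output (m_last >= 2 guarantees agreement)
    if k >= 2:
        b_prev = bvals[-1]
        a_k = 0 if int(residual.outputs[0]) == b_prev else 1
    else:
        a_k = 0
    b_k = int(residual.outputs[a_k])
    avals = list(avals) + [a_k]
    bvals = list(bvals) + [b_k]
    structure = layers_from_bias(k, f.bias)
    # literal sign at position i < k: positive iff a_i == b_i;
    # at position k the literal is the residual itself
    signs = [a == b for a, b in zip(avals[:-1], bvals[:-1])]
    signs.append(int(residual.outputs[1]) == 1)
    # layer sizes recovered from runs of equal canalyzed outputs must agree
    # with the (k, P) prediction
    runs = []
    cur = 1
    for x, y in zip(bvals, bvals[1:]):
        if y == x:
            cur += 1
        else:
            runs.append(cur)
            cur = 1
    runs.append(cur)
    if tuple(runs) != structure.layer_sizes:
        raise AssertionError(
            f"peeled layers {runs} disagree with bias-derived {structure.layer_sizes}"
        )
    return NCFForm(tuple(sigma), tuple(avals), tuple(bvals), tuple(signs), structure)


def ncf_decompose(f: BooleanFunction) -> Optional[NCFForm]:
    """Recover a nested canalyzing form of ``f``, or None when not an NCF.

    Every input must be essential; constants and functions with dummy
    inputs are not nested canalyzing.
    """
    if f.k == 0 or f.is_constant():
        return None
    if len(essential_inputs(f)) != f.k:
        return None
    peeled = _peel(f)
    if peeled is None:
        return None
    return _finish_form(f, *peeled)


def _chain_peel(f: BooleanFunction, value: int):
    """Peel with every canalyzing value fixed to ``value``; None on failure."""
    if f.k == 0 or f.is_constant():
        return None
    if len(essential_inputs(f)) != f.k:
        return None
    return _peel(f, allowed_values=(value,))


def classify(f: BooleanFunction) -> ClassLabel:
    """Class membership of ``f`` among the nested canalyzing sub-types.

    Returns ``CHF0`` / ``CHF1`` when a peel using only canalyzing value
    0 / 1 for the first k-1 inputs succeeds (with a non-constant final
    residual), ``CHF_BOTH`` when both do (possible only for k <= 2),
    ``NCF_NON_CHFU`` for the remaining nested canalyzing functions, and
    ``NOT_NCF`` otherwise.
    """
    p0 = _chain_peel(f, 0)
    p1 = _chain_peel(f, 1)
    if p0 is not None and p1 is not None:
        return ClassLabel(Label.CHF_BOTH, _finish_form(f, *p0))
    if p0 is not None:
        return ClassLabel(Label.CHF0, _finish_form(f, *p0))
    if p1 is not None:
        return ClassLabel(Label.CHF1, _finish_form(f, *p1))
    form = ncf_decompose(f)
    if form is not None:
        return ClassLabel(Label.NCF_NON_CHFU, form)
    return ClassLabel(Label.NOT_NCF)


def classify_exhaustive(f: BooleanFunction) -> ClassLabel:
    """Peel-order-oracle classification: tries every peel order.

    Exponential in k; intended as an independent check of the greedy
    production path for small k (<= 6).
    """

    def chain_ok(g: BooleanFunction, value: int) -> bool:
        if g.k == 0 or g.is_constant():
            return False
        if g.k == 1:
            return True
        ten = g.tensor()
        for pos in range(1, g.k + 1):
            half = np.take(ten, value, axis=pos - 1)
            first = int(half.flat[0])
            if (half == first).all():
                if chain_ok(restrict(g, pos, 1 - value), value):
                    return True
        return False

    def ncf_ok(g: BooleanFunction) -> bool:
        if g.k == 0 or g.is_constant():
            return False
        if g.k == 1:
            return True
        ten = g.tensor()
        for pos in range(1, g.k + 1):
            for a in (0, 1):
                half = np.take(ten, a, axis=pos - 1)
                first = int(half.flat[0])
                if (half == first).all():
                    if ncf_ok(restrict(g, pos, 1 - a)):
                        return True
        return False

    if f.k == 0 or len(essential_inputs(f)) != f.k:
        return ClassLabel(Label.NOT_NCF)
    c0 = chain_ok(f, 0)
    c1 = chain_ok(f, 1)
    if c0 and c1:
        return ClassLabel(Label.CHF_BOTH)
    if c0:
        return ClassLabel(Label.CHF0)
    if c1:
        return ClassLabel(Label.CHF1)
    if ncf_ok(f):
        return ClassLabel(Label.NCF_NON_CHFU)
    return ClassLabel(Label.NOT_NCF)


# ---------------------------------------------------------------------------
# constructive building


def _chain_literal_signs(structure: LayerStructure) -> list:
    """Canonical chain-0 literal signs: positive in AND layers, negated in
    OR layers (the final literal takes its layer's sign)."""
    k = structure.k
    signs = []
    for j in range(1, k + 1):
        li = structure.layer_of_position(j)
        signs.append(structure.layer_operator(li) == AND)
    return signs


def _fold_truth_table(k, sigma, signs, operators) -> BooleanFunction:
    """Evaluate the nested expression lit_1 op_1 (lit_2 op_2 (...)) on all rows."""
    n = 2**k
    rows = np.arange(n)
    lits = []
    for j in range(k):
        var = sigma[j]  # 1-based original index
        bit = (rows >> (k - var)) & 1
        lits.append(bit if signs[j] else 1 - bit)
    acc = lits[-1]
    for j in range(k - 2, -1, -1):
        if operators[j] == AND:
            acc = lits[j] & acc
        else:
            acc = lits[j] | acc
    return BooleanFunction(k, acc.astype(np.uint8))


def build_function(
    cls: str,
    k: int,
    P: int,
    layer_assignment: Optional[Sequence[Sequence[int]]] = None,
    *,
    signs: Optional[Sequence[bool]] = None,
    deviant: Optional[int] = None,
) -> BooleanFunction:
    """Construct an NCF / chain-0 / chain-1 member with bias ``P``.

    ``layer_assignment`` partitions inputs 1..k into the layers prescribed
    by ``layers_from_bias(k, P)`` (identity split by default).  For the
    chain classes the literal signs are dictated by the layer operators;
    ``deviant`` optionally names the one input of the *last* layer whose
    literal sign is flipped.  For ``cls="NCF"``, ``signs`` gives the literal
    sign (True = plain) per peel position, all-positive by default.
    """
    cls = cls.upper()
    if cls not in ("NCF", "CHF0", "CHF1"):
        raise ValueError(f"unknown class {cls!r}")
    structure = layers_from_bias(k, P)
    if layer_assignment is None:
        bounds = np.cumsum((0,) + structure.layer_sizes)
        layer_assignment = [
            list(range(int(bounds[i]) + 1, int(bounds[i + 1]) + 1))
            for i in range(structure.layer_number)
        ]
    layer_assignment = [list(layer) for layer in layer_assignment]
    if [len(layer) for layer in layer_assignment] != list(structure.layer_sizes):
        raise ValueError(
            f"layer assignment sizes {[len(m) for m in layer_assignment]} do not "
            f"match layer sizes {structure.layer_sizes} for (k={k}, P={P})"
        )
    flat = [i for layer in layer_assignment for i in layer]
    if sorted(flat) != list(range(1, k + 1)):
        raise ValueError("layer assignment must partition inputs 1..k")

    operators = list(structure.operator_sequence)
    if cls == "NCF":
        if deviant is not None:
            raise ValueError("deviant applies to the chain classes only")
        lit_signs = [True] * k if signs is None else list(signs)
        if len(lit_signs) != k:
            raise ValueError("signs must have length k")
    else:
        if signs is not None:
            raise ValueError("chain classes have structurally forced signs")
        lit_signs = _chain_literal_signs(structure)
        if deviant is not None:
            if deviant not in layer_assignment[-1]:
                raise ValueError(
                    f"deviant input {deviant} must lie in the last layer "
                    f"{layer_assignment[-1]}"
                )
            pos = flat.index(deviant)
            lit_signs[pos] = not lit_signs[pos]
        if cls == "CHF1":
            lit_signs = [not s for s in lit_signs]
    return _fold_truth_table(k, flat, lit_signs, operators)


def form_to_expression(form: NCFForm, names: Optional[Sequence[str]] = None) -> str:
    """Pretty-print the nested-parenthesis normal form, layers regrouped."""
    k = form.k
    if names is None:
        names = [f"x{i}" for i in range(1, k + 1)]
    lits = []
    for j in range(k):
        name = names[form.sigma[j] - 1]
        lits.append(name if form.literal_signs[j] else f"!{name}")
    sizes = form.structure.layer_sizes
    bounds = np.cumsum((0,) + sizes)
    groups = []
    for li in range(len(sizes)):
        op = " & " if form.structure.layer_operator(li) == AND else " | "
        groups.append(op.join(lits[int(bounds[li]) : int(bounds[li + 1])]))
    expr = groups[-1]
    for li in range(len(sizes) - 2, -1, -1):
        op = " & " if form.structure.layer_operator(li) == AND else " | "
        expr = groups[li] + op + "(" + expr + ")"
    return expr
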