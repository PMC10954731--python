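"""Exact counting of nested canalyzing and chain functions.

Closed forms (all exact, big-integer / rational arithmetic):

* number of k-input NCFs with odd bias P:
  ``2^k * k! / (m_1! ... m_last!)`` with the layer sizes fixed by (k, P);
* number of k-input chain-0 functions with bias P:
  ``k! * (1 + m_last) / (m_1! ... m_last!)`` -- the multinomial counts the
  distinct layer assignments, and 1 + m_last the distinct negation choices
  (identity or one flipped last-layer literal); chain-1 counts are equal;
* per-bias chain-within-NCF fraction ``f_CN(k, P) = (1 + m_last) / 2^k``;
* the class totals sum over odd biases; complement symmetry (P <-> 2^k - P
  preserves the layer sizes) lets the sum run over odd P < 2^(k-1), doubled.

The chain-0 share of NCFs equals ``C(k) / 2^k`` where

    C(k) = [sum over layer compositions of (1 + m_last)/prod(m_i!)] /
           [sum over layer compositions of 1/prod(m_i!)]

with the compositions of k having last part >= 2 (each composition stands
for one complement pair of biases).  ``C`` lies in [3, k+1] and is computed
here by a dynamic programme over composition suffixes, so large k (say 30
or 200) costs O(k^2) exact-rational operations rather than a sum over
2^(k-1) biases.
"""

from __future__ import annotations

from fractions import Fraction
from functools import lru_cache
from itertools import combinations
from math import factorial
from typing import Iterator, Optional

from .bfcore import BooleanFunction
from .chainclass import Label, layers_from_bias

__all__ = [
    "count_ncf",
    "count_chain",
    "fraction_chain_in_ncf",
    "chain_fraction_constant",
    "enumerate_class",
    "class_size",
]

NCF_ENUM_MAX_K = 8
CHAIN_ENUM_MAX_K = 10
MAX_COUNT_K = 200


def _require_odd(P: int) -> None:
    if P % 2 == 0:
        raise ValueError(
            f"bias P={P} is even; nested canalyzing functions have odd bias"
        )


def _layer_factorial_product(sizes) -> int:
    prod = 1
    for m in sizes:
        prod *= factorial(m)
    return prod


@lru_cache(maxsize=None)
def _g(s: int) -> Fraction:
    """sum over compositions (m_1..m_n), parts >= 1, of s of 1/prod(m_i!)."""
    if s == 0:
        return Fraction(1)
    return sum((_g(s - j) / factorial(j) for j in range(1, s + 1)), Fraction(0))


@lru_cache(maxsize=None)
def _composition_sums(k: int):
    """(S0, S1) over compositions of k with last part >= 2:
    S0 = sum 1/prod(m_i!),  S1 = sum (1 + m_last)/prod(m_i!)."""
    if k < 2:
        raise ValueError("composition sums require k >= 2")
    S0 = sum((_g(k - m) / factorial(m) for m in range(2, k + 1)), Fraction(0))
    S1 = sum(
        ((1 + m) * _g(k - m) / factorial(m) for m in range(2, k + 1)), Fraction(0)
    )
    return S0, S1


def count_ncf(k: int, P: Optional[int] = None) -> int:
    """Number of k-input NCFs, with bias P or in total (exact integer)."""
    if k < 1 or k > MAX_COUNT_K:
        raise ValueError(f"k={k} outside supported range 1..{MAX_COUNT_K}")
    if P is not None:
        _require_odd(P)
        st = layers_from_bias(k, P)
        return 2**k * factorial(k) // _layer_factorial_product(st.layer_sizes)
    if k == 1:
        return 2
    S0, _ = _composition_sums(k)
    total = 2 * 2**k * factorial(k) * S0
    assert total.denominator == 1
    return int(total)


def count_chain(k: int, P: Optional[int] = None, cls: str = "CHF0") -> int:
    """Number of k-input chain functions of the given class (exact integer).

    ``cls`` is one of ``CHF0``, ``CHF1`` (equal cardinalities) or ``CHFU``.
    For k <= 2 every NCF is a generalized chain function, so the CHFU total
    equals the NCF total there; for k >= 3 the chain-0 and chain-1 classes
    are disjoint and CHFU is twice the chain-0 count.
    """
    cls = cls.upper()
    if cls not in ("CHF0", "CHF1", "CHFU"):
        raise ValueError(f"unknown chain class {cls!r}")
    if k < 1 or k > MAX_COUNT_K:
        raise ValueError(f"k={k} outside supported range 1..{MAX_COUNT_K}")
    if P is not None:
        _require_odd(P)
        st = layers_from_bias(k, P)
        base = factorial(k) * (1 + st.m_last) // _layer_factorial_product(st.layer_sizes)
        if cls == "CHFU":
            if k >= 3:
                return 2 * base
            return count_ncf(k, P)  # classes overlap and exhaust the NCFs
        return base
    if k == 1:
        return 2  # {x, !x}, whatever the class
    if cls == "CHFU" and k <= 2:
        return count_ncf(k)
    S0_, S1 = _composition_sums(k)
    total = 2 * factorial(k) * S1
    assert total.denominator == 1
    base = int(total)
    return 2 * base if cls == "CHFU" else base


def fraction_chain_in_ncf(k: int, P: int) -> Fraction:
    """Exact chain-0 (equivalently chain-1) share of the bias-P NCFs:
    ``(1 + m_last) / 2^k``."""
    _require_odd(P)
    st = layers_from_bias(k, P)
    return Fraction(1 + st.m_last, 2**k)


def chain_fraction_constant(k: int) -> Fraction:
    """The constant C(k) = 2^k * |ChF0|_k / |NCF|_k, exact rational.

    Computed from the composition dynamic programme; lies in [3, k + 1]
    for every k >= 2 and converges rapidly with k.
    """
    if not (2 <= k <= MAX_COUNT_K):
        raise ValueError(f"k={k} outside supported range 2..{MAX_COUNT_K}")
    S0, S1 = _composition_sums(k)
    return S1 / S0


def class_size(k: int, cls: str) -> int:
    """Cardinality of a function class at k inputs (ALL, NCF, chain types)."""
    cls = cls.upper()
    if cls == "ALL":
        return 2 ** (2**k)
    if cls == "NCF":
        return count_ncf(k)
    if cls in ("CHF0", "CHF1", "CHFU"):
        return count_chain(k, cls=cls)
    if cls == "NCF_NON_CHFU":
        return count_ncf(k) - count_chain(k, cls="CHFU")
    raise ValueError(f"unknown class {cls!r}")


# ---------------------------------------------------------------------------
# enumeration (brute-force oracle generators)


def _variable_masks(k: int):
    """mask[v] has bit r set iff x_v = 1 in row r (row-index LSB = row 0)."""
    n = 2**k
    masks = [0] * (k + 1)
    for r in range(n):
        for v in range(1, k + 1):
            if (r >> (k - v)) & 1:
                masks[v] |= 1 << r
    return masks


def _ordered_partitions(items: tuple, sizes: tuple):
    """All ways to split ``items`` into consecutive blocks of the given sizes,
    each block a sorted tuple (order within a layer is immaterial)."""
    if not sizes:
        yield ()
        return
    m = sizes[0]
    for block in combinations(items, m):
        rest = tuple(x for x in items if x not in block)
        for tail in _ordered_partitions(rest, sizes[1:]):
            yield (block,) + tail


def _fold_int(k, order, signs, op_bits, masks, full):
    """Truth-table integer of the nested expression (LSB = row 0)."""
    v = order[-1]
    acc = masks[v] if signs[-1] else full ^ masks[v]
    for j in range(k - 2, -1, -1):
        v = order[j]
        lit = masks[v] if signs[j] else full ^ masks[v]
        acc = (lit & acc) if op_bits[j] == 0 else (lit | acc)
    return acc


def _iter_ncf_ints(k: int, masks, full) -> Iterator[int]:
    for P in range(1, 2**k, 2):
        st = layers_from_bias(k, P)
        op_bits = [0 if op == "AND" else 1 for op in st.operator_sequence]
        for part in _ordered_partitions(tuple(range(1, k + 1)), st.layer_sizes):
            order = [v for block in part for v in block]
            # one literal-sign choice per variable subset to negate
            for neg in range(2**k):
                signs = [not ((neg >> (v - 1)) & 1) for v in order]
                yield _fold_int(k, order, signs, op_bits, masks, full)


def _iter_chain_ints(k: int, value: int, masks, full) -> Iterator[int]:
    """Chain-0 (value=0) or chain-1 (value=1) truth-table integers."""
    for P in range(1, 2**k, 2):
        st = layers_from_bias(k, P)
        op_bits = [0 if op == "AND" else 1 for op in st.operator_sequence]
        base_signs = []
        for j in range(1, k + 1):
            li = st.layer_of_position(j)
            base_signs.append(st.layer_operator(li) == "AND")
        if value == 1:
            base_signs = [not s for s in base_signs]
        m_last = st.m_last
        for part in _ordered_partitions(tuple(range(1, k + 1)), st.layer_sizes):
            order = [v for block in part for v in block]
            yield _fold_int(k, order, base_signs, op_bits, masks, full)
            for dpos in range(k - m_last, k):  # flip one last-layer literal
                signs = list(base_signs)
                signs[dpos] = not signs[dpos]
                yield _fold_int(k, order, signs, op_bits, masks, full)


def enumerate_class(k: int, cls: str, *, encoding: Optional[str] = None):
    """Stream the distinct members of a function class, deduplicated.

    ``cls`` is one of ``NCF``, ``CHF0``, ``CHF1``, ``CHFU``.  Capacity caps:
    k <= 8 for NCFs, k <= 10 for the chain classes (the streams themselves
    are exhaustive; memory for deduplication grows with the class size).
    By default :class:`BooleanFunction` objects are yielded; with
    ``encoding="msb-rowlast"`` (the cheap path) or ``"msb-row0"`` the truth
    tables are yielded as integers in the named dialect (bit position of
    row r is r, respectively ``2^k - 1 - r``).
    """
    if encoding not in (None, "msb-row0", "msb-rowlast"):
        raise ValueError(f"unknown encoding {encoding!r}")
    cls = cls.upper()
    if cls == "NCF":
        if k > NCF_ENUM_MAX_K:
            raise ValueError(
                f"NCF enumeration capped at k={NCF_ENUM_MAX_K} (got {k})"
            )
    elif cls in ("CHF0", "CHF1", "CHFU"):
        if k > CHAIN_ENUM_MAX_K:
            raise ValueError(
                f"chain enumeration capped at k={CHAIN_ENUM_MAX_K} (got {k})"
            )
    else:
        raise ValueError(f"unknown class {cls!r}")
    if k < 1:
        raise ValueError("k must be >= 1")

    masks = _variable_masks(k)
    full = (1 << 2**k) - 1
    if cls == "NCF":
        source = _iter_ncf_ints(k, masks, full)
    elif cls == "CHF0":
        source = _iter_chain_ints(k, 0, masks, full)
    elif cls == "CHF1":
        source = _iter_chain_ints(k, 1, masks, full)
    else:

        def chfu():
            yield from _iter_chain_ints(k, 0, masks, full)
            yield from _iter_chain_ints(k, 1, masks, full)

        source = chfu()

    def stream():
        seen = set()
        n = 2**k
        for tt in source:
            if tt in seen:
                continue
            seen.add(tt)
            if encoding == "msb-rowlast":
                yield tt  # internal dialect: bit r = output of row r
            elif encoding == "msb-row0":
                yield int(f"{tt:0{n}b}"[::-1], 2)
            else:
                yield BooleanFunction.from_int(k, tt, msb_row0=False)

    return stream()
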