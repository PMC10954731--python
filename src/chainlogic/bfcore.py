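"""Truth-table representation of Boolean functions and elementary operations.

A :class:`BooleanFunction` stores the output column of a truth table over
``k`` binary inputs.  Row ``r`` of the table encodes the input assignment
whose bits, read most-significant-first, are ``(x_1, ..., x_k)``; i.e.
``x_i = (r >> (k - i)) & 1``.  The *bias* of a function is the number of
rows on which it outputs 1 -- biologically, the number of regulator
configurations that switch the target gene on.

All structural analyses elsewhere in the package (canalyzation peeling,
layer recovery, chain-class membership) reduce to the primitives defined
here: restriction of an input to a constant, input negation/permutation,
output complementation, essentiality and unateness checks.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BooleanFunction",
    "InputTransform",
    "truth_table_from_expression",
    "bias",
    "transform",
    "restrict",
    "essential_inputs",
    "unate_directions",
]

MAX_K = 20  # 2^20 truth-table rows; counting routines have no such cap


class BooleanFunction:
    """A k-input Boolean function stored as its truth-table output vector.

    Parameters
    ----------
    k : int
        Number of inputs, ``0 <= k <= 20``.  ``k == 0`` encodes a constant
        (accepted for network dynamics, rejected by classification).
    outputs : sequence of {0, 1} or str
        Output column of length ``2**k``; row 0 first.  A string such as
        ``"0001"`` is accepted.
    """

    __slots__ = ("k", "outputs")

    def __init__(self, k: int, outputs) -> None:
        if not (0 <= k <= MAX_K):
            raise ValueError(f"input count k={k} outside supported range 0..{MAX_K}")
        if isinstance(outputs, str):
            if not set(outputs) <= {"0", "1"}:
                raise ValueError("output string must contain only '0' and '1'")
            arr = np.frombuffer(outputs.encode(), dtype=np.uint8) - ord("0")
        else:
            arr = np.asarray(outputs, dtype=np.uint8)
        if arr.ndim != 1 or arr.size != 2**k:
            raise ValueError(
                f"outputs must have length 2^{k}={2**k}, got {arr.size}"
            )
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("outputs must be 0/1 valued")
        arr = arr.copy()
        arr.setflags(write=False)
        self.k = k
        self.outputs = arr

    # -- alternate constructors ------------------------------------------

    @classmethod
    def from_int(cls, k: int, value: int, *, msb_row0: bool = True) -> "BooleanFunction":
        """Build from the integer encoding of the output vector.

        With ``msb_row0`` (the package's canonical dialect) row 0 is the most
        significant bit, so ``(k=2, value=1)`` decodes to ``"0001"``.  The
        other dialect (row ``2^k - 1`` most significant) is used by some
        published truth-table collections and is supported for file I/O.
        """
        n = 2**k
        if not (0 <= value < 2**n):
            raise ValueError(f"integer {value} out of range for k={k}")
        bits = [(value >> i) & 1 for i in range(n)]
        if msb_row0:
            bits.reverse()
        return cls(k, bits)

    @classmethod
    def constant(cls, value: int, k: int = 0) -> "BooleanFunction":
        """A constant function (0-input by default)."""
        return cls(k, np.full(2**k, int(bool(value)), dtype=np.uint8))

    # -- basic properties -------------------------------------------------

    @property
    def bias(self) -> int:
        """Number of 1s in the output vector."""
        return int(self.outputs.sum())

    def is_constant(self) -> bool:
        b = self.bias
        return b == 0 or b == self.outputs.size

    def as_int(self, *, msb_row0: bool = True) -> int:
        """Integer encoding of the output vector (see :meth:`from_int`)."""
        bits = self.outputs if msb_row0 else self.outputs[::-1]
        value = 0
        for b in bits:
            value = (value << 1) | int(b)
        return value

    def as_bitstring(self) -> str:
        return "".join("01"[b] for b in self.outputs)

    def tensor(self) -> np.ndarray:
        """Output vector reshaped to a (2,)*k tensor; axis i-1 indexes x_i."""
        return self.outputs.reshape((2,) * self.k) if self.k else self.outputs

    def __call__(self, assignment: Sequence[int]) -> int:
        if len(assignment) != self.k:
            raise ValueError("assignment length must equal k")
        r = 0
        for b in assignment:
            r = (r << 1) | int(b)
        return int(self.outputs[r])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BooleanFunction)
            and self.k == other.k
            and bool(np.array_equal(self.outputs, other.outputs))
        )

    def __hash__(self) -> int:
        return hash((self.k, self.outputs.tobytes()))

    def __repr__(self) -> str:
        if self.k <= 6:
            return f"BooleanFunction(k={self.k}, outputs='{self.as_bitstring()}')"
        return f"BooleanFunction(k={self.k}, bias={self.bias})"


@dataclass(frozen=True)
class InputTransform:
    """Negation of an input subset, an input permutation, or complementation.

    Exactly one mode is active.  ``permutation`` maps position ``i`` to
    ``sigma(i)`` (1-based): variable ``x_i`` in the expression is replaced by
    ``x_{sigma(i)}``.  Negation and permutation preserve the bias;
    complementation maps bias ``P`` to ``2^k - P``.
    """

    mode: str  # "negate" | "permute" | "complement"
    negate_set: frozenset = frozenset()
    permutation: tuple = ()

    def __post_init__(self):
        if self.mode not in ("negate", "permute", "complement"):
            raise ValueError(f"unknown transform mode {self.mode!r}")
        if self.mode == "permute":
            k = len(self.permutation)
            if sorted(self.permutation) != list(range(1, k + 1)):
                raise ValueError("permutation must be a bijection on 1..k")


# ---------------------------------------------------------------------------
# expression parsing


_TOKEN_RE = re.compile(
    r"\s*(?:(?P<and>&|∧|\bAND\b)|(?P<or>\||∨|\bOR\b)"
    r"|(?P<not>!|~|¬|\bNOT\b)|(?P<lpar>\()|(?P<rpar>\))"
    r"|(?P<const>[01])(?![\w.])|(?P<var>[A-Za-z_][\w.\-]*))",
    re.IGNORECASE,
)


class ExpressionError(ValueError):
    """Raised for malformed Boolean expressions; names the offending token."""


def _tokenize(expr: str):
    pos = 0
    tokens = []
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if m is None:
            if expr[pos:].strip() == "":
                break
            raise ExpressionError(
                f"unexpected character {expr[pos]!r} at position {pos}"
            )
        kind = m.lastgroup
        tokens.append((kind, m.group(kind), m.start(kind)))
        pos = m.end()
    tokens.append(("end", "", len(expr)))
    return tokens


def truth_table_from_expression(
    expr: str, var_order: Sequence[str]
) -> BooleanFunction:
    """Evaluate a Boolean expression into a truth table.

    Accepted syntax: ``&``/``AND``/``∧``, ``|``/``OR``/``∨``, ``!``/``~``/
    ``NOT``, parentheses, and the constants ``0``/``1``; keywords are
    case-insensitive.  Every name in ``var_order`` occupies one input slot of
    the result even if it does not appear in ``expr`` (it is then a dummy
    input).  OR binds more loosely than AND.
    """
    names = list(var_order)
    if len(set(names)) != len(names):
        raise ValueError("duplicate variable names in var_order")
    k = len(names)
    if k > MAX_K:
        raise ValueError(f"too many inputs ({k} > {MAX_K})")
    index = {name: i for i, name in enumerate(names)}
    tokens = _tokenize(expr)
    tpos = [0]

    shape = (2,) * k if k else ()

    def var_tensor(i: int) -> np.ndarray:
        ax = np.zeros(shape, dtype=np.uint8)
        if k:
            sl = [slice(None)] * k
            sl[i] = 1
            ax[tuple(sl)] = 1
        return ax

    def peek():
        return tokens[tpos[0]]

    def advance():
        tok = tokens[tpos[0]]
        tpos[0] += 1
        return tok

    def parse_or() -> np.ndarray:
        left = parse_and()
        while peek()[0] == "or":
            advance()
            left = left | parse_and()
        return left

    def parse_and() -> np.ndarray:
        left = parse_atom()
        while peek()[0] == "and":
            advance()
            left = left & parse_atom()
        return left

    def parse_atom() -> np.ndarray:
        kind, text, at = advance()
        if kind == "not":
            return 1 - parse_atom()
        if kind == "lpar":
            inner = parse_or()
            kind2, text2, at2 = advance()
            if kind2 != "rpar":
                raise ExpressionError(f"expected ')' at position {at2}, got {text2!r}")
            return inner
        if kind == "const":
            return np.full(shape, int(text), dtype=np.uint8)
        if kind == "var":
            if text not in index:
                raise ExpressionError(f"unknown variable {text!r} at position {at}")
            return var_tensor(index[text])
        raise ExpressionError(f"unexpected token {text!r} at position {at}")

    result = parse_or()
    kind, text, at = peek()
    if kind != "end":
        raise ExpressionError(f"trailing token {text!r} at position {at}")
    return BooleanFunction(k, np.asarray(result, dtype=np.uint8).reshape(2**k))


# ---------------------------------------------------------------------------
# elementary operations


def bias(f: BooleanFunction) -> int:
    """Number of 1s in the output vector of ``f``."""
    return f.bias


def transform(f: BooleanFunction, t: InputTransform) -> BooleanFunction:
    """Apply an input negation, input permutation, or output complementation."""
    if t.mode == "complement":
        return BooleanFunction(f.k, 1 - f.outputs)
    if t.mode == "negate":
        bad = [i for i in t.negate_set if not 1 <= i <= f.k]
        if bad:
            raise ValueError(f"negate indices out of range: {sorted(bad)}")
        ten = f.tensor()
        for i in t.negate_set:
            ten = np.flip(ten, axis=i - 1)
        return BooleanFunction(f.k, ten.reshape(-1))
    # permute
    if len(t.permutation) != f.k:
        raise ValueError("permutation length must equal k")
    # replacing x_j by x_{sigma(j)} means g[y_1..y_k] = f[y_{sigma(1)}, ...];
    # the f-axis d must therefore read the y-axis sigma(d+1)-1
    axes = [0] * f.k
    for pos, s in enumerate(t.permutation):
        axes[s - 1] = pos
    ten = np.transpose(f.tensor(), axes=axes) if f.k else f.tensor()
    return BooleanFunction(f.k, np.ascontiguousarray(ten).reshape(-1))


def negate(f: BooleanFunction, inputs: Iterable[int]) -> BooleanFunction:
    return transform(f, InputTransform("negate", negate_set=frozenset(inputs)))


def permute(f: BooleanFunction, sigma: Sequence[int]) -> BooleanFunction:
    return transform(f, InputTransform("permute", permutation=tuple(sigma)))


def complement(f: BooleanFunction) -> BooleanFunction:
    return transform(f, InputTransform("complement"))


def restrict(f: BooleanFunction, i: int, v: int) -> BooleanFunction:
    """Fix input ``x_i`` to the bit ``v``; remaining inputs keep their order.

    Restricting a 1-input function yields a 0-input constant.
    """
    if not 1 <= i <= f.k:
        raise ValueError(f"input index {i} out of range 1..{f.k}")
    half = np.take(f.tensor(), int(v), axis=i - 1)
    return BooleanFunction(f.k - 1, np.ascontiguousarray(half).reshape(-1))


def essential_inputs(f: BooleanFunction) -> set:
    """Indices i whose two restrictions differ (the function depends on x_i)."""
    ten = f.tensor()
    out = set()
    for i in range(1, f.k + 1):
        lo = np.take(ten, 0, axis=i - 1)
        hi = np.take(ten, 1, axis=i - 1)
        if not np.array_equal(lo, hi):
            out.add(i)
    return out


def unate_directions(f: BooleanFunction) -> tuple:
    """Per-input monotonicity label.

    ``"positive"`` if the output is non-decreasing in that input over every
    context of the other inputs, ``"negative"`` if non-increasing,
    ``"dummy"`` if the input never matters, ``"non-unate"`` otherwise.
    Activators of a gene are positive-unate inputs; inhibitors negative.
    """
    ten = f.tensor()
    labels = []
    for i in range(1, f.k + 1):
        lo = np.take(ten, 0, axis=i - 1)
        hi = np.take(ten, 1, axis=i - 1)
        nondec = bool((lo <= hi).all())
        noninc = bool((lo >= hi).all())
        if nondec and noninc:
            labels.append("dummy")
        elif nondec:
            labels.append("positive")
        elif noninc:
            labels.append("negative")
        else:
            labels.append("non-unate")
    return tuple(labels)
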