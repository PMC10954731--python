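"""Readers and writers for the on-disk formats.

Supported formats (all plain text, UTF-8, deterministic writers):

* ``.bnet`` Boolean models: a ``targets, factors`` header followed by one
  ``node, expression`` line per node, with ``&``, ``|``, ``!`` and
  parentheses in the factor expressions (the convention used by the
  common Boolean-network model repositories);
* truth-table collections: TSV with columns ``source  node  k  output``
  and an ``# encoding=...`` header line naming the output dialect, one of
  ``bitstring``, ``integer-msb-row0`` (row 0 of the truth table is the
  most significant bit: "0001" <-> 1 at k = 2) or ``integer-msb-rowlast``;
* network configurations: an edges CSV (``source,target,sign``), a
  fixed-points CSV (``name`` column plus one column per node), and a
  hierarchy string such as ``"QC<VI,QC<CEI"``.

Readers validate and reject malformed input rather than coercing it.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .bfcore import BooleanFunction, truth_table_from_expression
from .bndyn import BooleanModel
from .enrich import BFRecord
from .modelselect import SignedNetwork

__all__ = [
    "read_bnet",
    "write_bnet",
    "read_bf_table",
    "write_bf_table",
    "read_network_config",
]

logger = logging.getLogger("chainlogic")

ENCODINGS = ("bitstring", "integer-msb-row0", "integer-msb-rowlast")


# ---------------------------------------------------------------------------
# .bnet models


def _parse_factor_vars(expr: str) -> list:
    """Variable names in first-appearance order (regulator order)."""
    import re

    seen = []
    for m in re.finditer(r"[A-Za-z_][\w.\-]*", expr):
        tok = m.group()
        if tok.upper() in ("AND", "OR", "NOT"):
            continue
        if tok not in seen:
            seen.append(tok)
    return seen


def read_bnet(path) -> BooleanModel:
    """Parse a ``targets, factors`` model file into a BooleanModel.

    Regulator order of each node is the first-appearance order of names in
    its factor expression.  Constant factors (``A, 0``) become 0-input
    constant rules (valid for dynamics, excluded from classification).
    """
    lines = Path(path).read_text().splitlines()
    entries = []
    for ln, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.lower().replace(" ", "") in ("targets,factors", "targets,\tfactors"):
            continue
        if "," not in line:
            raise ValueError(f"{path}:{ln}: expected 'target, factors'")
        target, factors = line.split(",", 1)
        target, factors = target.strip(), factors.strip()
        if not target or not factors:
            raise ValueError(f"{path}:{ln}: empty target or factor")
        entries.append((ln, target, factors))
    names = [t for _, t, _ in entries]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"{path}: duplicate target lines for {dup}")
    declared = set(names)
    regulators = []
    functions = []
    for ln, target, factors in entries:
        regs = _parse_factor_vars(factors)
        unknown = [r for r in regs if r not in declared]
        if unknown:
            raise ValueError(
                f"{path}:{ln}: factor of {target!r} references undeclared {unknown}"
            )
        f = truth_table_from_expression(factors, regs)
        regulators.append(tuple(names.index(r) for r in regs))
        functions.append(f)
    return BooleanModel(tuple(names), tuple(regulators), tuple(functions))


def write_bnet(model: BooleanModel, path, expressions: Optional[dict] = None) -> None:
    """Write a model in ``targets, factors`` form.

    Expressions are emitted as the full disjunctive normal form of each
    rule unless ``expressions`` supplies nicer text per node; the induced
    state-transition function round-trips exactly either way.
    """
    lines = ["targets, factors"]
    for i, name in enumerate(model.nodes):
        if expressions and name in expressions:
            expr = expressions[name]
        else:
            f = model.functions[i]
            regs = [model.nodes[r] for r in model.regulators[i]]
            if f.k == 0 or f.is_constant():
                expr = "1" if f.bias else "0"
            else:
                terms = []
                for row in range(2**f.k):
                    if f.outputs[row]:
                        lits = []
                        for j, rname in enumerate(regs):
                            bit = (row >> (f.k - 1 - j)) & 1
                            lits.append(rname if bit else f"!{rname}")
                        terms.append("(" + " & ".join(lits) + ")")
                expr = " | ".join(terms)
        lines.append(f"{name}, {expr}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# truth-table collections


def _decode_output(text: str, k: int, encoding: str, where: str) -> BooleanFunction:
    n = 2**k
    if encoding == "bitstring":
        if len(text) != n or set(text) - {"0", "1"}:
            raise ValueError(
                f"{where}: output {text!r} is not a {n}-bit string for k={k}"
            )
        return BooleanFunction(k, text)
    try:
        value = int(text)
    except ValueError:
        raise ValueError(f"{where}: output {text!r} is not an integer") from None
    if not 0 <= value < 2**n:
        raise ValueError(f"{where}: integer {value} out of range for k={k}")
    return BooleanFunction.from_int(k, value, msb_row0=(encoding == "integer-msb-row0"))


def _encode_output(f: BooleanFunction, encoding: str) -> str:
    if encoding == "bitstring":
        return f.as_bitstring()
    return str(f.as_int(msb_row0=(encoding == "integer-msb-row0")))


def read_bf_table(path, kmax: int = 10) -> list:
    """Read a truth-table collection TSV into BFRecords.

    The first non-blank line must be ``# encoding=<dialect>``; a column
    header ``source  node  k  output`` follows.  Rows with more than
    ``kmax`` inputs are dropped with a logged count, mirroring the usual
    restriction of regulatory-rule analyses to at most 10 inputs.
    """
    lines = Path(path).read_text().splitlines()
    encoding = None
    body_start = 0
    for i, line in enumerate(lines):
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            if "encoding=" in s:
                encoding = s.split("encoding=", 1)[1].strip()
            continue
        body_start = i
        break
    if encoding is None:
        raise ValueError(f"{path}: missing '# encoding=...' header")
    if encoding not in ENCODINGS:
        raise ValueError(f"{path}: unknown encoding {encoding!r}; use one of {ENCODINGS}")
    header = [c.strip() for c in lines[body_start].split("\t")]
    expected = ["source", "node", "k", "output"]
    if header != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {header}")
    records = []
    dropped = 0
    for ln, raw in enumerate(lines[body_start + 1 :], start=body_start + 2):
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if len(parts) != 4:
            raise ValueError(f"{path}:{ln}: expected 4 tab-separated fields")
        source, node, k_text, output = (p.strip() for p in parts)
        try:
            k = int(k_text)
        except ValueError:
            raise ValueError(f"{path}:{ln}: bad input count {k_text!r}") from None
        if not 1 <= k <= 20:
            raise ValueError(f"{path}:{ln}: input count {k} outside 1..20")
        if k > kmax:
            dropped += 1
            continue
        f = _decode_output(output, k, encoding, f"{path}:{ln}")
        records.append(BFRecord(source, node, f))
    if dropped:
        logger.info("read_bf_table: dropped %d rows with k > %d", dropped, kmax)
    return records


def write_bf_table(records: Sequence[BFRecord], path, encoding: str = "bitstring") -> None:
    if encoding not in ENCODINGS:
        raise ValueError(f"unknown encoding {encoding!r}")
    lines = [f"# encoding={encoding}", "source\tnode\tk\toutput"]
    for rec in records:
        lines.append(
            f"{rec.source}\t{rec.node}\t{rec.k}\t{_encode_output(rec.function, encoding)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# network configuration (edges + fixed points + hierarchy)


_SIGN_TOKENS = {
    "+": 1, "+1": 1, "1": 1, "activation": 1, "positive": 1,
    "-": -1, "-1": -1, "inhibition": -1, "negative": -1,
}


def read_network_config(
    edges_path, fixed_points_path, hierarchy: str = ""
):
    """Read a signed network, named fixed points, and hierarchy constraints.

    Returns ``(network, fixed_points, hierarchy_pairs)`` where
    ``fixed_points`` maps state names to {node: bit} and the hierarchy
    pairs are (less stable, more stable) name tuples parsed from a comma
    list like ``"QC<VI,QC<CEI"``.  Every hierarchy name must be a declared
    fixed point.
    """
    edf = pd.read_csv(edges_path)
    need = ["source", "target", "sign"]
    if list(edf.columns[:3]) != need:
        raise ValueError(f"{edges_path}: expected columns {need}")
    edges = []
    for _, row in edf.iterrows():
        tok = str(row["sign"]).strip().lower()
        if tok not in _SIGN_TOKENS:
            raise ValueError(
                f"{edges_path}: unknown sign {row['sign']!r} on edge "
                f"{row['source']!r} -> {row['target']!r}"
            )
        edges.append((str(row["source"]), str(row["target"]), _SIGN_TOKENS[tok]))
    network = SignedNetwork.from_edges(edges)

    fdf = pd.read_csv(fixed_points_path)
    if fdf.columns[0] != "name":
        raise ValueError(f"{fixed_points_path}: first column must be 'name'")
    node_cols = list(fdf.columns[1:])
    missing = [n for n in network.nodes if n not in node_cols]
    if missing:
        raise ValueError(f"{fixed_points_path}: missing node columns {missing}")
    fixed_points = {}
    for _, row in fdf.iterrows():
        name = str(row["name"])
        state = {}
        for n in node_cols:
            v = int(row[n])
            if v not in (0, 1):
                raise ValueError(f"{fixed_points_path}: non-binary value for {n!r}")
            state[n] = v
        fixed_points[name] = state

    pairs = []
    if hierarchy.strip():
        for item in hierarchy.split(","):
            item = item.strip()
            if "<" not in item:
                raise ValueError(f"hierarchy item {item!r} must be 'A<B'")
            less, more = (s.strip() for s in item.split("<", 1))
            for nm in (less, more):
                if nm not in fixed_points:
                    raise ValueError(
                        f"hierarchy names undeclared fixed point {nm!r}"
                    )
            pairs.append((less, more))
    return network, fixed_points, tuple(pairs)
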