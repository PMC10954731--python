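"""Constraint-based ensembles of Boolean GRN models and stability selection.

Starting from a signed interaction network and a set of named biological
fixed points (cell states), each node's admissible update rules are the
members of a prescribed function class (chain-0, chain-1, generalized
chain, or NCF) that

1. reproduce every declared fixed point (the rows of the node's truth
   table touched by the fixed points are pinned),
2. belong to the class, and
3. conform to the interaction signs: the rule must be positive-unate in
   each activator and negative-unate in each inhibitor (for nested
   canalyzing rules, unate direction coincides with the literal sign).

The biologically plausible ensemble is the Cartesian product of the
per-node lists.  A model is *selected* when its noisy dynamics reproduce
the published relative-stability hierarchies (via MFPTs), the summed
basin of the biological fixed points is at least a reference value, and
(optionally) no spurious attractor exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .bfcore import BooleanFunction
from .chainclass import AND, OR, layers_from_bias
from .chainclass import build_function
from .bndyn import (
    ATTRACTOR_MAX_N,
    EXACT_MFPT_MAX_N,
    Attractor,
    BooleanModel,
    StochasticDynamics,
    attractors,
    stability_analysis,
    update_table,
)

__all__ = [
    "SignedNetwork",
    "NodeConstraint",
    "SelectionCriteria",
    "EnsembleResult",
    "SelectionResult",
    "fixed_point_constraints",
    "admissible_functions",
    "ensemble",
    "select_models",
]

ADMISSIBLE_MAX_K = 10


@dataclass(frozen=True)
class SignedNetwork:
    """Signed directed regulatory structure."""

    nodes: tuple  # node names, declaration order
    regulators: dict  # target -> ordered tuple of source names
    signs: dict  # target -> tuple of +1/-1, aligned with regulators

    def __post_init__(self):
        declared = set(self.nodes)
        for target, srcs in self.regulators.items():
            if target not in declared:
                raise ValueError(f"undeclared target node {target!r}")
            if len(set(srcs)) != len(srcs):
                raise ValueError(f"duplicate regulator of {target!r}")
            for s in srcs:
                if s not in declared:
                    raise ValueError(f"undeclared source node {s!r} -> {target!r}")
            for sg in self.signs[target]:
                if sg not in (1, -1):
                    raise ValueError(
                        f"sign {sg!r} on an edge into {target!r}; use +1/-1"
                    )
            if len(self.signs[target]) != len(srcs):
                raise ValueError(f"sign/regulator length mismatch at {target!r}")

    @classmethod
    def from_edges(cls, edges: Sequence[tuple], nodes: Optional[Sequence[str]] = None):
        """Build from (source, target, sign) triples; node order is first
        appearance unless given explicitly."""
        seen = []
        regs: dict = {}
        sgs: dict = {}
        pairs = set()
        for src, tgt, sign in edges:
            if (src, tgt) in pairs:
                raise ValueError(f"duplicate edge {src!r} -> {tgt!r}")
            pairs.add((src, tgt))
            for n in (src, tgt):
                if n not in seen:
                    seen.append(n)
            regs.setdefault(tgt, []).append(src)
            sgs.setdefault(tgt, []).append(int(sign))
        order = tuple(nodes) if nodes is not None else tuple(seen)
        return cls(
            order,
            {t: tuple(v) for t, v in regs.items()},
            {t: tuple(v) for t, v in sgs.items()},
        )

    def in_degree(self, node: str) -> int:
        return len(self.regulators.get(node, ()))


@dataclass(frozen=True)
class NodeConstraint:
    """Everything that pins down one node's admissible update rules."""

    node: str
    k: int
    signs: tuple  # +1/-1 per regulator
    io_pairs: dict  # truth-table row -> required output bit
    cls: str = "CHFU"
    fallback_cls: Optional[str] = None
    infeasible: bool = False


@dataclass(frozen=True)
class SelectionCriteria:
    """What a model must satisfy to be selected."""

    hierarchies: tuple  # ((less_stable_name, more_stable_name), ...)
    basin_floor: Optional[int] = None  # minimal summed biological basin
    require_no_spurious: bool = False
    dynamics: StochasticDynamics = field(default_factory=StochasticDynamics)
    mfpt_mode: str = "auto"  # exact for N <= 12, sampled above


def fixed_point_constraints(
    network: SignedNetwork, fixed_points: dict, cls: str = "CHFU",
    fallback_cls: Optional[str] = None,
) -> dict:
    """Per-node truth-table rows pinned by the declared fixed points.

    ``fixed_points`` maps state names to {node: bit} mappings covering all
    nodes.  For a fixed point X* and node i, the row spelled by X* on i's
    regulators must output X*_i.  Contradictory requirements mark the node
    infeasible.
    """
    out = {}
    for node in network.nodes:
        regs = network.regulators.get(node, ())
        k = len(regs)
        io: dict = {}
        infeasible = False
        for name, state in fixed_points.items():
            missing = [n for n in network.nodes if n not in state]
            if missing:
                raise ValueError(f"fixed point {name!r} misses nodes {missing}")
            row = 0
            for r in regs:
                row = (row << 1) | int(state[r])
            want = int(state[node])
            if io.get(row, want) != want:
                infeasible = True
            io[row] = want if row not in io else io[row]
        out[node] = NodeConstraint(
            node, k, tuple(network.signs.get(node, ())), io, cls.upper(),
            fallback_cls.upper() if fallback_cls else None, infeasible,
        )
    return out


def _partitions_with_pools(layers_needs, pools, last_flexible):
    """Yield layer assignments (tuple of tuples of variables).

    ``layers_needs`` is a list of (size, required_sign_or_None); ``pools``
    maps +1/-1 to the available variables of that sign.  When
    ``last_flexible`` the final layer may contain exactly one variable of
    the opposite sign (the deviant); those assignments are yielded as
    (partition, deviant) with deviant None for the all-conforming case.
    """

    def rec(li, avail_pos, avail_neg):
        if li == len(layers_needs):
            yield ()
            return
        size, req = layers_needs[li]
        is_last = li == len(layers_needs) - 1
        if req is None:  # unconstrained placement (NCF class)
            allv = tuple(sorted(avail_pos | avail_neg))
            for block in combinations(allv, size):
                bs = set(block)
                for tail in rec(li + 1, avail_pos - bs, avail_neg - bs):
                    yield (block,) + tail
            return
        own = avail_pos if req == 1 else avail_neg
        other = avail_neg if req == 1 else avail_pos
        if is_last and last_flexible:
            # all-conforming choice
            for block in combinations(tuple(sorted(own)), size):
                yield ((tuple(block), None),)
            # one deviant of opposite sign
            if size >= 1:
                for dev in sorted(other):
                    for rest in combinations(tuple(sorted(own)), size - 1):
                        block = tuple(sorted(rest + (dev,)))
                        yield ((block, dev),)
            return
        for block in combinations(tuple(sorted(own)), size):
            bs = set(block)
            for tail in rec(li + 1, avail_pos - bs, avail_neg - bs):
                yield (block,) + tail

    pos = set(pools.get(1, ()))
    neg = set(pools.get(-1, ()))
    yield from rec(0, pos, neg)


def _chain_candidates(k, required_signs, value) -> Iterator[BooleanFunction]:
    """Sign-conforming chain-0 (value=0) / chain-1 (value=1) functions."""
    cls = "CHF0" if value == 0 else "CHF1"
    pools = {1: [], -1: []}
    for v, s in zip(range(1, k + 1), required_signs):
        pools[s].append(v)
    for P in range(1, 2**k, 2):
        st = layers_from_bias(k, P)
        needs = []
        for li, m in enumerate(st.layer_sizes):
            base_positive = st.layer_operator(li) == AND
            if value == 1:
                base_positive = not base_positive
            needs.append((m, 1 if base_positive else -1))
        for item in _partitions_with_pools(needs[:-1], pools, False):
            used = set(v for block in item for v in block)
            rem_pos = [v for v in pools[1] if v not in used]
            rem_neg = [v for v in pools[-1] if v not in used]
            size, req = needs[-1]
            own, other = (rem_pos, rem_neg) if req == 1 else (rem_neg, rem_pos)
            if len(own) + len(other) != size:
                continue  # partition of all k inputs required
            options = []
            if len(other) == 0:
                options.append((tuple(sorted(own)), None))
            if len(other) == 1 and size >= 1:
                options.append((tuple(sorted(own + other)), other[0]))
            for block, dev in options:
                layer_assignment = [list(b) for b in item] + [list(block)]
                yield build_function(
                    cls, k, P, layer_assignment, deviant=dev
                )


def _ncf_candidates(k, required_signs) -> Iterator[BooleanFunction]:
    """Sign-conforming NCFs: literal signs are pinned by the edge signs, so
    there is exactly one candidate per (bias, layer assignment)."""
    pools = {1: [], -1: []}
    for v, s in zip(range(1, k + 1), required_signs):
        pools[s].append(v)
    for P in range(1, 2**k, 2):
        st = layers_from_bias(k, P)
        needs = [(m, None) for m in st.layer_sizes]
        for part in _partitions_with_pools(needs, pools, False):
            order = [v for block in part for v in block]
            signs = [required_signs[v - 1] == 1 for v in order]
            yield build_function(
                "NCF", k, P, [list(b) for b in part], signs=signs
            )


def admissible_functions(constraint: NodeConstraint) -> list:
    """All class members satisfying the sign and fixed-point constraints.

    Constructive: iterates odd biases, sign-compatible layer assignments
    (with the chain classes' forced per-layer signs and at most one
    last-layer deviant), then filters on the pinned truth-table rows.
    Returns an empty list for infeasible constraints; if a fallback class
    is configured it is tried when the primary class yields nothing.
    """
    if constraint.infeasible:
        return []
    if constraint.k > ADMISSIBLE_MAX_K:
        raise ValueError(
            f"admissible-function generation capped at k={ADMISSIBLE_MAX_K}"
        )
    result = _admissible_for_class(constraint, constraint.cls)
    if not result and constraint.fallback_cls:
        result = _admissible_for_class(constraint, constraint.fallback_cls)
    return result


def _admissible_for_class(constraint: NodeConstraint, cls: str) -> list:
    k = constraint.k
    if k == 0:
        # constant input node: any constant consistent with the pinned rows
        out = []
        for v in (0, 1):
            if all(bit == v for bit in constraint.io_pairs.values()):
                out.append(BooleanFunction.constant(v))
        return out
    if cls == "CHF0":
        cands = _chain_candidates(k, constraint.signs, 0)
    elif cls == "CHF1":
        cands = _chain_candidates(k, constraint.signs, 1)
    elif cls == "CHFU":

        def both():
            yield from _chain_candidates(k, constraint.signs, 0)
            yield from _chain_candidates(k, constraint.signs, 1)

        cands = both()
    elif cls == "NCF":
        cands = _ncf_candidates(k, constraint.signs)
    else:
        raise ValueError(f"unknown function class {cls!r}")
    seen = set()
    out = []
    for f in cands:
        key = f.outputs.tobytes()
        if key in seen:
            continue
        seen.add(key)
        if all(int(f.outputs[row]) == bit for row, bit in constraint.io_pairs.items()):
            out.append(f)
    return out


@dataclass(frozen=True)
class EnsembleResult:
    """Per-node admissible rules and the ensemble they generate."""

    network: SignedNetwork
    per_node: dict  # node -> list[BooleanFunction]

    @property
    def counts(self) -> dict:
        return {n: len(fs) for n, fs in self.per_node.items()}

    @property
    def size(self) -> int:
        size = 1
        for fs in self.per_node.values():
            size *= len(fs)
        return size

    def model(self, index: int) -> BooleanModel:
        """The index-th model in mixed-radix order (last node fastest)."""
        if not 0 <= index < self.size:
            raise IndexError(index)
        nodes = self.network.nodes
        choice = {}
        rem = index
        for node in reversed(nodes):
            fs = self.per_node[node]
            rem, d = divmod(rem, len(fs))
            choice[node] = fs[d]
        return self._assemble(choice)

    def _assemble(self, choice: dict) -> BooleanModel:
        nodes = self.network.nodes
        idx = {n: i for i, n in enumerate(nodes)}
        regulators = tuple(
            tuple(idx[s] for s in self.network.regulators.get(n, ()))
            for n in nodes
        )
        return BooleanModel(nodes, regulators, tuple(choice[n] for n in nodes))

    def __iter__(self) -> Iterator[BooleanModel]:
        for i in range(self.size):
            yield self.model(i)

    def index_of(self, model: BooleanModel) -> Optional[int]:
        """Mixed-radix index of a model whose rules all appear in the
        per-node lists; None when some rule is not admissible."""
        index = 0
        for node in self.network.nodes:
            fs = self.per_node[node]
            f = model.functions[model.node_index(node)]
            match = next(
                (d for d, g in enumerate(fs) if g == f), None
            )
            if match is None:
                return None
            index = index * len(fs) + match
        return index


def ensemble(network: SignedNetwork, per_node: dict) -> EnsembleResult:
    return EnsembleResult(network, dict(per_node))


@dataclass(frozen=True)
class SelectionResult:
    ensemble: EnsembleResult
    audit: pd.DataFrame  # one row per model
    selected: tuple  # model indices

    @property
    def n_single_hierarchy_violations(self) -> int:
        return int((self.audit["n_hierarchy_violations"] == 1).sum())


def _fixed_point_states(network: SignedNetwork, fixed_points: dict) -> dict:
    nodes = network.nodes
    out = {}
    for name, state in fixed_points.items():
        s = 0
        for n in nodes:
            s = (s << 1) | int(state[n])
        out[name] = s
    return out


def select_models(
    ens: EnsembleResult,
    fixed_points: dict,
    criteria: SelectionCriteria,
    master_seed: Optional[int] = None,
) -> SelectionResult:
    """Exhaustive screen of the ensemble against the selection criteria.

    For each model: enumerate attractors (cheap screen first), flag
    attractors that are not declared fixed points as spurious, sum the
    basins of the biological fixed points, then evaluate the MFPT
    hierarchy verdicts.  A model is selected when every hierarchy holds
    decisively, the biological basin sum reaches the floor, and -- if
    required -- no spurious attractor exists.  Undecided verdicts (ties)
    count as violations.
    """
    N = len(ens.network.nodes)
    if N > ATTRACTOR_MAX_N:
        raise ValueError(f"exhaustive selection capped at N={ATTRACTOR_MAX_N}")
    fp_states = _fixed_point_states(ens.network, fixed_points)
    fp_set = set(fp_states.values())
    mode = criteria.mfpt_mode
    if mode == "auto":
        mode = "exact" if N <= EXACT_MFPT_MAX_N else "sampled"
    rows = []
    selected = []
    for i, model in enumerate(ens):
        table = update_table(model)
        atts = attractors(model, table)
        spurious = [
            a for a in atts if not (a.is_fixed_point and a.states[0] in fp_set)
        ]
        basin_sum = sum(
            a.basin_size
            for a in atts
            if a.is_fixed_point and a.states[0] in fp_set
        )
        has_fps = {s for a in atts if a.is_fixed_point for s in a.states}
        missing_fp = [n for n, s in fp_states.items() if s not in has_fps]
        violations = 0
        verdict_map = {}
        if missing_fp:
            # fixed points are guaranteed by construction; surface otherwise
            violations = len(criteria.hierarchies)
            verdict_map = {h: "missing-fixed-point" for h in criteria.hierarchies}
        elif criteria.hierarchies:
            stab = stability_analysis(
                model,
                fp_states,
                criteria.dynamics,
                mode=mode,
                master_seed=None if master_seed is None else master_seed + i,
            )
            for less, more in criteria.hierarchies:
                verdict = stab.verdicts[(more, less)]
                ok = verdict == "u>v"  # "more" is the more stable state
                verdict_map[(less, more)] = verdict
                if not ok:
                    violations += 1
        basin_ok = (
            criteria.basin_floor is None or basin_sum >= criteria.basin_floor
        )
        spurious_ok = not (criteria.require_no_spurious and spurious)
        is_selected = violations == 0 and basin_ok and spurious_ok
        if is_selected:
            selected.append(i)
        rows.append(
            {
                "model": i,
                "n_attractors": len(atts),
                "n_spurious": len(spurious),
                "basin_sum": basin_sum,
                "n_hierarchy_violations": violations,
                "basin_ok": basin_ok,
                "spurious_ok": spurious_ok,
                "selected": is_selected,
                **{
                    f"{less}<{more}": verdict_map.get((less, more), "")
                    for less, more in criteria.hierarchies
                },
            }
        )
    return SelectionResult(ens, pd.DataFrame(rows), tuple(selected))
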