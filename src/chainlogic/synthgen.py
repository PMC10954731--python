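"""Synthetic data: class-conditioned rule sampling, random signed GRNs with
planted fixed points, and planted-mixture rule collections.

The generators stand in for curated collections of reconstructed models:
a mixture dataset emulates a per-k table of regulatory logic rules with a
known (hidden) class composition, and a random signed network fixture
emulates a reconstructed GRN whose interaction signs, fixed points and
per-node rule classes are known by construction -- the ground truth the
enrichment statistics and the model-selection pipeline are tested
against.  All generators are pure functions of their parameters and the
seed.

Sampling within a class is enumeration-backed: the class members are
materialized once per (k, class) and drawn uniformly, which is exact but
caps k at the enumeration limits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np

from .bfcore import BooleanFunction, unate_directions
from .chaincount import enumerate_class
from .bndyn import BooleanModel, attractors
from .enrich import BFRecord
from .modelselect import SignedNetwork

__all__ = [
    "MixtureSpec",
    "sample_function",
    "random_model",
    "synthetic_bf_dataset",
]

CLASSES = ("CHF0", "CHF1", "NCF", "CHFU", "NCF_NON_CHFU", "RANDOM")


@lru_cache(maxsize=64)
def _class_pool(k: int, cls: str) -> tuple:
    """Materialized, deduplicated class members as truth-table integers
    (row-last-most-significant dialect)."""
    if cls == "NCF_NON_CHFU":
        ncf = set(enumerate_class(k, "NCF", encoding="msb-rowlast"))
        chfu = set(enumerate_class(k, "CHFU", encoding="msb-rowlast"))
        return tuple(sorted(ncf - chfu))
    return tuple(sorted(enumerate_class(k, cls, encoding="msb-rowlast")))


def sample_function(k: int, cls: str, rng: np.random.Generator) -> BooleanFunction:
    """One uniform draw from a function class.

    ``cls`` is one of CHF0, CHF1, CHFU, NCF, NCF_NON_CHFU, or RANDOM
    (uniform over all 2^(2^k) functions, the unstructured background).
    """
    cls = cls.upper()
    if cls not in CLASSES:
        raise ValueError(f"unknown class {cls!r}")
    if cls == "RANDOM":
        bits = rng.integers(0, 2, size=2**k)
        return BooleanFunction(k, bits.astype(np.uint8))
    pool = _class_pool(k, cls)
    if not pool:
        raise ValueError(f"class {cls} is empty at k={k}")
    tt = pool[int(rng.integers(len(pool)))]
    return BooleanFunction.from_int(k, int(tt), msb_row0=False)


@dataclass(frozen=True)
class MixtureSpec:
    """A planted mixture of rule classes over a range of input counts."""

    n: int
    proportions: dict = field(
        default_factory=lambda: {"CHF0": 0.25, "CHF1": 0.25, "NCF_NON_CHFU": 0.25, "RANDOM": 0.25}
    )
    k_weights: dict = field(default_factory=lambda: {4: 1.0})
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        tot = sum(self.proportions.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {tot}, not 1")
        for cls in self.proportions:
            if cls.upper() not in CLASSES:
                raise ValueError(f"unknown class {cls!r} in mixture")


def synthetic_bf_dataset(spec: MixtureSpec):
    """A planted-mixture rule collection.

    Returns ``(records, labels)``: the BFRecords and, as hidden ground
    truth, the planted class of each record (which the classifier may
    refine, e.g. a RANDOM draw can land in a structured class).
    """
    rng = np.random.default_rng(spec.seed)
    classes = sorted(spec.proportions)
    probs = np.array([spec.proportions[c] for c in classes])
    ks = sorted(spec.k_weights)
    kw = np.array([spec.k_weights[k] for k in ks], dtype=float)
    kw = kw / kw.sum()
    records = []
    labels = []
    for i in range(spec.n):
        cls = classes[int(rng.choice(len(classes), p=probs))]
        k = ks[int(rng.choice(len(ks), p=kw))]
        f = sample_function(k, cls, rng)
        records.append(BFRecord(f"synthetic-m{i:05d}", f"g{i}", f))
        labels.append(cls.upper())
    return records, labels


def random_model(
    N: int,
    max_in_degree: int,
    cls: str,
    rng: np.random.Generator,
    min_fixed_points: int = 0,
    max_tries: int = 200,
):
    """A random signed GRN with rules drawn from a class.

    Every node receives 1..max_in_degree distinct regulators and a rule
    sampled uniformly from ``cls``; edge signs are set to the rule's unate
    directions, so the fixture is sign-conforming by construction.  Fixed
    points are found by exact attractor enumeration; when
    ``min_fixed_points`` is positive the draw is repeated until enough
    fixed points exist (failing loudly after ``max_tries``).

    Returns ``(network, model, fixed_points)`` with fixed points named
    FP0, FP1, ... (states as {node: bit} mappings).
    """
    if N > 12 or max_in_degree > 6:
        raise ValueError("random_model fixtures capped at N <= 12, in-degree <= 6")
    nodes = tuple(f"g{i}" for i in range(N))
    for _ in range(max_tries):
        regulators = []
        functions = []
        edges = []
        for i in range(N):
            k = int(rng.integers(1, min(max_in_degree, N) + 1))
            regs = tuple(int(r) for r in rng.choice(N, size=k, replace=False))
            f = sample_function(k, cls, rng)
            dirs = unate_directions(f)
            regulators.append(regs)
            functions.append(f)
            for j, r in enumerate(regs):
                sign = 1 if dirs[j] == "positive" else -1
                edges.append((nodes[r], nodes[i], sign))
        model = BooleanModel(nodes, tuple(regulators), tuple(functions))
        atts = attractors(model)
        fps = [a.states[0] for a in atts if a.is_fixed_point]
        if len(fps) < min_fixed_points:
            continue
        network = SignedNetwork.from_edges(edges, nodes=nodes)
        fixed_points = {
            f"FP{j}": dict(zip(nodes, model.state_to_bits(s)))
            for j, s in enumerate(sorted(fps))
        }
        return network, model, fixed_points
    raise RuntimeError(
        f"no draw with >= {min_fixed_points} fixed points in {max_tries} tries"
    )
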