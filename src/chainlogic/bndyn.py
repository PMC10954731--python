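"""Synchronous Boolean-network dynamics, attractors, and MFPT-based stability.

A network state is the integer whose bits, most-significant-first, follow
the node declaration order.  Under the synchronous scheme every node is
updated simultaneously, giving a deterministic map on the 2^N states whose
terminal cycles are the attractors (fixed points when of length 1) and
whose converging states form their basins.

Noise is modelled by flipping every node independently with probability
``eta`` at each step; when at least one node flips, the flipped state is
the next state, otherwise the deterministic image is taken.  The one-step
law is the column-stochastic matrix

    T* = (1 - eta)^N T + P,     P_lm = eta^d(l,m) (1 - eta)^(N - d(l,m))

with d the Hamming distance (P_mm = 0).  The mean first passage time
M_uv from state v to state u is estimated by averaging first-passage
times over trajectories, or computed exactly from the absorbing-chain
linear system for small networks.  The relative stability of two cell
states is RS(u, v) = 1/M_uv - 1/M_vu; u is called the more stable state
when RS(u, v) > 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .bfcore import BooleanFunction

__all__ = [
    "BooleanModel",
    "StochasticDynamics",
    "Attractor",
    "MFPTEstimate",
    "StabilityResult",
    "synchronous_step",
    "update_table",
    "attractors",
    "noisy_step",
    "transition_matrix",
    "mfpt",
    "relative_stability",
    "stability_analysis",
]

ATTRACTOR_MAX_N = 24
EXACT_MFPT_MAX_N = 12


@dataclass(frozen=True)
class BooleanModel:
    """Nodes, per-node ordered regulator lists, and one update rule each."""

    nodes: tuple  # node names, declaration order
    regulators: tuple  # per node, tuple of node indices (0-based)
    functions: tuple  # per node, BooleanFunction with arity = len(regulators)

    def __post_init__(self):
        for name, regs, f in zip(self.nodes, self.regulators, self.functions):
            if len(regs) != f.k:
                raise ValueError(
                    f"node {name!r}: function arity {f.k} != {len(regs)} regulators"
                )
            for r in regs:
                if not 0 <= r < len(self.nodes):
                    raise ValueError(f"node {name!r}: regulator index {r} unresolved")

    @property
    def N(self) -> int:
        return len(self.nodes)

    def node_index(self, name: str) -> int:
        return self.nodes.index(name)

    def state_to_bits(self, state: int) -> tuple:
        return tuple((state >> (self.N - 1 - i)) & 1 for i in range(self.N))

    def bits_to_state(self, bits: Sequence[int]) -> int:
        s = 0
        for b in bits:
            s = (s << 1) | int(b)
        return s

    def state_to_str(self, state: int) -> str:
        return format(state, f"0{self.N}b")


@dataclass(frozen=True)
class StochasticDynamics:
    """Noise level and sampling settings for the stochastic dynamics."""

    eta: float = 0.05
    n_traj: int = 3000
    max_steps: int = 1_000_000
    seed: Optional[int] = None

    def __post_init__(self):
        if not 0 <= self.eta < 1:
            raise ValueError("eta must lie in [0, 1)")
        if self.n_traj < 1:
            raise ValueError("n_traj must be >= 1")


@dataclass(frozen=True)
class Attractor:
    states: tuple  # cycle states, rotated so the smallest comes first
    basin_size: int

    @property
    def is_fixed_point(self) -> bool:
        return len(self.states) == 1


def synchronous_step(model: BooleanModel, state: int) -> int:
    """Deterministic simultaneous update of every node."""
    N = model.N
    if not 0 <= state < 2**N:
        raise ValueError(f"state {state} out of range for N={N}")
    nxt = 0
    for i in range(N):
        regs = model.regulators[i]
        row = 0
        for r in regs:
            row = (row << 1) | ((state >> (N - 1 - r)) & 1)
        nxt |= int(model.functions[i].outputs[row]) << (N - 1 - i)
    return nxt


def update_table(model: BooleanModel) -> np.ndarray:
    """Image of every state under the synchronous map, as an int64 array."""
    N = model.N
    if N > ATTRACTOR_MAX_N:
        raise ValueError(
            f"full state space of N={N} exceeds the cap of {ATTRACTOR_MAX_N} nodes"
        )
    states = np.arange(2**N, dtype=np.int64)
    nxt = np.zeros_like(states)
    for i in range(N):
        regs = model.regulators[i]
        row = np.zeros_like(states)
        for r in regs:
            row = (row << 1) | ((states >> (N - 1 - r)) & 1)
        out = model.functions[i].outputs.astype(np.int64)[row]
        nxt |= out << (N - 1 - i)
    return nxt


def attractors(model: BooleanModel, table: Optional[np.ndarray] = None) -> list:
    """All attractors of the synchronous dynamics with exact basin sizes.

    Enumerates the full state space (N <= 24); basin sizes sum to 2^N and
    every state belongs to exactly one basin.
    """
    if table is None:
        table = update_table(model)
    n = table.size
    # attractor id per state; -1 unknown, -2 on current walk
    color = np.full(n, -1, dtype=np.int64)
    cycles = []
    for s0 in range(n):
        if color[s0] != -1:
            continue
        path = []
        s = s0
        while color[s] == -1:
            color[s] = -2
            path.append(s)
            s = int(table[s])
        if color[s] == -2:  # new cycle discovered along this walk
            cyc_start = path.index(s)
            cyc = path[cyc_start:]
            aid = len(cycles)
            cycles.append(cyc)
        else:
            aid = int(color[s])
        for t in path:
            color[t] = aid
    result = []
    for aid, cyc in enumerate(cycles):
        rot = cyc.index(min(cyc))
        states = tuple(cyc[rot:] + cyc[:rot])
        result.append(Attractor(states, int((color == aid).sum())))
    return result


def noisy_step(
    model: BooleanModel,
    state: int,
    dynamics: StochasticDynamics,
    rng: np.random.Generator,
    table: Optional[np.ndarray] = None,
) -> int:
    """One step of the noisy dynamics: independent bit flips with
    probability eta; the deterministic image when nothing flips."""
    N = model.N
    flips = rng.random(N) < dynamics.eta
    if flips.any():
        mask = 0
        for i in range(N):
            if flips[i]:
                mask |= 1 << (N - 1 - i)
        return state ^ mask
    if table is not None:
        return int(table[state])
    return synchronous_step(model, state)


def transition_matrix(model: BooleanModel, eta: float) -> np.ndarray:
    """The explicit column-stochastic one-step matrix T*[l, m] = P(m -> l)."""
    N = model.N
    if N > EXACT_MFPT_MAX_N:
        raise ValueError(f"dense transition matrix capped at N={EXACT_MFPT_MAX_N}")
    n = 2**N
    table = update_table(model)
    states = np.arange(n)
    d = np.bitwise_count(np.bitwise_xor.outer(states, states))
    P = (eta**d) * ((1 - eta) ** (N - d))
    np.fill_diagonal(P, 0.0)
    T = np.zeros((n, n))
    T[table, states] = 1.0
    return (1 - eta) ** N * T + P


@dataclass(frozen=True)
class MFPTEstimate:
    value: float
    se: float = 0.0
    mode: str = "exact"
    n_traj: int = 0
    n_failures: int = 0  # trajectories truncated at max_steps


def _mfpt_exact(model: BooleanModel, target: int, eta: float,
                Tstar: Optional[np.ndarray] = None) -> np.ndarray:
    """Exact MFPT to ``target`` from every state, via the absorbing chain.

    Solves t_v = 1 + sum_{l != u} T*[l, v] t_l over the states v != u.
    """
    if Tstar is None:
        Tstar = transition_matrix(model, eta)
    n = Tstar.shape[0]
    keep = [s for s in range(n) if s != target]
    B = Tstar[np.ix_(keep, keep)].T  # B[v, l] = T*[l, v]
    t = np.linalg.solve(np.eye(n - 1) - B, np.ones(n - 1))
    full = np.zeros(n)
    full[keep] = t
    return full


def _mfpt_sampled(
    table: np.ndarray,
    N: int,
    target: int,
    source: int,
    dynamics: StochasticDynamics,
    rng: np.random.Generator,
) -> MFPTEstimate:
    n_traj = dynamics.n_traj
    cur = np.full(n_traj, source, dtype=np.int64)
    times = np.zeros(n_traj, dtype=np.int64)
    active = np.arange(n_traj)
    shifts = (1 << np.arange(N - 1, -1, -1)).astype(np.int64)
    step = 0
    eta = dynamics.eta
    while active.size and step < dynamics.max_steps:
        step += 1
        m = active.size
        flips = rng.random((m, N)) < eta
        mask = (flips * shifts).sum(axis=1).astype(np.int64)
        nxt = np.where(mask > 0, cur[active] ^ mask, table[cur[active]])
        cur[active] = nxt
        arrived = nxt == target
        times[active[arrived]] = step
        active = active[~arrived]
    n_fail = active.size
    done = times[times > 0] if n_fail else times
    if done.size == 0:
        return MFPTEstimate(np.inf, np.inf, "sampled", n_traj, n_fail)
    mean = float(done.mean())
    se = float(done.std(ddof=1) / np.sqrt(done.size)) if done.size > 1 else np.inf
    return MFPTEstimate(mean, se, "sampled", n_traj, n_fail)


def mfpt(
    model: BooleanModel,
    target: int,
    source: int,
    dynamics: StochasticDynamics,
    mode: str = "sampled",
    rng: Optional[np.random.Generator] = None,
    table: Optional[np.ndarray] = None,
) -> MFPTEstimate:
    """Mean first passage time from ``source`` to ``target``.

    ``mode="exact"`` solves the absorbing-chain linear system (N <= 12);
    ``mode="sampled"`` averages first-passage times over ``n_traj``
    trajectories of the noisy dynamics.  Trajectories still running at
    ``max_steps`` are reported as failures, never silently dropped.
    M_uu = 0 by convention.
    """
    if target == source:
        return MFPTEstimate(0.0, 0.0, mode, 0, 0)
    if mode == "exact":
        if dynamics.eta <= 0:
            raise ValueError("exact MFPT requires eta > 0 (irreducible chain)")
        full = _mfpt_exact(model, target, dynamics.eta)
        return MFPTEstimate(float(full[source]), 0.0, "exact")
    if mode != "sampled":
        raise ValueError(f"unknown mode {mode!r}")
    if rng is None:
        rng = np.random.default_rng(dynamics.seed)
    if table is None:
        table = update_table(model)
    return _mfpt_sampled(table, model.N, target, source, dynamics, rng)


def relative_stability(
    M_uv: float, M_vu: float, se_uv: float = 0.0, se_vu: float = 0.0, n_se: float = 3.0
):
    """RS(u, v) = 1/M_uv - 1/M_vu with a hierarchy verdict.

    Returns ``(rs, verdict)`` with verdict ``"u>v"``, ``"v>u"`` or
    ``"undecided"``; antisymmetric in its arguments.  In sampled mode the
    verdict is undecided when |RS| is within ``n_se`` propagated standard
    errors of zero.
    """
    if M_uv <= 0 or M_vu <= 0:
        raise ValueError("MFPTs must be positive")
    rs = 1.0 / M_uv - 1.0 / M_vu
    tol = n_se * np.hypot(se_uv / M_uv**2, se_vu / M_vu**2)
    # floating-point tie guard for the exact mode (se = 0)
    tol = max(tol, 1e-9 * (1.0 / M_uv + 1.0 / M_vu))
    if abs(rs) <= tol:
        return rs, "undecided"
    return rs, ("u>v" if rs > 0 else "v>u")


@dataclass(frozen=True)
class StabilityResult:
    """Pairwise MFPTs, relative stabilities and hierarchy verdicts."""

    states: tuple  # named cell states: ((name, state int), ...)
    mfpt: dict  # (u_name, v_name) -> MFPTEstimate of M_uv
    rs: dict  # (u_name, v_name) -> float
    verdicts: dict  # (u_name, v_name) -> "u>v" | "v>u" | "undecided"


def stability_analysis(
    model: BooleanModel,
    cell_states: dict,
    dynamics: StochasticDynamics,
    mode: str = "sampled",
    master_seed: Optional[int] = None,
) -> StabilityResult:
    """MFPTs, RS values and verdicts for every ordered pair of cell states.

    In sampled mode each (target, source) pair gets its own generator
    seeded from ``master_seed`` and the pair's position, so estimates do
    not depend on evaluation order.
    """
    names = list(cell_states)
    table = update_table(model)
    est: dict = {}
    if mode == "exact":
        Tstar = transition_matrix(model, dynamics.eta)
        for u in names:
            full = _mfpt_exact(model, cell_states[u], dynamics.eta, Tstar)
            for v in names:
                est[(u, v)] = (
                    MFPTEstimate(0.0, 0.0, mode, 0, 0)
                    if u == v
                    else MFPTEstimate(float(full[cell_states[v]]), 0.0, "exact")
                )
    else:
        for iu, u in enumerate(names):
            for iv, v in enumerate(names):
                if u == v:
                    est[(u, v)] = MFPTEstimate(0.0, 0.0, mode, 0, 0)
                    continue
                seed = master_seed if master_seed is not None else dynamics.seed
                rng = np.random.default_rng((0 if seed is None else seed, iu, iv))
                est[(u, v)] = mfpt(
                    model,
                    cell_states[u],
                    cell_states[v],
                    dynamics,
                    mode=mode,
                    rng=rng,
                    table=table,
                )
    rs: dict = {}
    verdicts: dict = {}
    for u in names:
        for v in names:
            if u == v:
                continue
            a, b = est[(u, v)], est[(v, u)]
            r, verdict = relative_stability(a.value, b.value, a.se, b.se)
            rs[(u, v)] = r
            verdicts[(u, v)] = verdict
    return StabilityResult(
        tuple((n, cell_states[n]) for n in names), est, rs, verdicts
    )
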