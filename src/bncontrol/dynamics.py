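"""Exhaustive synchronous state-space analysis.

The synchronous dynamics of an n-node Boolean network is a functional graph
on 2^n states: every state has exactly one successor.  For n up to
:data:`STATE_SPACE_LIMIT` this module materializes the full successor table
(bit-parallel evaluation over all states at once) and derives attractors,
basins of attraction, controller rankings and nonessential-edge pruning
from it.  Beyond the limit it refuses rather than silently sampling.

State indices encode bitstrings with x_1 as the most significant bit, so
index order equals bitstring order.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np

from .controls import ControlledNetwork, ControlPolicy, specialize
from .network import BooleanNetwork, State, state_from_string, state_to_string

__all__ = [
    "StateTransitionMap",
    "Attractor",
    "BasinReport",
    "transition_map",
    "attractors",
    "basin_sizes",
    "basin_of_state",
    "rank_policies",
    "prune_nonessential",
    "STATE_SPACE_LIMIT",
]

STATE_SPACE_LIMIT = 22


def _check_size(n: int, limit: int):
    if n > limit:
        raise ValueError(
            f"n={n} exceeds the exhaustive-analysis limit of {limit} nodes"
        )


def _state_index(state: Sequence[int] | str, n: int) -> int:
    if isinstance(state, str):
        state = state_from_string(state)
    if len(state) != n:
        raise ValueError(f"state length {len(state)} != network size {n}")
    idx = 0
    for b in state:
        idx = (idx << 1) | (b & 1)
    return idx


def _index_state(idx: int, n: int) -> State:
    return tuple((idx >> (n - 1 - i)) & 1 for i in range(n))


@dataclass
class StateTransitionMap:
    """Total successor map over all 2^n states (out-degree exactly one)."""

    n: int
    successor: np.ndarray  # uint32, length 2^n

    def __call__(self, state: Sequence[int]) -> State:
        return _index_state(int(self.successor[_state_index(state, self.n)]), self.n)

    def fixed_state_indices(self) -> np.ndarray:
        idx = np.arange(1 << self.n, dtype=np.uint32)
        return idx[self.successor == idx]

    def terminal_indices(self) -> np.ndarray:
        """F^(2^n)(s) for every s: the cycle state each trajectory lands on."""
        s = self.successor
        for _ in range(self.n):
            s = s[s]  # pointer doubling: after k rounds this is F^(2^k)
        return s


@dataclass(frozen=True)
class Attractor:
    """A terminal cycle, stored from its lexicographically smallest state."""

    states: tuple[State, ...]

    @property
    def period(self) -> int:
        return len(self.states)

    @property
    def is_fixed_point(self) -> bool:
        return self.period == 1

    def bitstrings(self) -> tuple[str, ...]:
        return tuple(state_to_string(s) for s in self.states)

    def __repr__(self):
        return f"Attractor({'|'.join(self.bitstrings())})"


@dataclass
class BasinReport:
    """Per-attractor basin sizes; deterministic dynamics partition the state
    space, so the sizes sum to 2^n and include the attractor states."""

    attractors: tuple[Attractor, ...]
    sizes: tuple[int, ...]
    total: int

    def percent(self, i: int) -> float:
        return round(100.0 * self.sizes[i] / self.total, 2)

    def as_rows(self) -> list[dict]:
        rows = []
        for i, (att, size) in enumerate(zip(self.attractors, self.sizes)):
            rows.append(
                {
                    "attractor": "|".join(att.bitstrings()),
                    "period": att.period,
                    "size": size,
                    "percent": self.percent(i),
                }
            )
        return rows


def transition_map(net: BooleanNetwork, limit: int = STATE_SPACE_LIMIT) -> StateTransitionMap:
    """Evaluate every update polynomial over all 2^n states at once."""
    n = net.n
    _check_size(n, limit)
    size = 1 << n
    idx = np.arange(size, dtype=np.uint32)
    cols = {
        name: ((idx >> np.uint32(n - 1 - i)) & 1).astype(bool)
        for i, name in enumerate(net.space.names)
    }
    succ = np.zeros(size, dtype=np.uint32)
    for i, f in enumerate(net.updates):
        val = np.zeros(size, dtype=bool)
        for term in f.terms:
            prod = np.ones(size, dtype=bool)
            for v in term:
                prod &= cols[v]
            val ^= prod
        succ |= val.astype(np.uint32) << np.uint32(n - 1 - i)
    return StateTransitionMap(n, succ)


def _attractors_from_map(tm: StateTransitionMap) -> tuple[tuple[Attractor, ...], np.ndarray]:
    """All terminal cycles plus a per-state attractor label array."""
    term = tm.terminal_indices()
    succ = tm.successor
    cycle_states = np.unique(term)
    label = np.full(1 << tm.n, -1, dtype=np.int32)
    atts: list[Attractor] = []
    for s in cycle_states:
        s = int(s)
        if label[s] >= 0:
            continue
        cyc = [s]
        t = int(succ[s])
        while t != s:
            cyc.append(t)
            t = int(succ[t])
        start = cyc.index(min(cyc))
        cyc = cyc[start:] + cyc[:start]
        aid = len(atts)
        atts.append(Attractor(tuple(_index_state(c, tm.n) for c in cyc)))
        for c in cyc:
            label[c] = aid
    order = sorted(range(len(atts)), key=lambda i: atts[i].states[0])
    remap = {old: new for new, old in enumerate(order)}
    relabel = np.array([remap[i] for i in range(len(atts))], dtype=np.int32)
    atts_sorted = tuple(atts[i] for i in order)
    state_label = relabel[label[term]]
    return atts_sorted, state_label


def attractors(net: BooleanNetwork, limit: int = STATE_SPACE_LIMIT) -> tuple[Attractor, ...]:
    """All attractors (fixed points and limit cycles) of the synchronous
    dynamics, found by pointer-doubling cycle detection on the functional
    graph; sorted by smallest member state."""
    tm = transition_map(net, limit)
    atts, _ = _attractors_from_map(tm)
    return atts


def basin_sizes(net: BooleanNetwork, limit: int = STATE_SPACE_LIMIT) -> BasinReport:
    """Count the states whose trajectory enters each attractor."""
    tm = transition_map(net, limit)
    atts, state_label = _attractors_from_map(tm)
    counts = np.bincount(state_label, minlength=len(atts))
    return BasinReport(atts, tuple(int(c) for c in counts), 1 << net.n)


def basin_of_state(net: BooleanNetwork, y0: Sequence[int], limit: int = STATE_SPACE_LIMIT) -> int:
    """Number of states (including y0 itself) whose trajectory reaches the
    fixed point y0; errors if y0 is not a fixed point."""
    if isinstance(y0, str):
        y0 = state_from_string(y0)
    tm = transition_map(net, limit)
    idx = _state_index(y0, net.n)
    if int(tm.successor[idx]) != idx:
        raise ValueError(f"{state_to_string(y0)} is not a fixed point")
    term = tm.terminal_indices()
    return int(np.count_nonzero(term == idx))


def rank_policies(
    cnet: ControlledNetwork,
    policies: Iterable[ControlPolicy],
    y0: Sequence[int],
    limit: int = STATE_SPACE_LIMIT,
) -> list[dict]:
    """Rank policies by the basin size of y0 in the specialized network,
    descending; ties break lexicographically by support.  Every policy must
    make y0 a fixed point (basin_of_state errors otherwise)."""
    rows = []
    total = 1 << cnet.base.n
    for policy in policies:
        net = specialize(cnet, policy)
        size = basin_of_state(net, y0, limit)
        rows.append(
            {
                "policy": policy,
                "controls": sorted(policy.support),
                "basin": size,
                "percent": round(100.0 * size / total, 2),
            }
        )
    rows.sort(key=lambda r: (-r["basin"], r["policy"].sort_key()))
    return rows


def prune_nonessential(
    cnet: ControlledNetwork, policy: ControlPolicy, limit: int = STATE_SPACE_LIMIT
) -> ControlPolicy:
    """Drop active edge controls that are nonessential given the rest.

    An edge control u_{i,j} in the set is nonessential when, in the network
    specialized by the *other* active controls, f_j no longer depends on
    x_i — deleting the edge then changes nothing.  Dropping is repeated to a
    fixed point, and the specialized updates before and after pruning are
    asserted identical.
    """
    active = set(policy.support)
    changed = True
    while changed:
        changed = False
        for name in sorted(active):
            tag = cnet.tag(name)
            if tag.kind != "edge":
                continue
            others = ControlPolicy.from_support(active - {name})
            net = specialize(cnet, others)
            if tag.source not in net.update(tag.target).variables():
                active.discard(name)
                changed = True
                break
    pruned = ControlPolicy.from_support(active)
    before = specialize(cnet, policy)
    after = specialize(cnet, pruned)
    assert before.updates == after.updates, "pruning altered the dynamics"
    return pruned
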