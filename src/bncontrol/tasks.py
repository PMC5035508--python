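"""The three control problems on Boolean networks, posed algebraically.

* :func:`create_steady_state` — make a desirable state y0 a fixed point:
  solve F_j(y0, u) - y0j = 0 (j = 1..n) for the control parameters u.
* :func:`block_transition` / :func:`destroy_steady_state` — prevent
  F(x0, u) = z0 by solving the single product equation
  (F_1(x0,u) - z01 + 1) ... (F_n(x0,u) - z0n + 1) = 0,
  which vanishes at u exactly when F(x0, u) != z0.
* :func:`block_region` — guarantee no steady state has a prescribed
  signature (e.g. Apoptosis = 0): find the u for which the steady-state
  system joined with the region clauses has no solution, via the
  elimination ideal onto the control variables or, for large control
  spaces, an exact per-candidate satisfiability check.

Every task reports ``raw`` solutions (total assignments of the active
controls, when enumerable) and ``minimal`` policies: supports with no
proper subset that already solves the problem, free controls set to 0.
Returned policies are re-verified against the defining dynamical condition
by direct simulation.
"""

from __future__ import annotations

import itertools
import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

from .algebra import (
    BooleanPolynomial,
    PolynomialSystem,
    count_solutions,
    eliminate,
    occurring_variables,
    solve_system,
)
from .controls import ControlledNetwork, ControlPolicy, specialize
from .network import State, fixed_points, state_from_string, state_to_string, step

__all__ = [
    "RegionConstraint",
    "ControlSolutionSet",
    "create_steady_state",
    "block_transition",
    "destroy_steady_state",
    "block_region",
    "minimal_policies",
]

# Raw solution sets are enumerated explicitly only up to this many controls.
RAW_ENUMERATION_LIMIT = 16
# block_region switches from Groebner elimination to candidate search when
# the joint state+control variable count exceeds this.
ELIMINATION_VARIABLE_LIMIT = 20


@dataclass(frozen=True)
class RegionConstraint:
    """A conjunction of clamps ``variable = bit`` on state variables."""

    clauses: tuple[tuple[str, int], ...]

    def __init__(self, clauses: Iterable[tuple[str, int]] | Mapping[str, int]):
        if isinstance(clauses, Mapping):
            clauses = clauses.items()
        cl = tuple((str(v), b & 1) for v, b in clauses)
        if len({v for v, _ in cl}) != len(cl):
            raise ValueError("at most one clause per variable")
        object.__setattr__(self, "clauses", cl)

    def as_dict(self) -> dict[str, int]:
        return dict(self.clauses)

    def matches(self, names: Sequence[str], state: Sequence[int]) -> bool:
        a = dict(zip(names, state))
        return all(a[v] == b for v, b in self.clauses)


@dataclass
class ControlSolutionSet:
    """Solutions of one control problem.

    ``raw`` holds total assignments of the active controls (None when the
    control space is too large to enumerate — the solution set is then
    represented implicitly by ``system``/``minimal``).  ``minimal`` holds
    support-minimal policies with free controls set to 0, sorted by support
    size then name; ``verified`` records the per-policy re-simulation check.
    """

    problem: dict
    minimal: tuple[ControlPolicy, ...]
    verified: tuple[bool, ...]
    raw: tuple[ControlPolicy, ...] | None = None
    raw_count: int | None = None
    occurring_count: int | None = None
    system: PolynomialSystem | None = None
    factors: tuple[BooleanPolynomial, ...] = field(default=())

    def to_json_dict(self) -> dict:
        out = {
            "problem": self.problem,
            "raw_count": self.raw_count,
            "minimal": [sorted(p.support) for p in self.minimal],
            "verified": list(self.verified),
        }
        if self.occurring_count is not None:
            out["occurring_count"] = self.occurring_count
        return out


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _as_state(state, n: int) -> State:
    if isinstance(state, str):
        state = state_from_string(state)
    state = tuple(int(b) & 1 for b in state)
    if len(state) != n:
        raise ValueError(f"state length {len(state)} != network size {n}")
    return state


def _negation_pairs(cnet: ControlledNetwork) -> list[frozenset[str]]:
    by_node: dict[str, set[str]] = {}
    for name, tag in cnet.registry:
        if tag.kind in ("node_off", "node_on"):
            by_node.setdefault(tag.target, set()).add(name)
    return [frozenset(v) for v in by_node.values() if len(v) == 2]

def _is_negation(support: frozenset[str], pairs: list[frozenset[str]]) -> bool:
    return any(p <= support for p in pairs)


def _substitute_state(cnet: ControlledNetwork, state: State) -> list[BooleanPolynomial]:
    """F_j(state, u): plug the state bits in, leaving controls symbolic."""
    assignment = dict(zip(cnet.base.space.names, state))
    return [u.restrict(assignment) for u in cnet.updates]


def _policy_assignment(cnet: ControlledNetwork, support: Iterable[str]) -> dict[str, int]:
    s = set(support)
    return {c: (1 if c in s else 0) for c in cnet.control_names}


def _local_minimal_supports(
    gens: Sequence[BooleanPolynomial], varlist: Sequence[str], vanish: bool
) -> list[frozenset[str]] | None:
    """Inclusion-minimal supports S ⊆ varlist whose zero-filled assignment
    makes every generator equal 0 (vanish=True) or some generator 0
    (vanish=False, for product factors).  None if no support works."""
    sols: list[frozenset[str]] = []
    k = len(varlist)
    for bits in itertools.product((0, 1), repeat=k):
        a = dict(zip(varlist, bits))
        vals = [g.evaluate(a) for g in gens]
        ok = all(v == 0 for v in vals) if vanish else any(v == 0 for v in vals)
        if ok:
            sols.append(frozenset(v for v, b in a.items() if b))
    if not sols:
        return None
    return _inclusion_minimal(sols)


def _inclusion_minimal(supports: Iterable[frozenset[str]]) -> list[frozenset[str]]:
    supports = sorted(set(supports), key=lambda s: (len(s), tuple(sorted(s))))
    out: list[frozenset[str]] = []
    for s in supports:
        if not any(t < s or t == s for t in out):
            out.append(s)
    return out


def _finalize(
    cnet: ControlledNetwork,
    supports: Iterable[frozenset[str]],
    condition,
    exclude_negation: bool,
    exclude_controls: Iterable[str],
) -> tuple[tuple[ControlPolicy, ...], tuple[bool, ...]]:
    pairs = _negation_pairs(cnet)
    excluded = set(exclude_controls)
    kept = []
    for s in sorted(set(supports), key=lambda s: (len(s), tuple(sorted(s)))):
        if exclude_negation and _is_negation(s, pairs):
            continue
        if s & excluded:
            continue
        kept.append(s)
    policies = tuple(ControlPolicy.from_support(s) for s in kept)
    verified = tuple(bool(condition(p)) for p in policies)
    return policies, verified


def _enumerate_raw(
    cnet: ControlledNetwork, system: PolynomialSystem
) -> tuple[tuple[ControlPolicy, ...] | None, int]:
    controls = list(cnet.control_names)
    n_sol = count_solutions(system, over=controls)
    if len(controls) > RAW_ENUMERATION_LIMIT or n_sol > (1 << RAW_ENUMERATION_LIMIT):
        return None, n_sol
    sols = solve_system(system, over=controls)
    return tuple(ControlPolicy(a) for a in sols), n_sol


# ---------------------------------------------------------------------------
# Task 1: generating new steady states
# ---------------------------------------------------------------------------

def create_steady_state(
    cnet: ControlledNetwork,
    y0,
    exclude_negation: bool = True,
    exclude_controls: Iterable[str] = (),
) -> ControlSolutionSet:
    """Controls u that make y0 a fixed point: F_j(y0, u) = y0j for all j.

    Because each control variable occurs only in the update it affects, the
    system decomposes into independent per-update blocks; raw counts are
    exact even when the full assignment set is too large to enumerate.
    """
    y0 = _as_state(y0, cnet.base.n)
    evals = _substitute_state(cnet, y0)
    gens = [fj + cnet.space.const(b) for fj, b in zip(evals, y0)]
    system = PolynomialSystem(cnet.space, gens)
    if any(g.is_one() for g in gens):
        return ControlSolutionSet(
            problem={"task": "fix", "y0": state_to_string(y0)},
            minimal=(), verified=(), raw=(), raw_count=0,
            occurring_count=0, system=system,
        )
    live = [g for g in gens if not g.is_zero()]
    occ = occurring_variables(system)
    occurring_count = count_solutions(system, over=occ) if occ else 1
    raw, raw_count = _enumerate_raw(cnet, system)

    # minimal supports: cartesian product of per-component minimal supports
    comp_min: list[list[frozenset[str]]] = []
    solvable = True
    if live:
        comps = _group_by_shared_vars(live)
        for cgens, cvars in comps:
            local = _local_minimal_supports(cgens, cvars, vanish=True)
            if local is None:
                solvable = False
                break
            comp_min.append(local)
    supports: list[frozenset[str]] = []
    if solvable:
        for combo in itertools.product(*comp_min) if comp_min else [()]:
            supports.append(frozenset().union(*combo) if combo else frozenset())

    def condition(policy: ControlPolicy) -> bool:
        return step(specialize(cnet, policy), y0) == y0

    minimal, verified = _finalize(cnet, supports, condition, exclude_negation, exclude_controls)
    return ControlSolutionSet(
        problem={"task": "fix", "y0": state_to_string(y0)},
        minimal=minimal, verified=verified, raw=raw, raw_count=raw_count,
        occurring_count=occurring_count, system=system,
    )


def _group_by_shared_vars(gens: Sequence[BooleanPolynomial]):
    """Connected components of generators sharing variables, with each
    component's variable list in space order."""
    space = gens[0].space
    remaining = list(range(len(gens)))
    comps = []
    while remaining:
        seed = remaining.pop(0)
        members = [seed]
        vs = set(gens[seed].variables())
        changed = True
        while changed:
            changed = False
            for j in list(remaining):
                if gens[j].variables() & vs:
                    remaining.remove(j)
                    members.append(j)
                    vs |= gens[j].variables()
                    changed = True
        varlist = [v for v in space.names if v in vs]
        comps.append(([gens[i] for i in members], varlist))
    return comps


# ---------------------------------------------------------------------------
# Task 2: blocking transitions / destroying steady states
# ---------------------------------------------------------------------------

def block_transition(
    cnet: ControlledNetwork,
    x0,
    z0,
    exclude_negation: bool = True,
    exclude_controls: Iterable[str] = (),
) -> ControlSolutionSet:
    """Controls u with F(x0, u) != z0, via the product equation
    prod_j (F_j(x0,u) + z0j + 1) = 0: the product vanishes iff some
    coordinate of F(x0, u) differs from z0.

    The factors have pairwise-disjoint control variables (each control only
    touches one update), so the equation is solved factor-by-factor without
    expanding the product.
    """
    x0 = _as_state(x0, cnet.base.n)
    z0 = _as_state(z0, cnet.base.n)
    evals = _substitute_state(cnet, x0)
    factors = [fj + cnet.space.const(b ^ 1) for fj, b in zip(evals, z0)]
    problem = {
        "task": "block-transition",
        "x0": state_to_string(x0),
        "z0": state_to_string(z0),
    }
    controls = list(cnet.control_names)
    m = len(controls)

    def condition(policy: ControlPolicy) -> bool:
        return step(specialize(cnet, policy), x0) != z0

    live = [f for f in factors if f.constant_value() is None]
    zero_blocks = any(f.constant_value() == 0 for f in factors)

    supports: list[frozenset[str]] = []
    if zero_blocks:
        supports.append(frozenset())
        raw_count = 1 << m
    else:
        # assignments where *every* factor equals 1 do not block
        fac_vars = [sorted(f.variables(), key=cnet.space.index) for f in live]
        flat = [v for vs in fac_vars for v in vs]
        if len(flat) != len(set(flat)):
            raise NotImplementedError(
                "block_transition factors share control variables"
            )
        nonblocking = 1
        for f, vs in zip(live, fac_vars):
            ones = sum(
                f.evaluate(dict(zip(vs, bits))) == 1
                for bits in itertools.product((0, 1), repeat=len(vs))
            )
            nonblocking *= ones
        nonblocking <<= m - len(flat)
        raw_count = (1 << m) - nonblocking
        for f, vs in zip(live, fac_vars):
            local = _local_minimal_supports([f], vs, vanish=True)
            if local:
                supports.extend(local)
        supports = _inclusion_minimal(supports)

    raw = None
    if m <= RAW_ENUMERATION_LIMIT:
        raw_list = []
        for bits in itertools.product((0, 1), repeat=m):
            a = dict(zip(controls, bits))
            if any(f.evaluate(a) == 0 for f in factors):
                raw_list.append(ControlPolicy(a))
        raw = tuple(raw_list)
        assert len(raw) == raw_count

    minimal, verified = _finalize(cnet, supports, condition, exclude_negation, exclude_controls)
    return ControlSolutionSet(
        problem=problem, minimal=minimal, verified=verified, raw=raw,
        raw_count=raw_count, factors=tuple(factors),
    )


def destroy_steady_state(
    cnet: ControlledNetwork,
    x0,
    exclude_negation: bool = True,
    exclude_controls: Iterable[str] = (),
) -> ControlSolutionSet:
    """Controls that make the fixed point x0 no longer fixed:
    block the self-transition x0 -> x0."""
    x0 = _as_state(x0, cnet.base.n)
    if step(cnet.base, x0) != x0:
        warnings.warn(
            f"{state_to_string(x0)} is not a fixed point of the base network",
            stacklevel=2,
        )
    result = block_transition(cnet, x0, x0, exclude_negation, exclude_controls)
    result.problem = {"task": "destroy", "x0": state_to_string(x0)}
    return result


# ---------------------------------------------------------------------------
# Task 3: blocking regions of the state space
# ---------------------------------------------------------------------------

def block_region(
    cnet: ControlledNetwork,
    region: RegionConstraint | Mapping[str, int],
    method: str = "auto",
    max_support: int = 3,
    exclude_negation: bool = True,
    exclude_controls: Iterable[str] = (),
) -> ControlSolutionSet:
    """Controls u for which *no* steady state of F(., u) lies in the region.

    Builds the steady-state system joined with the region clauses over state
    and control variables.  The ``groebner`` method eliminates the state
    variables and returns the u outside the projection of the solution set;
    the ``search`` method (used automatically for large control spaces)
    tests candidate supports of size <= ``max_support`` directly — a
    candidate blocks iff the specialized network has no fixed point in the
    region, checked by enumerating the region's states.
    """
    if not isinstance(region, RegionConstraint):
        region = RegionConstraint(region)
    state_names = cnet.base.space.names
    for v, _ in region.clauses:
        if v not in state_names:
            raise KeyError(f"region variable {v!r} is not a state variable")
    gens = [
        u + cnet.space.var(name) for name, u in zip(state_names, cnet.updates)
    ]
    gens += [cnet.space.var(v) + cnet.space.const(b) for v, b in region.clauses]
    system = PolynomialSystem(cnet.space, gens)
    controls = list(cnet.control_names)
    m = len(controls)
    problem = {"task": "block-region", "region": region.as_dict()}

    def condition(policy: ControlPolicy) -> bool:
        net = specialize(cnet, policy)
        return not any(
            region.matches(state_names, s) for s in fixed_points(net)
        )

    if method == "auto":
        method = (
            "groebner" if len(cnet.space) <= ELIMINATION_VARIABLE_LIMIT else "search"
        )

    if method == "groebner":
        projection = eliminate(system, keep=controls)
        if m > RAW_ENUMERATION_LIMIT:
            raise ValueError(
                "too many controls to enumerate the projection complement; "
                "use method='search'"
            )
        blocking: list[frozenset[str]] = []
        raw_list: list[ControlPolicy] = []
        for bits in itertools.product((0, 1), repeat=m):
            a = dict(zip(controls, bits))
            if any(g.evaluate(a) == 1 for g in projection):
                raw_list.append(ControlPolicy(a))
                blocking.append(frozenset(c for c, b in a.items() if b))
        supports = _inclusion_minimal(blocking)
        minimal, verified = _finalize(
            cnet, supports, condition, exclude_negation, exclude_controls
        )
        return ControlSolutionSet(
            problem=problem, minimal=minimal, verified=verified,
            raw=tuple(raw_list), raw_count=len(raw_list), system=projection,
        )

    if method != "search":
        raise ValueError(f"unknown method {method!r}")

    region_dict = region.as_dict()
    pairs = _negation_pairs(cnet)
    excluded = set(exclude_controls)
    candidates = [c for c in controls if c not in excluded]
    found: list[frozenset[str]] = []
    for size in range(0, max_support + 1):
        for combo in itertools.combinations(candidates, size):
            s = frozenset(combo)
            if exclude_negation and _is_negation(s, pairs):
                continue
            if any(f < s for f in found):
                continue  # a smaller blocker is contained: s is not minimal
            if _blocks_region(cnet, s, region_dict):
                found.append(s)
    minimal, verified = _finalize(
        cnet, found, condition, exclude_negation, exclude_controls
    )
    return ControlSolutionSet(
        problem=problem, minimal=minimal, verified=verified,
        raw=None, raw_count=None, system=system,
    )


def _blocks_region(
    cnet: ControlledNetwork, support: frozenset[str], region: dict[str, int]
) -> bool:
    """True iff the support's zero-filled policy leaves no fixed point in the
    region; checked by bit-parallel enumeration of the region's states."""
    import numpy as np

    net = specialize(cnet, ControlPolicy.from_support(support))
    names = net.space.names
    free = [v for v in names if v not in region]
    k = len(free)
    if k > 26:
        raise ValueError("region state space too large to enumerate")
    size = 1 << k
    idx = np.arange(size, dtype=np.uint32)
    cols: dict[str, "np.ndarray"] = {}
    for i, v in enumerate(free):
        cols[v] = ((idx >> np.uint32(k - 1 - i)) & 1).astype(bool)
    for v, b in region.items():
        cols[v] = np.full(size, bool(b))
    ok = np.ones(size, dtype=bool)
    for name, f in zip(names, net.updates):
        val = np.zeros(size, dtype=bool)
        for term in f.terms:
            prod = np.ones(size, dtype=bool)
            for v in term:
                prod &= cols[v]
            val ^= prod
        ok &= val == cols[name]
        if not ok.any():
            return True
    return not bool(ok.any())


# ---------------------------------------------------------------------------
# Minimal-policy post-processing
# ---------------------------------------------------------------------------

def minimal_policies(
    raw: Iterable[ControlPolicy],
    is_solution=None,
    monotone: bool = False,
) -> list[ControlPolicy]:
    """Support-minimal policies among (and below) a raw solution set.

    A support S qualifies when S (all other controls 0) is a solution and no
    proper subset of S is.  With ``monotone=True`` the inclusion-minimal
    supports of ``raw`` are returned directly; otherwise ``is_solution``
    (default: membership of the zero-filled support in ``raw``) is queried
    on subsets, smallest first.
    """
    raw = list(raw)
    raw_supports = {p.support for p in raw}
    if is_solution is None:
        def is_solution(s: frozenset[str]) -> bool:  # noqa: F811
            return s in raw_supports
    solving = [s for s in raw_supports if is_solution(s)]
    if monotone:
        return [ControlPolicy.from_support(s) for s in _inclusion_minimal(solving)]
    out: set[frozenset[str]] = set()
    for s in solving:
        best = s
        for size in range(0, len(s) + 1):
            hit = None
            for combo in itertools.combinations(sorted(s), size):
                if is_solution(frozenset(combo)):
                    hit = frozenset(combo)
                    break
            if hit is not None:
                best = hit
                break
        out.add(best)
    return [
        ControlPolicy.from_support(s) for s in _inclusion_minimal(out)
    ]
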