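"""Control encodings: turn a Boolean network F(x) into a controlled network
F(x, u) whose extra GF(2) parameters switch interventions on and off.

Two intervention types are encoded, matching what drugs and genetic
perturbations can do to a regulatory network:

* **edge deletion** u_{i,j}: inside f_j, the regulator x_i is replaced by
  (u_{i,j} + 1) * x_i, so u=1 pins x_i to 0 within f_j only (the regulation
  x_i -> x_j is severed) and u=0 is inert;
* **node knockout / constant expression** (u_i^-, u_i^+): the update of
  node i becomes (u_i^- + u_i^+ + 1) * f_i + u_i^+, which specializes to
  f_i, 0, 1, or f_i + 1 for (u^-, u^+) = (0,0), (1,0), (0,1), (1,1).  The
  last (negation) setting is representable but excluded from enumerated
  policies by default.

Setting every control to 0 always reproduces the base network: F(x, 0) = F(x).
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

from .algebra import BooleanPolynomial, VariableSpace
from .network import BooleanNetwork, wiring_diagram

__all__ = [
    "ControlTag",
    "ControlledNetwork",
    "ControlPolicy",
    "edge_control_name",
    "node_control_name",
    "add_edge_controls",
    "add_node_controls",
    "add_controls",
    "specialize",
]


@dataclass(frozen=True)
class ControlTag:
    """What a control variable does: ``edge`` deletion of source->target,
    or ``node_off`` (knockout) / ``node_on`` (constant expression) of node."""

    kind: str  # "edge" | "node_off" | "node_on"
    source: str | None
    target: str

    def __post_init__(self):
        if self.kind not in ("edge", "node_off", "node_on"):
            raise ValueError(f"unknown control kind {self.kind!r}")
        if (self.kind == "edge") != (self.source is not None):
            raise ValueError("edge tags need a source; node tags must not have one")


def edge_control_name(source: str, target: str) -> str:
    return f"u_{source}_{target}"


def node_control_name(node: str, mode: str) -> str:
    if mode not in ("off", "on"):
        raise ValueError(f"unknown node control mode {mode!r}")
    return f"u{mode}_{node}"


class ControlledNetwork:
    """A Boolean network plus a registry of control variables.

    ``registry`` is an ordered list of (control variable name, ControlTag);
    ``updates`` are polynomials over state + control variables.  Each control
    variable occurs only in the update its tag affects, and specializing all
    controls to 0 reproduces the base network exactly.
    """

    def __init__(
        self,
        base: BooleanNetwork,
        registry: Sequence[tuple[str, ControlTag]],
        updates: Sequence[BooleanPolynomial],
        space: VariableSpace,
    ):
        self.base = base
        self.registry = tuple(registry)
        self.updates = tuple(updates)
        self.space = space
        if len(self.updates) != base.n:
            raise ValueError("one controlled update per state variable required")

    @property
    def control_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.registry)

    def tag(self, control: str) -> ControlTag:
        for name, tag in self.registry:
            if name == control:
                return tag
        raise KeyError(f"unknown control variable {control!r}")

    def update(self, node: str) -> BooleanPolynomial:
        return self.updates[self.base.space.index(node)]

    def __repr__(self):
        return (
            f"<ControlledNetwork n={self.base.n} "
            f"controls={list(self.control_names)}>"
        )


@dataclass(frozen=True)
class ControlPolicy:
    """An assignment of bits to control variables; unset controls read as 0.

    ``support`` is the set of active (=1) controls — the interventions the
    policy actually applies.
    """

    values: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(
            self, "values", {k: v & 1 for k, v in dict(self.values).items()}
        )

    @property
    def support(self) -> frozenset[str]:
        return frozenset(k for k, v in self.values.items() if v)

    def sort_key(self) -> tuple:
        return (len(self.support), tuple(sorted(self.support)))

    def __getitem__(self, control: str) -> int:
        return self.values.get(control, 0)

    def __eq__(self, other):
        return isinstance(other, ControlPolicy) and self.support == other.support

    def __hash__(self):
        return hash(self.support)

    def __repr__(self):
        inside = ", ".join(f"{k}=1" for k in sorted(self.support)) or "0"
        return f"ControlPolicy({inside})"

    @classmethod
    def from_support(cls, support: Iterable[str]) -> "ControlPolicy":
        return cls({k: 1 for k in support})


def _extended_space(base: BooleanNetwork, control_names: Sequence[str]) -> VariableSpace:
    roles = {n: "state" for n in base.space.names}
    roles.update({c: "control" for c in control_names})
    return VariableSpace(tuple(base.space.names) + tuple(control_names), roles)


def _as_controlled(net: BooleanNetwork | ControlledNetwork) -> ControlledNetwork:
    if isinstance(net, ControlledNetwork):
        return net
    space = _extended_space(net, ())
    updates = [u.rename(space) for u in net.updates]
    return ControlledNetwork(net, (), updates, space)


def add_edge_controls(
    net: BooleanNetwork | ControlledNetwork, edges: Iterable[tuple[str, str]]
) -> ControlledNetwork:
    """Add an edge-deletion control u_{i,j} for each wiring-diagram edge (i, j).

    In f_j every occurrence of x_i becomes (u_{i,j} + 1) * x_i.  Controlling
    a pair that is not an edge of the base wiring diagram is an error.
    """
    cnet = _as_controlled(net)
    wd_edges = wiring_diagram(cnet.base).edges
    edges = list(edges)
    existing = set(cnet.control_names)
    new_names = []
    for i, j in edges:
        if (i, j) not in wd_edges:
            raise ValueError(f"({i}, {j}) is not an edge of the wiring diagram")
        name = edge_control_name(i, j)
        if name in existing or name in new_names:
            raise ValueError(f"duplicate control for edge ({i}, {j})")
        new_names.append(name)
    registry = list(cnet.registry) + [
        (edge_control_name(i, j), ControlTag("edge", i, j)) for i, j in edges
    ]
    space = _extended_space(cnet.base, [name for name, _ in registry])
    updates = [u.rename(space) for u in cnet.updates]
    for i, j in edges:
        u = space.var(edge_control_name(i, j))
        xi = space.var(i)
        tgt = cnet.base.space.index(j)
        updates[tgt] = updates[tgt].substitute(i, (u + 1) * xi)
    return ControlledNetwork(cnet.base, registry, updates, space)


def add_node_controls(
    net: BooleanNetwork | ControlledNetwork,
    nodes: Iterable[str],
    modes: Mapping[str, Iterable[str]] | None = None,
) -> ControlledNetwork:
    """Add knockout/constant-expression controls for the given nodes.

    ``modes`` maps a node to the subset of {"off", "on"} it may receive
    (default: both).  The update of node i becomes
    (u_i^- + u_i^+ + 1) * f_i + u_i^+, with an absent mode's variable fixed
    to 0 (so off-only gives (u^- + 1) * f_i, on-only (u^+ + 1) * f_i + u^+).
    """
    cnet = _as_controlled(net)
    nodes = list(nodes)
    modes = dict(modes or {})
    registry = list(cnet.registry)
    for node in nodes:
        cnet.base.space.index(node)
        for mode in ("off", "on"):
            if mode in modes.get(node, ("off", "on")):
                name = node_control_name(node, mode)
                if name in (n for n, _ in registry):
                    raise ValueError(f"duplicate control {name!r}")
                registry.append((name, ControlTag(f"node_{mode}", None, node)))
    space = _extended_space(cnet.base, [name for name, _ in registry])
    updates = [u.rename(space) for u in cnet.updates]
    for node in nodes:
        allowed = modes.get(node, ("off", "on"))
        u_off = (
            space.var(node_control_name(node, "off"))
            if "off" in allowed
            else space.zero()
        )
        u_on = (
            space.var(node_control_name(node, "on"))
            if "on" in allowed
            else space.zero()
        )
        tgt = cnet.base.space.index(node)
        updates[tgt] = (u_off + u_on + 1) * updates[tgt] + u_on
    return ControlledNetwork(cnet.base, registry, updates, space)


def add_controls(
    net: BooleanNetwork,
    edges: Iterable[tuple[str, str]] = (),
    nodes: Iterable[str] = (),
    modes: Mapping[str, Iterable[str]] | None = None,
) -> ControlledNetwork:
    """Convenience: edge controls then node controls (order is immaterial up
    to registry ordering)."""
    cnet = _as_controlled(net)
    edges = list(edges)
    nodes = list(nodes)
    if edges:
        cnet = add_edge_controls(cnet, edges)
    if nodes:
        cnet = add_node_controls(cnet, nodes, modes)
    return cnet


def specialize(
    cnet: ControlledNetwork, policy: ControlPolicy | Mapping[str, int] | None = None
) -> BooleanNetwork:
    """Substitute a policy's bits (unset controls read 0) into every update,
    yielding an ordinary Boolean network over the state variables alone.

    The empty policy returns the base network.
    """
    if policy is None:
        policy = ControlPolicy()
    if not isinstance(policy, ControlPolicy):
        policy = ControlPolicy(policy)
    known = set(cnet.control_names)
    stray = set(policy.values) - known
    if stray:
        raise KeyError(f"unknown control variables: {sorted(stray)}")
    assignment = {c: policy[c] for c in cnet.control_names}
    base_space = cnet.base.space
    updates = [u.restrict(assignment).rename(base_space) for u in cnet.updates]
    return BooleanNetwork(base_space, updates)
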