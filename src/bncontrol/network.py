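"""Boolean networks: rule-file parsing, logic-to-polynomial conversion,
synchronous dynamics and the wiring diagram.

A Boolean network is a map F = (f_1, ..., f_n) : {0,1}^n -> {0,1}^n whose
coordinate functions update all nodes simultaneously.  Internally every
update rule is stored in canonical ANF (see :mod:`bncontrol.algebra`), which
makes functional dependence a purely syntactic property: x_j -> x_i is a
wiring-diagram edge exactly when x_j occurs in the ANF of f_i.

States are bitstrings with x_1 leftmost: the state written 01001 assigns
x_1=0, x_2=1, x_3=0, x_4=0, x_5=1.
"""

from __future__ import annotations

import re
from collections.abc import Sequence
from dataclasses import dataclass

import networkx as nx

from .algebra import (
    BooleanPolynomial,
    PolynomialSystem,
    VariableSpace,
    format_anf,
    parse_anf,
    solve_system,
)

__all__ = [
    "BooleanNetwork",
    "WiringDiagram",
    "NetworkSyntaxError",
    "parse_network",
    "write_network",
    "boolean_to_polynomial",
    "step",
    "steady_state_system",
    "fixed_points",
    "wiring_diagram",
    "state_from_string",
    "state_to_string",
]

# Exhaustive state enumeration refuses above this size rather than sampling.
ENUMERATION_LIMIT = 22

State = tuple[int, ...]


def state_from_string(bits: str) -> State:
    if not re.fullmatch(r"[01]+", bits):
        raise ValueError(f"malformed state bitstring {bits!r}")
    return tuple(int(b) for b in bits)


def state_to_string(state: Sequence[int]) -> str:
    return "".join(str(b & 1) for b in state)


class BooleanNetwork:
    """Ordered variables x_1..x_n with one update polynomial per variable."""

    def __init__(self, space: VariableSpace, updates: Sequence[BooleanPolynomial]):
        if len(updates) != len(space):
            raise ValueError("need exactly one update polynomial per variable")
        for u in updates:
            if u.space != space:
                raise ValueError("update polynomial not over the network's space")
        self.space = space
        self.updates = tuple(updates)

    @property
    def n(self) -> int:
        return len(self.space)

    def update(self, name: str) -> BooleanPolynomial:
        return self.updates[self.space.index(name)]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BooleanNetwork)
            and self.space == other.space
            and self.updates == other.updates
        )

    def __hash__(self):
        return hash((self.space, self.updates))

    def __repr__(self):
        return f"<BooleanNetwork n={self.n} vars={list(self.space.names)}>"


@dataclass(frozen=True)
class WiringDiagram:
    """Directed graph with an edge x_j -> x_i when f_i depends on x_j."""

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(sorted(self.edges))
        return g


# ---------------------------------------------------------------------------
# Logic expressions and conversion to ANF
# ---------------------------------------------------------------------------
# Expression trees are nested tuples: ("var", name), ("const", bit),
# ("not", e), ("and", a, b), ("or", a, b).

def boolean_to_polynomial(expr: tuple, space: VariableSpace) -> BooleanPolynomial:
    """Convert an AND/OR/NOT expression tree to canonical ANF.

    Uses the GF(2) rewrites a AND b = ab, a OR b = a+b+ab, NOT a = 1+a.
    """
    op = expr[0]
    if op == "var":
        return space.var(expr[1])
    if op == "const":
        return space.const(expr[1])
    if op == "not":
        return 1 + boolean_to_polynomial(expr[1], space)
    a = boolean_to_polynomial(expr[1], space)
    b = boolean_to_polynomial(expr[2], space)
    if op == "and":
        return a * b
    if op == "or":
        return a + b + a * b
    raise ValueError(f"unknown operator {op!r}")


class NetworkSyntaxError(ValueError):
    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


_TOKEN = re.compile(r"\s*(?:(!|&|\||\(|\)|[01](?![\w]))|([A-Za-z_]\w*))")


def _parse_bool_expr(text: str, line: int) -> tuple:
    """Recursive-descent parser for !, &, | with ! tightest, | loosest."""
    tokens: list[str] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or m.end() == pos:
            if text[pos:].strip():
                raise NetworkSyntaxError(f"unexpected character {text[pos]!r}", line)
            break
        tokens.append(m.group(1) or m.group(2))
        pos = m.end()
    i = 0

    def peek():
        return tokens[i] if i < len(tokens) else None

    def expect(tok):
        nonlocal i
        if peek() != tok:
            raise NetworkSyntaxError(f"expected {tok!r}, found {peek()!r}", line)
        i += 1

    def atom():
        nonlocal i
        t = peek()
        if t is None:
            raise NetworkSyntaxError("unexpected end of expression", line)
        if t == "(":
            i += 1
            e = disj()
            expect(")")
            return e
        if t == "!":
            i += 1
            return ("not", atom())
        if t in ("0", "1"):
            i += 1
            return ("const", int(t))
        if re.fullmatch(r"[A-Za-z_]\w*", t):
            i += 1
            return ("var", t)
        raise NetworkSyntaxError(f"unexpected token {t!r}", line)

    def conj():
        e = atom()
        while peek() == "&":
            expect("&")
            e = ("and", e, atom())
        return e

    def disj():
        e = conj()
        while peek() == "|":
            expect("|")
            e = ("or", e, conj())
        return e

    result = disj()
    if peek() is not None:
        raise NetworkSyntaxError(f"trailing input from token {peek()!r}", line)
    return result


def _rule_lines(text: str):
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if lineno == 1 and re.fullmatch(r"targets\s*,\s*factors", line, re.I):
            continue
        yield lineno, line


def parse_network(text: str, dialect: str = "bnet") -> BooleanNetwork:
    """Parse a rule file, one ``target, expression`` line per node.

    ``bnet`` rules use the BoolNet-style operators ``!``, ``&``, ``|`` with
    parentheses; ``anf`` rules use the ANF text format (terms joined by
    ``+``, variables by ``*``).  Variables are ordered by first appearance
    as a rule target.
    """
    if dialect not in ("bnet", "anf"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rules: list[tuple[int, str, str]] = []
    seen: dict[str, int] = {}
    for lineno, line in _rule_lines(text):
        if "," not in line:
            raise NetworkSyntaxError("expected 'target, expression'", lineno)
        target, expr = line.split(",", 1)
        target = target.strip()
        if not re.fullmatch(r"[A-Za-z_]\w*", target):
            raise NetworkSyntaxError(f"invalid target name {target!r}", lineno)
        if target in seen:
            raise NetworkSyntaxError(f"duplicate target {target!r}", lineno)
        seen[target] = lineno
        rules.append((lineno, target, expr.strip()))
    if not rules:
        raise ValueError("no rules found")
    space = VariableSpace([t for _, t, _ in rules])
    updates = []
    for lineno, target, expr in rules:
        if dialect == "bnet":
            tree = _parse_bool_expr(expr, lineno)
            for v in _tree_vars(tree):
                if v not in space:
                    raise NetworkSyntaxError(f"unknown variable {v!r}", lineno)
            updates.append(boolean_to_polynomial(tree, space))
        else:
            try:
                updates.append(parse_anf(expr, space))
            except (KeyError, ValueError) as exc:
                raise NetworkSyntaxError(str(exc), lineno) from exc
    return BooleanNetwork(space, updates)


def _tree_vars(tree: tuple) -> set[str]:
    if tree[0] == "var":
        return {tree[1]}
    if tree[0] == "const":
        return set()
    out: set[str] = set()
    for child in tree[1:]:
        out |= _tree_vars(child)
    return out


def _poly_to_bool_text(poly: BooleanPolynomial) -> str:
    """Render a polynomial as a !/&/| expression via its truth table (DNF)."""
    c = poly.constant_value()
    if c is not None:
        return str(c)
    vs = sorted(poly.variables(), key=poly.space.index)
    clauses = []
    for bits in _all_bits(len(vs)):
        if poly.evaluate(dict(zip(vs, bits))):
            lits = [v if b else f"!{v}" for v, b in zip(vs, bits)]
            clauses.append(" & ".join(lits) if len(lits) > 1 else lits[0])
    if not clauses:
        return "0"
    if len(clauses) == 1:
        return clauses[0]
    return " | ".join(f"({cl})" if "&" in cl else cl for cl in clauses)


def _all_bits(k: int):
    for i in range(1 << k):
        yield tuple((i >> (k - 1 - j)) & 1 for j in range(k))


def write_network(net: BooleanNetwork, dialect: str = "bnet") -> str:
    """Serialize a network; ``parse_network(write_network(net))`` round-trips."""
    lines = ["targets, factors"]
    for name, update in zip(net.space.names, net.updates):
        if dialect == "anf":
            lines.append(f"{name}, {format_anf(update)}")
        elif dialect == "bnet":
            lines.append(f"{name}, {_poly_to_bool_text(update)}")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------

def step(net: BooleanNetwork, state: Sequence[int] | str) -> State:
    """One synchronous update: bit i of the result is f_i evaluated at state."""
    if isinstance(state, str):
        state = state_from_string(state)
    if len(state) != net.n:
        raise ValueError(f"state length {len(state)} != network size {net.n}")
    assignment = dict(zip(net.space.names, state))
    return tuple(f.evaluate(assignment) for f in net.updates)


def steady_state_system(net: BooleanNetwork) -> PolynomialSystem:
    """The fixed-point system g_i = f_i + x_i = 0 (subtraction is addition
    in GF(2)); its {0,1} solutions are exactly the network's steady states."""
    gens = [f + net.space.var(name) for name, f in zip(net.space.names, net.updates)]
    return PolynomialSystem(net.space, gens)


def fixed_points(net: BooleanNetwork, method: str = "auto") -> list[State]:
    """All states s with F(s) = s, sorted as bitstrings.

    ``algebra`` solves the steady-state polynomial system; ``enumerate``
    checks all 2^n states (n <= 22); the two agree.
    """
    if method == "auto":
        method = "enumerate" if net.n <= ENUMERATION_LIMIT else "algebra"
    if method == "enumerate":
        if net.n > ENUMERATION_LIMIT:
            raise ValueError(f"n={net.n} too large for exhaustive enumeration")
        from .dynamics import transition_map  # local import to avoid cycle

        tm = transition_map(net)
        fixed = [int(s) for s in tm.fixed_state_indices()]
        return [tuple((s >> (net.n - 1 - i)) & 1 for i in range(net.n)) for s in fixed]
    if method == "algebra":
        sols = solve_system(steady_state_system(net))
        states = [tuple(a[v] for v in net.space.names) for a in sols]
        return sorted(states)
    raise ValueError(f"unknown method {method!r}")


def wiring_diagram(net: BooleanNetwork) -> WiringDiagram:
    """Edges from ANF variable occurrence; because ANF is canonical this is
    exactly functional dependence.  Self-loops are reported as-is."""
    edges = set()
    for name, f in zip(net.space.names, net.updates):
        for v in f.variables():
            edges.add((v, name))
    return WiringDiagram(tuple(net.space.names), frozenset(edges))
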