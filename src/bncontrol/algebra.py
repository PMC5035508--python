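"""Exact polynomial algebra over the Boolean quotient ring F2[x1..xn]/(xi^2+xi).

Every Boolean function has a unique multilinear XOR-of-AND representation
(algebraic normal form, ANF); this module implements arithmetic on that
canonical form together with Groebner bases, solving, counting and
elimination for systems of polynomial equations ``g = 0`` over {0,1}.

Arithmetic is performed directly in the quotient ring: products are reduced
multilinearly (``x*x = x``) and coefficients live in GF(2), so duplicate
monomials cancel pairwise.  Ideals therefore never need the field equations
``xi^2 + xi`` appended explicitly; the Buchberger loop accounts for them
through extra S-polynomial tasks (see :func:`groebner_basis`).
"""

from __future__ import annotations

import itertools
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np

__all__ = [
    "VariableSpace",
    "BooleanPolynomial",
    "PolynomialSystem",
    "MonomialOrder",
    "GroebnerBasis",
    "parse_anf",
    "groebner_basis",
    "solve_system",
    "count_solutions",
    "eliminate",
    "occurring_variables",
]

# Exhaustive enumeration is used for components with at most this many
# variables (2^22 ~ 4M assignments, vectorized); larger components fall back
# to a splitting search with constant propagation.
BRUTE_FORCE_THRESHOLD = 22


class VariableSpace:
    """An ordered list of distinct variable names with per-variable roles.

    The declared order is fixed for the lifetime of every polynomial built
    over the space; it fixes bitstring conventions, display order and the
    default monomial order.  Roles distinguish ``state`` from ``control``
    variables.
    """

    __slots__ = ("names", "roles", "_index")

    def __init__(self, names: Sequence[str], roles: Mapping[str, str] | None = None):
        names = tuple(names)
        if len(set(names)) != len(names):
            raise ValueError("variable names must be unique")
        self.names = names
        self.roles = {n: (roles or {}).get(n, "state") for n in names}
        self._index = {n: i for i, n in enumerate(names)}

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown variable {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __len__(self) -> int:
        return len(self.names)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, VariableSpace)
            and self.names == other.names
            and self.roles == other.roles
        )

    def __hash__(self) -> int:
        return hash(self.names)

    def __repr__(self) -> str:
        return f"VariableSpace({list(self.names)!r})"

    def state_variables(self) -> tuple[str, ...]:
        return tuple(n for n in self.names if self.roles[n] == "state")

    def control_variables(self) -> tuple[str, ...]:
        return tuple(n for n in self.names if self.roles[n] == "control")

    # -- polynomial constructors ------------------------------------------
    def zero(self) -> "BooleanPolynomial":
        return BooleanPolynomial(self, frozenset())

    def one(self) -> "BooleanPolynomial":
        return BooleanPolynomial(self, frozenset({frozenset()}))

    def const(self, bit: int) -> "BooleanPolynomial":
        return self.one() if bit & 1 else self.zero()

    def var(self, name: str) -> "BooleanPolynomial":
        self.index(name)
        return BooleanPolynomial(self, frozenset({frozenset({name})}))


class BooleanPolynomial:
    """A multilinear polynomial over GF(2) in canonical ANF.

    ``terms`` is a frozenset of monomials, each a frozenset of variable
    names; the empty monomial is the constant 1 and the empty term set is
    the zero polynomial.  Two polynomials represent the same Boolean
    function iff their term sets are equal.
    """

    __slots__ = ("space", "terms")

    def __init__(self, space: VariableSpace, terms: Iterable[Iterable[str]]):
        fterms = frozenset(frozenset(t) for t in terms)
        for t in fterms:
            for v in t:
                if v not in space:
                    raise KeyError(f"variable {v!r} not in space")
        self.space = space
        self.terms = fterms

    # -- ring operations --------------------------------------------------
    def __add__(self, other: "BooleanPolynomial | int") -> "BooleanPolynomial":
        other = self._coerce(other)
        self._check(other)
        return BooleanPolynomial(self.space, self.terms ^ other.terms)

    __radd__ = __add__
    __sub__ = __add__  # characteristic 2

    def __mul__(self, other: "BooleanPolynomial | int") -> "BooleanPolynomial":
        other = self._coerce(other)
        self._check(other)
        acc: set[frozenset] = set()
        for a in self.terms:
            for b in other.terms:
                m = a | b  # idempotent: x*x = x
                if m in acc:
                    acc.discard(m)  # mod-2 cancellation
                else:
                    acc.add(m)
        return BooleanPolynomial(self.space, acc)

    __rmul__ = __mul__

    def _coerce(self, other):
        if isinstance(other, int):
            return self.space.const(other)
        return other

    def _check(self, other: "BooleanPolynomial"):
        if self.space is not other.space and self.space != other.space:
            raise ValueError("polynomials live in different variable spaces")

    # -- queries -----------------------------------------------------------
    def variables(self) -> frozenset[str]:
        out: set[str] = set()
        for t in self.terms:
            out |= t
        return frozenset(out)

    def is_zero(self) -> bool:
        return not self.terms

    def is_one(self) -> bool:
        return self.terms == frozenset({frozenset()})

    def constant_value(self) -> int | None:
        """The bit this polynomial is, if it is constant, else None."""
        if self.is_zero():
            return 0
        if self.is_one():
            return 1
        return None

    def evaluate(self, assignment: Mapping[str, int]) -> int:
        """Evaluate at a total 0/1 assignment of this polynomial's variables."""
        acc = 0
        for t in self.terms:
            prod = 1
            for v in t:
                try:
                    prod &= assignment[v] & 1
                except KeyError:
                    raise KeyError(f"variable {v!r} is unassigned") from None
                if not prod:
                    break
            acc ^= prod
        return acc

    def restrict(self, assignment: Mapping[str, int]) -> "BooleanPolynomial":
        """Substitute constants for a subset of variables (partial evaluation)."""
        acc: set[frozenset] = set()
        for t in self.terms:
            keep = []
            dead = False
            for v in t:
                if v in assignment:
                    if not assignment[v] & 1:
                        dead = True
                        break
                else:
                    keep.append(v)
            if dead:
                continue
            m = frozenset(keep)
            if m in acc:
                acc.discard(m)
            else:
                acc.add(m)
        return BooleanPolynomial(self.space, acc)

    def substitute(self, var: str, replacement: "BooleanPolynomial") -> "BooleanPolynomial":
        """Replace every occurrence of ``var`` by ``replacement`` and re-canonicalize.

        Substituting a variable that does not occur is the identity.
        """
        self._check(replacement)
        result = self.space.zero()
        for t in self.terms:
            factor = BooleanPolynomial(self.space, [frozenset(t - {var})])
            if var in t:
                factor = factor * replacement
            result = result + factor
        return result

    def rename(self, space: VariableSpace, mapping: Mapping[str, str] | None = None) -> "BooleanPolynomial":
        """Re-home this polynomial in another space, optionally renaming variables."""
        mapping = mapping or {}
        return BooleanPolynomial(
            space, [frozenset(mapping.get(v, v) for v in t) for t in self.terms]
        )

    # -- dunder plumbing ---------------------------------------------------
    def __eq__(self, other) -> bool:
        if isinstance(other, int):
            return self.constant_value() == other
        return (
            isinstance(other, BooleanPolynomial)
            and self.space == other.space
            and self.terms == other.terms
        )

    def __hash__(self) -> int:
        return hash(self.terms)

    def __str__(self) -> str:
        return format_anf(self)

    def __repr__(self) -> str:
        return f"<BooleanPolynomial {format_anf(self)}>"


# ---------------------------------------------------------------------------
# ANF text format: terms joined by "+", variables joined by "*", constant "1".
# ---------------------------------------------------------------------------

def parse_anf(text: str, space: VariableSpace) -> BooleanPolynomial:
    """Parse ANF text like ``"1 + x3 + x5 + x3*x5"`` (whitespace-insensitive)."""
    text = text.strip()
    if not text:
        raise ValueError("empty ANF expression")
    acc: set[frozenset] = set()
    for raw in text.split("+"):
        token = raw.strip()
        if not token:
            raise ValueError(f"malformed ANF term in {text!r}")
        if token == "0":
            continue
        if token == "1":
            mono: frozenset[str] = frozenset()
        else:
            vs = [v.strip() for v in token.split("*")]
            for v in vs:
                if not v:
                    raise ValueError(f"malformed ANF term {token!r}")
                space.index(v)
            mono = frozenset(vs)
        if mono in acc:
            acc.discard(mono)
        else:
            acc.add(mono)
    return BooleanPolynomial(space, acc)


def format_anf(poly: BooleanPolynomial) -> str:
    if poly.is_zero():
        return "0"
    idx = poly.space.index
    keyed = sorted(
        (tuple(sorted(idx(v) for v in t)) for t in poly.terms),
        key=lambda k: (len(k), k),
    )
    parts = []
    for k in keyed:
        if not k:
            parts.append("1")
        else:
            parts.append("*".join(poly.space.names[i] for i in k))
    return " + ".join(parts)


# ---------------------------------------------------------------------------
# Systems and monomial orders
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PolynomialSystem:
    """A finite set of polynomials read as simultaneous ``g = 0`` constraints."""

    space: VariableSpace
    generators: tuple[BooleanPolynomial, ...]

    def __init__(self, space: VariableSpace, generators: Iterable[BooleanPolynomial]):
        gens = tuple(generators)
        for g in gens:
            if g.space != space:
                raise ValueError("generator not over the system's variable space")
        object.__setattr__(self, "space", space)
        object.__setattr__(self, "generators", gens)

    def __iter__(self):
        return iter(self.generators)

    def __len__(self):
        return len(self.generators)


@dataclass(frozen=True)
class MonomialOrder:
    """lex or graded-reverse-lex, optionally with an eliminate-first block.

    With ``first_block`` set, the order ranks the block's variables above all
    others (each block internally in declared-space order) and compares
    lexicographically, which is an elimination order for the block.
    """

    kind: str = "grevlex"
    first_block: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.kind not in ("lex", "grevlex"):
            raise ValueError(f"unknown order kind {self.kind!r}")
        if self.first_block is not None:
            object.__setattr__(self, "first_block", tuple(self.first_block))

    def ranking(self, space: VariableSpace) -> list[str]:
        """Variable names from most to least significant."""
        if self.first_block is None:
            return list(space.names)
        block = set(self.first_block)
        for v in block:
            space.index(v)
        first = [n for n in space.names if n in block]
        rest = [n for n in space.names if n not in block]
        return first + rest


@dataclass(frozen=True)
class GroebnerBasis:
    order: MonomialOrder
    polys: tuple[BooleanPolynomial, ...]

    def __iter__(self):
        return iter(self.polys)

    def __len__(self):
        return len(self.polys)

    def is_inconsistent(self) -> bool:
        """True iff the basis is {1}: the system has no {0,1} solution."""
        return len(self.polys) == 1 and self.polys[0].is_one()


# ---------------------------------------------------------------------------
# Buchberger in the Boolean quotient ring, on integer bitmask monomials.
# ---------------------------------------------------------------------------

def _mask_key_fns(kind: str, nbits: int):
    if kind == "lex":
        def key(m: int) -> tuple:
            return (m,)
    else:  # grevlex: higher total degree wins; ties go to the monomial whose
        # reversed bit pattern is smaller (last differing variable absent).
        def key(m: int) -> tuple:
            rev = int(format(m, f"0{nbits}b")[::-1], 2) if m else 0
            return (m.bit_count(), -rev)
    return key


def _mono_mul_poly(mono: int, terms: frozenset[int]) -> frozenset[int]:
    """Idempotent monomial-times-polynomial with mod-2 collection."""
    acc: set[int] = set()
    for t in terms:
        m = mono | t
        if m in acc:
            acc.discard(m)
        else:
            acc.add(m)
    return frozenset(acc)


def _normal_form(terms: frozenset[int], basis: list[tuple[int, frozenset[int]]], key) -> frozenset[int]:
    """Fully reduce ``terms`` by ``basis`` (list of (leading monomial, terms))."""
    work = set(terms)
    progress = True
    while progress:
        progress = False
        for t in sorted(work, key=key, reverse=True):
            for lm, g in basis:
                if t & lm == lm:
                    q = t & ~lm
                    work ^= set(_mono_mul_poly(q, g))
                    progress = True
                    break
            if progress:
                break
    return frozenset(work)


def _buchberger(gens: list[frozenset[int]], key) -> list[frozenset[int]]:
    basis: list[tuple[int, frozenset[int]]] = []

    def lead(terms: frozenset[int]) -> int:
        return max(terms, key=key)

    def push(terms: frozenset[int]) -> int | None:
        nf = _normal_form(terms, basis, key)
        if not nf:
            return None
        basis.append((lead(nf), nf))
        return len(basis) - 1

    pending: list[tuple] = []
    for g in gens:
        i = push(g)
        if i is None:
            continue
        for j in range(i):
            pending.append(("pair", j, i))
        pending.append(("field", i))

    while pending:
        task = pending.pop()
        if task[0] == "pair":
            _, a, b = task
            lma, fa = basis[a]
            lmb, fb = basis[b]
            lcm = lma | lmb
            s = set(_mono_mul_poly(lcm & ~lma, fa))
            s ^= set(_mono_mul_poly(lcm & ~lmb, fb))
            snew = frozenset(s)
        else:
            # S-polynomials against the implicit field equations x^2+x: for
            # each variable dividing the leading monomial, the multilinear
            # normal form of S(f, x^2+x) is x*f computed idempotently.
            _, a = task
            lma, fa = basis[a]
            snew = None
            m = lma
            while m:
                bit = m & -m
                m ^= bit
                cand = _mono_mul_poly(bit, fa)
                i = push(cand)
                if i is not None:
                    for j in range(i):
                        pending.append(("pair", j, i))
                    pending.append(("field", i))
            continue
        i = push(snew)
        if i is not None:
            for j in range(i):
                pending.append(("pair", j, i))
            pending.append(("field", i))

    # minimalize: drop members whose leading monomial is divisible by another's
    keep = []
    lms = [lm for lm, _ in basis]
    for i, (lm, f) in enumerate(basis):
        divisible = any(
            j != i and lms[j] & lm == lms[j] and (lms[j] != lm or j < i)
            for j in range(len(basis))
        )
        if not divisible:
            keep.append((lm, f))
    # interreduce tails for the unique reduced basis
    changed = True
    while changed:
        changed = False
        for i in range(len(keep)):
            lm, f = keep[i]
            others = keep[:i] + keep[i + 1 :]
            nf = _normal_form(f, others, key)
            if nf != f:
                keep[i] = (lm, nf)
                changed = True
    keep.sort(key=lambda p: key(p[0]), reverse=True)
    return [f for _, f in keep]


def _to_masks(poly: BooleanPolynomial, bit_of: Mapping[str, int]) -> frozenset[int]:
    out: set[int] = set()
    for t in poly.terms:
        m = 0
        for v in t:
            m |= 1 << bit_of[v]
        out.add(m)
    return frozenset(out)


def _from_masks(terms: frozenset[int], names_by_bit: Mapping[int, str], space: VariableSpace) -> BooleanPolynomial:
    monos = []
    for m in terms:
        vs = []
        b = m
        while b:
            bit = b & -b
            b ^= bit
            vs.append(names_by_bit[bit.bit_length() - 1])
        monos.append(frozenset(vs))
    return BooleanPolynomial(space, monos)


def groebner_basis(system: PolynomialSystem, order: MonomialOrder | None = None) -> GroebnerBasis:
    """Reduced Groebner basis of the ideal of ``system`` in the Boolean ring.

    The basis generates the same {0,1} solution set as the input system; an
    inconsistent system yields the basis {1}.  The reduced basis is unique
    given the order, so recomputation from permuted generators returns the
    same polynomials.
    """
    if len(system.space) == 0:
        raise ValueError("empty variable space")
    order = order or MonomialOrder("grevlex")
    ranking = order.ranking(system.space)
    L = len(ranking)
    # earlier (more significant) variable <-> higher bit
    bit_of = {name: L - 1 - i for i, name in enumerate(ranking)}
    names_by_bit = {b: n for n, b in bit_of.items()}
    key = _mask_key_fns(order.kind, L)
    gens = [_to_masks(g, bit_of) for g in system.generators if not g.is_zero()]
    reduced = _buchberger(gens, key)
    polys = tuple(_from_masks(f, names_by_bit, system.space) for f in reduced)
    return GroebnerBasis(order, polys)


# ---------------------------------------------------------------------------
# Solving and counting
# ---------------------------------------------------------------------------

def occurring_variables(system: PolynomialSystem) -> tuple[str, ...]:
    """Variables that occur in at least one generator, in declared order."""
    used: set[str] = set()
    for g in system.generators:
        used |= g.variables()
    return tuple(n for n in system.space.names if n in used)


def _components(generators: Sequence[BooleanPolynomial]):
    """Partition generators into connected components by shared variables."""
    gen_vars = [g.variables() for g in generators]
    unseen = set(range(len(generators)))
    comps = []
    while unseen:
        stack = [unseen.pop()]
        members = {stack[0]}
        vars_acc = set(gen_vars[stack[0]])
        changed = True
        while changed:
            changed = False
            for j in list(unseen):
                if gen_vars[j] & vars_acc:
                    unseen.discard(j)
                    members.add(j)
                    vars_acc |= gen_vars[j]
                    changed = True
        comps.append((sorted(members), vars_acc))
    return comps


def _enumerate_component(gens: Sequence[BooleanPolynomial], varlist: Sequence[str]) -> list[tuple[int, ...]]:
    """All satisfying assignments of a small component, vectorized.

    Returns bit tuples aligned with ``varlist``.
    """
    k = len(varlist)
    n = 1 << k
    idx = np.arange(n, dtype=np.uint32)
    cols = {
        v: ((idx >> np.uint32(k - 1 - i)) & 1).astype(bool)
        for i, v in enumerate(varlist)
    }
    ok = np.ones(n, dtype=bool)
    for g in gens:
        val = np.zeros(n, dtype=bool)
        for term in g.terms:
            prod = np.ones(n, dtype=bool)
            for v in term:
                prod &= cols[v]
            val ^= prod
        ok &= ~val
        if not ok.any():
            return []
    sats = np.flatnonzero(ok)
    return [tuple((int(s) >> (k - 1 - i)) & 1 for i in range(k)) for s in sats]


def _split_count(gens: list[BooleanPolynomial], varlist: list[str]) -> int:
    """Count satisfying assignments by variable splitting with propagation."""
    live: list[BooleanPolynomial] = []
    for g in gens:
        c = g.constant_value()
        if c == 1:
            return 0
        if c == 0:
            continue
        live.append(g)
    used: set[str] = set()
    for g in live:
        used |= g.variables()
    free = [v for v in varlist if v not in used]
    active = [v for v in varlist if v in used]
    if not live:
        return 1 << len(varlist)
    if len(active) <= BRUTE_FORCE_THRESHOLD:
        return len(_enumerate_component(live, active)) << len(free)
    # split on the variable occurring in the most generators
    counts = {v: 0 for v in active}
    for g in live:
        for v in g.variables():
            counts[v] += 1
    pivot = max(active, key=lambda v: (counts[v], -varlist.index(v)))
    rest = [v for v in active if v != pivot]
    total = 0
    for b in (0, 1):
        sub = [g.restrict({pivot: b}) for g in live]
        total += _split_count(sub, rest)
    return total << len(free)


def _split_solve(gens: list[BooleanPolynomial], varlist: list[str]) -> list[tuple[int, ...]]:
    live = [g for g in gens if g.constant_value() != 0]
    if any(g.constant_value() == 1 for g in live):
        return []
    if len(varlist) <= BRUTE_FORCE_THRESHOLD:
        return _enumerate_component(live, varlist)
    pivot = varlist[0]
    rest = varlist[1:]
    out = []
    for b in (0, 1):
        sub = [g.restrict({pivot: b}) for g in live]
        for tail in _split_solve(sub, rest):
            out.append((b,) + tail)
    return out


def _check_over(system: PolynomialSystem, over: Iterable[str] | None) -> list[str]:
    if over is None:
        overlist = list(system.space.names)
    else:
        overlist = [n for n in system.space.names if n in set(over)]
        extra = set(over) - set(system.space.names)
        if extra:
            raise KeyError(f"variables not in space: {sorted(extra)}")
    allowed = set(overlist)
    for g in system.generators:
        stray = g.variables() - allowed
        if stray:
            raise ValueError(
                f"generator mentions variables outside 'over': {sorted(stray)}"
            )
    return overlist


def count_solutions(system: PolynomialSystem, over: Iterable[str] | None = None) -> int:
    """Number of assignments of ``over`` at which every generator vanishes.

    Decomposes the system into variable-sharing components, counts each by
    exhaustive (vectorized) enumeration or splitting, and multiplies, with a
    factor 2 per unconstrained variable.
    """
    overlist = _check_over(system, over)
    gens = [g for g in system.generators if not g.is_zero()]
    if any(g.is_one() for g in gens):
        return 0
    if not gens:
        return 1 << len(overlist)
    comps = _components(gens)
    used: set[str] = set()
    total = 1
    for members, vars_acc in comps:
        varlist = [v for v in overlist if v in vars_acc]
        used |= vars_acc
        sub = [gens[i] for i in members]
        if len(varlist) <= BRUTE_FORCE_THRESHOLD:
            total *= len(_enumerate_component(sub, varlist))
        else:
            total *= _split_count(sub, varlist)
        if total == 0:
            return 0
    free = len([v for v in overlist if v not in used])
    return total << free


def solve_system(
    system: PolynomialSystem,
    over: Iterable[str] | None = None,
    max_solutions: int = 1 << 20,
) -> list[dict[str, int]]:
    """All assignments of ``over`` at which every generator vanishes.

    Exhaustive per-component enumeration below :data:`BRUTE_FORCE_THRESHOLD`
    variables, splitting search above; the two agree (tested).  Raises if the
    solution set would exceed ``max_solutions``.
    """
    overlist = _check_over(system, over)
    n_sol = count_solutions(system, overlist)
    if n_sol > max_solutions:
        raise ValueError(f"{n_sol} solutions exceed max_solutions={max_solutions}")
    gens = [g for g in system.generators if not g.is_zero()]
    if any(g.is_one() for g in gens):
        return []
    comps = _components(gens) if gens else []
    per_comp: list[tuple[list[str], list[tuple[int, ...]]]] = []
    used: set[str] = set()
    for members, vars_acc in comps:
        varlist = [v for v in overlist if v in vars_acc]
        used |= vars_acc
        sub = [gens[i] for i in members]
        if len(varlist) <= BRUTE_FORCE_THRESHOLD:
            sols = _enumerate_component(sub, varlist)
        else:
            sols = _split_solve(sub, varlist)
        per_comp.append((varlist, sols))
    free = [v for v in overlist if v not in used]
    per_comp.append((free, list(itertools.product((0, 1), repeat=len(free)))))
    out: list[dict[str, int]] = []
    for combo in itertools.product(*(sols for _, sols in per_comp)):
        a: dict[str, int] = {}
        for (varlist, _), bits in zip(per_comp, combo):
            a.update(zip(varlist, bits))
        out.append(a)
    out.sort(key=lambda a: tuple(a[v] for v in overlist))
    return out


def eliminate(system: PolynomialSystem, keep: Iterable[str]) -> PolynomialSystem:
    """Generators of the elimination ideal onto the ``keep`` variables.

    Computes a Groebner basis under a lex block order that eliminates the
    complement of ``keep`` first and returns the members containing only kept
    variables.  An assignment of the kept variables extends to a full
    solution of ``system`` iff it solves the returned system.
    """
    keepset = set(keep)
    for v in keepset:
        system.space.index(v)
    drop = tuple(n for n in system.space.names if n not in keepset)
    if not drop:
        gb = groebner_basis(system, MonomialOrder("lex"))
        return PolynomialSystem(system.space, tuple(gb))
    order = MonomialOrder("lex", first_block=drop)
    gb = groebner_basis(system, order)
    kept = tuple(g for g in gb if g.variables() <= keepset)
    return PolynomialSystem(system.space, kept)
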