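"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the code paths they check: solution sets are
recomputed by plain per-assignment evaluation, Boolean functions by direct
recursion on expression trees, functional dependence by bit-flipping.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from bncontrol import (
    GeneratorSpec,
    PolynomialSystem,
    VariableSpace,
    random_network,
    tlgl_network,
    toy_network,
)


@pytest.fixture(scope="session")
def toy():
    return toy_network()


@pytest.fixture(scope="session")
def tlgl():
    return tlgl_network()


def random_nets(count, n, k, seed0=0):
    return [random_network(GeneratorSpec(n=n, k=k, seed=seed0 + i)) for i in range(count)]


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def brute_solutions(generators, varlist):
    """{0,1} solution set of g=0 constraints by plain enumeration."""
    sols = set()
    for bits in itertools.product((0, 1), repeat=len(varlist)):
        a = dict(zip(varlist, bits))
        if all(g.evaluate(a) == 0 for g in generators):
            sols.add(bits)
    return sols


def eval_tree(tree, assignment):
    """Evaluate a logic expression tree directly (independent of ANF)."""
    op = tree[0]
    if op == "var":
        return assignment[tree[1]] & 1
    if op == "const":
        return tree[1] & 1
    if op == "not":
        return 1 - eval_tree(tree[1], assignment)
    a, b = eval_tree(tree[1], assignment), eval_tree(tree[2], assignment)
    return (a & b) if op == "and" else (a | b)


def random_tree(rng: np.random.Generator, names, depth):
    """A random AND/OR/NOT expression tree over the given variables."""
    if depth == 0 or rng.random() < 0.3:
        if rng.random() < 0.1:
            return ("const", int(rng.integers(0, 2)))
        return ("var", names[int(rng.integers(0, len(names)))])
    op = ("and", "or", "not")[int(rng.integers(0, 3))]
    if op == "not":
        return ("not", random_tree(rng, names, depth - 1))
    return (op, random_tree(rng, names, depth - 1), random_tree(rng, names, depth - 1))


def depends_on(net, source, target):
    """True iff flipping ``source`` changes f_target at some state (brute force)."""
    names = net.space.names
    f = net.update(target)
    for bits in itertools.product((0, 1), repeat=len(names)):
        a = dict(zip(names, bits))
        b = dict(a)
        b[source] ^= 1
        if f.evaluate(a) != f.evaluate(b):
            return True
    return False


def random_system(seed, n_vars=6, n_gens=4, max_terms=5):
    """A random polynomial system for Groebner/solver property tests."""
    rng = np.random.default_rng(seed)
    names = tuple(f"v{i}" for i in range(n_vars))
    space = VariableSpace(names)
    gens = []
    for _ in range(n_gens):
        poly = space.zero()
        for _ in range(int(rng.integers(1, max_terms + 1))):
            size = int(rng.integers(0, min(3, n_vars) + 1))
            mono = space.one()
            for i in rng.choice(n_vars, size=size, replace=False):
                mono = mono * space.var(names[int(i)])
            poly = poly + mono
        gens.append(poly)
    return PolynomialSystem(space, gens)
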