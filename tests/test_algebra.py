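"""Polynomial arithmetic, Groebner bases, solving, counting, elimination."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bncontrol import (
    MonomialOrder,
    PolynomialSystem,
    VariableSpace,
    count_solutions,
    eliminate,
    groebner_basis,
    occurring_variables,
    parse_anf,
    solve_system,
    steady_state_system,
)
from bncontrol.algebra import _split_count, format_anf

from conftest import brute_solutions, random_system


@pytest.fixture
def space():
    return VariableSpace(["x1", "x2", "x3", "x4", "x5", "u"])


class TestArithmetic:
    def test_addition_is_xor_of_term_sets(self, space):
        one, x2 = space.one(), space.var("x2")
        assert (one + x2) + x2 == one  # characteristic-2 cancellation
        f1 = parse_anf("1 + x3 + x5 + x3*x5", space)
        assert f1 + space.var("x1") == parse_anf("1 + x1 + x3 + x5 + x3*x5", space)

    def test_zero_is_additive_identity_for_random_polys(self, space):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = _random_poly(rng, space)
            assert p + space.zero() == p
            assert p + p == space.zero()

    def test_product_distributes_with_idempotent_reduction(self, space):
        x3, x5, x1, x = space.var("x3"), space.var("x5"), space.var("x1"), space.var("x2")
        assert (1 + x3) * (1 + x5) == parse_anf("1 + x3 + x5 + x3*x5", space)
        assert x1 * x1 == x1
        assert (x + 1) * x == space.zero()  # x^2 = x and char 2

    def test_evaluation(self, space):
        p = parse_anf("1 + x1 + x1*x4", space)
        assert p.evaluate({"x1": 0, "x2": 0, "x3": 1, "x4": 0, "x5": 1}) == 1
        assert space.zero().evaluate({}) == 0
        with pytest.raises(KeyError):
            p.evaluate({"x1": 1})

    def test_substitution_matches_edge_control_form(self, space):
        p = parse_anf("1 + x2", space)
        u, x2 = space.var("u"), space.var("x2")
        assert p.substitute("x2", (u + 1) * x2) == parse_anf("1 + x2 + x2*u", space)
        assert p.substitute("x2", x2) == p
        # substituting a variable that does not occur is the identity
        assert p.substitute("x4", space.zero()) == p

    @settings(max_examples=60, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_substitute_then_evaluate_commutes(self, seed):
        rng = np.random.default_rng(seed)
        space = VariableSpace([f"v{i}" for i in range(5)])
        p = _random_poly(rng, space)
        r = _random_poly(rng, space)
        var = f"v{rng.integers(0, 5)}"
        q = p.substitute(var, r)
        for bits in itertools.product((0, 1), repeat=5):
            a = dict(zip(space.names, bits))
            b = dict(a)
            b[var] = r.evaluate(a)
            assert q.evaluate(a) == p.evaluate(b)

    def test_anf_text_round_trip(self, space):
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = _random_poly(rng, space)
            assert parse_anf(format_anf(p), space) == p


def _random_poly(rng, space, max_terms=6):
    n = len(space)
    p = space.zero()
    for _ in range(int(rng.integers(0, max_terms + 1))):
        m = space.one()
        for i in rng.choice(n, size=int(rng.integers(0, min(3, n) + 1)), replace=False):
            m = m * space.var(space.names[int(i)])
        p = p + m
    return p


class TestGroebner:
    def test_toy_steady_state_basis_is_triangular(self, toy):
        gb = groebner_basis(steady_state_system(toy), MonomialOrder("lex"))
        expected = {"x1", "1 + x2", "x3", "x4", "1 + x5"}
        assert {str(p) for p in gb} == expected

    def test_unit_ideal_stays_unit(self):
        space = VariableSpace(["a"])
        gb = groebner_basis(PolynomialSystem(space, [space.one()]))
        assert gb.is_inconsistent()
        # contradictory generators also collapse to {1}
        a = space.var("a")
        gb2 = groebner_basis(PolynomialSystem(space, [a, a + 1]))
        assert gb2.is_inconsistent()

    def test_quotient_ring_ideal_membership(self):
        # <xy+x+y> in the Boolean ring contains x and y (x*(xy+x+y)=x):
        # the basis must expose the single solution x=y=0 triangularly.
        space = VariableSpace(["x", "y"])
        x, y = space.var("x"), space.var("y")
        gb = groebner_basis(PolynomialSystem(space, [x * y + x + y]))
        assert {str(p) for p in gb} == {"x", "y"}

    @pytest.mark.parametrize("seed", range(25))
    def test_solution_set_preserved_on_random_systems(self, seed):
        sys = random_system(seed, n_vars=6, n_gens=4)
        for kind in ("lex", "grevlex"):
            gb = groebner_basis(sys, MonomialOrder(kind))
            assert brute_solutions(gb.polys, sys.space.names) == brute_solutions(
                sys.generators, sys.space.names
            )

    @pytest.mark.parametrize("seed", range(8))
    def test_reduced_basis_is_order_independent(self, seed):
        sys = random_system(seed, n_vars=5, n_gens=4)
        gb = groebner_basis(sys, MonomialOrder("lex"))
        rng = np.random.default_rng(seed)
        perm = list(rng.permutation(len(sys.generators)))
        permuted = PolynomialSystem(sys.space, [sys.generators[i] for i in perm])
        assert groebner_basis(permuted, MonomialOrder("lex")).polys == gb.polys

    @pytest.mark.parametrize("seed", range(10))
    def test_basis_members_lie_in_ideal_sympy_oracle(self, seed):
        """Cross-check against sympy: every member of our reduced basis
        reduces to zero modulo sympy's Groebner basis of the same ideal
        (with the field equations appended); together with the exhaustive
        solution-set check this pins down the ideal exactly."""
        sympy = pytest.importorskip("sympy")
        sys = random_system(seed, n_vars=5, n_gens=3)
        symbols = {n: sympy.Symbol(n) for n in sys.space.names}

        def to_sympy(p):
            expr = sympy.Integer(0)
            for t in p.terms:
                term = sympy.Integer(1)
                for v in t:
                    term *= symbols[v]
                expr += term
            return sympy.Poly(expr, *symbols.values(), modulus=2)

        field = [
            sympy.Poly(s**2 + s, *symbols.values(), modulus=2)
            for s in symbols.values()
        ]
        ref = sympy.groebner(
            [to_sympy(g) for g in sys.generators] + field,
            *symbols.values(), modulus=2, order="lex",
        )
        ours = groebner_basis(sys, MonomialOrder("lex"))
        for p in ours:
            remainder = ref.reduce(to_sympy(p).as_expr())[1]
            assert remainder == 0


class TestSolveCount:
    def test_forced_unique_solution(self):
        space = VariableSpace(["u23", "u45"], roles={"u23": "control", "u45": "control"})
        sys = PolynomialSystem(
            space, [space.var("u23") + 1, space.var("u45") + 1]
        )
        assert solve_system(sys) == [{"u23": 1, "u45": 1}]

    def test_inconsistent_system_has_no_solutions(self):
        space = VariableSpace(["a"])
        assert solve_system(PolynomialSystem(space, [space.one()])) == []

    def test_blocking_product_has_five_solutions(self):
        space = VariableSpace(["u31", "u51", "u34"])
        u31, u51, u34 = (space.var(v) for v in space.names)
        sys = PolynomialSystem(space, [(u31 * u51 + 1) * (u34 + 1)])
        sols = solve_system(sys)
        assert len(sols) == 5
        assert {tuple(s.values()) for s in sols} == brute_solutions(
            sys.generators, space.names
        )

    def test_empty_system_counts_full_cube(self):
        space = VariableSpace(["a", "b", "c"])
        assert count_solutions(PolynomialSystem(space, [])) == 8

    @pytest.mark.parametrize("seed", range(15))
    def test_count_and_solve_match_brute_force(self, seed):
        sys = random_system(seed + 100, n_vars=7, n_gens=4)
        expected = brute_solutions(sys.generators, sys.space.names)
        assert count_solutions(sys) == len(expected)
        got = {tuple(a[v] for v in sys.space.names) for a in solve_system(sys)}
        assert got == expected

    @pytest.mark.parametrize("seed", range(8))
    def test_splitting_search_agrees_with_enumeration(self, seed):
        sys = random_system(seed + 300, n_vars=8, n_gens=4)
        live = [g for g in sys.generators if not g.is_zero()]
        assert _split_count(live, list(sys.space.names)) == count_solutions(sys)

    @pytest.mark.parametrize("seed", range(8))
    def test_counts_partition_by_any_polynomial(self, seed):
        sys = random_system(seed + 200, n_vars=6, n_gens=3)
        rng = np.random.default_rng(seed)
        p = _random_poly(rng, sys.space)
        with_p = PolynomialSystem(sys.space, list(sys.generators) + [p])
        with_np = PolynomialSystem(sys.space, list(sys.generators) + [p + 1])
        assert count_solutions(with_p) + count_solutions(with_np) == count_solutions(sys)

    def test_over_restriction_errors_on_stray_variables(self):
        space = VariableSpace(["a", "b"])
        sys = PolynomialSystem(space, [space.var("a") + space.var("b")])
        with pytest.raises(ValueError):
            solve_system(sys, over=["a"])


class TestEliminate:
    def test_keep_all_is_plain_groebner(self):
        sys = random_system(3, n_vars=5, n_gens=3)
        kept = eliminate(sys, keep=sys.space.names)
        gb = groebner_basis(sys, MonomialOrder("lex"))
        assert set(kept.generators) == set(gb.polys)

    @pytest.mark.parametrize("seed", range(12))
    def test_projection_matches_brute_force(self, seed):
        sys = random_system(seed + 400, n_vars=6, n_gens=4)
        names = sys.space.names
        keep = names[:3]
        proj = eliminate(sys, keep=keep)
        for g in proj.generators:
            assert g.variables() <= set(keep)
        full = brute_solutions(sys.generators, names)
        projected = {bits[:3] for bits in full}
        got = brute_solutions(proj.generators, keep)
        assert got == projected

    def test_occurring_variables_in_declared_order(self):
        space = VariableSpace(["a", "b", "c"])
        sys = PolynomialSystem(space, [space.var("c") + space.var("a")])
        assert occurring_variables(sys) == ("a", "c")
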