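"""The three control problems and minimal-policy post-processing."""

import itertools

import pytest

from bncontrol import (
    ControlPolicy,
    GeneratorSpec,
    add_controls,
    add_edge_controls,
    add_node_controls,
    block_region,
    block_transition,
    count_solutions,
    create_steady_state,
    destroy_steady_state,
    fixed_points,
    minimal_policies,
    parse_network,
    random_network,
    specialize,
    steady_state_system,
    step,
    wiring_diagram,
)
from bncontrol.tasks import PolynomialSystem



def _supports(result):
    return [tuple(sorted(p.support)) for p in result.minimal]


class TestCreateSteadyState:
    def test_toy_edge_control_unique_policy(self, toy):
        cnet = add_edge_controls(
            toy, [("x1", "x2"), ("x4", "x2"), ("x2", "x3"), ("x4", "x5")]
        )
        res = create_steady_state(cnet, "01111")
        assert _supports(res) == [("u_x2_x3", "u_x4_x5")]
        assert res.occurring_count == 1  # unique over the occurring controls
        assert all(res.verified)

    def test_toy_node_control_combinatorial_policy(self, toy):
        cnet = add_node_controls(
            toy, ["x1", "x3", "x4"],
            modes={"x1": ["on"], "x3": ["off", "on"], "x4": ["on"]},
        )
        res = create_steady_state(cnet, "11110")
        assert _supports(res) == [("uon_x1", "uon_x3")]
        # neither control alone suffices (combinatorial policy)
        for single in (("uon_x1",), ("uon_x3",)):
            snet = specialize(cnet, ControlPolicy.from_support(single))
            assert step(snet, "11110") != tuple(int(b) for b in "11110")

    def test_already_fixed_state_needs_no_control(self, toy):
        cnet = add_node_controls(toy, toy.space.names)
        res = create_steady_state(cnet, "01001")
        assert _supports(res)[0] == ()

    def test_unreachable_target_returns_empty(self):
        # constant-zero update, only an edge-free control set that cannot help
        net = parse_network("a, 0\nb, a")
        cnet = add_edge_controls(net, [("a", "b")])
        res = create_steady_state(cnet, "11")
        assert res.minimal == () and res.raw_count == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_raw_set_matches_brute_force(self, seed):
        net = random_network(GeneratorSpec(n=5, k=2, seed=seed + 700))
        cnet = add_node_controls(net, net.space.names[:3])
        y0 = tuple(int(b) for b in f"{seed % 32:05b}")
        res = create_steady_state(cnet, y0, exclude_negation=False)
        controls = cnet.control_names
        expected = {
            tuple(bits)
            for bits in itertools.product((0, 1), repeat=len(controls))
            if step(specialize(cnet, dict(zip(controls, bits))), y0) == y0
        }
        got = {tuple(p[c] for c in controls) for p in res.raw}
        assert got == expected
        assert res.raw_count == len(expected)


class TestBlockTransition:
    def test_toy_edge_blocking(self, toy):
        cnet = add_edge_controls(
            toy, [("x3", "x1"), ("x5", "x1"), ("x2", "x3"), ("x3", "x4")]
        )
        res = block_transition(cnet, "00101", "01111")
        # the product equation factors are (u31 u51 + 1) and (u34 + 1)
        nontrivial = sorted(str(f) for f in res.factors if not f.is_one())
        assert nontrivial == ["1 + u_x3_x1*u_x5_x1", "1 + u_x3_x4"]
        assert _supports(res) == [("u_x3_x4",), ("u_x3_x1", "u_x5_x1")]
        assert all(res.verified)

    def test_zero_policy_blocks_a_non_transition(self, toy):
        cnet = add_edge_controls(toy, [("x2", "x3")])
        res = block_transition(cnet, "00101", "00000")  # F(00101)=01111 != 00000
        assert _supports(res) == [()]

    @pytest.mark.parametrize("seed", range(10))
    def test_product_equation_iff_characterization(self, seed):
        """The product polynomial vanishes at u exactly when F(x0,u) != z0."""
        net = random_network(GeneratorSpec(n=5, k=2, seed=seed + 800))
        edges = sorted(wiring_diagram(net).edges)[:4]
        cnet = add_controls(net, edges=edges, nodes=net.space.names[:1])
        x0 = tuple(int(b) for b in f"{(seed * 7) % 32:05b}")
        z0 = step(net, x0)
        res = block_transition(cnet, x0, z0, exclude_negation=False)
        controls = cnet.control_names
        for bits in itertools.product((0, 1), repeat=len(controls)):
            a = dict(zip(controls, bits))
            product_vanishes = any(f.evaluate(a) == 0 for f in res.factors)
            blocked = step(specialize(cnet, a), x0) != z0
            assert product_vanishes == blocked
        got = {tuple(p[c] for c in controls) for p in res.raw}
        expected = {
            bits
            for bits in itertools.product((0, 1), repeat=len(controls))
            if step(specialize(cnet, dict(zip(controls, bits))), x0) != z0
        }
        assert got == expected


class TestDestroySteadyState:
    def test_identity_network_knockout(self):
        net = parse_network("a, a\nb, b")
        cnet = add_node_controls(net, ["a"], modes={"a": ["off"]})
        res = destroy_steady_state(cnet, "11")
        assert _supports(res) == [("uoff_a",)]

    def test_warns_when_state_is_not_fixed(self, toy):
        cnet = add_node_controls(toy, ["x1"])
        with pytest.warns(UserWarning, match="not a fixed point"):
            destroy_steady_state(cnet, "00000")

    def test_tlgl_disease_state_ceramide_on(self, tlgl):
        cnet = add_node_controls(tlgl, tlgl.space.names)
        res = destroy_steady_state(cnet, "0001101000101110")
        assert ("uon_Ceramide",) in _supports(res)
        assert all(res.verified)


class TestBlockRegion:
    def test_toy_node_control_region(self, toy):
        cnet = add_node_controls(
            toy, ["x2", "x3", "x4"],
            modes={"x2": ["off"], "x3": ["on"], "x4": ["on"]},
        )
        res = block_region(cnet, {"x3": 0})
        assert _supports(res) == [("uoff_x2",), ("uon_x3",)]
        # the elimination ideal exposes the two controls directly
        assert {str(g) for g in res.system} == {"uoff_x2", "uon_x3"}

    def test_region_contradicting_constant_update_blocks_for_free(self):
        net = parse_network("a, 1\nb, b")
        cnet = add_node_controls(net, ["b"])
        res = block_region(cnet, {"a": 0})
        assert _supports(res) == [()]

    def test_search_and_groebner_methods_agree(self, toy):
        cnet = add_node_controls(toy, ["x2", "x3", "x4"])
        kwargs = dict(max_support=2)
        a = block_region(cnet, {"x3": 0}, method="groebner", **kwargs)
        b = block_region(cnet, {"x3": 0}, method="search", **kwargs)
        assert _supports(a) == _supports(b)

    @pytest.mark.parametrize("seed", range(6))
    def test_complement_law(self, seed):
        """A policy is returned iff the specialized steady-state-plus-region
        system has no solution."""
        net = random_network(GeneratorSpec(n=4, k=2, seed=seed + 900))
        cnet = add_node_controls(net, net.space.names[:2])
        region = {net.space.names[-1]: 1}
        res = block_region(cnet, region, method="groebner", exclude_negation=False)
        controls = cnet.control_names
        blocking = {tuple(p[c] for c in controls) for p in res.raw}
        for bits in itertools.product((0, 1), repeat=len(controls)):
            snet = specialize(cnet, dict(zip(controls, bits)))
            sys = steady_state_system(snet)
            clamped = PolynomialSystem(
                snet.space,
                list(sys.generators)
                + [snet.space.var(v) + snet.space.const(b) for v, b in region.items()],
            )
            has_bad_steady_state = count_solutions(clamped) > 0
            assert (bits in blocking) == (not has_bad_steady_state)


class TestMinimalPolicies:
    def test_blocking_example(self):
        raw = [
            ControlPolicy(dict(zip(("u34", "u31", "u51"), bits)))
            for bits in itertools.product((0, 1), repeat=3)
            if bits[0] == 1 or (bits[1] and bits[2])
        ]
        got = {tuple(sorted(p.support)) for p in minimal_policies(raw)}
        assert got == {("u34",), ("u31", "u51")}

    def test_zero_policy_dominates(self):
        raw = [ControlPolicy({}), ControlPolicy({"a": 1})]
        assert [p.support for p in minimal_policies(raw)] == [frozenset()]

    @pytest.mark.parametrize("seed", range(6))
    def test_minimality_by_exhaustive_subset_check(self, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        controls = [f"u{i}" for i in range(5)]
        solution_set = {
            bits
            for bits in itertools.product((0, 1), repeat=5)
            if rng.random() < 0.4
        }
        raw = [ControlPolicy(dict(zip(controls, b))) for b in solution_set]
        minimal = minimal_policies(raw)
        for p in minimal:
            bits = tuple(p[c] for c in controls)
            assert bits in solution_set
            for r in range(len(p.support)):
                for sub in itertools.combinations(sorted(p.support), r):
                    sub_bits = tuple(1 if c in sub else 0 for c in controls)
                    assert sub_bits not in solution_set


class TestSoundness:
    """Every returned policy must satisfy its defining dynamical condition."""

    @pytest.mark.parametrize("seed", range(5))
    def test_all_tasks_verified_on_random_instances(self, seed):
        net = random_network(GeneratorSpec(n=5, k=2, seed=seed + 1000))
        edges = sorted(wiring_diagram(net).edges)[:3]
        cnet = add_controls(net, edges=edges, nodes=net.space.names[:2])
        y0 = tuple(int(b) for b in f"{(seed * 3) % 32:05b}")
        fix = create_steady_state(cnet, y0)
        assert all(fix.verified)
        for p in fix.minimal:
            assert step(specialize(cnet, p), y0) == y0
        blk = block_transition(cnet, y0, step(net, y0))
        assert all(blk.verified)
        reg = block_region(cnet, {net.space.names[0]: 0})
        assert all(reg.verified)
        names = net.space.names
        for p in reg.minimal:
            for s in fixed_points(specialize(cnet, p)):
                assert dict(zip(names, s))[names[0]] != 0
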