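"""Bundled Boolean network models and a seeded random-network generator.

Two models ship with the package:

* a five-node toy signaling network small enough to analyze by hand, used
  throughout the documentation and tests;
* the 16-node reduction of the T-LGL (T cell large granular lymphocyte)
  leukemia survival-signaling Boolean model, whose disease steady states
  (Apoptosis and Caspase OFF) are the classic target for intervention
  analysis.

A related fixture provides the seven generator polynomials of the control
ideal for making the apoptosis state of a 16-node p53-mdm2 breast-cancer
cell model a fixed point under edge deletions; the full p53 model itself is
not bundled (load it from a rule file), but the generator system alone
supports exact solution counting.  The random-network generator draws a
uniformly random truth table over a random bounded-size input set per node
and is the workhorse of the property-based tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .algebra import BooleanPolynomial, PolynomialSystem, VariableSpace
from .network import BooleanNetwork, parse_network

__all__ = [
    "ModelFixture",
    "GeneratorSpec",
    "toy_network",
    "tlgl_network",
    "p53_edge_control_ideal",
    "random_network",
    "load_network",
    "MODELS",
]


@dataclass(frozen=True)
class ModelFixture:
    name: str
    provenance: str

    def build(self) -> BooleanNetwork:
        return _BUILDERS[self.name]()


TOY_RULES = """\
targets, factors
x1, !x3 & !x5
x2, !x1 | x4
x3, !x2
x4, x3
x5, !x4
"""


def toy_network() -> BooleanNetwork:
    """The five-node toy network: f1 = !x3 & !x5, f2 = !x1 | x4, f3 = !x2,
    f4 = x3, f5 = !x4.  Its unique steady state is 01001."""
    return parse_network(TOY_RULES, dialect="bnet")


TLGL_NODES = (
    "CREB", "IFNG", "P2", "GPCR", "SMAD", "Fas", "sFas", "Ceramide",
    "DISC", "Caspase", "FLIP", "BID", "IAP", "MCL1", "S1P", "Apoptosis",
)


def tlgl_network() -> BooleanNetwork:
    """The 16-node reduced T-LGL leukemia survival-signaling network.

    Node order is x1=CREB ... x16=Apoptosis, so state bitstrings read CREB
    leftmost.  Every update except Apoptosis's carries a (1 + Apoptosis)
    factor: once Apoptosis switches on, all other nodes switch off and the
    network absorbs into the apoptotic state 0000000000000001.
    """
    space = VariableSpace(TLGL_NODES)
    x = {i + 1: space.var(n) for i, n in enumerate(TLGL_NODES)}
    a = x[16] + 1  # alive factor: 1 + Apoptosis
    updates = [
        x[2] * a,                                            # CREB
        (x[5] + 1) * (x[3] + 1) * a,                         # IFNG
        (x[2] * x[3] + x[2] + x[3]) * a,                     # P2
        x[15] * a,                                           # GPCR
        x[4] * a,                                            # SMAD
        (x[7] + 1) * a,                                      # Fas
        x[15] * a,                                           # sFas
        (x[15] + 1) * x[6] * a,                              # Ceramide
        (x[6] * x[8] * x[11] + x[6] * x[8] + x[6] * x[11]
         + x[6] + x[8]) * a,                                 # DISC
        (x[9] * x[12] * x[13] + x[9] * x[12] + x[12] * x[13]
         + x[9] + x[12]) * a,                                # Caspase
        (x[9] + 1) * a,                                      # FLIP
        (x[14] + 1) * a,                                     # BID
        (x[12] + 1) * a,                                     # IAP
        (x[9] + 1) * a,                                      # MCL1
        (x[8] + 1) * a,                                      # S1P
        x[10] * x[16] + x[16] + x[10],                       # Apoptosis
    ]
    return BooleanNetwork(space, updates)


# Control variables of the p53-mdm2 cancer-cell edge-control ideal, named
# u_<i>_<j> for deletion of the edge x_i -> x_j in the 16-node indexing
# (x1=ATM, x2=p53, x3=Mdm2, x4=MdmX, x5=Wip1, x6=cyclinG, x7=PTEN, x8=p21,
# x9=AKT, x10=cyclinE, x11=Rb, x12=E2F1, x13=p14ARf, x14=Bcl2, x15=Bax,
# x16=caspase).
P53_CONTROL_IDEAL_VARIABLES = (
    "u_2_5", "u_16_11", "u_1_11", "u_8_8", "u_3_8", "u_2_2", "u_3_2",
    "u_1_2", "u_1_1", "u_12_1", "u_12_16", "u_16_16", "u_8_16",
)


def p53_edge_control_ideal() -> PolynomialSystem:
    """The seven generator polynomials of the edge-control ideal that makes
    the cell-death state of the p53-mdm2 cancer-cell model a fixed point.

    The system has 945 solutions over its 13 control variables; each is an
    edge-deletion combination guaranteeing the desired steady state.
    """
    space = VariableSpace(
        P53_CONTROL_IDEAL_VARIABLES, roles={n: "control" for n in P53_CONTROL_IDEAL_VARIABLES}
    )
    u = {name: space.var(name) for name in P53_CONTROL_IDEAL_VARIABLES}
    gens = (
        u["u_2_5"] + 1,
        u["u_16_11"] * (u["u_1_11"] + 1),
        u["u_8_8"] * (u["u_3_8"] + 1),
        u["u_2_2"] * (u["u_3_2"] + 1),
        u["u_1_2"] * (u["u_3_2"] + 1),
        u["u_1_1"] * u["u_12_1"],
        u["u_12_16"] * u["u_16_16"] * (u["u_8_16"] + 1),
    )
    return PolynomialSystem(space, gens)


@dataclass(frozen=True)
class GeneratorSpec:
    """Seeded recipe for a random network: n nodes, in-degree at most k."""

    n: int
    k: int
    seed: int

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("need at least one node")
        if not 0 <= self.k <= self.n:
            raise ValueError("max in-degree must be between 0 and n")


def _truth_table_to_terms(inputs: tuple[str, ...], table: np.ndarray):
    """ANF coefficients of a truth table by the binary Moebius transform.

    Table index bits follow ``inputs`` with the first input most
    significant, matching the bitstring convention.
    """
    d = len(inputs)
    coef = [int(b) & 1 for b in table]
    for b in range(d):
        for m in range(1 << d):
            if m & (1 << b):
                coef[m] ^= coef[m ^ (1 << b)]
    terms = []
    for m in range(1 << d):
        if coef[m]:
            terms.append(
                frozenset(
                    inputs[i] for i in range(d) if (m >> (d - 1 - i)) & 1
                )
            )
    return terms


def random_network(spec: GeneratorSpec | None = None, *, n: int | None = None,
                   k: int | None = None, seed: int | None = None) -> BooleanNetwork:
    """A random Boolean network: each node takes a uniformly random Boolean
    function of a uniformly random input set of size <= k.  The same spec
    always yields the identical network."""
    if spec is None:
        spec = GeneratorSpec(n=n, k=k, seed=seed)
    rng = np.random.default_rng(spec.seed)
    names = tuple(f"x{i+1}" for i in range(spec.n))
    space = VariableSpace(names)
    updates = []
    for _ in range(spec.n):
        d = int(rng.integers(0, spec.k + 1))
        chosen = sorted(rng.choice(spec.n, size=d, replace=False))
        inputs = tuple(names[i] for i in chosen)
        table = rng.integers(0, 2, size=1 << d)
        updates.append(BooleanPolynomial(space, _truth_table_to_terms(inputs, table)))
    return BooleanNetwork(space, updates)


def load_network(path: str | Path, dialect: str = "bnet") -> BooleanNetwork:
    """Parse a rule file from disk (``bnet`` or ``anf`` dialect)."""
    return parse_network(Path(path).read_text(), dialect=dialect)


_BUILDERS = {"toy": toy_network, "tlgl": tlgl_network}

MODELS = {
    "toy": ModelFixture(
        "toy",
        "five-node toy signaling network used in the worked examples",
    ),
    "tlgl": ModelFixture(
        "tlgl",
        "16-node reduction of the 60-node T-LGL leukemia survival-signaling "
        "Boolean model (Zhang et al. 2008, as reduced for steady-state "
        "analysis by Saadatpour et al. 2011)",
    ),
}
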