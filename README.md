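# bncontrol

Algebraic identification of control targets in Boolean molecular network
models: which edge deletions, gene knockouts, or constant expressions will
create a desired steady state, destroy a disease attractor, or keep the
dynamics out of a forbidden region?

## Who this is for

Systems biologists working with Boolean models of signaling or gene
regulation (BoolNet-style rule files) who want an *exhaustive* answer to
"which combinations of interventions achieve my control objective?" —
including combinatorial policies where no single intervention suffices —
without enumerating the `2^edges` or `3^nodes` modified networks one at a
time.

## The method

A Boolean network `F = (f_1, …, f_n) : {0,1}^n → {0,1}^n` is encoded as a
polynomial dynamical system over GF(2) via `a ∧ b = ab`, `a ∨ b = a+b+ab`,
`¬a = 1+a`; every update rule becomes a canonical multilinear XOR-of-AND
polynomial (algebraic normal form). Interventions become extra GF(2)
parameters:

* **edge deletion** `u_{i,j}`: inside `f_j`, replace `x_i` by
  `(u_{i,j}+1)·x_i` — setting `u_{i,j}=1` severs the regulation `x_i → x_j`;
* **node knockout / constant expression** `(u_i⁻, u_i⁺)`: replace `f_i` by
  `(u_i⁻ + u_i⁺ + 1)·f_i + u_i⁺`, giving `f_i`, `0`, `1`, or `f_i+1`.

Each control objective is then a system of polynomial equations in `u`:

* **create a steady state** `y₀`:  `F_j(y₀, u) − y₀ⱼ = 0` for all `j`;
* **block a transition** `x₀ → z₀` (destroying a fixed point is the case
  `z₀ = x₀`):  `∏_j (F_j(x₀,u) − z₀ⱼ + 1) = 0`, which vanishes at `u`
  exactly when `F(x₀,u) ≠ z₀`;
* **block a region** (e.g. no steady state with `Apoptosis = 0`): join the
  steady-state system `F_j(x,u) − x_j = 0` with the region clamps
  `x_k − a = 0`, eliminate the state variables, and keep the `u` *outside*
  the projection.

The systems are solved exactly — reduced Gröbner bases in the Boolean
quotient ring `F₂[x]/(x²+x)`, elimination ideals, and exhaustive vectorized
enumeration — and every returned policy is re-verified by simulating the
controlled network. Solutions are reported as *minimal policies*: sets of
active controls no proper subset of which already works. Exhaustive
attractor/basin analysis (up to 22 nodes) then ranks the candidates by the
basin of attraction of the desired state.

## Worked example

The five-node toy network (`f1 = ¬x3 ∧ ¬x5`, `f2 = ¬x1 ∨ x4`, `f3 = ¬x2`,
`f4 = x3`, `f5 = ¬x4`) has the unique steady state `01001`. To block its
transition `00101 → 01111` using only the edges `x3→x1`, `x5→x1`, `x2→x3`,
`x3→x4`:

```sh
bncontrol control-block --model toy \
    --edges "x3->x1,x5->x1,x2->x3,x3->x4" --from 00101 --to 01111
```

prints

```json
{
  "minimal": [["u_x3_x4"], ["u_x3_x1", "u_x5_x1"]],
  "problem": {"task": "block-transition", "x0": "00101", "z0": "01111"},
  "raw_count": 10,
  "verified": [true, true]
}
```

Deleting the edge `x3→x4` alone blocks the transition; so does deleting
`x3→x1` **and** `x5→x1` together — a combinatorial policy, since neither of
those two deletions works alone (`raw_count` counts all 10 of the 16 total
control assignments that block).

On the bundled 16-node T-LGL leukemia network, asking for node
interventions under which no steady state has Apoptosis and Caspase both
off (Apoptosis itself being a conceptual readout node, excluded from
intervention):

```sh
bncontrol control-region --model tlgl --nodes all \
    --region Apoptosis=0,Caspase=0 --exclude-nodes Apoptosis
```

returns exactly eight minimal policies: constant expression of Ceramide,
DISC, Caspase, or BID; deletion of MCL1 or S1P; and the two combinatorial
pairs {FLIP off, Fas on} and {FLIP off, sFas off}. Specializing any of them
and running `basins` shows a single remaining fixed point whose basin is
100 % of the 65536 states.

## Layout

| module | contents |
| --- | --- |
| `bncontrol.algebra` | ANF polynomials, Gröbner bases, solving/counting, elimination |
| `bncontrol.network` | rule parsing (bnet/ANF), logic→ANF, dynamics, wiring diagram |
| `bncontrol.controls` | edge/node control encodings, policies, specialization |
| `bncontrol.tasks` | the three control problems, minimal-policy reduction |
| `bncontrol.dynamics` | transition map, attractors, basins, ranking, pruning |
| `bncontrol.models` | bundled toy/T-LGL models, p53 control ideal, random networks |
| `bncontrol.cli` | `bncontrol` command-line interface |

See `docs/methods.md` for the model assumptions, numerical choices and
limitations.
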