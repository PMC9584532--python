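# Methods

## The PEW operator

A probabilistic edge-weight operator `P_e(f, w_on, w_off)` is attached to a
clause of a Boolean rule — a single regulator or a parenthesized
multi-regulator clause (a hyperedge). When the rule is evaluated, the
operand clause `x` is evaluated first; the operator then selects a branch
parameter by comparing `x` with a threshold θ (`w_on` if `x > θ`, `w_off`
if `x ≤ θ`; θ = 0.5 throughout the Boolean case) and feeds it to a noise
function `f`. The default `f` is a Bernoulli coin toss: the operator's
output is 1 with the selected probability, independently of everything
else. Two modelling consequences drive the design:

* **Edge weights through noise.** `[0.3,0] C` behaves as a C→target link
  that functions 30% of the time C is present.
* **State dependence.** The OFF branch is separate, so an absent regulator
  can be given zero (or any other) spontaneous activity. This is the
  biologically meaningful asymmetry: a complex that cannot form (source
  OFF) should not fire by accident.

Each PEW operator draws one fresh coin per rule evaluation; coins are never
shared between operators, cached across time steps, or reused within a
step. `and`/`or` do not short-circuit, so the number and order of draws
depend only on the expression tree — this makes seeded runs replayable.
Parameters are constant in time.

Operator algebra: a `not` to the left of an operator complements its
weights, `not [a,b] X ≡ [1−a,1−b] X`, for any operand clause `X`; an
operator to the left of a `not` acts on the outcome of the negation
(`[a,b] not C` selects its branch by `not C`). Both are consequences of
the definition and are property-tested on a weight grid.

### Grammar

The rule dialect is a superset of BooleanNet syntax (`name* = expr`,
`and/or/not`, parentheses, `True`/`False`, `#` comments), case-sensitive
names. The PEW bracket binds like `not`: to the first clause on its right.
Chained unary operators compose in textual order. Referenced-but-unruled
names are held inputs, changed only by perturbation protocols. The parser
is a hand-written tokenizer plus recursive descent; `parse ∘ render` is the
structural identity on expression trees (property-tested on generated
models).

Named noise functions `[f_name, p1, p2]` resolve against a registry at
evaluation time; `p1`/`p2` are the ON/OFF branch parameters. A registered
function receives `(operand value, selected branch parameter, uniform
draw)`; outputs are thresholded at θ so the Boolean engine stays closed
over {0,1}. A function may also register a closed-form branch probability,
which admits it to exact chain analysis; without one, exact analysis
raises rather than guessing.

## Update schemes and time units

* **Synchronous** — all nodes recomputed from the pre-step state; one step
  = N node updates. Coins are drawn in node-declaration order.
* **Random-order asynchronous** — a fresh uniform permutation per sweep;
  each node updated once, seeing earlier in-sweep updates (standard
  BooleanNet behaviour); one time step = one sweep.
* **General asynchronous** — one uniformly chosen node per update,
  repetition allowed; one time step = one node update (an option records
  every N updates instead, for cross-scheme comparisons).

Perturbations model input "concentration": during the active window the
node is re-drawn each step — set to the target value with probability `p`,
to its complement otherwise. They are applied after the scheme step and
before recording (including at t = 0). After the window a perturbation may
hold the node at a configured value (`after_value`, used for washout of
input pulses) or leave it alone.

## Exact Markov chain

Given a fixed source state, distinct PEW coins are independent and the
subtrees of `and`/`or` nodes share no coins, so the probability that any
(sub)expression evaluates to 1 has an exact recursive closed form; for a
PEW node with stochastic operand probability q it is
`q·P(ON branch) + (1−q)·P(OFF branch)`. From the per-node update
probabilities the transition matrix on the 2^N state space is assembled
per scheme: a product measure (synchronous), a uniform mixture of
single-node update operators (general asynchronous), or a uniform mixture
of the N! ordered products of those operators (random order; enumerated
exactly up to N = 6, an oracle scale — beyond that use Monte-Carlo
estimates from the engine). State index bit i is node i in declaration
order.

Attractors of noise-free models (all operators absent or `[1,0]`) are
enumerated exhaustively under synchronous dynamics by walking the
deterministic successor function; they coincide with the recurrent classes
of the matrix (cross-checked in tests). For noisy models the long-run
structure is given by ergodic subsets: strongly connected components of
the positive-probability transition graph with no outgoing edges (computed
with networkx). Stationary distributions solve the linear system
`πP = π, Σπ = 1` by least squares, which handles periodic chains; the
residual is required to be ≤ 1e−10. Row sums are within 1e−12 of 1 by
construction. Matrices are dense up to N = 12 and sparse above; exact
enumeration is capped at N = 16 by default.

Numerical note: probabilities entering the matrix are IEEE doubles;
complementary branches are formed as `1 − p`, so two algebraically equal
constructions can differ by one ulp (≈ 1e−16). Tests that compare against
independently coded oracles therefore use a 1e−14 absolute tolerance, not
bitwise equality.

## Ensembles and summaries

Long-run behaviour is summarized as ensemble averages over independently
seeded runs from a common initial condition; stochastic nodes show up as
non-binary averages, akin to intermediate concentrations. Run k of an
ensemble is seeded from `SeedSequence(base_seed, spawn_key=(k,))` (masked
to 31 bits), so the whole ensemble is reproducible from one integer and
runs are independent. Derived summaries:

* **Window statistics** — per-run time averages of a node over `[t0, t1)`,
  with the across-run median and a fixed-bin histogram (bin width 0.05 on
  [0,1]).
* **Dose–response** — a fresh ensemble per input level, the input re-drawn
  each step with ON-probability equal to the level (sustained for the whole
  run unless a pulse window is given); the readout's window statistics are
  tabulated per level.
* **Propensity curves** — fraction of runs whose final state satisfies an
  event predicate, per value of a model parameter, with binomial standard
  error `sqrt(f(1−f)/runs)`.
* **First-return times** — the first time a target node pattern holds for
  a persistence window (default 10 consecutive recorded steps), which
  avoids counting transient flickers through the pattern.

## The EMT model

The bundled epithelial–mesenchymal transition network is a compact
reconstruction around the ZEB/miR-200 mutual-repression switch:

```
SMAD*   = TGFB                      # fast shortcut to ZEB
d1..dn  : delay chain TGFB -> SNAI1 (n = 6)
a1..am  : delay chain TGFB -| miR200 (m = 3, m < n)
SNAI1*  = dn or [w_s] SNAI1         # delayed activation + weighted self-loop
ZEB*    = (SMAD or SNAI1) and not miR200
miR200* = not [w_zm] ZEB and not am
Ecad*   = not ZEB
TGFB    : held input, driven by pulse protocols
```

Wild type puts `[0.95, 0]` on both feedback edges (`w_zm` on ZEB⊣miR200,
`w_s` on the SNAI1 self-loop); the mutant — an almost-severed ZEB binding
site on miR200 — changes only `w_zm` to `[0.05, 0]`. The OFF weights are
0 in both variants: an inactive ZEB never represses miR200 by accident.
With identity weights and TGFB = 0 the epithelial state
(Ecad = miR200 = ON, all else OFF) is a fixed point, and a sufficient
TGFB pulse locks the network permanently into the mesenchymal pattern
(ZEB = 1, miR200 = 0, Ecad = 0) — the stable-motif lock-in that the PEW
weights then soften into a slow, reversible commitment.

Protocol choices (the literature this model summarizes does not pin them
down, so they are package defaults, exposed as parameters):

* **MET return (ensemble average) experiment**: general asynchronous
  updates, a saturating TGFB pulse on updates [0, 200) with washout
  (`after_value = 0`), 100–200 runs, a 2000–4000-update budget. Under
  per-update time the wild type's median return to the epithelial pattern
  is ≈ 450 updates and the mutant's ≈ 290 — the "few hundred steps"
  scale, with the mutant strictly sooner. (Under per-sweep time the 5%
  per-sweep escape rate would compress both to tens of sweeps; the
  ordering survives but the timescale does not, which is why per-update
  time is the default here.)
* **Dose–response experiment**: random-order asynchronous updates, the
  TGFB level sustained for the whole run, per-run average E-cadherin over
  sweeps [100, 150), 200 runs per level. The wild type's median drops
  from the epithelial to the mesenchymal plateau within a narrow band of
  input levels (transition width ≈ 0.3 on the [0,1] concentration axis),
  while the mutant declines near-linearly across the whole range
  (width ≈ 0.6) — the sudden-vs-gradual bistability contrast. The tests
  assert the contrast through those transition widths and the steepest
  adjacent-level drop, not through absolute step counts.

## The anti-apoptotic edge-weakening recipe

For cell-cycle models in which the CyclinB–Cdk1 complex inhibits the
anti-apoptotic nodes MCL1, BCLXL and BCL2, `cyclin_cdk1_edits(p_on)`
installs `[p_on, 0]` on the `Cdk1 and CyclinB` clause of each of the three
rules (structural AST matching, one unambiguous clause per rule). The
published 89-node cell-cycle network is distributed with its own
publication; load it with `load_booleannet_file` and apply the recipe
(adjusting node spellings to the file). The repository bundles a small
*synthetic* apoptosis-commitment miniature
(`models/apoptosis_toy_synthetic.txt`) that mirrors only the targeted
motif — three anti-apoptotic nodes inhibited by the complex, with the
caspase-activated DNase CAD latching ON once all three are lost
simultaneously. On this miniature the CAD propensity falls monotonically
as `p_on` decreases, which validates the recipe's machinery and direction;
quantitative apoptosis rates of the full model can only be computed
against its actual rule file.

## BNp emulation

`bnp_wrap(model, p)` replaces every rule expression `E` by `[1−p, p] (E)`:
evaluate the deterministic function, then flip the outcome with
probability p — the classical perturbed Boolean network. For 0 < p < 1
the synchronous chain becomes irreducible (every state reachable from
every state), which tests verify via the ergodic-subset computation, and
the resulting matrix is checked against an independently coded BNp
construction.

## What the random-model generator does and does not emulate

`generate_random_model` produces Kauffman-style NK networks: k uniformly
chosen regulators per node, random and/or/not combinations, literals
wrapped in random Bernoulli operators with a configurable probability. It
is the fixture factory for the engine-vs-exact-chain equivalence tests and
round-trip property tests. It does not emulate the degree heterogeneity,
canalizing functions or motif structure of curated biological networks, so
agreement on these fixtures certifies the *simulation semantics*, not
biological realism of any particular model.

## Known limitations

* Exact analysis is exponential in N (and factorial for random-order
  sweeps); beyond desk scale the engine's Monte-Carlo estimates are the
  only route.
* Multi-level (non-binary) node values are out of scope; the bracket
  syntax is reserved for a future vector form.
* Named noise functions without a declared closed form are excluded from
  exact analysis by design.
* Time-dependent weights are not scheduled by the engine (parsed rules may
  be edited between runs).
* The EMT network is a deliberately small reconstruction for studying
  feedback-edge noise; it is not a curated, literature-complete EMT model.
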