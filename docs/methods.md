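# Methods

## Model

A Boolean network is a pair `G(V, F)`: ordered nodes `V = {v1, …, vn}` and
Boolean functions `F = {f1, …, fn}`, each `f_i` depending on an ordered
input list `IN(v_i)` of at most `K` nodes (the maximum indegree).  Updates
are synchronous: `v_i(t+1) = f_i(v(t))`.  Functions are stored as explicit
truth tables indexed by reading the input assignment `(b1 … bk)` as a
big-endian binary number; states render as bitstrings with `v1` leftmost.
Only singleton attractors (fixed points, `v = f(v)`) are considered; cyclic
attractors and asynchronous semantics are out of scope.

Indegree-0 (constant) nodes are first-class.  This closes the model under
control: clamping node `i` to bit `b` replaces its function with the
constant `b`, and the fixed points of the clamped network are exactly the
states in which controlled nodes hold their assigned values while free
nodes satisfy their functions.

## ILP encoding

For each node with `k ≥ 1` inputs, one binary indicator per truth-table row
links the row's literals (via `τ1(x) = x`, `τ0(x) = 1 − x`) to the node's
value variable:

* rows with `f_i(b) = 1`:  `x_{i,b} ≥ Σ_j τ_{b_j}(x_{ij}) − (k−1)` and
  `x_{i,b} ≤ (1/k) Σ_j τ_{b_j}(x_{ij})`;
* rows with `f_i(b) = 0`:  `x_{i,b} = 0`;
* value link:  `x_i ≤ Σ_b x_{i,b}` and `x_i ≥ (1/2^k) Σ_b x_{i,b}`.

Constant nodes fix the value variable directly.  Fractional coefficients
are kept as written by default; an `integer_coefficients` flag multiplies
the rows through by `k` and `2^k` (identical feasible set over binaries) for
workflows that prefer integral data.  Model size is `n + Σ_i 2^{k_i}`
variables and `O(Σ_i 2^{k_i})` constraints.

Detection is a decision problem, so the detection model's default objective
is constant (pure feasibility); any linear objective may be supplied.
Enumerating *all* fixed points repeatedly solves the model, each time adding
the state-exclusion cut `Σ_{v_i=1}(1 − x_i) + Σ_{v_i=0} x_i ≥ 1` — plumbing
built on the same no-good idea used for controls.

## Control problems

Both networks share the control variables: `w_i = 1` marks node `i` as
controlled and `z_i` carries its clamped bit.  Effective states `x_i`
(cancer) and `s_i` (normal) are tied to internal function values `p_i`,
`q_i` by the pinching rows `p_i − w_i ≤ x_i ≤ p_i + w_i` and
`z_i + w_i − 1 ≤ x_i ≤ z_i − w_i + 1` (and symmetrically for `s_i`), with
`Σ w_i = m`.  Auxiliary binaries linearise the products in the scores:
`u_i ≤ x_i`, `u_i ≤ 1 − w_i` (ON and free in the cancer network) and
`r_i ≤ 1 − s_i`, `r_i ≤ 1 − w_i` (OFF and free in the normal network);
maximisation pushes them to the products' values.

* **max phase (ILP-A)** — SAC maximises `Σ α_i u_i + γ_i r_i`; ACDC adds
  `Σ d_i u_i ≥ ξ₁` and maximises `Σ γ_i r_i`; ACKN adds `Σ γ_i r_i ≥ ξ₂`
  and maximises `Σ α_i u_i`.
* **min phase (ILP-A′)** — the found control is substituted in (each clamped
  node's function replaced by its constant, which is algebraically the same
  as fixing `w_i = 1, z_i = b_i`) and the worst attractor is sought: SAC
  minimises `Σ_{i∉I} α_i x_i + γ_i (1 − s_i)` over both networks, ACDC
  minimises `Σ_{i∉I} γ_i (1 − s_i)` over the normal network only, ACKN
  minimises `Σ_{i∉I} α_i x_i` over the cancer network only.
* **no-good cut (ILP-B)** — a rejected control `(V′, B′)` is excluded by
  `Σ_{i∈I} [b_i=1 : (−z_i − w_i) | b_i=0 : (z_i − w_i)] ≥ 1 − Σ_{i∈I}(1+b_i)`,
  which is violated only by re-selecting the identical node-value set.
  Because the control is shared, one cut family over `(w, z)` serves both
  networks in every mode.

The loop accepts when the min phase meets the threshold and reports
`none_exists` as soon as the max phase cannot: the max-phase optimum is
non-increasing as cuts accumulate and bounds every remaining control's
minimum, so this early exit is sound in all three modes (for ACDC it
strengthens a halt-on-infeasibility rule into a threshold test).  If neither
happens within `max_repeats` iterations the result is the explicit status
`repeat_limit` — the procedure is exponential in the worst case, and an
undecided budget exhaustion is reported rather than guessed.

### Threshold conventions and defaults

Acceptance comparisons follow each algorithm's own wording: `min ≥ θ` for
SAC, `min > θ₁` for ACDC, `min ≥ θ₂` for ACKN (all configurable).  Defaults
are the calibrated values `θ = 1.2n` and `θ₁ = ξ₁ = θ₂ = ξ₂ = 0.6n`, tuned
for unit coefficients `α_i = γ_i = 1`; with them the desired attractors
exist often but not always, which is the informative regime.  `max_repeats`
defaults to 20.  ACDC's damage constraint is written with its own
coefficient vector `d`, defaulting to `α` (damage is measured on the cancer
network); a `gamma` option reproduces the alternative reading in which the
normal-cell coefficients are reused — the two coincide for unit
coefficients.  Scores are real-valued throughout so non-unit coefficient
vectors pass through unchanged.

## Solver

Models live in a solver-agnostic container (named binaries, two-sided
linear rows, linear objective) and are solved by HiGHS through
`scipy.optimize.milp`: open source, single-threaded, and deterministic for
a fixed model, so identical inputs give identical reports.  Tie-breaking
among equally scoring controls is still a solver implementation detail;
consumers should compare statuses and scores, not the identity of the
returned control.  Any model exports to LP text with the stable naming
`x[i]`, `s[i]`, `p[i]`, `q[i]`, `w[i]`, `z[i]`, `u[i]`, `r[i]`,
`xind[i][bits]`, `sind[i][bits]` so exports are diffable across runs.

## Synthetic instances

The random ensemble draws, per node, `K` distinct inputs uniformly at
random (self-inputs excluded by default; both choices are flags) and a
truth table uniformly from the `2^{2^K}` Boolean functions — the
conventional random-BN model, chosen because the sampling distribution for
"randomly generated networks with `K = 2`" is otherwise underdetermined.
Pairs share the node list but draw wiring and functions independently.
Generation is a pure function of `(config, seed)`.

`biased_pair` builds a qualitative cancer/normal caricature: shared wiring,
cancer functions mostly ORs of literals (mostly-ON attractors), normal
functions mostly ANDs (mostly-OFF attractors), literal signs negated with
probability 0.25 by default.  It is an explicitly synthetic stand-in — the
real mouse network that motivates the construction has no published Boolean
functions — so conclusions from it are about the construction, not about
any real topology.

What the generator does **not** emulate: scale-free wiring, canalyzing
function biases, correlated functions between the two cell types, or any
real regulatory topology.  Passing tests therefore demonstrate correctness
of the algorithms on the stated random ensemble, not biological fidelity.

## Verification strategy and problem sizes

Every ILP path is checked against an independent exhaustive oracle:

* encoding — the ILP-feasible state set equals brute-force fixed-point
  enumeration on 200 random networks with `n ≤ 12`, `K ≤ 3`, plus all 16
  two-input functions row by row;
* control — status and optimal min score match exhaustive search over all
  `C(n,m)·2^m` controls on 100 random pairs per mode at `n = 8, m = 2`
  (repeat budget raised above the control count so found/none_exists is
  decisive; with a small budget the `repeat_limit` outcome can depend on
  solver tie-breaking among equal-score controls);
* cuts — on a 4-node instance with identity dynamics the loop enumerates
  all 24 controls exactly once and then proves infeasibility.

The benchmark-style run in the suite uses 10 seeded pairs at
`n = 30, m = 3, K = 2` per mode — large enough to exercise the repeat loop
and the calibrated thresholds, small enough for a routine test run.  Larger
instances (hundreds of nodes) are reachable through the same API and the
`experiment` subcommand.  Wall-clock time is reported for information only
and never asserted.

## Known limitations

* Only synchronous dynamics and period-1 attractors; the time-indexed
  extension for cyclic attractors is not implemented.
* ACDC's damage constraint binds the attractor in the current max-phase
  solution, not every cancer attractor under the control; a control may
  therefore admit additional, less-damaged cancer attractors.
* The repeat loop can be exponential; `repeat_limit` is a real outcome on
  adversarial instances.
* The `bnet` writer emits full-DNF expressions (exact round trip, including
  input order, at the cost of readability for dense tables); expressions
  with more than 16 inputs are refused to bound table size.
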