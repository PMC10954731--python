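# Methods

This note records the models, conventions, numerical choices and known
limitations of the package, in the order a user meets them.

## Truth-table conventions

A k-input Boolean function is stored as its output vector of length 2^k.
Row r encodes the assignment whose bits, most-significant-first, are
(x₁, …, x_k); so x₁ is the high bit of the row index, matching the way
truth tables are conventionally printed.  Two integer encodings of the
output vector circulate in published rule collections and both are
supported by the table reader, declared in the file header:
`integer-msb-row0` (row 0 is the most significant bit, "0001" ↔ 1 at
k = 2 — the package's canonical dialect) and `integer-msb-rowlast`
(row 2^k − 1 most significant).  The bias P is the popcount of the output
vector.  Truth-table operations are capped at k = 20 (2^20 rows); the
counting routines, which never materialize tables, run to k = 200.

0-input constants are representable (they arise from constant factors in
model files and from restricting a 1-input function) but are rejected by
all classification operations, as are functions with inessential
("dummy") inputs: nested canalyzation requires every input to canalyze.

## Canalyzation, layers, chain classes

Classification peels canalyzing inputs greedily: at each stage the
lowest-index input with a canalyzing value fixes the output, and the
recursion continues on the restriction to the complementary value.  Within
a layer all inputs canalyze simultaneously, so the greedy order is safe; a
peel-order-exhaustive classifier is kept as an oracle and the test suite
asserts agreement on every function up to k = 3 and on random and
structured samples at k = 4, 5.  A function is chain-0 (chain-1) when a
peel restricted to canalyzing value 0 (1) succeeds for the first k − 1
inputs and leaves a non-constant single-input residual.  For k ≤ 2 the two
chain classes overlap; such functions are labelled `CHF_BOTH` and both
single-input non-constants x and x̄ carry that label (the "last input
canalyzes in both values" clause is the only applicable one at k = 1).

The layer structure of an NCF is recovered from (k, P) alone: the first
k − 1 bits of the k-bit binary form of P are the operator sequence
(0 ↔ AND, 1 ↔ OR), run lengths of which — with the final run extended by
one — are the layer sizes.  The decomposer cross-checks the peeled layer
sizes against this prediction and fails loudly on disagreement.

Chain-function construction canonicalizes the sign freedom of the last
layer as follows: the canonical member gives every literal the sign
dictated by its layer's operator (positive in AND layers, negated in OR
layers), and the 1 + m_last distinct negation variants are the canonical
member plus "flip exactly one last-layer literal" (the deviant).  This
reproduces the class exactly — the per-bias count k!(1+m_last)/∏mᵢ! is
verified against exhaustive enumeration — without designating a
distinguished "last variable", which commutation inside the last layer
makes arbitrary anyway.

## Counting and the constant C

All counts and fractions are exact: Python big integers and
`fractions.Fraction`, floats only at presentation.  Class totals sum the
per-bias closed forms over odd biases; complement symmetry (P ↔ 2^k − P
preserves layer sizes) halves the work.  For large k the sums run over
layer *compositions* instead of biases: every composition of k with last
part ≥ 2 stands for exactly one complement pair, and the helper
g(s) = Σ 1/∏ mᵢ! over compositions of s satisfies a simple convolution
recurrence, giving the two composition sums — and hence C(k) — in O(k²)
exact-rational operations.  The DP is validated against the direct
odd-bias sums for every k ≤ 20.  C(30) evaluates in well under a second
and agrees with the independently published 14-digit value.

Class enumeration (the brute-force oracle) constructs each member once
from (bias, layer assignment, sign choice) and deduplicates through a set;
it is exhaustively feasible to k = 7 for NCFs (3.7 × 10⁶ members) and
k = 8 for the chain classes (2.2 × 10⁶).  The k = 8 NCF class
(85 755 392 members) is beyond in-memory deduplication on a desk machine;
its total is checked through the composition identity instead.

## Enrichment statistics

For a sub-type T_s inside an englobing type T, the relative enrichment is
E_R = (f_s1/f_1)/(f_s0/f_0) with dataset fractions in the numerator and
exact theoretical fractions (from the counting module, never sampled
estimates) in the denominator.  Significance is the inclusive binomial
upper tail P(m′ ≥ m) with success probability f_R = |T_s|/|T|, computed by
`scipy.stats.binom.sf`; no continuity correction and no multiple-testing
adjustment are applied.  Chain-versus-NCF rows at k ≤ 2 are flagged
undefined: there the union of the chain classes *is* the NCF class, so
relative enrichment is meaningless.  Dataset analyses default to rules
with at most 10 inputs (a CLI option): rarer, larger rules leave per-k
strata too thin for inference.

Because the tail test is discrete, its attained level sits below the
nominal threshold; at the calibration condition used in the tests (200
uniform NCF draws per replicate, k = 4, chain-1 sub-type) the attained
level is 0.0464, and the simulated type-I error over 2000 seeded
replicates is asserted within three binomial standard errors of 0.05.

## Stochastic dynamics and relative stability

Synchronous update only; the asynchronous schemes common in the literature
are out of scope.  Network states are integers whose bits follow node
declaration order, most significant first.  Noise flips every node
independently with probability η per step; when no node flips, the
deterministic image is taken.  The induced one-step law is the
column-stochastic matrix T* = (1−η)^N T + P with
P_lm = η^d(l,m) (1−η)^(N−d(l,m)) and d the Hamming distance; the simulated
one-step frequencies are tested against T* columns.

MFPTs are estimated two ways.  Sampled mode averages first-passage times
over n_traj trajectories (default 3000, η default 0.05); trajectories
exceeding max_steps (default 10⁶) are counted and reported as failures,
never silently dropped.  Exact mode solves the absorbing-chain linear
system on the 2^N states (kept to N ≤ 12, where the dense solve is cheap)
and serves as the oracle for the sampler.  In sampled mode every
(target, source) pair draws from its own generator seeded by
(master seed, pair indices), so estimates are independent of evaluation
order.  Relative stability RS(u,v) = 1/M_uv − 1/M_vu; a hierarchy verdict
is undecided when |RS| lies within three propagated standard errors of
zero (sampled) or within a 10⁻⁹ relative floating-point guard (exact) —
undecided verdicts count against a model during selection.  Verdicts on
the test fixtures are checked to be insensitive to η across 0.01–0.05.

## Model selection

Given a signed network and named fixed points, each node's admissible
rules are generated constructively: iterate odd biases, then
sign-compatible layer assignments — the chain classes force each layer's
literal sign, with at most one last-layer deviant, while for plain NCFs
the required signs pin the literal of every variable — then filter on the
truth-table rows pinned by the fixed points.  Sign-conformity is defined
as unate direction matching the edge sign, which for nested canalyzing
rules coincides with the literal sign.  The constructive generator is
asserted equal to brute filtering of the enumerated class for k ≤ 5.  An
infeasible node (contradictory pinned rows) yields an empty list; a
configured fallback class (e.g. NCF behind a chain class) is tried when
the primary class admits nothing.

Selection screens the ensemble product exhaustively: attractor and basin
screening first (cheapest), then MFPT hierarchies — exact mode for
N ≤ 12, sampled above.  A model is selected when every hierarchy holds
decisively, the summed basin of the biological fixed points reaches the
reference floor, and (optionally) no spurious attractor — an attractor
not among the declared fixed points — exists.  The audit table retains
per-model verdicts, including the count of models violating exactly one
hierarchy.

## Synthetic data

Class-conditioned sampling is enumeration-backed: members are materialized
once per (k, class) and drawn uniformly, which is exact but inherits the
enumeration caps; a parameterization-backed sampler would be cheaper at
large k but risks subtle non-uniformity from within-layer symmetry
collapse.  `RANDOM` means uniform over all 2^(2^k) functions.  Random GRN
fixtures give every node 1–max_in_degree distinct regulators, a rule drawn
from the requested class, and edge signs copied from the rule's unate
directions, so fixtures are sign-conforming by construction; fixed points
come from exact attractor enumeration.  The recovery tests use N = 6
nodes, in-degree ≤ 3, generalized-chain rules, and redraw fixtures until
the constrained ensemble holds at most 200 models, keeping the exhaustive
screen fast.

What the generators do not emulate: the topological structure of real
GRNs (no scale-free or motif-enriched wiring), curation biases of
published models, or correlations between a node's in-degree and its rule
class.  Passing tests therefore establish correctness of the machinery
and calibration of the statistics under the stated null, not claims about
any particular biological dataset.

## Known limitations

* Full enumeration of NCFs beyond k = 7 (chains beyond k = 8–10) is not
  desk-feasible; counting is exact at any k but sampling and oracle
  checks inherit the caps.
* Exact MFPTs require N ≤ 12; larger networks fall back to sampling with
  its Monte-Carlo error, and verdict ties widen accordingly.
* Reproducing the published three-GRN case studies requires their network
  definitions under `data/reference/` (not bundled); the corresponding
  end-to-end test fails with an explicit message until they are supplied.
* Asynchronous updating, SBML-qual/GINsim interchange, BDD/ANF function
  representations, and heuristic search over non-exhaustible ensembles
  are out of scope.
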