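# Methods

## Model class

First-order HMMs over a finite alphabet with exactly two silent states:
Start (index 0, no incoming transitions) and End (last index, no outgoing
transitions). A sequence `x_1..x_L` is produced by a path
`Start, pi_1, ..., pi_L, End`, so every path uses `L + 1` transitions and
`L` emissions. Probabilities are stored in linear space; Viterbi values
are computed in log space, forward values in scaled linear space with
per-position scale factors (the back-tracing ratios are scale-invariant
within a position pair, which keeps posterior sampling a cheap categorical
draw; the log-likelihood is accumulated from the scale logs).

## Parameterization

Trainable structure is a set of *factor groups*, each a small probability
distribution over named members (free members plus at most one derived
remainder), and a map from every structural probability coordinate to a
fixed constant times a product of group members. This expresses:

* plain per-row training (one factor per coordinate, e.g. the toy models),
* tying across states (several coordinates referencing the same member,
  e.g. the extended casino's fair emissions shared by all three F states),
* structured transition matrices (products, e.g. the CpG model's
  `(1 - tau) x switch-or-stay x next-base-row` factorisation with the End
  probability `tau` a shared fixed constant).

Count-based updates are exact M-steps for this class: every coordinate
count is added to each member it references, and each group re-normalises
`(count + pseudocount) / sum`. One pseudocount is added per group member
(tied coordinates pool into a single member and therefore receive one
pseudocount, not one per coordinate); the derived member receives one as
well, which reduces to plain Laplace smoothing for untied rows.
Pseudocounts keep every structural probability positive, so training can
never paint itself into a zero-probability corner and terminate
prematurely; with pseudocount 0 the Baum-Welch loop is exact EM and its
log-likelihood is non-decreasing (asserted to 1e-12 in tests), while any
positive pseudocount regularises and voids strict monotonicity.

Random initialization draws each group flat (Dirichlet with concentration
1) on its member simplex. Fixed constants are never perturbed.

## The one-pass (linear-memory) passes

All three share one pattern: alongside the DP column for position `k`,
keep for every current state `m` a cumulative transition-count table
`T(., ., k, m)` and emission-count table `E(., ., k, m)` describing the
path(s) into `(k, m)`; advance them by *selecting* a predecessor `l` and
copying its tables plus an increment. The selection rule is what
distinguishes the algorithms:

* **Viterbi**: `l = argmax_n v_n(k-1) t_{n,m}`, ties broken toward the
  lowest previous-state index — the same rule in the one-pass kernel and
  in the full-matrix traceback, so their counts agree *exactly*
  (integers), not merely within tolerance.
* **Stochastic EM**: `l` is drawn from `p_m(k, n) ∝ f_n(k-1) t_{n,m}`,
  independently for each of the K chains; at the silent End termination
  the final draw adds a transition but no emission. The chain's final
  table is then distributed exactly as the counts of one posterior path
  draw. The one-pass sampler consumes randomness at every reachable
  (position, state, chain) cell, whereas the two-step back-tracer draws
  only along one path: the two are equivalent in distribution, never
  draw-for-draw, so all cross-checks are distributional (total-variation
  distance to the enumerated exact posterior, chi-square tests,
  expectation against forward-backward).
* **Baum-Welch**: the sample is replaced by its expectation — the new
  table is the `p_m(k, .)`-weighted mixture of the predecessors' tables.
  This pass is validated purely by an equivalence contract against the
  textbook forward-backward counts (relative 1e-8 over hundreds of random
  models).

Retained state is `O(M)` DP values plus `O(M x #coordinates)` count
tables (`x K` for SEM) — independent of `L`. Each kernel sums the
`.nbytes` of the buffers it actually allocates and returns that number,
so the length-independence test compares real allocations at L = 100 and
L = 10,000, not a formula. The kernels are numba-compiled; stochastic
kernels seed numba's own legacy `np.random` stream per (sequence,
iteration) with seeds derived deterministically from the root seed, so
every run replays exactly regardless of evaluation order.

Degenerate inputs: a sequence with zero probability raises an explicit
"unreachable" error naming the record; length-0 sequences are rejected by
the training entry points; states that become unreachable mid-sequence
simply carry no mass and are never selected as predecessors.

## Training loops and stopping

* Viterbi training stops when the pooled member counts repeat exactly
  between iterations (the update is then a fixed point). The classical
  stop rule — "the Viterbi paths no longer change" — cannot be tested
  directly because the one-pass algorithm never materialises paths;
  count identity is an almost-always-equivalent surrogate, and a rolling
  per-sequence hash of the implied traceback path (propagated through the
  same recursion) provides strict path identity behind the
  `strict_path_identity` flag.
* Stochastic EM and Baum-Welch stop on `|delta log-likelihood| < tol` or
  `max_iter`. For SEM the recorded score is the true forward
  log-likelihood (a by-product of the pass), for Viterbi training it is
  the summed Viterbi-path log-probability (a different objective; the two
  are never compared directly).

## Example models and generating parameters

The published model descriptions fix the structure (casino: 4 states, 8
transitions, 12 emissions, 12 free parameters; extended casino: 7 states,
11 transitions, 30 tied emissions, 12 free parameters; CpG: 10 states, 80
transitions, fixed delta emissions) but not the numeric generating values.
The package defaults are the field's canonical choices and are all
overridable:

* casino / extended casino — fair die uniform (1/6 each); loaded die
  `e(6) = 0.5`, `e(1..5) = 0.1`; switch probabilities `F->L 0.05`,
  `L->F 0.10`; End probability fixed at 0.0004 (casino) / 0.001
  (extended), giving mean simulated lengths of a few thousand symbols,
  commensurate with the 5000-symbol study datasets.
* CpG — the classic CpG-enriched '+' / depleted '-' next-base frequency
  tables (normalised to exact row sums); block-switch probabilities
  0.005 (+ to -) and 0.0025 (- to +); uniform Start distribution; shared
  fixed End probability 0.0004. This decomposition has 33 free members,
  all trained; the published account of the same model counts "33
  parameters, 32 of which were determined in training", a bookkeeping
  difference that cannot be settled from the description, so the CpG free
  count is configurable and not hard-asserted.

Fixed-length datasets are simulated by rejection: whole paths are redrawn
until one emits exactly the target length (with early abort on overshoot,
which does not change the accepted distribution). This preserves the
model's conditional distribution given length. The simulator emulates the
study data exactly — symbols drawn from the generating model with known
labels; it does not emulate any property of real genomic sequence
(composition heterogeneity, repeats), so passing tests demonstrate
algorithmic correctness and estimator behaviour under the model, not
biological performance.

## Evaluation

Performance is per-position: Viterbi-decode held-out sequences, classify
each position as positive (loaded / '+' states) or negative, and report
sensitivity `TP/(TP+FN)`, specificity `TN/(TN+FP)` (the published
definition of specificity is not stated; `precision` mode `TP/(TP+FP)` is
available), and their product. Empty denominators count as 1 (nothing to
misclassify). Parameter convergence is the mean absolute difference
between trained and generating free-member values, reported separately
for emission-kind and transition-kind groups.

**Identifiability.** The casino (F<->L) and CpG (+/-) models are invariant
under relabelling their emitting states, so from a random initialization
training converges to either of two equivalent optima. Convergence
metrics therefore align trained to generating values by the best
relabelling from the model's declared symmetry group before averaging
(`align="strict"` disables this). The extended casino's two chains have
different lengths, so it has no such symmetry.

Cross-evaluation splits the dataset into near-equal folds (default 3),
trains every configured algorithm on 2/3 and evaluates on the held-out
1/3 after every iteration, sharing one random initialization per fold
across algorithms by default (fairer comparison; flag-controlled). The
harness's scaled-down problem sizes — 30 sequences of 1000 symbols,
20 iterations — were chosen as the desk-scale rendition of the study's
300 x 5000 experiments.

## Known limitations

* From a flat Dirichlet initialization the initial casino model is nearly
  memoryless, which hides the autocorrelation signal separating the two
  dice; EM-family trainers then pass near a weakly repelling saddle
  (both states drifting toward the pooled emission distribution) and the
  switch parameters typically need 100-200 iterations to converge, with
  occasional runs trapped much longer. This is a property of the
  likelihood surface (an independent EM implementation reproduces it),
  not of the one-pass algorithms, whose correctness contracts are exact.
  Short training budgets therefore often leave transition estimates far
  from the generating values even when emissions look reasonable.
* Scope is single-sequence first-order HMMs with silent Start/End only:
  no higher-order models, pair-HMMs, extra silent states or continuous
  emissions; no checkpointing or Hirschberg decoding; posterior decoding
  for evaluation is not implemented (Viterbi decoding only).
* Training always updates all free parameters simultaneously; the
  partial-parameter memory/time trade-off (training P of Q parameters per
  pass) is not implemented.
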