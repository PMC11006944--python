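# Methods

## The generating chain

The penalty taker's kicks form a stochastic chain with memory of variable
length over A = {0, 1, 2}. Its probabilistic context tree
(`goalkeeper_generating_tree`) has contexts τ = {0, 2, 01, 11, 21}; after a 0
the next symbol is 2 with probability 0.7 and 1 otherwise, and all other
transitions are deterministic, so the realised sequence is a concatenation of
`0 * 1` triplets. Contexts are stored oldest-symbol-first (`"21"` means
X[n−1] = 2, X[n] = 1); the empty tuple is the root and represents a
memoryless chain. Simulation starts from the fixed admissible past
(0, 2, 1) rather than a stationary draw: it guarantees a defined context at
step 1, and because the chain revisits the triplet boundary every three
steps the initialisation is forgotten immediately.

## The synthetic cohort

`CohortConfig` defaults encode the study conditions: 22 participants, 1000
trials, rest breaks after trials 334 and 668 (epochs [1, 334], [335, 668],
[669, 1000]).

**Predictions.** The goalkeeper's strategy is not observed, so the simulator
uses a deliberately simple stand-in: the prediction is correct with a
per-context accuracy (default 0.90 for the deterministic contexts, 0.65 for
the uncertain context 0) and otherwise uniform over the two remaining
symbols. Trial 1 — and any early trial whose short past matches no context —
is predicted uniformly. Predictions never feed back into the kicks.

**Response times.** Log-normal:
`T[n] = exp(μ(w) + δ(w)·F[n] + σ·ε[n])` with w the context ending at trial
n − 1, ε standard normal, and F[n] = 1 when the prediction at the most
recent symbol-0 transition strictly before trial n failed. The log-normal
family is a modelling choice (positive support, standard for response
times); the estimator is distribution-free (KS-based), so downstream results
do not hinge on it. Defaults, chosen once as a plausible human regime that
also separates sibling contexts:

| context | median (s) | μ = log median | outcome shift δ |
|---------|-----------|----------------|------------------|
| 0       | 0.95      | −0.051         | 0                |
| 2       | 0.70      | −0.357         | +0.30            |
| 01      | 1.25      | +0.223         | −0.20            |
| 11      | 0.92      | −0.083         | 0                |
| 21      | 0.68      | −0.386         | +0.15            |

σ = 0.1 on the log scale, so within-family separations (≈ 0.30) are ≥ 3σ —
the separated regime in which tree recovery is expected. The shifts act one
step after the 0 for contexts 2 and 01 and two steps after for 21,
reproducing an outcome effect that propagates up to two steps forward; their
signs encode slower responses after failure in the highly predictable
contexts (2, 21) and slower responses after success in the rarely predicted
context 01. `RTModel.context_free()` is the null model (all locations
equal, no shifts). Leading trials with no defined context get the mean
location and are flagged in the debug log.

What the generator does **not** emulate: learning dynamics across epochs
(parameters are stationary within a session), trial-to-trial autocorrelation
of rts beyond the context/outcome structure, lapses and outliers, rest-break
duration effects, and any adaptive goalkeeper strategy. Passing tests
therefore demonstrate correctness of the algorithms under the stated model,
not the behavioral findings themselves.

**Seeding.** A cohort is a pure function of its config: participant streams
are spawned from `numpy.random.SeedSequence(seed)`, with independent child
streams for kicks, predictions and rts.

## Tree estimation from response times

`estimate_context_tree(kicks, rts, K, alpha, min_count)` extends the Context
algorithm to a real-valued response series. The sample attached to a
candidate string w is {T[n+1] : an occurrence of w ends at n}; occurrences
ending at the final trial are dropped. The candidate list C starts with all
length-K strings occurring in the sequence, sorted in reverse lexicographic
order (most recent symbol first); only occurring strings are ever enqueued.
Iteratively the first w is taken and its sibling family F(w) — occurring
strings obtained by prepending one symbol to w's suffix — is formed:

* F(w) = {w}: the lone sibling is pruned to its suffix without testing
  (implemented exactly as specified even though it bypasses the test);
* F(w) ⊆ C: every unordered pair of siblings with at least `min_count`
  observations each is compared by the two-sample KS test; if **any** pair
  has p < alpha the whole family is kept as leaves, otherwise the family is
  pruned and the common suffix appended to the end of C. No multiplicity
  correction is applied within a branch ("at least two leaves differ" is the
  decision rule); with fewer than two testable siblings the family is
  retained for lack of evidence and flagged.
* F(w) ⊄ C: some sibling's subtree was already kept deeper down, so the
  members still pending become leaves directly.

When pruning reaches the root the empty suffix is simply not re-enqueued;
if nothing was kept the output is the root-only tree. Each iteration either
removes strings from C or replaces strings of length l by one of length
l − 1, so the loop terminates; because sibling families are processed as
units the output is suffix-free (asserted by the `ContextTree` invariant on
every construction).

Numerical choices: alpha defaults to 0.05 and K to 3 (one level beyond the
generating tree's depth); `min_count` defaults to 5 because the two-sample
KS test is meaningless on smaller samples — a rarer sibling cannot drive a
rejection. KS p-values use `scipy.stats.ks_2samp(method="auto")`, which
switches between the exact and asymptotic null distribution by sample size;
the method is recorded in the estimation metadata, and ties are handled by
the standard empirical-CDF statistic. All pairwise D statistics and
p-values are kept in the per-branch records serialised with each tree.

`estimate_by_epoch` applies the estimator independently to the trial ranges
delimited by the rest breaks; epochs shorter than K + 1 trials are skipped
with a warning. `mode_context_tree` counts, for every context appearing in
any participant's tree, the number of trees containing it and keeps those
present in strictly more than the threshold fraction (unanimous contexts
always qualify, so threshold 1.0 means "in every tree"); suffix conflicts
among survivors are resolved in favour of the more frequent context, ties
favouring the longer one, so the summary is again a valid context tree.

## Outcome conditioning and the statistical battery

For a context w, each occurrence ending at n (with T[n+1] defined) is
assigned to the *success* or *failure* subsample according to the prediction
at m* + 1, where m* is the most recent step with m* + 1 ≤ n at which the
symbol 0 occurred. Since 0 is the unique length-1 context opening each
triplet, "an occurrence of symbol 0" and "an occurrence of context 0"
coincide for this chain; the anchor symbol is configurable for other chains.
This makes the conditioning one step forward for contexts 2 and 01, two
steps for 21, and — for context 0 itself — refers back to the previous
triplet. Occurrences with no prior anchor are discarded; the partition
(success + failure + discarded = counted occurrences) is a tested invariant.

Per participant and context the summary is the trimmed-mean difference,
failure minus success. The trim fraction defaults to 0.2 (the usual robust
compromise between efficiency and outlier resistance); `floor(trim·n)`
observations are dropped from each tail. Differences are tested across
participants with the two-tailed Wilcoxon signed-rank test: zero differences
are dropped, ranks are midranks, and the reported Z uses the tie-corrected
normal approximation with sign following the direction of the rank sum; an
exact sign-flip enumeration (feasible to n ≈ 20) is available and is the
default below n = 16. The per-context p-values of one analysis run form the
Benjamini–Hochberg family, screened at q = 0.05 by the step-up rule
(reject the k smallest p-values, k the largest rank i with
p(i) ≤ q·i/M). Participants with fewer than `min_samples = 5` observations
in either subsample are excluded per context and logged.

The index of correctly predicted transitions I(w→a) =
N(w→a) / (N(w→a) + N(w→a̸)) quantifies per-transition prediction accuracy,
and `kruskal_wallis_by_group` (tie-corrected H, χ² reference with
df = groups − 1) compares response times across response fingers, grouping
by the predicted symbol (0 index, 1 middle, 2 ring). Degenerate all-tied
input returns H = 0, p = 1 rather than an error.

## Problem sizes

The study-scale checks run at the protocol's native sizes — 22 participants
× 1000 trials; 20 replicate cohorts for the recovery and effect-sign rates;
100 replicate sessions for the null-safety rate; 100,000 symbols for chain
fidelity — sizes at which the binomial noise on the reported rates is small
relative to the margins being asserted. Oracle comparisons (sign-flip and
rank-formula enumeration) use n ≤ 10 where enumeration is exact.

## Known limitations

* The goalkeeper model is memoryless given the context; it cannot produce
  the asymmetry in per-transition accuracy (e.g. a participant who always
  guesses 2 after a 0) that real players show — only per-context accuracy is
  parameterised.
* Wilcoxon Z values across participants saturate at ±4.107 for n = 22 when
  every participant shifts the same way; with strong simulated effects the
  reported Z is often exactly this bound.
* The estimator prunes with per-branch KS tests at a fixed level; no
  consistency guarantees are claimed at finite n, and spurious depth-3
  contexts survive in a few percent of participants at alpha = 0.05 (visible
  in the mode-tree counts).
* File ingestion supports the session CSV schema only; no other formats.
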