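# Methods notes

This note records the modeling choices behind `perturbenc`: what each stage
computes, the defaults and why, what the synthetic data do and do not
emulate, and the numerical conventions a reimplementer would need.

## Stimulus model and normalization

A stimulus set is a fixed hierarchy experiment → topic → passage →
sentence; sentence order within a passage is contiguous and 1-indexed.
Normalization lower-cases, strips all sentence-internal punctuation except
hyphens and apostrophes (curly apostrophes become ASCII), and appends a
distinguished terminal period token. The period is excluded from word
counts, class filters, PMI pair extraction, swaps and scrambles; it stays
terminal in every condition. Rationale: every perturbed condition keeps a
final period in place, and the last-token sequence summary is then always
the period token's representation, which in a causal model aggregates the
whole sentence.

Part-of-speech classification is total over word tokens with five classes
(NOUN, VERB, ADJ, ADV, FUNCTION); pronouns and proper names count as
nouns. Taggers are pluggable callables returning Penn-Treebank-style tags;
the package ships a lexicon tagger, and the synthetic generator emits
classes by construction, so no external tagger is ever required in the
test path and golden outputs cannot drift with tagger versions.

## PMI

`string_pmi` averages positive PMI (natural log, negatives clipped to
zero) over all index pairs with gap ≤ 3 — the sliding four-word window —
and divides by `3n−2` exactly as the reference formulation states, although
the number of windowed pairs is `3n−6` for `n ≥ 4`. The constant rescales
all strings identically and no use of the score depends on its absolute
value (the LowPMIRandom argmin and all comparisons are invariant to it),
so fidelity to the stated formula was preferred over "correcting" it.

Pair probabilities are estimated over *unordered* pairs: this is what
makes the PMI profile exactly invariant under sequence reversal, a stated
property of the reversal condition. Laplace smoothing adds α = 0.1 to all
V unigram cells and all V(V+1)/2 unordered pair cells (self-pairs
included, since a word can co-occur with itself inside a window).
Summation uses `math.fsum`, so the score is bit-identical under any
reordering of the pair multiset. Possessive clitics ("beekeeper's")
remain single tokens.

## Perturbation conditions

* **k local swaps** — apply k random adjacent transpositions, then verify
  that the adjacent-transposition (Kendall) distance between the index
  permutations equals k, i.e. no swap undid another; resample otherwise.
  Duplicate words are matched stably (leftmost unused occurrence), which
  minimizes the distance over all consistent matchings. Sentences with
  n ≤ k words receive the largest feasible count (k′ = n−1): the sentence
  length floor (5) is below the largest swap count (7), and dropping such
  sentences would desynchronize conditions.
* **LowPMI** — content and function words are listed in sentence order;
  each list is split into odd- and even-numbered members (1-based position
  *within the class list*), re-concatenated as oddContent ++ oddFunction
  ++ evenFunction ++ evenContent. The worked reference example uniquely
  determines this order; the prose description alone does not.
* **LowPMIRandom** — 10 sampled distinct word permutations, excluding the
  identity and the same sentence's local-swap outputs (compared as full
  token sequences), scored by `string_pmi`; argmin wins, ties to the
  first sampled.
* **Information loss** — ordered subsequences by class membership; an
  empty result (e.g. all-function sentence under KeepN) is permitted and
  yields a bare period.
* **Sentence substitution** — uniform fixed-point-free permutations
  (rejection sampling from uniform permutations, max 100 tries, success
  probability ≈ 1−1/e per try) within passage, topic, or whole-experiment
  scope; singleton groups necessarily map to themselves. Sentences never
  cross experiments.
* **RandWordList** — one global permutation of all word tokens,
  re-partitioned into the original sentence lengths; a word may land in
  its original slot (only draw-without-replacement is enforced).
* **RandN** — per sentence, `|KeepN|` nouns drawn without replacement from
  the dataset-wide noun pool. **LengthControl** — n copies of a single
  fill word (default "thing", a mid-frequency noun; configurable).
* **Paraphrase** — externally supplied, normalized like all stimuli;
  validation reports per-sentence word-count differences and word-overlap
  as |shared types| / |union of types| (the overlap metric is a package
  choice; it is not standardized).

## Embeddings

The backend contract is per-token, per-layer vectors given an optional
preceding-context token sequence, plus per-token surprisal (nats) —
deterministic, and sensitive to preceding text only through the context
argument. Contextualized embedding of sentence i concatenates the
same-condition perturbed versions of all earlier sentences in its passage
(tokens with their periods, no separator tokens); the first sentence of a
passage has empty context, so its contextualized and decontextualized
representations coincide. Summary modes: `last_token` (default) and
`mean_token` (mean over the sentence's own tokens). Surprisal averages
include the terminal period — it is part of the input string.

## Encoding

Ordinary least squares (scikit-learn `LinearRegression`, lstsq-backed:
minimum-norm solution when features outnumber samples, which is the
realistic regime for wide language-model layers). 5-fold by-sentence
cross-validation by default; fold sizes as equal as possible with the
remainder on the earliest folds, assignment by uniform shuffle; folds
drawn independently per experiment; a by-passage scheme keeps passages
intact for leakage-sensitive analyses. Per-voxel Pearson r on held-out
sentences, with r defined as 0 when either side has zero variance (no
linear association is demonstrable for a constant signal); mean over
folds, median over voxels per participant; experiments fitted separately
and averaged **with equal weight** per participant. Equal weighting (not
sentence-count weighting) matches the aggregation convention of the
analysis this package implements; the unshuffled-fraction statistics below
are only consistent with equal weighting.

For substitution conditions under TrainIntact-TestPerturbed, the test-set
features are the *Original* features deranged within the applicable scope
group inside each test fold (singleton-in-fold sentences stay put), so all
such conditions train on identical intact representations and no perturbed
test sentence leaks into training. The fraction of sentences left
unshuffled is recorded, averaged over folds and (equal-weight) experiments.
Per-fold derangements are seeded from (global seed, experiment, fold,
scope) via CRC-stable keys, so runs are reproducible across processes.

Layer selection: argmax over layers of the participant-median score,
either per condition (default) or fixed on the Original condition; ties
break to the lowest layer.

## Noise ceiling

Each target participant's voxels are predicted from the concatenated voxel
responses of s subsampled predictor participants, using the same
cross-validated OLS mapping; per-(target, subsample) scores are the median
over target voxels of mean-over-folds r, averaged across experiments. Per
pool size: mean over subsamples, median over targets. The pool-size means
are fitted with `v(s) = v∞·s/(s+τ)` (bounded least squares, v∞ ∈ [0,1]);
v∞ is the ceiling. The saturating form is a package choice — the exact
extrapolation function is not fixed by the reference procedure — and is swappable; it matters little in practice because the
per-size means flatten quickly. On shared-signal synthetic participants
the fitted asymptote matches sqrt(SNR/(SNR+1)) to within ~0.02 under the
test conditions (5 participants, pools 1–4, 288 sentences).

## Follow-up analyses and statistics

Representational similarity: per layer, Spearman ρ between the original
and perturbed summary vectors of each sentence (over vector units),
averaged over sentences; pairs with a constant vector are skipped with a
warning and counted. The same summary vectors used for encoding are used
here. Similarity and predictivity are then correlated over all condition ×
layer points (Pearson).

Surprisal analysis: per condition, token surprisals are averaged within
each string and then across strings; the per-condition surprisal
*increase* over Original is correlated with the per-condition predictivity
*drop* from Original, so a positive r means more-surprising stimuli
predict brain responses less well (the sign convention matches how the
result is usually reported). Substitution conditions are excluded — their
pooled surprisal equals Original's by construction.

Statistics: two-sided dependent-samples t-tests on participant-aligned
scores, Bonferroni-corrected within the declared family (corrected p =
min(1, p·family)); identical samples give t = 0, p = 1; constant nonzero
differences are reported as undefined rather than imputed. Dispersion:
within-participant centered median absolute deviation, scaled by
1/0.6745 for normal consistency (scipy `median_abs_deviation`,
scale="normal"). The design-axis comparison concatenates participant
scores across a manipulation's conditions before the paired test, as the
reference procedure does; note this treats participant × condition entries as
independent pairs (pseudo-replication) and its p-values should be read
accordingly.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structural* properties the analyses rely
on: the reference hierarchy (384 sentences = 24 topics × 4 passages × 4
sentences with lengths 7–18; 243 sentences = 24 topics × 72 passages of
three or four sentences — 27 fours and 45 threes, the unique integer
split — with lengths 5–20), topic-specific content vocabularies with a
shared function-word pool (function rate 0.35, about the rate in ordinary
English text), and token classes known by construction. Sentences are not
grammatical English; the pipeline's operations are symbol-level, so
statistical structure is what matters. Reduced hierarchies (default 2 ×
12 topics × 3 passages × 4 sentences = 288 sentences) are used where
content-level simulation is needed; per-topic vocabularies default to 8
nouns / 5 verbs / 3 adjectives / 2 adverbs, sized so that a 64-dimensional
mock embedding retains a usable share of the content-word signal.

The n-gram table accumulates unigrams and windowed pairs over the stimuli
plus a topic-coherent background corpus from the same vocabulary,
guaranteeing nonzero marginals for every stimulus token — a stand-in for
a large external n-gram corpus.

The mock backend builds token vectors from hash-seeded per-word base
vectors (stable under vocabulary growth), an optional position-keyed
component weighted by `order_sensitivity`, an optional surprisal-keyed
distortion weighted by `surprisal_coupling` (emulating representation
degradation on unpredictable input), and a running mean over all
contributions (context included) whose per-layer mixing weight rises from
0.25 to 0.9 — later layers aggregate more context, as in deep causal
models. With `order_sensitivity=0` the final-period summary is exactly
order-invariant, which gives sharp expectations for word-order conditions.
Surprisal comes from a uniform, oracle, or Laplace-smoothed bigram model.

Simulated voxels are `w·f(sentence) + noise` with f either the bag of
content words or a random subspace of a backend layer; the noise-free
signal is standardized per voxel within experiment, so per-voxel SNR is
exactly 1/σ² and all participants share the signal — enabling the
closed-form ceiling check.

Known divergences from real data, hence limits on what green tests show:
no hemodynamics or temporal autocorrelation (noise is i.i.d. Gaussian);
participants share signal exactly (no idiosyncratic functional topology);
the bigram surprisal model cannot make function-word-only strings
surprising the way a real language model would, so the surprisal analysis
is exercised on the word-order and control families where the coupling
mechanism is well defined; and absolute predictivity magnitudes are not
comparable to real fMRI values — the tests check recovery, ordering, and
sign, not magnitudes.

## Numerical conventions

All randomness flows through numpy Generators seeded from explicit seeds;
per-stage and per-fold streams derive from the global seed via CRC32-based
spawn keys (process-independent, unlike Python's randomized `hash`).
Re-running any stage with the same config is byte-identical. Pearson
correlations are clipped to [−1, 1] against rounding; undefined
correlations are 0 (encoding, where a score is required) or skipped with
a warning (similarity, where the pair can be dropped). Derangement
sampling caps at 100 rejection tries. Fold counts must be ≥ 2 and no
larger than the number of groups.
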