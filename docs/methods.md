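# Methods

`ppispotter` classifies sentences by whether they assert a protein–protein
interaction (PPI). It combines three ingredients: a nine-feature sentence
representation, pool-based active learning with the breaking-ties
criterion, and a deterministic-annealing semi-supervised SVM. This note
records the models, the numerical choices, and what the synthetic fixtures
do and do not demonstrate.

## Sentence representation

A sentence is tokenized (maximal runs of word characters; every other
non-space character is its own token, with character offsets retained) and
mapped to nine features:

1. **Is negated** — NegEx-style detection. Findings are protein mentions
   and interaction trigger terms. A pre-negation phrase (e.g. "no",
   "lack of") opens a forward scope and a post-negation phrase (e.g.
   "was ruled out") a backward one. The scope spans a window of 5 tokens,
   but the token counter **resets at coordinating tokens** (`,`, `and`,
   `or`) and the scope closes at boundary punctuation (`.", `;`, `:`) or
   "but". The coordination reset is deliberate: negation distributes over
   coordinated lists ("No relevant changes in heart rate, body weight,
   and plasma levels of renin activity …" negates *renin* even though it
   sits 13 raw tokens after "no"), while an uncoordinated finding six or
   more tokens away stays un-negated. Pseudo-negation phrases ("not
   only", "no increase") are matched first and block any trigger they
   overlap. The per-finding statuses are returned; the feature itself is
   the boolean "any finding negated".
2. **Number of protein occurrences** — gazetteer named-entity matching
   with greedy longest match over token sequences (so "SigK factor"
   outranks "SigK"), non-overlapping, case-insensitive. Corpora that
   carry gold mention spans can bypass the gazetteer.
3. **Interactor name** — each token is conservatively stemmed (plural
   *-s/-es/-ies*, verbal *-ed/-ing* with consonant undoubling and
   magic-e restoration; never below three characters) and looked up in a
   trigger lexicon. The chosen occurrence is the first one strictly
   between the outermost protein mentions, else the first anywhere.
   The conservative stemmer exists because the trigger's part of speech
   must survive stemming; an aggressive stemmer would fold nouns and
   verbs together.
4. **Interactor POS** — from the lexicon (`term<TAB>POS` file); the tag
   set is closed and unknown tags map to OTHER.
5. **Interactor position** — character offset of the matched token in the
   raw text (a token index is recoverable from the stored offsets).
6.–8. **Words between / left of / right of** the outermost protein
   mentions. A quantity that is undefined — fewer than two mentions, or
   no token on that side — carries the sentinel −1.
9. **Link path** — whether a grammatical chain plausibly connects the two
   outermost proteins. The built-in provider is a heuristic stand-in for
   a dependency/link parser: *yes* iff a trigger term occurs between the
   outermost mentions with no sentence-boundary punctuation intervening.
   The provider is pluggable so a real parser can be dropped in.

**Encoding.** Booleans become 0/1 (plus a missingness indicator for the
link path), the interactor name is hashed into 64 indicator buckets
(md5-based, stable across processes), the POS tag is one-hot, and each
count/position is z-scored **using statistics fitted on training rows
only**, with sentinel −1 diverted to a dedicated indicator column rather
than polluting the standardization. Cross-validation refits the encoder
inside every fold.

## Linear SVM and probability calibration

The base learner minimizes
½‖w‖² + C Σᵢ sᵢ·max(0, 1 − yᵢ(w·xᵢ + b))
with per-sample weights sᵢ, solved by libsvm (SMO) at tolerance 1e-8 with
a one-million-iteration cap. Decision values are mapped to probabilities
by a one-parameter sigmoid on the margin-normalized score f̂ = f/‖w‖:

P(+1 | x) = 1 / (1 + exp(A·f̂(x))), A < 0.

The intercept is eliminated exactly by pinning P = ½ to the decision
boundary; A is fitted by maximum likelihood with smoothed targets
(N₊+1)/(N₊+2) and 1/(N₋+2), bounded in [−50, −10⁻⁶] to keep probabilities
finite and the orientation fixed. SVM and sigmoid are fitted sequentially
(SVM first), which is the stable reading of a jointly-estimated
"pragmatic approximation".

## Break-tie active learning

For two classes the gap between the best two class probabilities is
|P₊ − P₋| = |2P₊ − 1|. Each round queries the k pool instances with the
smallest gap (ties broken by ascending index, so selection is
deterministic), in a batch. Defaults: one round, budget 20, confidence
threshold θ = 0.9. The confidence split sends {P₊ ≥ θ or P₊ ≤ 1−θ} to the
machine-labeled set and everything else to the fuzzy set the expert sees.

## Deterministic-annealing semi-supervised SVM

Unlabeled labels are relaxed to Bernoulli probabilities pⱼ and the free
energy

F(w,b,p;T) = ½‖w‖² + C Σ_L H1(yᵢfᵢ) + C* Σ_U [pⱼH1(fⱼ) + (1−pⱼ)H1(−fⱼ)] − T Σ_U S(pⱼ)

is minimized by block-coordinate descent while T anneals down a geometric
schedule (defaults T₀ = 10, ratio 1.5, floor 1e-4). Both blocks are
exact: the (w,b) step is a weighted SVM with every unlabeled point
duplicated under both labels, and the p step is closed-form,
pⱼ = 1/(1 + exp(gⱼ/T)) with gⱼ = C*(H1(fⱼ) − H1(−fⱼ)). An optional class
balance constraint shifts g by a multiplier found by bisection so that
mean(p) hits a target ratio (tolerance 1e-8); it is off by default, and
when on in the driver, the target comes from the *initially* labeled set
(actively queried labels oversample the boundary and are not a
representative class sample).

The inner loop at fixed T stops when the symmetrized Bernoulli KL
divergence between consecutive p vectors drops below 1e-6 (that is the
operational form of the "consecutive-iteration agreement" stopping
statistic) or after 50 iterations; the outer loop stops when the total
entropy falls below 1e-6 per unlabeled point or the temperature floor is
reached. The returned state is the recorded one minimizing the
temperature-free objective E_p[F] — free energies at different
temperatures are not comparable because of the −T·S term, and selecting
on raw free energy would always return the hottest state.

Three optimizer-robustness details matter in practice:

* **Warm start.** The incumbent model starts at the supervised solution
  on the labeled data, so the very first block update must beat a
  sensible baseline rather than being accepted unconditionally.
* **Monotone safeguard.** libsvm is inexact at machine scale (and SMO can
  cycle on the duplicated, dual-degenerate subproblem — the weighted fits
  therefore run at tolerance 1e-6 with a 50k-iteration cap). A refit that
  would *raise* the free energy at fixed p is rejected and the incumbent
  kept. Together with the exact p step this makes within-temperature
  descent hold by construction.
* **Symmetry breaking.** Above the phase transition the spatially uniform
  label distribution is a fixed point: if the incumbent hyperplane
  collapses (w = 0), every gⱼ is equal, the update returns identical pⱼ,
  and no signal survives into the cold phase. When the update returns a
  spatially uniform p (std < 1e-6), the labels are re-seeded once per
  temperature from the supervised baseline's decision values — the
  annealing analogue of perturbing duplicated centroids in annealed
  clustering. Re-seed events are flagged in the trace; they are
  initialization events, not block updates, and never fire on
  well-separated fixtures.

No global optimality is claimed anywhere; the guarantees asserted by the
tests are descent, the temperature limit laws, and recovery on cluster
fixtures.

## The combined driver and baselines

`run_btda` executes the loop: per round, train + calibrate on the current
labeled set, split the pool by confidence, query the oracle on the most
tied fuzzy instances; after the last round, anneal with the enlarged
labeled set, warm-starting soft labels at the calibrated machine
probabilities on the high-confidence set and ½ elsewhere. In the
annealing stage the per-point unlabeled weight is C*·C·|L|/|U| — the
**equal-mass convention**: the pool's total influence equals C* times the
labeled set's. With a per-point weight of 1 and |U| ≫ |L| the homotopy
cannot bootstrap orientation from the labeled anchors and collapses; the
pairing of the two constants is a convention the transductive-SVM
literature leaves to the implementation, and equal mass is the choice
here (exposed through `RunConfig.C_star` as a multiplier).

Baselines: `run_supervised` (labeled set only); `run_rs` (seeded uniform
oracle queries, then supervised; an optional `post_da` flag adds the
annealing stage and is off by default); `run_cluster` (seeded k-means,
k-means++ with 10 restarts; each cluster takes the majority label of its
labeled members, clusters without any take the label of the nearest
labeled point by centroid distance, degenerate one-class propagation
falls back to nearest-labeled-point labels); `run_bt` (active learning
rounds, then supervised on the enlarged labeled set).

## Evaluation

Positive-class precision/recall/F1 with zero-division-to-zero, rank-based
AUC with ties at ½, stratified seeded k-fold cross-validation (stratified
because PPI corpora are class-imbalanced and unstratified folds are
unstable at small per-fold counts), and transductive learning curves:
for each labeled-set size, labeled sentences are drawn at random and the
remainder is both the unlabeled pool and the test set, averaged over
seeded repeats.

## Synthetic data: what it shows and what it does not

`make_clusters` draws Gaussian clusters — the geometry the cluster
assumption of semi-supervised learning is about — with a stratified
labeled split, gold labels retained on the unlabeled pool (for the
simulated oracle and transductive scoring), and optional label-flip
noise. Two standard regimes are used throughout the tests: well-separated
(centers ±(2,0), σ = 0.5; one label per class, 100 unlabeled), where
annealing recovers ≥95% of generating labels from two labels, and
overlapping (centers ±(1,0), σ = 0.8; four labels, 200 unlabeled, oracle
budget 10), where over 20 paired seeds the mean test F1 orders
combined ≥ break-tie ≥ supervised.

`make_sentences` fills short English templates with sampled single-token
protein names and third-person trigger forms. Positives place a trigger
between two proteins; negatives lack a trigger or negate it with a
pre-negation phrase; gold labels and mention spans are recorded. The
default corpus is 500 sentences at positive fraction 0.5, matching the
roughly balanced composition of the smaller hand-annotated PPI corpora.

The templated corpus is nearly separable in the nine-feature space, so
end-to-end cross-validated scores sit near 1.0. That validates the
plumbing — features discriminate, encoders do not leak, folds are
reproducible — but says nothing about performance on natural biomedical
text, whose lexical variety, parse ambiguity, and annotation noise the
templates do not emulate. Likewise the Gaussian fixtures validate the
optimization and the relative ordering of the methods under the cluster
assumption, not absolute performance on real corpora.

## Problem sizes and determinism

Test and acceptance runs use the fixture sizes above (≤20-point datasets
for the QP cross-check, 100–200-point pools, 500-sentence corpora,
10-fold CV, 20 seeds per simulation), chosen as the smallest sizes at
which the compared quantities are stable. Every stochastic procedure
takes an explicit seed and is bitwise reproducible given it; the
annealing loop itself is deterministic.

## Known limitations

* The link-path provider is a heuristic; it reports *yes* only when a
  trigger lies between the mentions, which correlates with, but does not
  implement, grammatical connectivity.
* The stemmer is intentionally weak; irregular verb forms ("bound" for
  "bind") do not map to their trigger stems.
* The negation scope model handles coordination but not clause-level
  syntax ("although no inhibition was seen, X binds Y" negates nothing
  in the second clause only because of the comma reset heuristic).
* Annealing cost is dominated by repeated weighted SVM fits; pools beyond
  a few thousand points need a warmer T floor or a looser inner
  tolerance.
* With the balance constraint on, a badly estimated target ratio directly
  biases the labeling; the constraint helps only when the labeled sample
  (or prior knowledge) pins the ratio reasonably.
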