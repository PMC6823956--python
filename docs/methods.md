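# Methods

This note documents the models and procedures `riskdomains` implements,
the design of the synthetic data the tests run on, and the numerical
choices made where the design was genuinely open.

## Problem setting

Sentences from psychiatric clinical narratives are classified into seven
risk-factor domains (Appearance, Mood, Interpersonal, Occupation, Thought
Content, Thought Process, Substance). The task is open-world and
multilabel: a sentence may express several domains, and a sentence
expressing none is assigned the fallback label *Other*, which is never a
training class. Training labels come from weak supervision; only the test
corpus carries adjudicated human labels.

## Weak supervision

A clinician lexicon maps each domain to single-token keywords and
2–3-token keyphrases (multiword expressions, MWEs). A sentence joins the
training corpus with label *D* when it contains one of *D*'s keywords as a
whole token or a keyphrase as a contiguous token span. Every training
sentence receives exactly one label: a sentence matching several domains
is assigned the domain with the most matching occurrences (*majority*
policy — such sentences genuinely may involve several domains, which is a
known, accepted source of training-label noise in weakly supervised corpus
construction); ties remain ambiguous and are excluded, as are sentences
with no hit. A stricter `policy="exclude"` that drops every multi-domain
hit is available.

The per-domain *megadocument* — all training sentences of one domain — is
the unit for three downstream steps: TF-IDF mining, baseline similarity,
and RBF prototype clustering.

**TF-IDF MWE mining.** Candidate bigrams/trigrams are ranked per domain
with term frequency = raw count in the domain megadocument and a smoothed
inverse document frequency over the megadocuments,
`idf = ln((1 + D)/(1 + df)) + 1`. The smoothed form is strictly positive,
so a degenerate single-megadocument corpus reduces to plain frequency
ranking; an unsmoothed `ln(D/df)` would rank *everything* below rare noise
once `df = D` makes the idf negative. Mining output is a human-review
artifact; accepted phrases are merged into the lexicon
(`DomainLexicon.with_keyphrases`), never auto-accepted.

**Preprocessing order.** Tokenize (lowercase; punctuation stripped except
intra-token `/`, `-`, `+`, `'`), merge accepted MWEs into underscore
tokens (leftmost-first, longest-first, non-overlapping, idempotent), then
Porter-stem the remaining tokens. Merged MWE tokens are exempt from
stemming by construction. The Porter stemmer is implemented in-package
from the classic algorithm and validated against its canonical
input/output pairs.

## Encoding

Sentences are embedded as 512-dimensional vectors behind a two-kind
encoder contract:

* `pretrained_adapter` — a registration slot for an external sentence
  encoder (raw text in, matrix out). If none is registered the call fails
  loudly; nothing is silently substituted. Adapter output is never used in
  tests.
* `hashed_fallback` — the default and the encoder under test: each token
  is hashed (BLAKE2, keyed by the encoder seed) to a dense ±1 pattern,
  patterns are summed over the merged+stemmed token bag and L2-normalized.
  Empty sentences map to the zero vector and are flagged degenerate
  downstream. Distinct tokens give near-orthogonal patterns at d = 512, so
  shared vocabulary — not word order — drives similarity.

The fallback is a bag-of-words model: it reproduces the *separability
structure* a pretrained encoder would expose (shared vocabulary between
domains ⇒ overlapping regions) but none of its compositional
generalization. Conclusions from the test suite are therefore about the
pipeline's mechanics and relative orderings, not about absolute
performance on real clinical text.

## Classifiers

**Cosine baseline.** Each domain is summarized by the L2-normalized
centroid of its megadocument's sentence vectors; a test sentence's score
for a domain is the cosine to that centroid (`aggregate="centroid"`,
default). The exact pairwise variant (`aggregate="max"`: best cosine
against every member sentence, quadratic in corpus size) is provided for
sensitivity analysis.

**MLP.** 512 inputs (dropout 0.2) → 250 ReLU (dropout 0.5) → 7 sigmoid
outputs; Adam (lr 0.001, β₁ 0.9, β₂ 0.999, ε 1e-8 — framework defaults),
categorical cross entropy, 60 epochs, batch 128, Glorot-uniform
initialization, seeded shuffling and dropout. The categorical cross
entropy over sigmoid outputs follows the standard deep-learning-framework
convention for probability inputs: predictions are renormalized to sum to
one *inside the loss only*. A literal `-Σ y log p` over independent
sigmoids has zero gradient on every non-target output (nothing is ever
pushed down) and empirically saturates all outputs to 1; the renormalized
form is what the major frameworks compute for this layer/loss pairing and
trains correctly. The model's reported scores remain the raw, unnormalized
sigmoids — independent per-domain likelihoods, deliberately not a softmax.

**RBF network.** 512 inputs (dropout 0.2) → 700 Gaussian hidden units → 7
linear outputs; MSE loss, Adam, 50 epochs, batch 128. Hidden prototypes
are fixed before training: k-means (k-means++ seeding, 10 restarts, best
inertia, seeded) is run on each domain megadocument individually, 100
centroids per domain (700/7). Every unit shares one width derived from the
maximum pairwise Euclidean centroid distance `d_max`; the activation is
`exp(-‖x − p‖² / (2σ²))`. Only the output layer is trained. Width rules:

* `dmax_sqrt2m` — the classical heuristic σ = d_max/√(2m), m = number of
  prototypes. With 700 prototypes crowding seven clusters on the unit
  sphere this collapses σ to ~d_max/37 and the kernel has no support.
* `dmax_sqrt2c` (default) — the same normalization applied at the level of
  the well-separated clusters actually present, the c = 7 domains:
  σ = d_max/√(2c). This is the operating default.
* `dmax`, `custom` — σ = d_max, or user-supplied.

**Single-label training, multilabel inference.** Both networks train on
one-hot targets (the weakly supervised corpus is single-label) but emit
seven independent scores at inference, so thresholding can assign several
domains or none.

## Open-world thresholding

Domains differ in the homogeneity of their language, so scores are not
comparable across domains. Each domain *D* gets

```
threshold_D = mean(scores_D) + α · sd(scores_D)
```

with population standard deviation (the n vs n−1 distinction is
immaterial at corpus scale; population form is fixed for determinism) and
"meets threshold" read as ≥. Reference α: 0.5 (MLP), 1.25 (RBF); the
baseline uses 0.5. α is a precision/recall dial set by its users by trial
and error, not learned.

**Score population.** The statistics are computed, by default, over the
model's scores on the *unlabeled target corpus* (`"target"`): the
formula's stated virtue is adapting to target data whose average
similarity to the training distribution varies, which requires the
population to be the target corpus's own scores. No gold labels are
consulted. Two alternatives are provided for sensitivity analysis:
`"train_in_domain"` (each domain's statistics from its own training
sentences' scores) and `"train_all"`. Train-derived thresholds
systematically overshoot whenever the model fits its training set closely
— training scores saturate above the test-score range and recall
collapses — which is why they are not the default.

## Evaluation

Per-domain true/false positives and false negatives are counted by set
membership between gold and predicted label sets (gold label *order*
encodes prevalence and is ignored for scoring; a separate first-domain
accuracy mirrors the "most prevalent domain only" view). Macro precision,
recall and F1 are unweighted means over the seven risk domains; domains
with zero support are excluded from the mean with a defined-as-zero row in
the table. A secondary macro including Other is reported alongside, since
reasonable conventions differ on whether the fallback class belongs in the
headline average.

## Annotation agreement

Annotators assign ordered label lists. Two categorical reductions make the
multilabel data amenable to kappa statistics: `label_set` (each distinct
set is one category — the "overall" view) and `first_label`. Fleiss's
kappa uses pooled category marginals for chance agreement; the
Davies–Fleiss multi-kappa keeps the same observed pairwise agreement but
averages annotator-specific marginal products over annotator pairs. Both
are validated against independent brute-force pair-counting
implementations and (Fleiss) against statsmodels. Total agreement is
defined set-theoretically as all annotators producing identical label
sets; total disagreement as every annotator pair's sets intersecting
emptily. Gold adjudication takes the exact label set shared by at least
two of three annotators; remaining items go to a manual-review list,
never auto-labeled. Annotator accuracy against gold is strict set equality by
default, with a first-label variant.

## Synthetic data

The generator emits word-like nonsense tokens (no clinical text, no PHI)
with the statistical shape the pipeline cares about. Design:

* **Vocabularies.** 50 tokens per domain; a configurable symmetric overlap
  matrix shares tokens between domain pairs. The default plants 20%
  pairwise overlap among Interpersonal/Mood/ThoughtContent — the
  confusable trio occupying one noisy region — and none elsewhere. A
  250-word background vocabulary follows a Zipf (s = 1) frequency law:
  everyday words are heavily reused, which realistically degrades naive
  centroid similarity (frequent-word dominance) while leaving supervised
  models to learn around it.
* **MWEs.** Per domain, 2–3-token sequences unique as sequences, whose
  component words are drawn from one shared pool of mid-frequency
  background words (ranks 20–29). Components are therefore individually
  quotidian — they appear in ordinary background use and in *other*
  domains' expressions — and only the merged expression is informative,
  which is the phenomenon MWE merging exists to exploit.
* **Sentences.** 8–24 tokens; in-domain sentences draw each slot from
  their domain vocabulary with probability 0.6 (clinical sentences about a
  domain are dominated by its vocabulary; this also compensates for the
  fallback encoder generalizing less than a pretrained one), the rest from
  background with a 5% chance of a stray token from an unrelated domain
  (vocabulary is context-sensitive). 20% of domain sentences additionally
  carry an MWE and thin out their plain-keyword signal. Test corpora
  contain ~5% two-domain sentences (labels ordered by token prevalence)
  and ~6% background-only Other sentences — proportions matching published
  sentence-level psychiatric annotation corpora. Training pools are
  single-domain by construction, mirroring single-label weak supervision.
* **Planted lexicon.** 85% of each domain's unique keywords and of its
  MWEs are exported, so weak labeling has partial coverage and is
  imperfect by design.
* **Determinism and paired experiments.** All draws derive from one seed
  through fixed, named substreams (vocabulary per domain, shared pools,
  background, MWEs, lexicon per domain, train, test). Regeneration is
  byte-identical, and changing one knob — say the trio overlap — leaves
  every unrelated component's draws untouched (common random numbers), so
  paired comparisons isolate the manipulated factor.
* **Simulated annotators.** Each annotator reproduces gold with
  probability 1 − noise; corrupted items substitute labels through a
  confusion kernel concentrated on overlapping domain pairs (or a uniform
  kernel for chance-level controls).

**Reference conditions.** The reference bundle is 2000 training / 500 test
sentences at seed 13. The MWE-effect condition (`small_n_mwe_config`)
uses 2 MWEs per domain at 90% incidence with domain-token rate 0.15, so
the expressions carry most of the signal; the comparison holds the weakly
labeled corpus fixed and toggles only the merging step
(`mwe_mode="no_merge"`), and MLP epochs scale inversely with corpus size
(reference: 60 epochs at n = 2000) so both arms see comparable
optimization steps.

## Known limitations

* **MLP thresholds in the scaled-down regime.** At 2000 training
  sentences the MLP separates its training corpus almost perfectly; since
  the renormalized cross entropy constrains only score *ratios*, raw
  sigmoid magnitudes on less familiar test sentences drift toward zero and
  the per-domain score columns become extremely skewed. The
  `mean + 0.5·sd` threshold then sits far above the balanced operating
  point: macro precision pins at 1.0 with recall ≈ 0.71 (macro-F1 ≈ 0.83
  on the reference bundle), while per-domain F1-optimal thresholds on the
  *same scores* reach ≈ 0.90. The RBF, whose MSE-trained linear outputs
  are magnitude-calibrated, does not exhibit this and reaches ≈ 0.88 at
  α = 1.25. The α values are corpus-tuned constants; on data large and
  noisy enough that the network cannot saturate, sigmoid columns are
  better conditioned and the formula behaves.
* The cosine baseline's weakness on the default bundle (macro-F1 ≈ 0.45)
  is dominated by Zipf background words in the centroids; it is a faithful
  rendering of why unsupervised similarity trails trained classifiers, but
  the magnitude of the gap is a property of the synthetic world.
* The MWE-merging gain shrinks from n = 200 to n = 2000 at the reference
  seed; across other seeds the direction is within experiment noise at
  these corpus sizes. The small-n gain itself (≥ 0.05) is robust.
* The fallback encoder ignores word order entirely; any conclusion
  requiring compositional sentence semantics needs a pretrained encoder
  through the adapter.
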