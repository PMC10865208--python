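# Methods

This note documents the models, procedures and design choices of
`triage-enrich` — what each stage assumes, which knobs matter, and what
the synthetic validation does and does not demonstrate.

## Problem setting

Patients with chronic low back pain referred to a multidisciplinary
spine centre are triaged to one of four paths: rehabilitation (label 1),
anesthesiologic pain therapy (2), neurosurgery (3), or a minimal
"other" intervention (0). A decision-support model predicts this triage
from a baseline questionnaire (work, pain, history, psychosocial items,
pre-scored as numbers). The package quantifies the added value of
*enriching* that quantitative table with two kinds of information mined
from the free-text referral letter: the referring clinician's stated
**referral reason** (5 categories: second opinion, anesthesiology,
rehabilitation, advice, treatment options) and the patient's stated
**goal** (4 categories: know the cause, pain reduction, better
functioning, advice). The comparison is between an extended data set
(ED, questionnaire + letter flags) and a basic data set (BD,
questionnaire only) run through the identical split, balancing,
selection and models.

## Letter mining (lexicon + regular expressions)

Letters are normalized (lower-casing, diacritic transliteration to
ASCII, whitespace collapse) and a configurable list of unification
rewrites maps variant spellings onto canonical forms (e.g.
`tweede mening` → `2e mening`) before anything else, so that even
section markers with variant spellings are found. Section markers
(e.g. `reden van verwijzing`, `hulpvraag`) split the letter into a
referral-reason segment and a patient-goal segment: each segment runs
from its marker to the next marker of either kind or the end of the
letter. A category flag is set iff at least one of its code-word
patterns matches *inside its own segment*; several categories may fire
at once (a letter can ask for pain reduction *and* a second opinion).
Matching is substring-based without word boundaries because Dutch
compounds embed code words (`pijnklachten` contains `pijn`). When no
marker matches at all, both families are searched over the whole letter
(configurable, default on) — real letters are frequently unstructured.
Only a patient's earliest letter is mined; date ties break by input
order.

The shipped lexicon is a reconstruction from published exemplar terms
and documented common variants, not a validated clinical resource; a
deployment against real letters is expected to extend it, which is the
point of keeping the whole lexicon in one YAML file.

No negation handling, spelling correction or statistical language model
is involved: the method is deliberately transparent, and its failure
modes (a negated "geen revalidatie" still fires) are inherited by
design.

## Cohort assembly

Patients are included iff they have a letter in which at least one
category was recognised. The ED merges the questionnaire columns with a
configurable subset of the nine flags; the default carries four of the
five referral reasons plus all four goals. `SecondOpinionReRe` is the
one left out by default because its content (second opinion / further
diagnostics) duplicates the `MoreCausePaG` goal category; the choice is
a config list, not a constant. The evaluation split draws exactly
`per_class` (default 50) rows of every class uniformly without
replacement — a deliberately balanced held-out set of original (never
oversampled) patients — and everything else becomes training data.
Because the draw depends only on labels and seed, the ED and BD tag
identical rows.

Z-scoring is applied per split and per column after splitting.
`sd_convention` chooses the divisor: the default `population` (divide
by n) matches the convention of the standard scaler in scikit-learn;
`sample` (n−1) is provided because descriptions of z-scoring often
assume it. Zero-variance columns map to 0, missing cells stay missing,
and binary flag columns are scored like any other column. A
`train_params` mode reuses the training moments for the evaluation
split (the leak-free deployment convention); the default normalizes
each split with its own moments.

Missing questionnaire values are never imputed. They survive assembly
as NaN; feature ranking is missing-tolerant (below), and the model
stage drops rows that are incomplete *on the selected features only* —
enforcing completeness as late as possible retains the most rows.

## SMOTE balancing

The training split is heavily imbalanced (the study proportions are
roughly 43 : 21 : 15 : 5 rehabilitation : other : anesthesiology :
neurosurgery). Every minority class is oversampled to the majority
count: a synthetic row is `x + u·(x_nn − x)` with `x` a uniformly drawn
minority row, `x_nn` one of its k = 5 nearest same-class neighbours
(Euclidean), and `u ~ Uniform(0,1)`. Original rows are preserved
verbatim and synthetic rows are tagged. When a class has fewer than
k + 1 members, k clamps to class size − 1 with a warning; a singleton
class is an error. Balancing happens after normalization and after
feature selection/complete-case filtering, so the oversampler never
sees missing values. Binary flag columns are interpolated like any
numeric column, so synthetic rows may carry fractional flag values;
users wanting hard flags can round, but the classifiers do not care.

## ReliefF feature ranking

For every training instance (m = n, deterministic) the k = 50 nearest
same-class hits and the k nearest misses *per other class* are located
using the summed range-normalized per-feature difference as the
distance. Each feature's weight accumulates

    W[f] += ( Σ_{c ≠ class(x)} w_c · meandiff_f(x, NM_c) − meandiff_f(x, NH) ) / m

with miss-class weights `w_c = P(c)/(1 − P(class(x)))` by default
(`uniform` gives 1/(C−1)). Larger W = more class-relevant; a raw score
S with the opposite orientation (hit-diff minus miss-diff, miss classes
unweighted) is reported alongside for reference. Per-feature
differences are `|x_i − x_j| / range(f)`, which bounds every weight by
1, makes the ranking invariant to positive rescaling of any feature,
and reduces to an exact-match indicator for 0/1 flags. A difference
involving a missing value contributes the feature's mean observed
normalized difference, so incomplete rows still participate. Constant
features score exactly 0. Ranking runs on the pre-balancing training
rows only: oversampled points would manufacture artificial near hits.

Selection keeps features with `W ≥ tau`. The package default
`tau = 0.07` sits at the scale where, on real questionnaire data of
this kind, the weakest reported selected features score (~0.07) — but
tau has no universal value: it must sit between the noise floor and the
weakest signal of the data at hand, and the synthetic study uses its
own calibration (below). An empty selection raises rather than
silently proceeding.

## Classifiers

kNN (k = 5), SVM (RBF kernel, C = 1) and a single-hidden-layer MLP
(64 rectified-linear units, Adam, cross-entropy loss, initial learning
rate 0.01, at most 300 epochs with early stopping on a held-out quarter
of the training rows, patience 30) share one train/predict interface.
The comparatively high initial learning rate and long patience are a
small-data choice: with a few hundred training rows and a tiny
validation share, the default slow schedule stalls inside the patience
window before learning anything. Stratified 4-fold cross-validation on
the training table records per-fold accuracy and macro F1 as
diagnostics; the final model refits on all training rows, and the fixed
balanced evaluation set is never touched during training. Each
model/condition pair is trained `n_runs` times (default 4) with
run-offset seeds; kNN and SVM are deterministic so their runs coincide,
while MLP runs differ in initialization.

## Scoring

Per-class one-versus-rest precision `P = TP/(TP+FP)`, recall
`R = TP/(TP+FN)` and `F1 = 2PR/(P+R)` come from the 4×4 confusion
matrix (rows = annotated, columns = predicted). "The" F1 of a model is
the unweighted macro mean — the natural summary for a deliberately
balanced evaluation set — with micro and support-weighted means
reported alongside. A class with `P + R = 0` contributes F1 = 0 with a
logged warning. The headline comparison is the per-model difference
`100·(F1_ED − F1_BD)` in percentage points, averaged over runs.

## Synthetic cohort generator

The generator emulates exactly the structure the pipeline consumes:

- **Labels** from the study's class proportions
  (0.249, 0.472, 0.189, 0.090 for other/rehab/anesth/neuro).
- **Questionnaire**: 40 unit-variance features, the first 10
  informative via class-mean shifts of `effect_size` (default 1.0 SD;
  the replicated study uses 0.5) along per-feature random permutations
  of (−1, −⅓, ⅓, 1), so different items separate different class pairs.
  Every second feature is discretized to a 1–5 ordinal item through
  fixed cut points shared across classes, so class signal survives
  binning. 5% of cells go missing completely at random.
- **Letters**: 83.4% of patients get one templated Dutch letter with
  marker-opened sections; each category's canonical code word is
  embedded independently with a per-class probability calibrated to the
  published per-category training-split proportions (e.g. the
  anesthesiology referral reason appears in ~45% of anesthesiology-class
  letters vs 2–10% elsewhere). Filler text is drawn from a vocabulary
  verified to match no code word or marker, which is what makes the
  100%-round-trip extraction check meaningful.
- **Signal dial**: `inject_letter_signal(spec, s)` interpolates every
  per-class probability between the prior-weighted marginal (s = 0,
  flags carry no label information) and the calibrated class pattern
  (s = 1). This isolates the causal claim: any ED−BD gap at s = 0 is
  spurious.

What the generator does *not* emulate: real Dutch clinical prose,
correlated questionnaire items, informative missingness, multiple or
contradictory letters per patient, and lexicon misses/false hits
(extraction on templates is exact by construction). Passing synthetic
tests therefore validates the machinery and the logic of the
comparison, not extraction recall on real letters.

## The replicated synthetic study

One replicate = generate a 2000-patient cohort at a given signal
strength, run both conditions through the shared split, and record each
model's evaluation macro F1. The study runs 20 replicates at strength 1
(expect ED > BD for every model in nearly every replicate) and 20 at
strength 0 (expect the mean gap per model to vanish). Replicates use
`n_runs = 1` — the replicate axis already averages over training
randomness, and kNN/SVM are deterministic anyway. Problem sizes
(n = 2000, 20 replicates) were chosen so one replicate runs in seconds
and a full study in minutes on one CPU.

Two study conventions differ from the pipeline defaults, for reasons
worth recording.

*Evaluation normalization.* The study z-scores evaluation rows with the
training moments (`train_params`). Because the evaluation set is
deliberately balanced (25% per class) while training keeps the cohort's
imbalance, normalizing each split by its own moments re-centres every
class-informative feature against a different class mix — a systematic
train/eval misalignment that adds noise and bias to every model and
model comparison. Reusing the training moments is also the deployment
convention.

*Selection threshold.* The study uses `tau = 0.015`, calibrated with an
explicit grid on cohorts from this generator. The calibration exposed
two opposing failure modes of threshold selection. First, ReliefF
weights of *class-independent binary flags* are inflated — up to
~0.02–0.03 here, versus ≤ ~0.009 for continuous noise — because
neighbour selection intensity differs across unequal class sizes and
the inflation scales with a feature's difference variance, which is
maximal for a balanced 0/1 attribute; a low threshold therefore admits
noise flags into the ED in nearly every replicate, and pure-noise
dimensions systematically *hurt* distance-based models. Second, a high
threshold invites cross-condition selection flips: the ED ranking
measures distances in a metric containing the extra flag columns, which
slightly depresses questionnaire-feature weights, so a near-threshold
informative feature can survive in the BD but drop from the ED — rare
but large, single-replicate swings. No threshold separates the two
populations perfectly (weak informative features overlap the binary
noise ceiling); 0.015 balances the two costs. The package-level default
(`tau = 0.07`) is unaffected: it matches the weight scale reported for
real questionnaire data of this kind, and the lesson of the calibration
is precisely that tau is a per-data-set quantity.

## Numerical and tie-breaking conventions

- Neighbour ordering is by (distance, row index), stable, in both the
  vectorized implementation and the brute-force test oracle.
- Per-stage seeds derive from the master seed by hashing
  `(seed, stage name)` (SHA-256, reduced below 2³¹), giving independent
  streams from a single knob; reruns of an identical config are
  bit-stable and the manifest records config and results digests.
- Percentage-point differences are computed on F1 × 100.

## Known limitations

- The lexicon is a reconstruction; extraction quality on real letters
  is untested and certainly below the synthetic 100%.
- Complete-case enforcement on the selected features can shrink small
  classes sharply when many features are selected; the row ledger in
  the manifest makes the shrinkage visible, but the package offers no
  imputation by design.
- The per-split z-scoring default normalizes the evaluation split with
  its own moments; this is distribution-shifting relative to deployment
  (where training moments would be reused) — both modes exist, and the
  comparison is unaffected because both conditions share the convention.
- SMOTE assumes locally convex minority regions; with 59-member classes
  the synthetic points are near-duplicates of real ones.
- ReliefF weight inflation for high-variance binary attributes under
  strongly unequal class sizes (see the threshold calibration above)
  means flag features and questionnaire items are not scored on a fully
  comparable scale; rankings that mix the two should be read with that
  bias in mind — on real data as much as on synthetic data.
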