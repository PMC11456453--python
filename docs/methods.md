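# Methods

This note documents the models, rules and numerical choices behind
`speechmarker`: how the 15 connected-speech features are defined and
computed, what the statistical protocols do, how the synthetic cohort
generator is built and calibrated, and where genuinely open design choices
were resolved. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Transcript model and cleaning rules

A transcript is one participant's speech over up to three pictures. Tokens
carry a surface form, a Chinese-character count, an upstream POS tag mapped
to a coarse class (NOUN, VERB, ADJ, PRON, ADV, the two passive markers, or
OTHER), and disfluency flags. Utterances carry the silent gap, in seconds,
to the next utterance. POS tagging, utterance segmentation and disfluency
flagging are upstream annotation tasks; the package validates and consumes
them.

Cleaning is applied in a fixed order, once, before any feature is computed:

1. **Repetition collapsing.** Runs of an identical adjacent word within an
   utterance keep one copy (the first); runs of identical adjacent
   utterances keep the last copy, so the survivor carries the gap to the
   next distinct utterance. Surface-identical immediate repeats qualify
   whether or not the annotator flagged them.
2. **Filler separation.** Filled pauses are removed and tallied — they are
   hesitations, not words. An utterance emptied by the removal is dropped
   and its trailing gap added to its predecessor's gap; two sub-threshold
   gaps can thereby merge into one long pause, which is intended (the
   silence was continuous but for the filler).

Revision-flagged fragments are retained as words; only repetitions are
excluded. Incomplete-flagged tokens count toward total words and character
totals but never toward content words.

Two thresholds govern pauses, both **inclusive**: 120 ms for an automatic
utterance boundary (used only when a transcript arrives unsegmented —
manually segmented input is taken verbatim, because the human segmentation
also used semantic and syntactic completeness, which is not implementable
from duration alone), and 2 s for a long pause ("2 s or more" is explicit in
the definition; 120 ms inclusivity was chosen for consistency).

**Sentences** are utterances containing a noun or pronoun followed — not
necessarily adjacently — by a verb or adjective. Any verb-class token is
accepted as a potential main verb; Mandarin serial-verb disambiguation is
out of scope. **Passive constructions** require realized flanking
structure: a *bèi* marker with a noun/pronoun before it and a verb after, or
a *ba* marker with a noun/pronoun after it and a verb after that. A bare
marker counts zero; each marker counts at most once.

## Feature definitions and conventions

The 15 features are computed per image and averaged (unweighted) over the
available images; a feature undefined for an image (for example MLS when an
image has no sentences) is excluded from that feature's average rather than
treated as zero, so group means are not biased toward zero. All undefined
ratios are reported as missing (NaN), never 0.

Conventions that needed a decision:

* A "word" for TW/UW/MLS is any non-filler token, particles and passive
  markers included; only filled pauses are excluded from word counts.
* CWF averages corpus frequency over content-word **tokens** (a reading of
  "all content words"); a switch (`cwf_over_tokens=False`) gives the
  type-wise average. Out-of-vocabulary content words are skipped from both
  numerator and denominator under the default `skip` policy, or imputed at
  the lexicon's minimum frequency under `min_frequency`.
* MLU divides the total character count of all word tokens by the utterance
  count (a global ratio, not a mean of per-utterance ratios).
* Unique-word identity is exact surface-form match after repetition
  collapsing; no lemmatization.

## Group comparison

Each feature is compared between groups with OLS
`feature ~ group + age + education` on that feature's complete cases. The
feature is standardized first so group coefficients are comparable across
features (p-values are unaffected). Raw per-feature p-values are reported;
Benjamini-Hochberg adjustment is available behind a flag but off by
default, matching the per-feature reporting convention of the field.

## Classification protocol

Three predictor sets — 15 linguistic features, 2 biomarkers (SUVR,
hippocampal volume in cm³), and their union — each always include age and
education as ordinary predictors. The covariates are deliberately not
protected in feature selection: they compete like any feature and are
frequently selected, which is informative in itself.

Per repeat (10 stratified 70/30 splits):

1. **RFE.** For every subset size 1..p, repeated stratified k-fold CV
   estimates the model's accuracy on the top-s features, with the ranking
   recomputed from model-specific importance at every elimination step
   inside each training fold. The size with the best mean accuracy wins;
   ties go to the smaller size (a documented local choice). A final
   elimination pass on the whole training set yields the selected set.
2. **Tuning.** Grid search with repeated stratified CV scored by ROC AUC:
   SVM cost log-spaced over [0.25, 128] and RBF width spanning [0.1x, 10x] a
   median-heuristic estimate (10 values each); KNN odd neighbor counts
   5..23; random-forest candidate-variables-per-split integer-spaced 1..p.
   The original study used library-internal default ranges; these are
   re-specified explicitly and configurable. Predictors are standardized
   inside the CV pipeline (statistics from training folds only).
3. **Evaluation.** AUC is the rank statistic over score pairs with ties
   counted one half; specificity, precision, recall and F1 use a 0.5 score
   threshold with early-AD as the positive class. SVM decision values are
   mapped through a logistic (Platt) fit on the training data so threshold
   metrics are defined.
4. **Importance.** Random forest: accumulated Gini-impurity decrease. SVM:
   training-AUC change when each predictor is removed and the model refit at
   fixed hyperparameters. KNN: permutation importance (mean accuracy drop
   over 10 column permutations). Scores are clipped at zero and scaled so
   the maximum is 100. Mean importance per feature is computed over the
   repeats in which RFE selected it, alongside its selection frequency.

The protocol intentionally optimizes **accuracy** inside RFE but **AUC** in
tuning — both are as specified, despite the apparent inconsistency.

One departure from common library defaults: the random forest's minimum
leaf size scales with the training set (≈1% of n, fully grown below
n=200). Fully grown trees produce high-variance class-probability
estimates whose rank errors depress test AUC measurably in low dimensions;
the scaled leaf keeps probability ranking faithful at simulation sizes
while leaving study-scale cohorts (n≈80) at the conventional fully-grown
setting.

All randomness flows from a single master seed through per-repeat seed
sequences; reruns are bit-identical.

## Score regressions

Candidates (15 features + age + education) pass a single global VIF screen:
iteratively remove the predictor with the largest VIF while it exceeds 5.
The threshold is strict — a VIF of exactly 5 survives — with a 1e-9
relative guard against floating-point noise; ties and infinite VIFs drop
the later-listed predictor. The screen is global rather than per outcome
because the study reports one retained set across all nine models.

Each outcome is then modeled on its complete cases: RFE ranked by |t| in
the joint fit and sized by repeated cross-validated RMSE (smaller subset on
ties), followed by OLS of the outcome (native scale) on standardized
predictors. AIC/BIC use the Gaussian log-likelihood convention with the
constant included, so values are comparable to standard statistical
software. Residual diagnostics report skewness, kurtosis, an omnibus
normality test, the residual-vs-fitted slope (zero by construction for OLS;
reported as a sanity flag) and a curvature term (residuals on squared
fitted values), flagging only — no automatic refitting.

## Synthetic cohort generator

The generator is parametric-by-construction: it emits token streams with
fillers, repetitions, passives and timed gaps so that the full cleaning and
extraction pipeline is exercised, never bypassed. Three identities make the
calibration exact where a closed form exists:

* Words are sampled from a class-mixture-weighted, concentration-tempered
  lexicon distribution with immediate repeats rejected. The first token of
  each utterance is drawn from the stationary law π ∝ p(1−p) of that
  rejection chain, which makes every token marginally π-distributed, so the
  expected characters-per-word μ_c = Σ π_w c_w is exact. Utterance word
  counts are 1 + Poisson(mlu_i/μ_c − 1), making extracted MLU an unbiased
  estimator of the planted participant-level value mlu_i.
* Each passive utterance realizes exactly one *bèi*/*ba* construction with
  valid flanking structure (markers never appear in the general
  vocabulary), so expected PCR equals the per-utterance insertion
  probability.
* Participant-level parameters (MLU, long-pause rate, biomarkers,
  demographics) are drawn with symmetric clipping about the group mean,
  which preserves planted group means exactly.

A standard-normal latent severity factor per participant loads negatively
on utterance length and hippocampal volume and positively on long-pause
rate and SUVR, so the reported feature-biomarker dependences (hippocampal
volume vs LPR ≈ −0.49, vs UW ≈ +0.32 in the mixed cohort) emerge from both
between-group separation and within-group variation. Cognitive scores are
planted linear models of the standardized latents with group-specific
intercepts at the published group means and noise scaled to leave roughly
half the variance unexplained.

The synthetic lexicon assigns coarse classes and 1/2-character lengths to
Zipf-ranked vocabulary **deterministically** (largest-remainder
apportionment interleaved across ranks). Only the surfaces are random.
This matters: with random assignment, the identity of the few
highest-probability words changes across realizations and moves the
expected type-token ratio by several hundredths, which would make any
fixed calibration seed-specific.

**Calibration.** Structure parameters (utterance counts, MLU, passive and
filler rates, biomarker and demographic means/SDs, group sizes 32/48) are
the published group statistics directly. Quantities without a closed form
under the full pipeline are set by `calibrate_defaults()` — Monte-Carlo
bisection/secant on the generator itself with common random numbers — and
its output is frozen as the defaults: lexical concentration 1.07095 (NC)
and 1.14513 (early-AD) for type-token ratios of 0.56 and 0.51, and
per-gap long-pause probabilities 0.018655 and 0.077657 for long-pause
ratios of 0.0035 and 0.02. (The control-group LPR is calibrated to the
0.35% figure given in the running text rather than the table's rounded
0.00.) The lexicon's top frequency (3209) scales mean content-word
frequency to ≈857 for controls. The calibration routine remains in the
package for recalibrating after configuration changes.

**What the generator does not emulate.** The synthetic speech is not
Mandarin prose: word order is exchangeable within utterances, sentences
arise from class co-occurrence rather than grammar, and the joint
distribution of features beyond the planted correlations is an assumption
of the latent-factor structure, not an estimate. Feature SDs other than
MLU's are emergent rather than planted, and are generally narrower than the
published ones because real between-speaker heterogeneity has more sources
than one latent factor. Consequently, passing round-trip tests shows the
pipeline and the planted calibration are mutually consistent — it does not
show that real clinical speech would reproduce the published effect sizes,
and classification on the default synthetic cohort is easier than on the
real one (near-ceiling AUCs at the planted separations).

## Problem sizes and tolerances in the tests

Round-trip checks use 200 transcripts per group (tolerances of roughly one
Monte-Carlo standard error: ±0.25 / ±0.15 characters for group MLU, ±0.01
for TTR, ±0.003 for LPR, ±0.03 for SUVR) and n=500 for correlation recovery
(±0.1). The analytic AUC check plants a single Gaussian feature shifted by
1.5σ at n=1000/group, where the sampling noise of the empirical AUC
(SE ≈ 0.008) is small against the ±0.03 band; at a few hundred participants
the band would be dominated by data-draw noise rather than estimator
fidelity. Simulation-heavy checks run the protocols with reduced
cross-validation repeats and coarser grids — the structure (stratified
splits, per-fold re-ranked elimination, CV-sized subsets) is always the full
one. Exact-arithmetic checks (feature oracles, AUC vs brute-force pairwise
counting, VIF strictness) use no tolerance beyond 1e-12.

## Known limitations

* Context-dependent fillerhood (Mandarin "this"/"that" used as fillers) is
  resolved by the upstream annotator via the filled-pause flag; the package
  never guesses from surface form.
* The default CKIP tag mapping is a documented approximation (tagset version
  unstated upstream); unknown tags fall back to OTHER via longest-prefix
  lookup.
* Whether a bare passive marker should count without flanking structure is
  not decidable from the feature definitions; the flanking requirement here
  is a documented choice.
* `segment_utterances` implements only the duration rule; prosodic/semantic
  boundary placement is out of scope.
* Acoustic features (pitch, speech rate) are not computed; transcripts are
  the input boundary.
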