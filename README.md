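# speechmarker

Connected-speech analysis for early Alzheimer's disease screening in Mandarin.

Spontaneous speech elicited by a picture-description task degrades early in
Alzheimer's disease: utterances shorten, vocabulary narrows toward common
words, complex constructions (the Mandarin *bèi*/*ba* passives) thin out, and
silent pauses lengthen. `speechmarker` turns annotated transcripts of such
speech into quantitative biomarkers and carries them through the full
statistical workflow used in clinical speech studies. It is a library first
(see `examples/`), with a thin `speechmarker` CLI for running the pipeline on
files.

The package is aimed at researchers in digital speech biomarkers and
neuropsychology who have tokenized, POS-tagged, pause-timed transcripts
(tagging and timing happen upstream) and want reproducible feature
extraction and modeling.

## What it computes

**Fifteen linguistic features** per participant, computed per image and
averaged over the three pictures of the task:

* *Lexical content* — total words TW, unique words UW, type-token ratio
  TTR = UW/TW, content words CW (nouns, verbs, adjectives, pronouns,
  adverbs), content density CD = CW/TW, mean content-word corpus frequency
  CWF.
* *Syntactic complexity* — utterances U, sentences S (a noun/pronoun
  followed by a main verb or adjective phrase), mean length of utterance
  MLU = characters/U, mean length of sentence MLS, passive-construction
  ratio PCR (realized NP + *bèi* + VP and *ba* + NP + VP patterns per
  utterance), verb ratio VR and pronoun ratio PR over CW.
* *Disfluency* — filler ratio FR and long-pause ratio LPR, both over the
  total verbal output (words + filled pauses); a long pause is a silent
  inter-utterance gap of 2 s or more.

Before extraction, transcripts are cleaned exactly once: immediate
repetitions of a word or utterance collapse to one copy, then filled pauses
are separated out and tallied (they are not words).

**Statistical protocols** on top of the features:

* covariate-adjusted group comparison (OLS `feature ~ group + age +
  education` per feature);
* early-AD classification with SVM (RBF), KNN and random forest over three
  predictor sets (linguistic, biomarkers = SUVR + hippocampal volume,
  combined): 10 stratified 70/30 splits, recursive feature elimination sized
  by repeated cross-validated accuracy, grid-search tuning by
  cross-validated AUC, test-set AUC/specificity/precision/recall/F1, and
  model-specific importance scaled to 100 with per-feature selection
  frequencies;
* cognitive-score regressions (MMSE, CDR-SB, WLM-I/II, DS, CTT-1/2, VF,
  BNT): a single variance-inflation-factor screen (VIF > 5 removed), RFE by
  cross-validated RMSE per outcome, standardized coefficients with R², AIC,
  BIC and residual diagnostics.

**A calibrated synthetic-cohort generator** stands in for the private
clinical data: it emits token-level transcripts (with fillers, repetitions,
passives and timed gaps for the pipeline to clean), biomarkers and cognitive
scores whose group means, SDs and feature-biomarker correlations are planted
at the published cohort's values. Every protocol above is therefore testable
end-to-end; see `docs/methods.md` for what the generator does and does not
emulate.

## Worked example

`python examples/01_extract_features.py` builds a three-utterance transcript
(one filled pause, one *bèi* passive, a 2.5 s silence) and prints:

```
  TW: 10.0000
  UW: 9.0000
 TTR: 0.9000
  CW: 8.0000
  CD: 0.8000
 CWF: 1931.2500
   U: 3.0000
   S: 2.0000
 MLU: 3.6667
 MLS: 4.0000
 PCR: 0.3333
  VR: 0.3750
  PR: 0.1250
  FR: 0.0909
 LPR: 0.0909
```

Ten words survive cleaning (the filler is removed and counted separately);
茶 "tea" appears twice, so 9 unique words give TTR = 0.9. Eight content
words with a mean lexicon frequency of 1931.25 give CD = 0.8. Two of the
three utterances have a subject-predicate skeleton (S = 2), the *bèi*
construction yields PCR = 1/3, and the single ≥2 s gap over a verbal output
of 11 makes LPR = FR = 1/11 ≈ 0.0909.

The other examples cover the synthetic generator (`02`), group comparison
(`03`), classification (`04`) and score regression (`05`). The same stages
run from the shell:

```sh
speechmarker simulate --out run --seed 1
speechmarker features --transcripts run/transcripts --lexicon run/lexicon.tsv --out run
speechmarker compare  --cohort run/cohort.csv --out run
```

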