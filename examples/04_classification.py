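"""Classify early-AD vs controls with the RFE + repeated-split protocol.

Runs a lightened version of the classification protocol (fewer CV repeats
and a coarser grid, same structure) on a synthetic cohort: three predictor
sets (linguistic features, biomarkers, both; age and education always
included) across SVM, KNN and random-forest models.
"""

import logging

import pandas as pd

from speechmarker import extract_features
from speechmarker.classify import ClassificationProtocol, run_classification
from speechmarker.synthetic import default_config, generate_cohort

logging.getLogger("speechmarker").setLevel(logging.ERROR)

cohort = generate_cohort(default_config(seed=5))  # 32 NC / 48 early-AD
features = pd.DataFrame(
    [extract_features(t, cohort.lexicon) for t in cohort.transcripts],
    index=[t.participant_id for t in cohort.transcripts],
)
frame = cohort.frame().set_index("participant_id").join(features).reset_index()

protocol = ClassificationProtocol(
    n_repeats=3, rfe_cv_folds=5, rfe_cv_repeats=1,
    tune_cv_folds=3, tune_cv_repeats=1, grid_points=4,
    rf_n_estimators=100, n_permutations=5,
)
report = run_classification(frame, models=("rf", "svm"), protocol=protocol, seed=5)

print(report.metrics.round(3).to_string(index=False))
print()
for (set_name, model), feats in report.top_features.items():
    print(f"top features [{set_name}/{model}]: {', '.join(feats)}")

print()
print("AUC is the probability a random early-AD participant outscores a")
print("random control. Biomarkers separate strongly by construction (planted")
print("SUVR gap ~2.6 SD); among linguistic features the selection frequencies")
print("concentrate on utterance length and long pauses.")
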