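"""Covariate-adjusted group comparison of every linguistic feature.

Simulates a cohort at the published group sizes (32 controls, 48 early-AD),
extracts the 15 features, and fits feature ~ group + age + education for
each, printing the standardized group effect and its p-value.
"""

import logging

import pandas as pd

from speechmarker import compare_groups, extract_features
from speechmarker.synthetic import default_config, generate_cohort

logging.getLogger("speechmarker").setLevel(logging.ERROR)

cohort = generate_cohort(default_config(seed=11))  # default 32 NC / 48 early-AD
features = pd.DataFrame(
    [extract_features(t, cohort.lexicon) for t in cohort.transcripts],
    index=[t.participant_id for t in cohort.transcripts],
)
frame = cohort.frame().set_index("participant_id").join(features).reset_index()

table = compare_groups(frame)
with pd.option_context("display.float_format", "{:8.3f}".format):
    print(table.to_string(index=False))

print()
print("Negative coefficients mean the early-AD group scores lower after")
print("adjusting for age and education. At these group sizes the shortened")
print("utterances (MLU), rarer passives (PCR) and more frequent long pauses")
print("(LPR) separate the groups, mirroring the planted contrasts.")
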