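"""Coreness metrics for a candidate formula.

Computes the average confidence (alpha), the supports at several confidence
levels, and the patient-based support of a hand-picked herb subset on a
synthetic cohort.
"""

import cefminer as cm
from cefminer.metrics import (
    CEFCandidate,
    average_confidence,
    patient_based_support,
    support,
)

table = cm.generate_analysis_table(cm.study_config(seed=1))
cand = CEFCandidate.from_indices(range(5), table.m)  # the 5 most popular herbs

alpha = average_confidence(cand, table)
print(f"candidate: {', '.join(cand.herb_names(table.vocab))}")
print(f"alpha (mean coverage over {table.n} records): {alpha:.3f}")
for level in (0.7, 0.8, 0.9, 1.0):
    print(f"S_{level}: {support(cand, table, level):.3f}")
print(f"patient-based support: {patient_based_support(cand, table, 1.0):.3f}")
# S_level is the fraction of prescriptions containing at least level x 100%
# of the candidate's herbs; at level 1 it is classic itemset support.  PBS
# counts qualifying patients instead of records, guarding against one
# frequently-returning patient inflating the support.
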