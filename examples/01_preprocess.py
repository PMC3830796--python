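"""Preprocess visit records into the binary prescription-outcome table.

Builds a small synthetic cohort, pairs each non-final visit's prescription
with the symptom change observed at the following visit, and prints the
resulting analysis-table summary.
"""

import cefminer as cm

cfg = cm.study_config(seed=1)
visits = cm.generate_cohort(cfg)
table = cm.build_analysis_table(visits, cfg.vocabulary())

print(f"visits: {len(visits)}  patients with >1 visit contribute records")
print(f"analysis records: {table.n} from {table.n_patients} patients")
print(f"records dropped for undefined SCV: {table.n_missing_removed}")
print(f"effective proportion: {100 * table.effective_proportion:.1f}%")
# The effective proportion is the fraction of prescriptions followed by a
# >= 30% drop in the total symptom score at the next visit.
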