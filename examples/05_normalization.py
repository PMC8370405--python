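"""Normalizing patients' predictions to the control distribution.

For each of the 21 task conditions, each patient's contrast prediction is
converted to a modified z-score against the 14 controls (0.6745 * deviation
from the control median / MAD); |z| > 1.96 flags the condition as deviating,
with sign 'weaker' (reduced FPN>DMN dissociation) or 'stronger'.
"""

import neuroloop as nl
from neuroloop.profiles import normalize_patients

space = nl.build_task_space()
cohort = nl.generate_cohort(master_seed=12)
controls = {s.subject_id: s.true_surface for s in cohort.controls}
patients = {s.subject_id: s.true_surface for s in cohort.patients}

table = normalize_patients(patients, controls, space)
flagged = table[table.outlier]
print(f"{len(flagged)} of {len(table)} patient x condition cells flagged (|z| > 1.96):\n")
for _, row in flagged.head(12).iterrows():
    print(
        f"{row.patient}: {row.task} (level {row.difficulty})  "
        f"z = {row.modified_z:+.2f}  -> {row.sign}"
    )
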