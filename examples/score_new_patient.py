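"""Assign a new patient to a cluster of a previously fitted model.

Scoring standardizes the patient's six indices with the scaling stored
in the model and evaluates memberships against the frozen centroids —
no refitting, mirroring how a clinical front end assigns one patient
against published clusters.
"""

from eoscluster import (
    PatientRecord,
    PipelineConfig,
    default_specs,
    generate_cohort,
    score_new_patient,
)
from eoscluster.pipeline import analyze_etiology

records, _ = generate_cohort(default_specs(seed=7)["idiopathic"])
result = analyze_etiology(records, PipelineConfig(seed=7))

new_patient = PatientRecord(
    subject_id="NEW-001", etiology="idiopathic",
    age=4.2, cobb_major=62.0, kyphosis=30.0,
    levels_cobb=9, levels_kyphosis=8,
)
label, memberships, outlier = score_new_patient(new_patient, result.model)

print("memberships per cluster:",
      ", ".join(f"{u:.3f}" for u in memberships))
print(f"assigned cluster: {label}  (1 = mildest mean Cobb angle)")
print(f"outlier (max membership < 0.6): {outlier}")

# A membership close to 1 means the patient sits near that cluster's
# centroid; an outlier flag means no cluster describes the patient with
# sufficient certainty and the assignment should not be trusted.
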