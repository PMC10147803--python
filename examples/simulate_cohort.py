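"""Generate a synthetic EOS cohort and inspect its structure.

Each etiology's cohort is a three-component Gaussian mixture over the
five measured clinical indices, plus 5% injected uniform-range
outliers.  The ground-truth table lets recovery be checked later.
"""

from eoscluster import default_specs, generate_cohort, write_patient_csv

specs = default_specs(seed=7)
spec = specs["neuromuscular"]

records, truth = generate_cohort(spec)
write_patient_csv(records, "neuromuscular_cohort.csv")

print(f"etiology: {spec.etiology}, n = {spec.n_subjects}, "
      f"outlier fraction = {spec.outlier_fraction}")
for j, comp in enumerate(spec.clusters):
    n_j = int((truth["true_component"] == j).sum())
    print(f"  component {j}: weight {comp.weight:.2f}, drawn n = {n_j}, "
          f"mean Cobb {comp.mean[1]:.0f} deg, mean kyphosis {comp.mean[2]:.0f} deg")
print(f"  injected outliers: {int(truth['is_outlier'].sum())}")

# The component counts follow the mixing weights multinomially; the
# outlier count is exactly round(outlier_fraction * n).  The CSV written
# above is in the standard patient-table schema the pipeline reads.
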