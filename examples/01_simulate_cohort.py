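"""Simulate a TCD/MRI measurement cohort and inspect its structure.

Generates the default cohort — 88 older patients contributing 261
left/right middle-cerebral-artery measurements with group- and
side-specific covariate distributions — then punches missing cells into
the measured predictors and writes the table to CSV.
"""

import cbfsurrogate as cs

cfg = cs.CohortConfig(seed=7)
cohort = cs.generate_cohort(cfg)

print(f"rows: {len(cohort)}  patients: {cohort['patient_id'].nunique()}")
print("\nmeasurements per patient:")
print(cohort.groupby("patient_id").size().value_counts().sort_index()
      .rename_axis("k").to_string())

print("\nCBF by health status and side (mean ± sd):")
health = (cohort["diabetes"].eq("Y") | cohort["hypertension"].eq("Y")) \
    .map({True: "diseased", False: "healthy"})
print(cohort.groupby([health, "side"])["cbf"].agg(["mean", "std"]).round(1))

missing = cs.inject_missingness(cohort, seed=8)
complete = missing[cs.PREDICTORS + ["cbf"]].notna().all(axis=1).sum()
print(f"\ncomplete rows after default missingness: {complete} / "
      f"{len(missing)} (calibrated to ~134)")

cs.write_cohort_csv(missing, "cohort.csv")
print("wrote cohort.csv in the canonical schema")
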