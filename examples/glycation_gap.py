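"""Observational glycation-gap pipeline on a synthetic cohort.

Simulates a 7,600-person outpatient cohort (14.4% pre-T2D), applies the
study's exclusion filters, classifies glycemic status, computes the
triglyceride-glucose index (TGI) and the glycation gap, runs the
stratified gap-on-TGI regressions and the hemoglobin regression, and
validates the pre-T2D model with the 0.632 bootstrap.
"""

from mrgap import glycation as gl, simulate as sim

cohort = sim.simulate_cohort(sim.CohortSimConfig(seed=11))
kept, tally = gl.apply_cohort_filters(cohort)
print(f"filters: {tally}")

d = gl.add_derived_columns(kept)
n_pre = (d["glycemic_status"] == "preT2D").sum()
print(f"analysis cohort: {len(d)} records, {n_pre} pre-T2D "
      f"({100 * n_pre / len(d):.1f}%)\n")

print("median TGI by stratum:")
print(d.groupby("glycemic_status")[["tgi", "gap", "hba1c"]].median().round(2).to_string())

print("\ngap ~ TGI by stratum (generator truth: -0.087 pre-T2D, +0.023 healthy):")
results = gl.regress_gap_on_tgi(d)
print(gl.regression_table(results).round(4).to_string(index=False))

hb = gl.regress_hb_on_tgi(d)
print(f"\nhb ~ TGI: beta = {hb.beta:.2f} +/- {hb.se:.2f} g/L per TGI unit "
      "(generator truth 1.88; the sex-specific hemoglobin inclusion range "
      "truncates the outcome and attenuates the fitted slope — the same "
      "selection any real normal-range cohort carries)")

pre = d[d["glycemic_status"] == "preT2D"]
val = gl.bootstrap_validate_632(gl.ModelSpec("gap", ("tgi",)), pre, n_boot=200, seed=3)
print(f"\n0.632 bootstrap (pre-T2D gap ~ TGI): R2 apparent = {val.r2_apparent:.4f}, "
      f"corrected = {val.r2_corrected:.4f}, optimism = {val.optimism:.4f} "
      f"({'overfit' if val.overfit else 'not overfit'})")
print("\nA negative pre-T2D slope means measured HbA1c falls further below "
      "its glucose-predicted value as insulin resistance (TGI) rises — the "
      "non-glycemic, erythrocytosis-consistent signature; the positive "
      "healthy slope shows the contrast.")
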