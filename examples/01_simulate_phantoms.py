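"""Simulate a small CT-like phantom cohort with weak PFT labels.

Generates healthy and diseased lung phantoms, prints the covariate manifest,
and writes one subject to NIfTI.  Diseased subjects carry low-attenuation
lesions (~-975 HU) in correlated parenchyma texture (~-850 HU); the realized
lesion burden drives simulated FEV1/DLCO downward, so thresholding the
covariates reproduces the COPD and DLCO<60% weak labelings.
"""

from pathlib import Path

from emphymil.phantom import PhantomSpec, cohort_table, make_cohort, save_subject

out_dir = Path("scratch/examples/phantoms")

spec = PhantomSpec(shape=(64, 64, 64))  # desk-scale; default is 128^3
cohort = make_cohort(n_healthy=4, n_diseased=4, spec=spec, seed=7)

table = cohort_table(cohort)
print(table.round(2).to_string(index=False))
print()
print("label_copd = +1 for GOLD A-D subjects; label_dlco = +1 for DLCO < 60%.")
print("lesion_fraction is the ground-truth emphysema burden of the lung.")

save_subject(cohort[-1], out_dir)
print(f"\nwrote {cohort[-1].subject_id} volume + masks as NIfTI under {out_dir}/")
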