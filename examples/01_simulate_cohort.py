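"""Generate the packaged 10-patient paired-foci cohort and inspect its truth.

Six patients follow the multicentric (MC) model — two independent tumors
with almost no shared somatic variation — and four the metastatic (ME)
model, where a shared trunk clone seeds both foci.
"""

import multifoci as m

config = m.default_cohort_config(base_seed=1)
bundles = m.simulate_cohort(config)

print(f"{'patient':8} {'model':6} {'target':>7} {'realized':>9} {'union':>6}")
for b in bundles:
    t = b.truth
    print(
        f"{b.patient_id:8} {t.origin_model:6} {t.target_shared_snv_fraction:7.3f} "
        f"{t.realized_shared_fraction:9.3f} {t.n_union:6d}"
    )
# 'realized' is the Jaccard fraction of variant keys the two foci truly
# share; MC rows sit in 0-2.7%, ME rows in 58-67.6%, matching the bands the
# generator is calibrated to.
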