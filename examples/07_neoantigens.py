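"""Filter neoantigen candidates and count their recurrence across foci.

A mutant peptide is a candidate when its predicted MHC binding affinity is
strictly under 500 nM and stronger (lower) than the wild-type peptide's.
Recurrence counts distinct foci with at least one candidate peptide per
mutation.
"""

import multifoci as m

bundles = m.simulate_cohort(m.default_cohort_config(base_seed=1))
candidates = []
for b in bundles:
    kept = m.filter_candidates(b.affinities)
    candidates.extend(kept)
print(f"{sum(len(b.affinities) for b in bundles)} affinity records -> {len(candidates)} candidates")

rec = m.recurrent_neoantigens(candidates, min_foci=3)
print(rec.head(5).to_string(index=False))
# The one mutation recurring in >2 foci is the planted TP53 hotspot: the
# same site is mutated in one focus of each of the six MC patients.
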