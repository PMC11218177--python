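"""Call each patient multicentric or metastatic and compare the groups.

The label is a simple threshold on the shared SNV fraction (default 0.10,
inside the empirical gap between the two bands). Group differences in the
SNV, CNV-gene and SV sharing channels are tested with an exact Wilcoxon
rank-sum test computed by full enumeration.
"""

import multifoci as m
from multifoci.genome import load_gene_table
from multifoci.sharing import FocusPair, cnv_gene_overlap, sharing_summary, sv_overlap

bundles = m.simulate_cohort(m.default_cohort_config(base_seed=1))
genes = load_gene_table()

summaries = []
for b in bundles:
    s = sharing_summary(FocusPair.from_bundle(b))
    _, s.shared_fraction_cnv_genes = cnv_gene_overlap(b.segments["Ca1"], b.segments["Ca2"], genes)
    _, s.shared_fraction_sv = sv_overlap(b.svs["Ca1"], b.svs["Ca2"])
    summaries.append(s)

calls = [m.classify_origin(s) for s in summaries]
table, report = m.cohort_report(calls, summaries)
print(table[["patient_id", "label", "shared_fraction_snv", "shared_fraction_sv"]].to_string(index=False))
print(f"\n{report['n_mc']} MC vs {report['n_me']} ME")
for channel, p in report["p_values"].items():
    print(f"  {channel:10} p = {p:.5f}")
# With complete separation of 6 MC vs 4 ME the exact two-sided p-value is
# 2/C(10,6) = 2/210 ~ 0.00952 in every channel.
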