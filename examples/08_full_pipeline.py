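"""Run every stage end to end and read the cohort report.

simulate -> share -> classify -> germline -> clusters -> cnv -> neo; all
stage outputs land under <cohort_dir>/results and the aggregated report is
returned (and written as report.json). Reruns with the same seed are
identical.
"""

import tempfile

import multifoci as m

with tempfile.TemporaryDirectory() as tmp:
    config = m.RunConfig(cohort_dir=tmp, seed=1, restarts=10, k_max=4)
    report = m.run_pipeline(config)

    classify = report["stages"]["classify"]
    print(f"{classify['n_mc']} MC / {classify['n_me']} ME patients; "
          f"SNV-channel p = {classify['p_values']['snv']:.5f}")
    print(f"germline immune p = {report['stages']['germline']['comparisons']['immune']['p_value']:.5f}")
    mono = [f for f, v in report["stages"]["clusters"]["foci"].items() if v["monoclonal"]]
    print(f"monoclonal foci: {mono}")
    print(f"recurrent CNV genes: {report['stages']['cnv']['recurrent_genes'][:6]} ...")
    print(f"recurrent neoantigen mutations: {report['stages']['neo']['recurrent_mutations']}")
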