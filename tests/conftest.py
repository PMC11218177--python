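import numpy as np
import pytest

import multifoci as m
from multifoci.records import SiteEvidence, VariantRecord
from multifoci.synthetic import CohortConfig, PatientConfig


def make_variant(chrom="chr1", pos=100, ref="A", alt="T", **kw):
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, **kw)


def make_evidence(sample="S1", chrom="chr1", pos=100, ref="A", alt="T",
                  ref_depth=30, alt_depth=10, hq=True):
    return SiteEvidence(sample_id=sample, chrom=chrom, pos=pos, ref=ref, alt=alt,
                        ref_depth=ref_depth, alt_depth=alt_depth, hq_flag=hq)


def mini_cohort_config(base_seed=11):
    """4 patients (2 MC / 2 ME) at reduced scale: fast but structurally
    identical to the packaged default cohort."""
    gains = [("CCND1", "gain"), ("CTTN", "gain")]
    patients = [
        PatientConfig(
            patient_id="M01", origin_model="MC", target_shared_snv_fraction=0.0,
            n_somatic_per_focus=60, n_clusters=(2, 1), purity=0.8,
            cnv_profile={"Ca1": gains + [("EGFR", "gain")], "Ca2": gains + [("MET", "loss")]},
            sv_count_per_focus=10, germline_total=12, germline_immune=6,
            planted_drivers=["TP53"], hotspot_genes=["TP53"],
        ),
        PatientConfig(
            patient_id="M02", origin_model="MC", target_shared_snv_fraction=0.025,
            n_somatic_per_focus=60, n_clusters=(1, 1), purity=0.75,
            cnv_profile={"Ca1": gains, "Ca2": gains + [("RB1", "loss")]},
            sv_count_per_focus=10, germline_total=12, germline_immune=7,
            planted_drivers=["TP53"], hotspot_genes=["TP53"],
        ),
        PatientConfig(
            patient_id="E01", origin_model="ME", target_shared_snv_fraction=0.60,
            n_somatic_per_focus=60, n_clusters=(2, 2), purity=0.85,
            cnv_profile={"Ca1": gains, "Ca2": gains},
            sv_count_per_focus=10, sv_shared_fraction=0.6,
            germline_total=12, germline_immune=2, planted_drivers=["TP53"],
        ),
        PatientConfig(
            patient_id="E02", origin_model="ME", target_shared_snv_fraction=0.65,
            n_somatic_per_focus=60, n_clusters=(2, 2), purity=0.8,
            cnv_profile={"Ca1": gains + [("PTEN", "loss")], "Ca2": gains + [("PTEN", "loss")]},
            sv_count_per_focus=10, sv_shared_fraction=0.6,
            germline_total=12, germline_immune=1, planted_drivers=["TP53"],
        ),
    ]
    return CohortConfig(patients=patients, base_seed=base_seed)


@pytest.fixture(scope="session")
def mini_bundles():
    return m.simulate_cohort(mini_cohort_config())


@pytest.fixture(scope="session")
def default_bundles():
    """The packaged 10-patient cohort at a fixed session seed."""
    return m.simulate_cohort(m.default_cohort_config(base_seed=101))


@pytest.fixture(scope="session")
def default_summaries(default_bundles):
    from multifoci.genome import load_gene_table
    from multifoci.sharing import FocusPair, cnv_gene_overlap, sharing_summary, sv_overlap

    genes = load_gene_table()
    out = []
    for b in default_bundles:
        s = sharing_summary(FocusPair.from_bundle(b))
        _, s.shared_fraction_cnv_genes = cnv_gene_overlap(b.segments["Ca1"], b.segments["Ca2"], genes)
        _, s.shared_fraction_sv = sv_overlap(b.svs["Ca1"], b.svs["Ca2"])
        out.append(s)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(42)
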