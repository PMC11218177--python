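"""Shared / unique / excluded classification of somatic variants between
paired tumor foci, and the per-channel shared fractions (SNV+indel,
CNV genes, SV breakpoints).

The classifier applies three rules to each somatic call of one focus,
after a coverage gate of >= 10 total reads in both the calling tumor and
the matched normal:

(i)   >= 1 read carrying the alternative allele in the partner focus's
      pileup  -> **shared** (read-level rescue);
(iii) no partner alt reads but the site lies in a partner LOH segment
      -> **excluded** (loss in the partner cannot be distinguished from
      true absence);
(ii)  otherwise (partner covered by reference bases only) -> **unique**.

Shared fractions are Jaccard: shared / union, with excluded-LOH and
coverage-failed sites removed from both numerator and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import InputDataError
from .records import Segment, SharingSummary, SiteEvidence, SVBreakpoint, VariantRecord

__all__ = [
    "MIN_SITE_DEPTH",
    "HQ_MIN_ALT",
    "coverage_gate",
    "classify_site",
    "FocusPair",
    "sharing_summary",
    "cnv_gene_overlap",
    "sv_overlap",
]

#: "a minimum of 10 reads" in tumor and matched normal, inclusive
MIN_SITE_DEPTH = 10
#: alt reads required for a call to count as high-quality support
HQ_MIN_ALT = 3


def coverage_gate(
    evidence_tumor: SiteEvidence,
    evidence_normal: SiteEvidence,
    min_depth: int = MIN_SITE_DEPTH,
) -> bool:
    """A site is adequately covered iff total depth >= ``min_depth`` in both
    the tumor and the matched normal (boundary inclusive)."""
    if evidence_tumor.site != evidence_normal.site:
        raise InputDataError(
            f"coverage_gate: tumor and normal evidence refer to different sites "
            f"({evidence_tumor.site} vs {evidence_normal.site})"
        )
    return evidence_tumor.depth >= min_depth and evidence_normal.depth >= min_depth


def classify_site(
    variant: VariantRecord,
    partner_evidence: SiteEvidence,
    partner_loh: Sequence[Segment],
) -> str:
    """Classify one somatic call against the partner focus.

    Returns ``"shared"``, ``"unique"`` or ``"excluded_loh"``. Precedence:
    a single partner alt read makes the site shared; an alt-free site inside
    a partner LOH segment is excluded; an alt-free covered site is unique.
    """
    if variant.key != partner_evidence.site:
        raise InputDataError(
            f"classify_site: partner evidence is for {partner_evidence.site}, "
            f"variant is {variant.key}"
        )
    if partner_evidence.alt_depth >= 1:
        return "shared"
    if any(seg.loh and seg.contains(variant.chrom, variant.pos) for seg in partner_loh):
        return "excluded_loh"
    return "unique"


@dataclass
class FocusPair:
    """Inputs for one patient's sharing analysis.

    ``evidence`` is keyed by (chrom, pos, ref, alt, sample_id); segments are
    the full per-focus segment lists (only ``loh`` segments matter here).
    """

    patient_id: str
    focus_a: str
    focus_b: str
    variants_a: Sequence[VariantRecord]
    variants_b: Sequence[VariantRecord]
    evidence: dict
    segments_a: Sequence[Segment]
    segments_b: Sequence[Segment]
    sample_a: str
    sample_b: str
    sample_normal: str

    @classmethod
    def from_bundle(cls, bundle) -> "FocusPair":
        from .io import evidence_lookup

        return cls(
            patient_id=bundle.patient_id,
            focus_a="Ca1",
            focus_b="Ca2",
            variants_a=bundle.somatic["Ca1"],
            variants_b=bundle.somatic["Ca2"],
            evidence=evidence_lookup(bundle.evidence),
            segments_a=bundle.segments["Ca1"],
            segments_b=bundle.segments["Ca2"],
            sample_a=bundle.sample_id("Ca1"),
            sample_b=bundle.sample_id("Ca2"),
            sample_normal=bundle.normal_id,
        )


def _eligible(v: VariantRecord) -> bool:
    """Nonsynonymous SNVs and indels in exonic/splicing regions enter the
    sharing statistics."""
    return v.consequence != "synonymous" and v.region in ("exonic", "splicing")


def sharing_summary(
    pair: FocusPair,
    min_depth: int = MIN_SITE_DEPTH,
    min_alt_hq: int = HQ_MIN_ALT,
) -> SharingSummary:
    """Classify every eligible somatic variant of both foci and aggregate.

    Classification runs in both directions (A's calls against B's pileup and
    vice versa) and is de-duplicated by variant key; a key shared in either
    direction is shared. The category counts partition the union of eligible
    variant keys. The SNV shared fraction is
    ``n_shared / (n_shared + n_unique_a + n_unique_b)`` (0 with a warning
    flag when the denominator is empty); CNV-gene and SV fractions are
    filled in by :func:`cnv_gene_overlap` / :func:`sv_overlap` callers.
    """
    calls = {"a": {}, "b": {}}
    directions = [
        ("a", pair.variants_a, pair.sample_a, pair.sample_b, pair.segments_b),
        ("b", pair.variants_b, pair.sample_b, pair.sample_a, pair.segments_a),
    ]
    loh_only = {
        "a": [s for s in pair.segments_b if s.loh],
        "b": [s for s in pair.segments_a if s.loh],
    }
    for side, variants, own_sample, partner_sample, _segs in directions:
        partner_loh = loh_only[side]
        for v in variants:
            if not _eligible(v):
                continue
            ev_own = pair.evidence.get((*v.key, own_sample))
            ev_normal = pair.evidence.get((*v.key, pair.sample_normal))
            ev_partner = pair.evidence.get((*v.key, partner_sample))
            if ev_own is None or ev_normal is None or ev_partner is None:
                raise InputDataError(
                    f"{pair.patient_id}: missing pileup evidence at {v.key} "
                    f"(somatic sites must be covered in all three samples)"
                )
            hq = ev_own.hq_flag and ev_own.alt_depth >= min_alt_hq
            if not coverage_gate(ev_own, ev_normal, min_depth) or not hq:
                calls[side][v.key] = "failed_coverage"
                continue
            calls[side][v.key] = classify_site(v, ev_partner, partner_loh)

    n_shared = n_unique_a = n_unique_b = n_excluded = n_failed = 0
    union = set(calls["a"]) | set(calls["b"])
    for key in union:
        ca = calls["a"].get(key)
        cb = calls["b"].get(key)
        statuses = {c for c in (ca, cb) if c is not None}
        if "shared" in statuses:
            n_shared += 1
        elif statuses == {"failed_coverage"}:
            n_failed += 1
        elif "excluded_loh" in statuses:
            n_excluded += 1
        elif ca == "unique":
            n_unique_a += 1
        elif cb == "unique":
            n_unique_b += 1
        else:  # pragma: no cover - defensive; statuses is never empty
            n_failed += 1

    denom = n_shared + n_unique_a + n_unique_b
    return SharingSummary(
        patient_id=pair.patient_id,
        n_shared=n_shared,
        n_unique_a=n_unique_a,
        n_unique_b=n_unique_b,
        n_excluded_loh=n_excluded,
        n_failed_coverage=n_failed,
        shared_fraction_snv=(n_shared / denom) if denom else 0.0,
        empty_denominator=denom == 0,
    )


def cnv_gene_overlap(
    segments_a: Sequence[Segment],
    segments_b: Sequence[Segment],
    genes: pd.DataFrame,
) -> tuple[set, float]:
    """Genes with concordant copy-number status in both foci.

    A gene is a CNV gene of a focus if it overlaps >= 1 non-neutral segment
    (gain wins over loss if both overlap, which non-overlapping segment sets
    preclude); shared requires the same direction in both foci. Returns the
    shared gene set and |shared| / |union of CNV genes| (0 if the union is
    empty)."""
    required = {"gene", "contig", "start", "end"}
    if not required.issubset(genes.columns):
        raise InputDataError(f"gene table missing columns {required - set(genes.columns)}")

    def gene_status(segments: Sequence[Segment]) -> dict[str, str]:
        out: dict[str, str] = {}
        for seg in segments:
            if seg.status == "neutral":
                continue
            hit = (
                (genes["contig"] == seg.contig)
                & (genes["start"] < seg.end)
                & (genes["end"] > seg.start)
            )
            for g in genes.loc[hit, "gene"]:
                out.setdefault(g, seg.status)
        return out

    status_a = gene_status(segments_a)
    status_b = gene_status(segments_b)
    union = set(status_a) | set(status_b)
    shared = {g for g in status_a if g in status_b and status_a[g] == status_b[g]}
    fraction = len(shared) / len(union) if union else 0.0
    return shared, fraction


def _sv_match(a: SVBreakpoint, b: SVBreakpoint, tol: int) -> bool:
    if a.svtype != b.svtype:
        return False
    same = (
        a.chrom1 == b.chrom1
        and a.chrom2 == b.chrom2
        and abs(a.pos1 - b.pos1) <= tol
        and abs(a.pos2 - b.pos2) <= tol
    )
    if same:
        return True
    if a.svtype == "TRA":  # translocations may be recorded with ends swapped
        return (
            a.chrom1 == b.chrom2
            and a.chrom2 == b.chrom1
            and abs(a.pos1 - b.pos2) <= tol
            and abs(a.pos2 - b.pos1) <= tol
        )
    return False


def sv_overlap(
    sv_a: Sequence[SVBreakpoint],
    sv_b: Sequence[SVBreakpoint],
    tol: int = 10,
) -> tuple[list, float]:
    """One-to-one matching of SV breakpoints between foci.

    Two SVs match iff they have the same type and both breakpoints lie
    within ``tol`` bp (default 10); translocations also match with the two
    ends swapped. Returns the matched pairs and
    |matched| / (|A| + |B| - |matched|)."""
    if tol < 0:
        raise InputDataError("sv tolerance must be >= 0")
    matched = []
    used_b: set[int] = set()
    for a in sv_a:
        for j, b in enumerate(sv_b):
            if j in used_b:
                continue
            if _sv_match(a, b, tol):
                matched.append((a, b))
                used_b.add(j)
                break
    union = len(sv_a) + len(sv_b) - len(matched)
    fraction = len(matched) / union if union else 0.0
    return matched, fraction
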