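"""Core record types shared across the analysis stages.

All genomic coordinates on :class:`VariantRecord` are 1-based (VCF
convention); :class:`Segment` intervals are 0-based half-open (BED
convention). Converters live at the I/O boundary, not here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "VariantRecord",
    "SiteEvidence",
    "Segment",
    "SVBreakpoint",
    "AffinityRecord",
    "SharingSummary",
    "OriginCall",
    "CCFEstimate",
    "ClusterResult",
]

REGION_CLASSES = {"exonic", "splicing", "ncRNA", "intronic", "intergenic", "UTR"}
CONSEQUENCES = {
    "synonymous",
    "nonsynonymous",
    "stopgain",
    "stoploss",
    "frameshift",
    "nonframeshift",
}


@dataclass(frozen=True)
class VariantRecord:
    """One small variant (SNV or indel) with its functional annotations.

    ``variant_class`` distinguishes somatic calls from germline calls;
    population allele frequencies and the COSMIC / repeat-region flags are
    carried for the germline filter cascade, SIFT / PolyPhen-2 scores for
    key-mutation selection. Missing annotations are ``None``.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    variant_class: str = "somatic"  # somatic | germline
    gene: Optional[str] = None
    region: str = "exonic"
    consequence: str = "nonsynonymous"
    af_dbsnp: Optional[float] = None
    af_1kg: Optional[float] = None
    af_exac: Optional[float] = None
    cosmic_flag: bool = False
    repeat_flag: bool = False
    sift: Optional[float] = None
    polyphen: Optional[float] = None
    depth: Optional[int] = None  # caller DP, used by the germline depth filter

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")
        if self.variant_class not in ("somatic", "germline"):
            raise ValueError(f"bad variant_class {self.variant_class!r}")
        if self.region not in REGION_CLASSES:
            raise ValueError(f"bad region {self.region!r}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"bad consequence {self.consequence!r}")
        for name in ("af_dbsnp", "af_1kg", "af_exac"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} outside [0,1]: {v}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity of the variant: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    def max_population_af(self) -> float:
        """Largest population AF across dbSNP/1KG/ExAC, missing treated as 0."""
        return max(
            (v for v in (self.af_dbsnp, self.af_1kg, self.af_exac) if v is not None),
            default=0.0,
        )

    def with_(self, **kw) -> "VariantRecord":
        return replace(self, **kw)


@dataclass(frozen=True)
class SiteEvidence:
    """Read support for one allele in one sample at one site."""

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    ref_depth: int
    alt_depth: int
    hq_flag: bool = False  # "high-quality alternative allele reads" indicator

    def __post_init__(self) -> None:
        if self.ref_depth < 0 or self.alt_depth < 0:
            raise ValueError("read depths must be non-negative")

    @property
    def depth(self) -> int:
        return self.ref_depth + self.alt_depth

    @property
    def site(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class Segment:
    """Copy-number / BAF segment; coordinates 0-based half-open."""

    contig: str
    start: int
    end: int
    copy_number: int
    baf: Optional[float] = None
    genotype: str = "AB"
    status: str = "neutral"  # gain | loss | neutral
    loh: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty segment [{self.start}, {self.end})")
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")
        if self.baf is not None and not (0.0 <= self.baf <= 0.5):
            raise ValueError(f"baf outside [0, 0.5]: {self.baf}")
        if self.status not in ("gain", "loss", "neutral"):
            raise ValueError(f"bad status {self.status!r}")

    def contains(self, contig: str, pos_1based: int) -> bool:
        """Whether a 1-based point position falls inside the segment."""
        return self.contig == contig and self.start < pos_1based <= self.end


@dataclass(frozen=True)
class SVBreakpoint:
    """Structural variant described by its two breakpoints and a type."""

    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    svtype: str  # DEL | DUP | INV | TRA
    orientation: str = "+-"

    def __post_init__(self) -> None:
        if self.svtype not in ("DEL", "DUP", "INV", "TRA"):
            raise ValueError(f"bad svtype {self.svtype!r}")


@dataclass(frozen=True)
class AffinityRecord:
    """Predicted MHC binding affinity of one mutant peptide and its wild type."""

    mutation_id: str
    focus_id: str
    hla_allele: str
    peptide: str
    mut_affinity_nM: float
    wt_affinity_nM: float

    def __post_init__(self) -> None:
        if self.mut_affinity_nM <= 0 or self.wt_affinity_nM <= 0:
            raise ValueError("affinities must be positive")
        if not (9 <= len(self.peptide) <= 11):
            raise ValueError(f"peptide length must be 9-11, got {len(self.peptide)}")


@dataclass
class SharingSummary:
    """Per-patient somatic sharing bookkeeping across the three channels.

    Category counts partition the eligible somatic variants:
    ``n_shared + n_unique_a + n_unique_b + n_excluded_loh + n_failed_coverage``
    equals the number of distinct variant keys considered.
    """

    patient_id: str
    n_shared: int = 0
    n_unique_a: int = 0
    n_unique_b: int = 0
    n_excluded_loh: int = 0
    n_failed_coverage: int = 0
    shared_fraction_snv: float = 0.0
    shared_fraction_cnv_genes: float = 0.0
    shared_fraction_sv: float = 0.0
    empty_denominator: bool = False

    @property
    def n_total(self) -> int:
        return (
            self.n_shared
            + self.n_unique_a
            + self.n_unique_b
            + self.n_excluded_loh
            + self.n_failed_coverage
        )


@dataclass(frozen=True)
class OriginCall:
    """Multicentric (MC) vs metastatic (ME) label for one patient."""

    patient_id: str
    label: str  # MC | ME
    shared_fraction_snv: float
    threshold_used: float
    notes: str = ""


@dataclass(frozen=True)
class CCFEstimate:
    """Cancer cell fraction of one mutation, VAF corrected for purity and CN."""

    mutation_id: str
    vaf: float
    copy_number: int
    multiplicity: int
    purity: float
    ccf: float


@dataclass
class ClusterResult:
    """Binomial-mixture clustering of CCFs for one tumor focus."""

    focus_id: str
    assignments: "list[int]"  # per-mutation cluster index
    means: "list[float]"  # cluster CCF means
    weights: "list[float]"
    k: int
    scores: "dict[int, float]" = field(default_factory=dict)  # BIC per K tried
    log_likelihood: float = float("nan")
    warning: str = ""

    @property
    def monoclonal(self) -> bool:
        return self.k == 1
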