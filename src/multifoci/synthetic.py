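"""Synthetic paired-foci cohort generator.

Each simulated patient carries two tumor foci (Ca1, Ca2) and a matched
normal, on the toy genome of :mod:`multifoci.genome`. The generator's
defaults emulate the statistical structure of a 10-patient multifocal
esophageal/cardiac (MECC) whole-genome cohort:

* **multicentric (MC)** patients: two near-independent somatic variant sets
  whose shared fraction (Jaccard over the union of both foci) lies in the
  0-2.7% band, and no shared structural variants;
* **metastatic (ME)** patients: a clonal trunk shared by both foci plus
  private branch variants, with shared fractions in the 58-67.6% band;
* per-focus clonal structure of 1-3 cancer-cell-fraction (CCF) clusters;
* copy-number gains/losses over cancer genes, copy-neutral LOH regions
  (with a few partner-private variants deliberately trapped inside them to
  exercise the LOH exclusion rule), sparse SV sharing;
* germline variants with population AFs, COSMIC/repeat flags and functional
  categories, sized so MC patients carry more immune-gene germline variants
  than ME patients at equal total burden;
* peptide-MHC affinity tables with a guaranteed non-empty candidate subset.

Read counts follow a Poisson(depth) / Binomial(depth, VAF) allele-sampling
model with VAF = CCF x purity x multiplicity / (purity x CN + (1-purity) x 2),
multiplicity 1 (ordinary variants are placed outside gains). Everything is
deterministic given the per-patient seeds derived from the base seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as mio
from .errors import ConfigurationError
from .genome import CONTIGS, genes_overlapping, load_gene_categories, load_gene_table
from .records import AffinityRecord, Segment, SiteEvidence, SVBreakpoint, VariantRecord

__all__ = [
    "PatientConfig",
    "CohortConfig",
    "TruthRecord",
    "PatientBundle",
    "simulate_patient",
    "simulate_cohort",
    "write_cohort",
    "load_cohort",
    "default_cohort_config",
    "FOCI",
]

FOCI = ("Ca1", "Ca2")

#: truth CCF cluster means by configured cluster count
CLUSTER_MEANS = {1: [1.0], 2: [1.0, 0.4], 3: [1.0, 0.55, 0.25]}
_CLUSTER_WEIGHTS = {1: [1.0], 2: [0.6, 0.4], 3: [0.5, 0.3, 0.2]}

_AA = "ACDEFGHIKLMNPQRSTVWY"
_HLA = ("HLA-A*02:01", "HLA-A*01:01", "HLA-B*07:02")

MC_TARGET_MAX = 0.027
ME_TARGET_RANGE = (0.58, 0.676)


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class PatientConfig:
    """Generator settings for one paired-foci patient.

    ``target_shared_snv_fraction`` is the Jaccard fraction
    shared / |union of both foci| the emitted truth realizes (to integer
    rounding). ``cnv_profile`` maps each focus to (gene, gain|loss) pairs;
    ``planted_drivers`` genes receive one clonal deleterious mutation per
    focus; ``hotspot_genes`` (subset of planted drivers) use one fixed
    canonical site in focus Ca1, so the same mutation recurs across patients.
    """

    patient_id: str
    origin_model: str  # MC | ME
    target_shared_snv_fraction: float
    n_somatic_per_focus: int = 200
    n_clusters: tuple[int, int] = (2, 2)  # per focus, 1-3
    purity: float = 0.8
    cnv_profile: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    sv_count_per_focus: int = 40
    sv_shared_fraction: float = 0.0
    germline_total: int = 45
    germline_immune: int = 3
    germline_cosmic_rescued: int = 2
    germline_noise_per_rule: int = 2
    n_loh_per_focus: int = 2
    n_loh_trapped: int = 3  # partner-private variants placed inside this focus's partner LOH
    planted_drivers: list[str] = field(default_factory=lambda: ["TP53"])
    hotspot_genes: list[str] = field(default_factory=list)
    tumor_depth: float = 50.0
    normal_depth: float = 30.0
    seed: Optional[int] = None  # resolved from the cohort base seed if None

    def validate(self) -> None:
        if self.origin_model not in ("MC", "ME"):
            raise ConfigurationError(f"{self.patient_id}: bad origin_model {self.origin_model!r}")
        if not (0.0 <= self.target_shared_snv_fraction <= 1.0):
            raise ConfigurationError(f"{self.patient_id}: target fraction outside [0,1]")
        if self.target_shared_snv_fraction > 0 and self.n_somatic_per_focus == 0:
            raise ConfigurationError(
                f"{self.patient_id}: shared fraction > 0 unreachable with 0 somatic variants"
            )
        if not (0.0 < self.purity <= 1.0):
            raise ConfigurationError(f"{self.patient_id}: purity must be in (0,1]")
        for k in self.n_clusters:
            if not 1 <= k <= 3:
                raise ConfigurationError(f"{self.patient_id}: n_clusters entries must be 1-3")
        if not set(self.hotspot_genes) <= set(self.planted_drivers):
            raise ConfigurationError(f"{self.patient_id}: hotspot_genes must be planted drivers")

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["n_clusters"] = list(self.n_clusters)
        d["cnv_profile"] = {f: [list(t) for t in v] for f, v in self.cnv_profile.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PatientConfig":
        d = dict(d)
        d["n_clusters"] = tuple(d["n_clusters"])
        d["cnv_profile"] = {f: [tuple(t) for t in v] for f, v in d.get("cnv_profile", {}).items()}
        return cls(**d)


@dataclass
class CohortConfig:
    """A cohort is a base seed plus per-patient entries; per-patient seeds
    are derived deterministically from (base_seed, patient index) unless set
    explicitly."""

    patients: list[PatientConfig]
    base_seed: int = 20240601

    def resolve_seeds(self) -> None:
        for i, p in enumerate(self.patients):
            if p.seed is None:
                # stable per-patient stream independent of the other patients
                p.seed = int(np.random.SeedSequence([self.base_seed, i]).generate_state(1)[0] % (2**31))

    def validate(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ConfigurationError(f"duplicate patient ids: {dup}")
        for p in self.patients:
            p.validate()

    def to_dict(self) -> dict:
        return {"base_seed": self.base_seed, "patients": [p.to_dict() for p in self.patients]}

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        return cls(
            patients=[PatientConfig.from_dict(p) for p in d["patients"]],
            base_seed=d.get("base_seed", 20240601),
        )


# ---------------------------------------------------------------------------
# Truth and bundles


@dataclass
class TruthRecord:
    """Ground truth emitted alongside each simulated patient."""

    patient_id: str
    origin_model: str
    target_shared_snv_fraction: float
    purity: float
    shared_keys: set = field(default_factory=set)
    # focus -> {variant key -> cluster index}; cluster means per focus
    cluster_assignment: dict = field(default_factory=dict)
    cluster_means: dict = field(default_factory=dict)
    loh_regions: dict = field(default_factory=dict)  # focus -> [(contig, start, end)]
    cnv_truth: dict = field(default_factory=dict)  # focus -> {gene: direction}
    trapped_keys: dict = field(default_factory=dict)  # focus carrying the call -> keys in partner LOH
    n_shared: int = 0
    n_union: int = 0

    @property
    def realized_shared_fraction(self) -> float:
        return self.n_shared / self.n_union if self.n_union else 0.0

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "origin_model": self.origin_model,
            "target_shared_snv_fraction": self.target_shared_snv_fraction,
            "purity": self.purity,
            "shared_keys": sorted(["|".join(map(str, k)) for k in self.shared_keys]),
            "cluster_assignment": {
                f: {"|".join(map(str, k)): int(c) for k, c in a.items()}
                for f, a in self.cluster_assignment.items()
            },
            "cluster_means": {f: list(map(float, m)) for f, m in self.cluster_means.items()},
            "loh_regions": {f: [list(r) for r in v] for f, v in self.loh_regions.items()},
            "cnv_truth": self.cnv_truth,
            "trapped_keys": {
                f: sorted(["|".join(map(str, k)) for k in v]) for f, v in self.trapped_keys.items()
            },
            "n_shared": self.n_shared,
            "n_union": self.n_union,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthRecord":
        def unkey(s: str) -> tuple:
            c, p, r, a = s.split("|")
            return (c, int(p), r, a)

        return cls(
            patient_id=d["patient_id"],
            origin_model=d["origin_model"],
            target_shared_snv_fraction=d["target_shared_snv_fraction"],
            purity=d["purity"],
            shared_keys={unkey(s) for s in d["shared_keys"]},
            cluster_assignment={
                f: {unkey(s): c for s, c in a.items()} for f, a in d["cluster_assignment"].items()
            },
            cluster_means={f: list(m) for f, m in d["cluster_means"].items()},
            loh_regions={f: [tuple(r) for r in v] for f, v in d["loh_regions"].items()},
            cnv_truth=d["cnv_truth"],
            trapped_keys={f: {unkey(s) for s in v} for f, v in d["trapped_keys"].items()},
            n_shared=d["n_shared"],
            n_union=d["n_union"],
        )


@dataclass
class PatientBundle:
    """Everything emitted for one patient, in memory."""

    patient_id: str
    somatic: dict  # focus -> list[VariantRecord]
    somatic_depths: dict  # focus -> {key: (ref_depth, alt_depth)}
    germline: list
    evidence: list  # list[SiteEvidence] over somatic union sites x 3 samples
    segments: dict  # focus -> list[Segment]
    svs: dict  # focus -> list[SVBreakpoint]
    affinities: list  # list[AffinityRecord]
    truth: TruthRecord

    @property
    def purity(self) -> float:
        return self.truth.purity

    def sample_id(self, focus: str) -> str:
        return f"{self.patient_id}_{focus}"

    @property
    def normal_id(self) -> str:
        return f"{self.patient_id}_N"


# ---------------------------------------------------------------------------
# Helpers


def trunk_size(n_per_focus: int, target: float, origin_model: str) -> int:
    """Shared-variant count realizing Jaccard ``target`` with ``n`` variants
    per focus: s/(2n - s) = f  =>  s = 2nf/(1+f).

    MC targets are the top of a 0-2.7% band, so integerization floors to
    avoid overshooting it; ME targets sit inside their band and round.
    """
    s_exact = 2 * n_per_focus * target / (1 + target)
    s = int(np.floor(s_exact)) if origin_model == "MC" else int(round(s_exact))
    return min(s, n_per_focus)


def _mutation_id(key: tuple) -> str:
    chrom, pos, ref, alt = key
    return f"{chrom}:{pos}:{ref}>{alt}"


def _hotspot_site(gene_row) -> tuple[str, int, str, str]:
    """Canonical recurrent site of a gene: fixed offset, fixed alleles."""
    return (gene_row.contig, int(gene_row.start) + 501, "C", "T")


class _SitePool:
    """Draws unique variant sites inside gene bodies of the toy genome."""

    def __init__(self, genes: pd.DataFrame, rng: np.random.Generator):
        self.genes = genes.reset_index(drop=True)
        self.rng = rng
        self.used: set = set()
        self._bases = np.array(list("ACGT"))

    def _alleles(self, indel: bool) -> tuple[str, str]:
        ref = str(self.rng.choice(self._bases))
        if indel:
            if self.rng.random() < 0.5:  # insertion
                ins = "".join(self.rng.choice(self._bases, size=int(self.rng.integers(1, 4))))
                return ref, ref + ins
            return ref + str(self.rng.choice(self._bases)), ref
        alt = str(self.rng.choice(self._bases))
        while alt == ref:
            alt = str(self.rng.choice(self._bases))
        return ref, alt

    def draw(self, allowed: pd.DataFrame, indel_rate: float = 0.1) -> tuple[tuple, str]:
        """One unique (key, gene) with the site inside an allowed gene body."""
        for _ in range(1000):
            row = allowed.iloc[int(self.rng.integers(len(allowed)))]
            pos = int(row.start) + 1 + int(self.rng.integers(int(row.end) - int(row.start)))
            ref, alt = self._alleles(self.rng.random() < indel_rate)
            key = (row.contig, pos, ref, alt)
            if key not in self.used and (row.contig, pos) not in {(k[0], k[1]) for k in self.used}:
                self.used.add(key)
                return key, str(row.gene)
        raise ConfigurationError("could not draw a unique variant site (pool exhausted)")

    def draw_in_region(self, contig: str, start: int, end: int) -> tuple:
        for _ in range(1000):
            pos = start + 1 + int(self.rng.integers(end - start))
            ref, alt = self._alleles(False)
            key = (contig, pos, ref, alt)
            if key not in self.used:
                self.used.add(key)
                return key
        raise ConfigurationError("could not draw a unique site inside region")

    def claim(self, key: tuple) -> None:
        self.used.add(key)


# ---------------------------------------------------------------------------
# Patient simulation


def simulate_patient(cfg: PatientConfig, genes: Optional[pd.DataFrame] = None) -> PatientBundle:
    """Generate one paired-foci patient from its config entry.

    Deterministic given ``cfg.seed`` (which must be resolved). Returns the
    in-memory bundle; :func:`write_cohort` serializes bundles to disk.
    """
    cfg.validate()
    if cfg.seed is None:
        raise ConfigurationError(f"{cfg.patient_id}: seed not resolved")
    rng = np.random.default_rng(cfg.seed)
    genes = genes if genes is not None else load_gene_table()
    categories = load_gene_categories()

    truth = TruthRecord(
        patient_id=cfg.patient_id,
        origin_model=cfg.origin_model,
        target_shared_snv_fraction=cfg.target_shared_snv_fraction,
        purity=cfg.purity,
    )

    # --- copy-number segments and LOH regions (placed first: variants avoid CNV genes)
    segments: dict[str, list[Segment]] = {}
    cnv_genes_by_focus: dict[str, set] = {}
    for focus in FOCI:
        segs = []
        profile = cfg.cnv_profile.get(focus, [])
        truth.cnv_truth[focus] = {g: d for g, d in profile}
        cnv_genes_by_focus[focus] = {g for g, _ in profile}
        for gene_sym, direction in profile:
            row = genes.loc[genes["gene"] == gene_sym]
            if row.empty:
                raise ConfigurationError(f"{cfg.patient_id}: unknown CNV gene {gene_sym}")
            row = row.iloc[0]
            pad = 150_000
            start = max(0, int(row.start) - pad)
            end = min(CONTIGS[row.contig], int(row.end) + pad)
            if direction == "gain":
                segs.append(
                    Segment(row.contig, start, end, 4, baf=0.25, genotype="AAAB", status="gain")
                )
            elif direction == "loss":
                segs.append(
                    Segment(row.contig, start, end, 1, baf=0.0, genotype="A", status="loss", loh=True)
                )
            else:
                raise ConfigurationError(f"bad CNV direction {direction!r}")
        # copy-neutral LOH regions, 1-20 Mb, non-overlapping with existing
        # segments and clear of planted driver genes (the LOH exclusion rule
        # is exercised only by deliberately trapped variants)
        driver_iv = [
            (r.contig, int(r.start), int(r.end))
            for _, r in genes.loc[genes["gene"].isin(cfg.planted_drivers)].iterrows()
        ]
        loh_regions = []
        for _ in range(cfg.n_loh_per_focus):
            for _attempt in range(100):
                contig = f"chr{int(rng.integers(1, 6))}"
                length = int(rng.integers(1_000_000, 20_000_001))
                start = int(rng.integers(0, CONTIGS[contig] - length))
                end = start + length
                clash = any(
                    s.contig == contig and s.start < end and s.end > start for s in segs
                ) or any(c == contig and s0 < end and e0 > start for c, s0, e0 in driver_iv)
                if not clash:
                    segs.append(
                        Segment(contig, start, end, 2, baf=0.0, genotype="AA", status="neutral", loh=True)
                    )
                    loh_regions.append((contig, start, end))
                    break
        truth.loh_regions[focus] = loh_regions
        segments[focus] = sorted(segs, key=lambda s: (s.contig, s.start))

    # genes eligible for ordinary variant placement: outside any CNV of either
    # focus (keeps the allele-sampling model diploid), outside planted drivers,
    # and outside LOH regions of either focus (only trapped variants sit there)
    loh_genes: set = set()
    for focus in FOCI:
        for contig, start, end in truth.loh_regions[focus]:
            loh_genes.update(genes_overlapping(genes, contig, start, end))
    excluded = set().union(*cnv_genes_by_focus.values()) | set(cfg.planted_drivers) | loh_genes
    allowed = genes.loc[~genes["gene"].isin(excluded)].reset_index(drop=True)
    pool = _SitePool(genes, rng)

    # --- somatic variant keys
    n = cfg.n_somatic_per_focus
    s = trunk_size(n, cfg.target_shared_snv_fraction, cfg.origin_model)
    n_drivers = len(cfg.planted_drivers)
    n_trapped = cfg.n_loh_trapped if cfg.n_loh_per_focus > 0 else 0
    if n - s < n_drivers + n_trapped and n > 0:
        raise ConfigurationError(
            f"{cfg.patient_id}: private budget {n - s} too small for "
            f"{n_drivers} drivers + {n_trapped} trapped variants"
        )

    trunk: list[tuple[tuple, str]] = [pool.draw(allowed) for _ in range(s)]
    variants: dict[str, list[VariantRecord]] = {f: [] for f in FOCI}
    key_gene: dict[str, list[tuple[tuple, str]]] = {f: [] for f in FOCI}
    driver_keys: dict[str, list[tuple[tuple, str]]] = {f: [] for f in FOCI}
    trapped_by_focus: dict[str, list[tuple]] = {f: [] for f in FOCI}

    for fi, focus in enumerate(FOCI):
        partner = FOCI[1 - fi]
        # planted drivers: one clonal deleterious mutation per gene
        for gene_sym in cfg.planted_drivers:
            row = genes.loc[genes["gene"] == gene_sym].iloc[0]
            if gene_sym in cfg.hotspot_genes and focus == "Ca1":
                key = _hotspot_site(row)
                pool.claim(key)
            else:
                key, _ = pool.draw(genes.loc[genes["gene"] == gene_sym], indel_rate=0.0)
            driver_keys[focus].append((key, gene_sym))
        # partner-private variants trapped inside this partner's LOH regions
        partner_loh = truth.loh_regions.get(partner, [])
        trapped = []
        if partner_loh and n > 0:
            for j in range(n_trapped):
                contig, start, end = partner_loh[j % len(partner_loh)]
                key = pool.draw_in_region(contig, start, end)
                hit = genes_overlapping(genes, contig, key[1] - 1, key[1])
                trapped.append((key, hit[0] if hit else None))
        trapped_by_focus[focus] = [k for k, _ in trapped]
        truth.trapped_keys[focus] = set(trapped_by_focus[focus])
        n_ordinary = max(0, n - s - len(driver_keys[focus]) - len(trapped))
        ordinary = [pool.draw(allowed) for _ in range(n_ordinary)]
        key_gene[focus] = trunk + driver_keys[focus] + trapped + ordinary

    truth.shared_keys = {k for k, _ in trunk}
    truth.n_shared = s
    truth.n_union = 2 * n - s if n > 0 else 0

    # --- cluster assignment and truth CCFs
    for fi, focus in enumerate(FOCI):
        k_clusters = cfg.n_clusters[fi]
        means = CLUSTER_MEANS[k_clusters]
        weights = np.asarray(_CLUSTER_WEIGHTS[k_clusters])
        assign = {}
        for j, (key, _g) in enumerate(key_gene[focus]):
            clonal = j < s + len(driver_keys[focus])  # trunk + planted drivers
            assign[key] = 0 if clonal else int(rng.choice(k_clusters, p=weights))
        truth.cluster_assignment[focus] = assign
        truth.cluster_means[focus] = list(means)

    # --- variant records with annotations
    for focus in FOCI:
        driver_set = {k for k, _ in driver_keys[focus]}
        for key, gene_sym in key_gene[focus]:
            chrom, pos, ref, alt = key
            is_indel = len(ref) != len(alt)
            if key in driver_set:
                csq = "nonsynonymous"
                sift, pph = round(float(rng.uniform(0.0, 0.05)), 4), round(float(rng.uniform(0.96, 1.0)), 4)
            else:
                csq = (
                    "frameshift"
                    if is_indel and rng.random() < 0.7
                    else ("nonframeshift" if is_indel else ("stopgain" if rng.random() < 0.05 else "nonsynonymous"))
                )
                sift = round(float(rng.uniform(0, 1)), 4) if rng.random() < 0.8 else None
                pph = round(float(rng.uniform(0, 1)), 4) if rng.random() < 0.8 else None
            variants[focus].append(
                VariantRecord(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    variant_class="somatic",
                    gene=gene_sym,
                    region="exonic",
                    consequence=csq,
                    sift=sift,
                    polyphen=pph,
                )
            )

    # --- read-count evidence over the union of somatic sites
    evidence: list[SiteEvidence] = []
    somatic_depths: dict[str, dict] = {f: {} for f in FOCI}
    union_keys = sorted({k for f in FOCI for k, _ in key_gene[f]}, key=lambda k: (k[0], k[1], k[2], k[3]))
    present = {f: {k for k, _ in key_gene[f]} for f in FOCI}

    def local_cn(focus: str, chrom: str, pos: int) -> int:
        for seg in segments[focus]:
            if seg.contains(chrom, pos):
                return seg.copy_number
        return 2

    for key in union_keys:
        chrom, pos, ref, alt = key
        for focus in FOCI:
            depth = max(1, int(rng.poisson(cfg.tumor_depth)))
            if key in present[focus]:
                ccf = truth.cluster_means[focus][truth.cluster_assignment[focus][key]]
                cn = local_cn(focus, chrom, pos)
                vaf = ccf * cfg.purity / (cfg.purity * cn + (1 - cfg.purity) * 2)
                alt_d = int(rng.binomial(depth, min(vaf, 1.0)))
                alt_d = max(alt_d, 3)  # callers only emit supported calls
                depth = max(depth, alt_d)
                somatic_depths[focus][key] = (depth - alt_d, alt_d)
            else:
                alt_d = 0
            evidence.append(
                SiteEvidence(
                    sample_id=f"{cfg.patient_id}_{focus}",
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    ref_depth=depth - alt_d,
                    alt_depth=alt_d,
                    hq_flag=alt_d >= 3,
                )
            )
        ndepth = max(1, int(rng.poisson(cfg.normal_depth)))
        evidence.append(
            SiteEvidence(
                sample_id=f"{cfg.patient_id}_N",
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                ref_depth=ndepth,
                alt_depth=0,
                hq_flag=False,
            )
        )

    # --- structural variants
    svs = _simulate_svs(cfg, rng)

    # --- germline variants
    germline = _simulate_germline(cfg, rng, genes, categories, pool)

    # --- peptide-MHC affinity table
    affinities = _simulate_affinities(cfg, rng, driver_keys, key_gene)

    return PatientBundle(
        patient_id=cfg.patient_id,
        somatic=variants,
        somatic_depths=somatic_depths,
        germline=germline,
        evidence=evidence,
        segments=segments,
        svs=svs,
        affinities=affinities,
        truth=truth,
    )


def _simulate_svs(cfg: PatientConfig, rng: np.random.Generator) -> dict:
    """Per-focus SV breakpoint lists with a target shared Jaccard fraction."""
    m = cfg.sv_count_per_focus
    s = trunk_size(m, cfg.sv_shared_fraction, cfg.origin_model)
    types = ["DEL", "DUP", "INV", "TRA"]

    def one() -> SVBreakpoint:
        t = types[int(rng.integers(4))]
        c1 = f"chr{int(rng.integers(1, 6))}"
        p1 = int(rng.integers(10_000, CONTIGS[c1] - 10_000))
        if t == "TRA":
            c2 = f"chr{int(rng.integers(1, 6))}"
            p2 = int(rng.integers(10_000, CONTIGS[c2] - 10_000))
        else:
            c2 = c1
            p2 = p1 + int(rng.integers(1_000, 1_000_000))
        return SVBreakpoint(c1, p1, c2, p2, t, "+-")

    shared = [one() for _ in range(s)]
    out = {}
    for focus in FOCI:
        out[focus] = shared + [one() for _ in range(m - s)]
    return out


def _simulate_germline(
    cfg: PatientConfig,
    rng: np.random.Generator,
    genes: pd.DataFrame,
    categories: pd.DataFrame,
    pool: "_SitePool",
) -> list:
    """Germline variants: exactly ``germline_total`` survive the rare-variant
    filter cascade (``germline_immune`` of them in immune-category genes,
    ``germline_cosmic_rescued`` carried through on the COSMIC exception),
    plus ``germline_noise_per_rule`` decoys per filter rule."""
    cat_genes = {c: g["gene"].tolist() for c, g in categories.groupby("category")}
    other_cats = [c for c in sorted(cat_genes) if c != "immune"]
    n_other = cfg.germline_total - cfg.germline_immune
    if n_other < 0:
        raise ConfigurationError(f"{cfg.patient_id}: germline_immune exceeds germline_total")
    plan = ["immune"] * cfg.germline_immune + [
        other_cats[i % len(other_cats)] for i in range(n_other)
    ]
    out: list[VariantRecord] = []
    for i, cat in enumerate(plan):
        gene_sym = cat_genes[cat][int(rng.integers(len(cat_genes[cat])))]
        key, _ = pool.draw(genes.loc[genes["gene"] == gene_sym], indel_rate=0.05)
        rescued = i < cfg.germline_cosmic_rescued
        if rescued:
            af = round(float(np.exp(rng.uniform(np.log(2e-3), np.log(5e-2)))), 6)
        else:
            af = 0.0 if rng.random() < 0.7 else round(float(np.exp(rng.uniform(np.log(1e-5), np.log(1e-3)))), 6)
        out.append(
            VariantRecord(
                chrom=key[0],
                pos=key[1],
                ref=key[2],
                alt=key[3],
                variant_class="germline",
                gene=gene_sym,
                region="exonic",
                consequence="nonsynonymous" if rng.random() < 0.9 else "stopgain",
                af_dbsnp=af if af > 0 else None,
                af_1kg=af if af > 0 and rng.random() < 0.5 else None,
                cosmic_flag=rescued,
                repeat_flag=False,
                depth=int(max(10, rng.poisson(30))),
            )
        )
    # decoys: one batch per filter rule, each failing exactly that rule
    any_gene = genes
    for _ in range(cfg.germline_noise_per_rule):  # (i) depth < 10
        key, g = pool.draw(any_gene)
        out.append(
            VariantRecord(*key, variant_class="germline", gene=g, region="exonic",
                          consequence="nonsynonymous", depth=int(rng.integers(1, 10)))
        )
    for _ in range(cfg.germline_noise_per_rule):  # (ii) common, not in COSMIC
        key, g = pool.draw(any_gene)
        af = round(float(np.exp(rng.uniform(np.log(2e-3), np.log(0.5)))), 6)
        out.append(
            VariantRecord(*key, variant_class="germline", gene=g, region="exonic",
                          consequence="nonsynonymous", af_1kg=af,
                          depth=int(max(10, rng.poisson(30))))
        )
    for j in range(cfg.germline_noise_per_rule):  # (iii) noncoding or synonymous
        key, g = pool.draw(any_gene)
        region, csq = [("intronic", "nonsynonymous"), ("exonic", "synonymous"),
                       ("intergenic", "nonsynonymous"), ("UTR", "nonsynonymous")][j % 4]
        out.append(
            VariantRecord(*key, variant_class="germline", gene=g, region=region,
                          consequence=csq, depth=int(max(10, rng.poisson(30))))
        )
    for _ in range(cfg.germline_noise_per_rule):  # (iv) repeat region
        key, g = pool.draw(any_gene)
        out.append(
            VariantRecord(*key, variant_class="germline", gene=g, region="exonic",
                          consequence="nonsynonymous", repeat_flag=True,
                          depth=int(max(10, rng.poisson(30))))
        )
    return out


def _simulate_affinities(
    cfg: PatientConfig,
    rng: np.random.Generator,
    driver_keys: dict,
    key_gene: dict,
) -> list:
    """Affinity rows per focus: planted drivers are forced below 500 nM and
    below wild type (guaranteed candidates); a sample of other mutations gets
    log-uniform affinities in [10, 5000] nM."""
    out: list[AffinityRecord] = []

    def peptide() -> str:
        length = int(rng.integers(9, 12))
        return "".join(np.array(list(_AA))[rng.integers(0, len(_AA), size=length)])

    for focus in FOCI:
        sample = f"{cfg.patient_id}_{focus}"
        forced = {k for k, _ in driver_keys[focus]}
        for key in sorted(forced, key=lambda k: (k[0], k[1])):
            mut = float(np.exp(rng.uniform(np.log(10), np.log(450))))
            wt = mut * float(rng.uniform(2.0, 20.0))
            out.append(
                AffinityRecord(_mutation_id(key), sample, _HLA[int(rng.integers(3))], peptide(), mut, wt)
            )
        others = [k for k, _ in key_gene[focus] if k not in forced]
        take = min(20, len(others))
        idx = rng.choice(len(others), size=take, replace=False) if take else []
        for i in sorted(int(j) for j in np.atleast_1d(idx)):
            key = others[i]
            mut = float(np.exp(rng.uniform(np.log(10), np.log(5000))))
            wt = float(np.exp(rng.uniform(np.log(10), np.log(5000))))
            out.append(
                AffinityRecord(_mutation_id(key), sample, _HLA[int(rng.integers(3))], peptide(), mut, wt)
            )
    return out


# ---------------------------------------------------------------------------
# Cohort-level API


def simulate_cohort(config: CohortConfig) -> list[PatientBundle]:
    """Simulate all patients of a cohort config (seeds resolved in place)."""
    config.validate()
    config.resolve_seeds()
    genes = load_gene_table()
    return [simulate_patient(p, genes=genes) for p in config.patients]


def write_cohort(config: CohortConfig, out_dir: str | Path) -> dict:
    """Simulate and serialize a cohort: one directory per patient plus a
    cohort ``manifest.json`` recording files, seeds and truth. Deterministic
    given the config seeds (two runs are byte-identical)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundles = simulate_cohort(config)
    manifest: dict = {"base_seed": config.base_seed, "patients": []}
    for cfg, b in zip(config.patients, bundles):
        pdir = out_dir / b.patient_id
        pdir.mkdir(exist_ok=True)
        files = {}
        for focus in FOCI:
            files[f"somatic_{focus}"] = str(
                mio.write_vcf(
                    b.somatic[focus],
                    pdir / f"somatic_{focus}.vcf",
                    b.sample_id(focus),
                    depths=b.somatic_depths[focus],
                ).relative_to(out_dir)
            )
            files[f"segments_{focus}"] = str(
                mio.write_segments(b.segments[focus], pdir / f"segments_{focus}.tsv").relative_to(out_dir)
            )
            files[f"sv_{focus}"] = str(
                mio.write_svs(b.svs[focus], pdir / f"sv_{focus}.tsv").relative_to(out_dir)
            )
        files["germline"] = str(
            mio.write_vcf(b.germline, pdir / "germline.vcf", b.normal_id).relative_to(out_dir)
        )
        files["evidence"] = str(mio.write_evidence(b.evidence, pdir / "evidence.tsv").relative_to(out_dir))
        files["affinities"] = str(
            mio.write_affinities(b.affinities, pdir / "affinities.tsv").relative_to(out_dir)
        )
        manifest["patients"].append(
            {
                "patient_id": b.patient_id,
                "seed": cfg.seed,
                "config": cfg.to_dict(),
                "files": files,
                "truth": b.truth.to_dict(),
            }
        )
    mio.write_manifest(manifest, out_dir / "manifest.json")
    return manifest


def load_cohort(cohort_dir: str | Path) -> list[PatientBundle]:
    """Reload a serialized cohort (manifest + per-patient files) into bundles."""
    cohort_dir = Path(cohort_dir)
    manifest = mio.read_manifest(cohort_dir / "manifest.json")
    bundles = []
    for entry in manifest["patients"]:
        pid = entry["patient_id"]
        files = entry["files"]
        somatic, depths, segments, svs = {}, {}, {}, {}
        for focus in FOCI:
            recs = mio.read_vcf(cohort_dir / files[f"somatic_{focus}"], "somatic")
            somatic[focus] = recs
            segments[focus] = mio.read_segments(cohort_dir / files[f"segments_{focus}"])
            svs[focus] = mio.read_svs(cohort_dir / files[f"sv_{focus}"])
        evidence = mio.read_evidence(cohort_dir / files["evidence"])
        lookup = mio.evidence_lookup(evidence)
        for focus in FOCI:
            depths[focus] = {}
            for r in somatic[focus]:
                ev = lookup.get((*r.key, f"{pid}_{focus}"))
                if ev is not None:
                    depths[focus][r.key] = (ev.ref_depth, ev.alt_depth)
        bundles.append(
            PatientBundle(
                patient_id=pid,
                somatic=somatic,
                somatic_depths=depths,
                germline=mio.read_vcf(cohort_dir / files["germline"], "germline"),
                evidence=evidence,
                segments=segments,
                svs=svs,
                affinities=mio.read_affinities(cohort_dir / files["affinities"]),
                truth=TruthRecord.from_dict(entry["truth"]),
            )
        )
    return bundles


# ---------------------------------------------------------------------------
# Packaged default cohort


def default_cohort_config(base_seed: int = 20240601) -> CohortConfig:
    """The packaged 10-patient cohort: 6 multicentric patients with target
    shared SNV fractions spread over the 0-2.7% band (none sharing SVs) and
    4 metastatic patients over 58-67.6% (high SV sharing). Patient P04
    mirrors the monoclonal-both-foci case, P01 has one monoclonal focus.
    Recurrent CNVs: CCND1/CTTN gained in every focus, CDKN2A/CDKN2B lost in
    six foci. MC patients carry more immune-gene germline variants than ME
    patients at matched total burden."""
    gains = [("CCND1", "gain"), ("CTTN", "gain")]
    dels = [("CDKN2A", "loss"), ("CDKN2B", "loss")]
    mc_private = [  # per MC patient: (Ca1-only genes, Ca2-only genes)
        ((["EGFR", "MYC"], ["FGFR1", "MET"])),
        ((["KRAS", "ERBB2"], ["BRAF", "PIK3CA"])),
        ((["RB1", "E2F1"], ["CDK4", "CDK6"])),
        ((["SMAD4"], [])),  # P1423-like: few CNV events in Ca2
        ((["PTEN", "ARID1A"], ["KMT2D", "NFE2L2"])),
        ((["ZNF750", "CCNE1"], ["APC", "CDH1"])),
    ]
    me_shared = [  # per ME patient: genes altered identically in both foci
        ["EGFR", "MYC", "KRAS"],
        ["PIK3CA", "ERBB2"],
        ["RB1", "PTEN", "SMAD4"],
        ["KMT2D", "ARID1A"],
    ]

    def profile_mc(i):
        ca1, ca2 = mc_private[i]
        extra = dels if i in (0, 2) else []
        return {
            "Ca1": gains + extra + [(g, "gain") for g in ca1],
            "Ca2": gains + extra + [(g, "loss") for g in ca2],
        }

    def profile_me(i):
        extra = dels if i == 0 else []
        prof = gains + extra + [(g, "gain") for g in me_shared[i]]
        return {"Ca1": list(prof), "Ca2": list(prof)}

    mc_targets = [0.0, 0.005, 0.010, 0.015, 0.020, 0.027]
    me_targets = [0.58, 0.61, 0.645, 0.676]
    mc_clusters = [(2, 1), (2, 2), (3, 2), (1, 1), (2, 3), (3, 3)]
    me_clusters = [(2, 2), (2, 3), (3, 2), (2, 2)]
    mc_purity = [0.80, 0.75, 0.85, 0.80, 0.70, 0.90]
    me_purity = [0.80, 0.75, 0.85, 0.80]
    mc_immune = [9, 11, 8, 12, 10, 13]
    me_immune = [3, 2, 4, 1]
    mc_total = [44, 47, 43, 46, 45, 44]
    me_total = [45, 44, 46, 45]
    mc_drivers = [
        ["TP53", "MUC16"],
        ["TP53", "MUC16", "DGKZ"],
        ["TP53", "MUC16"],
        ["TP53", "DGKZ"],
        ["TP53"],
        ["TP53", "DGKZ"],
    ]

    patients = []
    for i in range(6):
        patients.append(
            PatientConfig(
                patient_id=f"P{i + 1:02d}",
                origin_model="MC",
                target_shared_snv_fraction=mc_targets[i],
                n_clusters=mc_clusters[i],
                purity=mc_purity[i],
                cnv_profile=profile_mc(i),
                sv_shared_fraction=0.0,
                germline_total=mc_total[i],
                germline_immune=mc_immune[i],
                planted_drivers=mc_drivers[i],
                hotspot_genes=["TP53"],
            )
        )
    for i in range(4):
        patients.append(
            PatientConfig(
                patient_id=f"P{i + 7:02d}",
                origin_model="ME",
                target_shared_snv_fraction=me_targets[i],
                n_clusters=me_clusters[i],
                purity=me_purity[i],
                cnv_profile=profile_me(i),
                sv_shared_fraction=0.60,
                germline_total=me_total[i],
                germline_immune=me_immune[i],
                planted_drivers=["TP53"],
            )
        )
    return CohortConfig(patients=patients, base_seed=base_seed)
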