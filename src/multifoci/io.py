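"""Readers and writers for the on-disk cohort formats.

Variants travel as VCF 4.2 (1-based) with the annotation schema documented
below; read-count evidence, copy-number segments, SV breakpoints and
peptide-MHC affinities travel as TSV. Writing is plain-text serialization;
reading VCF goes through :mod:`pysam`.

VCF INFO keys: GENE, REGION, CSQ (consequence), AF_DBSNP, AF_1KG, AF_EXAC,
COSMIC (0/1), REPEAT (0/1), SIFT, PPH2. FORMAT: AD (ref,alt), DP.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import pysam

from .genome import CONTIGS
from .records import AffinityRecord, Segment, SiteEvidence, SVBreakpoint, VariantRecord

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_evidence",
    "read_evidence",
    "evidence_lookup",
    "write_segments",
    "read_segments",
    "write_svs",
    "read_svs",
    "write_affinities",
    "read_affinities",
    "write_manifest",
    "read_manifest",
]

_VCF_INFO_DEFS = [
    ('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">'),
    ('##INFO=<ID=REGION,Number=1,Type=String,Description="Region class">'),
    ('##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">'),
    ('##INFO=<ID=AF_DBSNP,Number=1,Type=Float,Description="dbSNP allele frequency">'),
    ('##INFO=<ID=AF_1KG,Number=1,Type=Float,Description="1000 Genomes allele frequency">'),
    ('##INFO=<ID=AF_EXAC,Number=1,Type=Float,Description="ExAC allele frequency">'),
    ('##INFO=<ID=COSMIC,Number=1,Type=Integer,Description="Present in COSMIC (0/1)">'),
    ('##INFO=<ID=REPEAT,Number=1,Type=Integer,Description="In genome repeat region (0/1)">'),
    ('##INFO=<ID=SIFT,Number=1,Type=Float,Description="SIFT score">'),
    ('##INFO=<ID=PPH2,Number=1,Type=Float,Description="PolyPhen-2 score">'),
    ('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Ref,alt read depths">'),
    ('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">'),
]


def _fmt_float(x: float) -> str:
    return format(float(x), ".6g")


def write_vcf(
    records: Iterable[VariantRecord],
    path: str | Path,
    sample_id: str,
    depths: Optional[dict[tuple, tuple[int, int]]] = None,
    contigs: Optional[dict[str, int]] = None,
) -> Path:
    """Serialize variant records to an uncompressed VCF 4.2 file.

    ``depths`` maps variant keys to (ref_depth, alt_depth) for the sample
    column; variants without an entry fall back to ``record.depth`` (DP only).
    """
    path = Path(path)
    contigs = contigs if contigs is not None else CONTIGS
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={name},length={length}>" for name, length in contigs.items()]
    lines += _VCF_INFO_DEFS
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id
    )
    order = {name: i for i, name in enumerate(contigs)}
    recs = sorted(records, key=lambda r: (order.get(r.chrom, len(order)), r.pos, r.ref, r.alt))
    for r in recs:
        info = [f"GENE={r.gene or '.'}", f"REGION={r.region}", f"CSQ={r.consequence}"]
        for tag, val in (
            ("AF_DBSNP", r.af_dbsnp),
            ("AF_1KG", r.af_1kg),
            ("AF_EXAC", r.af_exac),
        ):
            if val is not None:
                info.append(f"{tag}={_fmt_float(val)}")
        info.append(f"COSMIC={int(r.cosmic_flag)}")
        info.append(f"REPEAT={int(r.repeat_flag)}")
        if r.sift is not None:
            info.append(f"SIFT={_fmt_float(r.sift)}")
        if r.polyphen is not None:
            info.append(f"PPH2={_fmt_float(r.polyphen)}")
        if depths is not None and r.key in depths:
            rd, ad = depths[r.key]
            sample = f"{rd},{ad}:{rd + ad}"
        elif r.depth is not None:
            sample = f".,.:{r.depth}"
        else:
            sample = ".,.:."
        lines.append(
            "\t".join(
                [
                    r.chrom,
                    str(r.pos),
                    ".",
                    r.ref,
                    r.alt,
                    ".",
                    "PASS",
                    ";".join(info),
                    "AD:DP",
                    sample,
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_vcf(path: str | Path, variant_class: str = "somatic") -> list[VariantRecord]:
    """Parse a VCF written by :func:`write_vcf` (or any VCF carrying the
    documented INFO schema) into variant records."""
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            info = rec.info
            gene = info.get("GENE")
            if gene == ".":
                gene = None
            dp = None
            if len(rec.samples):
                s = rec.samples[0]
                dp = s.get("DP")
            for alt in rec.alts or ():
                out.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        variant_class=variant_class,
                        gene=gene,
                        region=info.get("REGION", "exonic"),
                        consequence=info.get("CSQ", "nonsynonymous"),
                        af_dbsnp=_maybe_float(info.get("AF_DBSNP")),
                        af_1kg=_maybe_float(info.get("AF_1KG")),
                        af_exac=_maybe_float(info.get("AF_EXAC")),
                        cosmic_flag=bool(info.get("COSMIC", 0)),
                        repeat_flag=bool(info.get("REPEAT", 0)),
                        sift=_maybe_float(info.get("SIFT")),
                        polyphen=_maybe_float(info.get("PPH2")),
                        depth=int(dp) if dp is not None else None,
                    )
                )
    return out


def _maybe_float(v) -> Optional[float]:
    if v is None:
        return None
    # pysam rounds Float INFO values through C floats; renormalize
    return float(format(float(v), ".6g"))


# ---------------------------------------------------------------------------
# TSV tables

_EVIDENCE_COLS = ["chrom", "pos", "ref", "alt", "sample_id", "ref_depth", "alt_depth", "hq_flag"]


def write_evidence(rows: Iterable[SiteEvidence], path: str | Path) -> Path:
    df = pd.DataFrame(
        [
            (e.chrom, e.pos, e.ref, e.alt, e.sample_id, e.ref_depth, e.alt_depth, int(e.hq_flag))
            for e in rows
        ],
        columns=_EVIDENCE_COLS,
    )
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_evidence(path: str | Path) -> list[SiteEvidence]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str, "sample_id": str})
    missing = set(_EVIDENCE_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"evidence table {path}: missing columns {sorted(missing)}")
    return [
        SiteEvidence(
            sample_id=r.sample_id,
            chrom=r.chrom,
            pos=int(r.pos),
            ref=r.ref,
            alt=r.alt,
            ref_depth=int(r.ref_depth),
            alt_depth=int(r.alt_depth),
            hq_flag=bool(r.hq_flag),
        )
        for r in df.itertuples()
    ]


def evidence_lookup(rows: Iterable[SiteEvidence]) -> dict[tuple, SiteEvidence]:
    """Index evidence by (chrom, pos, ref, alt, sample_id)."""
    return {(e.chrom, e.pos, e.ref, e.alt, e.sample_id): e for e in rows}


def write_segments(segments: Iterable[Segment], path: str | Path) -> Path:
    df = pd.DataFrame(
        [
            (
                s.contig,
                s.start,
                s.end,
                s.copy_number,
                "" if s.baf is None else _fmt_float(s.baf),
                s.genotype,
                s.status,
                int(s.loh),
            )
            for s in segments
        ],
        columns=["contig", "start", "end", "copy_number", "baf", "genotype", "status", "loh"],
    )
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_segments(path: str | Path) -> list[Segment]:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "genotype": str})
    return [
        Segment(
            contig=r.contig,
            start=int(r.start),
            end=int(r.end),
            copy_number=int(r.copy_number),
            baf=None if pd.isna(r.baf) else float(r.baf),
            genotype=r.genotype,
            status=r.status,
            loh=bool(r.loh),
        )
        for r in df.itertuples()
    ]


def write_svs(svs: Iterable[SVBreakpoint], path: str | Path) -> Path:
    df = pd.DataFrame(
        [(s.chrom1, s.pos1, s.chrom2, s.pos2, s.svtype, s.orientation) for s in svs],
        columns=["chrom1", "pos1", "chrom2", "pos2", "svtype", "orientation"],
    )
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_svs(path: str | Path) -> list[SVBreakpoint]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom1": str, "chrom2": str, "orientation": str})
    return [
        SVBreakpoint(
            chrom1=r.chrom1,
            pos1=int(r.pos1),
            chrom2=r.chrom2,
            pos2=int(r.pos2),
            svtype=r.svtype,
            orientation=r.orientation,
        )
        for r in df.itertuples()
    ]


def write_affinities(records: Iterable[AffinityRecord], path: str | Path) -> Path:
    df = pd.DataFrame(
        [
            (a.mutation_id, a.focus_id, a.hla_allele, a.peptide, a.mut_affinity_nM, a.wt_affinity_nM)
            for a in records
        ],
        columns=["mutation_id", "focus_id", "hla_allele", "peptide", "mut_affinity_nM", "wt_affinity_nM"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")
    return Path(path)


def read_affinities(path: str | Path) -> list[AffinityRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"mutation_id": str, "focus_id": str})
    return [
        AffinityRecord(
            mutation_id=r.mutation_id,
            focus_id=r.focus_id,
            hla_allele=r.hla_allele,
            peptide=r.peptide,
            mut_affinity_nM=float(r.mut_affinity_nM),
            wt_affinity_nM=float(r.wt_affinity_nM),
        )
        for r in df.itertuples()
    ]


def write_manifest(manifest: dict, path: str | Path) -> Path:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return Path(path)


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
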