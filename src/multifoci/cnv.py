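"""Copy-number / LOH segment calls and gene-level recurrence across foci.

Status is called relative to ploidy (default diploid): CN above ploidy is a
gain, below is a loss. LOH is a genotype property — a segment whose
genotype carries exactly one distinct allele symbol (AA, A, AAA, ...) with
at least one copy is LOH, which includes copy-neutral LOH (AA at CN 2).
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .errors import InputDataError
from .records import Segment

__all__ = [
    "call_status",
    "call_loh",
    "validate_segments",
    "recurrence_matrix",
]


def call_status(segment: Segment, ploidy: int = 2) -> str:
    """gain | loss | neutral relative to ``ploidy``."""
    if ploidy < 1:
        raise InputDataError(f"ploidy must be >= 1, got {ploidy}")
    if segment.copy_number > ploidy:
        return "gain"
    if segment.copy_number < ploidy:
        return "loss"
    return "neutral"


def call_loh(segment: Segment) -> bool:
    """True iff the genotype has a single distinct allele and CN >= 1."""
    if not segment.genotype:
        raise InputDataError("segment has empty genotype")
    return len(set(segment.genotype)) == 1 and segment.copy_number >= 1


def validate_segments(segments: Sequence[Segment]) -> None:
    """Reject overlapping segments within one focus."""
    by_contig: dict[str, list[Segment]] = {}
    for s in segments:
        by_contig.setdefault(s.contig, []).append(s)
    for contig, segs in by_contig.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise InputDataError(
                    f"overlapping segments on {contig}: "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )


def recurrence_matrix(
    cohort_segments: dict,
    genes: pd.DataFrame,
    min_foci: int = 3,
    ploidy: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x focus CNV status matrix and per-gene recurrence counts.

    ``cohort_segments`` maps focus id -> segment list. A gene's status in a
    focus is gain/loss if it overlaps a non-neutral segment by >= 1 bp
    (neutral otherwise). Returns (matrix, counts); ``counts`` has the number
    of non-neutral foci per gene and a ``recurrent`` flag at >= ``min_foci``
    (default 3, i.e. "more than 2 foci")."""
    foci = sorted(cohort_segments)
    for f in foci:
        validate_segments(cohort_segments[f])
    matrix = pd.DataFrame("neutral", index=list(genes["gene"]), columns=foci)
    for f in foci:
        for seg in cohort_segments[f]:
            status = call_status(seg, ploidy)
            if status == "neutral":
                continue
            hit = (
                (genes["contig"] == seg.contig)
                & (genes["start"] < seg.end)
                & (genes["end"] > seg.start)
            )
            for g in genes.loc[hit, "gene"]:
                matrix.loc[g, f] = status
    n_foci = (matrix != "neutral").sum(axis=1)
    counts = pd.DataFrame(
        {
            "gene": matrix.index,
            "n_foci": n_foci.to_numpy(),
            "n_gain": (matrix == "gain").sum(axis=1).to_numpy(),
            "n_loss": (matrix == "loss").sum(axis=1).to_numpy(),
        }
    )
    counts["recurrent"] = counts["n_foci"] >= min_foci
    counts = counts.sort_values(
        ["n_foci", "gene"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return matrix, counts
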