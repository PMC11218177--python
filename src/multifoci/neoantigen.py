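"""Neoantigen candidate filtering and cross-focus recurrence.

A peptide-MHC record is a candidate iff the mutant binding affinity is
strictly below 500 nM **and** strictly below the wild-type peptide's
affinity (stronger binding = lower nM). Recurrence counts the distinct
foci in which a mutation yields at least one candidate peptide.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .records import AffinityRecord

__all__ = ["AFFINITY_CUTOFF_NM", "filter_candidates", "recurrent_neoantigens"]

AFFINITY_CUTOFF_NM = 500.0


def filter_candidates(
    records: Sequence[AffinityRecord],
    cutoff_nM: float = AFFINITY_CUTOFF_NM,
) -> list[AffinityRecord]:
    """Records with mut_affinity < cutoff and mut_affinity < wt_affinity
    (both strict). Record validity (positive affinities, 9-11mer peptides)
    is enforced by :class:`AffinityRecord` itself."""
    return [
        r
        for r in records
        if r.mut_affinity_nM < cutoff_nM and r.mut_affinity_nM < r.wt_affinity_nM
    ]


def recurrent_neoantigens(
    candidates: Sequence[AffinityRecord],
    min_foci: int = 3,
) -> pd.DataFrame:
    """Per-mutation focus counts over candidate records.

    A focus counts once per mutation no matter how many peptides/alleles
    pass. Returns mutation_id, n_foci, best (lowest) mutant affinity, and a
    ``recurrent`` flag at >= ``min_foci`` (default 3, "more than 2 foci")."""
    foci: dict[str, set] = {}
    best: dict[str, float] = {}
    for r in candidates:
        foci.setdefault(r.mutation_id, set()).add(r.focus_id)
        best[r.mutation_id] = min(best.get(r.mutation_id, float("inf")), r.mut_affinity_nM)
    df = pd.DataFrame(
        [
            {"mutation_id": m, "n_foci": len(f), "best_affinity_nM": best[m]}
            for m, f in foci.items()
        ]
    )
    if df.empty:
        return pd.DataFrame(columns=["mutation_id", "n_foci", "best_affinity_nM", "recurrent"])
    df["recurrent"] = df["n_foci"] >= min_foci
    return df.sort_values(
        ["n_foci", "mutation_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
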