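"""Germline rare-variant filter cascade, susceptibility-gene screen,
functional categorization and group comparisons.

The cascade retains a germline variant iff

* (i)   caller depth >= 10x;
* (ii)  max population AF across dbSNP / 1000 Genomes / ExAC <= 0.001
        (missing AF counts as 0 / novel), **or** the variant is in COSMIC
        (cancer-associated sites are kept regardless of population AF);
* (iii) the region is exonic or splicing and the consequence is not
        synonymous (UTR / ncRNA / intronic / intergenic are dropped);
* (iv)  the site is not in a genome repeat region.

Retention is a conjunction, so rules (ii)-(iv) commute; only the
per-rule drop attribution depends on the (i)->(iv) order. Retained variants
are intersected with a Cancer Gene Census-style list and tallied by
functional category (immune, cell_cycle, proliferation, dna_repair,
adhesion, other); MC-vs-ME category comparisons reuse the exact rank-sum
test; gene-set enrichment is a hypergeometric upper tail with
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import InputDataError
from .records import VariantRecord

__all__ = [
    "GermlineProfile",
    "filter_germline",
    "intersect_cgc",
    "compare_category",
    "enrich_sets",
    "CATEGORIES",
]

CATEGORIES = ("immune", "cell_cycle", "proliferation", "dna_repair", "adhesion", "other")

AF_THRESHOLD = 0.001
MIN_GERMLINE_DEPTH = 10

_RULES = ("no_depth", "depth", "population_af", "region", "repeat")


@dataclass
class GermlineProfile:
    """Filter-cascade output for one patient."""

    patient_id: str
    retained: list = field(default_factory=list)
    drop_counts: dict = field(default_factory=lambda: {r: 0 for r in _RULES})
    category_counts: dict = field(default_factory=lambda: {c: 0 for c in CATEGORIES})

    @property
    def n_input(self) -> int:
        return len(self.retained) + sum(self.drop_counts.values())


def filter_germline(
    variants: Sequence[VariantRecord],
    patient_id: str = "",
    categories: Optional[pd.DataFrame] = None,
    af_threshold: float = AF_THRESHOLD,
    min_depth: int = MIN_GERMLINE_DEPTH,
) -> GermlineProfile:
    """Run the four-rule cascade; attribute each drop to the first failing
    rule in order (i) depth, (ii) population AF (with COSMIC rescue),
    (iii) region/consequence, (iv) repeat. Variants with no recorded depth
    are dropped with a distinct ``no_depth`` count.

    ``categories`` (gene, category) assigns retained variants to functional
    categories; genes absent from the table count as ``other``.
    """
    profile = GermlineProfile(patient_id=patient_id)
    cat_map = (
        dict(zip(categories["gene"], categories["category"])) if categories is not None else {}
    )
    for v in variants:
        if v.depth is None:
            profile.drop_counts["no_depth"] += 1
        elif v.depth < min_depth:
            profile.drop_counts["depth"] += 1
        elif v.max_population_af() > af_threshold and not v.cosmic_flag:
            profile.drop_counts["population_af"] += 1
        elif v.region not in ("exonic", "splicing") or v.consequence == "synonymous":
            profile.drop_counts["region"] += 1
        elif v.repeat_flag:
            profile.drop_counts["repeat"] += 1
        else:
            profile.retained.append(v)
            cat = cat_map.get(v.gene, "other")
            if cat not in profile.category_counts:
                profile.category_counts[cat] = 0
            profile.category_counts[cat] += 1
    return profile


def intersect_cgc(profile: GermlineProfile, cgc: Sequence[str]) -> list[str]:
    """De-duplicated, sorted genes of retained variants present in the
    census list (candidate cancer-susceptibility genes)."""
    cgc_set = set(cgc)
    return sorted({v.gene for v in profile.retained if v.gene in cgc_set})


def compare_category(
    mc_profiles: Sequence[GermlineProfile],
    me_profiles: Sequence[GermlineProfile],
    category: str,
) -> tuple[float, list[int], list[int]]:
    """Exact two-sided rank-sum comparison of per-patient retained-variant
    counts in one category (or ``"total"``) between the MC and ME groups."""
    from .origin import exact_rank_sum

    def counts(profiles):
        if category == "total":
            return [len(p.retained) for p in profiles]
        for p in profiles:
            if category not in p.category_counts:
                raise InputDataError(f"category {category!r} absent from profile {p.patient_id}")
        return [p.category_counts[category] for p in profiles]

    mc, me = counts(mc_profiles), counts(me_profiles)
    return exact_rank_sum(mc, me), mc, me


def enrich_sets(
    genes: Sequence[str],
    annotation: pd.DataFrame,
    universe: Sequence[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query gene list in each gene
    set, BH-adjusted across sets.

    ``annotation`` has columns (gene, set); the per-set p-value is the
    upper tail P(X >= k) of Hypergeometric(M=|universe|, K=|set|, N=|query|).
    """
    universe_set = set(universe)
    query = set(genes)
    missing = sorted(query - universe_set)
    if missing:
        raise InputDataError(f"query genes not in universe: {missing}")
    required = {"gene", "set"}
    if not required.issubset(annotation.columns):
        raise InputDataError(f"annotation table missing columns {required - set(annotation.columns)}")
    M, N = len(universe_set), len(query)
    rows = []
    for set_name, grp in annotation.groupby("set"):
        members = set(grp["gene"]) & universe_set
        K = len(members)
        k = len(query & members)
        p = float(hypergeom.sf(k - 1, M, K, N)) if K else 1.0
        rows.append({"set": set_name, "n_set": K, "n_overlap": k, "p_value": p})
    out = pd.DataFrame(rows).sort_values("p_value", kind="stable").reset_index(drop=True)
    if len(out):
        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    else:
        out["p_adjusted"] = []
    return out
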