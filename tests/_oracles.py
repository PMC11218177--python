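"""Independent brute-force oracles used only by the tests.

Each oracle recomputes a quantity by the most literal method available
(pairwise comparisons, explicit set algebra, permutation draws) without
sharing code with the implementation it checks.
"""

from itertools import combinations

import numpy as np


def rank_sum_p_oracle(x, y):
    """Two-sided exact rank-sum p-value via the Mann-Whitney U statistic
    computed by pairwise comparisons (ties count 1/2), enumerated over all
    assignments of the pooled values to the first group."""
    pooled = list(x) + list(y)
    n1, n = len(x), len(x) + len(y)

    def u_stat(group1_idx):
        g1 = [pooled[i] for i in group1_idx]
        g2 = [pooled[i] for i in range(n) if i not in group1_idx]
        u = 0.0
        for a in g1:
            for b in g2:
                u += 1.0 if a > b else (0.5 if a == b else 0.0)
        return u

    u_obs = u_stat(set(range(n1)))
    us = [u_stat(set(idx)) for idx in combinations(range(n), n1)]
    eps = 1e-9
    n_le = sum(1 for u in us if u <= u_obs + eps)
    n_ge = sum(1 for u in us if u >= u_obs - eps)
    return min(1.0, 2.0 * min(n_le, n_ge) / len(us))


def sharing_oracle(variants_a, variants_b, evidence, loh_b, loh_a,
                   sample_a, sample_b, sample_n, min_depth=10, min_alt=3):
    """Literal set computation of the sharing categories on a toy pair.

    ``evidence`` maps (chrom,pos,ref,alt,sample) -> (ref_depth, alt_depth,
    hq); ``loh_*`` are lists of (contig, start0, end0) LOH intervals.
    Returns dict of category -> set of variant keys.
    """

    def in_loh(key, regions):
        chrom, pos = key[0], key[1]
        return any(c == chrom and s < pos <= e for c, s, e in regions)

    def classify(key, own, partner, partner_loh):
        rd, ad, hq = evidence[(*key, own)]
        nrd, nad, _ = evidence[(*key, sample_n)]
        if rd + ad < min_depth or nrd + nad < min_depth or not hq or ad < min_alt:
            return "failed"
        prd, pad, _ = evidence[(*key, partner)]
        if pad >= 1:
            return "shared"
        if in_loh(key, partner_loh):
            return "excluded"
        return "unique"

    keys_a = {v.key for v in variants_a if v.consequence != "synonymous" and v.region in ("exonic", "splicing")}
    keys_b = {v.key for v in variants_b if v.consequence != "synonymous" and v.region in ("exonic", "splicing")}
    out = {"shared": set(), "unique_a": set(), "unique_b": set(), "excluded": set(), "failed": set()}
    for key in keys_a | keys_b:
        cls = set()
        if key in keys_a:
            cls.add(("a", classify(key, sample_a, sample_b, loh_b)))
        if key in keys_b:
            cls.add(("b", classify(key, sample_b, sample_a, loh_a)))
        statuses = {c for _, c in cls}
        if "shared" in statuses:
            out["shared"].add(key)
        elif statuses == {"failed"}:
            out["failed"].add(key)
        elif "excluded" in statuses:
            out["excluded"].add(key)
        elif ("a", "unique") in cls:
            out["unique_a"].add(key)
        else:
            out["unique_b"].add(key)
    return out


def hypergeom_permutation_oracle(n_universe, n_set, n_query, n_overlap_obs,
                                 n_draws=10_000, seed=0):
    """P(overlap >= observed) estimated by random draws of the query from
    the universe; returns (estimate, standard error)."""
    rng = np.random.default_rng(seed)
    universe = np.arange(n_universe)
    in_set = universe < n_set
    hits = 0
    for _ in range(n_draws):
        draw = rng.choice(n_universe, size=n_query, replace=False)
        if in_set[draw].sum() >= n_overlap_obs:
            hits += 1
    p = hits / n_draws
    se = np.sqrt(max(p * (1 - p), 1.0 / n_draws) / n_draws)
    return p, se
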