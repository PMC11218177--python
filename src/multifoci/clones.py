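"""Cancer-cell-fraction estimation, clone clustering and key mutations.

The clustering is a deliberately simple, deterministic stand-in for
Dirichlet-process CCF clustering tools: a finite binomial mixture over alt
read counts, fitted by EM for K = 1..K_max with multiple k-means++-style
restarts, with K selected by BIC. Component k has a CCF parameter c_k; the
success probability at mutation i is phi_i * c_k, where

    phi_i = purity * multiplicity_i / (purity * CN_i + (1 - purity) * 2)

is the CCF-to-VAF conversion factor of the site (CN_i: local tumor copy
number). A focus whose selected K is 1 is called monoclonal.

Key mutations are deleterious mutations in clonal clusters: cluster mean
CCF >= 0.5 and SIFT <= 0.05 or PolyPhen-2 >= 0.957 (missing scores count
as non-deleterious for that criterion).
"""

from __future__ import annotations

from math import lgamma
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputDataError
from .records import CCFEstimate, ClusterResult, Segment, VariantRecord

__all__ = [
    "estimate_ccf",
    "ccf_inputs_for_focus",
    "fit_clusters",
    "select_key_mutations",
    "driver_recurrence",
    "CCF_CAP",
    "KEY_CCF_MIN",
    "KEY_SIFT_MAX",
    "KEY_POLYPHEN_MIN",
]

CCF_CAP = 1.5
KEY_CCF_MIN = 0.5
KEY_SIFT_MAX = 0.05
KEY_POLYPHEN_MIN = 0.957


def _phi(purity: float, copy_number: int, multiplicity: int) -> float:
    return purity * multiplicity / (purity * copy_number + (1.0 - purity) * 2.0)


def estimate_ccf(
    alt_depth: int,
    ref_depth: int,
    copy_number: int,
    purity: float,
    multiplicity: int = 1,
    mutation_id: str = "",
) -> CCFEstimate:
    """CCF of one mutation from its VAF, purity-and-CN corrected:

    ccf = vaf * (purity*CN + (1-purity)*2) / (purity * multiplicity),
    capped at 1.5 (values above 1 flag inconsistent CN/purity, not biology).
    """
    if alt_depth < 0 or ref_depth < 0:
        raise InputDataError("read depths must be non-negative")
    total = alt_depth + ref_depth
    if total == 0:
        raise InputDataError("zero total depth at mutation site")
    if not (0.0 < purity <= 1.0):
        raise InputDataError(f"purity must be in (0,1], got {purity}")
    vaf = alt_depth / total
    ccf = min(vaf / _phi(purity, copy_number, multiplicity), CCF_CAP)
    return CCFEstimate(
        mutation_id=mutation_id,
        vaf=vaf,
        copy_number=copy_number,
        multiplicity=multiplicity,
        purity=purity,
        ccf=ccf,
    )


def ccf_inputs_for_focus(
    variants: Sequence[VariantRecord],
    depths: dict,
    segments: Sequence[Segment],
    purity: float,
) -> tuple[list[CCFEstimate], np.ndarray, np.ndarray]:
    """Per-mutation CCF estimates plus (alt, total) depth arrays for one
    focus. Local copy number comes from the overlapping segment (2 outside
    segments); multiplicity is 1 except inside gains, where it is
    round(vaf * CN / purity) clipped to [1, CN]."""
    estimates, alts, totals = [], [], []
    for v in variants:
        if v.key not in depths:
            raise InputDataError(f"no read depths recorded for {v.key}")
        ref_d, alt_d = depths[v.key]
        cn, status = 2, "neutral"
        for seg in segments:
            if seg.contains(v.chrom, v.pos):
                cn, status = seg.copy_number, seg.status
                break
        mult = 1
        if status == "gain":
            vaf = alt_d / (alt_d + ref_d)
            mult = int(np.clip(round(vaf * cn / purity), 1, cn))
        estimates.append(
            estimate_ccf(alt_d, ref_d, cn, purity, mult, mutation_id=f"{v.chrom}:{v.pos}:{v.ref}>{v.alt}")
        )
        alts.append(alt_d)
        totals.append(alt_d + ref_d)
    return estimates, np.asarray(alts), np.asarray(totals)


def _em_once(
    alt: np.ndarray,
    depth: np.ndarray,
    phi: np.ndarray,
    c_init: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """One EM run; returns (loglik, component CCFs, weights, responsibilities)."""
    n, k = alt.size, c_init.size
    log_binom = np.array(
        [lgamma(d + 1) - lgamma(a + 1) - lgamma(d - a + 1) for a, d in zip(alt, depth)]
    )
    c = c_init.astype(float).copy()
    w = np.full(k, 1.0 / k)
    prev_ll = -np.inf
    resp = np.full((n, k), 1.0 / k)
    for _ in range(max_iter):
        p = np.clip(phi[:, None] * c[None, :], 1e-9, 1.0 - 1e-9)
        log_pmf = log_binom[:, None] + alt[:, None] * np.log(p) + (depth - alt)[:, None] * np.log1p(-p)
        log_joint = np.log(np.clip(w, 1e-12, None))[None, :] + log_pmf
        m = log_joint.max(axis=1, keepdims=True)
        log_norm = m[:, 0] + np.log(np.exp(log_joint - m).sum(axis=1))
        ll = float(log_norm.sum())
        resp = np.exp(log_joint - log_norm[:, None])
        w = resp.mean(axis=0)
        num = resp.T @ alt
        den = resp.T @ (depth * phi)
        c = np.where(den > 0, num / np.clip(den, 1e-12, None), c)
        c = np.clip(c, 1e-4, CCF_CAP)
        if abs(ll - prev_ll) < tol:
            prev_ll = ll
            break
        prev_ll = ll
    return prev_ll, c, w, resp


def _kmeanspp_init(values: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    centers = [values[int(rng.integers(values.size))]]
    while len(centers) < k:
        d2 = np.min([(values - c) ** 2 for c in centers], axis=0)
        if d2.sum() <= 0:
            centers.append(values[int(rng.integers(values.size))])
        else:
            centers.append(values[int(rng.choice(values.size, p=d2 / d2.sum()))])
    return np.asarray(centers)


def fit_clusters(
    estimates: Sequence[CCFEstimate],
    alt: np.ndarray,
    depth: np.ndarray,
    k_max: int = 6,
    restarts: int = 50,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    focus_id: str = "",
) -> ClusterResult:
    """Fit binomial mixtures for K = 1..k_max and select K by BIC.

    Deterministic given ``seed``. Fewer than 5 mutations short-circuits to a
    single cluster at the mean CCF with a warning.
    """
    alt = np.asarray(alt)
    depth = np.asarray(depth)
    n = len(estimates)
    if n != alt.size or n != depth.size:
        raise InputDataError("estimates and read-count arrays disagree in length")
    ccfs = np.array([e.ccf for e in estimates])
    phi = np.array([_phi(e.purity, e.copy_number, e.multiplicity) for e in estimates])
    if n < 5:
        mean = float(ccfs.mean()) if n else 0.0
        return ClusterResult(
            focus_id=focus_id,
            assignments=[0] * n,
            means=[mean],
            weights=[1.0],
            k=1,
            warning=f"only {n} mutations; returning a single cluster",
        )
    rng = np.random.default_rng(seed)
    best = None  # (bic, k, ll, c, w, resp)
    scores: dict[int, float] = {}
    for k in range(1, k_max + 1):
        best_ll, best_fit = -np.inf, None
        for _ in range(restarts if k > 1 else 1):
            c0 = _kmeanspp_init(np.clip(ccfs, 1e-3, CCF_CAP), k, rng)
            ll, c, w, resp = _em_once(alt, depth, phi, c0, tol, max_iter)
            if ll > best_ll:
                best_ll, best_fit = ll, (c, w, resp)
        n_params = 2 * k - 1  # k CCFs + (k-1) free weights
        bic = -2.0 * best_ll + n_params * np.log(n)
        scores[k] = float(bic)
        if best is None or bic < best[0] - 1e-9:
            best = (bic, k, best_ll, *best_fit)
    _, k_sel, ll, c, w, resp = best
    order = np.argsort(-c)  # report clusters by descending CCF
    c, w = c[order], w[order]
    resp = resp[:, order]
    assignments = resp.argmax(axis=1)
    return ClusterResult(
        focus_id=focus_id,
        assignments=[int(a) for a in assignments],
        means=[float(x) for x in c],
        weights=[float(x) for x in w],
        k=int(k_sel),
        scores=scores,
        log_likelihood=float(ll),
    )


def select_key_mutations(
    cluster_result: ClusterResult,
    variants: Sequence[VariantRecord],
    ccf_min: float = KEY_CCF_MIN,
) -> list[VariantRecord]:
    """Deleterious mutations whose cluster mean CCF is >= ``ccf_min``.

    The clonal frequency of a mutation is its cluster's mean CCF;
    deleterious means SIFT <= 0.05 or PolyPhen-2 >= 0.957 (inclusive
    boundaries; a missing score fails its criterion)."""
    if len(variants) != len(cluster_result.assignments):
        raise InputDataError("variants and cluster assignments disagree in length")
    out = []
    for v, a in zip(variants, cluster_result.assignments):
        clonal = cluster_result.means[a] >= ccf_min
        deleterious = (v.sift is not None and v.sift <= KEY_SIFT_MAX) or (
            v.polyphen is not None and v.polyphen >= KEY_POLYPHEN_MIN
        )
        if clonal and deleterious:
            out.append(v)
    return out


def driver_recurrence(
    key_by_focus: dict,
    all_by_focus: dict,
) -> pd.DataFrame:
    """Gene-level recurrence of key mutations across a cohort's foci.

    ``key_by_focus`` / ``all_by_focus`` map focus id -> variant lists. For
    each gene, counts the foci carrying any mutation in the gene and the
    subset where at least one such mutation is key; sorted by descending
    key-focus ratio then count."""
    rows = {}
    for focus, variants in all_by_focus.items():
        genes = {v.gene for v in variants if v.gene}
        key_genes = {v.gene for v in key_by_focus.get(focus, []) if v.gene}
        for g in genes:
            rec = rows.setdefault(g, {"gene": g, "n_foci_key": 0, "n_foci_mutated": 0})
            rec["n_foci_mutated"] += 1
            if g in key_genes:
                rec["n_foci_key"] += 1
    df = pd.DataFrame(list(rows.values()))
    if df.empty:
        return pd.DataFrame(columns=["gene", "n_foci_key", "n_foci_mutated", "ratio"])
    df["ratio"] = df["n_foci_key"] / df["n_foci_mutated"]
    return df.sort_values(
        ["ratio", "n_foci_key", "gene"], ascending=[False, False, True], kind="stable"
    ).reset_index(drop=True)
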