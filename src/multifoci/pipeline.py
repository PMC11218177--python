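"""End-to-end orchestration: simulate -> share -> classify -> germline ->
clusters -> cnv -> neo -> report.

:class:`RunConfig` carries every threshold the stages expose plus stage
toggles; :func:`run_pipeline` runs the enabled stages in order against a
cohort directory (optionally simulating it first), writes per-stage TSV/JSON
outputs under ``<cohort_dir>/results`` and returns the aggregated cohort
report. Stages are pure functions of the cohort on disk plus the config, so
reruns with the same seeds are identical.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .clones import ccf_inputs_for_focus, driver_recurrence, fit_clusters, select_key_mutations
from .cnv import recurrence_matrix
from .errors import ConfigurationError
from .genome import load_cgc_genes, load_gene_categories, load_gene_table
from .germline import CATEGORIES, compare_category, filter_germline, intersect_cgc
from .neoantigen import filter_candidates, recurrent_neoantigens
from .origin import classify_origin, cohort_report
from .sharing import FocusPair, cnv_gene_overlap, sharing_summary, sv_overlap
from .synthetic import FOCI, CohortConfig, default_cohort_config, load_cohort, write_cohort

log = logging.getLogger("multifoci")

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

STAGES = ("simulate", "share", "classify", "germline", "clusters", "cnv", "neo")

_NEEDS = {
    "classify": ("share",),
    "clusters": (),
    "cnv": (),
    "neo": (),
    "germline": (),
}


@dataclass
class RunConfig:
    """All knobs of one pipeline run. Round-trips through JSON unchanged."""

    cohort_dir: str
    seed: int = 20240601
    simulate: bool = True  # generate the cohort (default packaged config) first
    origin_threshold: float = 0.10
    sv_tol: int = 10
    af_cutoff: float = 0.001
    affinity_cutoff: float = 500.0
    min_foci: int = 3
    k_max: int = 6
    restarts: int = 50
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})

    def __post_init__(self) -> None:
        if not (0.0 < self.origin_threshold < 1.0):
            raise ConfigurationError("origin_threshold must be in (0,1)")
        if self.sv_tol < 0 or self.min_foci < 1 or self.k_max < 1 or self.restarts < 1:
            raise ConfigurationError("sv_tol/min_foci/k_max/restarts out of range")
        if not (0.0 <= self.af_cutoff <= 1.0) or self.affinity_cutoff <= 0:
            raise ConfigurationError("af_cutoff/affinity_cutoff out of range")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
        for s in STAGES:
            self.stages.setdefault(s, True)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def run_pipeline(
    config: RunConfig, cohort_config: Optional[CohortConfig] = None
) -> dict:
    """Run all enabled stages; returns (and writes) the cohort report.

    ``cohort_config`` overrides the packaged default cohort when simulating.
    A disabled stage is marked ``"skipped"`` in the report; a stage whose
    prerequisite was skipped raises :class:`ConfigurationError`.
    """
    cohort_dir = Path(config.cohort_dir)
    out = cohort_dir / "results"
    report: dict = {"seed": config.seed, "thresholds": asdict(config), "stages": {}}

    for stage, needs in _NEEDS.items():
        if config.stages.get(stage, True):
            for dep in needs:
                if not config.stages.get(dep, True):
                    raise ConfigurationError(
                        f"stage {stage!r} requires {dep!r}, which is toggled off"
                    )

    if config.stages["simulate"]:
        cc = cohort_config if cohort_config is not None else default_cohort_config(config.seed)
        log.info("simulating cohort of %d patients into %s", len(cc.patients), cohort_dir)
        write_cohort(cc, cohort_dir)
        report["stages"]["simulate"] = {"n_patients": len(cc.patients)}
    else:
        report["stages"]["simulate"] = "skipped"
    if not (cohort_dir / "manifest.json").exists():
        raise ConfigurationError(
            f"no manifest.json in {cohort_dir}; enable the simulate stage or point "
            "cohort_dir at an existing cohort"
        )
    bundles = load_cohort(cohort_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes = load_gene_table()

    summaries = []
    if config.stages["share"]:
        for b in bundles:
            s = sharing_summary(FocusPair.from_bundle(b))
            _, s.shared_fraction_cnv_genes = cnv_gene_overlap(
                b.segments["Ca1"], b.segments["Ca2"], genes
            )
            _, s.shared_fraction_sv = sv_overlap(b.svs["Ca1"], b.svs["Ca2"], config.sv_tol)
            summaries.append(s)
        share_df = pd.DataFrame([vars(s) for s in summaries])
        share_df.to_csv(out / "sharing.tsv", sep="\t", index=False)
        report["stages"]["share"] = {"n_patients": len(summaries)}
    else:
        report["stages"]["share"] = "skipped"

    if config.stages["classify"]:
        calls = [classify_origin(s, config.origin_threshold) for s in summaries]
        table, origin_rep = cohort_report(calls, summaries, config.origin_threshold)
        table.to_csv(out / "origin.tsv", sep="\t", index=False)
        report["stages"]["classify"] = origin_rep
        labels = {c.patient_id: c.label for c in calls}
    else:
        report["stages"]["classify"] = "skipped"
        labels = {b.patient_id: b.truth.origin_model for b in bundles}

    if config.stages["germline"]:
        categories = load_gene_categories()
        cgc = load_cgc_genes()
        profiles = {
            b.patient_id: filter_germline(
                b.germline, b.patient_id, categories, af_threshold=config.af_cutoff
            )
            for b in bundles
        }
        mc = [profiles[p] for p, lab in labels.items() if lab == "MC"]
        me = [profiles[p] for p, lab in labels.items() if lab == "ME"]
        comparisons = {}
        if mc and me:
            for cat in ("total",) + CATEGORIES:
                p, mc_counts, me_counts = compare_category(mc, me, cat)
                comparisons[cat] = {"p_value": p, "mc_counts": mc_counts, "me_counts": me_counts}
        candidates = {p: intersect_cgc(prof, cgc) for p, prof in profiles.items()}
        germline_rep = {
            "comparisons": comparisons,
            "cgc_candidates": candidates,
            "retained": {p: len(prof.retained) for p, prof in profiles.items()},
            "drops": {p: prof.drop_counts for p, prof in profiles.items()},
        }
        (out / "germline.json").write_text(json.dumps(germline_rep, indent=2) + "\n")
        report["stages"]["germline"] = germline_rep
    else:
        report["stages"]["germline"] = "skipped"

    if config.stages["clusters"]:
        cluster_rep, key_by_focus, all_by_focus = {}, {}, {}
        rows = []
        for b in bundles:
            for focus in FOCI:
                fid = b.sample_id(focus)
                variants = b.somatic[focus]
                est, alt, depth = ccf_inputs_for_focus(
                    variants, b.somatic_depths[focus], b.segments[focus], b.purity
                )
                res = fit_clusters(
                    est,
                    alt,
                    depth,
                    k_max=config.k_max,
                    restarts=config.restarts,
                    seed=(config.seed + zlib.crc32(fid.encode())) % (2**31),
                    focus_id=fid,
                )
                keys = select_key_mutations(res, variants)
                key_by_focus[fid] = keys
                all_by_focus[fid] = variants
                cluster_rep[fid] = {
                    "k": res.k,
                    "means": res.means,
                    "weights": res.weights,
                    "monoclonal": res.monoclonal,
                    "n_key_mutations": len(keys),
                }
                rows.append({"focus": fid, **cluster_rep[fid]})
        drivers = driver_recurrence(key_by_focus, all_by_focus)
        drivers.to_csv(out / "driver_recurrence.tsv", sep="\t", index=False)
        pd.DataFrame(rows).to_csv(out / "clusters.tsv", sep="\t", index=False)
        report["stages"]["clusters"] = {
            "foci": cluster_rep,
            "driver_recurrence": drivers.head(20).to_dict(orient="records"),
        }
    else:
        report["stages"]["clusters"] = "skipped"

    if config.stages["cnv"]:
        cohort_segments = {
            b.sample_id(focus): b.segments[focus] for b in bundles for focus in FOCI
        }
        matrix, counts = recurrence_matrix(cohort_segments, genes, min_foci=config.min_foci)
        matrix.to_csv(out / "cnv_matrix.tsv", sep="\t")
        counts.to_csv(out / "cnv_recurrence.tsv", sep="\t", index=False)
        recurrent = counts.loc[counts["recurrent"]]
        report["stages"]["cnv"] = {
            "n_recurrent_genes": int(len(recurrent)),
            "recurrent_genes": recurrent["gene"].tolist(),
        }
    else:
        report["stages"]["cnv"] = "skipped"

    if config.stages["neo"]:
        all_candidates = []
        for b in bundles:
            all_candidates.extend(filter_candidates(b.affinities, config.affinity_cutoff))
        rec = recurrent_neoantigens(all_candidates, min_foci=config.min_foci)
        rec.to_csv(out / "neoantigens.tsv", sep="\t", index=False)
        kept = rec.loc[rec["recurrent"]]
        report["stages"]["neo"] = {
            "n_candidates": len(all_candidates),
            "n_recurrent_mutations": int(len(kept)),
            "recurrent_mutations": kept["mutation_id"].tolist(),
        }
    else:
        report["stages"]["neo"] = "skipped"

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str) + "\n")
    return report
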