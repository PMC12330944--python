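"""End-to-end orchestration: simulate -> harmonize -> score -> cluster ->
screen -> composite -> adverse-feature survival stratification.

Every stage persists its inputs and outputs as plain tab-separated tables in
the run directory so any stage can be re-run from intermediates, and a
machine-readable ``summary.json`` records the seed, stage products, the
cluster assignment, the univariate screen, the multivariable fit and the
adverse-score survival groups.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .enrichment import EnrichmentParams, gsva_scores
from .gene_sets import read_gmt, write_gmt
from .harmonize import combat_adjust, rank_transform
from .pathway_structure import (
    cluster_pathways,
    composite_matrix,
    composite_scores,
    pathway_correlation,
)
from .prognostics import (
    adverse_feature_score,
    cochran_armitage_trend,
    km_logrank,
    multivariable_fit,
    select_analysis_samples,
    univariate_screen,
    wilcoxon_signed_rank,
)
from .synthetic_cohort import (
    PROGRAM_TO_AXIS,
    SimConfig,
    generate_expression,
    generate_paired_and_response,
    generate_survival,
    program_gene_sets,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]


@dataclass
class RunConfig:
    """Declarative configuration of a pipeline run.

    Either external input paths are given (``expression_path`` etc.) or a
    synthetic cohort is generated from ``sim`` overrides. ``seed`` drives
    both simulation and any stochastic stage and is recorded in the report.
    """

    outdir: str = "prostaxis_run"
    seed: int = 0
    expression_path: str | None = None
    meta_path: str | None = None
    survival_path: str | None = None
    gmt_path: str | None = None
    sim: dict = field(default_factory=dict)
    sets_per_program: int = 4
    k_clusters: int = 5
    linkage: str = "average"
    enrichment: dict = field(default_factory=dict)
    ties: str = "efron"
    alpha: float = 0.05
    tertile_reference: str = "survival_subset"  # or "all_samples"
    run_paired: bool = True


def load_run_config(path: str | Path) -> RunConfig:
    import yaml

    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
    return RunConfig(**data)


def _axis_label(members, cluster_id: int) -> str:
    """Name a cluster by the dominant program its member signatures track."""
    votes: dict[str, int] = {}
    for m in members:
        prog = m.rsplit("_sig", 1)[0]
        axis = PROGRAM_TO_AXIS.get(prog)
        if axis:
            votes[axis] = votes.get(axis, 0) + 1
    if votes:
        return max(sorted(votes), key=votes.get)
    return f"cluster_{cluster_id}"


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the summary dict (also written to disk).

    Stages that lack their inputs (no survival table, no paired samples)
    are skipped with a logged warning; upstream outputs are still written.
    Any stage failure aborts with the stage name and cause.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": [], "skipped": []}

    def stage(name):
        summary["stages"].append(name)
        logger.info("stage: %s", name)

    try:
        # ------------------------------------------------------ inputs
        stage("inputs")
        paired = None
        activities = None
        if config.expression_path:
            expr = pio.read_matrix(config.expression_path)
            meta = pio.read_table(config.meta_path)
            surv = (
                pio.read_table(config.survival_path, index_col="patient_id")
                if config.survival_path
                else None
            )
            gs = read_gmt(config.gmt_path)
        else:
            sim = SimConfig(**{**config.sim, "seed": config.seed})
            expr, meta, activities = generate_expression(sim)
            surv = generate_survival(activities, meta, sim)
            gs = program_gene_sets(sim, sets_per_program=config.sets_per_program)
            if config.run_paired:
                paired = generate_paired_and_response(activities, meta, sim)
            pio.write_matrix(expr, out / "expression.tsv")
            pio.write_table(meta, out / "meta.tsv")
            pio.write_table(surv.reset_index(), out / "survival.tsv")
            pio.write_matrix(
                activities.T, out / "true_activities.tsv", index_label="program"
            )
            write_gmt(gs, out / "gene_sets.gmt")

        # --------------------------------------------------- harmonize
        stage("harmonize")
        ranks = rank_transform(expr)
        batches = meta.set_index("sample_id").loc[expr.columns, "cohort"]
        adjusted = combat_adjust(ranks, batches)
        pio.write_matrix(adjusted, out / "adjusted.tsv")

        # ------------------------------------------------------- score
        stage("score")
        params = EnrichmentParams(**config.enrichment)
        scores = gsva_scores(adjusted, gs, params)
        pio.write_matrix(scores, out / "scores.tsv", index_label="pathway")

        # ----------------------------------------------------- cluster
        stage("cluster")
        corr = pathway_correlation(scores)
        clustering = cluster_pathways(corr, config.k_clusters, config.linkage)
        pio.write_table(
            clustering.assignment.rename("cluster").rename_axis("pathway").reset_index(),
            out / "clusters.tsv",
        )
        summary["n_clusters"] = int(clustering.assignment.nunique())

        if surv is None:
            summary["skipped"].append("survival stages (no survival input)")
            logger.warning("no survival input; survival stages skipped")
        else:
            # ------------------------------------------------- screen
            stage("screen")
            analysis = select_analysis_samples(meta)
            sample_to_patient = analysis.set_index("sample_id")["patient_id"]
            cols = [s for s in scores.columns if s in sample_to_patient.index]
            patient_scores = scores[cols].rename(columns=sample_to_patient)
            screen = univariate_screen(
                patient_scores, surv, alpha=config.alpha, ties=config.ties
            )
            pio.write_table(screen.reset_index(), out / "screen.tsv")
            summary["n_significant_pathways"] = int(screen["significant"].sum())

            # --------------------------------------------- composites
            stage("composite")
            labels = {
                int(cid): _axis_label(clustering.members(cid), int(cid))
                for cid in clustering.assignment.unique()
            }
            comps = composite_scores(
                scores,
                clustering,
                screen["significant"],
                labels=labels,
                directions=screen["direction"],
            )
            if not comps:
                raise RuntimeError("no cluster has a prognostic member")
            comp_mat = composite_matrix(comps)
            pio.write_matrix(comp_mat, out / "composites.tsv", index_label="axis")
            summary["composites"] = sorted(comp_mat.index)

            axes = ["Luminal_AR", "Proliferation", "mTOR_glycolysis", "NEPC"]
            comp_pat = comp_mat[cols].rename(columns=sample_to_patient)
            if all(a in comp_mat.index for a in axes):
                # ------------------------------------- multivariable
                stage("multivariable")
                mv = multivariable_fit(
                    comp_pat.loc[axes], surv, ties=config.ties
                )
                pio.write_table(
                    mv.summary.reset_index(), out / "multivariable.tsv"
                )
                summary["multivariable_p"] = {
                    a: float(mv[a]["p"]) for a in axes
                }

                # ------------------------------------------- adverse
                stage("adverse")
                profile = adverse_feature_score(
                    comp_pat.loc[axes],
                    reference_population=(
                        None
                        if config.tertile_reference == "survival_subset"
                        else list(comp_pat.columns)
                    ),
                )
                pio.write_table(
                    profile.table.reset_index(names="patient_id"),
                    out / "adverse.tsv",
                )
                groups = profile.table["group"].astype(str)
                shared = [p for p in groups.index if p in surv.index]
                km = km_logrank(surv.loc[shared], groups.loc[shared])
                summary["adverse_groups"] = {
                    g: int((groups == g).sum()) for g in ("0", "1-2", "3-4")
                }
                summary["adverse_km"] = {
                    "chi2": km.chi2,
                    "p": km.p,
                    "medians": {str(k): v for k, v in km.medians.items()},
                }
            else:
                summary["skipped"].append(
                    "multivariable/adverse (canonical axes incomplete)"
                )

            if paired is not None:
                # -------------------------------- paired + response
                stage("paired_response")
                shifts = {}
                for prog in paired.activities_pre.columns:
                    w, p = wilcoxon_signed_rank(
                        paired.activities_pre[prog].to_numpy(),
                        paired.activities_on[prog].to_numpy(),
                    )
                    shifts[prog] = {"w": w, "p": p}
                summary["paired_wilcoxon"] = shifts
                counts = paired.adverse_count.loc[paired.response.index]
                trend = cochran_armitage_trend(
                    paired.response.to_numpy(), counts.to_numpy()
                )
                summary["response_trend"] = {"z": trend.z, "p": trend.p}
    except Exception as exc:
        failed = summary["stages"][-1] if summary["stages"] else "inputs"
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_json_default) + "\n"
    )
    return summary


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
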