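"""End-to-end orchestration: cohort -> decomposition -> subnetworks -> reports.

All randomness (ICA run seeds, permutation nulls, CV splits) derives
deterministically from one master seed, so a config + seed pair fully
reproduces every table.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import classifier as clf
from . import fc_io, graph_metrics, group_stats, pruning, rsn_overlap
from .decomposition import RankedComponents, ReducedFeatures, decompose
from .synthetic import SyntheticConfig, generate_cohort

log = logging.getLogger("fcsubnet")

SCHEMA_VERSION = 1


@dataclasses.dataclass
class PipelineConfig:
    """All stage parameters; defaults follow the reference analysis."""

    # input: either a directory of matrices + labels, or a synthetic config
    data_dir: str | None = None
    labels_file: str | None = None
    rsn_file: str | None = None
    synthetic: SyntheticConfig | None = None

    variance_target: float = 0.90
    ica_runs: int = 100
    ica_max_iter: int = 5000
    ica_tol: float = 1e-7
    match_threshold: float = 0.8
    n_components_keep: int = 8

    pruning_threshold: float = 0.2
    pruning_mode: str = "relative_max"

    alpha_subnetwork: float = 0.005
    alpha_overlap: float = 0.005
    alpha_graph: float = 0.05
    alpha_links: float = 0.01
    ica_cut: float = 3.5
    n_perm: int = 1000

    cv_folds: int = 6
    cv_repeats: int = 10
    prevalence: float = 0.5
    classifier_subnetworks: tuple[int, ...] | None = None  # 1-based ranks

    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if syn is not None:
            if "effect_components" in syn:
                syn["effect_components"] = tuple(syn["effect_components"])
            cfg.synthetic = SyntheticConfig(**syn)
        return cfg


@dataclasses.dataclass
class PipelineResult:
    stack: fc_io.CohortStack
    normality: pd.DataFrame
    reduced: ReducedFeatures
    ranked: RankedComponents
    subnetworks: list[pruning.Subnetwork]
    stats_table: pd.DataFrame
    discriminant: dict[int, pd.DataFrame]
    overlap: pd.DataFrame | None
    graph_comparison: pd.DataFrame
    classifier_ranks: list[int]
    subject_scores: pd.DataFrame
    full_sample_metrics: clf.PerformanceMetrics
    cv_metrics: dict[str, float]
    cv_folds_table: pd.DataFrame
    summary: dict[str, Any]


def _load_cohort(config: PipelineConfig):
    if config.synthetic is not None:
        syn = dataclasses.replace(config.synthetic)
        stack, truth = generate_cohort(syn)
        rsn_labels = truth.rsn_map["rsn"].to_numpy(dtype=object)
        return stack, rsn_labels, truth
    if config.data_dir is None or config.labels_file is None:
        raise ValueError("either data_dir+labels_file or synthetic config needed")
    labels_df = fc_io.read_labels(config.labels_file)
    data_dir = Path(config.data_dir)
    matrices, labels, ids = [], [], []
    for _, row in labels_df.iterrows():
        path = data_dir / f"{row.subject_id}.tsv"
        matrices.append(fc_io.read_fc_matrix(path))
        labels.append(row.group)
        ids.append(row.subject_id)
    stack = fc_io.stack_cohort(matrices, labels, ids)
    rsn_labels = None
    if config.rsn_file:
        rsn_df = fc_io.read_rsn_map(config.rsn_file)
        rsn_labels = rsn_df["rsn"].to_numpy(dtype=object)
    return stack, rsn_labels, None


def run_pipeline(config: PipelineConfig,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Execute every stage; optionally write the report bundle to outdir."""
    root = np.random.SeedSequence(config.seed)
    seed_ica, seed_perm, seed_cv = (
        int(s) for s in root.generate_state(3) % (2 ** 31))

    stack, rsn_labels, _truth = _load_cohort(config)
    log.info("cohort: N=%d (HC=%d, SZ=%d), K=%d, E=%d", stack.N,
             int((stack.labels == "HC").sum()),
             int((stack.labels == "SZ").sum()), stack.K, stack.E)

    normality = fc_io.normality_screen(stack)

    reduced, ranked = decompose(
        stack, variance_target=config.variance_target,
        n_runs=config.ica_runs, seed=seed_ica,
        match_threshold=config.match_threshold,
        n_select=config.n_components_keep,
        max_iter=config.ica_max_iter, tol=config.ica_tol)
    log.info("PCA kept C=%d (%.1f%% variance); selected %d of the ranked "
             "components", reduced.C, 100 * reduced.explained_variance,
             len(ranked))

    subnets = pruning.prune(ranked, pruning.PruningConfig(
        threshold=config.pruning_threshold, mode=config.pruning_mode))

    stats_table = group_stats.subnetwork_stat_table(
        subnets, stack, alpha=config.alpha_subnetwork)

    b_rows = stats_table[stats_table["method"] == "B"]
    sig_b = sorted(b_rows[b_rows["significant"]]["subnetwork"].tolist())
    if config.classifier_subnetworks is not None:
        clf_ranks = sorted(config.classifier_subnetworks)
    elif sig_b:
        clf_ranks = sig_b
    else:
        fallback = int(b_rows.sort_values("p")["subnetwork"].iloc[0])
        warnings.warn("no subnetwork significant under method B; classifier "
                      f"falls back to the lowest-p subnetwork #{fallback}",
                      RuntimeWarning, stacklevel=2)
        clf_ranks = [fallback]

    discriminant = {}
    for rank in clf_ranks:
        discriminant[rank] = group_stats.discriminant_links(
            subnets[rank - 1], stack, ica_cut=config.ica_cut,
            p_cut=config.alpha_links)

    overlap = None
    if rsn_labels is not None:
        overlap = rsn_overlap.overlap_table(
            subnets, rsn_labels, n_perm=config.n_perm, seed=seed_perm,
            alpha=config.alpha_overlap)

    networks: dict[str, pruning.Subnetwork | None] = {"whole_brain": None}
    for rank in clf_ranks:
        networks[f"subnetwork_{rank}"] = subnets[rank - 1]
    graph_cmp = graph_metrics.group_graph_comparison(
        stack, networks, alpha=config.alpha_graph)

    projections = np.column_stack([
        group_stats.project_method_B(subnets[rank - 1], stack).scores
        for rank in clf_ranks])
    model = clf.fit_score_model(projections, stack.labels)
    totals = clf.score_subjects(model, projections)
    full_metrics = clf.evaluate(totals, stack.labels,
                                prevalence=config.prevalence)
    cv_means, cv_folds_table = clf.cross_validate(
        projections, stack.labels, k=config.cv_folds,
        repeats=config.cv_repeats, seed=seed_cv,
        prevalence=config.prevalence)

    subject_scores = pd.DataFrame({
        "subject_id": stack.subject_ids,
        "group": stack.labels,
        "total_score": totals,
        "predicted": clf.classify(totals),
    })

    summary = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "N": stack.N, "K": stack.K, "E": stack.E,
        "C": reduced.C,
        "explained_variance": reduced.explained_variance,
        "n_subnetworks": len(subnets),
        "retained_fraction_mean": float(np.mean(
            [s.retained_fraction for s in subnets])),
        "significant_method_A": sorted(
            stats_table.query("method == 'A' and significant")
            ["subnetwork"].tolist()),
        "significant_method_B": sig_b,
        "classifier_subnetworks": clf_ranks,
        "full_sample": full_metrics.as_dict(),
        "cv": cv_means,
        "normality_min_p": normality.attrs.get("min_p"),
    }

    result = PipelineResult(
        stack=stack, normality=normality, reduced=reduced, ranked=ranked,
        subnetworks=subnets, stats_table=stats_table,
        discriminant=discriminant, overlap=overlap,
        graph_comparison=graph_cmp, classifier_ranks=clf_ranks,
        subject_scores=subject_scores, full_sample_metrics=full_metrics,
        cv_metrics=cv_means, cv_folds_table=cv_folds_table, summary=summary)
    if outdir is not None:
        write_reports(result, outdir)
    return result


def write_reports(result: PipelineResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.normality.to_csv(outdir / "normality.tsv", sep="\t", index=False)
    result.stats_table.to_csv(outdir / "subnetwork_stats.tsv", sep="\t",
                              index=False)
    if result.overlap is not None:
        result.overlap.to_csv(outdir / "rsn_overlap.tsv", sep="\t", index=False)
    result.graph_comparison.to_csv(outdir / "graph_comparison.tsv", sep="\t",
                                   index=False)
    result.subject_scores.to_csv(outdir / "subject_scores.tsv", sep="\t",
                                 index=False)
    result.cv_folds_table.to_csv(outdir / "cv_folds.tsv", sep="\t", index=False)
    for rank, df in result.discriminant.items():
        df.to_csv(outdir / f"discriminant_links_subnetwork_{rank}.tsv",
                  sep="\t", index=False)
    ranking = pd.DataFrame([
        {"rank": i + 1, "source_index": c.source_index,
         "reproducibility": c.reproducibility, "match_count": c.match_count,
         "mean_abs_corr": c.mean_abs_corr,
         "retained_fraction": result.subnetworks[i].retained_fraction}
        for i, c in enumerate(result.ranked.components)])
    ranking.to_csv(outdir / "component_ranking.tsv", sep="\t", index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True, default=float)
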