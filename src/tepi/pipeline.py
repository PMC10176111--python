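"""End-to-end orchestration of the analysis stages.

`run_study` executes the full chain on a simulated experiment: counting (or
direct use of the simulated matrix), differential transcription for the main
and control contrasts, the double-control consistency filter, up-set
selection, composition/partition/context analyses, piRNA-cluster scoring and
ChIP profiling.  It returns all intermediate objects plus a JSON-ready
summary, and is the engine behind the ``run-all`` command.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from . import chip as chip_mod
from . import pirna as pirna_mod
from . import te_analysis
from .annotations import assign_precursors_to_clusters, expected_composition
from .counting import CountMatrix
from .diffexp import (
    DETable,
    estimate_dispersion,
    nb_wald_test,
    select_up,
    size_factors_median_of_ratios,
)
from .synthetic_data import AnnotationBundle, SimConfig, SimTruth, simulate_annotation, simulate_chip, simulate_counts

logger = logging.getLogger(__name__)

MUTANT_CONDITIONS = {"Set2KO": "Set2", "NSDKO": "NSD", "ash1KO": "ash1"}


@dataclass
class StudyResult:
    config: SimConfig
    bundle: AnnotationBundle
    counts: CountMatrix
    truth: SimTruth
    size_factors: pd.Series
    de_tables: dict[str, DETable]            # contrast label -> filtered DETable
    de_unfiltered: dict[str, DETable]
    filter_reports: dict[str, te_analysis.FilterReport]
    up_sets: dict[str, set[str]]
    composition: dict[str, te_analysis.CompositionTable]
    partition: te_analysis.MutantPartition | None
    context: te_analysis.ContextPartition | None
    cluster_table: pd.DataFrame
    chip_profiles: dict[str, chip_mod.EnrichmentProfile]
    summary: dict


def batch_groups(counts: CountMatrix) -> dict[str, list[str]]:
    """Replicate groups keyed by condition and batch (dispersion strata)."""
    groups: dict[str, list[str]] = {}
    for m in counts.meta:
        groups.setdefault(f"{m.condition}:{m.batch}", []).append(m.sample_id)
    return groups


def de_for_contrast(
    counts: CountMatrix,
    sf: pd.Series,
    treatment,
    control,
    feature_ids: list[str] | None = None,
    **labels,
) -> DETable:
    sub = counts.subset_features(feature_ids) if feature_ids is not None else counts
    disp = estimate_dispersion(sub, sf, groups=batch_groups(sub))
    return nb_wald_test(sub, sf, disp, treatment, control, **labels)


def run_study(
    config: SimConfig,
    lfc_min: float = 2.0,
    alpha: float = 0.05,
    use_adjusted: bool = True,
    expressed_min_mean: float = 10.0,
    with_chip: bool = True,
) -> StudyResult:
    """Simulate one experiment and run every analysis stage on it."""
    bundle = simulate_annotation(config)
    counts, truth = simulate_counts(config, bundle)
    sf = size_factors_median_of_ratios(counts)

    te_ids = bundle.repeats.feature_ids
    gene_ids = bundle.genes.feature_ids
    prec_ids = bundle.precursors.feature_ids
    wt_b1 = counts.samples_for("WT", batch="1")
    wt_b2 = counts.samples_for("WT", batch="2")

    contrasts: dict[str, tuple] = {"H3K36R": ("H3K36R", "H3K36K")}
    for cond in MUTANT_CONDITIONS:
        contrasts[cond] = (cond, "WT")

    de_unfiltered: dict[str, DETable] = {}
    de_tables: dict[str, DETable] = {}
    filter_reports: dict[str, te_analysis.FilterReport] = {}
    up_sets: dict[str, set[str]] = {}

    # control comparisons on the TE universe
    control_runs = de_for_contrast(
        counts, sf, wt_b1, wt_b2, te_ids,
        treatment_label="WT_b1", control_label="WT_b2",
    )
    control_geno = de_for_contrast(counts, sf, "H3K36K", "WT", te_ids)

    for label, (treat, ctrl) in contrasts.items():
        de = de_for_contrast(counts, sf, treat, ctrl, te_ids)
        de_unfiltered[label] = de
        filtered, report = te_analysis.control_consistency_filter(
            de, control_runs, control_geno, alpha=alpha, use_adjusted=use_adjusted
        )
        de_tables[label] = filtered
        filter_reports[label] = report
        up_sets[label] = select_up(filtered, lfc_min=lfc_min, alpha=alpha, use_adjusted=use_adjusted)

    # composition against genome abundance
    expected = expected_composition(bundle.repeats, level="order", weighting="element_count")
    composition = {}
    for label, up in up_sets.items():
        if up:
            composition[label] = te_analysis.composition_chi_square(
                up, bundle.repeats, expected, level="order"
            )

    # membership partition of the replacement-mutant up-set across knockouts
    partition = None
    if up_sets.get("H3K36R"):
        partition = te_analysis.partition_by_mutants(
            up_sets["H3K36R"],
            {name: up_sets[cond] for cond, name in MUTANT_CONDITIONS.items()},
        )

    # genomic context of up-regulated LTR/LINE elements
    context = None
    if up_sets.get("H3K36R"):
        retro_up = {
            fid for fid in up_sets["H3K36R"] if bundle.repeats[fid].order in ("LTR", "LINE")
        }
        wt_cols = counts.samples_for("WT")
        norm = counts.counts.loc[gene_ids, wt_cols] / sf[wt_cols].to_numpy()
        wt_gene_mean = norm.mean(axis=1)
        gene_de = de_for_contrast(counts, sf, "H3K36R", "H3K36K", gene_ids)
        mutant_up_genes = select_up(gene_de, lfc_min=lfc_min, alpha=alpha, use_adjusted=use_adjusted)
        if retro_up:
            context = te_analysis.classify_genomic_context(
                retro_up, bundle.repeats, bundle.genes, wt_gene_mean,
                mutant_up_genes, expressed_min_mean=expressed_min_mean,
            )

    # piRNA cluster scoring
    precursors = assign_precursors_to_clusters(bundle.precursors, bundle.clusters)
    prec_counts = counts.subset_features(prec_ids)
    wt_means = pirna_mod.precursor_means(prec_counts, sf, "WT")
    summaries = []
    for cluster in bundle.clusters:
        wt_summary = pirna_mod.cluster_summary(wt_means, precursors, cluster, "WT")
        summaries.append(wt_summary)
        for cond in ("H3K36R", "Set2KO", "NSDKO", "ash1KO"):
            cond_means = pirna_mod.precursor_means(prec_counts, sf, cond)
            s = pirna_mod.cluster_summary(cond_means, precursors, cluster, cond)
            summaries.append(pirna_mod.with_fold(s, wt_summary))
    cluster_table = pirna_mod.summaries_to_frame(summaries)

    # ChIP enrichment profile
    chip_profiles: dict[str, chip_mod.EnrichmentProfile] = {}
    if with_chip:
        sim = simulate_chip(config, bundle)
        for target in sim.chip:
            chip_avg = chip_mod.average_replicates(sim.chip[target])
            input_avg = chip_mod.average_replicates(sim.input_[target])
            ratios = chip_mod.feature_ratio(
                chip_avg, input_avg, chip_lib=sim.chip_lib[target], input_lib=sim.input_lib[target]
            )
            chip_profiles[target] = chip_mod.class_profile(ratios, sim.class_sets, target=target)

    summary = {
        "n_features": {"repeat": len(te_ids), "gene": len(gene_ids), "precursor": len(prec_ids)},
        "up_counts": {k: len(v) for k, v in up_sets.items()},
        "filtered_out": {k: r.n_removed for k, r in filter_reports.items()},
        "composition_p": {k: c.p_value for k, c in composition.items()},
        "context_fractions": context.fractions if context else None,
        "cluster_mean_fold_by_mode": (
            cluster_table.dropna(subset=["fold_raw"])
            .groupby("strand_mode")["fold_raw"].mean().to_dict()
            if not cluster_table.empty else {}
        ),
    }
    return StudyResult(
        config=config,
        bundle=bundle,
        counts=counts,
        truth=truth,
        size_factors=sf,
        de_tables=de_tables,
        de_unfiltered=de_unfiltered,
        filter_reports=filter_reports,
        up_sets=up_sets,
        composition=composition,
        partition=partition,
        context=context,
        cluster_table=cluster_table,
        chip_profiles=chip_profiles,
        summary=summary,
    )
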