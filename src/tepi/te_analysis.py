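"""Transposon-level inference: consistency filtering, composition tests,
mutant membership partitioning, genomic context, and positional density.

These stages sit downstream of the differential-expression tables.  The
double-control consistency filter removes features whose apparent response
is confounded by batch (two independently sequenced wild-type runs) or by
genetic background (control genotype vs wild type); what survives is
attributable to the treatment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import FeatureSet
from .diffexp import DETable

logger = logging.getLogger(__name__)

MUTANT_ORDER = ("Set2", "NSD", "ash1")


@dataclass
class FilterReport:
    contrast: str
    removed: set[str]
    removed_by_control_runs: set[str]
    removed_by_control_genotype: set[str]

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "feature_id": fid,
                "in_control_runs": fid in self.removed_by_control_runs,
                "in_control_genotype": fid in self.removed_by_control_genotype,
            }
            for fid in sorted(self.removed)
        ]
        return pd.DataFrame(rows, columns=["feature_id", "in_control_runs", "in_control_genotype"])


@dataclass
class CompositionTable:
    """Observed vs expected repeat-class composition with a chi-square test."""

    classes: list[str]
    expected_fraction: dict[str, float]
    observed_fraction: dict[str, float]
    n_observed: int
    chi2_stat: float
    df: int
    p_value: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": self.classes,
                "expected_fraction": [self.expected_fraction[c] for c in self.classes],
                "observed_fraction": [self.observed_fraction[c] for c in self.classes],
            }
        )


@dataclass
class MutantPartition:
    """Membership of a base up-set across the three methyltransferase mutants.

    Every base feature gets its exact membership signature over the mutants;
    the 2**3 signature classes are disjoint and cover the base set.  Labels
    use " + "-joined mutant names, plus "none" for features recovered in no
    single-mutant set.
    """

    base_size: int
    class_counts: dict[str, int]
    membership: pd.DataFrame  # index feature_id, one bool column per mutant

    @staticmethod
    def class_label(signature: tuple[bool, ...]) -> str:
        names = [m for m, flag in zip(MUTANT_ORDER, signature) if flag]
        return " + ".join(names) if names else "none"


@dataclass
class ContextPartition:
    """Genic-context partition of an up-regulated TE set."""

    counts: dict[str, int]               # intergenic / expressed_gene / unexpressed_gene
    fractions: dict[str, float]
    sub_counts: dict[str, int]           # activated_in_mutant / silent_in_mutant
    sub_fractions: dict[str, float]
    assignments: pd.DataFrame            # per-feature context (+ host gene)


@dataclass
class DensityTrack:
    chrom: str
    window: int
    counts: np.ndarray  # per-window feature counts tiling the chromosome

    def to_bedgraph_rows(self):
        for i, c in enumerate(self.counts):
            yield self.chrom, i * self.window, (i + 1) * self.window, int(c)


def control_consistency_filter(
    main: DETable,
    control_runs: DETable,
    control_genotypes: DETable,
    alpha: float = 0.05,
    use_adjusted: bool = True,
    lfc_floor: float | None = None,
) -> tuple[DETable, FilterReport]:
    """Remove features that respond in either control comparison.

    A feature is removed when its chosen p-value is below ``alpha`` in the
    wild-type batch-vs-batch contrast OR in the control-genotype-vs-wild-type
    contrast (optionally additionally requiring ``|log2fc| > lfc_floor``).
    The filtered table restricts the main contrast to the survivors.
    """
    pcol = "p_adj" if use_adjusted else "p_value"
    universe = set(main.feature_ids)
    shared = universe & set(control_runs.feature_ids) & set(control_genotypes.feature_ids)
    if not shared:
        raise ValueError("no shared feature universe between main and control tables")
    if shared != universe:
        logger.warning(
            "feature universes differ; filtering on the %d shared features", len(shared)
        )

    def flagged(de: DETable) -> set[str]:
        tab = de.table.loc[sorted(shared)]
        mask = (tab[pcol] < alpha) & (~tab["untested"].astype(bool))
        if lfc_floor is not None:
            mask &= tab["log2fc"].abs() > lfc_floor
        return set(tab.index[mask])

    by_runs = flagged(control_runs)
    by_geno = flagged(control_genotypes)
    removed = by_runs | by_geno
    keep = [fid for fid in main.feature_ids if fid in shared and fid not in removed]
    filtered = DETable(main.table.loc[keep], main.treatment, main.control)
    report = FilterReport(
        contrast=f"{main.treatment} vs {main.control}",
        removed=removed,
        removed_by_control_runs=by_runs,
        removed_by_control_genotype=by_geno,
    )
    return filtered, report


def composition_chi_square(
    up: set[str],
    repeats: FeatureSet,
    expected: dict[str, float],
    level: str = "order",
    observed_other: dict[str, int] | None = None,
) -> CompositionTable:
    """Goodness-of-fit of an up-set's class composition against expectation.

    ``chi2 = sum_k (O_k - n e_k)^2 / (n e_k)`` over classes with positive
    expected share, ``df = K - 1``.  With ``observed_other`` given, a
    two-sample contingency chi-square between the two observed count vectors
    is performed instead (the expectation argument is ignored for the test).
    """
    observed: dict[str, int] = {}
    for fid in up:
        feat = repeats[fid]
        cls = getattr(feat, level)
        observed[cls] = observed.get(cls, 0) + 1

    if observed_other is not None:
        classes = sorted(set(observed) | set(observed_other))
        table = np.array(
            [[observed.get(c, 0) for c in classes], [observed_other.get(c, 0) for c in classes]]
        )
        keep = table.sum(axis=0) > 0
        chi2, p, df, _ = stats.chi2_contingency(table[:, keep])
        n = int(table[0].sum())
        obs_frac = {c: observed.get(c, 0) / n for c in classes}
        other_n = table[1].sum()
        exp_frac = {c: observed_other.get(c, 0) / other_n for c in classes}
        return CompositionTable(classes, exp_frac, obs_frac, n, float(chi2), int(df), float(p))

    unknown = [c for c, o in observed.items() if expected.get(c, 0.0) == 0.0 and o > 0]
    if unknown:
        raise ValueError(f"observed classes with zero expectation: {unknown}")
    classes = sorted(expected)
    n = sum(observed.values())
    if n == 0:
        raise ValueError("empty up-set")
    exp_counts = np.array([n * expected[c] for c in classes])
    obs_counts = np.array([observed.get(c, 0) for c in classes])
    if (exp_counts[exp_counts > 0] < 5).any():
        logger.warning("expected count below 5 in some class; chi-square approximation weak")
    pos = exp_counts > 0
    chi2 = float(np.sum((obs_counts[pos] - exp_counts[pos]) ** 2 / exp_counts[pos]))
    df = len(classes) - 1
    p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return CompositionTable(
        classes,
        {c: expected[c] for c in classes},
        {c: observed.get(c, 0) / n for c in classes},
        n,
        chi2,
        df,
        p,
    )


def partition_by_mutants(base: set[str], per_mutant: dict[str, set[str]]) -> MutantPartition:
    """Partition a base up-set by exact membership across mutant up-sets."""
    mutants = [m for m in MUTANT_ORDER if m in per_mutant]
    extra = sorted(set(per_mutant) - set(mutants))
    mutants += extra
    rows = {}
    counts: dict[str, int] = {}
    for fid in sorted(base):
        signature = tuple(fid in per_mutant[m] for m in mutants)
        names = [m for m, flag in zip(mutants, signature) if flag]
        label = " + ".join(names) if names else "none"
        counts[label] = counts.get(label, 0) + 1
        rows[fid] = dict(zip(mutants, signature))
    membership = pd.DataFrame.from_dict(rows, orient="index", columns=mutants, dtype=bool)
    return MutantPartition(base_size=len(base), class_counts=counts, membership=membership)


def classify_genomic_context(
    up: set[str],
    repeats: FeatureSet,
    genes: FeatureSet,
    wt_mean_expression: pd.Series,
    mutant_up_genes: set[str],
    expressed_min_mean: float = 10.0,
) -> ContextPartition:
    """Classify up-regulated TEs by genic context.

    A TE overlapping (>= 1 bp) a gene expressed in wild type (mean normalised
    count >= ``expressed_min_mean``) is ``expressed_gene``; overlapping only
    unexpressed genes, ``unexpressed_gene``; otherwise ``intergenic``.
    TEs in unexpressed genes are subdivided by whether a host gene becomes
    transcribed in the mutant (``mutant_up_genes``).
    """
    rows = []
    for fid in sorted(up):
        te = repeats[fid]
        iv = te.interval
        hosts = genes.query(iv.chrom, iv.start, iv.end)
        expressed_hosts = [
            g for g in hosts if wt_mean_expression.get(g.gene_id, 0.0) >= expressed_min_mean
        ]
        if expressed_hosts:
            context, sub, host = "expressed_gene", None, expressed_hosts[0].gene_id
        elif hosts:
            activated = [g for g in hosts if g.gene_id in mutant_up_genes]
            host = (activated or hosts)[0].gene_id
            context = "unexpressed_gene"
            sub = "activated_in_mutant" if activated else "silent_in_mutant"
        else:
            context, sub, host = "intergenic", None, None
        rows.append({"feature_id": fid, "context": context, "sub_context": sub, "host_gene": host})
    assignments = pd.DataFrame(rows, columns=["feature_id", "context", "sub_context", "host_gene"])
    counts = {
        c: int((assignments["context"] == c).sum())
        for c in ("intergenic", "expressed_gene", "unexpressed_gene")
    }
    total = max(sum(counts.values()), 1)
    fractions = {c: n / total for c, n in counts.items()}
    sub_counts = {
        s: int((assignments["sub_context"] == s).sum())
        for s in ("activated_in_mutant", "silent_in_mutant")
    }
    sub_total = max(sum(sub_counts.values()), 1)
    sub_fractions = {s: n / sub_total for s, n in sub_counts.items()}
    return ContextPartition(counts, fractions, sub_counts, sub_fractions, assignments)


def bin_density(
    up: set[str],
    repeats: FeatureSet,
    chrom_sizes: dict[str, int],
    window: int = 100_000,
) -> tuple[list[DensityTrack], int]:
    """Per-window counts of up-set features along each chromosome.

    A feature falls into the window containing its interval midpoint
    (half-open windows, midpoint exactly on a boundary belongs to the
    right-hand window).  Returns the tracks and a tally of features skipped
    for lying on unknown chromosomes.
    """
    tracks = {
        chrom: DensityTrack(chrom, window, np.zeros(int(np.ceil(size / window)), dtype=int))
        for chrom, size in chrom_sizes.items()
    }
    skipped = 0
    for fid in sorted(up):
        iv = repeats[fid].interval
        track = tracks.get(iv.chrom)
        if track is None:
            skipped += 1
            continue
        track.counts[iv.midpoint() // window] += 1
    if skipped:
        logger.warning("%d up-set features on chromosomes absent from chrom_sizes", skipped)
    return [tracks[c] for c in sorted(tracks)], skipped
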