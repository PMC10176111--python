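"""piRNA-cluster transcription scoring.

For each annotated cluster and condition: the mean normalised read count per
precursor interval, a 95% t-interval across precursors, and the fold change
over the wild-type control.  Dual-strand clusters (Rhino-dependent,
heterochromatic) are contrasted with uni-strand clusters (canonical
promoters) via their fold changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import FeatureSet, PiRNACluster
from .counting import CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class ClusterSummary:
    cluster_id: str
    strand_mode: str
    condition: str
    n_precursors: int
    mean_reads_per_precursor: float
    ci95_low: float
    ci95_high: float
    fold_over_control: float | None = None       # raw ratio
    fold_reported: float | None = None           # one-decimal, half-away-from-zero

    def __post_init__(self) -> None:
        if self.n_precursors < 1:
            raise ValueError("a reported cluster summary needs >= 1 precursor")
        if not (self.ci95_low <= self.mean_reads_per_precursor <= self.ci95_high):
            raise ValueError("confidence interval must bracket the mean")


def precursor_means(
    counts: CountMatrix,
    sf: pd.Series,
    condition: str,
) -> pd.Series:
    """Per-precursor mean of size-factor-normalised counts over a condition's replicates."""
    cols = counts.samples_for(condition)
    if not cols:
        raise ValueError(f"condition {condition!r} has no samples")
    norm = counts.counts[cols] / sf.reindex(cols).to_numpy()
    return norm.mean(axis=1)


def cluster_summary(
    means: pd.Series,
    precursors: FeatureSet,
    cluster: PiRNACluster,
    condition: str,
) -> ClusterSummary:
    """Average the per-precursor means over one cluster's assigned precursors.

    The 95% CI is ``mean +/- t_{0.975, n-1} * s / sqrt(n)`` across the
    cluster's precursors; degenerate (equal to the mean) when n = 1.
    """
    assigned = [p.precursor_id for p in precursors if p.cluster_id == cluster.cluster_id]
    if not assigned:
        raise ValueError(f"cluster {cluster.cluster_id} has no assigned precursors")
    values = means.reindex(assigned).to_numpy(dtype=float)
    n = len(values)
    mean = float(values.mean())
    if n == 1:
        lo = hi = mean
    else:
        half = stats.t.ppf(0.975, n - 1) * values.std(ddof=1) / np.sqrt(n)
        lo, hi = mean - half, mean + half
    return ClusterSummary(
        cluster_id=cluster.cluster_id,
        strand_mode=cluster.strand_mode,
        condition=condition,
        n_precursors=n,
        mean_reads_per_precursor=mean,
        ci95_low=lo,
        ci95_high=hi,
    )


def round_half_away(value: float, decimals: int = 1) -> float:
    """Decimal rounding with ties going away from zero (12.65 -> 12.7)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def fold_over_control(
    mean_treatment: float,
    mean_control: float,
    report_decimals: int = 1,
) -> tuple[float, float]:
    """Fold change of a cluster mean over the control mean.

    Returns ``(raw_ratio, reported)`` where the reported value is rounded
    half-away-from-zero to ``report_decimals``.  A zero control mean makes
    the fold undefined.
    """
    if mean_control <= 0:
        raise ValueError("control mean must be positive for a defined fold")
    raw = mean_treatment / mean_control
    return raw, round_half_away(raw, report_decimals)


def with_fold(summary: ClusterSummary, control: ClusterSummary) -> ClusterSummary:
    raw, rep = fold_over_control(
        summary.mean_reads_per_precursor, control.mean_reads_per_precursor
    )
    summary.fold_over_control = raw
    summary.fold_reported = rep
    return summary


def compare_cluster_types(summaries: list[ClusterSummary]) -> pd.DataFrame:
    """Tabulate per-cluster folds and per-strand-mode mean folds.

    No hypothesis test is attached; the contrast is descriptive (dual-strand
    clusters respond more strongly than uni-strand ones when piRNA production
    is induced).
    """
    rows = [
        {
            "cluster_id": s.cluster_id,
            "strand_mode": s.strand_mode,
            "condition": s.condition,
            "n_precursors": s.n_precursors,
            "mean": s.mean_reads_per_precursor,
            "ci95_low": s.ci95_low,
            "ci95_high": s.ci95_high,
            "fold_raw": s.fold_over_control,
            "fold_reported": s.fold_reported,
        }
        for s in summaries
        if s.fold_over_control is not None
    ]
    table = pd.DataFrame(rows)
    for mode in ("uni", "dual"):
        if table.empty or mode not in set(table["strand_mode"]):
            logger.warning("no %s-strand cluster with a defined fold; partial table", mode)
    if not table.empty:
        mode_means = table.groupby("strand_mode")["fold_raw"].transform("mean")
        table["strand_mode_mean_fold"] = mode_means
    return table


def summaries_to_frame(summaries: list[ClusterSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster_id": s.cluster_id,
                "strand_mode": s.strand_mode,
                "condition": s.condition,
                "n_precursors": s.n_precursors,
                "mean": s.mean_reads_per_precursor,
                "ci95_low": s.ci95_low,
                "ci95_high": s.ci95_high,
                "fold_raw": s.fold_over_control,
                "fold_reported": s.fold_reported,
            }
            for s in summaries
        ]
    )
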