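"""Negative-binomial differential-transcription testing.

A self-contained two-group pipeline: median-of-ratios size factors,
method-of-moments dispersion with clipping, a Wald test on the log2 fold
change of group means (delta-method standard error from the NB Fisher
information), Benjamini-Hochberg adjustment, and threshold selection of
up-regulated features.

The NB is parameterised by mean and dispersion, ``variance = mu + alpha *
mu**2``; ``alpha`` is shared across the two groups of a contrast and
estimated per feature.  No shrinkage of fold changes is applied — estimates
are raw log ratios of pseudocount-stabilised group means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .counting import CountMatrix

logger = logging.getLogger(__name__)

ALPHA_MIN = 1e-8
ALPHA_MAX = 10.0

DE_COLUMNS = ["base_mean", "log2fc", "se", "wald_z", "p_value", "p_adj", "untested"]


@dataclass
class DETable:
    """Per-feature differential-transcription results for one contrast."""

    table: pd.DataFrame  # index feature_id, columns DE_COLUMNS
    treatment: str
    control: str

    @property
    def feature_ids(self) -> list[str]:
        return list(self.table.index)

    def to_tsv(self, path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            fh.write(f"# contrast: {self.treatment} vs {self.control}\n")
            self.table.to_csv(fh, sep="\t", index_label="feature_id")

    @classmethod
    def from_tsv(cls, path) -> "DETable":
        treatment = control = "?"
        with open(path) as fh:
            for line in fh:
                if line.startswith("# contrast:"):
                    parts = line.split(":", 1)[1].strip().split(" vs ")
                    treatment, control = parts[0], parts[1]
                if not line.startswith("#"):
                    break
        table = pd.read_csv(path, sep="\t", index_col="feature_id", comment="#")
        return cls(table, treatment, control)


def size_factors_median_of_ratios(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each sample the factor is the median, over features with all-positive
    counts, of the ratio of that sample's count to the feature's geometric
    mean across samples.  With no all-positive feature the method degrades to
    total-count scaling with a warning.
    """
    mat = counts.counts.to_numpy(dtype=float)
    if mat.shape[1] < 2:
        raise ValueError("size factors require at least two samples")
    positive = (mat > 0).all(axis=1)
    if positive.sum() == 0:
        logger.warning("no feature with all-positive counts; falling back to total-count scaling")
        totals = mat.sum(axis=0).astype(float)
        if (totals == 0).any():
            raise ValueError("sample with zero total counts")
        factors = totals
    else:
        ref = mat[positive]
        log_geo = np.log(ref).mean(axis=1, keepdims=True)
        ratios = ref / np.exp(log_geo)
        factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def _group_columns(counts: CountMatrix, group) -> list[str]:
    """Resolve a group spec: a condition label, or an explicit sample-id list."""
    if isinstance(group, str):
        cols = counts.samples_for(group)
        if not cols:
            raise ValueError(f"condition {group!r} absent from sample metadata")
        return cols
    cols = list(group)
    missing = [c for c in cols if c not in counts.sample_ids]
    if missing:
        raise ValueError(f"unknown sample ids {missing}")
    if not cols:
        raise ValueError("empty sample group")
    return cols


def estimate_dispersion(
    counts: CountMatrix,
    sf: pd.Series,
    groups: dict[str, list[str]] | None = None,
    alpha_min: float = ALPHA_MIN,
    alpha_max: float = ALPHA_MAX,
    median_floor: bool = True,
) -> pd.Series:
    """Per-feature method-of-moments dispersion on normalized counts.

    Within-group residual variance (group-mean-centred, pooled, with the
    Bessel-style ``N - G`` denominator) and the grand mean give
    ``alpha_hat = (s2 - mu) / mu**2``, clipped to ``[alpha_min, alpha_max]``.

    With ``median_floor`` (default), per-feature estimates are floored at
    the cross-feature median.  At typical replicate numbers the per-feature
    moment estimate is noisy, and features whose dispersion is underestimated
    get too-small Wald standard errors; flooring at the experiment-wide
    median removes that anticonservative tail without introducing any
    mean-dispersion trend (for data near the Poisson limit the median itself
    sits at ``alpha_min``, so the floor is inert).
    """
    if groups is None:
        groups = {}
        for m in counts.meta:
            groups.setdefault(m.condition, []).append(m.sample_id)
    sizes = [len(cols) for cols in groups.values()]
    if all(n < 2 for n in sizes):
        raise ValueError(
            "all groups are singletons; dispersion cannot be estimated — supply a fixed alpha"
        )
    norm = counts.counts / sf.reindex(counts.sample_ids).to_numpy()
    n_total = 0
    ss = np.zeros(len(norm), dtype=float)
    grand = np.zeros(len(norm), dtype=float)
    for cols in groups.values():
        sub = norm[cols].to_numpy(dtype=float)
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        grand += sub.sum(axis=1)
        n_total += sub.shape[1]
    s2 = ss / max(n_total - len(groups), 1)
    mu = grand / n_total
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - mu) / np.square(mu)
    alpha = np.where(np.isfinite(alpha), alpha, alpha_min)
    alpha = np.clip(alpha, alpha_min, alpha_max)
    if median_floor and len(alpha):
        alpha = np.maximum(alpha, np.median(alpha))
    return pd.Series(alpha, index=counts.counts.index, name="dispersion")


def nb_wald_test(
    counts: CountMatrix,
    sf: pd.Series,
    dispersion: pd.Series,
    treatment,
    control,
    pseudocount: float = 0.5,
    treatment_label: str | None = None,
    control_label: str | None = None,
) -> DETable:
    """Two-group NB Wald test on the log2 ratio of group means.

    Group means are means of size-factor-normalised counts (the NB mean MLE
    at fixed dispersion).  The standard error follows the delta method on the
    NB Fisher information, evaluated at pseudocount-stabilised means::

        se^2 = (1/ln 2)^2 * [ (1/n_t)(1/(mu_t + pc) + alpha)
                            + (1/n_c)(1/(mu_c + pc) + alpha) ]

    Features with zero counts in both groups are reported untested with
    ``log2fc = 0`` and ``p = 1``.
    """
    t_cols = _group_columns(counts, treatment)
    c_cols = _group_columns(counts, control)
    norm = counts.counts / sf.reindex(counts.sample_ids).to_numpy()
    mu_t = norm[t_cols].mean(axis=1).to_numpy()
    mu_c = norm[c_cols].mean(axis=1).to_numpy()
    alpha = dispersion.reindex(counts.counts.index).to_numpy()
    n_t, n_c = len(t_cols), len(c_cols)

    log2fc = np.log2((mu_t + pseudocount) / (mu_c + pseudocount))
    se2 = (1.0 / np.log(2)) ** 2 * (
        (1.0 / n_t) * (1.0 / (mu_t + pseudocount) + alpha)
        + (1.0 / n_c) * (1.0 / (mu_c + pseudocount) + alpha)
    )
    se = np.sqrt(se2)
    wald_z = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(wald_z))

    untested = (mu_t == 0) & (mu_c == 0)
    log2fc[untested] = 0.0
    wald_z[untested] = 0.0
    p[untested] = 1.0

    table = pd.DataFrame(
        {
            "base_mean": norm[t_cols + c_cols].mean(axis=1).to_numpy(),
            "log2fc": log2fc,
            "se": se,
            "wald_z": wald_z,
            "p_value": p,
            "p_adj": bh_adjust(p, exclude=untested),
            "untested": untested,
        },
        index=counts.counts.index,
    )
    t_label = treatment_label or (treatment if isinstance(treatment, str) else "+".join(treatment))
    c_label = control_label or (control if isinstance(control, str) else "+".join(control))
    return DETable(table, treatment=t_label, control=c_label)


def bh_adjust(p_values, exclude=None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving.

    ``exclude`` marks untested entries left out of the number of tests m
    (their adjusted p is reported as 1).
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    exclude = np.zeros(len(p), bool) if exclude is None else np.asarray(exclude, bool)
    adj = np.ones_like(p)
    tested = ~exclude
    if tested.any():
        adj[tested] = multipletests(p[tested], method="fdr_bh")[1]
    return adj


def select_up(
    de: DETable,
    lfc_min: float = 2.0,
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> set[str]:
    """Features up-regulated past strict thresholds: log2fc > lfc_min and p < alpha."""
    pcol = "p_adj" if use_adjusted else "p_value"
    tab = de.table
    mask = (tab["log2fc"] > lfc_min) & (tab[pcol] < alpha) & (~tab["untested"].astype(bool))
    return set(tab.index[mask])
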