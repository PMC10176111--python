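"""ChIP-over-input enrichment profiling across feature classes.

Per-feature sample/input ratios are formed from library-size-normalised,
pseudocount-guarded counts (ChIP replicates averaged before the ratio) and
summarised per feature class — exons, simple repeats, LINE repeats, LTR
repeats, and a background of randomly sampled fixed-width regions — with a
t-based 95% confidence interval across the features of each class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import GenomicInterval

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RandomRegionSet:
    """Fixed-width regions sampled uniformly from the genome.

    Chromosomes are chosen with probability proportional to length (among
    those at least ``width`` long); starts are uniform.  Regeneration with
    the same seed and chromosome sizes is identical.
    """

    regions: tuple[GenomicInterval, ...]
    width: int
    seed: int

    @property
    def feature_ids(self) -> list[str]:
        return [f"random_{i}" for i in range(len(self.regions))]


@dataclass
class ClassEnrichment:
    label: str
    n_features: int
    mean_ratio: float
    ci95_low: float
    ci95_high: float


@dataclass
class EnrichmentProfile:
    target: str  # e.g. H3K36me1 / me2 / me3
    classes: list[ClassEnrichment]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "target": self.target,
                    "class": c.label,
                    "n_features": c.n_features,
                    "mean_ratio": c.mean_ratio,
                    "ci95_low": c.ci95_low,
                    "ci95_high": c.ci95_high,
                }
                for c in self.classes
            ]
        )


def sample_random_regions(
    chrom_sizes: dict[str, int],
    n: int = 10_000,
    width: int = 80,
    seed: int = 0,
) -> RandomRegionSet:
    """Sample ``n`` random regions of ``width`` bp, length-proportionally across chromosomes."""
    eligible = {c: L for c, L in chrom_sizes.items() if L >= width}
    dropped = set(chrom_sizes) - set(eligible)
    if dropped:
        logger.warning("chromosomes shorter than %d bp excluded: %s", width, sorted(dropped))
    if not eligible:
        raise ValueError(f"no chromosome of at least {width} bp")
    rng = np.random.default_rng(seed)
    chroms = sorted(eligible)
    lengths = np.array([eligible[c] for c in chroms], dtype=float)
    picks = rng.choice(len(chroms), size=n, p=lengths / lengths.sum())
    regions = []
    for i in picks:
        chrom = chroms[i]
        start = int(rng.integers(0, eligible[chrom] - width + 1))
        regions.append(GenomicInterval(chrom, start, start + width))
    return RandomRegionSet(tuple(regions), width=width, seed=seed)


def average_replicates(replicate_counts: list[pd.Series]) -> pd.Series:
    """Average per-feature counts across replicates (before the ratio)."""
    if not replicate_counts:
        raise ValueError("at least one replicate required")
    frame = pd.concat(replicate_counts, axis=1)
    return frame.mean(axis=1)


def feature_ratio(
    chip_counts: pd.Series,
    input_counts: pd.Series,
    chip_lib: float,
    input_lib: float,
    pseudocount: float = 0.5,
) -> pd.Series:
    """Per-feature sample/input ratio of library-normalised counts.

    ``ratio = ((chip + pc) / chip_lib) / ((input + pc) / input_lib)``; the
    pseudocount guards zero coverage on either side.
    """
    if chip_lib <= 0 or input_lib <= 0:
        raise ValueError("library sizes must be positive")
    if not chip_counts.index.equals(input_counts.index):
        raise ValueError("chip and input feature universes differ")
    chip_norm = (chip_counts + pseudocount) / chip_lib
    input_norm = (input_counts + pseudocount) / input_lib
    return chip_norm / input_norm


def class_profile(
    ratios: pd.Series,
    class_sets: dict[str, "set[str] | list[str]"],
    target: str = "",
) -> EnrichmentProfile:
    """Mean ratio and t-based 95% CI per feature class."""
    classes = []
    for label, ids in class_sets.items():
        ids = [i for i in ids if i in ratios.index]
        if not ids:
            logger.warning("class %s is empty; omitted from profile", label)
            continue
        values = ratios.loc[ids].to_numpy(dtype=float)
        n = len(values)
        mean = float(values.mean())
        if n == 1:
            lo = hi = mean
        else:
            half = stats.t.ppf(0.975, n - 1) * values.std(ddof=1) / np.sqrt(n)
            lo, hi = mean - half, mean + half
        classes.append(ClassEnrichment(label, n, mean, lo, hi))
    return EnrichmentProfile(target=target, classes=classes)
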