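"""Read counting over annotation features under a uniqueness criterion.

Alignments are streamed from SAM/BAM via pysam; reads passing the mapping-
quality filter (``mapQ > 0`` by default, i.e. uniquely aligned under most
aligners' conventions) are intersected with an overlap-indexed
:class:`~tepi.annotations.FeatureSet`.  Paired mates sharing a read name are
collapsed to one fragment so a fragment increments a feature at most once.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam

from .annotations import FeatureSet, GenomicInterval

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignmentRecord:
    """Minimal view of one SAM record used for counting."""

    read_id: str
    interval: GenomicInterval | None
    mapping_quality: int
    is_secondary: bool
    is_unmapped: bool
    mate_index: int | None = None  # 1, 2 or None for single-end

    def __post_init__(self) -> None:
        if self.is_unmapped and self.interval is not None:
            raise ValueError("unmapped records carry no interval")


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    condition: str
    batch: str = "1"
    replicate: int = 1


class CountMatrix:
    """Integer read counts, features x samples, plus per-sample library sizes.

    ``library_sizes`` is the number of retained fragments per sample (the
    denominator simple per-million scaling would use), not the column sum:
    a fragment overlapping several features counts once in the library but
    may increment several features.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        library_sizes: pd.Series | None = None,
        meta: Sequence[SampleMeta] | None = None,
    ):
        if (counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts.astype(np.int64)
        if library_sizes is None:
            library_sizes = counts.sum(axis=0)
        self.library_sizes = pd.Series(library_sizes, index=counts.columns).astype(np.int64)
        colmax = self.counts.max(axis=0) if len(counts) else pd.Series(0, index=counts.columns)
        if (self.library_sizes < colmax).any():
            raise ValueError("library size below a single feature count")
        self.meta = list(meta) if meta is not None else [
            SampleMeta(sample_id=s, condition=s) for s in counts.columns
        ]
        if [m.sample_id for m in self.meta] != list(counts.columns):
            raise ValueError("meta order must match count columns")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_for(self, condition: str, batch: str | None = None) -> list[str]:
        return [
            m.sample_id
            for m in self.meta
            if m.condition == condition and (batch is None or m.batch == batch)
        ]

    def subset_features(self, feature_ids: Iterable[str]) -> "CountMatrix":
        ids = [f for f in feature_ids if f in self.counts.index]
        return CountMatrix(self.counts.loc[ids], self.library_sizes, self.meta)

    def to_tsv(self, path, sidecar_path=None) -> None:
        self.counts.to_csv(path, sep="\t", index_label="feature_id")
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                json.dump(
                    {
                        "library_sizes": {s: int(v) for s, v in self.library_sizes.items()},
                        "samples": [
                            {
                                "sample_id": m.sample_id,
                                "condition": m.condition,
                                "batch": m.batch,
                                "replicate": m.replicate,
                            }
                            for m in self.meta
                        ],
                    },
                    fh,
                    indent=1,
                )

    @classmethod
    def from_tsv(cls, path, sidecar_path=None) -> "CountMatrix":
        counts = pd.read_csv(path, sep="\t", index_col="feature_id", comment="#")
        library_sizes = None
        meta = None
        if sidecar_path is not None:
            with open(sidecar_path) as fh:
                side = json.load(fh)
            library_sizes = pd.Series(side["library_sizes"])[counts.columns]
            meta = [SampleMeta(**m) for m in side["samples"]]
        return cls(counts, library_sizes, meta)


def stream_alignments(path) -> Iterator[AlignmentRecord]:
    """Stream AlignmentRecords from a SAM/BAM file in file order.

    Reference spans come from the CIGAR (M/D/N/=/X consume reference), as
    computed by pysam.  Secondary and supplementary flags are surfaced so the
    caller can exclude them.
    """
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        if not af.header.get("SQ"):
            raise ValueError(f"{path}: SAM/BAM header has no sequence dictionary")
        for read in af.fetch(until_eof=True):
            if read.is_unmapped:
                yield AlignmentRecord(
                    read_id=read.query_name,
                    interval=None,
                    mapping_quality=read.mapping_quality,
                    is_secondary=read.is_secondary or read.is_supplementary,
                    is_unmapped=True,
                )
                continue
            strand = "-" if read.is_reverse else "+"
            yield AlignmentRecord(
                read_id=read.query_name,
                interval=GenomicInterval(
                    read.reference_name, read.reference_start, read.reference_end, strand
                ),
                mapping_quality=read.mapping_quality,
                is_secondary=read.is_secondary or read.is_supplementary,
                is_unmapped=False,
                mate_index=(1 if read.is_read1 else 2) if read.is_paired else None,
            )


def count_overlaps(
    alignments: Iterable[AlignmentRecord],
    features: FeatureSet,
    min_mapq: int = 1,
    count_mode: str = "every_overlap",
    stranded: bool = False,
    paired_collapse: bool = True,
) -> tuple[pd.Series, dict]:
    """Count retained fragments per feature for one sample.

    Records that are unmapped, secondary/supplementary, or below ``min_mapq``
    are excluded.  Under ``every_overlap`` a fragment increments every feature
    it overlaps once; under ``largest_overlap`` only the feature with maximal
    overlap (summed over mates), ties to the lexicographically smallest
    feature_id.  Returns the per-feature counts plus an audit dict with the
    retained-fragment library size and skipped-read tallies.
    """
    if count_mode not in ("every_overlap", "largest_overlap"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    known_chroms = features.chromosomes
    # fragment-level accumulation: read_id -> {feature_id: overlap_bp}
    frag_overlaps: dict[str, dict[str, int]] = {}
    retained: set[str] = set()
    audit = {"skipped_unmapped": 0, "skipped_secondary": 0, "skipped_mapq": 0,
             "skipped_unknown_chrom": 0}
    unknown_seen: set[str] = set()
    for rec in alignments:
        if rec.is_unmapped:
            audit["skipped_unmapped"] += 1
            continue
        if rec.is_secondary:
            audit["skipped_secondary"] += 1
            continue
        if rec.mapping_quality < min_mapq:
            audit["skipped_mapq"] += 1
            continue
        iv = rec.interval
        if iv.chrom not in known_chroms:
            audit["skipped_unknown_chrom"] += 1
            if iv.chrom not in unknown_seen:
                unknown_seen.add(iv.chrom)
                logger.warning("reads on %s skipped: chromosome absent from annotation", iv.chrom)
            continue
        key = rec.read_id if paired_collapse else f"{rec.read_id}/{rec.mate_index}:{iv.start}"
        retained.add(key)
        per_feat = frag_overlaps.setdefault(key, {})
        for feat in features.query(iv.chrom, iv.start, iv.end):
            if stranded and feat.interval.strand in ("+", "-") and iv.strand != feat.interval.strand:
                continue
            ov = iv.overlap_length(feat.interval)
            per_feat[feat.feature_id] = per_feat.get(feat.feature_id, 0) + ov
    counts = pd.Series(0, index=pd.Index(features.feature_ids, name="feature_id"), dtype=np.int64)
    for per_feat in frag_overlaps.values():
        if not per_feat:
            continue
        if count_mode == "every_overlap":
            for fid in per_feat:
                counts[fid] += 1
        else:
            best = min(per_feat.items(), key=lambda kv: (-kv[1], kv[0]))[0]
            counts[best] += 1
    audit["library_size"] = len(retained)
    return counts, audit


def build_count_matrix(
    columns: Sequence[tuple[pd.Series, dict]],
    meta: Sequence[SampleMeta],
) -> CountMatrix:
    """Assemble per-sample count columns into a CountMatrix.

    All columns must share one feature universe; column order follows
    ``meta``.
    """
    if len(columns) != len(meta):
        raise ValueError("one column per sample required")
    universe = list(columns[0][0].index)
    for col, _ in columns[1:]:
        if list(col.index) != universe:
            diff = set(col.index).symmetric_difference(universe)
            raise ValueError(f"feature universes differ: {sorted(diff)[:10]} ...")
    counts = pd.DataFrame(
        {m.sample_id: col.values for (col, _), m in zip(columns, meta)},
        index=pd.Index(universe, name="feature_id"),
    )
    libs = pd.Series(
        {m.sample_id: audit["library_size"] for (_, audit), m in zip(columns, meta)}
    )
    for m, (col, audit) in zip(meta, columns):
        if audit["library_size"] == 0:
            logger.warning("sample %s retained no fragments", m.sample_id)
    return CountMatrix(counts, libs, meta)
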