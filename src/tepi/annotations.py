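"""Genomic annotation layer: repeats, genes, piRNA precursors and clusters.

All intervals use 0-based half-open coordinates (BED convention) internally.
1-based inclusive sources (RepeatMasker ``.out``, GTF, GFF3) are converted on
read.  The module provides loaders for the annotation dialects the pipeline
consumes, an overlap-queryable :class:`FeatureSet` container, precursor ->
cluster assignment, and genome-abundance composition expectations used as the
null for repeat-class enrichment tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: Closed vocabulary of repeat orders; anything else is bucketed as "Other"
#: so that composition tables are total.
REPEAT_ORDERS = ("LTR", "LINE", "DNA", "Simple_repeat", "Satellite", "RC", "Other")

STRANDS = ("+", "-", ".")


class AnnotationError(ValueError):
    """Malformed annotation record or configuration."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    Parameters
    ----------
    chrom : str
        Chromosome name (non-empty).
    start, end : int
        0-based half-open bounds; ``0 <= start < end``.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise AnnotationError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise AnnotationError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class RepeatFeature:
    """One RepeatMasker-style repeat annotation record."""

    interval: GenomicInterval
    repeat_name: str
    family: str
    order: str
    feature_id: str

    def __post_init__(self) -> None:
        if self.order not in REPEAT_ORDERS:
            raise AnnotationError(
                f"repeat order {self.order!r} outside closed vocabulary {REPEAT_ORDERS}"
            )


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        for exon in self.exons:
            if exon.chrom != self.interval.chrom:
                raise AnnotationError(
                    f"gene {self.gene_id}: exon on {exon.chrom} but gene on "
                    f"{self.interval.chrom}"
                )
            if exon.start < self.interval.start or exon.end > self.interval.end:
                raise AnnotationError(
                    f"gene {self.gene_id}: exon {exon.start}-{exon.end} outside "
                    f"gene span {self.interval.start}-{self.interval.end}"
                )

    @property
    def feature_id(self) -> str:
        return self.gene_id


@dataclass(frozen=True)
class PiRNAPrecursor:
    precursor_id: str
    interval: GenomicInterval
    cluster_id: str | None = None

    @property
    def feature_id(self) -> str:
        return self.precursor_id


@dataclass(frozen=True)
class PiRNACluster:
    """A piRNA cluster locus with its mode of transcription.

    ``strand_mode`` distinguishes uni-strand clusters (canonical promoter,
    one strand) from dual-strand clusters (Rhino-dependent, heterochromatic,
    transcribed from both strands).
    """

    cluster_id: str
    interval: GenomicInterval
    strand_mode: str

    def __post_init__(self) -> None:
        if self.strand_mode not in ("uni", "dual"):
            raise AnnotationError(
                f"cluster {self.cluster_id}: strand_mode must be 'uni' or 'dual', "
                f"got {self.strand_mode!r}"
            )


Feature = RepeatFeature | GeneModel | PiRNAPrecursor

_KINDS = ("repeat", "gene", "precursor")


class FeatureSet:
    """Homogeneous, ordered, overlap-queryable collection of features.

    The overlap index is an interval tree per chromosome; ``query`` returns
    exactly the features overlapping a half-open query interval, in input
    order.
    """

    def __init__(self, features: Iterable[Feature], kind: str):
        if kind not in _KINDS:
            raise AnnotationError(f"kind must be one of {_KINDS}, got {kind!r}")
        self.kind = kind
        self.features: list[Feature] = list(features)
        seen: set[str] = set()
        for f in self.features:
            if f.feature_id in seen:
                raise AnnotationError(f"duplicate feature_id {f.feature_id!r}")
            seen.add(f.feature_id)
        self._by_id = {f.feature_id: f for f in self.features}
        self._trees: dict[str, IntervalTree] = {}
        for idx, f in enumerate(self.features):
            iv = f.interval
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, idx)

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[Feature]:
        return iter(self.features)

    def __getitem__(self, feature_id: str) -> Feature:
        return self._by_id[feature_id]

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._by_id

    @property
    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    @property
    def chromosomes(self) -> set[str]:
        return set(self._trees)

    def query(self, chrom: str, start: int, end: int) -> list[Feature]:
        """Features overlapping ``chrom:[start, end)`` in input order."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = sorted(hit.data for hit in tree.overlap(start, end))
        return [self.features[i] for i in hits]

    def with_features(self, features: Iterable[Feature]) -> "FeatureSet":
        return FeatureSet(features, self.kind)

    def to_bed(self, path) -> None:
        """Write BED6; the name field round-trips identifiers and repeat class."""
        with open(path, "w") as fh:
            for f in self.features:
                iv = f.interval
                if self.kind == "repeat":
                    name = f"{f.feature_id};{f.repeat_name}#{f.order}/{f.family}"
                else:
                    name = f.feature_id
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# dialect parsing helpers


def _parse_class_family(text: str) -> tuple[str, str]:
    """Split a RepeatMasker class/family string into (order, family).

    Text before the first ``/`` is the order, after it the family; with no
    ``/`` the family repeats the order (e.g. ``Simple_repeat``).  Orders
    outside the closed vocabulary fall into ``Other``; query-style suffixes
    like ``LTR/Gypsy?`` are tolerated.
    """
    text = text.strip().rstrip("?")
    if "/" in text:
        order, family = text.split("/", 1)
    else:
        order = family = text
    if order not in REPEAT_ORDERS:
        order = "Other"
    return order, family


def _strand_token(token: str) -> str:
    if token in ("+", "-"):
        return token
    if token == "C":  # RepeatMasker complement notation
        return "-"
    return "."


def _unique_id(base: str, used: dict[str, int]) -> str:
    n = used.get(base, 0)
    used[base] = n + 1
    return base if n == 0 else f"{base}#{n}"


def _repeat_from_fields(
    chrom: str,
    start: int,
    end: int,
    strand: str,
    repeat_name: str,
    class_family: str,
    used_ids: dict[str, int],
    lineno: int,
) -> RepeatFeature:
    if start >= end:
        raise AnnotationError(f"line {lineno}: start >= end after coordinate conversion")
    order, family = _parse_class_family(class_family)
    base = f"{chrom}:{start}-{end}:{repeat_name}"
    return RepeatFeature(
        interval=GenomicInterval(chrom, start, end, strand),
        repeat_name=repeat_name,
        family=family,
        order=order,
        feature_id=_unique_id(base, used_ids),
    )


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        if " " in part:
            key, _, value = part.partition(" ")
            attrs[key] = value.strip().strip('"')
        elif "=" in part:  # GFF3 style
            key, _, value = part.partition("=")
            attrs[key] = value.strip()
    return attrs


def load_repeat_annotation(path, dialect: str) -> FeatureSet:
    """Load repeat annotations as a ``FeatureSet(kind="repeat")``.

    Supported dialects:

    ``repeatmasker_out``
        RepeatMasker ``.out`` table (up to 3 header lines tolerated);
        1-based inclusive coordinates.
    ``bed``
        BED with name field ``repeat_name#order/family`` (optionally
        prefixed ``feature_id;`` as written by :meth:`FeatureSet.to_bed`).
    ``gtf``
        GTF with attributes ``repeat_name``, ``order``, ``family``;
        1-based inclusive coordinates.
    """
    used_ids: dict[str, int] = {}
    features: list[RepeatFeature] = []
    explicit_ids = False
    with open(path) as fh:
        lines = fh.readlines()

    if dialect == "repeatmasker_out":
        body = lines
        # RepeatMasker writes a two-line column header plus a blank line.
        skipped = 0
        while body and skipped < 3 and (
            not body[0].strip()
            or body[0].lstrip().lower().startswith(("sw", "score"))
        ):
            body = body[1:]
            skipped += 1
        for lineno, line in enumerate(body, start=skipped + 1):
            if not line.strip():
                continue
            cols = line.split()
            if len(cols) < 11:
                raise AnnotationError(f"line {lineno}: expected >= 11 columns, got {len(cols)}")
            chrom, start1, end1 = cols[4], int(cols[5]), int(cols[6])
            features.append(
                _repeat_from_fields(
                    chrom, start1 - 1, end1, _strand_token(cols[8]),
                    cols[9], cols[10], used_ids, lineno,
                )
            )
    elif dialect == "bed":
        for lineno, line in enumerate(lines, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 4:
                raise AnnotationError(f"line {lineno}: BED repeat records need a name field")
            chrom, start, end, name = cols[0], int(cols[1]), int(cols[2]), cols[3]
            strand = cols[5] if len(cols) >= 6 else "."
            feature_id = None
            if ";" in name:
                feature_id, _, name = name.partition(";")
                explicit_ids = True
            if "#" in name:
                repeat_name, _, class_family = name.partition("#")
            else:
                repeat_name, class_family = name, "Other"
            feat = _repeat_from_fields(
                chrom, start, end, _strand_token(strand),
                repeat_name, class_family, used_ids, lineno,
            )
            if feature_id is not None:
                feat = replace(feat, feature_id=feature_id)
            features.append(feat)
    elif dialect == "gtf":
        for lineno, line in enumerate(lines, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise AnnotationError(f"line {lineno}: expected 9 GTF columns")
            attrs = _parse_gtf_attributes(cols[8])
            name = attrs.get("repeat_name", attrs.get("gene_id", "repeat"))
            order = attrs.get("order", "Other")
            family = attrs.get("family", order)
            features.append(
                _repeat_from_fields(
                    cols[0], int(cols[3]) - 1, int(cols[4]), _strand_token(cols[6]),
                    name, f"{order}/{family}" if order != family else order,
                    used_ids, lineno,
                )
            )
    else:
        raise AnnotationError(f"unknown repeat annotation dialect {dialect!r}")
    if explicit_ids:
        # ids supplied by the file must be unique as a whole
        return FeatureSet(features, "repeat")
    return FeatureSet(features, "repeat")


def load_gene_annotation(path, dialect: str) -> FeatureSet:
    """Load gene models (``gene`` + ``exon`` records) from GTF or GFF3.

    Exons are grouped under their parent gene (``gene_id`` attribute in GTF,
    ``Parent``/``gene_id`` chain in GFF3).  Span-only files (no exon records)
    load with empty exon lists and a logged warning.
    """
    if dialect not in ("gtf", "gff3"):
        raise AnnotationError(f"unknown gene annotation dialect {dialect!r}")
    genes: dict[str, dict] = {}
    exons: list[tuple[str, GenomicInterval]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise AnnotationError(f"line {lineno}: expected 9 columns")
            ftype = cols[2]
            attrs = _parse_gtf_attributes(cols[8])
            iv = GenomicInterval(cols[0], int(cols[3]) - 1, int(cols[4]), _strand_token(cols[6]))
            if ftype == "gene":
                gene_id = attrs.get("gene_id") or attrs.get("ID")
                if gene_id is None:
                    raise AnnotationError(f"line {lineno}: gene record without gene_id")
                if gene_id in genes:
                    raise AnnotationError(f"line {lineno}: duplicated gene_id {gene_id!r}")
                genes[gene_id] = {"interval": iv, "exons": []}
            elif ftype == "exon":
                gene_id = attrs.get("gene_id") or attrs.get("Parent")
                if gene_id is None:
                    raise AnnotationError(f"line {lineno}: exon record without parent gene")
                exons.append((gene_id, iv))
    for gene_id, iv in exons:
        if gene_id not in genes:
            raise AnnotationError(f"exon references unknown gene {gene_id!r}")
        genes[gene_id]["exons"].append(iv)
    if genes and not exons:
        logger.warning("gene annotation %s carries no exon records; spans only", path)
    models = [
        GeneModel(gene_id, rec["interval"], tuple(sorted(rec["exons"])))
        for gene_id, rec in genes.items()
    ]
    return FeatureSet(models, "gene")


def _read_bed_records(path) -> Iterator[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.rstrip("\n").split("\t")


def load_pirna_annotations(precursor_path, cluster_path) -> tuple[FeatureSet, list[PiRNACluster]]:
    """Load piRNA precursor intervals and cluster coordinates from BED.

    The cluster BED name field carries the transcription mode as
    ``cluster_id|uni`` or ``cluster_id|dual``.  Precursors load with
    ``cluster_id`` unassigned; see :func:`assign_precursors_to_clusters`.
    """
    precursors = []
    used: dict[str, int] = {}
    for lineno, cols in _read_bed_records(precursor_path):
        if len(cols) < 3:
            raise AnnotationError(f"precursor line {lineno}: too few BED columns")
        name = cols[3] if len(cols) >= 4 else f"precursor_{lineno}"
        strand = _strand_token(cols[5]) if len(cols) >= 6 else "."
        precursors.append(
            PiRNAPrecursor(
                precursor_id=_unique_id(name, used),
                interval=GenomicInterval(cols[0], int(cols[1]), int(cols[2]), strand),
            )
        )
    clusters = []
    for lineno, cols in _read_bed_records(cluster_path):
        if len(cols) < 4 or "|" not in cols[3]:
            raise AnnotationError(
                f"cluster line {lineno}: name field must be 'cluster_id|uni' or 'cluster_id|dual'"
            )
        cluster_id, _, mode = cols[3].partition("|")
        clusters.append(
            PiRNACluster(
                cluster_id=cluster_id,
                interval=GenomicInterval(cols[0], int(cols[1]), int(cols[2])),
                strand_mode=mode,
            )
        )
    _check_no_nesting(clusters)
    return FeatureSet(precursors, "precursor"), clusters


def _check_no_nesting(clusters: Sequence[PiRNACluster]) -> None:
    for a in clusters:
        for b in clusters:
            if a is b or a.interval.chrom != b.interval.chrom:
                continue
            if a.interval.start >= b.interval.start and a.interval.end <= b.interval.end:
                raise AnnotationError(
                    f"cluster {a.cluster_id} nested within {b.cluster_id}"
                )


def assign_precursors_to_clusters(
    precursors: FeatureSet,
    clusters: Sequence[PiRNACluster],
    min_overlap_fraction: float = 0.5,
) -> FeatureSet:
    """Assign each precursor to at most one cluster by overlap.

    A precursor is assigned to the cluster covering the largest fraction of
    its length, provided that fraction reaches ``min_overlap_fraction``;
    ties break to the lexicographically smallest ``cluster_id``.
    """
    if not 0 <= min_overlap_fraction <= 1:
        raise AnnotationError("min_overlap_fraction must lie in [0, 1]")
    assigned = []
    for prec in precursors:
        best: tuple[int, str] | None = None  # (-overlap, cluster_id) for min()
        for cluster in clusters:
            ov = prec.interval.overlap_length(cluster.interval)
            if ov / len(prec.interval) < min_overlap_fraction or ov == 0:
                continue
            key = (-ov, cluster.cluster_id)
            if best is None or key < best:
                best = key
        assigned.append(
            replace(prec, cluster_id=best[1] if best is not None else None)
        )
    return precursors.with_features(assigned)


def expected_composition(
    repeats: FeatureSet,
    level: str = "order",
    weighting: str = "element_count",
) -> dict[str, float]:
    """Expected repeat-class fractions from genome abundance.

    The expectation is the null for composition tests: the class shares one
    would see if transcriptional activation were unbiased with respect to
    annotation.  ``element_count`` weights each annotation record equally;
    ``base_pairs`` weights by annotated length.
    """
    if level not in ("order", "family"):
        raise AnnotationError(f"level must be 'order' or 'family', got {level!r}")
    if weighting not in ("element_count", "base_pairs"):
        raise AnnotationError(f"unknown weighting {weighting!r}")
    if len(repeats) == 0:
        raise AnnotationError("cannot compute composition of an empty repeat set")
    totals: dict[str, float] = {}
    for f in repeats:
        cls = getattr(f, level)
        w = 1.0 if weighting == "element_count" else float(len(f.interval))
        totals[cls] = totals.get(cls, 0.0) + w
    grand = sum(totals.values())
    return {cls: w / grand for cls, w in sorted(totals.items())}
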