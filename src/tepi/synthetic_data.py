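"""Fully in-silico inputs with the statistical structure the analysis assumes.

The generator emulates a small multi-chromosome genome with
pericentromere-enriched repeat annotations (LTR/Gypsy, LTR/Pao, LTR/Copia,
LINE/Jockey, Simple_repeat), genes with known expression states, two
dual-strand and two uni-strand piRNA clusters containing precursor
intervals, negative-binomial counts for wild-type batches, a control
genotype and four chromatin mutants with planted log2 fold changes,
single-end SAM alignments realising those counts, and ChIP/input coverage
with planted class-specific enrichment.  Every emitter is deterministic
under the config seed, and a truth table records the planted structure for
oracle checks.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotations import (
    FeatureSet,
    GeneModel,
    GenomicInterval,
    PiRNACluster,
    PiRNAPrecursor,
    RepeatFeature,
)
from .chip import RandomRegionSet, sample_random_regions
from .counting import CountMatrix, SampleMeta

# order matters for deterministic iteration
DEFAULT_REPEAT_COUNTS = {
    "LTR/Gypsy": 240,
    "LTR/Pao": 120,
    "LTR/Copia": 80,
    "LINE/Jockey": 160,
    "Simple_repeat": 960,
}

REPEAT_LENGTHS = {"LTR": (300, 600), "LINE": (400, 800), "Simple_repeat": (50, 200)}


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated design: five replicates per genotype with
    the wild type sequenced as two independent batches, a matched control
    genotype, a histone-replacement mutant and three methyltransferase
    knockouts; repeat annotation dominated by simple repeats with the
    retrotransposon orders concentrated in pericentromeric blocks; planted
    TE activation strongest in the replacement mutant and ordered
    Set2 > NSD > ash1 across knockouts; piRNA clusters responding more on
    the dual-strand side.
    """

    seed: int = 0
    chromosomes: dict[str, int] = field(
        default_factory=lambda: {"chr2L": 800_000, "chr2R": 800_000, "chr3L": 600_000, "chrX": 600_000}
    )
    pericentromere_fraction: float = 0.3   # leading block of each chromosome
    pericentromere_weight: float = 0.75     # share of retrotransposons placed there
    repeat_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_REPEAT_COUNTS))
    n_genes: int = 80
    gene_length: tuple[int, int] = (2_000, 4_000)
    exons_per_gene: tuple[int, int] = (2, 4)
    expressed_gene_fraction: float = 0.5
    # TEs intentionally embedded in genes (LTR/LINE only), for context truth
    te_in_expressed_gene: int = 10
    te_in_unexpressed_gene_activated: int = 8
    te_in_unexpressed_gene_silent: int = 12
    clusters: dict[str, str] = field(
        default_factory=lambda: {"42AB": "dual", "38C": "dual", "20A": "uni", "flamenco": "uni"}
    )
    precursors_per_cluster: int = 50
    # precursor intervals outside any cluster (the bulk of a piRNAdb-style
    # catalogue); transcriptionally stable across conditions
    n_precursors_outside: int = 1200
    precursor_length: tuple[int, int] = (150, 400)
    replicates: dict[str, int] = field(
        default_factory=lambda: {
            "WT_b1": 5, "WT_b2": 5, "H3K36K": 4,
            "H3K36R": 5, "Set2KO": 5, "NSDKO": 5, "ash1KO": 5,
        }
    )
    mu_te: float = 50.0
    mu_gene_expressed: float = 200.0
    mu_gene_unexpressed: float = 0.5
    mu_precursor: dict[str, float] = field(default_factory=lambda: {"dual": 3.0, "uni": 5.5})
    mu_precursor_outside: float = 5.0
    dispersion: float = 0.1
    sample_scale_sd: float = 0.1            # lognormal sd of per-sample depth factors
    te_up_fraction: dict[str, float] = field(
        default_factory=lambda: {"H3K36R": 0.08, "Set2KO": 0.05, "NSDKO": 0.025, "ash1KO": 0.015}
    )
    te_up_lfc: float = 3.0
    # sampling weight by order when choosing activated TEs (LTR/LINE favoured)
    te_up_class_weight: dict[str, float] = field(
        default_factory=lambda: {"LTR": 5.0, "LINE": 3.0, "Simple_repeat": 0.3}
    )
    # share of each knockout's up-set drawn from inside the replacement-mutant set
    mutant_within_base: float = 0.9
    gene_activation_lfc: float = 6.0
    activated_gene_fraction: float = 0.3    # of unexpressed genes, activated in H3K36R
    n_batch_inconsistent: int = 50
    batch_lfc: float = 2.0
    cluster_fold: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "H3K36R": {"dual": 8.0, "uni": 1.5},
            "Set2KO": {"dual": 6.0, "uni": 1.3},
            "NSDKO": {"dual": 3.0, "uni": 1.2},
            "ash1KO": {"dual": 1.8, "uni": 1.3},
        }
    )
    read_length: int = 75
    multi_fraction: float = 0.0             # share of reads emitted with mapQ 0
    chip_multipliers: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "me1": {"Simple_repeat": 1.3, "LINE": 0.7, "LTR": 0.7, "exon": 1.0, "random": 1.0},
            "me2": {"Simple_repeat": 0.8, "LINE": 2.0, "LTR": 2.0, "exon": 1.2, "random": 1.0},
            "me3": {"Simple_repeat": 0.7, "LINE": 0.6, "LTR": 0.6, "exon": 1.5, "random": 1.0},
        }
    )
    chip_depth_per_100bp: float = 20.0
    n_random_regions: int = 2_000
    random_region_width: int = 80

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("gene_length", "exons_per_gene", "precursor_length"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class AnnotationBundle:
    repeats: FeatureSet
    genes: FeatureSet
    precursors: FeatureSet
    clusters: list[PiRNACluster]
    chrom_sizes: dict[str, int]


@dataclass
class SimTruth:
    """Planted structure of a simulated experiment.

    ``means`` holds the true NB mean per feature and condition (before
    per-sample depth factors); the remaining fields record which features
    carry which planted effect.
    """

    means: pd.DataFrame                       # features x conditions
    te_up: dict[str, set[str]]                # condition -> activated TE ids
    batch_inconsistent: set[str]
    context: dict[str, str]                   # TE id -> planted context label
    host_gene: dict[str, str]                 # TE id -> embedding gene (where applicable)
    expressed_genes: set[str]
    activated_genes: set[str]                 # unexpressed in WT, transcribed in H3K36R
    cluster_assignment: dict[str, str]        # precursor id -> cluster id
    cluster_fold: dict[str, dict[str, float]]
    sample_scales: dict[str, float]
    chip_multipliers: dict[str, dict[str, float]]

    def to_json(self, path) -> None:
        payload = {
            "means": {c: self.means[c].round(6).to_dict() for c in self.means.columns},
            "te_up": {k: sorted(v) for k, v in self.te_up.items()},
            "batch_inconsistent": sorted(self.batch_inconsistent),
            "context": self.context,
            "host_gene": self.host_gene,
            "expressed_genes": sorted(self.expressed_genes),
            "activated_genes": sorted(self.activated_genes),
            "cluster_assignment": self.cluster_assignment,
            "cluster_fold": self.cluster_fold,
            "sample_scales": self.sample_scales,
            "chip_multipliers": self.chip_multipliers,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


class _Placer:
    """Rejection-sampling placement of non-overlapping intervals."""

    def __init__(self, chrom_sizes: dict[str, int], rng: np.random.Generator):
        self.sizes = dict(chrom_sizes)
        self.rng = rng
        self.occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}

    def _free(self, chrom: str, start: int, end: int) -> bool:
        return all(end <= s or start >= e for s, e in self.occupied[chrom])

    def reserve(self, chrom: str, start: int, end: int) -> None:
        self.occupied[chrom].append((start, end))

    def place(self, length: int, chrom: str, lo: int, hi: int, tries: int = 200) -> int:
        """A free start position for an interval of ``length`` within [lo, hi)."""
        hi = min(hi, self.sizes[chrom])
        if hi - lo < length:
            raise ValueError(f"no room for a {length} bp feature on {chrom}[{lo},{hi})")
        for _ in range(tries):
            start = int(self.rng.integers(lo, hi - length + 1))
            if self._free(chrom, start, start + length):
                self.reserve(chrom, start, start + length)
                return start
        raise ValueError(f"placement space exhausted on {chrom}[{lo},{hi})")


def _pick_chrom(rng: np.random.Generator, sizes: dict[str, int]) -> str:
    chroms = sorted(sizes)
    lengths = np.array([sizes[c] for c in chroms], dtype=float)
    return chroms[rng.choice(len(chroms), p=lengths / lengths.sum())]


def simulate_annotation(config: SimConfig) -> AnnotationBundle:
    """Generate the annotation layer: repeats, genes, piRNA clusters/precursors.

    Retrotransposons are enriched in a leading pericentromeric block on each
    chromosome; genes occupy the distal portion; clusters sit in the
    pericentromeric blocks with their precursors packed inside.  A planned
    subset of LTR/LINE elements is embedded in genes of known expression
    state so the genomic-context stage has exact truth labels.
    """
    rng = np.random.default_rng(config.seed)
    sizes = dict(config.chromosomes)
    placer = _Placer(sizes, rng)
    peri_end = {c: int(L * config.pericentromere_fraction) for c, L in sizes.items()}

    # --- piRNA clusters first: big contiguous blocks in pericentromere
    clusters: list[PiRNACluster] = []
    precursors: list[PiRNAPrecursor] = []
    cluster_len = config.precursors_per_cluster * (config.precursor_length[1] + 60)
    cluster_chroms = sorted(sizes)
    for i, (cid, mode) in enumerate(sorted(config.clusters.items())):
        chrom = cluster_chroms[i % len(cluster_chroms)]
        start = placer.place(cluster_len, chrom, 0, max(peri_end[chrom], cluster_len + 1))
        clusters.append(PiRNACluster(cid, GenomicInterval(chrom, start, start + cluster_len), mode))
        cursor = start
        for j in range(config.precursors_per_cluster):
            plen = int(rng.integers(*config.precursor_length))
            gap = int(rng.integers(5, 60))
            pstart = cursor + gap
            cursor = pstart + plen
            if cursor > start + cluster_len:
                raise ValueError(f"cluster {cid} cannot hold {config.precursors_per_cluster} precursors")
            precursors.append(
                PiRNAPrecursor(f"{cid}_p{j:03d}", GenomicInterval(chrom, pstart, cursor))
            )

    # --- genes in the distal (non-pericentromeric) portion
    # (large intervals are placed before the many small catalogue entries so
    # rejection sampling does not starve on a fragmented genome)
    genes: list[GeneModel] = []
    n_expressed = int(round(config.n_genes * config.expressed_gene_fraction))
    for g in range(config.n_genes):
        glen = int(rng.integers(*config.gene_length))
        start = None
        for attempt in range(50):
            chrom = _pick_chrom(rng, sizes)
            try:
                start = placer.place(glen, chrom, peri_end[chrom], sizes[chrom], tries=50)
                break
            except ValueError:
                continue
        if start is None:
            raise ValueError("gene placement space exhausted")
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        bounds = np.sort(rng.choice(np.arange(1, glen), size=2 * n_ex, replace=False))
        exons = tuple(
            GenomicInterval(chrom, start + int(bounds[2 * k]), start + int(bounds[2 * k + 1]))
            for k in range(n_ex)
            if bounds[2 * k + 1] > bounds[2 * k]
        )
        genes.append(GeneModel(f"gene{g:04d}", GenomicInterval(chrom, start, start + glen), exons))
    # precursors outside any cluster (stable background of the catalogue)
    for j in range(config.n_precursors_outside):
        plen = int(rng.integers(*config.precursor_length))
        for attempt in range(50):
            chrom = _pick_chrom(rng, sizes)
            try:
                start = placer.place(plen, chrom, peri_end[chrom], sizes[chrom], tries=50)
                break
            except ValueError:
                if attempt == 49:
                    raise
        precursors.append(
            PiRNAPrecursor(f"orphan_p{j:03d}", GenomicInterval(chrom, start, start + plen))
        )

    expressed_genes = {g.gene_id for g in genes[:n_expressed]}
    unexpressed = [g for g in genes if g.gene_id not in expressed_genes]
    n_act = int(round(len(unexpressed) * config.activated_gene_fraction))
    activated_genes = {g.gene_id for g in unexpressed[:n_act]}

    # --- repeats: planned genic embeddings, then free placement
    repeats: list[RepeatFeature] = []
    context: dict[str, str] = {}
    host_gene: dict[str, str] = {}
    counter = 0

    def add_repeat(chrom: str, start: int, length: int, key: str) -> RepeatFeature:
        nonlocal counter
        order = key.split("/")[0] if "/" in key else key
        family = key.split("/")[1] if "/" in key else key
        feat = RepeatFeature(
            interval=GenomicInterval(chrom, start, start + length),
            repeat_name=f"{family}-element",
            family=family,
            order=order,
            feature_id=f"te{counter:05d}",
        )
        counter += 1
        repeats.append(feat)
        return feat

    embed_plan = (
        [("expressed_gene", None)] * config.te_in_expressed_gene
        + [("unexpressed_gene", "activated_in_mutant")] * config.te_in_unexpressed_gene_activated
        + [("unexpressed_gene", "silent_in_mutant")] * config.te_in_unexpressed_gene_silent
    )
    retro_keys = [k for k in config.repeat_counts if k.startswith(("LTR", "LINE"))]
    remaining = dict(config.repeat_counts)
    gene_pools = {
        "expressed_gene": [g for g in genes if g.gene_id in expressed_genes],
        "activated_in_mutant": [g for g in unexpressed if g.gene_id in activated_genes],
        "silent_in_mutant": [g for g in unexpressed if g.gene_id not in activated_genes],
    }
    pool_cursor = {k: 0 for k in gene_pools}
    for ctx, sub in embed_plan:
        key = retro_keys[int(rng.integers(len(retro_keys)))]
        if remaining.get(key, 0) <= 0:
            key = max(retro_keys, key=lambda k: remaining.get(k, 0))
        remaining[key] -= 1
        pool_name = sub if ctx == "unexpressed_gene" else "expressed_gene"
        pool = gene_pools[pool_name]
        host = pool[pool_cursor[pool_name] % len(pool)]
        pool_cursor[pool_name] += 1
        lo, hi = REPEAT_LENGTHS[key.split("/")[0]]
        length = int(rng.integers(lo, min(hi, len(host.interval) - 2)))
        start = host.interval.start + int(
            rng.integers(1, len(host.interval) - length)
        )
        feat = add_repeat(host.interval.chrom, start, length, key)
        context[feat.feature_id] = ctx if sub is None else f"{ctx}/{sub}"
        host_gene[feat.feature_id] = host.gene_id

    for key in config.repeat_counts:
        order = key.split("/")[0] if "/" in key else key
        lo, hi = REPEAT_LENGTHS.get(order, (50, 200))
        peri_w = config.pericentromere_weight if order in ("LTR", "LINE") else 0.3
        for _ in range(max(remaining.get(key, 0), 0)):
            length = int(rng.integers(lo, hi))
            for attempt in range(50):
                chrom = _pick_chrom(rng, sizes)
                in_peri = rng.random() < peri_w
                lo_pos = 0 if in_peri else peri_end[chrom]
                hi_pos = peri_end[chrom] if in_peri else sizes[chrom]
                try:
                    start = placer.place(length, chrom, lo_pos, hi_pos, tries=50)
                    break
                except ValueError:
                    if attempt == 49:
                        raise
            feat = add_repeat(chrom, start, length, key)
            context[feat.feature_id] = "intergenic"

    bundle = AnnotationBundle(
        repeats=FeatureSet(repeats, "repeat"),
        genes=FeatureSet(genes, "gene"),
        precursors=FeatureSet(precursors, "precursor"),
        clusters=clusters,
        chrom_sizes=sizes,
    )
    bundle._context_truth = context  # type: ignore[attr-defined]
    bundle._host_truth = host_gene  # type: ignore[attr-defined]
    bundle._expressed_truth = expressed_genes  # type: ignore[attr-defined]
    bundle._activated_truth = activated_genes  # type: ignore[attr-defined]
    return bundle


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if alpha < 1e-8:
        return rng.poisson(mean)
    size = 1.0 / alpha
    p = size / (size + mean)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(size, p[pos])
    return out


def simulate_counts(config: SimConfig, bundle: AnnotationBundle) -> tuple[CountMatrix, SimTruth]:
    """NB counts for all features and samples, plus the planted truth.

    ``count ~ NB(mean = s_j * mu_i * 2**lfc_i(condition_j), dispersion)``
    with lognormal per-sample depth factors ``s_j``.  Planted effects:
    condition-specific TE activation (biased towards LTR/LINE and nested so
    the knockout up-sets fall mostly inside the replacement-mutant set),
    batch-inconsistent TEs differing between the two wild-type runs, gene
    activation in the replacement mutant, and strand-mode-specific piRNA
    cluster folds.
    """
    rng = np.random.default_rng(config.seed + 1)
    conditions = list(config.replicates)
    te_ids = bundle.repeats.feature_ids
    gene_ids = bundle.genes.feature_ids
    prec_ids = bundle.precursors.feature_ids
    all_ids = te_ids + gene_ids + prec_ids

    expressed = bundle._expressed_truth  # type: ignore[attr-defined]
    activated = bundle._activated_truth  # type: ignore[attr-defined]
    cluster_mode = {c.cluster_id: c.strand_mode for c in bundle.clusters}
    prec_cluster = {
        p.precursor_id: p.precursor_id.rsplit("_p", 1)[0]
        for p in bundle.precursors
        if p.precursor_id.rsplit("_p", 1)[0] in cluster_mode
    }

    # baseline means (wild-type state)
    base = pd.Series(0.0, index=all_ids)
    base[te_ids] = config.mu_te
    for gid in gene_ids:
        base[gid] = config.mu_gene_expressed if gid in expressed else config.mu_gene_unexpressed
    for pid in prec_ids:
        cid = prec_cluster.get(pid)
        base[pid] = (
            config.mu_precursor[cluster_mode[cid]] if cid else config.mu_precursor_outside
        )

    # planted TE activation, nested across mutants
    weights = np.array(
        [config.te_up_class_weight.get(bundle.repeats[fid].order, 1.0) for fid in te_ids]
    )
    te_up: dict[str, set[str]] = {}
    n_base = int(round(config.te_up_fraction.get("H3K36R", 0.0) * len(te_ids)))
    base_up = set(
        str(x) for x in rng.choice(te_ids, size=n_base, replace=False, p=weights / weights.sum())
    ) if n_base else set()
    # gene-embedded TEs are always part of the replacement-mutant response so
    # the genomic-context stage sees every planted context label
    base_up |= set(bundle._context_truth) - {  # type: ignore[attr-defined]
        fid for fid, ctx in bundle._context_truth.items() if ctx == "intergenic"  # type: ignore[attr-defined]
    }
    te_up["H3K36R"] = base_up
    for cond in ("Set2KO", "NSDKO", "ash1KO"):
        frac = config.te_up_fraction.get(cond, 0.0)
        n_cond = int(round(frac * len(te_ids)))
        n_inside = min(int(round(n_cond * config.mutant_within_base)), len(base_up))
        inside = {str(x) for x in rng.choice(sorted(base_up), size=n_inside, replace=False)} if n_inside else set()
        outside_pool = sorted(set(te_ids) - base_up)
        n_out = min(n_cond - n_inside, len(outside_pool))
        outside = {str(x) for x in rng.choice(outside_pool, size=n_out, replace=False)} if n_out else set()
        te_up[cond] = inside | outside

    batch_pool = sorted(set(te_ids) - base_up)
    batch_inconsistent = {
        str(x)
        for x in rng.choice(batch_pool, size=min(config.n_batch_inconsistent, len(batch_pool)), replace=False)
    }

    # condition-wise true means
    means = pd.DataFrame({c: base.copy() for c in conditions})
    for cond, ids in te_up.items():
        if cond in means:
            means.loc[sorted(ids), cond] *= 2.0 ** config.te_up_lfc
    if "H3K36R" in means:
        means.loc[sorted(activated), "H3K36R"] *= 2.0 ** config.gene_activation_lfc
    for cond, fold_by_mode in config.cluster_fold.items():
        if cond not in means:
            continue
        for pid in prec_ids:
            cid = prec_cluster.get(pid)
            if cid:
                means.loc[pid, cond] *= fold_by_mode[cluster_mode[cid]]
    if "WT_b2" in means:
        means.loc[sorted(batch_inconsistent), "WT_b2"] *= 2.0 ** config.batch_lfc

    # samples and draws
    meta: list[SampleMeta] = []
    for cond, n_rep in config.replicates.items():
        batch = cond.split("_b")[1] if cond.startswith("WT_b") else "1"
        cond_label = "WT" if cond.startswith("WT_b") else cond
        for r in range(1, n_rep + 1):
            meta.append(SampleMeta(f"{cond}_r{r}", condition=cond_label, batch=batch, replicate=r))
    scales = {
        m.sample_id: float(np.exp(rng.normal(0.0, config.sample_scale_sd))) for m in meta
    }
    columns = {}
    for m, cond in zip(meta, [c for c, n in config.replicates.items() for _ in range(n)]):
        mu = means[cond].to_numpy() * scales[m.sample_id]
        columns[m.sample_id] = _nb_draw(rng, mu, config.dispersion)
    counts = pd.DataFrame(columns, index=pd.Index(all_ids, name="feature_id"))
    matrix = CountMatrix(counts, counts.sum(axis=0), meta)

    truth = SimTruth(
        means=means,
        te_up=te_up,
        batch_inconsistent=batch_inconsistent,
        context=dict(bundle._context_truth),  # type: ignore[attr-defined]
        host_gene=dict(bundle._host_truth),  # type: ignore[attr-defined]
        expressed_genes=set(expressed),
        activated_genes=set(activated),
        cluster_assignment=prec_cluster,
        cluster_fold={c: dict(v) for c, v in config.cluster_fold.items()},
        sample_scales=scales,
        chip_multipliers={t: dict(v) for t, v in config.chip_multipliers.items()},
    )
    return matrix, truth


def simulate_alignments(
    config: SimConfig,
    bundle: AnnotationBundle,
    counts: CountMatrix,
    out_dir,
    feature_kinds: tuple[str, ...] = ("repeat", "gene", "precursor"),
) -> dict[str, Path]:
    """Write one coordinate-sorted SAM per sample realising the count matrix.

    Each count becomes that many single-end reads placed uniformly within the
    feature (clipped to the feature when it is shorter than the read length),
    with mapping quality 255, or 0 for the configured multi-mapper fraction.
    With disjoint features and no multi-mappers, counting the SAM reproduces
    the matrix exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 2)
    feature_lookup = {}
    for kind, fs in (("repeat", bundle.repeats), ("gene", bundle.genes), ("precursor", bundle.precursors)):
        if kind in feature_kinds:
            for f in fs:
                feature_lookup[f.feature_id] = f.interval
    chroms = sorted(bundle.chrom_sizes)
    header = "".join(
        ["@HD\tVN:1.6\tSO:coordinate\n"]
        + [f"@SQ\tSN:{c}\tLN:{bundle.chrom_sizes[c]}\n" for c in chroms]
    )
    paths = {}
    for sample in counts.sample_ids:
        reads = []  # (chrom_rank, pos0, name, mapq, cigar)
        serial = 0
        col = counts.counts[sample]
        for fid, n in col.items():
            iv = feature_lookup.get(fid)
            if iv is None or n == 0:
                continue
            flen = len(iv)
            rlen = min(config.read_length, flen)
            starts = rng.integers(iv.start, iv.end - rlen + 1, size=int(n))
            multi = rng.random(int(n)) < config.multi_fraction
            for s, is_multi in zip(starts, multi):
                reads.append((chroms.index(iv.chrom), int(s), f"r{serial:07d}", 0 if is_multi else 255, rlen))
                serial += 1
        reads.sort()
        path = out_dir / f"{sample}.sam"
        with open(path, "w") as fh:
            fh.write(header)
            for rank, pos, name, mapq, rlen in reads:
                fh.write(
                    f"{name}\t0\t{chroms[rank]}\t{pos + 1}\t{mapq}\t{rlen}M\t*\t0\t0\t*\t*\n"
                )
        paths[sample] = path
    return paths


@dataclass
class ChipSim:
    """Simulated ChIP/input counts for each methylation target.

    ``chip_lib``/``input_lib`` are genome-wide library sizes: the profiled
    feature counts plus the expected uniform background over the rest of the
    genome, so ratios are normalised the way depth-matched sequencing
    libraries would be.
    """

    chip: dict[str, list[pd.Series]]     # target -> replicate counts
    input_: dict[str, list[pd.Series]]
    chip_lib: dict[str, float]
    input_lib: dict[str, float]
    class_sets: dict[str, list[str]]
    regions: RandomRegionSet


def simulate_chip(config: SimConfig, bundle: AnnotationBundle) -> ChipSim:
    """ChIP/input coverage with class-specific enrichment multipliers.

    Input counts are proportional to feature length (noise-free, so the
    per-feature ratio denominator is unbiased); ChIP counts carry the
    per-class multiplier of each methylation target with Poisson noise.
    Two replicates per target, all deterministic under the config seed.
    """
    rng = np.random.default_rng(config.seed + 3)
    regions = sample_random_regions(
        bundle.chrom_sizes,
        n=config.n_random_regions,
        width=config.random_region_width,
        seed=config.seed + 4,
    )
    ids: list[str] = []
    lengths: list[int] = []
    class_sets: dict[str, list[str]] = {"random": [], "exon": [], "Simple_repeat": [], "LINE": [], "LTR": []}
    for rid, region in zip(regions.feature_ids, regions.regions):
        ids.append(rid)
        lengths.append(len(region))
        class_sets["random"].append(rid)
    for gene in bundle.genes:
        for i, exon in enumerate(gene.exons):
            eid = f"{gene.gene_id}_exon{i}"
            ids.append(eid)
            lengths.append(len(exon))
            class_sets["exon"].append(eid)
    for te in bundle.repeats:
        if te.order in ("Simple_repeat", "LINE", "LTR"):
            ids.append(te.feature_id)
            lengths.append(len(te.interval))
            class_sets[te.order].append(te.feature_id)
    length_arr = np.array(lengths, dtype=float)
    id_class = {}
    for label, members in class_sets.items():
        for fid in members:
            id_class[fid] = label
    base_rate = config.chip_depth_per_100bp * length_arr / 100.0
    genome_len = float(sum(bundle.chrom_sizes.values()))
    background = config.chip_depth_per_100bp * max(genome_len - length_arr.sum(), 0.0) / 100.0

    chip: dict[str, list[pd.Series]] = {}
    input_: dict[str, list[pd.Series]] = {}
    chip_lib: dict[str, float] = {}
    input_lib: dict[str, float] = {}
    for target, mults in config.chip_multipliers.items():
        mult_arr = np.array([mults.get(id_class[fid], 1.0) for fid in ids])
        chip[target] = [
            pd.Series(rng.poisson(base_rate * mult_arr), index=ids) for _ in range(2)
        ]
        input_[target] = [pd.Series(base_rate, index=ids) for _ in range(2)]
        # expected (not realised) totals: depth-matched library normalisation
        chip_lib[target] = float((base_rate * mult_arr).sum()) + background
        input_lib[target] = float(base_rate.sum()) + background
    return ChipSim(
        chip=chip, input_=input_, chip_lib=chip_lib, input_lib=input_lib,
        class_sets=class_sets, regions=regions,
    )


def write_bundle(config: SimConfig, bundle: AnnotationBundle, out_dir) -> None:
    """Export the annotation layer as plain-text files (BED/GTF/chrom.sizes)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "chrom.sizes", "w") as fh:
        for chrom in sorted(bundle.chrom_sizes):
            fh.write(f"{chrom}\t{bundle.chrom_sizes[chrom]}\n")
    bundle.repeats.to_bed(out / "repeats.bed")
    bundle.precursors.to_bed(out / "precursors.bed")
    with open(out / "clusters.bed", "w") as fh:
        for c in bundle.clusters:
            iv = c.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{c.cluster_id}|{c.strand_mode}\t0\t.\n")
    with open(out / "genes.gtf", "w") as fh:
        for gene in bundle.genes:
            iv = gene.interval
            attrs = f'gene_id "{gene.gene_id}";'
            fh.write(
                f"{iv.chrom}\tsim\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand if iv.strand != '.' else '+'}\t.\t{attrs}\n"
            )
            for exon in gene.exons:
                fh.write(
                    f"{exon.chrom}\tsim\texon\t{exon.start + 1}\t{exon.end}\t.\t+\t.\t{attrs}\n"
                )
    config.to_yaml(out / "simconfig.yaml")
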