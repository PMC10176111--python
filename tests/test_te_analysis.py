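"""TE inference stages: double-control filter, composition chi-square,
mutant membership partition, genomic context, positional density."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tepi.annotations import FeatureSet, GeneModel, GenomicInterval, RepeatFeature
from tepi.diffexp import DETable
from tepi.te_analysis import (
    bin_density,
    classify_genomic_context,
    composition_chi_square,
    control_consistency_filter,
    partition_by_mutants,
)


def de_table(p_by_feature, treatment="MUT", control="WT"):
    ids = sorted(p_by_feature)
    frame = pd.DataFrame(
        {
            "base_mean": 10.0,
            "log2fc": 1.0,
            "se": 0.5,
            "wald_z": 2.0,
            "p_value": [p_by_feature[f] for f in ids],
            "p_adj": [p_by_feature[f] for f in ids],
            "untested": False,
        },
        index=ids,
    )
    return DETable(frame, treatment, control)


def repeat_set(spans, order="LTR", family="Gypsy", chrom="chrA"):
    return FeatureSet(
        [
            RepeatFeature(GenomicInterval(chrom, s, e), "el", family, order, fid)
            for fid, (s, e) in spans.items()
        ],
        "repeat",
    )


class TestControlConsistencyFilter:
    def setup_method(self):
        self.main = de_table({"a": 0.001, "b": 0.001, "c": 0.001, "d": 0.8})
        self.runs = de_table({"a": 0.01, "b": 0.9, "c": 0.9, "d": 0.9}, "WT_b1", "WT_b2")
        self.geno = de_table({"a": 0.9, "b": 0.02, "c": 0.9, "d": 0.9}, "CTRL", "WT")

    def test_union_rule(self):
        filtered, report = control_consistency_filter(self.main, self.runs, self.geno)
        assert report.removed == {"a", "b"}
        assert report.removed_by_control_runs == {"a"}
        assert report.removed_by_control_genotype == {"b"}
        assert set(filtered.feature_ids) == {"c", "d"}

    def test_idempotent(self):
        filtered, _ = control_consistency_filter(self.main, self.runs, self.geno)
        again, report2 = control_consistency_filter(filtered, self.runs, self.geno)
        assert set(again.feature_ids) == set(filtered.feature_ids)
        assert report2.n_removed == 0

    def test_empty_universe_rejected(self):
        other = de_table({"z": 0.5})
        with pytest.raises(ValueError):
            control_consistency_filter(self.main, other, other)

    def test_planted_batch_effects_removed(self, small_config, small_study):
        """Features with a planted wild-type batch effect are filtered."""
        from tepi.pipeline import de_for_contrast
        from tepi.diffexp import size_factors_median_of_ratios

        bundle, counts, truth = small_study
        sf = size_factors_median_of_ratios(counts)
        te_ids = bundle.repeats.feature_ids
        runs = de_for_contrast(
            counts, sf, counts.samples_for("WT", "1"), counts.samples_for("WT", "2"),
            te_ids, treatment_label="WT_b1", control_label="WT_b2",
        )
        geno = de_for_contrast(counts, sf, "H3K36K", "WT", te_ids)
        main = de_for_contrast(counts, sf, "H3K36R", "H3K36K", te_ids)
        _, report = control_consistency_filter(main, runs, geno)
        planted = truth.batch_inconsistent
        assert len(report.removed & planted) / len(planted) >= 0.9
        consistent = set(te_ids) - planted
        assert len(report.removed & consistent) / len(consistent) <= 0.1


class TestCompositionChiSquare:
    def test_textbook_two_class_case(self):
        repeats = repeat_set(
            {f"L{i}": (i * 100, i * 100 + 50) for i in range(90)}
            | {f"J{i}": (10000 + i * 100, 10000 + i * 100 + 50) for i in range(10)},
        )
        # relabel the J features as LINE
        feats = [
            RepeatFeature(f.interval, f.repeat_name, "Jockey", "LINE", f.feature_id)
            if f.feature_id.startswith("J") else f
            for f in repeats
        ]
        repeats = FeatureSet(feats, "repeat")
        table = composition_chi_square(
            set(repeats.feature_ids), repeats, {"LTR": 0.5, "LINE": 0.5}
        )
        assert table.chi2_stat == pytest.approx(64.0)
        assert table.df == 1
        assert table.p_value == pytest.approx(stats.chi2.sf(64.0, 1))

    def test_observed_equals_expected(self):
        repeats = repeat_set({"a": (0, 50), "b": (100, 150)})
        table = composition_chi_square({"a", "b"}, repeats, {"LTR": 1.0})
        assert table.chi2_stat == 0.0 and table.p_value == 1.0

    def test_three_class_hand_case(self):
        spans = {f"f{i}": (i * 100, i * 100 + 50) for i in range(10)}
        feats = []
        orders = ["LTR"] * 6 + ["LINE"] * 3 + ["Simple_repeat"]
        for (fid, (s, e)), order in zip(spans.items(), orders):
            feats.append(RepeatFeature(GenomicInterval("c", s, e), "el", order, order, fid))
        repeats = FeatureSet(feats, "repeat")
        expected = {"LTR": 0.5, "LINE": 0.3, "Simple_repeat": 0.2}
        table = composition_chi_square(set(spans), repeats, expected)
        # chi2 = (6-5)^2/5 + (3-3)^2/3 + (1-2)^2/2 = 0.7
        assert table.chi2_stat == pytest.approx(0.7)
        assert table.df == 2

    def test_two_sample_mode_identical_vectors(self):
        repeats = repeat_set({"a": (0, 50), "b": (100, 150)})
        table = composition_chi_square(
            {"a", "b"}, repeats, {}, observed_other={"LTR": 2}
        )
        assert table.chi2_stat == pytest.approx(0.0)

    def test_unexpected_class_rejected(self):
        repeats = repeat_set({"a": (0, 50)})
        with pytest.raises(ValueError, match="zero expectation"):
            composition_chi_square({"a"}, repeats, {"LINE": 1.0})


class TestPartitionByMutants:
    def test_signature_labels(self):
        base = {"a", "b", "c"}
        part = partition_by_mutants(
            base,
            {"Set2": {"a", "b"}, "NSD": {"b"}, "ash1": set()},
        )
        assert part.class_counts == {"Set2": 1, "Set2 + NSD": 1, "none": 1}
        assert part.base_size == 3

    def test_counts_equal_brute_force_on_random_membership(self):
        rng = np.random.default_rng(9)
        base = {f"f{i}" for i in range(500)}
        per_mutant = {
            m: {f for f in base if rng.random() < q}
            for m, q in [("Set2", 0.6), ("NSD", 0.3), ("ash1", 0.15)]
        }
        part = partition_by_mutants(base, per_mutant)
        # brute force recount of every feature
        brute: dict[str, int] = {}
        for f in base:
            names = [m for m in ("Set2", "NSD", "ash1") if f in per_mutant[m]]
            label = " + ".join(names) if names else "none"
            brute[label] = brute.get(label, 0) + 1
        assert part.class_counts == brute
        assert sum(part.class_counts.values()) == len(base)


def make_genes(spans):
    return FeatureSet(
        [GeneModel(gid, GenomicInterval("chrA", s, e)) for gid, (s, e) in spans.items()],
        "gene",
    )


class TestGenomicContext:
    def setup_method(self):
        self.repeats = repeat_set(
            {
                "te_free": (10_000, 10_400),
                "te_expr": (1_100, 1_300),
                "te_silent": (3_100, 3_300),
                "te_activated": (5_100, 5_300),
            }
        )
        self.genes = make_genes(
            {"gA": (1_000, 2_000), "gB": (3_000, 4_000), "gC": (5_000, 6_000)}
        )
        self.wt_mean = pd.Series({"gA": 150.0, "gB": 0.0, "gC": 0.5})

    def classify(self, up=None):
        return classify_genomic_context(
            up or set(self.repeats.feature_ids),
            self.repeats,
            self.genes,
            self.wt_mean,
            mutant_up_genes={"gC"},
        )

    def test_rule_application(self):
        ctx = self.classify()
        table = ctx.assignments.set_index("feature_id")
        assert table.loc["te_free", "context"] == "intergenic"
        assert table.loc["te_expr", "context"] == "expressed_gene"
        assert table.loc["te_silent", "sub_context"] == "silent_in_mutant"
        assert table.loc["te_activated", "sub_context"] == "activated_in_mutant"

    def test_fractions_partition(self):
        ctx = self.classify()
        assert sum(ctx.fractions.values()) == pytest.approx(1.0)
        assert sum(ctx.sub_counts.values()) == ctx.counts["unexpressed_gene"]

    def test_expressed_priority_over_unexpressed(self):
        # TE overlapping both an expressed and an unexpressed gene
        repeats = repeat_set({"te": (1_900, 3_100)})
        genes = make_genes({"gA": (1_000, 2_000), "gB": (3_000, 4_000)})
        ctx = classify_genomic_context(
            {"te"}, repeats, genes, pd.Series({"gA": 100.0, "gB": 0.0}), set()
        )
        assert ctx.assignments.iloc[0].context == "expressed_gene"

    def test_gene_order_invariance(self):
        genes_rev = FeatureSet(list(self.genes)[::-1], "gene")
        a = self.classify()
        b = classify_genomic_context(
            set(self.repeats.feature_ids), self.repeats, genes_rev,
            self.wt_mean, {"gC"},
        )
        assert a.counts == b.counts and a.sub_counts == b.sub_counts

    def test_planted_labels_recovered_exactly(self, small_study):
        """On simulated data the classifier reproduces every planted label."""
        bundle, counts, truth = small_study
        from tepi.diffexp import size_factors_median_of_ratios

        sf = size_factors_median_of_ratios(counts)
        wt = counts.samples_for("WT")
        gene_ids = bundle.genes.feature_ids
        wt_mean = (counts.counts.loc[gene_ids, wt] / sf[wt].to_numpy()).mean(axis=1)
        embedded = {f for f, c in truth.context.items() if c != "intergenic"}
        ctx = classify_genomic_context(
            embedded | {next(iter(truth.te_up["H3K36R"] - embedded))},
            bundle.repeats, bundle.genes, wt_mean, truth.activated_genes,
        )
        predicted = {
            row.feature_id: (row.context if row.sub_context is None
                             else f"{row.context}/{row.sub_context}")
            for row in ctx.assignments.itertuples()
        }
        for fid, label in predicted.items():
            assert truth.context[fid] == label


class TestBinDensity:
    def test_midpoint_binning_and_conservation(self):
        repeats = repeat_set(
            {"a": (0, 10), "b": (20, 40), "c": (50, 70), "d": (199_990, 200_000)},
        )
        tracks, skipped = bin_density(
            set(repeats.feature_ids), repeats, {"chrA": 200_000}, window=100
        )
        (track,) = tracks
        assert track.counts[0] == 3
        assert track.counts.sum() == 4 and skipped == 0

    def test_boundary_midpoint_goes_right(self):
        # midpoint exactly at k*window belongs to window k
        repeats = repeat_set({"a": (90, 110)})  # midpoint 100
        tracks, _ = bin_density({"a"}, repeats, {"chrA": 300}, window=100)
        assert tracks[0].counts.tolist() == [0, 1, 0]

    def test_random_placements_brute_force(self):
        rng = np.random.default_rng(10)
        starts = rng.integers(0, 99_000, size=300)
        repeats = repeat_set({f"f{i}": (int(s), int(s) + 100) for i, s in enumerate(starts)})
        window = 10_000
        tracks, _ = bin_density(set(repeats.feature_ids), repeats, {"chrA": 100_000}, window)
        brute = np.zeros(10, dtype=int)
        for f in repeats:
            brute[f.interval.midpoint() // window] += 1
        assert tracks[0].counts.tolist() == brute.tolist()

    def test_unknown_chromosome_tallied(self):
        repeats = repeat_set({"a": (0, 10)}, chrom="chrZ")
        tracks, skipped = bin_density({"a"}, repeats, {"chrA": 1000})
        assert skipped == 1 and tracks[0].counts.sum() == 0
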