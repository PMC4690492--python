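"""Genomic-context labels, flank profiles, feature overlaps, breadth."""
import numpy as np
import pandas as pd
import pytest

from ecgi.annotate import (
    GeneModel,
    annotate_context,
    count_feature_overlaps,
    expression_breadth,
    flank_profile,
    read_genes_bed12,
)
from ecgi.seqfeatures import seq_stats

from _oracles import quadratic_group_counts
from conftest import make_matrix


def entries(pairs, chrom="chr1"):
    return pd.DataFrame([{"chrom": chrom, "start": a, "end": b} for a, b in pairs])


GENES = [
    GeneModel("g1", "chr1", "+", 10_000, 18_000, exons=[(10_000, 10_500), (17_000, 18_000)]),
    GeneModel("g2", "chr1", "-", 40_000, 46_000),
]


class TestContext:
    def test_upstream_window_is_promoter(self):
        ctx = annotate_context(entries([(7_500, 7_800)]), GENES)
        assert ctx.iloc[0]["label"] == "promoter"

    def test_intronic_entry_is_gene_body(self):
        ctx = annotate_context(entries([(14_000, 14_300)]), GENES)
        assert ctx.iloc[0]["label"] == "gene_body"
        assert ctx.iloc[0]["sublabel"] == "intron"

    def test_exonic_entry_flagged_exon(self):
        ctx = annotate_context(entries([(10_100, 10_200)]), GENES)
        assert ctx.iloc[0]["sublabel"] == "exon"

    def test_minus_strand_promoter_is_downstream_in_genomic_coords(self):
        # g2 is minus-strand: TSS at 46 000, promoter [46 000, 49 000)
        ctx = annotate_context(entries([(47_000, 47_100)]), GENES)
        assert ctx.iloc[0]["label"] == "promoter"

    def test_strand_aware_downstream(self):
        # past g1's TES (18 000) within 3 kb
        ctx = annotate_context(entries([(19_000, 19_100)]), GENES)
        assert ctx.iloc[0]["label"] == "downstream"

    def test_intergenic_distance(self):
        ctx = annotate_context(entries([(23_000, 23_200)]), GENES)
        assert ctx.iloc[0]["label"] == "intergenic"
        assert ctx.iloc[0]["distance_to_nearest_gene"] == 5_000

    def test_precedence_promoter_over_body(self):
        # overlaps both g1's body and g2's promoter region? construct overlap
        # with g1 promoter and g1 body: spans the TSS
        ctx = annotate_context(entries([(9_500, 10_200)]), GENES)
        assert ctx.iloc[0]["label"] == "promoter"

    def test_labels_partition_catalog(self, default_sim):
        truth, catalog = default_sim["truth"], default_sim["catalog"]
        genes = [
            GeneModel(r["name"], r["chrom"], r["strand"], int(r["start"]), int(r["end"]))
            for _, r in truth.genes.iterrows()
        ]
        ctx = annotate_context(catalog, genes)
        assert len(ctx) == len(catalog)
        counts = ctx["label"].value_counts()
        assert counts.sum() == len(catalog)
        assert set(counts.index) <= {"promoter", "gene_body", "downstream", "intergenic"}

    def test_bed12_reader_round_trips_generator_genes(self, tmp_path, default_sim):
        truth = default_sim["truth"]
        p = tmp_path / "genes.bed12"
        truth.genes.to_csv(p, sep="\t", header=False, index=False)
        genes = read_genes_bed12(p)
        assert len(genes) == len(truth.genes)
        g0 = genes[0]
        r0 = truth.genes.iloc[0]
        assert (g0.start, g0.end, g0.strand) == (r0["start"], r0["end"], r0["strand"])
        assert sum(e - s for s, e in g0.exons) == sum(
            int(x) for x in r0["sizes"].rstrip(",").split(",")
        )


class TestGtfReader:
    def test_longest_transcript_per_gene(self, tmp_path):
        from ecgi.annotate import read_genes_gtf

        gtf = tmp_path / "g.gtf"
        gtf.write_text(
            'chr1\tx\ttranscript\t101\t500\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
            'chr1\tx\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
            'chr1\tx\texon\t401\t500\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
            'chr1\tx\ttranscript\t101\t300\t.\t+\t.\tgene_id "g1"; transcript_id "t2";\n'
            'chr1\tx\texon\t101\t300\t.\t+\t.\tgene_id "g1"; transcript_id "t2";\n'
        )
        genes = read_genes_gtf(gtf)
        assert len(genes) == 1
        g = genes[0]
        assert (g.start, g.end, g.strand) == (100, 500, "+")  # longest transcript
        assert g.exons == [(100, 200), (400, 500)]


class TestFlankProfile:
    def test_single_bin_island_matches_seq_stats(self):
        seq = "ACGT" * 300
        m = make_matrix(np.array([500]), {"t": np.array([0.0])})
        anchors = entries([(400, 800)])
        prof = flank_profile(anchors, m, {"chr1": seq}, n_bins=1)
        island = prof[(prof["region"] == "island")].iloc[0]
        st_ = seq_stats(seq[400:800])
        assert island["gc"] == pytest.approx(st_.gc_content)
        assert island["cpg_oe"] == pytest.approx(st_.cpg_oe)

    def test_anchor_at_chromosome_start_truncates_flanks(self):
        seq = "ACGT" * 200
        m = make_matrix(np.array([10]), {"t": np.array([0.0])})
        prof = flank_profile(entries([(0, 200)]), m, {"chr1": seq}, n_bins=2)
        shore = prof[prof["region"] == "shore"]
        assert (shore["n_anchors"] == 0).all()
        island = prof[prof["region"] == "island"]
        assert (island["n_anchors"] == 1).all()

    def test_gc_gradient_declines_across_shores(self, default_sim):
        """Planted islands are GC-rich; background is GC-poor, so shore bins
        average below island bins."""
        catalog, genome, m = (
            default_sim["catalog"],
            default_sim["genome"],
            default_sim["matrix"],
        )
        anchors = catalog[catalog["breadth"] == len(m.tissues)].head(40)
        prof = flank_profile(anchors, m, genome, n_bins=4)
        island_gc = prof[prof["region"] == "island"]["gc"].mean()
        shore_gc = prof[prof["region"] == "shore"]["gc"].mean()
        shelf_gc = prof[prof["region"] == "shelf"]["gc"].mean()
        assert island_gc > shore_gc
        assert island_gc > shelf_gc

    def test_constitutive_islands_have_higher_breadth_than_shores(self, default_sim):
        catalog, genome, m = (
            default_sim["catalog"],
            default_sim["genome"],
            default_sim["matrix"],
        )
        anchors = catalog[catalog["breadth"] == len(m.tissues)].head(40)
        prof = flank_profile(anchors, m, genome, n_bins=2)
        isl = prof[prof["region"] == "island"]["mean_breadth"].mean()
        shore = prof[prof["region"] == "shore"]["mean_breadth"].mean()
        assert isl > shore


class TestFeatureOverlaps:
    def test_no_features_gives_zeros(self):
        counts, summary = count_feature_overlaps(
            entries([(0, 100)]), {"tf": pd.DataFrame(columns=["chrom", "start", "end", "group"])}
        )
        assert counts["tf"].tolist() == [0]
        assert summary["tf"]["fraction_with_overlap"] == 0.0

    def test_full_coverage_gives_fraction_one(self):
        feats = pd.DataFrame(
            [{"chrom": "chr1", "start": 0, "end": 10_000, "group": "x"}]
        )
        counts, summary = count_feature_overlaps(entries([(0, 100), (500, 700)]), {"f": feats})
        assert counts["f"].tolist() == [1, 1]
        assert summary["f"]["fraction_with_overlap"] == 1.0

    def test_toy_two_factor_counts(self):
        ents = entries([(0, 100), (200, 300), (400, 500)])
        feats = pd.DataFrame(
            [
                {"chrom": "chr1", "start": 10, "end": 20, "group": "TF1"},
                {"chrom": "chr1", "start": 210, "end": 220, "group": "TF1"},
                {"chrom": "chr1", "start": 250, "end": 260, "group": "TF2"},
            ]
        )
        counts, _ = count_feature_overlaps(ents, {"tf": feats})
        assert counts["tf"].tolist() == [1, 2, 0]

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(9)
        ents = entries(
            [(int(s), int(s) + int(w)) for s, w in
             zip(rng.integers(0, 50_000, 40), rng.integers(50, 500, 40))]
        )
        feats = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": rng.integers(0, 50_000, 100),
                "end": 0,
                "group": rng.choice(["a", "b", "c"], 100),
            }
        )
        feats["end"] = feats["start"] + rng.integers(10, 800, 100)
        counts, _ = count_feature_overlaps(ents, {"f": feats})
        by_group = {
            g: [(r["chrom"], int(r["start"]), int(r["end"])) for _, r in grp.iterrows()]
            for g, grp in feats.groupby("group")
        }
        oracle = quadratic_group_counts(
            [(r["chrom"], int(r["start"]), int(r["end"])) for _, r in ents.iterrows()],
            by_group,
        )
        assert counts["f"].tolist() == oracle


class TestExpressionBreadth:
    def test_constant_matrix_all_zero(self):
        expr = pd.DataFrame(np.ones((4, 10)))
        assert expression_breadth(expr).tolist() == [0, 0, 0, 0]

    def test_hand_computed_toy(self):
        expr = pd.DataFrame(np.zeros((4, 10)))
        expr.iloc[0, :3] = 5.0  # 3 tissues above the global median (0)
        # global median over 40 cells with 3 fives: median 0; gene0 breadth 3
        assert expression_breadth(expr).tolist() == [3, 0, 0, 0]

    def test_higher_quantile_is_monotone(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.random((20, 10)))
        b50 = expression_breadth(expr, 0.5)
        b75 = expression_breadth(expr, 0.75)
        assert (b75 <= b50).all()
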