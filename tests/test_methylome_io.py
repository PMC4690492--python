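"""Parsing, dyad collapsing and the site-level filter cascade."""
import itertools

import numpy as np
import pandas as pd
import pytest

from ecgi import io as mio


def _write(tmp_path, name, lines):
    p = tmp_path / name
    p.write_text("".join(line + "\n" for line in lines))
    return p


class TestReadMethylome:
    def test_bismark_cov_identity_parse(self, tmp_path):
        p = _write(
            tmp_path,
            "a.cov",
            ["chr1\t101\t101\t75\t3\t1", "chr1\t205\t205\t0\t0\t8", "chr2\t11\t11\t100\t5\t0"],
        )
        m = mio.read_methylome(p, "bismark-cov", tissue_id="t")
        assert len(m) == 3
        row = m.sites.iloc[0]
        assert (row["chrom"], row["pos"], row["meth"], row["total"]) == ("chr1", 100, 3, 4)

    def test_bedgraph_cov_keeps_zero_based_positions(self, tmp_path):
        p = _write(tmp_path, "a.bg", ["chr1\t100\t101\t50\t2\t2"])
        m = mio.read_methylome(p, "bedgraph-cov")
        assert m.sites.iloc[0]["pos"] == 100

    def test_empty_file_gives_empty_methylome(self, tmp_path):
        p = _write(tmp_path, "empty.cov", [])
        assert len(mio.read_methylome(p, "bismark-cov")) == 0

    def test_duplicate_position_error_names_position(self, tmp_path):
        p = _write(
            tmp_path, "dup.cov", ["chr1\t101\t101\t0\t0\t5", "chr1\t101\t101\t0\t1\t4"]
        )
        with pytest.raises(ValueError, match="chr1:100"):
            mio.read_methylome(p, "bismark-cov")

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = _write(tmp_path, "bad.cov", ["chr1\t101\t101\t0\t0\t5", "chr1\tx\ty\t0\t0\t5"])
        with pytest.raises(ValueError, match="line 2"):
            mio.read_methylome(p, "bismark-cov")

    def test_cx_report_collapses_strands(self, tmp_path):
        p = _write(
            tmp_path,
            "a.cx",
            [
                "chr1\t101\t+\t3\t2\tCG\tCGA",   # dyad C at pos0 100
                "chr1\t102\t-\t1\t4\tCG\tCGT",   # partner at pos0 101 -> 100
                "chr1\t150\t+\t2\t0\tCHH\tCAT",  # non-CG context dropped
            ],
        )
        m = mio.read_methylome(p, "cx-report")
        assert len(m) == 1
        row = m.sites.iloc[0]
        assert (row["pos"], row["meth"], row["total"]) == (100, 4, 10)

    @pytest.mark.parametrize("fmt", ["bismark-cov", "bedgraph-cov"])
    def test_round_trip(self, tmp_path, fmt):
        p = _write(
            tmp_path, "a.txt", ["chr1\t101\t101\t60\t3\t2", "chr2\t7\t7\t0\t0\t9"]
        )
        src = p if fmt == "bismark-cov" else _write(
            tmp_path, "b.txt", ["chr1\t100\t101\t60\t3\t2", "chr2\t6\t7\t0\t0\t9"]
        )
        m1 = mio.read_methylome(src, fmt, tissue_id="t")
        out = tmp_path / f"rt.{fmt}"
        mio.write_methylome(m1, out, fmt)
        m2 = mio.read_methylome(out, fmt, tissue_id="t")
        pd.testing.assert_frame_equal(m1.sites, m2.sites)


class TestCollapseDyads:
    def test_counts_are_additive(self):
        plus = pd.DataFrame({"chrom": ["chr1"], "pos": [100], "meth": [3], "total": [5]})
        minus = pd.DataFrame({"chrom": ["chr1"], "pos": [101], "meth": [1], "total": [5]})
        out = mio.collapse_dyads(plus, minus)
        assert out.iloc[0].tolist() == ["chr1", 100, 4, 10]

    def test_plus_only_passes_through(self):
        plus = pd.DataFrame({"chrom": ["chr1"], "pos": [100], "meth": [2], "total": [4]})
        out = mio.collapse_dyads(plus, plus.iloc[:0])
        assert out.iloc[0].tolist() == ["chr1", 100, 2, 4]

    def test_orphan_minus_anchors_at_pos_minus_one(self):
        minus = pd.DataFrame({"chrom": ["chr1"], "pos": [51], "meth": [1], "total": [2]})
        out = mio.collapse_dyads(minus.iloc[:0], minus)
        assert out.iloc[0]["pos"] == 50

    def test_total_reads_conserved(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(10_000, size=50, replace=False))
        plus = pd.DataFrame(
            {"chrom": "chr1", "pos": pos, "meth": rng.integers(0, 5, 50),
             "total": rng.integers(5, 10, 50)}
        )
        minus = plus.copy()
        minus["pos"] = minus["pos"] + 1
        out = mio.collapse_dyads(plus, minus)
        assert out["total"].sum() == plus["total"].sum() + minus["total"].sum()
        assert out["meth"].sum() == plus["meth"].sum() + minus["meth"].sum()

    def test_zero_coverage_dyad_kept_until_coverage_filter(self):
        plus = pd.DataFrame({"chrom": ["chr1"], "pos": [100], "meth": [0], "total": [0]})
        minus = pd.DataFrame({"chrom": ["chr1"], "pos": [101], "meth": [0], "total": [0]})
        out = mio.collapse_dyads(plus, minus)
        assert out.iloc[0]["total"] == 0
        m = mio.TissueMethylome("t", out)
        sm = mio.build_site_matrix([m], min_coverage=5)
        assert len(sm) == 0


def _toy_methylomes():
    """5 positions; one low-coverage in t2, one on chrX, one SNP-masked."""
    pos_chr1 = [100, 200, 300, 400]
    t1 = pd.DataFrame(
        {"chrom": ["chr1"] * 4 + ["chrX"], "pos": pos_chr1 + [50],
         "meth": [1, 2, 3, 0, 1], "total": [8, 9, 10, 6, 7]}
    )
    t2 = t1.copy()
    t2.loc[1, "total"] = 4  # coverage 4 < 5 at chr1:200
    return [mio.TissueMethylome("t1", t1), mio.TissueMethylome("t2", t2)]


def _toy_masks():
    return mio.MaskSet(snp={"chr1": np.array([301])})  # masks dyad at 300 (G position)


class TestBuildSiteMatrix:
    def test_filter_cascade_hand_enumeration(self):
        # chr1:200 fails coverage, chr1:300 is SNP-masked, chrX:50 not autosomal
        sm = mio.build_site_matrix(_toy_methylomes(), _toy_masks())
        assert sm.sites["pos"].tolist() == [100, 400]
        assert sm.filter_stats["retained"] == 2

    def test_no_masks_all_covered_retains_everything(self):
        ms = _toy_methylomes()
        ms[1].sites.loc[1, "total"] = 9
        sm = mio.build_site_matrix(ms, autosomes={"chr1", "chrX"})
        assert len(sm) == 5

    def test_min_coverage_zero_keeps_joint_presence(self):
        ms = _toy_methylomes()
        ms[0].sites = ms[0].sites.iloc[1:].reset_index(drop=True)  # drop chr1:100 from t1
        ms = [mio.TissueMethylome(m.tissue_id, m.sites) for m in ms]
        sm = mio.build_site_matrix(ms, min_coverage=0, autosomes={"chr1", "chrX"})
        assert sm.sites["pos"].tolist() == [200, 300, 400, 50]

    def test_filter_order_independence(self):
        ms = _toy_methylomes()
        masks = _toy_masks()
        reference = mio.build_site_matrix(ms, masks)
        joint = reference  # filters are per-position predicates; re-derive them
        frames = []
        for m in ms:
            frames.append(
                m.sites.rename(
                    columns={"meth": f"meth_{m.tissue_id}", "total": f"total_{m.tissue_id}"}
                )
            )
        joint = frames[0].merge(frames[1], on=["chrom", "pos"], how="inner")
        preds = {
            "coverage": (joint[["total_t1", "total_t2"]] >= 5).all(axis=1).to_numpy(),
            "autosome": joint["chrom"].isin({"chr1"}).to_numpy(),
            "snp": ~np.array(
                [masks.snp_hit(c, np.array([p]))[0] for c, p in zip(joint["chrom"], joint["pos"])]
            ),
            "mappability": np.ones(len(joint), dtype=bool),
        }
        for order in itertools.permutations(preds):
            keep = np.ones(len(joint), dtype=bool)
            for name in order:
                keep &= preds[name]
            got = joint.loc[keep, "pos"].tolist()
            assert got == reference.sites["pos"].tolist()

    def test_zero_survivors_warns_not_crashes(self, caplog):
        ms = _toy_methylomes()
        with caplog.at_level("WARNING"):
            sm = mio.build_site_matrix(ms, min_coverage=100)
        assert len(sm) == 0
        assert any("zero" in r.message for r in caplog.records)

    def test_site_matrix_tsv_round_trip(self, tmp_path, default_sim):
        sm = default_sim["matrix"]
        p = tmp_path / "m.tsv"
        sm.write_tsv(p)
        back = mio.SiteMatrix.read_tsv(p)
        assert back.tissues == sm.tissues
        pd.testing.assert_frame_equal(back.sites, sm.sites)


class TestMaskReaders:
    def test_vcf_af_threshold_and_biallelic_only(self, tmp_path):
        p = tmp_path / "s.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=AF,Number=A,Type=Float,Description="AF">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t101\t.\tC\tT\t.\tPASS\tAF=0.2\n"
            "chr1\t201\t.\tC\tT\t.\tPASS\tAF=0.005\n"     # below threshold
            "chr1\t301\t.\tC\tT,G\t.\tPASS\tAF=0.3,0.1\n"  # multiallelic
        )
        snp = mio.read_snp_vcf(p)
        assert snp["chr1"].tolist() == [100]

    def test_mappability_scores_with_default_for_uncovered(self, tmp_path):
        p = tmp_path / "map.bedgraph"
        p.write_text("chr1\t0\t100\t30\nchr1\t100\t200\t80\n")
        masks = mio.MaskSet(mappability=mio.read_mappability_bedgraph(p))
        got = masks.mappability_at("chr1", np.array([50, 150, 500]))
        assert got.tolist() == [30.0, 80.0, 100.0]
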