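"""Seed-and-extend island calling against the exhaustive oracle."""
import numpy as np
import pytest

import ecgi
from ecgi.detect import DetectionParams, detect_islands, islands_to_bed, qualify_window, sweep_params

from _oracles import oracle_islands
from conftest import make_matrix


def random_matrix(rng, span_bp=20_000, density=0.03, sparse_prob=0.5):
    """Random mixed-methylation matrix; fractions are multiples of 0.05."""
    n = max(int(span_bp * density), 1)
    pos = np.sort(rng.choice(span_bp, size=n, replace=False))
    sparse = rng.random(n) < sparse_prob
    lev = np.where(
        sparse, rng.integers(0, 4, n), rng.integers(4, 21, n)
    ) / 20.0
    return make_matrix(pos, {"t": lev}), pos, lev


class TestQualifyWindow:
    def test_hand_counted_sparse_fraction(self):
        pos = np.arange(12) * 15 + 10          # 12 CpGs inside [0, 200)
        lev = np.array([0.0] * 10 + [0.5, 0.5])
        ok, n, frac = qualify_window(pos, lev, 0, 200, DetectionParams())
        assert (ok, n) == (True, 12)
        assert frac == pytest.approx(10 / 12)

    def test_density_failure(self):
        pos = np.arange(9) * 20
        ok, n, _ = qualify_window(pos, np.zeros(9), 0, 200, DetectionParams())
        assert not ok and n == 9

    def test_sparse_fraction_failure(self):
        pos = np.arange(10) * 20
        ok, _, frac = qualify_window(pos, np.full(10, 0.5), 0, 200, DetectionParams())
        assert not ok and frac == 0.0

    def test_empty_window(self):
        ok, n, frac = qualify_window(np.array([500]), np.array([0.0]), 0, 200, DetectionParams())
        assert (ok, n, frac) == (False, 0, 0.0)


class TestDetectIslands:
    def test_single_hypomethylated_run_matches_oracle(self):
        # CpGs every 20 bp at 0.0 in [1000, 2000), dense methylated flanks
        pos = np.concatenate(
            [np.arange(0, 1000, 10), np.arange(1000, 2000, 20), np.arange(2000, 3000, 10)]
        )
        lev = np.where((pos >= 1000) & (pos < 2000), 0.0, 1.0)
        m = make_matrix(pos, {"t": lev})
        params = DetectionParams()
        islands = detect_islands(m, "t", params)
        expected = oracle_islands(pos, lev, params)
        assert [(i.start, i.end) for i in islands] == expected
        assert len(islands) == 1

    def test_uniformly_methylated_chromosome_is_empty(self):
        pos = np.arange(0, 5000, 20)
        m = make_matrix(pos, {"t": np.full(pos.size, 0.9)})
        assert detect_islands(m, "t") == []

    def test_chromosome_without_cpgs_is_empty(self):
        m = make_matrix(np.array([], dtype=int), {"t": np.array([])})
        assert detect_islands(m, "t") == []

    def test_unknown_tissue_raises(self):
        m = make_matrix(np.array([10]), {"t": np.array([0.0])})
        with pytest.raises(KeyError, match="nope"):
            detect_islands(m, "nope")

    def test_default_params_are_standard(self):
        p = DetectionParams()
        assert (p.window_bp, p.step_bp, p.min_cpgs) == (200, 50, 10)
        assert (p.sparse_meth_cutoff, p.min_sparse_fraction) == (0.2, 0.8)

    def test_random_matrices_match_oracle(self):
        rng = np.random.default_rng(42)
        params = DetectionParams()
        for _ in range(15):
            m, pos, lev = random_matrix(rng, span_bp=int(rng.integers(5_000, 25_000)))
            got = [(i.start, i.end) for i in detect_islands(m, "t", params)]
            assert got == oracle_islands(pos, lev, params)

    def test_monotone_relaxation_never_removes_bases(self):
        rng = np.random.default_rng(7)
        m, pos, lev = random_matrix(rng, span_bp=15_000, sparse_prob=0.6)
        base = DetectionParams()
        relaxed = [
            DetectionParams(min_cpgs=5),
            DetectionParams(sparse_meth_cutoff=0.3),
            DetectionParams(min_sparse_fraction=0.7),
        ]
        cover0 = set()
        for isl in detect_islands(m, "t", base):
            cover0.update(range(isl.start, isl.end))
        for params in relaxed:
            cover = set()
            for isl in detect_islands(m, "t", params):
                cover.update(range(isl.start, isl.end))
            assert cover0 <= cover

    def test_translation_equivariance(self):
        rng = np.random.default_rng(3)
        m, pos, lev = random_matrix(rng, span_bp=10_000)
        shift = 50 * 17
        m2 = make_matrix(pos + shift, {"t": lev})
        a = [(i.start, i.end) for i in detect_islands(m, "t")]
        b = [(i.start, i.end) for i in detect_islands(m2, "t")]
        assert b == [(s + shift, e + shift) for s, e in a]

    def test_byte_identical_bed_output(self):
        rng = np.random.default_rng(11)
        m, _, _ = random_matrix(rng)
        bed1 = islands_to_bed(detect_islands(m, "t"))
        bed2 = islands_to_bed(detect_islands(m, "t"))
        assert bed1.encode() == bed2.encode()

    def test_trim_sparse_snaps_to_hypomethylated_cpgs(self):
        pos = np.concatenate([np.arange(1000, 2000, 20), np.arange(2000, 4000, 50)])
        lev = np.where(pos < 2000, 0.0, 1.0)
        m = make_matrix(pos, {"t": lev})
        isl = detect_islands(m, "t", trim="sparse")
        assert len(isl) == 1
        assert isl[0].start == 1000 and isl[0].end == 1980 + 2
        untrimmed = detect_islands(m, "t")[0]
        assert untrimmed.start <= 1000 and untrimmed.end >= isl[0].end


class TestSweep:
    def test_single_point_grid_matches_detect(self, default_sim):
        m = default_sim["matrix"]
        table = sweep_params(m, "esc", [DetectionParams()])
        assert table.loc[0, "n_islands"] == len(ecgi.detect_islands(m, "esc"))

    def test_relaxing_min_cpgs_is_monotone(self, default_sim):
        m = default_sim["matrix"]
        table = sweep_params(
            m, "esc", [DetectionParams(min_cpgs=5), DetectionParams(min_cpgs=10)]
        )
        assert table.loc[0, "n_islands"] >= table.loc[1, "n_islands"]

    def test_lower_density_recovers_more_planted_islands(self, default_sim):
        # planted islands with < 10 retained CpGs are only callable at min_cpgs=5
        m, truth = default_sim["matrix"], default_sim["truth"]
        auto = default_sim["autosomes"]
        recs = {}
        for k in (5, 10):
            per = ecgi.detect_all(m, DetectionParams(min_cpgs=k), trim="sparse")
            cat = ecgi.merge_catalog(per, tissue_order=m.tissues)
            recs[k] = ecgi.score_recovery(
                cat, truth, matrix=m, min_cpgs=5, chroms=auto
            ).n_recovered
        assert recs[5] >= recs[10]

    def test_invalid_params_are_rejected(self):
        with pytest.raises(ValueError, match="window_bp"):
            DetectionParams(window_bp=10, step_bp=50).validate()
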