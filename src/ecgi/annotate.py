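"""Genomic-context annotation of catalog entries.

Context labels follow the precedence promoter > gene body > downstream >
intergenic, with a strand-aware 3 kb promoter window upstream of each TSS,
a strand-aware 3 kb downstream window past the transcription end, and
"intergenic" meaning more than 3 kb from any gene. Also here: shore/shelf
flank profiles (sequence composition, hypomethylation breadth and entropy in
bins around island anchors), grouped feature-overlap counting (CAGE TSS per
tissue, TF clusters, repeat classes, ...) and gene expression breadth.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .catalog import catalog_tissues, entropy
from .io import SiteMatrix
from .seqfeatures import seq_stats

logger = logging.getLogger(__name__)


@dataclass
class GeneModel:
    """One gene, reduced to its longest transcript.

    ``start``/``end`` are the 0-based half-open transcript span; the TSS is
    ``start`` on the plus strand and ``end`` on the minus strand (boundary
    coordinates, so upstream/downstream windows attach without off-by-one).
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] | None = None

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start


def read_genes_bed12(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    genes = []
    for _, r in df.iterrows():
        start, end = int(r[1]), int(r[2])
        exons = None
        if df.shape[1] >= 12 and not pd.isna(r[10]):
            sizes = [int(x) for x in str(r[10]).rstrip(",").split(",")]
            offs = [int(x) for x in str(r[11]).rstrip(",").split(",")]
            exons = [(start + o, start + o + s) for o, s in zip(offs, sizes)]
        genes.append(GeneModel(str(r[3]), str(r[0]), str(r[5]), start, end, exons))
    return genes


def read_genes_gtf(path) -> list[GeneModel]:
    """Longest transcript per gene from a GTF file (via gffutils)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    best: dict[str, tuple[int, GeneModel]] = {}
    for tx in db.features_of_type("transcript"):
        gene_id = tx.attributes.get("gene_id", [tx.id])[0]
        length = tx.end - tx.start + 1
        exons = [
            (e.start - 1, e.end)
            for e in db.children(tx, featuretype="exon", order_by="start")
        ] or None
        model = GeneModel(gene_id, tx.seqid, tx.strand, tx.start - 1, tx.end, exons)
        if gene_id not in best or length > best[gene_id][0]:
            best[gene_id] = (length, model)
    return [m for _, m in best.values()]


def annotate_context(
    entries: pd.DataFrame,
    genes: Sequence[GeneModel],
    promoter_bp: int = 3000,
    flank_bp: int = 3000,
) -> pd.DataFrame:
    """One context label per entry plus distance to the nearest gene.

    Returns a frame with columns ``label`` (promoter / gene_body /
    downstream / intergenic), ``sublabel`` (exon / intron for gene_body,
    else empty) and ``distance_to_nearest_gene`` (0 when overlapping a
    gene span).
    """
    if not genes:
        raise ValueError("gene list is empty")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    labels, sublabels, dists = [], [], []
    for _, r in entries.iterrows():
        chrom, a, b = r["chrom"], int(r["start"]), int(r["end"])
        glist = by_chrom.get(chrom, [])
        label, sub = "intergenic", ""
        dist = None
        is_prom = is_body = is_down = False
        body_sub = "intron"
        for g in glist:
            if g.strand == "+":
                prom = (g.tss - promoter_bp, g.tss)
                down = (g.tes, g.tes + flank_bp)
            else:
                prom = (g.tss, g.tss + promoter_bp)
                down = (g.tes - flank_bp, g.tes)
            if a < prom[1] and b > prom[0]:
                is_prom = True
            if a < g.end and b > g.start:
                is_body = True
                if g.exons and any(a < ee and b > es for es, ee in g.exons):
                    body_sub = "exon"
            if a < down[1] and b > down[0]:
                is_down = True
            d = 0 if (a < g.end and b > g.start) else max(g.start - b, a - g.end)
            dist = d if dist is None else min(dist, d)
        if is_prom:
            label = "promoter"
        elif is_body:
            label, sub = "gene_body", body_sub
        elif is_down:
            label = "downstream"
        labels.append(label)
        sublabels.append(sub)
        dists.append(dist if dist is not None else -1)
    return pd.DataFrame(
        {
            "label": labels,
            "sublabel": sublabels,
            "distance_to_nearest_gene": dists,
        },
        index=entries.index,
    )


def flank_profile(
    anchors: pd.DataFrame,
    matrix: SiteMatrix,
    genome: Mapping[str, str],
    shore_bp: int = 2000,
    shelf_bp: int = 2000,
    n_bins: int = 10,
    sparse_meth_cutoff: float = 0.2,
    strand: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Binned composition/methylation profile across shelf, shore and island.

    The upstream shelf ``[a-shore-shelf, a-shore)`` and shore ``[a-shore, a)``
    each get ``n_bins`` uniform bins, as does the island body (variable bin
    width). Upstream means genomic left unless a per-anchor strand is given
    (minus-strand anchors flip to the right flank). Per bin and anchor:
    GC content, CpG O/E, hypomethylation breadth (tissues whose mean bin
    methylation is < ``sparse_meth_cutoff``) and its entropy; the returned
    frame averages over anchors, skipping bins without data.
    """
    tissues = matrix.tissues
    T = len(tissues)
    regions = [("shelf", -shore_bp - shelf_bp, -shore_bp), ("shore", -shore_bp, 0)]
    rows = {}
    for region, lo, hi in regions + [("island", 0, 0)]:
        for b in range(n_bins):
            rows[(region, b)] = {"gc": [], "oe": [], "breadth": [], "entropy": []}

    for k, (_, r) in enumerate(anchors.iterrows()):
        chrom, a, b = r["chrom"], int(r["start"]), int(r["end"])
        seq = genome.get(chrom) if isinstance(genome, Mapping) else str(genome[chrom][:])
        if seq is None:
            continue
        clen = len(seq)
        flip = strand is not None and strand[k] == "-"
        pos = matrix.positions(chrom)
        fracs = np.stack([matrix.fractions(t, chrom) for t in tissues]) if T else None

        def bin_edges(region):
            if region == "island":
                return np.linspace(a, b, n_bins + 1)
            lo, hi = (
                (-shore_bp - shelf_bp, -shore_bp)
                if region == "shelf"
                else (-shore_bp, 0)
            )
            if flip:
                return np.linspace(b - hi, b - lo, n_bins + 1)
            return np.linspace(a + lo, a + hi, n_bins + 1)

        for region in ("shelf", "shore", "island"):
            edges = bin_edges(region)
            if flip and region != "island":
                # keep bin 0 = farthest from the island on the upstream side
                edges_pairs = [
                    (edges[n_bins - i - 1], edges[n_bins - i]) for i in range(n_bins)
                ]
            else:
                edges_pairs = [(edges[i], edges[i + 1]) for i in range(n_bins)]
            for bi, (lo_e, hi_e) in enumerate(edges_pairs):
                lo_i, hi_i = int(np.floor(lo_e)), int(np.ceil(hi_e))
                lo_c, hi_c = max(lo_i, 0), min(hi_i, clen)
                if hi_c <= lo_c:
                    if region != "island":
                        logger.debug("anchor %s:%d flank bin truncated", chrom, a)
                    continue
                st = seq_stats(seq[lo_c:hi_c])
                cell = rows[(region, bi)]
                cell["gc"].append(st.gc_content)
                cell["oe"].append(st.cpg_oe)
                i = int(np.searchsorted(pos, lo_c))
                j = int(np.searchsorted(pos, hi_c))
                if j > i and T:
                    means = np.nanmean(fracs[:, i:j], axis=1)
                    breadth = int(np.sum(means < sparse_meth_cutoff))
                    cell["breadth"].append(breadth)
                    cell["entropy"].append(entropy(breadth, T))
    out = []
    for (region, bi), cell in rows.items():
        out.append(
            {
                "region": region,
                "bin": bi,
                "gc": float(np.mean(cell["gc"])) if cell["gc"] else np.nan,
                "cpg_oe": float(np.mean(cell["oe"])) if cell["oe"] else np.nan,
                "mean_breadth": float(np.mean(cell["breadth"])) if cell["breadth"] else np.nan,
                "mean_entropy": float(np.mean(cell["entropy"])) if cell["entropy"] else np.nan,
                "n_anchors": len(cell["gc"]),
            }
        )
    return pd.DataFrame(out)


def count_feature_overlaps(
    entries: pd.DataFrame,
    feature_sets: Mapping[str, pd.DataFrame],
) -> tuple[pd.DataFrame, dict]:
    """Distinct-group overlap counts per entry for each named feature set.

    Each feature frame has columns ``chrom, start, end`` and optionally
    ``group`` (CAGE tissue, TF name, repeat class...; defaults to the set
    name). Returns (per-entry counts frame, summary dict) where the summary
    holds, per set, the fraction of entries with >= 1 overlap and the
    distribution of per-entry distinct-group counts.
    """
    counts = pd.DataFrame(index=entries.index)
    summary: dict[str, dict] = {}
    for name, feats in feature_sets.items():
        trees: dict[str, IntervalTree] = {}
        if len(feats):
            groups = feats["group"] if "group" in feats.columns else pd.Series(name, index=feats.index)
            for (chrom,), grp in feats.groupby(["chrom"]):
                tree = IntervalTree()
                for idx, r in grp.iterrows():
                    if int(r["end"]) > int(r["start"]):
                        tree.addi(int(r["start"]), int(r["end"]), groups.loc[idx])
                trees[str(chrom)] = tree
        vals = []
        for _, r in entries.iterrows():
            tree = trees.get(str(r["chrom"]))
            if tree is None:
                vals.append(0)
                continue
            hits = tree.overlap(int(r["start"]), int(r["end"]))
            vals.append(len({h.data for h in hits}))
        col = np.asarray(vals, dtype=np.int64)
        counts[name] = col
        dist = pd.Series(col).value_counts().sort_index()
        summary[name] = {
            "fraction_with_overlap": float((col > 0).mean()) if len(col) else 0.0,
            "count_distribution": {int(k): int(v) for k, v in dist.items()},
        }
    return counts, summary


def expression_breadth(expression: pd.DataFrame, quantile: float = 0.5) -> pd.Series:
    """Number of tissues per gene with expression strictly above the global
    cutoff (the given quantile over *all* cells; 0.5 = the global median)."""
    if expression.size == 0:
        raise ValueError("empty expression matrix")
    cutoff = float(np.nanquantile(expression.to_numpy(dtype=float), quantile))
    breadth = (expression > cutoff).sum(axis=1)
    if breadth.eq(0).all():
        logger.warning(
            "all expression breadths are zero (ties are not counted as above "
            "the cutoff %g)", cutoff,
        )
    return breadth
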