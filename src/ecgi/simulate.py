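"""Seed-deterministic synthetic multi-tissue methylome generator.

Emulates the data model of a multi-tissue whole-genome bisulfite sequencing
study: a small genome with CpG-depleted background sequence and planted
CpG/GC-rich islands, ten tissues whose methylomes are bimodal (heavily
methylated background, hypomethylated planted islands in the tissues of each
island's pattern), beta-binomial read counts at ~12x depth split over the
two strands of each CpG dyad, common-SNP corrupted sites, low-mappability
gaps, gene models and feature tracks (CAGE TSS per tissue, TF clusters,
chromatin states, repeats, ncRNA). Everything the pipeline consumes can be
generated here, and the planted truth supports recovery scoring.

What this does NOT emulate: read-level artifacts (bisulfite conversion
failure, alignment bias), CpG density autocorrelation of real genomes,
partially methylated domains, or cell-type heterogeneity.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import _intervals
from .detect import islands_to_frame

DEFAULT_TISSUES = (
    "esc", "sperm", "oocyte", "placenta", "liver",
    "lung", "heart", "neuron", "blood", "adrenal",
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic dataset.

    Defaults follow the emulated study design: 10 tissues, mean dyad depth
    12x, background methylation ~0.85 vs ~0.05 inside hypomethylated
    islands, and 200 planted islands split into constitutive (all tissues),
    tissue-specific (one tissue) and shared-subset patterns.
    """

    n_chroms: int = 4
    chrom_bp: int = 350_000
    sex_chrom_bp: int = 100_000          # one chrX to exercise the autosome filter
    background_gc: float = 0.40
    island_gc: float = 0.60
    background_cpg_rate: float = 0.02    # CG starts per bp outside islands
    island_cpg_rate: float = 0.12
    island_len_range: tuple[int, int] = (300, 900)
    n_constitutive: int = 80
    n_tissue_specific: int = 70
    n_shared: int = 50
    min_island_sep: int = 2_000
    meth_background: float = 0.85
    meth_island: float = 0.05
    beta_concentration: float = 30.0     # dispersion of per-site true methylation
    depth_mean: float = 12.0             # Poisson mean per dyad (both strands)
    snp_rate: float = 0.003              # fraction of dyads carrying a SNP
    snp_low_af_fraction: float = 0.2     # SNPs with AF <= 1% (escape the mask)
    lowmap_fraction: float = 0.02
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    seed: int = 0

    @property
    def n_islands(self) -> int:
        return self.n_constitutive + self.n_tissue_specific + self.n_shared

    def validate(self) -> None:
        problems = []
        for name in (
            "background_gc", "island_gc", "meth_background", "meth_island",
            "snp_rate", "lowmap_fraction", "background_cpg_rate", "island_cpg_rate",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                problems.append(f"{name}={v} outside [0, 1]")
        if self.island_cpg_rate <= self.background_cpg_rate:
            problems.append("island_cpg_rate must exceed background_cpg_rate")
        if not self.meth_island < 0.2 < self.meth_background:
            problems.append("need meth_island < 0.2 < meth_background")
        if self.island_len_range[0] > self.island_len_range[1]:
            problems.append("bad island_len_range")
        if self.n_islands > 0 and self.n_chroms < 1:
            problems.append("need at least one autosome")
        approx_need = self.n_islands * (
            self.island_len_range[1] + self.min_island_sep
        )
        have = self.n_chroms * self.chrom_bp + self.sex_chrom_bp
        if approx_need > 0.8 * have:
            problems.append(
                f"islands do not fit: need ~{approx_need} bp of {have} bp genome"
            )
        if problems:
            raise ValueError("invalid SimConfig: " + "; ".join(problems))


@dataclass
class SyntheticTruth:
    """Planted ground truth used for recovery scoring."""

    islands: pd.DataFrame        # chrom start end class pattern n_cpg
    genes: pd.DataFrame          # BED12-style columns
    features: dict[str, pd.DataFrame]
    snps: pd.DataFrame           # chrom pos af
    lowmap: pd.DataFrame         # chrom start end score
    tissues: list[str]

    def island_patterns(self) -> list[set[str]]:
        return [set(p.split(",")) if p else set() for p in self.islands["pattern"]]


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_bases(rng, n, gc) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def _depleted_segment(rng, n, gc, cpg_rate) -> np.ndarray:
    """iid bases with all CG dinucleotides removed, then CGs planted at an
    exact per-bp rate -- gives direct control of CpG density."""
    seg = _random_bases(rng, n, gc)
    if n > 1:
        cg = np.flatnonzero((seg[:-1] == ord("C")) & (seg[1:] == ord("G")))
        seg[cg + 1] = ord("A")  # break the dinucleotide; cannot create a new CG
    if n > 2 and cpg_rate > 0:
        cand = np.flatnonzero(rng.random(n - 1) < cpg_rate)
        if cand.size:
            keep = np.ones(cand.size, dtype=bool)
            keep[1:] = np.diff(cand) > 1
            cand = cand[keep]
            seg[cand] = ord("C")
            seg[cand + 1] = ord("G")
    return seg


def _place_in_segments(rng, free: list[tuple[int, int]], length: int, sep: int):
    """Place one interval of ``length`` inside the free segments, keeping
    ``sep`` bp of clearance; returns (start, updated free list) or None."""
    weights = np.array([max(0, (e - s) - length) for s, e in free], dtype=float)
    if weights.sum() <= 0:
        return None
    k = int(rng.choice(len(free), p=weights / weights.sum()))
    s, e = free[k]
    start = int(rng.integers(s, e - length + 1))
    new = []
    for i, (fs, fe) in enumerate(free):
        if i != k:
            new.append((fs, fe))
            continue
        left = (fs, start - sep)
        right = (start + length + sep, fe)
        for seg in (left, right):
            if seg[1] - seg[0] >= length:
                new.append(seg)
    return start, new


def simulate_genome(config: SimConfig = SimConfig()):
    """Generate the genome and the planted truth. Deterministic given seed.

    Returns ``(genome, truth)`` where genome maps chromosome name -> DNA
    string with elevated GC and CpG density inside planted islands.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tissues = list(config.tissues)
    T = len(tissues)

    chrom_sizes = {f"chr{i + 1}": config.chrom_bp for i in range(config.n_chroms)}
    if config.sex_chrom_bp > 0:
        chrom_sizes["chrX"] = config.sex_chrom_bp
    chroms = list(chrom_sizes)

    # low-mappability intervals first; islands are placed clear of them so
    # that the planted truth stays assessable after the mappability filter
    lowmap_rows = []
    for chrom, clen in chrom_sizes.items():
        target = config.lowmap_fraction * clen
        placed = 0
        tries = 0
        spans = []
        while placed < target and tries < 1000:
            tries += 1
            w = int(rng.integers(500, 2001))
            s = int(rng.integers(0, clen - w))
            if any(s < e2 + 200 and s + w > s2 - 200 for s2, e2 in spans):
                continue
            spans.append((s, s + w))
            placed += w
        for s, e in sorted(spans):
            lowmap_rows.append(
                {"chrom": chrom, "start": s, "end": e,
                 "score": int(rng.integers(0, 50))}
            )
    lowmap = pd.DataFrame(lowmap_rows, columns=["chrom", "start", "end", "score"])

    # island placement: share islands across chromosomes by length
    margin = 5_000
    total_bp = sum(chrom_sizes.values())
    counts = {
        c: int(round(config.n_islands * chrom_sizes[c] / total_bp)) for c in chroms
    }
    # adjust rounding drift on the largest autosome
    drift = config.n_islands - sum(counts.values())
    counts[chroms[0]] += drift

    island_rows = []
    for chrom, clen in chrom_sizes.items():
        free = [(margin, clen - margin)]
        lm = lowmap[lowmap["chrom"] == chrom]
        for _, r in lm.iterrows():
            nxt = []
            for fs, fe in free:
                a, b = int(r["start"]) - 200, int(r["end"]) + 200
                if b <= fs or a >= fe:
                    nxt.append((fs, fe))
                else:
                    if a - fs > 0:
                        nxt.append((fs, a))
                    if fe - b > 0:
                        nxt.append((b, fe))
            free = nxt
        for _ in range(counts[chrom]):
            length = int(rng.integers(*config.island_len_range, endpoint=True))
            placed = _place_in_segments(rng, free, length, config.min_island_sep)
            if placed is None:
                break
            start, free = placed
            island_rows.append({"chrom": chrom, "start": start, "end": start + length})
    islands = (
        pd.DataFrame(island_rows, columns=["chrom", "start", "end"])
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
    )

    # tissue patterns
    order = rng.permutation(len(islands))
    class_of = np.empty(len(islands), dtype=object)
    pat_of = np.empty(len(islands), dtype=object)
    for rank, idx in enumerate(order):
        if rank < min(config.n_constitutive, len(islands)):
            cls, pat = "constitutive", list(tissues)
        elif rank < min(config.n_constitutive + config.n_tissue_specific, len(islands)):
            cls, pat = "tissue_specific", [tissues[rank % T]]
        else:
            k = int(rng.integers(2, T))
            cls = "shared"
            pat = sorted(rng.choice(tissues, size=k, replace=False).tolist())
        class_of[idx] = cls
        pat_of[idx] = ",".join(pat)
    islands["class"] = class_of
    islands["pattern"] = pat_of

    # sequence
    genome: dict[str, str] = {}
    for chrom, clen in chrom_sizes.items():
        seq = _depleted_segment(rng, clen, config.background_gc, config.background_cpg_rate)
        for _, r in islands[islands["chrom"] == chrom].iterrows():
            s, e = int(r["start"]), int(r["end"])
            seq[s:e] = _depleted_segment(
                rng, e - s, config.island_gc, config.island_cpg_rate
            )
            # avoid a chimeric CG across the island boundary
            if s > 0 and seq[s - 1] == ord("C") and seq[s] == ord("G"):
                seq[s - 1] = ord("A")
            if e < clen and seq[e - 1] == ord("C") and seq[e] == ord("G"):
                seq[e] = ord("A")
        genome[chrom] = seq.tobytes().decode("ascii")

    # per-island CpG counts from the realized sequence
    n_cpg = []
    for _, r in islands.iterrows():
        sub = genome[r["chrom"]][int(r["start"]): int(r["end"])]
        n_cpg.append(sub.count("CG"))
    islands["n_cpg"] = n_cpg

    # SNPs over dyads
    snp_rows = []
    for chrom in chroms:
        dyads = _dyad_positions(genome[chrom])
        flag = rng.random(dyads.size) < config.snp_rate
        for pos in dyads[flag]:
            low = rng.random() < config.snp_low_af_fraction
            af = (
                float(rng.uniform(0.001, 0.01))
                if low
                else float(rng.uniform(0.011, 0.5))
            )
            snp_rows.append({"chrom": chrom, "pos": int(pos), "af": af})
    snps = pd.DataFrame(snp_rows, columns=["chrom", "pos", "af"])

    genes = _simulate_genes(rng, islands, chrom_sizes)
    features = _simulate_features(rng, islands, genes, chrom_sizes, tissues)

    truth = SyntheticTruth(
        islands=islands, genes=genes, features=features,
        snps=snps, lowmap=lowmap, tissues=tissues,
    )
    return genome, truth


def _dyad_positions(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))


def _simulate_genes(rng, islands, chrom_sizes) -> pd.DataFrame:
    """Genes anchored at a third of the islands (island in the promoter) plus
    scattered background genes; BED12-style frame."""
    rows = []
    gid = 0
    for _, r in islands.iterrows():
        if rng.random() > 1 / 3:
            continue
        chrom = r["chrom"]
        clen = chrom_sizes[chrom]
        strand = "+" if rng.random() < 0.5 else "-"
        glen = int(rng.integers(2000, 6001))
        if strand == "+":
            tss = int(r["end"]) + int(rng.integers(0, 500))
            start, end = tss, min(tss + glen, clen)
        else:
            tss = int(r["start"]) - int(rng.integers(0, 500))
            start, end = max(tss - glen, 0), tss
        if end - start < 500:
            continue
        rows.append(_gene_row(rng, f"gene_{gid}", chrom, start, end, strand))
        gid += 1
    for chrom, clen in chrom_sizes.items():
        for _ in range(5):
            glen = int(rng.integers(2000, 6001))
            start = int(rng.integers(0, max(clen - glen, 1)))
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append(
                _gene_row(rng, f"gene_{gid}", chrom, start, start + glen, strand)
            )
            gid += 1
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "name", "score", "strand",
            "thick_start", "thick_end", "rgb", "n_exons", "sizes", "offsets",
        ],
    )


def _gene_row(rng, name, chrom, start, end, strand):
    n_ex = int(rng.integers(2, 5))
    glen = end - start
    cuts = np.sort(rng.choice(np.arange(100, glen - 100), size=2 * n_ex - 2, replace=False))
    bounds = np.concatenate([[0], cuts, [glen]])
    sizes, offsets = [], []
    for i in range(0, len(bounds) - 1, 2):
        offsets.append(int(bounds[i]))
        sizes.append(int(bounds[i + 1] - bounds[i]))
    return {
        "chrom": chrom, "start": start, "end": end, "name": name, "score": 0,
        "strand": strand, "thick_start": start, "thick_end": end, "rgb": "0",
        "n_exons": len(sizes),
        "sizes": ",".join(str(s) for s in sizes) + ",",
        "offsets": ",".join(str(o) for o in offsets) + ",",
    }


GENERAL_TFS = ["CREB1", "TAF7", "SP1", "MYC"]
SPECIFIC_TFS = {t: f"TF_{t.upper()}" for t in DEFAULT_TISSUES}


def _simulate_features(rng, islands, genes, chrom_sizes, tissues):
    """Feature tracks mirroring the annotation inputs of the emulated study."""
    cage, tf, states, repeats, ncrna = [], [], [], [], []
    for _, r in islands.iterrows():
        chrom, s, e = r["chrom"], int(r["start"]), int(r["end"])
        pat = r["pattern"].split(",") if r["pattern"] else []
        for t in pat:
            for _ in range(int(rng.integers(1, 3))):
                p = int(rng.integers(s, e))
                cage.append({"chrom": chrom, "start": p, "end": p + 1, "group": t})
        if r["class"] == "constitutive":
            for name in rng.choice(GENERAL_TFS, size=2, replace=False):
                tf.append({"chrom": chrom, "start": s - 50, "end": e + 50, "group": str(name)})
            states.append(
                {"chrom": chrom, "start": s - 100, "end": e + 100, "group": "active_promoter"}
            )
        elif r["class"] == "tissue_specific":
            tf.append(
                {"chrom": chrom, "start": s, "end": e, "group": SPECIFIC_TFS.get(pat[0], "TF_X")}
            )
            states.append(
                {"chrom": chrom, "start": s - 100, "end": e + 100, "group": "strong_enhancer"}
            )
        if rng.random() < 0.15:
            repeats.append(
                {"chrom": chrom, "start": s - 100, "end": s + 100, "group": "Alu"}
            )
    for chrom, clen in chrom_sizes.items():
        for _ in range(20):
            w = int(rng.integers(200, 2000))
            s = int(rng.integers(0, clen - w))
            repeats.append({"chrom": chrom, "start": s, "end": s + w, "group": "L1"})
        for _ in range(10):
            w = int(rng.integers(1000, 5000))
            s = int(rng.integers(0, clen - w))
            states.append({"chrom": chrom, "start": s, "end": s + w, "group": "heterochromatin"})
    for _, g in genes.iterrows():
        states.append(
            {"chrom": g["chrom"], "start": int(g["start"]), "end": int(g["end"]),
             "group": "transcription"}
        )
    # ncRNA near intergenic islands (no gene within 3 kb)
    for chrom, grp in islands.groupby("chrom"):
        gg = genes[genes["chrom"] == chrom]
        for _, r in grp.iterrows():
            s, e = int(r["start"]), int(r["end"])
            near = (
                (gg["start"] < e + 3000) & (gg["end"] > s - 3000)
            ).any() if len(gg) else False
            if not near and rng.random() < 0.5:
                ncrna.append(
                    {"chrom": chrom, "start": s, "end": e + int(rng.integers(0, 2000)),
                     "group": "lincRNA"}
                )
    cols = ["chrom", "start", "end", "group"]
    mk = lambda rows: (
        pd.DataFrame(rows, columns=cols)
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
    )
    return {
        "cage_tss": mk(cage),
        "tf_clusters": mk(tf),
        "chromatin_states": mk(states),
        "repeats": mk(repeats),
        "ncrna": mk(ncrna),
    }


def simulate_methylomes(
    genome: dict[str, str], truth: SyntheticTruth, config: SimConfig = SimConfig()
) -> dict[str, pd.DataFrame]:
    """Per-tissue strand-level methylation counts for every CpG dyad.

    Returns tissue -> frame with columns chrom, pos (0-based C position of
    that strand's cytosine), strand, meth, total. The plus-strand C sits at
    the dyad position, the minus-strand C at position + 1. True per-site
    methylation is beta-distributed around the island or background mean;
    read totals are Poisson(depth/2) per strand and methylated counts
    binomial. SNP-flagged dyads are emitted with calls forced toward zero
    (C->T alleles read as unmethylated C), and dyads in low-mappability
    regions get uniform-random levels (mismapping noise).
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1_000_003)
    tissues = list(config.tissues)
    out: dict[str, list[pd.DataFrame]] = {t: [] for t in tissues}
    conc = config.beta_concentration
    for chrom, seq in genome.items():
        dyads = _dyad_positions(seq)
        if dyads.size == 0:
            continue
        isl = truth.islands[truth.islands["chrom"] == chrom]
        snp_pos = truth.snps.loc[truth.snps["chrom"] == chrom, "pos"].to_numpy()
        is_snp = np.isin(dyads, snp_pos)
        lm = truth.lowmap[truth.lowmap["chrom"] == chrom]
        in_lowmap = np.zeros(dyads.size, dtype=bool)
        if len(lm):
            in_lowmap = _intervals.has_overlap(
                dyads, dyads + 2, lm["start"].to_numpy(), lm["end"].to_numpy()
            )
        pattern_sets = [set(p.split(",")) if p else set() for p in isl["pattern"]]
        for tissue in tissues:
            mu = np.full(dyads.size, config.meth_background)
            for (_, r), pat in zip(isl.iterrows(), pattern_sets):
                if tissue in pat:
                    sel = (dyads >= int(r["start"])) & (dyads < int(r["end"]))
                    mu[sel] = config.meth_island
            if in_lowmap.any():
                mu[in_lowmap] = rng.uniform(0.0, 1.0, int(in_lowmap.sum()))
            mu = np.clip(mu, 1e-3, 1 - 1e-3)
            m = rng.beta(mu * conc, (1 - mu) * conc)
            m[is_snp] = 0.02  # C->T allele: reads appear unmethylated
            n_plus = rng.poisson(config.depth_mean / 2, dyads.size)
            n_minus = rng.poisson(config.depth_mean / 2, dyads.size)
            k_plus = rng.binomial(n_plus, m)
            k_minus = rng.binomial(n_minus, m)
            df = pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": np.concatenate([dyads, dyads + 1]),
                    "strand": ["+"] * dyads.size + ["-"] * dyads.size,
                    "meth": np.concatenate([k_plus, k_minus]),
                    "total": np.concatenate([n_plus, n_minus]),
                }
            ).sort_values("pos", kind="stable")
            out[tissue].append(df)
    return {
        t: pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["chrom", "pos", "strand", "meth", "total"])
        for t, frames in out.items()
    }


# ---------------------------------------------------------------------------
# file output


def write_fasta(genome: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


def write_cx_report(per_strand: pd.DataFrame, path) -> None:
    """Bismark-style cytosine report (CG rows only, 1-based positions)."""
    out = pd.DataFrame(
        {
            "chrom": per_strand["chrom"],
            "pos": per_strand["pos"].astype(np.int64) + 1,
            "strand": per_strand["strand"],
            "meth": per_strand["meth"].astype(np.int64),
            "unmeth": (per_strand["total"] - per_strand["meth"]).astype(np.int64),
            "context": "CG",
            "tri": "CGA",
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def write_snp_vcf(snps: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">\n')
        for chrom in dict.fromkeys(snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, r in snps.iterrows():
            fh.write(
                f"{r['chrom']}\t{int(r['pos']) + 1}\t.\tC\tT\t.\tPASS\tAF={r['af']:.4f}\n"
            )


def write_bed(df: pd.DataFrame, path, cols: Sequence[str] = ("chrom", "start", "end")) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=list(cols))


def write_mappability(lowmap: pd.DataFrame, chrom_sizes: dict[str, int], path) -> None:
    """bedGraph covering the genome: 100 everywhere except low-map intervals."""
    rows = []
    for chrom, clen in chrom_sizes.items():
        cursor = 0
        lm = lowmap[lowmap["chrom"] == chrom].sort_values("start")
        for _, r in lm.iterrows():
            s, e = int(r["start"]), int(r["end"])
            if s > cursor:
                rows.append((chrom, cursor, s, 100))
            rows.append((chrom, s, e, int(r["score"])))
            cursor = e
        if cursor < clen:
            rows.append((chrom, cursor, clen, 100))
    with open(path, "w") as fh:
        for chrom, s, e, sc in rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{sc}\n")


def write_dataset(config: SimConfig, outdir) -> dict:
    """Generate and write a complete dataset; returns a path manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, truth = simulate_genome(config)
    methylomes = simulate_methylomes(genome, truth, config)
    chrom_sizes = {c: len(s) for c, s in genome.items()}

    paths: dict = {"methylomes": {}, "features": {}}
    fasta = outdir / "genome.fa"
    write_fasta(genome, fasta)
    paths["genome_fasta"] = str(fasta)
    for tissue, df in methylomes.items():
        p = outdir / f"{tissue}.cx.txt"
        write_cx_report(df, p)
        paths["methylomes"][tissue] = str(p)
    write_snp_vcf(truth.snps, outdir / "snps.vcf")
    paths["snp_vcf"] = str(outdir / "snps.vcf")
    write_mappability(truth.lowmap, chrom_sizes, outdir / "mappability.bedgraph")
    paths["mappability"] = str(outdir / "mappability.bedgraph")
    truth.genes.to_csv(outdir / "genes.bed12", sep="\t", header=False, index=False)
    paths["genes_bed12"] = str(outdir / "genes.bed12")
    for name, df in truth.features.items():
        p = outdir / f"{name}.bed"
        write_bed(df, p, cols=("chrom", "start", "end", "group"))
        paths["features"][name] = str(p)
    truth.islands.to_csv(outdir / "truth_islands.tsv", sep="\t", index=False)
    paths["truth_islands"] = str(outdir / "truth_islands.tsv")
    with open(outdir / "chrom.sizes", "w") as fh:
        for chrom, clen in chrom_sizes.items():
            fh.write(f"{chrom}\t{clen}\n")
    paths["chrom_sizes"] = str(outdir / "chrom.sizes")
    with open(outdir / "sim_config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=1, sort_keys=True)
    paths["sim_config"] = str(outdir / "sim_config.json")
    return paths


def methylomes_from_strands(strand_frames: dict[str, pd.DataFrame]):
    """Collapse simulate_methylomes output into TissueMethylome objects."""
    from .io import TissueMethylome, collapse_dyads

    out = []
    for tissue, df in strand_frames.items():
        plus = df[df["strand"] == "+"][["chrom", "pos", "meth", "total"]]
        minus = df[df["strand"] == "-"][["chrom", "pos", "meth", "total"]]
        out.append(TissueMethylome(tissue, collapse_dyads(plus, minus)))
    return out


def masks_from_truth(truth: SyntheticTruth, min_af: float = 0.01):
    """MaskSet equivalent to reading the written VCF/mappability files."""
    from .io import MaskSet

    snp = {
        str(c): np.unique(g["pos"].to_numpy())
        for c, g in truth.snps[truth.snps["af"] > min_af].groupby("chrom")
    }
    mapp = {
        str(c): (
            g["start"].to_numpy(),
            g["end"].to_numpy(),
            g["score"].to_numpy(dtype=float),
        )
        for c, g in truth.lowmap.groupby("chrom")
    }
    return MaskSet(snp=snp, mappability=mapp)


# ---------------------------------------------------------------------------
# recovery scoring


@dataclass
class RecoveryResult:
    n_eligible: int
    n_recovered: int
    n_calls: int
    n_true_calls: int
    recall: float
    precision: float
    boundary_mean: float
    boundary_median: float
    boundary_max: float
    pattern_accuracy: float | None


def score_recovery(
    called,
    truth: SyntheticTruth,
    matrix=None,
    min_cpgs: int = 10,
    min_reciprocal: float = 0.5,
    chroms: Sequence[str] | None = None,
) -> RecoveryResult:
    """Score called islands (or a merged catalog) against the planted truth.

    A planted island is recovered iff some call overlaps it reciprocally by
    >= ``min_reciprocal`` of both lengths. Planted islands with fewer than
    ``min_cpgs`` CpGs (retained CpGs, when a site matrix is given) are
    excluded from the recall denominator. Boundary error is the larger
    endpoint deviation of the best-overlapping call. Pattern accuracy (when
    ``called`` is a catalog with presence columns) is the fraction of
    recovered islands whose presence vector equals the planted pattern.
    """
    if isinstance(called, pd.DataFrame):
        calls = called
    else:
        calls = islands_to_frame(list(called))
    tissue_cols = [c for c in calls.columns if c in set(truth.tissues)]

    tr = truth.islands
    if chroms is not None:
        tr = tr[tr["chrom"].isin(set(chroms))]
    tr = tr.reset_index(drop=True)

    if matrix is not None:
        counts = []
        for _, r in tr.iterrows():
            pos = matrix.positions(r["chrom"])
            counts.append(
                int(
                    np.searchsorted(pos, int(r["end"]))
                    - np.searchsorted(pos, int(r["start"]))
                )
            )
        eligible = np.asarray(counts) >= min_cpgs
    else:
        eligible = tr["n_cpg"].to_numpy() >= min_cpgs

    recovered = np.zeros(len(tr), dtype=bool)
    best_call = np.full(len(tr), -1)
    boundary = []
    call_true = np.zeros(len(calls), dtype=bool)
    for ti, r in tr.iterrows():
        cm = calls[calls["chrom"] == r["chrom"]]
        if not len(cm):
            continue
        cs = cm["start"].to_numpy()
        ce = cm["end"].to_numpy()
        s, e = int(r["start"]), int(r["end"])
        ov = np.minimum(ce, e) - np.maximum(cs, s)
        rec = (ov >= min_reciprocal * (e - s)) & (ov >= min_reciprocal * (ce - cs))
        if rec.any():
            call_true[cm.index[rec]] = True
            k = int(np.argmax(np.where(rec, ov, -1)))
            recovered[ti] = True
            best_call[ti] = cm.index[k]
            if eligible[ti]:
                boundary.append(max(abs(int(cs[k]) - s), abs(int(ce[k]) - e)))

    n_eligible = int(eligible.sum())
    n_rec_eligible = int((recovered & eligible).sum())
    recall = n_rec_eligible / n_eligible if n_eligible else 0.0
    precision = float(call_true.mean()) if len(calls) else 0.0

    pattern_accuracy = None
    if tissue_cols:
        correct = 0
        considered = 0
        for ti, r in tr.iterrows():
            if not (recovered[ti] and eligible[ti]):
                continue
            considered += 1
            row = calls.loc[best_call[ti]]
            pres = {t for t in tissue_cols if int(row[t]) == 1}
            if pres == (set(r["pattern"].split(",")) if r["pattern"] else set()):
                correct += 1
        pattern_accuracy = correct / considered if considered else 0.0

    barr = np.asarray(boundary, dtype=float)
    return RecoveryResult(
        n_eligible=n_eligible,
        n_recovered=n_rec_eligible,
        n_calls=len(calls),
        n_true_calls=int(call_true.sum()),
        recall=recall,
        precision=precision,
        boundary_mean=float(barr.mean()) if barr.size else 0.0,
        boundary_median=float(np.median(barr)) if barr.size else 0.0,
        boundary_max=float(barr.max()) if barr.size else 0.0,
        pattern_accuracy=pattern_accuracy,
    )
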