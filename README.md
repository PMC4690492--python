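# ecgi — experimentally defined CpG islands from multi-tissue WGBS

CpG islands were originally an *epigenetic* concept — clusters of CpG
dinucleotides that escape the genome-wide methylation default — but the
island sets in everyday use are predicted from sequence composition alone
and carry substantial false positives (methylated GC-rich exons) and false
negatives (hypomethylated clusters below the GC/O-E thresholds). `ecgi`
implements the experimental alternative for anyone with per-CpG bisulfite
counts from several tissues: call hypomethylated islands directly from the
methylation signal in each tissue, merge them into a cross-tissue catalog,
and characterize each entry by how broadly it is hypomethylated.

## Method

**Site filters.** Fractional methylation at a CpG dyad is
`m = meth_reads / total_reads` after summing both strands. Sites must be
covered by ≥ 5 reads in *every* tissue, lie on an autosome, overlap no
common SNP (> 1% allele frequency) and have a mappability score ≥ 50
(0–100 scale).

**Island calling (per tissue).** A 200 bp window stepping by 50 bp seeds an
island when it contains ≥ 10 retained CpGs of which ≥ 80% are sparsely
methylated (m < 0.2). A qualifying seed extends its right edge step by step
while the enlarged window still satisfies both criteria; maximal extents are
unioned into disjoint islands. Boundaries can optionally be trimmed to the
outermost (hypomethylated) CpG so they follow the local methylation signal
rather than the 50 bp grid.

**Catalog.** Islands overlapping across tissues merge into one entry per
connected component. Each entry carries a 0/1 presence vector over the T
tissues, its *hypomethylation breadth* `b = Σ presence`, and the Shannon
information `−P log₂ P` with `P = b/T`. Breadth T is "constitutive",
breadth 1 "tissue-specific".

**Sequence comparison.** Computational islands are predicted from the
genome with the classical thresholds (length ≥ 200 bp, GC ≥ 0.5, CpG
O/E = n_CpG·L/(n_C·n_G) > 0.6) and cross-classified against the catalog:
validated vs false-positive predictions, shared vs novel catalog entries.

**Annotation and enrichment.** Entries get one context label (promoter =
3 kb upstream of a TSS, then gene body, 3 kb downstream, else intergenic),
shore/shelf composition-and-breadth profiles, and grouped overlap counts
against CAGE TSS, TF-cluster, repeat and ncRNA tracks. Enrichment in a
feature set uses a 1000× length- and count-matched bootstrap
(`fold = observed / mean null`, add-one empirical P) or, for ncRNA overlap,
a 1-df χ² against the mappable-genome expectation.

Everything is testable without external data: `ecgi.simulate` generates a
seed-deterministic genome with planted CpG-rich islands, ten bimodal
methylomes at ~12× depth, SNP-corrupted sites, low-mappability gaps, gene
models and feature tracks, plus the ground truth for recovery scoring.

## Worked example

```python
import ecgi
from ecgi.simulate import SimConfig, masks_from_truth, methylomes_from_strands

cfg = SimConfig(seed=1)                       # 10 tissues, depth 12, 200 islands
genome, truth = ecgi.simulate_genome(cfg)
strands = ecgi.simulate_methylomes(genome, truth, cfg)
matrix = ecgi.build_site_matrix(methylomes_from_strands(strands),
                                masks_from_truth(truth))
print(matrix.filter_stats)
# {'joint_positions': 39800, 'after_coverage': 36869, 'after_autosome': 34556,
#  'after_snp': 34479, 'after_mappability': 33889, 'retained': 33889}

per_tissue = ecgi.detect_all(matrix, trim="sparse")
catalog = ecgi.merge_catalog(per_tissue, tissue_order=matrix.tissues)
rec = ecgi.score_recovery(catalog, truth, matrix=matrix,
                          chroms={c for c in genome if c != "chrX"})
print(len(catalog), rec.recall, rec.precision, round(rec.boundary_mean, 1))
# 187 1.0 1.0 19.9
```

39 800 CpG dyads survive the joint-coverage join, 33 889 the full cascade;
the ten per-tissue island sets merge into 187 catalog entries that recover
every eligible planted island with no false calls, and the called
boundaries sit ~20 bp from the planted ones — less than half a detection
step. The `examples/` scripts walk through each capability (detection,
catalog statistics, sequence concordance, enrichment, full pipeline) with
commented output.

A thin CLI mirrors the stages:

```bash
ecgi simulate --seed 7 --outdir ds --n-tissues 3
ecgi filter --methylome esc=ds/esc.cx.txt:cx-report ... --out matrix.tsv
ecgi detect --matrix matrix.tsv --tissue esc --trim sparse --out-bed esc.bed
ecgi run --config config.yaml --outdir run/      # all stages + manifest
```

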