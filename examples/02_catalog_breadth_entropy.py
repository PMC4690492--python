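"""Merge per-tissue islands into a catalog with breadth and entropy.

Hypomethylation breadth counts the tissues in which a merged entry is
hypomethylated; the Shannon information -P log2 P of P = breadth/T peaks for
entries hypomethylated in an intermediate number of tissues, i.e. the most
tissue-restricted regulatory candidates.
"""
import ecgi
from ecgi.catalog import classify_breadth, saturation_curve
from ecgi.simulate import SimConfig, masks_from_truth, methylomes_from_strands

cfg = SimConfig(seed=11)
genome, truth = ecgi.simulate_genome(cfg)
strands = ecgi.simulate_methylomes(genome, truth, cfg)
matrix = ecgi.build_site_matrix(methylomes_from_strands(strands), masks_from_truth(truth))

per_tissue = ecgi.detect_all(matrix, trim="sparse")
catalog = classify_breadth(ecgi.merge_catalog(per_tissue, tissue_order=matrix.tissues))

n_calls = sum(len(v) for v in per_tissue.values())
print(f"{n_calls} per-tissue islands merged into {len(catalog)} catalog entries")
print("\nbreadth distribution (tissues hypomethylated):")
print(catalog["breadth"].value_counts().sort_index().to_string())
print("\ncategory counts:", catalog["category"].value_counts().to_dict())
# constitutive = hypomethylated in all 10 tissues, tissue_specific = exactly 1

curve = saturation_curve(per_tissue, n_orders=50, seed=0)
print("\ndiscovery saturation (fraction of catalog found after k tissues):")
for k, v in enumerate(curve, 1):
    print(f"  k={k:2d}  {v:.3f}")
# the curve plateaus after a handful of tissues: most constitutive islands
# are found immediately, later tissues mostly add tissue-specific ones
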