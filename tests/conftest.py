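import numpy as np
import pandas as pd
import pytest

import ecgi
from ecgi import io as mio


def make_matrix(positions, fracs, chrom="chr1", denom=20):
    """Build a SiteMatrix directly from per-tissue methylation fractions.

    ``fracs`` maps tissue -> sequence of fractions aligned with positions;
    fractions must be multiples of 1/denom so counts reproduce them exactly.
    ``positions`` may also be a dict chrom -> positions (then fracs values
    are dicts too).
    """
    if not isinstance(positions, dict):
        positions = {chrom: positions}
        fracs = {t: {chrom: v} for t, v in fracs.items()}
    frames = []
    tissues = list(fracs)
    for c, pos in positions.items():
        pos = np.asarray(pos, dtype=np.int64)
        data = {"chrom": c, "pos": pos}
        for t in tissues:
            f = np.asarray(fracs[t][c], dtype=float)
            meth = np.rint(f * denom).astype(np.int64)
            assert np.allclose(meth / denom, f), "fractions must be exact multiples"
            data[f"meth_{t}"] = meth
            data[f"total_{t}"] = denom
        frames.append(pd.DataFrame(data))
    df = pd.concat(frames, ignore_index=True).sort_values(["chrom", "pos"])
    return mio.SiteMatrix(tissues, df.reset_index(drop=True))


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic study: genome, truth, matrix, calls, catalog."""
    cfg = ecgi.SimConfig(seed=1)
    genome, truth = ecgi.simulate_genome(cfg)
    strands = ecgi.simulate_methylomes(genome, truth, cfg)
    methylomes = ecgi.simulate.methylomes_from_strands(strands)
    masks = ecgi.simulate.masks_from_truth(truth)
    matrix = ecgi.build_site_matrix(methylomes, masks)
    per_tissue = ecgi.detect_all(matrix, trim="sparse")
    catalog = ecgi.merge_catalog(per_tissue, tissue_order=matrix.tissues)
    return {
        "config": cfg,
        "genome": genome,
        "truth": truth,
        "strands": strands,
        "methylomes": methylomes,
        "masks": masks,
        "matrix": matrix,
        "per_tissue": per_tissue,
        "catalog": catalog,
        "autosomes": {c for c in genome if c != "chrX"},
    }
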