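"""Cross-tissue island catalog: merging, breadth, entropy, saturation.

Per-tissue islands that overlap across tissues are merged into one catalog
entry per connected component of the overlap graph. Each entry carries a
presence vector over tissues, its hypomethylation breadth (number of tissues
hypomethylated) and the Shannon information -P log2 P of the presence ratio
P = breadth / T.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _intervals
from .detect import Island, islands_to_frame

BASE_COLS = ["chrom", "start", "end", "breadth", "entropy", "source_ids"]


def entropy(breadth, n_tissues: int):
    """Shannon information -P log2 P of P = breadth / n_tissues (bits).

    Defined as 0 at P = 0 (limit) and P = 1. Accepts scalars or arrays.
    """
    if n_tissues < 1:
        raise ValueError("n_tissues must be >= 1")
    b = np.asarray(breadth, dtype=float)
    if np.any(b < 0) or np.any(b > n_tissues):
        raise ValueError("breadth must lie in [0, n_tissues]")
    p = b / n_tissues
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where((p > 0) & (p < 1), -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    # -1*log2(1) is exactly 0, but keep the explicit branch for clarity at p=1
    return float(h) if np.isscalar(breadth) else h


def _tissue_frames(per_tissue, tissue_order):
    if isinstance(per_tissue, Mapping):
        items = list(per_tissue.items())
    else:
        raise TypeError("per_tissue must map tissue_id -> islands")
    frames = {}
    for tissue, islands in items:
        if isinstance(islands, pd.DataFrame):
            df = islands
        else:
            df = islands_to_frame(list(islands))
        frames[tissue] = df[["chrom", "start", "end"]].copy()
    if tissue_order is None:
        tissue_order = list(frames)
    else:
        missing = set(tissue_order) ^ set(frames)
        if missing:
            raise ValueError(f"tissue label mismatch: {sorted(missing)}")
    return frames, list(tissue_order)


def merge_catalog(
    per_tissue: Mapping[str, Sequence[Island] | pd.DataFrame],
    tissue_order: Sequence[str] | None = None,
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Merge per-tissue islands into a disjoint cross-tissue catalog.

    Entries are the connected components of the >= ``min_overlap`` bp overlap
    graph over all tissues' islands. The presence column of tissue ``t`` is 1
    iff some island of ``t`` overlaps the merged entry by >= 1 bp, and
    breadth is the row sum of presences.
    """
    frames, tissues = _tissue_frames(per_tissue, tissue_order)
    T = len(tissues)
    all_int = []
    for ti, tissue in enumerate(tissues):
        df = frames[tissue]
        for chrom, grp in df.groupby("chrom", sort=True):
            all_int.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": grp["start"].to_numpy(),
                        "end": grp["end"].to_numpy(),
                        "tissue_idx": ti,
                        "island_idx": np.arange(len(grp)),
                    }
                )
            )
    cols = BASE_COLS + list(tissues)
    if not all_int:
        return pd.DataFrame(columns=cols)
    allf = pd.concat(all_int, ignore_index=True)
    rows = []
    for chrom in sorted(allf["chrom"].unique()):
        grp = allf[allf["chrom"] == chrom]
        ms, me, groups = _intervals.merge_intervals(
            grp["start"].to_numpy(), grp["end"].to_numpy(), min_overlap=min_overlap
        )
        # presence recomputed against merged entries: an island overlapping
        # two final entries (possible when min_overlap > 1) marks both
        presence = np.zeros((ms.size, T), dtype=np.int64)
        src = [[] for _ in range(ms.size)]
        for (_, r), g in zip(grp.iterrows(), groups):
            src[g].append(f"{tissues[r['tissue_idx']]}:{chrom}:{r['island_idx']}")
        for ti, tissue in enumerate(tissues):
            tg = grp[grp["tissue_idx"] == ti].sort_values("start")
            if len(tg) == 0:
                continue
            hit = _intervals.has_overlap(
                ms, me, tg["start"].to_numpy(), tg["end"].to_numpy()
            )
            presence[:, ti] = hit.astype(np.int64)
        breadth = presence.sum(axis=1)
        ent = entropy(breadth, T)
        for k in range(ms.size):
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(ms[k]),
                    "end": int(me[k]),
                    "breadth": int(breadth[k]),
                    "entropy": float(ent[k]),
                    "source_ids": ",".join(sorted(src[k])),
                    **{t: int(presence[k, ti]) for ti, t in enumerate(tissues)},
                }
            )
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def catalog_tissues(entries: pd.DataFrame) -> list[str]:
    """Tissue (presence) columns of a catalog frame, in order."""
    return [c for c in entries.columns if c not in BASE_COLS and c != "category"]


def merge_adjacent(entries: pd.DataFrame, max_gap: int) -> pd.DataFrame:
    """Fuse catalog entries whose gap is <= ``max_gap`` bp; presence is OR-ed.

    Idempotent: one pass reaches the fixed point because merged entries are
    separated by gaps > max_gap by construction.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    tissues = catalog_tissues(entries)
    T = len(tissues)
    rows = []
    for chrom in sorted(entries["chrom"].unique()):
        grp = entries[entries["chrom"] == chrom].sort_values("start")
        ms, me, groups = _intervals.merge_intervals(
            grp["start"].to_numpy(), grp["end"].to_numpy(), max_gap=max_gap
        )
        pres = np.zeros((ms.size, T), dtype=np.int64)
        src = [[] for _ in range(ms.size)]
        for (_, r), g in zip(grp.iterrows(), groups):
            pres[g] |= r[tissues].to_numpy(dtype=np.int64)
            if r["source_ids"]:
                src[g].extend(str(r["source_ids"]).split(","))
        breadth = pres.sum(axis=1)
        ent = entropy(breadth, T) if T else np.zeros(ms.size)
        for k in range(ms.size):
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(ms[k]),
                    "end": int(me[k]),
                    "breadth": int(breadth[k]),
                    "entropy": float(ent[k]),
                    "source_ids": ",".join(sorted(src[k])),
                    **{t: int(pres[k, ti]) for ti, t in enumerate(tissues)},
                }
            )
    return (
        pd.DataFrame(rows, columns=BASE_COLS + tissues)
        .sort_values(["chrom", "start"], kind="stable")
        .reset_index(drop=True)
    )


def classify_breadth(entries: pd.DataFrame) -> pd.DataFrame:
    """Add a category column: constitutive (breadth == T), tissue_specific
    (breadth == 1) or shared."""
    T = len(catalog_tissues(entries))
    out = entries.copy()
    cat = np.where(
        out["breadth"] == T,
        "constitutive",
        np.where(out["breadth"] == 1, "tissue_specific", "shared"),
    )
    out["category"] = cat
    return out


def saturation_curve(
    per_tissue: Mapping[str, Sequence[Island] | pd.DataFrame],
    n_orders: int = 100,
    seed: int = 0,
    tissue_order: Sequence[str] | None = None,
) -> np.ndarray:
    """Discovery saturation: mean fraction of final catalog entries already
    hit after including k = 1..T tissues, averaged over random orderings.

    Non-decreasing and exactly 1.0 at k = T.
    """
    if n_orders < 1:
        raise ValueError("n_orders must be >= 1")
    cat = merge_catalog(per_tissue, tissue_order=tissue_order)
    tissues = catalog_tissues(cat)
    T = len(tissues)
    if len(cat) == 0:
        return np.ones(T)
    M = cat[tissues].to_numpy(dtype=bool)
    rng = np.random.default_rng(seed)
    curves = np.zeros((n_orders, T))
    for o in range(n_orders):
        order = rng.permutation(T)
        seen = np.zeros(len(cat), dtype=bool)
        for k in range(T):
            seen |= M[:, order[k]]
            curves[o, k] = seen.mean()
    return curves.mean(axis=0)


def catalog_to_bed(entries: pd.DataFrame) -> str:
    lines = []
    for k, r in entries.iterrows():
        lines.append(
            f"{r['chrom']}\t{int(r['start'])}\t{int(r['end'])}\t"
            f"eCGI_{k}\t{int(r['breadth'])}\t."
        )
    return "\n".join(lines) + ("\n" if lines else "")
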