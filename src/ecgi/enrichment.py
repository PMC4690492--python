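"""Interval enrichment: length-matched bootstrap and the χ² overlap test.

The bootstrap null keeps the number and widths of the observed islands and
replaces only their locations, drawn uniformly over the eligible genome
space; fold enrichment is observed statistic / mean null statistic and the
empirical P uses the add-one estimator (1 + #{null >= observed}) / (n + 1).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import _intervals

logger = logging.getLogger(__name__)

STATISTICS = ("bp_overlap", "count_overlapping")


@dataclass
class EnrichmentResult:
    feature_name: str
    statistic: str
    observed: float
    expected_mean: float
    fold: float
    p_upper: float
    p_lower: float
    n_resamples: int


def _eligible_space(genome_space) -> pd.DataFrame:
    """Normalize chrom->length mappings or interval frames to an interval frame."""
    if isinstance(genome_space, pd.DataFrame):
        df = genome_space[["chrom", "start", "end"]].copy()
    else:
        df = pd.DataFrame(
            [{"chrom": c, "start": 0, "end": int(n)} for c, n in genome_space.items()]
        )
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def _union_by_chrom(df: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for chrom, grp in df.groupby("chrom"):
        ms, me, _ = _intervals.merge_intervals(
            grp["start"].to_numpy(), grp["end"].to_numpy(), min_overlap=1
        )
        out[str(chrom)] = (ms, me)
    return out


def _stat(chroms, starts, ends, feat_union, statistic) -> float:
    per = np.zeros(len(starts), dtype=np.int64)
    for chrom in np.unique(chroms):
        m = chroms == chrom
        us_ue = feat_union.get(str(chrom))
        if us_ue is None:
            continue
        per[m] = _intervals.overlap_bp(starts[m], ends[m], us_ue[0], us_ue[1])
    if statistic == "bp_overlap":
        return float(per.sum())
    return float((per > 0).sum())


def bootstrap_enrichment(
    entries: pd.DataFrame,
    features: pd.DataFrame,
    genome_space,
    n: int = 1000,
    seed: int | None = 0,
    statistic: str = "bp_overlap",
    non_overlapping: bool = False,
    feature_name: str = "features",
) -> EnrichmentResult:
    """Length/count-matched bootstrap enrichment of entries in a feature set.

    Each of the ``n`` resamples places ``len(entries)`` intervals with the
    observed widths uniformly over ``genome_space`` (a chrom->length mapping
    or an eligible-interval frame). By default resampled intervals may
    overlap one another; ``non_overlapping`` switches to rejection sampling.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"statistic must be one of {STATISTICS}")
    if len(entries) == 0:
        raise ValueError("entries are empty")
    space = _eligible_space(genome_space)
    widths = (entries["end"] - entries["start"]).to_numpy(dtype=np.int64)
    seg_len = (space["end"] - space["start"]).to_numpy(dtype=np.int64)
    if widths.max() > seg_len.max():
        raise ValueError(
            f"an entry of width {int(widths.max())} exceeds every eligible region"
        )
    if len(features) == 0:
        warnings.warn("empty feature set: fold 0, p 1", stacklevel=2)
        return EnrichmentResult(feature_name, statistic, 0.0, 0.0, 0.0, 1.0, 1.0, n)
    feat_union = _union_by_chrom(features)
    obs = _stat(
        entries["chrom"].to_numpy(),
        entries["start"].to_numpy(np.int64),
        entries["end"].to_numpy(np.int64),
        feat_union,
        statistic,
    )
    rng = np.random.default_rng(seed)
    space_chroms = space["chrom"].to_numpy()
    space_starts = space["start"].to_numpy(np.int64)
    m = len(widths)

    # one uniform draw over all valid (segment, offset) slots per interval;
    # placements are vectorized over resamples, grouped by interval width
    all_starts = np.empty((n, m), dtype=np.int64)
    all_seg = np.empty((n, m), dtype=np.int64)
    for w in np.unique(widths):
        cols = np.flatnonzero(widths == w)
        slots = np.maximum(seg_len - w + 1, 0)
        cum = np.cumsum(slots)
        u = rng.integers(0, cum[-1], size=(n, cols.size))
        si = np.searchsorted(cum, u, side="right")
        offset = u - np.where(si > 0, cum[si - 1], 0)
        all_seg[:, cols] = si
        all_starts[:, cols] = space_starts[si] + offset
    if non_overlapping:
        for b in range(n):
            for k in range(1, m):
                prev = slice(0, k)
                for _ in range(10000):
                    clash = np.any(
                        (all_seg[b, prev] == all_seg[b, k])
                        & (all_starts[b, prev] < all_starts[b, k] + widths[k])
                        & (all_starts[b, prev] + widths[prev] > all_starts[b, k])
                    )
                    if not clash:
                        break
                    w = widths[k]
                    slots = np.maximum(seg_len - w + 1, 0)
                    cum = np.cumsum(slots)
                    u = int(rng.integers(0, cum[-1]))
                    si = int(np.searchsorted(cum, u, side="right"))
                    all_seg[b, k] = si
                    all_starts[b, k] = space_starts[si] + u - (cum[si - 1] if si else 0)
                else:
                    raise RuntimeError("could not place non-overlapping resample")

    flat_chroms = space_chroms[all_seg.ravel()]
    flat_starts = all_starts.ravel()
    flat_ends = flat_starts + np.tile(widths, n)
    per = np.zeros(flat_starts.size, dtype=np.int64)
    for chrom in np.unique(flat_chroms):
        sel = flat_chroms == chrom
        us_ue = feat_union.get(str(chrom))
        if us_ue is None:
            continue
        per[sel] = _intervals.overlap_bp(
            flat_starts[sel], flat_ends[sel], us_ue[0], us_ue[1]
        )
    per = per.reshape(n, m)
    if statistic == "bp_overlap":
        null = per.sum(axis=1).astype(float)
    else:
        null = (per > 0).sum(axis=1).astype(float)
    expected = float(null.mean())
    fold = obs / expected if expected > 0 else (0.0 if obs == 0 else float("inf"))
    p_upper = (1 + int(np.sum(null >= obs))) / (n + 1)
    p_lower = (1 + int(np.sum(null <= obs))) / (n + 1)
    return EnrichmentResult(
        feature_name, statistic, obs, expected, fold, p_upper, p_lower, n
    )


def chisq_overlap_test(
    n_entries: int,
    n_overlapping: int,
    feature_footprint_bp: float,
    autosomal_bp: float,
    mappable_fraction: float = 0.89,
):
    """1-df χ² of observed vs expected overlap counts.

    The expected overlap probability is the feature footprint divided by the
    mappable autosomal genome, p0 = footprint / (mappable_fraction *
    autosomal_bp). Returns (statistic, p_value).
    """
    if not 0 <= n_overlapping <= n_entries:
        raise ValueError("need 0 <= n_overlapping <= n_entries")
    p0 = feature_footprint_bp / (mappable_fraction * autosomal_bp)
    if not 0 < p0 < 1:
        raise ValueError(f"expected overlap proportion p0={p0:g} outside (0, 1)")
    exp_hit = n_entries * p0
    exp_miss = n_entries * (1 - p0)
    stat = (n_overlapping - exp_hit) ** 2 / exp_hit + (
        (n_entries - n_overlapping) - exp_miss
    ) ** 2 / exp_miss
    p = float(sps.chi2.sf(stat, df=1))
    return float(stat), p
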