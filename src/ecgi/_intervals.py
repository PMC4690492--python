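"""Half-open genomic interval primitives shared across the package.

All coordinates are 0-based, half-open ``[start, end)``. Functions operate on
plain numpy arrays for a single chromosome; callers are responsible for
splitting by chromosome.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "merge_intervals",
    "union_length",
    "overlap_bp",
    "has_overlap",
]


def merge_intervals(starts, ends, min_overlap: int = 1, max_gap: int | None = None):
    """Merge intervals into disjoint runs.

    Two intervals fuse when they overlap by at least ``min_overlap`` bp.
    ``min_overlap=0`` additionally fuses book-ended intervals. If ``max_gap``
    is given it overrides ``min_overlap``: intervals separated by a gap of at
    most ``max_gap`` bp fuse.

    Returns ``(mstarts, mends, groups)`` where ``groups[i]`` is the index of
    the merged interval that input interval ``i`` belongs to.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends, np.empty(0, dtype=np.int64)
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    groups_sorted = np.empty(s.size, dtype=np.int64)
    mstarts, mends = [int(s[0])], [int(e[0])]
    groups_sorted[0] = 0
    for i in range(1, s.size):
        if max_gap is not None:
            fuse = int(s[i]) - mends[-1] <= max_gap
        else:
            fuse = mends[-1] - int(s[i]) >= min_overlap
        if fuse:
            mends[-1] = max(mends[-1], int(e[i]))
        else:
            mstarts.append(int(s[i]))
            mends.append(int(e[i]))
        groups_sorted[i] = len(mstarts) - 1
    groups = np.empty(s.size, dtype=np.int64)
    groups[order] = groups_sorted
    return np.asarray(mstarts, dtype=np.int64), np.asarray(mends, dtype=np.int64), groups


def union_length(starts, ends) -> int:
    """Total number of base pairs covered by the union of the intervals."""
    ms, me, _ = merge_intervals(starts, ends, min_overlap=1)
    return int(np.sum(me - ms))


def _coverage_before(x, ustarts, uends, cum):
    """Covered bp strictly left of each coordinate in ``x`` (disjoint sorted union)."""
    x = np.asarray(x, dtype=np.int64)
    idx = np.searchsorted(ustarts, x, side="right")
    base = cum[idx]
    prev = np.maximum(idx - 1, 0)
    # part of the last-started interval that lies right of x
    over = np.clip(uends[prev] - x, 0, uends[prev] - ustarts[prev])
    over = np.where(idx > 0, over, 0)
    return base - over


def overlap_bp(qstarts, qends, ustarts, uends):
    """bp of overlap of each query with a *disjoint, sorted* interval union."""
    qstarts = np.asarray(qstarts, dtype=np.int64)
    qends = np.asarray(qends, dtype=np.int64)
    ustarts = np.asarray(ustarts, dtype=np.int64)
    uends = np.asarray(uends, dtype=np.int64)
    if ustarts.size == 0:
        return np.zeros(qstarts.shape, dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(uends - ustarts)])
    return _coverage_before(qends, ustarts, uends, cum) - _coverage_before(
        qstarts, ustarts, uends, cum
    )


def has_overlap(qstarts, qends, ustarts, uends):
    """Boolean array: does each query overlap the union by >= 1 bp."""
    return overlap_bp(qstarts, qends, ustarts, uends) > 0
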