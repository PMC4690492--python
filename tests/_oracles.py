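"""Independent brute-force reference implementations used only by tests."""
import math


def oracle_islands(positions, fractions, params):
    """Exhaustive seed-and-extend enumeration over one chromosome.

    Pure-python reimplementation: every anchor k*step is tried; qualifying
    seed windows grow one step at a time while the enlarged window still
    qualifies; maximal extents are unioned (book-ended included). Returns a
    list of (start, end) tuples.
    """
    p = [int(x) for x in positions]
    f = [float(x) for x in fractions]
    if not p:
        return []
    step, w = params.step_bp, params.window_bp

    def ok(a, b):
        inside = [ff for pp, ff in zip(p, f) if a <= pp < b]
        n = len(inside)
        if n == 0:
            return False
        n_sparse = sum(1 for x in inside if x == x and x < params.sparse_meth_cutoff)
        return n >= params.min_cpgs and n_sparse / n >= params.min_sparse_fraction

    last = max(p)
    cap = math.ceil((last + 2) / step) * step
    extents = []
    k = 0
    while k * step <= last:
        s = k * step
        e = s + w
        if ok(s, e):
            while e + step <= cap and ok(s, e + step):
                e += step
            extents.append((s, e))
        k += 1
    merged = []
    for s, e in sorted(extents):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def quadratic_group_counts(entries, features_by_group):
    """All-pairs overlap check: per entry, number of groups with >= 1 hit."""
    counts = []
    for chrom, a, b in entries:
        n = 0
        for group, feats in features_by_group.items():
            if any(c == chrom and a < fe and b > fs for c, fs, fe in feats):
                n += 1
        counts.append(n)
    return counts
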