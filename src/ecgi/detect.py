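"""Per-tissue hypomethylated-island calling by seed-and-extend sliding window.

An island is seeded by a fixed-width window (default 200 bp) anchored at
multiples of the step size (default 50 bp) that contains at least
``min_cpgs`` retained CpGs of which at least ``min_sparse_fraction`` are
sparsely methylated (fractional methylation strictly below
``sparse_meth_cutoff``). Each qualifying seed grows its right edge one step
at a time for as long as the *enlarged* window still satisfies both
criteria; left extension emerges from seeds at earlier anchors. All maximal
extents of a tissue are then unioned (overlapping or book-ended) into
disjoint islands.

The stage is deterministic: no randomness, and identical inputs produce
identical output.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import _intervals
from .io import SiteMatrix

DEFAULT_TRIM = "none"
TRIM_MODES = ("none", "cpg", "sparse")


@dataclass(frozen=True)
class DetectionParams:
    """Sliding-window parameters.

    window_bp : seed window width (bp)
    step_bp : anchor spacing and extension increment (bp)
    min_cpgs : minimum retained CpGs inside a (possibly extended) window
    sparse_meth_cutoff : a CpG is "sparse" when its methylation is < this
    min_sparse_fraction : a window qualifies when sparse CpGs / CpGs >= this
    """

    window_bp: int = 200
    step_bp: int = 50
    min_cpgs: int = 10
    sparse_meth_cutoff: float = 0.2
    min_sparse_fraction: float = 0.8

    def validate(self) -> None:
        problems = []
        if not (self.window_bp >= self.step_bp > 0):
            problems.append("require window_bp >= step_bp > 0")
        if not (0 < self.sparse_meth_cutoff < 1):
            problems.append("sparse_meth_cutoff must be in (0, 1)")
        if not (0 < self.min_sparse_fraction < 1):
            problems.append("min_sparse_fraction must be in (0, 1)")
        if self.min_cpgs < 1:
            problems.append("min_cpgs must be >= 1")
        if problems:
            raise ValueError("invalid DetectionParams: " + "; ".join(problems))


@dataclass
class Island:
    """One per-tissue hypomethylated interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    tissue_id: str
    n_cpg: int
    sparse_fraction: float
    mean_meth: float


def qualify_window(positions, fractions, start, end, params: DetectionParams):
    """Evaluate one window. Returns (qualifies, n_cpg, sparse_fraction).

    CpGs are counted by their C position: ``start <= pos < end``. Sites with
    undefined methylation (NaN fraction) count as CpGs but never as sparse.
    """
    positions = np.asarray(positions)
    fractions = np.asarray(fractions, dtype=float)
    i = int(np.searchsorted(positions, start, side="left"))
    j = int(np.searchsorted(positions, end, side="left"))
    n = j - i
    if n == 0:
        return False, 0, 0.0
    f = fractions[i:j]
    n_sparse = int(np.sum(f < params.sparse_meth_cutoff))
    frac = n_sparse / n
    ok = n >= params.min_cpgs and frac >= params.min_sparse_fraction
    return ok, n, frac


def detect_islands(
    matrix: SiteMatrix,
    tissue_id: str,
    params: DetectionParams = DetectionParams(),
    trim: str = DEFAULT_TRIM,
) -> list[Island]:
    """Call hypomethylated islands for one tissue.

    trim : {"none", "cpg", "sparse"}
        "none" reports window-derived coordinates (multiples of step_bp,
        length >= window_bp). "cpg" trims each island to its outermost
        retained CpG; "sparse" trims to the outermost *sparse* CpG, so
        boundaries follow the local methylation signal rather than the
        window grid.
    """
    params.validate()
    if trim not in TRIM_MODES:
        raise ValueError(f"trim must be one of {TRIM_MODES}")
    if tissue_id not in matrix.tissues:
        raise KeyError(f"unknown tissue {tissue_id!r}; have {matrix.tissues}")
    out: list[Island] = []
    w, step = params.window_bp, params.step_bp
    min_n, min_sf = params.min_cpgs, params.min_sparse_fraction
    for chrom in matrix.chroms:
        p = matrix.positions(chrom)
        if p.size == 0:
            continue
        f = matrix.fractions(tissue_id, chrom)
        sparse = f < params.sparse_meth_cutoff  # NaN compares False
        cs = np.concatenate([[0], np.cumsum(sparse)])
        last_pos = int(p[-1])
        # growing past the last dyad adds nothing; cap extents there
        cap = int(math.ceil((last_pos + 2) / step)) * step

        anchors = np.arange(0, last_pos // step + 1, dtype=np.int64) * step
        i0 = np.searchsorted(p, anchors, side="left")
        j0 = np.searchsorted(p, anchors + w, side="left")
        n0 = j0 - i0
        sp0 = cs[j0] - cs[i0]
        with np.errstate(invalid="ignore", divide="ignore"):
            seed_ok = (n0 >= min_n) & (np.where(n0 > 0, sp0 / np.maximum(n0, 1), 0.0) >= min_sf)

        extents: list[tuple[int, int]] = []
        for s in anchors[seed_ok]:
            s = int(s)
            i = int(np.searchsorted(p, s, side="left"))
            e = s + w
            while e + step <= cap:
                j = int(np.searchsorted(p, e + step, side="left"))
                n = j - i
                if n >= min_n and (cs[j] - cs[i]) / n >= min_sf:
                    e += step
                else:
                    break
            extents.append((s, e))
        if not extents:
            continue
        starts = np.array([a for a, _ in extents], dtype=np.int64)
        ends = np.array([b for _, b in extents], dtype=np.int64)
        ms, me, _ = _intervals.merge_intervals(starts, ends, min_overlap=0)
        for a, b in zip(ms, me):
            a, b = int(a), int(b)
            i = int(np.searchsorted(p, a, side="left"))
            j = int(np.searchsorted(p, b, side="left"))
            if trim != "none":
                sel = slice(i, j)
                if trim == "sparse":
                    idx = np.flatnonzero(sparse[sel]) + i
                else:
                    idx = np.arange(i, j)
                if idx.size == 0:
                    continue
                a = int(p[idx[0]])
                b = int(p[idx[-1]]) + 2
                i = int(np.searchsorted(p, a, side="left"))
                j = int(np.searchsorted(p, b, side="left"))
            n = j - i
            n_sparse = int(cs[j] - cs[i])
            mean_meth = float(np.nanmean(f[i:j])) if n else float("nan")
            out.append(
                Island(
                    chrom=chrom,
                    start=a,
                    end=b,
                    tissue_id=tissue_id,
                    n_cpg=n,
                    sparse_fraction=n_sparse / n if n else 0.0,
                    mean_meth=mean_meth,
                )
            )
    return out


def detect_all(
    matrix: SiteMatrix,
    params: DetectionParams = DetectionParams(),
    trim: str = DEFAULT_TRIM,
) -> dict[str, list[Island]]:
    """detect_islands for every tissue in the matrix."""
    return {t: detect_islands(matrix, t, params, trim=trim) for t in matrix.tissues}


def islands_to_frame(islands: list[Island]) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "tissue_id", "n_cpg", "sparse_fraction", "mean_meth"]
    if not islands:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([asdict(i) for i in islands])[cols]


def islands_to_bed(islands: list[Island]) -> str:
    """BED6 text: name = tissue/index, score = round(1000 * sparse_fraction)."""
    lines = []
    for k, isl in enumerate(islands):
        score = int(round(1000 * isl.sparse_fraction))
        lines.append(
            f"{isl.chrom}\t{isl.start}\t{isl.end}\t{isl.tissue_id}_{k}\t{score}\t."
        )
    return "\n".join(lines) + ("\n" if lines else "")


def sweep_params(
    matrix: SiteMatrix,
    tissue_id: str,
    grid: list[DetectionParams],
    trim: str = DEFAULT_TRIM,
) -> pd.DataFrame:
    """Island counts and size statistics across a parameter grid."""
    if not grid:
        raise ValueError("empty parameter grid")
    rows = []
    for params in grid:
        params.validate()
        islands = detect_islands(matrix, tissue_id, params, trim=trim)
        lengths = np.array([i.end - i.start for i in islands], dtype=float)
        rows.append(
            {
                **asdict(params),
                "n_islands": len(islands),
                "total_bp": int(lengths.sum()),
                "len_min": float(lengths.min()) if len(islands) else 0.0,
                "len_median": float(np.median(lengths)) if len(islands) else 0.0,
                "len_max": float(lengths.max()) if len(islands) else 0.0,
            }
        )
    return pd.DataFrame(rows)
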