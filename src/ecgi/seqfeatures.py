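"""Sequence composition and sequence-based CpG-island prediction.

Computational CpG islands (cCGIs) are predicted from the genome sequence
alone with the classical composition thresholds: minimum length 200 bp,
GC content >= 50% and CpG observed/expected ratio strictly above 0.6, where
O/E = (n_CpG * L) / (n_C * n_G). These predictions exist to be compared
against the methylation-defined islands (concordance analysis), not to
replace them.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import _intervals

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeqStats:
    """Composition of one sequence. N bases count toward length but are
    excluded from base and dinucleotide counts."""

    length_bp: int
    n_C: int
    n_G: int
    n_CpG: int

    @property
    def gc_content(self) -> float:
        return (self.n_C + self.n_G) / self.length_bp

    @property
    def cpg_oe(self) -> float:
        denom = self.n_C * self.n_G
        if denom == 0:
            return 0.0
        return self.n_CpG * self.length_bp / denom


def seq_stats(sequence: str) -> SeqStats:
    """Base and overlapping-dinucleotide counts of a DNA string."""
    if len(sequence) == 0:
        raise ValueError("empty sequence")
    s = sequence.upper()
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    n_cpg = int(np.sum(is_c[:-1] & is_g[1:])) if arr.size > 1 else 0
    return SeqStats(len(s), int(is_c.sum()), int(is_g.sum()), n_cpg)


@dataclass(frozen=True)
class CcgiParams:
    min_len: int = 200
    min_gc: float = 0.50   # inclusive ("minimum GC content of 50%")
    min_oe: float = 0.60   # strict ("observed/expected ratio above 0.6")

    def validate(self) -> None:
        if self.min_len <= 0 or not (0 < self.min_gc <= 1) or not (0 < self.min_oe):
            raise ValueError("invalid CcgiParams")


def _chrom_seqs(genome) -> Mapping[str, str]:
    if isinstance(genome, Mapping):
        return genome
    # pyfaidx.Fasta or similar mapping-like object
    return {name: str(genome[name][:]) for name in genome.keys()}


def predict_ccgi(
    genome,
    params: CcgiParams = CcgiParams(),
    mask_repeats: bool = False,
    repeats: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Windowed composition scan for computational CpG islands.

    Every window of ``min_len`` bp (step 1) is tested against the GC and O/E
    thresholds; overlapping qualifying windows are merged, so reported
    intervals are maximal and never shorter than ``min_len``. When
    ``mask_repeats`` is set, soft-masked (lowercase) bases and any intervals
    in ``repeats`` (BED-like frame: chrom/start/end) are treated as N.

    This is a windowed composition scan, not a maximal-segment search; the
    two agree on clearly CpG-rich sequence but can draw different boundaries
    around marginal flanks. An externally produced island BED can be used in
    the concordance analysis instead.
    """
    params.validate()
    rows = []
    for chrom, seq in _chrom_seqs(genome).items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        if mask_repeats:
            lower = (arr >= ord("a")) & (arr <= ord("z"))
            arr[lower] = ord("N")
            if repeats is not None:
                rep = repeats[repeats["chrom"] == chrom]
                for _, r in rep.iterrows():
                    arr[int(r["start"]): int(r["end"])] = ord("N")
        else:
            lower = (arr >= ord("a")) & (arr <= ord("z"))
            arr[lower] -= 32  # uppercase
        w = params.min_len
        if arr.size < w:
            continue
        is_c = (arr == ord("C")).astype(np.int64)
        is_g = (arr == ord("G")).astype(np.int64)
        is_cg = np.zeros(arr.size, dtype=np.int64)
        is_cg[: arr.size - 1] = is_c[:-1] & is_g[1:]
        cum_c = np.concatenate([[0], np.cumsum(is_c)])
        cum_g = np.concatenate([[0], np.cumsum(is_g)])
        cum_cg = np.concatenate([[0], np.cumsum(is_cg)])
        starts = np.arange(0, arr.size - w + 1)
        n_c = cum_c[starts + w] - cum_c[starts]
        n_g = cum_g[starts + w] - cum_g[starts]
        # dinucleotides wholly inside the window: start offsets [i, i+w-1)
        n_cg = cum_cg[starts + w - 1] - cum_cg[starts]
        gc = (n_c + n_g) / w
        denom = n_c * n_g
        with np.errstate(divide="ignore", invalid="ignore"):
            oe = np.where(denom > 0, n_cg * w / np.maximum(denom, 1), 0.0)
        ok = (gc >= params.min_gc) & (oe > params.min_oe)
        if not ok.any():
            continue
        qs = starts[ok]
        ms, me, _ = _intervals.merge_intervals(qs, qs + w, min_overlap=1)
        for a, b in zip(ms, me):
            st = seq_stats(arr[a:b].tobytes().decode("ascii"))
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(a),
                    "end": int(b),
                    "length": int(b - a),
                    "gc": st.gc_content,
                    "oe": st.cpg_oe,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "length", "gc", "oe"])


@dataclass
class ConcordanceResult:
    ccgi_labels: pd.Series       # validated_cCGI | false_positive_cCGI
    ecgi_labels: pd.Series       # shared | novel_eCGI
    summary: dict


def classify_concordance(
    ecgis: pd.DataFrame, ccgis: pd.DataFrame
) -> ConcordanceResult:
    """Cross-classify methylation-defined and sequence-predicted islands.

    A sequence-predicted island is *validated* iff it overlaps (>= 1 bp) at
    least one methylation-defined entry; a methylation-defined entry is
    *novel* iff it overlaps no sequence prediction.
    """
    e_chroms = set(ecgis["chrom"].unique())
    c_chroms = set(ccgis["chrom"].unique())
    if len(ecgis) and len(ccgis) and not (e_chroms & c_chroms):
        raise ValueError(
            "no shared chromosome names between sets; "
            f"only in first: {sorted(e_chroms - c_chroms)}, "
            f"only in second: {sorted(c_chroms - e_chroms)}"
        )
    cc_hit = np.zeros(len(ccgis), dtype=bool)
    ec_hit = np.zeros(len(ecgis), dtype=bool)
    for chrom in sorted(e_chroms | c_chroms):
        em = (ecgis["chrom"] == chrom).to_numpy()
        cm = (ccgis["chrom"] == chrom).to_numpy()
        if not em.any() or not cm.any():
            continue
        e_idx = np.flatnonzero(em)
        c_idx = np.flatnonzero(cm)
        es = ecgis["start"].to_numpy()[e_idx]
        ee = ecgis["end"].to_numpy()[e_idx]
        cs = ccgis["start"].to_numpy()[c_idx]
        ce = ccgis["end"].to_numpy()[c_idx]
        cu_s, cu_e, _ = _intervals.merge_intervals(cs, ce, min_overlap=1)
        eu_s, eu_e, _ = _intervals.merge_intervals(es, ee, min_overlap=1)
        ec_hit[e_idx] = _intervals.has_overlap(es, ee, cu_s, cu_e)
        cc_hit[c_idx] = _intervals.has_overlap(cs, ce, eu_s, eu_e)
    ccgi_labels = pd.Series(
        np.where(cc_hit, "validated_cCGI", "false_positive_cCGI"), index=ccgis.index
    )
    ecgi_labels = pd.Series(
        np.where(ec_hit, "shared", "novel_eCGI"), index=ecgis.index
    )
    n_cc, n_ec = len(ccgis), len(ecgis)
    summary = {
        "n_ccgi": n_cc,
        "n_ecgi": n_ec,
        "n_validated_ccgi": int(cc_hit.sum()),
        "n_false_positive_ccgi": int(n_cc - cc_hit.sum()),
        "n_shared_ecgi": int(ec_hit.sum()),
        "n_novel_ecgi": int(n_ec - ec_hit.sum()),
        "validated_fraction": float(cc_hit.mean()) if n_cc else 0.0,
        "novel_fraction": float(1.0 - ec_hit.mean()) if n_ec else 0.0,
    }
    return ConcordanceResult(ccgi_labels, ecgi_labels, summary)
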