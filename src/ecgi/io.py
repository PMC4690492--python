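"""Methylome parsing, dyad collapsing and site-level filtering.

Whole-genome bisulfite sequencing yields, per cytosine, a methylated-read
count and a total-read count; fractional methylation is their ratio. This
module reads per-tissue count tables in the common dialects, collapses the
two strands of each CpG dyad onto the plus-strand C position, and applies
the site-level filter cascade (coverage in every tissue, autosomes only,
common-SNP mask, mappability threshold) that precedes island calling.

Internally every coordinate is 0-based half-open; 1-based dialects are
converted at the file boundary.
"""
from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from functools import reduce
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FORMATS = ("bismark-cov", "bedgraph-cov", "cx-report")

_SEX_MITO = re.compile(r"(chr)?(X|Y|M|MT|W|Z)$", re.IGNORECASE)


def infer_autosomes(chroms: Iterable[str]) -> set[str]:
    """Chromosome names that do not look like sex or organellar chromosomes."""
    return {c for c in chroms if not _SEX_MITO.match(c)}


@dataclass
class TissueMethylome:
    """Per-CpG methylation counts for one tissue.

    ``sites`` has columns ``chrom, pos, meth, total`` with ``pos`` the 0-based
    plus-strand C position of the dyad, sorted by (chrom, pos), unique.
    """

    tissue_id: str
    sites: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.sites.reset_index(drop=True)
        if not set(["chrom", "pos", "meth", "total"]).issubset(df.columns):
            raise ValueError("sites must have columns chrom, pos, meth, total")
        if (df["meth"] > df["total"]).any():
            bad = df.loc[df["meth"] > df["total"]].iloc[0]
            raise ValueError(
                f"meth_reads > total_reads at {bad['chrom']}:{int(bad['pos'])}"
            )
        if (df["pos"] < 0).any():
            raise ValueError("negative position")
        df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
        dup = df.duplicated(["chrom", "pos"])
        if dup.any():
            bad = df.loc[dup].iloc[0]
            raise ValueError(f"duplicate position {bad['chrom']}:{int(bad['pos'])}")
        self.sites = df

    def __len__(self) -> int:
        return len(self.sites)


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        if "w" in mode:
            # mtime=0 keeps written .gz files byte-reproducible
            return gzip.GzipFile(path, "wb", mtime=0)
        return gzip.open(path, mode)
    return open(path, mode)


def _read_table(path, n_cols_min):
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
    if df.shape[1] < n_cols_min:
        raise ValueError(
            f"{path}: expected at least {n_cols_min} tab-separated columns, "
            f"found {df.shape[1]}"
        )
    return df


def _to_int(df, col, path, what):
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ValueError(f"{path}: malformed {what} on line {line}")
    return vals.astype(np.int64)


def read_methylome(
    path,
    format: str = "bismark-cov",
    tissue_id: str | None = None,
    collapse: bool = True,
) -> TissueMethylome:
    """Read a per-tissue methylation count table.

    Dialects
    --------
    ``bismark-cov``
        chrom, start(1-based), end(1-based), %methylation, count_meth,
        count_unmeth. Records are assumed dyad-collapsed already.
    ``bedgraph-cov``
        chrom, start(0-based), end, %methylation, count_meth, count_unmeth.
    ``cx-report``
        chrom, pos(1-based), strand, count_meth, count_unmeth, context,
        trinucleotide. Only CG context rows are used; the two strands of each
        dyad are summed onto the plus-strand C position unless
        ``collapse=False`` (then minus-strand records keep their own C
        position).
    """
    if format not in FORMATS:
        raise ValueError(f"unknown methylome format {format!r}; one of {FORMATS}")
    tissue_id = tissue_id or str(path)
    raw = _read_table(path, 6 if format != "cx-report" else 7)
    if raw.empty:
        empty = pd.DataFrame(
            {"chrom": pd.Series(dtype=str)}
            | {c: pd.Series(dtype=np.int64) for c in ("pos", "meth", "total")}
        )
        return TissueMethylome(tissue_id, empty)
    if format in ("bismark-cov", "bedgraph-cov"):
        start = _to_int(raw, 1, path, "start coordinate")
        meth = _to_int(raw, 4, path, "methylated count")
        unmeth = _to_int(raw, 5, path, "unmethylated count")
        pos = start - 1 if format == "bismark-cov" else start
        df = pd.DataFrame(
            {"chrom": raw[0], "pos": pos, "meth": meth, "total": meth + unmeth}
        )
        return TissueMethylome(tissue_id, df)
    # cx-report
    pos1 = _to_int(raw, 1, path, "position")
    meth = _to_int(raw, 3, path, "methylated count")
    unmeth = _to_int(raw, 4, path, "unmethylated count")
    keep = raw[5].str.upper().eq("CG").to_numpy()
    df = pd.DataFrame(
        {
            "chrom": raw[0],
            "pos": pos1 - 1,
            "strand": raw[2],
            "meth": meth,
            "total": meth + unmeth,
        }
    ).loc[keep]
    plus = df[df["strand"] == "+"].drop(columns="strand")
    minus = df[df["strand"] == "-"].drop(columns="strand")
    if collapse:
        out = collapse_dyads(plus, minus)
    else:
        out = pd.concat([plus, minus], ignore_index=True)
    return TissueMethylome(tissue_id, out)


def write_methylome(meth: TissueMethylome, path, format: str = "bismark-cov") -> None:
    """Write counts back out in ``bismark-cov`` or ``bedgraph-cov`` dialect."""
    if format not in ("bismark-cov", "bedgraph-cov"):
        raise ValueError(f"cannot write format {format!r}")
    df = meth.sites
    total = df["total"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * df["meth"].to_numpy() / total, 0.0)
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["pos"] + (1 if format == "bismark-cov" else 0),
            "end": df["pos"] + 1,
            "pct": pct,
            "meth": df["meth"],
            "unmeth": df["total"] - df["meth"],
        }
    )
    with _open_text(path, "wt") as fh:
        out.to_csv(fh, sep="\t", header=False, index=False, float_format="%.6g")


def collapse_dyads(plus: pd.DataFrame, minus: pd.DataFrame) -> pd.DataFrame:
    """Sum the two strands of each CpG dyad onto the plus-strand C position.

    Minus-strand records sit at plus-position + 1; a minus-strand record with
    no plus-strand partner still anchors at its position − 1 (its dyad's C
    position on the reference). Total read counts are conserved.
    """
    cols = ["chrom", "pos", "meth", "total"]
    p = plus[cols].copy() if len(plus) else pd.DataFrame(columns=cols)
    m = minus[cols].copy() if len(minus) else pd.DataFrame(columns=cols)
    if len(m):
        m["pos"] = m["pos"] - 1
    both = pd.concat([p, m], ignore_index=True)
    if both.empty:
        return both
    out = (
        both.groupby(["chrom", "pos"], as_index=False, sort=True)[["meth", "total"]]
        .sum()
        .astype({"pos": np.int64, "meth": np.int64, "total": np.int64})
    )
    return out[cols]


# ---------------------------------------------------------------------------
# masks


@dataclass
class MaskSet:
    """Positions to exclude: common SNPs and low-mappability regions.

    ``snp`` maps chromosome -> sorted array of masked positions (0-based).
    ``mappability`` maps chromosome -> (starts, ends, scores) on the 0-100
    scale; positions not covered by the track get ``default_mappability``.
    """

    snp: dict[str, np.ndarray] = field(default_factory=dict)
    mappability: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )
    default_mappability: float = 100.0

    def snp_hit(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """True where the dyad at ``pos`` (C at pos, G at pos+1) hits a SNP."""
        snps = self.snp.get(chrom)
        if snps is None or snps.size == 0:
            return np.zeros(len(pos), dtype=bool)
        pos = np.asarray(pos, dtype=np.int64)
        hit_c = snps[np.clip(np.searchsorted(snps, pos), 0, snps.size - 1)] == pos
        g = pos + 1
        hit_g = snps[np.clip(np.searchsorted(snps, g), 0, snps.size - 1)] == g
        return hit_c | hit_g

    def mappability_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        track = self.mappability.get(chrom)
        pos = np.asarray(pos, dtype=np.int64)
        if track is None:
            return np.full(len(pos), self.default_mappability)
        starts, ends, scores = track
        idx = np.searchsorted(starts, pos, side="right") - 1
        idx_c = np.clip(idx, 0, starts.size - 1)
        inside = (idx >= 0) & (pos < ends[idx_c])
        return np.where(inside, scores[idx_c], self.default_mappability)


def read_snp_vcf(path, min_af: float = 0.01) -> dict[str, np.ndarray]:
    """Masked positions from a VCF: biallelic records with INFO/AF > min_af."""
    from cyvcf2 import VCF

    out: dict[str, list[int]] = {}
    for v in VCF(str(path)):
        if len(v.ALT) != 1:
            continue
        af = v.INFO.get("AF")
        if af is None:
            continue
        if isinstance(af, (tuple, list)):
            af = af[0]
        if float(af) > min_af:
            out.setdefault(v.CHROM, []).append(v.POS - 1)
    return {c: np.unique(np.asarray(p, dtype=np.int64)) for c, p in out.items()}


def read_snp_bed(path) -> dict[str, np.ndarray]:
    df = _read_table(path, 2)
    if df.empty:
        return {}
    starts = _to_int(df, 1, path, "start")
    out = {}
    for chrom, grp in pd.DataFrame({"chrom": df[0], "pos": starts}).groupby("chrom"):
        out[str(chrom)] = np.unique(grp["pos"].to_numpy())
    return out


def read_mappability_bedgraph(path) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    df = _read_table(path, 4)
    if df.empty:
        return {}
    starts = _to_int(df, 1, path, "start")
    ends = _to_int(df, 2, path, "end")
    scores = pd.to_numeric(df[3], errors="coerce")
    if scores.isna().any():
        raise ValueError(f"{path}: non-numeric mappability score")
    out = {}
    tab = pd.DataFrame(
        {"chrom": df[0], "start": starts, "end": ends, "score": scores.astype(float)}
    )
    for chrom, grp in tab.groupby("chrom"):
        grp = grp.sort_values("start")
        out[str(chrom)] = (
            grp["start"].to_numpy(),
            grp["end"].to_numpy(),
            grp["score"].to_numpy(),
        )
    return out


# ---------------------------------------------------------------------------
# site matrix


@dataclass
class SiteMatrix:
    """Joint positions x tissues count table after all site-level filters.

    ``sites`` has columns ``chrom, pos`` plus ``meth_<t>`` / ``total_<t>``
    for every tissue ``t``, sorted by (chrom, pos).
    ``filter_stats`` records the size of the cascade at each step.
    """

    tissues: list[str]
    sites: pd.DataFrame
    filter_stats: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.sites["chrom"]))

    def positions(self, chrom: str) -> np.ndarray:
        return self.sites.loc[self.sites["chrom"] == chrom, "pos"].to_numpy()

    def fractions(self, tissue: str, chrom: str | None = None) -> np.ndarray:
        """Fractional methylation for one tissue (NaN where total is 0)."""
        if tissue not in self.tissues:
            raise KeyError(f"unknown tissue {tissue!r}; have {self.tissues}")
        df = self.sites if chrom is None else self.sites[self.sites["chrom"] == chrom]
        total = df[f"total_{tissue}"].to_numpy(dtype=float)
        meth = df[f"meth_{tissue}"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, meth / total, np.nan)

    def write_tsv(self, path) -> None:
        with _open_text(path, "wt") as fh:
            self.sites.to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "SiteMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        tissues = [c[len("meth_"):] for c in df.columns if c.startswith("meth_")]
        return cls(tissues, df)


def build_site_matrix(
    methylomes: Sequence[TissueMethylome],
    masks: MaskSet | None = None,
    min_coverage: int = 5,
    min_mappability: float = 50.0,
    autosomes: set[str] | None = None,
) -> SiteMatrix:
    """Intersect tissues and apply the site-level filter cascade.

    A position is retained iff it is present in every tissue with
    ``total >= min_coverage``, lies on an autosome, its dyad overlaps no
    masked SNP, and its mappability score is ``>= min_mappability``. The four
    predicates are per-position and independent, so the cascade is
    order-independent.
    """
    if not methylomes:
        raise ValueError("need at least one methylome")
    tissues = [m.tissue_id for m in methylomes]
    if len(set(tissues)) != len(tissues):
        raise ValueError("duplicate tissue ids")
    frames = []
    for m in methylomes:
        df = m.sites.rename(
            columns={"meth": f"meth_{m.tissue_id}", "total": f"total_{m.tissue_id}"}
        )
        frames.append(df)
    joint = reduce(
        lambda a, b: a.merge(b, on=["chrom", "pos"], how="inner"), frames
    ).sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    stats = {"joint_positions": len(joint)}

    totals = joint[[f"total_{t}" for t in tissues]].to_numpy()
    keep = (totals >= min_coverage).all(axis=1)
    stats["after_coverage"] = int(keep.sum())

    if autosomes is None:
        autosomes = infer_autosomes(joint["chrom"].unique())
    keep &= joint["chrom"].isin(autosomes).to_numpy()
    stats["after_autosome"] = int(keep.sum())

    if masks is not None:
        snp_hit = np.zeros(len(joint), dtype=bool)
        mapp = np.full(len(joint), masks.default_mappability)
        for chrom, grp in joint.groupby("chrom", sort=False):
            idx = grp.index.to_numpy()
            pos = grp["pos"].to_numpy()
            snp_hit[idx] = masks.snp_hit(str(chrom), pos)
            mapp[idx] = masks.mappability_at(str(chrom), pos)
        keep &= ~snp_hit
        stats["after_snp"] = int(keep.sum())
        keep &= mapp >= min_mappability
        stats["after_mappability"] = int(keep.sum())

    out = joint.loc[keep].reset_index(drop=True)
    stats["retained"] = len(out)
    if len(out) == 0:
        logger.warning("site filter cascade retained zero positions")
    return SiteMatrix(tissues, out, stats)
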