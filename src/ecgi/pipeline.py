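"""Pipeline orchestration: stages, run manifest, checksum-based caching.

Stages run in order: simulate (optional) -> filter -> detect per tissue ->
merge -> predict cCGI + concordance -> annotate -> enrich -> score (when a
planted truth is available). Every stage records its parameters, input
checksums and output checksums in ``manifest.json``; re-running with
identical inputs skips completed stages and reproduces identical outputs.
The manifest stores paths relative to the run directory and no wall-clock
data, so two runs from the same seed are byte-identical.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import annotate as ann
from . import catalog as cat
from . import detect as det
from . import enrichment as enr
from . import io as mio
from . import seqfeatures as sf
from . import simulate as sim

logger = logging.getLogger(__name__)

EXIT_OK, EXIT_VALIDATION, EXIT_RUNTIME = 0, 1, 2


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping")
    return config


def _count_rows(path: Path) -> int:
    try:
        with open(path) as fh:
            return sum(1 for _ in fh)
    except UnicodeDecodeError:
        return -1


class Runner:
    """Executes pipeline stages under a run directory with a manifest."""

    def __init__(self, config: dict, outdir):
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.outdir / "manifest.json"
        self.manifest = {
            "version": __version__,
            "config": config,
            "stages": {},
        }
        self._old = {}
        if self.manifest_path.exists():
            with open(self.manifest_path) as fh:
                self._old = json.load(fh).get("stages", {})

    def _rel(self, path: Path) -> str:
        return str(Path(path).relative_to(self.outdir))

    def _stage_key(self, name, params, inputs):
        blob = json.dumps(
            {"params": params, "inputs": {str(k): _sha256(Path(v)) for k, v in inputs.items()}},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()

    def cached(self, name, params, inputs) -> bool:
        old = self._old.get(name)
        if not old:
            return False
        key = self._stage_key(name, params, inputs)
        if old.get("key") != key:
            return False
        for rel, meta in old.get("outputs", {}).items():
            p = self.outdir / rel
            if not p.exists() or _sha256(p) != meta["sha256"]:
                return False
        self.manifest["stages"][name] = old
        logger.info("stage %s: cached, skipping", name)
        return True

    def record(self, name, params, inputs, outputs):
        self.manifest["stages"][name] = {
            "key": self._stage_key(name, params, inputs),
            "params": params,
            "outputs": {
                self._rel(p): {"sha256": _sha256(Path(p)), "n_rows": _count_rows(Path(p))}
                for p in outputs
            },
        }
        self._write_manifest()

    def mark_failed(self, name, error):
        self.manifest["stages"][name] = {"failed": True, "error": str(error)}
        self._write_manifest()

    def _write_manifest(self):
        tmp = self.manifest_path.with_suffix(".json.tmp")
        with open(tmp, "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True, default=str)
            fh.write("\n")
        tmp.replace(self.manifest_path)


def run_pipeline(config, outdir, force: bool = False) -> dict:
    """Run all configured stages; returns the manifest dict."""
    cfg = load_config(config)
    runner = Runner(cfg, outdir)
    if force:
        runner._old = {}
    out = Path(outdir)

    # ----- simulate -------------------------------------------------------
    inputs = dict(cfg.get("inputs", {}))
    truth = None
    sim_cfg = None
    if "simulate" in cfg:
        sim_params = dict(cfg["simulate"])
        if "tissues" in sim_params:
            sim_params["tissues"] = tuple(sim_params["tissues"])
        if "island_len_range" in sim_params:
            sim_params["island_len_range"] = tuple(sim_params["island_len_range"])
        sim_cfg = sim.SimConfig(**sim_params)
        sim_dir = out / "inputs"
        marker = sim_dir / "sim_config.json"
        if not (runner._old.get("simulate") and marker.exists()
                and runner._old["simulate"].get("params") == asdict(sim_cfg)):
            paths = sim.write_dataset(sim_cfg, sim_dir)
            runner.manifest["stages"]["simulate"] = {"params": asdict(sim_cfg)}
            runner._write_manifest()
        else:
            runner.manifest["stages"]["simulate"] = runner._old["simulate"]
        inputs = {
            "genome_fasta": str(sim_dir / "genome.fa"),
            "snp_vcf": str(sim_dir / "snps.vcf"),
            "mappability": str(sim_dir / "mappability.bedgraph"),
            "genes_bed12": str(sim_dir / "genes.bed12"),
            "chrom_sizes": str(sim_dir / "chrom.sizes"),
            "truth_islands": str(sim_dir / "truth_islands.tsv"),
            "methylomes": {
                t: {"path": str(sim_dir / f"{t}.cx.txt"), "format": "cx-report"}
                for t in sim_cfg.tissues
            },
            "features": {
                n: str(sim_dir / f"{n}.bed")
                for n in ("cage_tss", "tf_clusters", "chromatin_states", "repeats", "ncrna")
            },
        }
    if not inputs.get("methylomes"):
        raise ValueError("no methylomes configured (inputs.methylomes or simulate)")
    for t, spec in inputs["methylomes"].items():
        if not Path(spec["path"]).exists():
            raise FileNotFoundError(f"methylome for {t}: {spec['path']}")

    # ----- filter ---------------------------------------------------------
    fcfg = dict(cfg.get("filter", {}))
    min_cov = int(fcfg.get("min_coverage", 5))
    min_af = float(fcfg.get("min_af", 0.01))
    min_map = float(fcfg.get("min_mappability", 50))
    autosomes = set(fcfg["autosomes"]) if "autosomes" in fcfg else None
    matrix_path = out / "site_matrix.tsv"
    stage_inputs = {t: s["path"] for t, s in inputs["methylomes"].items()}
    if "snp_vcf" in inputs:
        stage_inputs["snp_vcf"] = inputs["snp_vcf"]
    if "mappability" in inputs:
        stage_inputs["mappability"] = inputs["mappability"]
    if runner.cached("filter", fcfg, stage_inputs) and matrix_path.exists():
        matrix = mio.SiteMatrix.read_tsv(matrix_path)
    else:
        methylomes = [
            mio.read_methylome(s["path"], s.get("format", "bismark-cov"), tissue_id=t)
            for t, s in inputs["methylomes"].items()
        ]
        masks = mio.MaskSet(
            snp=mio.read_snp_vcf(inputs["snp_vcf"], min_af=min_af)
            if "snp_vcf" in inputs else {},
            mappability=mio.read_mappability_bedgraph(inputs["mappability"])
            if "mappability" in inputs else {},
        )
        matrix = mio.build_site_matrix(
            methylomes, masks, min_coverage=min_cov,
            min_mappability=min_map, autosomes=autosomes,
        )
        for step, count in matrix.filter_stats.items():
            logger.info("filter cascade %s: %d sites", step, count)
        matrix.write_tsv(matrix_path)
        runner.record("filter", {**fcfg, "cascade": matrix.filter_stats},
                      stage_inputs, [matrix_path])

    # ----- detect ---------------------------------------------------------
    dcfg = dict(cfg.get("detect", {}))
    trim = dcfg.pop("trim", "sparse")
    params = det.DetectionParams(**{k: v for k, v in dcfg.items()})
    det_dir = out / "islands"
    det_dir.mkdir(exist_ok=True)
    per_tissue = {}
    det_outputs = []
    for tissue in matrix.tissues:
        islands = det.detect_islands(matrix, tissue, params, trim=trim)
        per_tissue[tissue] = islands
        bed = det_dir / f"{tissue}.bed"
        bed.write_text(det.islands_to_bed(islands))
        tsv = det_dir / f"{tissue}.tsv"
        det.islands_to_frame(islands).to_csv(
            tsv, sep="\t", index=False, float_format="%.6g"
        )
        det_outputs += [bed, tsv]
        logger.info("detect %s: %d islands", tissue, len(islands))
    runner.record("detect", {**dcfg, "trim": trim}, {"site_matrix": matrix_path},
                  det_outputs)

    # ----- merge ----------------------------------------------------------
    ccfg = dict(cfg.get("catalog", {}))
    entries = cat.merge_catalog(
        per_tissue, tissue_order=matrix.tissues,
        min_overlap=int(ccfg.get("min_overlap", 1)),
    )
    if ccfg.get("max_gap") is not None:
        entries = cat.merge_adjacent(entries, int(ccfg["max_gap"]))
    entries = cat.classify_breadth(entries)
    catalog_tsv = out / "catalog.tsv"
    entries.to_csv(catalog_tsv, sep="\t", index=False, float_format="%.6g")
    (out / "catalog.bed").write_text(cat.catalog_to_bed(entries))
    runner.record("merge", ccfg, {"site_matrix": matrix_path},
                  [catalog_tsv, out / "catalog.bed"])

    # ----- ccgi + concordance --------------------------------------------
    results = {"catalog": entries, "matrix": matrix, "per_tissue": per_tissue}
    if "genome_fasta" in inputs:
        gcfg = dict(cfg.get("ccgi", {}))
        genome = _read_fasta(inputs["genome_fasta"])
        ccgi_params = sf.CcgiParams(
            min_len=int(gcfg.get("min_len", 200)),
            min_gc=float(gcfg.get("min_gc", 0.50)),
            min_oe=float(gcfg.get("min_oe", 0.60)),
        )
        auto = autosomes or mio.infer_autosomes(genome)
        ccgis = sf.predict_ccgi(
            {c: s for c, s in genome.items() if c in auto}, ccgi_params,
            mask_repeats=bool(gcfg.get("mask_repeats", False)),
        )
        ccgis.to_csv(out / "ccgi.tsv", sep="\t", index=False, float_format="%.6g")
        conc = sf.classify_concordance(entries, ccgis)
        with open(out / "concordance.json", "w") as fh:
            json.dump(conc.summary, fh, indent=1, sort_keys=True)
            fh.write("\n")
        runner.record("ccgi", gcfg, {"genome": inputs["genome_fasta"]},
                      [out / "ccgi.tsv", out / "concordance.json"])
        results["ccgis"] = ccgis
        results["concordance"] = conc

    # ----- annotate -------------------------------------------------------
    if "genes_bed12" in inputs:
        acfg = dict(cfg.get("annotate", {}))
        genes = ann.read_genes_bed12(inputs["genes_bed12"])
        ctx = ann.annotate_context(
            entries, genes,
            promoter_bp=int(acfg.get("promoter_bp", 3000)),
            flank_bp=int(acfg.get("flank_bp", 3000)),
        )
        annotated = pd.concat([entries, ctx], axis=1)
        feats = {}
        for name, p in inputs.get("features", {}).items():
            feats[name] = pd.read_csv(
                p, sep="\t", header=None,
                names=["chrom", "start", "end", "group"], dtype={"chrom": str},
            )
        if feats:
            counts, summary = ann.count_feature_overlaps(entries, feats)
            annotated = pd.concat([annotated, counts.add_prefix("n_")], axis=1)
            with open(out / "feature_overlap_summary.json", "w") as fh:
                json.dump(summary, fh, indent=1, sort_keys=True)
                fh.write("\n")
        annotated.to_csv(out / "catalog_annotated.tsv", sep="\t", index=False,
                         float_format="%.6g")
        runner.record("annotate", acfg, {"genes": inputs["genes_bed12"]},
                      [out / "catalog_annotated.tsv"])
        results["annotated"] = annotated
        results["features"] = feats

    # ----- enrich ---------------------------------------------------------
    ecfg = dict(cfg.get("enrich", {}))
    if ecfg.get("run", True) and "chrom_sizes" in inputs and results.get("features"):
        sizes = {}
        with open(inputs["chrom_sizes"]) as fh:
            for line in fh:
                c, n = line.split()
                sizes[c] = int(n)
        auto = autosomes or mio.infer_autosomes(sizes)
        sizes = {c: n for c, n in sizes.items() if c in auto}
        n_res = int(ecfg.get("n_resamples", 1000))
        seed = int(cfg.get("seed", 0))
        rows = []
        states = results["features"].get("chromatin_states")
        ent_c = cat.classify_breadth(entries)
        for category in ("constitutive", "tissue_specific", "shared"):
            sub = ent_c[ent_c["category"] == category]
            if not len(sub) or states is None:
                continue
            for state, feats in states.groupby("group"):
                res = enr.bootstrap_enrichment(
                    sub, feats, sizes, n=n_res, seed=seed,
                    statistic=ecfg.get("statistic", "bp_overlap"),
                    feature_name=f"{category}|{state}",
                )
                rows.append(asdict(res))
        if rows:
            pd.DataFrame(rows).to_csv(out / "enrichment.tsv", sep="\t",
                                      index=False, float_format="%.6g")
            runner.record("enrich", ecfg, {"catalog": catalog_tsv},
                          [out / "enrichment.tsv"])
            results["enrichment"] = pd.DataFrame(rows)

    # ----- score ----------------------------------------------------------
    if "truth_islands" in inputs and sim_cfg is not None:
        truth_df = pd.read_csv(inputs["truth_islands"], sep="\t",
                               dtype={"chrom": str}).fillna({"pattern": ""})
        truth = sim.SyntheticTruth(
            islands=truth_df, genes=pd.DataFrame(), features={},
            snps=pd.DataFrame(columns=["chrom", "pos", "af"]),
            lowmap=pd.DataFrame(columns=["chrom", "start", "end", "score"]),
            tissues=list(sim_cfg.tissues),
        )
        auto = autosomes or mio.infer_autosomes(truth_df["chrom"].unique())
        rec = sim.score_recovery(
            entries, truth, matrix=matrix,
            min_cpgs=params.min_cpgs, chroms=auto,
        )
        with open(out / "recovery.json", "w") as fh:
            json.dump(asdict(rec), fh, indent=1, sort_keys=True)
            fh.write("\n")
        runner.record("score", {}, {"catalog": catalog_tsv}, [out / "recovery.json"])
        results["recovery"] = rec

    return {"manifest": runner.manifest, "results": results}


def _read_fasta(path) -> dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}
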