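"""End-to-end orchestration: simulate -> dedup -> quant -> enrich -> morpho -> qpcr.

A single YAML (or dict) configuration drives all stages; every threshold the
method uses (FPKM cutoff, fold ratio, similarity, pseudo-count, display
band) lives here and is logged when applied. A machine-readable run manifest
records the config snapshot, the seed, per-stage output digests and
timestamps; re-running with the same config and seed reproduces the digests.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import dedup, enrichment, morphometry, qpcr, quant, synthetic
from .errors import InvalidConfigError

logger = logging.getLogger("ovatome")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 42,
    "out_dir": "ovatome_run",
    "simulate": {
        "enabled": True,
        "n_unique_reads": 200,
        "duplicate_rate": 0.3,
        "read_length": 101,
        "n_genes": 500,
        "n_up_mutant": 40,
        "n_up_wildtype": 40,
        "planted_fold": 4.0,
        "n_go_terms": 60,
        "dag_depth": 4,
    },
    "dedup": {"enabled": True, "prefix_len": 10, "min_similarity": 0.90},
    "quant": {"enabled": True, "fpkm_min": 5.0, "ratio": 2.0},
    "enrich": {
        "enabled": True,
        "obo": None,          # path; None = use simulated ontology
        "annotations": None,  # path; None = use simulated annotations
        "pseudo": 0.01,
        "band": 1.2,
        "min_level": 2,
    },
    "morpho": {"enabled": True, "area_mm2": 5.52, "follicles": None},
    "qpcr": {"enabled": True, "reference": "Ci-GAPDH", "calibrator": "wildtype",
             "ct_table": None},
}


def _merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(source: str | Path | Mapping | None = None) -> dict:
    """Merge a YAML file or mapping over the documented defaults."""
    if source is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    if isinstance(source, Mapping):
        return _merge(DEFAULT_CONFIG, source)
    with open(source) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, Mapping):
        raise InvalidConfigError(f"config file {source} must hold a mapping")
    return _merge(DEFAULT_CONFIG, data)


def validate_config(cfg: Mapping) -> list[str]:
    """Return every violation at once (empty list = ok)."""
    errs: list[str] = []
    unknown = set(cfg) - set(DEFAULT_CONFIG)
    if unknown:
        errs.append(f"unknown config keys: {sorted(unknown)}")
    if cfg["quant"]["fpkm_min"] <= 0:
        errs.append("quant.fpkm_min must be > 0")
    if cfg["quant"]["ratio"] <= 1:
        errs.append("quant.ratio must exceed 1 (the down direction is its reciprocal)")
    if not 0 < cfg["dedup"]["min_similarity"] < 1:
        errs.append("dedup.min_similarity must lie strictly in (0, 1)")
    if cfg["enrich"]["pseudo"] <= 0:
        errs.append("enrich.pseudo must be > 0")
    if cfg["enrich"]["band"] < 0:
        errs.append("enrich.band must be >= 0")
    if cfg["morpho"]["area_mm2"] <= 0:
        errs.append("morpho.area_mm2 must be > 0")
    sim_on = cfg["simulate"]["enabled"]
    if cfg["enrich"]["enabled"] and not sim_on and not cfg["enrich"]["obo"]:
        errs.append("enrich.obo is required when enrich is enabled without simulate")
    if cfg["enrich"]["enabled"] and not sim_on and not cfg["enrich"]["annotations"]:
        errs.append("enrich.annotations is required when enrich is enabled without simulate")
    for path_key in ("enrich.obo", "enrich.annotations", "morpho.follicles", "qpcr.ct_table"):
        section, key = path_key.split(".")
        p = cfg[section].get(key)
        if p is not None and not Path(p).exists():
            errs.append(f"{path_key}: path {p!r} does not exist")
    return errs


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: str | Path | Mapping | None = None) -> dict:
    """Run all enabled stages in dependency order; returns the manifest.

    Any stage failure halts the run with the failing stage named; outputs of
    completed stages are retained on disk.
    """
    cfg = load_config(config)
    violations = validate_config(cfg)
    if violations:
        raise InvalidConfigError("; ".join(violations))
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    sim_cfg = synthetic.SimulationConfig(seed=seed, **{
        k: v for k, v in cfg["simulate"].items() if k != "enabled"
    })
    manifest: dict[str, Any] = {
        "pipeline": "ovatome",
        "version": "0.1.0",
        "seed": seed,
        "config": cfg,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }
    stage = "simulate"
    try:
        artifacts: dict[str, Any] = {}
        if cfg["simulate"]["enabled"]:
            t0 = time.time()
            reads, read_truth = synthetic.generate_read_set(sim_cfg)
            dedup.write_fastq(reads, out / "reads.fastq")
            read_truth.to_csv(out / "reads.truth.csv", index=False)
            counts, expr_truth = synthetic.generate_expression_pair(sim_cfg)
            quant.write_tsv(counts, out / "counts.tsv")
            expr_truth.to_csv(out / "counts.truth.csv", index=False)
            dag, ann, set_a, set_b, go_truth = synthetic.generate_go_world(sim_cfg)
            synthetic.write_obo(dag, out / "ontology.obo")
            enrichment.write_annotations_tsv(ann, out / "annotations.tsv")
            (out / "set_a.txt").write_text("\n".join(set_a) + "\n")
            (out / "set_b.txt").write_text("\n".join(set_b) + "\n")
            follicles, fol_truth = synthetic.generate_ovary_section(sim_cfg)
            pd.DataFrame(
                [{"follicle_id": f.follicle_id, "diameter_um": f.diameter_um}
                 for f in follicles]
            ).to_csv(out / "follicles.csv", index=False)
            fol_truth.to_csv(out / "follicles.truth.csv", index=False)
            ct, ct_truth = synthetic.generate_ct_table(sim_cfg)
            ct.to_csv(out / "ct.csv", index=False)
            (out / "truth.json").write_text(json.dumps(
                {"go_planted": go_truth, "ct_ddct": ct_truth}, indent=2))
            artifacts.update(dag=dag, ann=ann, set_a=set_a, set_b=set_b)
            manifest["stages"]["simulate"] = {
                "status": "ok", "seconds": round(time.time() - t0, 3)}
        else:
            manifest["stages"]["simulate"] = {"status": "skipped"}

        stage = "dedup"
        if cfg["dedup"]["enabled"]:
            t0 = time.time()
            logger.info("dedup: prefix_len=%d min_similarity=%.2f",
                        cfg["dedup"]["prefix_len"], cfg["dedup"]["min_similarity"])
            reads_in = dedup.read_fastq(out / "reads.fastq")
            kept, report = dedup.deduplicate(reads_in)
            dedup.write_fastq(kept, out / "reads.dedup.fastq")
            (out / "dedup.report.json").write_text(report.to_json())
            manifest["stages"]["dedup"] = {
                "status": "ok", "seconds": round(time.time() - t0, 3),
                "n_input": report.n_input, "n_kept": report.n_kept}
        else:
            manifest["stages"]["dedup"] = {"status": "skipped"}

        stage = "quant"
        if cfg["quant"]["enabled"]:
            t0 = time.time()
            logger.info("quant: fpkm_min=%.1f ratio=%.1f",
                        cfg["quant"]["fpkm_min"], cfg["quant"]["ratio"])
            counts_in = quant.read_counts_tsv(out / "counts.tsv")
            q = quant.quantify(counts_in, fpkm_min=cfg["quant"]["fpkm_min"],
                               ratio_threshold=cfg["quant"]["ratio"])
            quant.write_tsv(q, out / "quant.tsv")
            quant.write_tsv(quant.scatter_table(q), out / "scatter.tsv")
            manifest["stages"]["quant"] = {
                "status": "ok", "seconds": round(time.time() - t0, 3),
                "n_genes": len(q),
                "calls": q["call"].value_counts().to_dict()}
        else:
            manifest["stages"]["quant"] = {"status": "skipped"}

        stage = "enrich"
        if cfg["enrich"]["enabled"]:
            t0 = time.time()
            e = cfg["enrich"]
            logger.info("enrich: pseudo=%g band=%.1f min_level=%d",
                        e["pseudo"], e["band"], e["min_level"])
            dag = (enrichment.parse_obo(e["obo"]) if e["obo"]
                   else artifacts["dag"])
            ann = (enrichment.read_annotations_tsv(e["annotations"])
                   if e["annotations"] else artifacts["ann"])
            set_a = artifacts.get("set_a") or (
                (out / "set_a.txt").read_text().split())
            set_b = artifacts.get("set_b") or (
                (out / "set_b.txt").read_text().split())
            results = enrichment.compute_enrichment(
                dag, ann, set_a, set_b, pseudo=e["pseudo"])
            results = enrichment.filter_display(
                results, min_level=e["min_level"], score_band=e["band"])
            quant.write_tsv(enrichment.results_table(results), out / "enrichment.tsv")
            for ns in sorted({dag.namespace(t) for t in dag.terms}):
                if ns in enrichment.NAMESPACES:
                    enrichment.export_graph(dag, results, ns, out / f"graph_{ns}.graphml")
            manifest["stages"]["enrich"] = {
                "status": "ok", "seconds": round(time.time() - t0, 3),
                "n_terms": len(results),
                "n_displayed": sum(r.displayed for r in results)}
        else:
            manifest["stages"]["enrich"] = {"status": "skipped"}

        stage = "morpho"
        if cfg["morpho"]["enabled"]:
            t0 = time.time()
            fol_path = cfg["morpho"]["follicles"] or out / "follicles.csv"
            follicles = morphometry.read_follicles_csv(fol_path)
            summary = morphometry.summarize_section(
                follicles, cfg["morpho"]["area_mm2"])
            (out / "morpho.json").write_text(json.dumps(summary.rounded(), indent=2))
            manifest["stages"]["morpho"] = {
                "status": "ok", "seconds": round(time.time() - t0, 3),
                **summary.rounded()}
        else:
            manifest["stages"]["morpho"] = {"status": "skipped"}

        stage = "qpcr"
        if cfg["qpcr"]["enabled"]:
            t0 = time.time()
            ct_path = cfg["qpcr"]["ct_table"] or out / "ct.csv"
            table = qpcr.CtTable.from_csv(ct_path)
            reference = cfg["qpcr"]["reference"]
            calibrator = cfg["qpcr"]["calibrator"]
            samples = set(table.data["sample"]) - {calibrator}
            targets = sorted(set(table.data["gene"]) - {reference})
            results = [
                qpcr.delta_delta_ct(table, g, reference, calibrator, test)
                for test in sorted(samples) for g in targets
            ]
            qpcr.fold_report(results).to_csv(out / "qpcr.csv", index=False)
            manifest["stages"]["qpcr"] = {
                "status": "ok", "seconds": round(time.time() - t0, 3),
                "n_genes": len(targets)}
        else:
            manifest["stages"]["qpcr"] = {"status": "skipped"}
    except Exception as exc:
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["digests"] = {
        p.name: _digest(p) for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
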