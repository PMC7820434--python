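"""End-to-end orchestration: peaks -> targets -> networks -> enrichment.

``run`` executes the full analysis from a single configuration, writes every
intermediate artifact under the output directory and returns a machine-
readable run report.  All outputs are deterministic functions of the inputs
(no timestamps inside artifacts), so re-running on identical inputs is
byte-identical.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import enrichment as en
from . import mass_annotation as ma
from . import network_core as nc
from . import target_assembly as ta

logger = logging.getLogger("phytonet")

__all__ = ["PipelineConfig", "run"]


@dataclass
class PipelineConfig:
    """Paths to the five input tables and the screening thresholds."""

    predictions: str
    disease: str
    ppi: str
    annotations: str
    out_dir: str
    peaks: str | None = None
    tolerance_ppm: float = 5.0
    probability_threshold: float = 0.0
    ppi_threshold: float = 0.9
    hub_k: int = 10
    alpha: float = 0.01
    top_pathways: int = 20
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self, require_files: bool = True) -> None:
        if not 0 < self.tolerance_ppm:
            raise ValueError("tolerance_ppm must be positive")
        if not 0 <= self.ppi_threshold <= 1:
            raise ValueError("ppi_threshold must lie in [0, 1]")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.hub_k < 1 or self.top_pathways < 1:
            raise ValueError("hub_k and top_pathways must be >= 1")
        if require_files:
            paths = [self.predictions, self.disease, self.ppi, self.annotations]
            if self.peaks:
                paths.append(self.peaks)
            for p in paths:
                if not Path(p).exists():
                    raise FileNotFoundError(f"input file not found: {p}")


def _configure_logging(config: PipelineConfig, out: Path) -> logging.Handler:
    logger.setLevel(config.log_level.upper())
    # timestamp-free format keeps re-runs byte-identical
    fmt = logging.Formatter("%(levelname)s %(name)s: %(message)s")
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(fmt)
    logger.addHandler(handler)
    if not any(isinstance(h, logging.StreamHandler)
               and getattr(h, "stream", None) is sys.stderr
               for h in logger.handlers):
        stream = logging.StreamHandler(sys.stderr)
        stream.setFormatter(fmt)
        logger.addHandler(stream)
    return handler


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run(config: PipelineConfig, dry_run: bool = False) -> dict:
    """Execute the pipeline; returns (and writes) the run report.

    Stages: peak annotation (optional) -> target screening and intersection
    -> compound-target network and main-ingredient screen -> PPI network and
    hub ranking -> over-representation analysis -> compound-target-pathway
    network.  An empty therapeutic intersection stops the run after target
    assembly with an explicit status.
    """
    config.validate(require_files=True)
    if dry_run:
        return {"status": "inputs-valid", "config": asdict(config)}
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _configure_logging(config, out)
    report: dict = {"status": "incomplete", "config": asdict(config)}
    try:
        return _run_stages(config, out, report)
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        report["error"] = str(exc)
        _write_json(report, out / "report.json")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run_stages(config: PipelineConfig, out: Path, report: dict) -> dict:
    # -- stage 1: mass annotation ------------------------------------------
    if config.peaks:
        report["stage"] = "mass_annotation"
        logger.info("mass_annotation: fitting peaks from %s", config.peaks)
        peaks = ma.read_peak_table(config.peaks)
        frames = []
        n_hit = 0
        for _, row in peaks.iterrows():
            peak = ma.MassPeak(str(row["peak_id"]), float(row["rt_min"]),
                               float(row["observed_mz"]), str(row["polarity"]))
            cands = ma.fit_formulas(peak, tolerance_ppm=config.tolerance_ppm)
            n_hit += bool(cands)
            frames.append(ma.candidates_to_frame(peak.peak_id, cands))
        candidates = (pd.concat(frames, ignore_index=True)
                      if frames else ma.candidates_to_frame("", []))
        candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)
        report["mass_annotation"] = {
            "n_peaks": int(len(peaks)),
            "n_peaks_with_candidates": int(n_hit),
            "tolerance_ppm": config.tolerance_ppm,
        }
        logger.info("mass_annotation: %d/%d peaks got candidates", n_hit, len(peaks))

    # -- stage 2: target assembly ------------------------------------------
    report["stage"] = "target_assembly"
    targets_dir = out / "targets"
    targets_dir.mkdir(exist_ok=True)
    predictions = ta.read_predictions(config.predictions)
    per_compound, compound_union, pred_report = ta.screen_predictions(
        predictions, config.probability_threshold)
    disease = ta.read_disease_targets(config.disease)
    per_source, disease_report = ta.screen_disease_targets(disease)
    disease_union = ta.merge_sources(per_source)
    therapeutic = ta.intersect_targets(compound_union, disease_union)
    logger.info("target_assembly: %d compound targets, %d disease targets, "
                "%d in intersection", len(compound_union), len(disease_union),
                len(therapeutic))
    ta.write_gene_set(compound_union, targets_dir / "compound_union.txt")
    ta.write_gene_set(disease_union, targets_dir / "disease_union.txt")
    ta.write_gene_set(therapeutic, targets_dir / "intersection.txt")
    with open(targets_dir / "per_compound.tsv", "w") as fh:
        fh.write("compound_id\tgene\n")
        for cid in sorted(per_compound):
            for gene in per_compound[cid]:
                fh.write(f"{cid}\t{gene}\n")
    report["target_assembly"] = {
        "predictions": pred_report.to_dict(),
        "disease": disease_report.to_dict(),
        "merged_disease_targets": len(disease_union),
        "therapeutic_targets": len(therapeutic),
    }
    if not therapeutic.genes:
        report["status"] = "empty therapeutic set"
        logger.warning("stopping: empty therapeutic set")
        _write_json(report, out / "report.json")
        return report

    # -- stage 3: compound-target network ----------------------------------
    report["stage"] = "network_core"
    net_dir = out / "net"
    net_dir.mkdir(exist_ok=True)
    ct = nc.build_compound_target_network(per_compound, therapeutic)
    ct.assert_bipartite()
    ct_summary = nc.summarize(ct)
    ct_table = nc.centrality(ct)
    ct_table.to_csv(net_dir / "ct_centrality.tsv", sep="\t", index=False)
    nc.write_graphml(ct, net_dir / "ct.graphml")
    nc.write_sif(ct, net_dir / "ct.sif")
    main_ingredients, mean_deg, mean_btw = nc.screen_main_ingredients(ct)
    logger.info("network_core: compound-target %d nodes / %d edges; "
                "%d main ingredients", ct_summary.n_nodes, ct_summary.n_edges,
                len(main_ingredients))

    ppi_edges = nc.read_ppi_edges(config.ppi)
    ppi = nc.build_ppi_network(ppi_edges, therapeutic, config.ppi_threshold)
    ppi_summary = nc.summarize(ppi)
    hubs, hub_overflow = nc.hub_genes(ppi, config.hub_k)
    nc.write_graphml(ppi, net_dir / "ppi.graphml")
    nc.write_sif(ppi, net_dir / "ppi.sif")
    with open(net_dir / "hubs.tsv", "w") as fh:
        fh.write("gene\tdegree\n")
        for gene, deg in hubs:
            fh.write(f"{gene}\t{deg}\n")
    logger.info("network_core: PPI %d nodes / %d edges", ppi_summary.n_nodes,
                ppi_summary.n_edges)
    report["network_core"] = {
        "compound_target": ct_summary.to_dict(),
        "main_ingredients": sorted(main_ingredients),
        "compound_mean_degree": mean_deg,
        "compound_mean_betweenness": mean_btw,
        "ppi": ppi_summary.to_dict(),
        "hub_genes": [{"gene": g, "degree": d} for g, d in hubs],
        "hub_tie_overflow": [{"gene": g, "degree": d} for g, d in hub_overflow],
    }

    # -- stage 4: enrichment ------------------------------------------------
    report["stage"] = "enrichment"
    enrich_dir = out / "enrich"
    enrich_dir.mkdir(exist_ok=True)
    db = en.read_gmt(config.annotations)
    rows, ora_report = en.ora(therapeutic, db, alpha=config.alpha)
    en.rows_to_frame(rows).to_csv(enrich_dir / "enrichment.tsv", sep="\t",
                                  index=False)
    top = en.select_top(rows, config.top_pathways)
    top_rows = [r for cat_rows in top.values() for r in cat_rows]
    en.rows_to_frame(top_rows).to_csv(enrich_dir / "top_terms.tsv", sep="\t",
                                      index=False)
    en.bubble_export(top_rows).to_csv(enrich_dir / "bubble.tsv", sep="\t",
                                      index=False)
    by_category = {cat: len([r for r in rows if r.category == cat])
                   for cat in en.CATEGORIES}
    logger.info("enrichment: %d significant terms %s", len(rows), by_category)
    report["enrichment"] = {**ora_report, "significant_by_category": by_category}

    # -- stage 5: compound-target-pathway network ---------------------------
    report["stage"] = "ctp_network"
    kegg_top = top.get("KEGG", [])
    membership = {t.term_id: ta.GeneSet(t.term_id, t.genes)
                  for t in db.terms}
    ctp = nc.build_ctp_network(ct, membership, [r.term_id for r in kegg_top])
    ctp_summary = nc.summarize(ctp)
    nc.write_graphml(ctp, net_dir / "ctp.graphml")
    nc.write_sif(ctp, net_dir / "ctp.sif")
    logger.info("ctp_network: %d nodes / %d edges", ctp_summary.n_nodes,
                ctp_summary.n_edges)
    report["ctp_network"] = {
        "summary": ctp_summary.to_dict(),
        "selected_pathways": [r.term_id for r in kegg_top],
    }

    report["status"] = "complete"
    report.pop("stage", None)
    _write_json(report, out / "report.json")
    return report
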