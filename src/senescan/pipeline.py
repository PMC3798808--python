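"""End-to-end orchestration: DE filtering -> promoter extraction -> motif
scanning -> background profiling -> candidate calling -> TF-target
concordance, with optional category/signature summaries.

Driven by one flat JSON config (paths + AnalysisConfig keys). Reports are
deterministic given identical inputs and config; a run manifest records the
config snapshot, input digests, stage timings and output paths. Timings live
only in the manifest so the reports themselves stay byte-identical across
re-runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

from . import __version__
from .de_analysis import filter_de, overlap_sets, signature_concordance, summarize_categories
from .enrichment import background_profiles, call_candidates, tf_target_concordance
from .io_formats import (read_annotation, read_categories, read_config,
                         read_de_table, read_genome, read_motifs, read_signature,
                         write_report, write_tsv_report)
from .motif_scan import scan_promoters
from .promoters import extract_promoters
from .types import AnalysisConfig

logger = logging.getLogger(__name__)

CONFIG_KEYS = ("p_cutoff", "use_adjusted_p", "lfc_cutoff", "promoter_window",
               "strands", "sd_multiplier", "seed")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def analysis_config_from(raw: dict) -> AnalysisConfig:
    return AnalysisConfig(**{k: raw[k] for k in CONFIG_KEYS if k in raw})


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config_path, out_dir: Optional[str] = None) -> dict:
    """Run every configured stage; returns the run manifest (also written).

    Config keys: de_table, genome, annotation (+ annotation_dialect), motifs,
    optional categories / signature, out_dir, plus AnalysisConfig keys.
    Missing inputs fail before any stage runs; a stage failure raises
    PipelineError naming the stage and leaves earlier outputs intact.
    """
    raw = read_config(config_path)
    config = analysis_config_from(raw)
    out = Path(out_dir or raw.get("out_dir", "."))
    out.mkdir(parents=True, exist_ok=True)

    input_keys = ["de_table", "genome", "annotation", "motifs"]
    optional_keys = ["categories", "signature"]
    inputs = {}
    for key in input_keys + optional_keys:
        if key in raw and raw[key] is not None:
            inputs[key] = Path(raw[key])
        elif key in input_keys:
            raise FileNotFoundError(f"config key {key!r} missing")
    absent = [str(p) for p in inputs.values() if not p.exists()]
    if absent:
        raise FileNotFoundError(f"input file(s) not found: {', '.join(absent)}")

    meta = {k: getattr(config, k) for k in CONFIG_KEYS}
    meta["version"] = __version__
    manifest: dict = {
        "config": meta,
        "inputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in inputs.items()},
        "stages": [],
        "outputs": [],
        "version": __version__,
        "seed": config.seed,
    }

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc
        manifest["stages"].append({"name": name,
                                   "elapsed_s": round(time.perf_counter() - t0, 3)})
        logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
        return result

    def emit(name, writer):
        path = out / name
        writer(path)
        manifest["outputs"].append(str(path))
        return path

    # --- filter-de ---------------------------------------------------------
    de_records = stage("read-inputs", lambda: read_de_table(inputs["de_table"]))
    de_sets = stage("filter-de", lambda: filter_de(de_records, config))
    rows = []
    for (tissue, comparison), s in sorted(de_sets.items()):
        for gene in sorted(s.up):
            rows.append({"tissue": tissue, "comparison": comparison,
                         "gene_id": gene, "direction": "up"})
        for gene in sorted(s.down):
            rows.append({"tissue": tissue, "comparison": comparison,
                         "gene_id": gene, "direction": "down"})
    import pandas as pd
    emit("de_sets.tsv", lambda p: pd.DataFrame(
        rows, columns=["tissue", "comparison", "gene_id", "direction"]
    ).to_csv(p, sep="\t", index=False))

    # overlap of every pair of (tissue, comparison) sets sharing a comparison
    overlaps = {}
    keys = sorted(de_sets)
    for i, ka in enumerate(keys):
        for kb in keys[i + 1:]:
            part = overlap_sets(de_sets[ka].genes, de_sets[kb].genes)
            overlaps["|".join(["-".join(ka), "-".join(kb)])] = {
                "a_only": len(part.a_only), "b_only": len(part.b_only),
                "common": len(part.common)}
    emit("overlaps.json", lambda p: write_report(overlaps, p, meta=meta))

    # --- promoters + scan --------------------------------------------------
    genome = stage("read-genome", lambda: read_genome(inputs["genome"]))
    genes = stage("read-annotation", lambda: read_annotation(
        inputs["annotation"], raw.get("annotation_dialect", "BED6")))
    motifs = stage("read-motifs", lambda: read_motifs(inputs["motifs"]))
    promoters = stage("extract-promoters", lambda: extract_promoters(
        genome, genes, config.promoter_window))
    matrix = stage("scan", lambda: scan_promoters(promoters, motifs, config.strands))
    emit("count_matrix.tsv",
         lambda p: matrix.total.rename_axis("gene_id").to_csv(p, sep="\t"))

    # --- background + candidates + targets ---------------------------------
    profiles = stage("background", lambda: background_profiles(
        matrix, config.sd_multiplier))
    emit("profiles.tsv", lambda p: pd.DataFrame(
        [dataclasses.asdict(profiles[m]) for m in sorted(profiles)]
    ).to_csv(p, sep="\t", index=False))

    de_gene_ids = sorted({g for s in de_sets.values() for g in s.genes})
    calls, skipped = stage("call-candidates", lambda: call_candidates(
        matrix, profiles, de_genes=de_gene_ids))
    emit("candidates.tsv", lambda p: write_tsv_report(
        calls, p, columns=["gene_id", "motif_id", "count", "call"], meta=meta))
    if skipped:
        emit("skipped_genes.tsv", lambda p: pd.DataFrame(
            {"gene_id": skipped}).to_csv(p, sep="\t", index=False))

    assignments = stage("targets", lambda: tf_target_concordance(
        calls, de_records, motifs, config,
        include_depleted=bool(raw.get("include_depleted", False)),
        keep_all=bool(raw.get("keep_all_assignments", False))))
    emit("targets.tsv", lambda p: write_tsv_report(
        assignments, p,
        columns=["tf_gene_id", "target_gene_id", "motif_id", "tissue",
                 "comparison", "tf_direction", "target_direction",
                 "concordant", "candidate_call"],
        meta=meta))

    # --- optional summaries -------------------------------------------------
    if "categories" in inputs:
        categories = read_categories(inputs["categories"])
        table_genes = sorted({r.gene_id for r in de_records})
        cat_rows = []
        for key in sorted(de_sets):
            for s in summarize_categories(de_sets[key], categories,
                                          table_genes=table_genes,
                                          split_roles=True):
                row = dataclasses.asdict(s)
                row["tissue"], row["comparison"] = key
                cat_rows.append(row)
        emit("category_summary.tsv", lambda p: pd.DataFrame(
            cat_rows, columns=["tissue", "comparison", "category", "n_up",
                               "n_down", "pct_down", "pct_down_of_table"]
        ).to_csv(p, sep="\t", index=False))
    if "signature" in inputs:
        signature = read_signature(inputs["signature"])
        conc = {}
        for (tissue, comparison) in sorted(de_sets):
            subset = [r for r in de_records
                      if r.tissue == tissue and r.comparison == comparison]
            result = signature_concordance(subset, signature, config)
            conc["-".join([tissue, comparison])] = {
                "n_consistent": result.n_consistent,
                "n_evaluated": result.n_evaluated,
                "fraction": result.fraction}
        emit("concordance.json", lambda p: write_report(conc, p, meta=meta))

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
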