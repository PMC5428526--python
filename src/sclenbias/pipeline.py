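"""End-to-end orchestration: simulate/load -> QC -> bias -> combine ->
overlap -> enrichment -> differential expression.

Each stage writes its artifacts into ``<outdir>/<stage>/`` and the run
finishes with a single ``summary.json`` of headline numbers.  Runs are
deterministic given the config and seed.  A stage failure aborts the run
with the stage name attached.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import bias, combine, de, qc, stats
from .config import RunConfig
from .ingest import ExpressionDataset, read_count_matrix, write_dataset
from .simulate import mesc_like_pair, write_truth

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def _write_json(obj, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured stages; returns the summary dict it also writes."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed, "stages": list(cfg.stages)}
    datasets: dict[str, ExpressionDataset] = {}
    truth = None

    stage = "simulate"
    try:
        if stage in cfg.stages and not cfg.datasets:
            sim = cfg.simulate
            ds_fl, ds_umi, truth = mesc_like_pair(
                n_genes=sim["n_genes"], n_cells=sim["n_cells"], seed=cfg.seed,
                fl_depth=sim["fl_depth"], umi_depth=sim["umi_depth"],
            )
            datasets = {"sim_fl": ds_fl, "sim_umi": ds_umi}
            for name, ds in datasets.items():
                write_dataset(ds, outdir / "simulate" / name)
            write_truth(truth, outdir / "simulate")
            logger.info("simulated matched pair: %d genes x %d cells",
                        ds_fl.n_genes, ds_fl.n_cells)
        for entry in cfg.datasets:
            datasets[entry.dataset_id] = read_count_matrix(
                entry.path, format=entry.format, protocol=entry.protocol
            )
    except Exception as exc:  # noqa: BLE001 - rethrown with stage context
        raise StageError(stage, exc) from exc
    if not datasets:
        raise StageError("simulate", ValueError("no datasets configured or simulated"))

    thresholds = {e.dataset_id: e.thresholds for e in cfg.datasets}
    filtered: dict[str, ExpressionDataset] = dict(datasets)

    stage = "qc"
    if stage in cfg.stages:
        try:
            for name, ds in datasets.items():
                cell_f = qc.filter_cells(ds, thresholds.get(name))
                gene_f = qc.filter_genes(cell_f, cfg.gene_filter)
                filtered[name] = gene_f
                report = qc.qc_report(ds, gene_f, cfg.gene_filter)
                qc.write_qc_report(report, outdir / "qc" / name)
                qc.compute_cell_metrics(ds).to_csv(
                    outdir / "qc" / name / "cell_metrics.tsv", sep="\t", index=False
                )
                summary.setdefault("qc", {})[name] = {
                    "cells_retained": gene_f.n_cells,
                    "genes_retained": gene_f.n_genes,
                }
                logger.info("qc %s: %d cells, %d genes retained",
                            name, gene_f.n_cells, gene_f.n_genes)
        except Exception as exc:
            raise StageError(stage, exc) from exc

    stage = "bias"
    if stage in cfg.stages:
        try:
            for name, ds in filtered.items():
                gs = bias.gene_summaries(ds, pseudocount=cfg.pseudocount,
                                         n_bins=cfg.n_bins)
                bs = bias.bin_summaries(gs)
                stage_dir = outdir / "bias" / name
                stage_dir.mkdir(parents=True, exist_ok=True)
                gs.to_csv(stage_dir / "gene_summaries.tsv", sep="\t", index=False)
                bs.to_csv(stage_dir / "bin_summaries.tsv", sep="\t", index=False)
                st = bias.length_bias_statistics(gs)
                _write_json(st.to_dict(), stage_dir / "bias_statistics.json")
                summary.setdefault("bias", {})[name] = st.to_dict()
                logger.info("bias %s: rho_count=%.3f rho_dropout=%.3f rho_rpkm=%.3f",
                            name, st.rho_count, st.rho_dropout, st.rho_rpkm)
        except Exception as exc:
            raise StageError(stage, exc) from exc

    stage = "combine"
    if stage in cfg.stages and len(filtered) >= 2:
        try:
            ds_list = list(filtered.values())
            shared = combine.common_genes(ds_list, cfg.min_cell_fraction)
            summary["combine"] = {"n_common_genes": len(shared)}
            if shared:
                merged = combine.combine_datasets(ds_list, shared)
                expr = combine.combined_log_expression(merged, cfg.pseudocount)
                n_comp = min(5, merged.n_cells, len(shared))
                coords, variances, _ = combine.pca_embedding(expr, n_comp)
                pca = pd.DataFrame(
                    coords, columns=[f"PC{i + 1}" for i in range(n_comp)]
                )
                pca.insert(0, "cell_id", merged.cells["cell_id"])
                pca.insert(1, "dataset_id", merged.cells["dataset_id"])
                stage_dir = outdir / "combine"
                stage_dir.mkdir(parents=True, exist_ok=True)
                pca.to_csv(stage_dir / "pca_coordinates.tsv", sep="\t", index=False)
                _write_json(
                    {"n_common_genes": len(shared), "n_cells": merged.n_cells,
                     "component_variances": variances.tolist()},
                    stage_dir / "combine.json",
                )
                summary["combine"].update(
                    {"n_cells": merged.n_cells,
                     "pc1_variance": float(variances[0])}
                )
                logger.info("combine: %d shared genes, %d cells",
                            len(shared), merged.n_cells)
        except Exception as exc:
            raise StageError(stage, exc) from exc

    overlap_result = None
    stage = "overlap"
    if stage in cfg.stages and len(filtered) >= 2:
        try:
            groups = cfg.groups or _default_groups(filtered)
            group_a = [filtered[i] for i in groups.get("a", [])]
            group_b = [filtered[i] for i in groups.get("b", [])]
            if group_a and group_b:
                overlap_result = combine.detection_overlap(
                    group_a, group_b, cfg.min_cell_fraction
                )
                stage_dir = outdir / "overlap"
                stage_dir.mkdir(parents=True, exist_ok=True)
                overlap_result.to_frame().to_csv(
                    stage_dir / "overlap_regions.tsv", sep="\t", index=False
                )
                lengths = _length_lookup(filtered.values())
                len_a = [lengths[g] for g in overlap_result.members_only_a
                         if g in lengths]
                len_b = [lengths[g] for g in overlap_result.members_only_b
                         if g in lengths]
                region = {
                    "universe_size": overlap_result.universe_size,
                    "in_both": overlap_result.in_both,
                    "only_group_a": overlap_result.only_group_a,
                    "only_group_b": overlap_result.only_group_b,
                    "median_length_only_a": float(np.median(len_a)) if len_a else None,
                    "median_length_only_b": float(np.median(len_b)) if len_b else None,
                }
                if len(len_a) > 1 and len(len_b) > 1:
                    w, p = stats.wilcoxon_rank_sum(len_a, len_b, "two_sided")
                    region["length_wilcoxon_p"] = p
                _write_json(region, stage_dir / "overlap.json")
                summary["overlap"] = region
                logger.info("overlap: both=%d only_a=%d only_b=%d",
                            overlap_result.in_both, overlap_result.only_group_a,
                            overlap_result.only_group_b)
        except Exception as exc:
            raise StageError(stage, exc) from exc

    stage = "enrich"
    if stage in cfg.stages and overlap_result is not None and cfg.enrich_gmt:
        try:
            categories = stats.read_gmt(cfg.enrich_gmt)
            universe = set(overlap_result.members_in_both) | set(
                overlap_result.members_only_a) | set(overlap_result.members_only_b)
            lengths = _length_lookup(filtered.values())
            stage_dir = outdir / "enrich"
            stage_dir.mkdir(parents=True, exist_ok=True)
            spreads = {}
            for region_name, members in (
                ("only_a", overlap_result.members_only_a),
                ("only_b", overlap_result.members_only_b),
            ):
                table = stats.enrich(set(members), categories, universe,
                                     lengths=lengths,
                                     fdr_alpha=cfg.enrich_fdr_alpha)
                table.to_csv(stage_dir / f"enrichment_{region_name}.tsv",
                             sep="\t", index=False)
                sig = table[table["significant"]]
                spreads[region_name] = sig["median_member_length"].dropna().to_numpy()
                summary.setdefault("enrich", {})[region_name] = {
                    "n_significant": int(table["significant"].sum()),
                    "n_tested": len(table),
                }
            if len(spreads.get("only_a", ())) > 1 and len(spreads.get("only_b", ())) > 1:
                F, p = stats.category_length_spread_test(
                    spreads["only_a"], spreads["only_b"]
                )
                summary["enrich"]["length_spread_F"] = F
                summary["enrich"]["length_spread_p"] = p
        except Exception as exc:
            raise StageError(stage, exc) from exc

    stage = "de"
    if stage in cfg.stages:
        try:
            for name, ds in filtered.items():
                labels = ds.cells[cfg.de_condition_column].to_numpy()
                if len(set(labels.tolist())) != 2:
                    continue
                lfc_cutoff = cfg.de_lfc_cutoff
                table = de.de_two_group(ds, labels, lfc_cutoff=lfc_cutoff,
                                        alpha=cfg.de_alpha,
                                        pseudocount=cfg.pseudocount)
                stage_dir = outdir / "de" / name
                stage_dir.mkdir(parents=True, exist_ok=True)
                table.to_csv(stage_dir / "de_results.tsv", sep="\t", index=False)
                entry = {
                    "n_significant": int(table["significant"].sum()),
                    "n_tested": len(table),
                }
                if overlap_result is not None:
                    region = ("only_a" if ds.protocol == "umi" else "only_b")
                    members = (overlap_result.members_only_a if region == "only_a"
                               else overlap_result.members_only_b)
                    in_table = set(members) & set(table["gene_id"])
                    if in_table:
                        entry["unique_region"] = de.de_fraction_in_set(table, in_table)
                summary.setdefault("de", {})[name] = entry
                logger.info("de %s: %d/%d significant", name,
                            entry["n_significant"], entry["n_tested"])
        except Exception as exc:
            raise StageError(stage, exc) from exc

    _write_json(summary, outdir / "summary.json")
    return summary


def _default_groups(filtered: dict[str, ExpressionDataset]) -> dict:
    """Group datasets by protocol: a = UMI, b = full-length."""
    return {
        "a": [n for n, d in filtered.items() if d.protocol == "umi"],
        "b": [n for n, d in filtered.items() if d.protocol == "full_length"],
    }


def _length_lookup(datasets) -> dict[str, float]:
    lengths: dict[str, float] = {}
    for ds in datasets:
        for gid, length in zip(ds.genes["gene_id"], ds.genes["length_bp"]):
            if not pd.isna(length):
                lengths.setdefault(gid, float(length))
    return lengths
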