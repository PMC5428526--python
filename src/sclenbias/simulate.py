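"""Mechanistic simulator of full-length and UMI single-cell RNA-seq counts.

The generative model separates biology from protocol:

1. *Truth*: each gene gets a length (log-normal, clipped to a plausible
   genomic range) and a baseline expression level (log-normal, wide enough
   to span the several orders of magnitude real transcriptomes cover).
   A fraction of ordinary genes carries a condition effect (log2 fold
   change ~ Normal).  Spike-in controls have fixed input across cells and
   conditions; mitochondrial and ribosomal-protein genes are flagged with
   conforming symbols so downstream classification recognises them.
2. *Molecules*: the number of transcript molecules captured from gene g in
   cell c is negative-binomial with mean
   ``expr_g * 2^(lfc_g * condition_c) * capture_c`` (per-cell log-normal
   capture efficiency) and a common over-dispersion.
3. *Reads*: sequencing observes Poisson counts with mean
   ``molecules * depth_factor * (length_g / L0)^alpha``.  With the length
   exponent ``alpha = 1`` fragmentation makes read counts proportional to
   gene length (full-length protocols); with ``alpha = 0`` counts track
   molecules only (UMI protocols).  The depth factor is calibrated so the
   expected per-cell total matches ``depth_scale``.

Dropout is emergent: nothing zero-inflates the counts beyond the sampling
hierarchy itself, which is sufficient to reproduce the length-dependent
dropout patterns of fragmentation protocols.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .ingest import ExpressionDataset, classify_genes

import math


@dataclass(frozen=True)
class SimulationDesign:
    """All truth-model and sampling parameters of one simulated dataset.

    Defaults emulate a mouse-embryonic-stem-cell-like experiment: gene
    lengths with median ~2.5 kb spanning roughly 300 bp - 30 kb, expression
    spanning ~4-5 orders of magnitude, 92 spike-in controls, two culture
    conditions, and a deep full-length protocol (~1e6 reads per cell).  Use
    :func:`umi_design` / :func:`mesc_like_pair` for the matched shallow UMI
    counterpart (~3e4 molecules per cell).
    """

    n_genes: int = 12000
    n_cells: int = 250
    protocol: str = "full_length"
    length_exponent: float = 1.0  # alpha: 1 = fragmentation, 0 = molecule counting
    length_log_mean: float = math.log(2500.0)
    length_log_sd: float = 1.15
    length_min_bp: float = 200.0
    length_max_bp: float = 100_000.0
    expr_log_mean: float = math.log(20.0)  # median ~20 molecules/gene/cell
    expr_log_sd: float = 2.5
    capture_log_mean: float = 0.0
    capture_log_sd: float = 0.35
    dispersion: float = 0.6  # NB over-dispersion phi: var = mu + phi mu^2
    reference_length: float = 1000.0  # L0 normaliser for the length factor
    fragment_offset_bp: float = 300.0  # fragment size; effective length = L - offset
    min_effective_bp: float = 10.0
    de_fraction: float = 0.1
    de_log2fc_sd: float = 1.0
    n_spikeins: int = 92
    n_mito: int = 13
    n_ribo: int = 80
    depth_scale: float = 1e6  # target mean reads (or molecules) per cell
    conditions: tuple = ("2i", "serum")
    dataset_id: str = "sim"
    seed: int = 0

    def __post_init__(self):
        if self.n_spikeins + self.n_mito + self.n_ribo > self.n_genes:
            raise ValueError("class counts exceed n_genes")
        if self.protocol not in ("full_length", "umi"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        for name in ("length_log_sd", "expr_log_sd", "capture_log_sd",
                     "dispersion", "depth_scale", "reference_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth aligned to the emitted dataset's gene and cell order."""

    genes: pd.DataFrame  # gene_id, symbol, length_bp, gene_class, expression, log2fc
    cells: pd.DataFrame  # cell_id, condition, capture_factor
    seed: int


def _gene_tables(design: SimulationDesign, rng: np.random.Generator) -> pd.DataFrame:
    n = design.n_genes
    n_ord = n - design.n_spikeins - design.n_mito - design.n_ribo
    ids, symbols, classes = [], [], []
    for i in range(n_ord):
        ids.append(f"G{i:06d}")
        symbols.append(f"Gene{i}")
        classes.append("ordinary")
    for i in range(design.n_mito):
        ids.append(f"MT{i:04d}")
        symbols.append(f"mt-Nd{i + 1}")
        classes.append("mito")
    for i in range(design.n_ribo):
        ids.append(f"RB{i:04d}")
        symbols.append(f"Rps{i + 1}" if i % 2 == 0 else f"Rpl{i + 1}")
        classes.append("ribo")
    for i in range(design.n_spikeins):
        ids.append(f"ERCC-{i:05d}")
        symbols.append(f"ERCC-{i:05d}")
        classes.append("spikein")
    lengths = np.clip(
        rng.lognormal(design.length_log_mean, design.length_log_sd, size=n),
        design.length_min_bp, design.length_max_bp,
    )
    spike = np.array(classes) == "spikein"
    # ERCC molecules are short in-vitro transcripts (~250-2000 bp)
    lengths[spike] = np.clip(rng.lognormal(math.log(700.0), 0.5, spike.sum()),
                             250.0, 2000.0)
    expression = rng.lognormal(design.expr_log_mean, design.expr_log_sd, size=n)
    log2fc = np.zeros(n)
    ordinary = np.flatnonzero(np.array(classes) == "ordinary")
    n_de = int(round(design.de_fraction * ordinary.size))
    if n_de:
        de_idx = rng.choice(ordinary, size=n_de, replace=False)
        log2fc[de_idx] = rng.normal(0.0, design.de_log2fc_sd, size=n_de)
    return pd.DataFrame(
        {
            "gene_id": ids,
            "symbol": symbols,
            "length_bp": np.round(lengths).astype(int),
            "gene_class": classes,
            "expression": expression,
            "log2fc": log2fc,
        }
    )


def draw_gene_truth(design: SimulationDesign) -> SimulationTruth:
    """Draw the ground-truth gene and cell tables for a design (seeded)."""
    rng = np.random.default_rng([design.seed, 101])
    genes = _gene_tables(design, rng)
    conditions = np.array(
        [design.conditions[i % len(design.conditions)] for i in range(design.n_cells)]
    )
    capture = rng.lognormal(design.capture_log_mean, design.capture_log_sd,
                            size=design.n_cells)
    cells = pd.DataFrame(
        {
            "cell_id": [f"{design.dataset_id}_cell{i:04d}" for i in range(design.n_cells)],
            "condition": conditions,
            "capture_factor": capture,
        }
    )
    return SimulationTruth(genes=genes, cells=cells, seed=design.seed)


def _molecule_means(truth: SimulationTruth, design: SimulationDesign) -> np.ndarray:
    genes = truth.genes
    expr = genes["expression"].to_numpy()
    lfc = genes["log2fc"].to_numpy()
    cond = (truth.cells["condition"] == design.conditions[-1]).to_numpy().astype(float)
    capture = truth.cells["capture_factor"].to_numpy().copy()
    mu = expr[:, None] * 2.0 ** (lfc[:, None] * cond[None, :]) * capture[None, :]
    # spike-ins: fixed input per cell, unaffected by condition or cellular capture
    spike = (genes["gene_class"] == "spikein").to_numpy()
    mu[spike, :] = expr[spike, None]
    return mu


def simulate_counts(truth: SimulationTruth, design: SimulationDesign) -> ExpressionDataset:
    """Sample an observed count matrix from a truth under a protocol design.

    Molecules are negative-binomial (gamma-Poisson) around the truth means;
    observed counts are Poisson around molecules scaled by the calibrated
    depth factor and the length factor ``(length/L0)^alpha``.
    """
    if len(truth.genes) != design.n_genes or len(truth.cells) != design.n_cells:
        raise ValueError("truth dimensions do not match design")
    rng = np.random.default_rng([design.seed, 202])
    mu = _molecule_means(truth, design)
    if not np.isfinite(mu).all():
        g, c = np.argwhere(~np.isfinite(mu))[0]
        raise ValueError(f"non-finite molecule mean at gene {g}, cell {c}")
    phi = design.dispersion
    lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
    molecules = rng.poisson(lam)
    lengths = truth.genes["length_bp"].to_numpy(dtype=float)
    # Fragmentation samples fragments from the part of the transcript that
    # can yield an insert: the effective length (length minus fragment size).
    # Irrelevant when alpha = 0 (molecule counting).
    effective = np.maximum(lengths - design.fragment_offset_bp,
                           design.min_effective_bp)
    length_factor = (effective / design.reference_length) ** design.length_exponent
    expected_cell_total = (mu * length_factor[:, None]).sum(axis=0).mean()
    depth_factor = design.depth_scale / expected_cell_total
    counts = rng.poisson(molecules * depth_factor * length_factor[:, None])
    genes = truth.genes[["gene_id", "symbol", "length_bp", "gene_class"]].copy()
    genes["curated"] = True
    genes = classify_genes(genes)  # recomputed from symbols; must agree with truth
    cells = pd.DataFrame(
        {
            "cell_id": truth.cells["cell_id"],
            "dataset_id": design.dataset_id,
            "condition": truth.cells["condition"],
            "batch": "batch1",
        }
    )
    return ExpressionDataset(
        counts=counts.astype(np.int64), genes=genes, cells=cells,
        protocol=design.protocol,
        provenance=f"simulated:{design.dataset_id} seed={design.seed} "
                   f"alpha={design.length_exponent} depth={design.depth_scale:g}",
    )


def simulate_dataset(design: SimulationDesign) -> tuple[ExpressionDataset, SimulationTruth]:
    """Draw a truth and sample one dataset from it."""
    truth = draw_gene_truth(design)
    return simulate_counts(truth, design), truth


def umi_design(base: SimulationDesign, depth_scale: float = 3e4,
               seed_offset: int = 1, dataset_id: str | None = None) -> SimulationDesign:
    """Shallow UMI counterpart of a full-length design (alpha=0)."""
    return replace(
        base,
        protocol="umi",
        length_exponent=0.0,
        depth_scale=depth_scale,
        seed=base.seed + seed_offset,
        dataset_id=dataset_id or (base.dataset_id + "_umi"),
    )


def simulate_protocol_pair(
    truth: SimulationTruth,
    design_fl: SimulationDesign,
    design_umi: SimulationDesign,
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Sample a matched full-length / UMI dataset pair from one shared truth.

    Both designs must have the dimensions of the truth; they differ in
    protocol, length exponent and depth (full-length deep, UMI shallow).
    """
    for design in (design_fl, design_umi):
        if len(truth.genes) != design.n_genes or len(truth.cells) != design.n_cells:
            raise ValueError("design dimensions do not match the shared truth")
    if design_fl.seed == design_umi.seed:
        design_umi = replace(design_umi, seed=design_umi.seed + 1)
    return simulate_counts(truth, design_fl), simulate_counts(truth, design_umi)


def mesc_like_pair(
    n_genes: int = 12000, n_cells: int = 250, seed: int = 0,
    fl_depth: float = 1e6, umi_depth: float = 3e4,
) -> tuple[ExpressionDataset, ExpressionDataset, SimulationTruth]:
    """Matched deep full-length and shallow UMI datasets from one truth.

    The depth contrast (~1e6 reads vs ~3e4 molecules per cell) mirrors the
    typical gap between plate-based full-length libraries and shallow UMI
    libraries.
    """
    design_fl = SimulationDesign(
        n_genes=n_genes, n_cells=n_cells, protocol="full_length",
        length_exponent=1.0, depth_scale=fl_depth, seed=seed,
        dataset_id="sim_fl",
    )
    design_umi = umi_design(design_fl, depth_scale=umi_depth, dataset_id="sim_umi")
    truth = draw_gene_truth(design_fl)
    ds_fl, ds_umi = simulate_protocol_pair(truth, design_fl, design_umi)
    return ds_fl, ds_umi, truth


def write_truth(truth: SimulationTruth, out_dir) -> None:
    """Write the ground-truth gene and cell tables as TSV."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth.genes.to_csv(out_dir / "truth_genes.tsv", sep="\t", index=False)
    truth.cells.to_csv(out_dir / "truth_cells.tsv", sep="\t", index=False)
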