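"""Run configuration: schema, validation, and defaults for the pipeline.

Configs are YAML mappings.  Validation collects *all* problems before
reporting, rejects unknown keys (with a nearest-key hint for typos), checks
referenced paths, and fills documented defaults: pseudocount 1, 10 length
bins, detection in at least 10% of cells.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .qc import THRESHOLD_PRESETS, GeneFilterPolicy, QCThresholds

ALL_STAGES = ("simulate", "qc", "bias", "combine", "overlap", "enrich", "de")

_TOP_KEYS = {
    "seed", "outdir", "pseudocount", "n_bins", "min_cell_fraction",
    "stages", "simulate", "datasets", "gene_filter", "groups", "enrich", "de",
}
_SIMULATE_KEYS = {"n_genes", "n_cells", "fl_depth", "umi_depth"}
_DATASET_KEYS = {"id", "path", "format", "protocol", "qc_preset", "thresholds"}
_THRESHOLD_KEYS = {"max_dropout", "min_library_size", "max_spikein_fraction"}
_GENE_FILTER_KEYS = {"max_zero_fraction", "excluded_classes", "require_curated",
                     "require_length"}
_ENRICH_KEYS = {"gmt", "fdr_alpha"}
_DE_KEYS = {"lfc_cutoff", "alpha", "condition_column"}


class ConfigError(ValueError):
    """Raised with the full list of configuration problems."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(errors))


@dataclass
class DatasetEntry:
    dataset_id: str
    path: Path | None
    format: str = "mtx_triplet"
    protocol: str = "full_length"
    thresholds: QCThresholds | None = None


@dataclass
class RunConfig:
    """Validated, defaults-filled pipeline configuration."""

    seed: int = 0
    outdir: Path = Path("sclenbias_out")
    pseudocount: float = 1.0
    n_bins: int = 10
    min_cell_fraction: float = 0.10
    stages: tuple = ALL_STAGES
    simulate: dict = field(default_factory=lambda: {"n_genes": 5000, "n_cells": 200,
                                                    "fl_depth": 1e6, "umi_depth": 3e4})
    datasets: list = field(default_factory=list)
    gene_filter: GeneFilterPolicy = field(default_factory=GeneFilterPolicy)
    groups: dict = field(default_factory=dict)  # {"a": [ids], "b": [ids]}
    enrich_gmt: Path | None = None
    enrich_fdr_alpha: float = 0.05
    de_lfc_cutoff: float = 0.5
    de_alpha: float = 0.05
    de_condition_column: str = "condition"


def _check_keys(section: dict, allowed: set, where: str, errors: list[str]) -> None:
    for key in section:
        if key not in allowed:
            hint = difflib.get_close_matches(str(key), allowed, n=1)
            suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
            errors.append(f"{where}: unknown key {key!r}{suffix}")


def validate_config(path_or_mapping) -> RunConfig:
    """Validate a YAML config file (or pre-parsed mapping) into a RunConfig.

    Raises :class:`ConfigError` listing every problem found at once.
    """
    if isinstance(path_or_mapping, (str, Path)):
        with open(path_or_mapping) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(path_or_mapping or {})
    errors: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a YAML mapping"])
    _check_keys(raw, _TOP_KEYS, "top level", errors)
    cfg = RunConfig()

    if "seed" in raw:
        try:
            cfg.seed = int(raw["seed"])
        except (TypeError, ValueError):
            errors.append(f"seed: not an integer ({raw['seed']!r})")
    if "outdir" in raw:
        cfg.outdir = Path(raw["outdir"])
    for name, caster, check in (
        ("pseudocount", float, lambda v: v > 0),
        ("n_bins", int, lambda v: v >= 1),
        ("min_cell_fraction", float, lambda v: 0.0 <= v <= 1.0),
    ):
        if name in raw:
            try:
                val = caster(raw[name])
                if not check(val):
                    raise ValueError
                setattr(cfg, name, val)
            except (TypeError, ValueError):
                errors.append(f"{name}: invalid value {raw[name]!r}")

    if "stages" in raw:
        stages = raw["stages"]
        if not isinstance(stages, list):
            errors.append("stages: must be a list")
        else:
            bad = [s for s in stages if s not in ALL_STAGES]
            for s in bad:
                hint = difflib.get_close_matches(str(s), ALL_STAGES, n=1)
                suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
                errors.append(f"stages: unknown stage {s!r}{suffix}")
            if not bad:
                cfg.stages = tuple(stages)

    if "simulate" in raw and raw["simulate"] is not None:
        sim = raw["simulate"]
        if not isinstance(sim, dict):
            errors.append("simulate: must be a mapping")
        else:
            _check_keys(sim, _SIMULATE_KEYS, "simulate", errors)
            merged = dict(cfg.simulate)
            for key in _SIMULATE_KEYS & set(sim):
                try:
                    merged[key] = (int if key.startswith("n_") else float)(sim[key])
                except (TypeError, ValueError):
                    errors.append(f"simulate.{key}: invalid value {sim[key]!r}")
            cfg.simulate = merged

    if "datasets" in raw and raw["datasets"]:
        entries = raw["datasets"]
        if not isinstance(entries, list):
            errors.append("datasets: must be a list")
            entries = []
        seen: dict[str, int] = {}
        for i, entry in enumerate(entries):
            where = f"datasets[{i}]"
            if not isinstance(entry, dict):
                errors.append(f"{where}: must be a mapping")
                continue
            _check_keys(entry, _DATASET_KEYS, where, errors)
            ds_id = str(entry.get("id", f"dataset{i}"))
            seen[ds_id] = seen.get(ds_id, 0) + 1
            path = entry.get("path")
            if path is None:
                errors.append(f"{where}: missing required key 'path'")
                continue
            path = Path(path)
            if not path.exists():
                errors.append(f"{where}: path does not exist: {path}")
            fmt = entry.get("format", "mtx_triplet")
            if fmt not in ("mtx_triplet", "tsv_dense"):
                errors.append(f"{where}: unknown format {fmt!r}")
            protocol = entry.get("protocol", "full_length")
            if protocol not in ("full_length", "umi"):
                errors.append(f"{where}: unknown protocol {protocol!r}")
            thresholds = None
            if "qc_preset" in entry and "thresholds" in entry:
                errors.append(f"{where}: give qc_preset or thresholds, not both")
            elif "qc_preset" in entry:
                preset = str(entry["qc_preset"])
                if preset not in THRESHOLD_PRESETS:
                    hint = difflib.get_close_matches(preset, THRESHOLD_PRESETS, n=1)
                    suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
                    errors.append(f"{where}: unknown qc_preset {preset!r}{suffix}")
                else:
                    thresholds = THRESHOLD_PRESETS[preset]
            elif "thresholds" in entry:
                thr = entry["thresholds"] or {}
                _check_keys(thr, _THRESHOLD_KEYS, f"{where}.thresholds", errors)
                try:
                    thresholds = QCThresholds(
                        max_dropout=float(thr.get("max_dropout", 1.0)),
                        min_library_size=float(thr.get("min_library_size", 0.0)),
                        max_spikein_fraction=(
                            None if thr.get("max_spikein_fraction") is None
                            else float(thr["max_spikein_fraction"])
                        ),
                    )
                except (TypeError, ValueError) as exc:
                    errors.append(f"{where}.thresholds: {exc}")
            cfg.datasets.append(
                DatasetEntry(ds_id, path, fmt, protocol, thresholds)
            )
        dupes = sorted(k for k, v in seen.items() if v > 1)
        if dupes:
            errors.append(f"datasets: duplicate dataset id(s): {dupes}")

    if "gene_filter" in raw and raw["gene_filter"] is not None:
        gf = raw["gene_filter"]
        if not isinstance(gf, dict):
            errors.append("gene_filter: must be a mapping")
        else:
            _check_keys(gf, _GENE_FILTER_KEYS, "gene_filter", errors)
            try:
                cfg.gene_filter = GeneFilterPolicy(
                    max_zero_fraction=float(gf.get("max_zero_fraction", 0.90)),
                    excluded_classes=frozenset(gf.get("excluded_classes",
                                                      ("mito", "ribo"))),
                    require_curated=bool(gf.get("require_curated", True)),
                    require_length=bool(gf.get("require_length", True)),
                )
            except (TypeError, ValueError) as exc:
                errors.append(f"gene_filter: {exc}")

    if "groups" in raw and raw["groups"] is not None:
        groups = raw["groups"]
        if not isinstance(groups, dict) or set(groups) - {"a", "b"}:
            errors.append("groups: must be a mapping with keys 'a' and 'b'")
        else:
            cfg.groups = {k: list(v) for k, v in groups.items()}

    if "enrich" in raw and raw["enrich"] is not None:
        en = raw["enrich"]
        _check_keys(en, _ENRICH_KEYS, "enrich", errors)
        if "gmt" in en:
            gmt = Path(en["gmt"])
            if not gmt.exists():
                errors.append(f"enrich.gmt: path does not exist: {gmt}")
            cfg.enrich_gmt = gmt
        if "fdr_alpha" in en:
            cfg.enrich_fdr_alpha = float(en["fdr_alpha"])

    if "de" in raw and raw["de"] is not None:
        de = raw["de"]
        _check_keys(de, _DE_KEYS, "de", errors)
        if "lfc_cutoff" in de:
            cfg.de_lfc_cutoff = float(de["lfc_cutoff"])
        if "alpha" in de:
            cfg.de_alpha = float(de["alpha"])
        if "condition_column" in de:
            cfg.de_condition_column = str(de["condition_column"])

    if errors:
        raise ConfigError(errors)
    return cfg
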