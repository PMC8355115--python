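"""YAML configuration loading for the command-line pipeline."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from .attribution import Thresholds
from .geogrid import GridSpec
from .otu_tables import FilterConfig
from .pipeline import PipelineConfig


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Build a PipelineConfig from a keyed YAML file plus CLI overrides.

    Recognized keys (all optional; defaults are the published operating
    point)::

        filter:     {min_total_reads, min_replicates_present, min_rel_abundance}
        grid:       {cell_km, center: [lon, lat], width_km, height_km}
        thresholds: {tp_cutoff, at5pe_cutoff_km, min_mapped_otus}
        gmm:        {k_max, n_rep}
        min_cell_occurrences, seed
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if overrides:
        for key, value in overrides.items():
            if value is None:
                continue
            section, _, leaf = key.partition(".")
            if leaf:
                raw.setdefault(section, {})[leaf] = value
            else:
                raw[section] = value

    grid_kw = dict(raw.get("grid", {}))
    if "center" in grid_kw:
        grid_kw["center"] = tuple(grid_kw["center"])
    gmm = raw.get("gmm", {})
    return PipelineConfig(
        filter=FilterConfig(**raw.get("filter", {})),
        grid=GridSpec(**grid_kw),
        thresholds=Thresholds(**raw.get("thresholds", {})),
        gmm_k_max=int(gmm.get("k_max", 10)),
        gmm_n_rep=int(gmm.get("n_rep", 100)),
        peak_mode=str(raw.get("peak_mode", "density")),
        min_cell_occurrences=int(raw.get("min_cell_occurrences", 2)),
        seed=int(raw.get("seed", 0)),
    )


def config_digest(cfg: PipelineConfig) -> str:
    """Stable hash of every pipeline tunable, for run manifests."""
    payload = {
        "filter": vars(cfg.filter),
        "grid": {
            "cell_km": cfg.grid.cell_km,
            "center": list(cfg.grid.center),
            "width_km": cfg.grid.width_km,
            "height_km": cfg.grid.height_km,
        },
        "thresholds": vars(cfg.thresholds),
        "gmm_k_max": cfg.gmm_k_max,
        "gmm_n_rep": cfg.gmm_n_rep,
        "peak_mode": cfg.peak_mode,
        "min_cell_occurrences": cfg.min_cell_occurrences,
        "seed": cfg.seed,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_path, cfg: PipelineConfig, inputs: list) -> None:
    """Record config hash, seed and input checksums needed to reproduce a run."""
    manifest = {
        "config_sha256": config_digest(cfg),
        "seed": cfg.seed,
        "inputs": {str(Path(p)): file_checksum(p) for p in inputs},
    }
    with open(out_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
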