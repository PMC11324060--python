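"""End-to-end run orchestration with a reproducibility manifest.

Stage order: standardize -> fragment catalog -> combination analysis ->
NP reference -> status assignment -> merge-back. The status of every
deduplicated molecule is merged back onto the full standardized input by
InChIKey; entries that are neither PNP, NPL nor NP are NonPNP. All
record-level work goes through :func:`pnpkit.standardize.chunked_map`, whose
output is independent of the chunk size by contract.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .analysis import summarize_library
from .catalog import build_catalog, write_catalog
from .combinations import MoleculeAnalysis, analyze_molecule
from .standardize import (
    ChunkFailure,
    MoleculeRecord,
    PipelineConfig,
    chunked_map,
    deduplicate,
    read_molecule_table,
    standardize_record,
    write_molecule_table,
)
from .status import build_np_reference, classify_molecule

logger = logging.getLogger(__name__)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    input_digests: dict[str, str] = field(default_factory=dict)
    output_digests: dict[str, str] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    version: str = ""
    failed_stage: str | None = None

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    for key in ("library", "fragments", "np_library", "out_dir"):
        if key not in cfg:
            raise ValueError(f"{path}: missing required config key {key!r}")
    return cfg


def _pipeline_config(cfg: dict) -> PipelineConfig:
    return PipelineConfig(
        chunk_size=int(cfg.get("chunk_size", 100)),
        timeout_s=float(cfg.get("timeout_s", 50.0)),
        random_seed=int(cfg.get("random_seed", 0)),
        connection_cutoff=int(cfg.get("connection_cutoff", 3)),
        fcg_compare_level=str(cfg.get("fcg_compare_level", "edge")),
        deglycosylate=bool(cfg.get("deglycosylate", True)),
    )


def standardize_library(
    records: list[MoleculeRecord], config: PipelineConfig
) -> list[MoleculeRecord]:
    """Standardize records through the chunked runner; failures are kept as
    records carrying a failure reason."""
    results = chunked_map(
        records, lambda r: standardize_record(r, deglyco=config.deglycosylate), config
    )
    out: list[MoleculeRecord] = []
    for rec, res in zip(records, results):
        if isinstance(res, ChunkFailure):
            rec.failure_reason = res.reason
            rec.passed_filters = False
            out.append(rec)
        else:
            out.append(res)
    return out


def fcg_table(
    records: list[MoleculeRecord], analyses: list[MoleculeAnalysis | ChunkFailure]
) -> pd.DataFrame:
    rows = []
    for rec, analysis in zip(records, analyses):
        if isinstance(analysis, ChunkFailure):
            continue
        for i, fcg in enumerate(analysis.fcgs):
            rows.append(
                {
                    "inchikey": rec.inchikey,
                    "fcg_index": i,
                    "signature": fcg.signature,
                    "n_edges": len(fcg.edges),
                    "edges": ";".join(fcg.edge_strings),
                }
            )
    return pd.DataFrame(rows, columns=["inchikey", "fcg_index", "signature", "n_edges", "edges"])


def run_pipeline(config_path: str | Path) -> RunManifest:
    """Run the full analysis described by a YAML config file.

    Writes standardized/status tables, the FCG table, the NP reference, a
    summary and the manifest into ``out_dir``. Raises on stage failure after
    saving a manifest that records the failed stage.
    """
    cfg = load_config(config_path)
    config = _pipeline_config(cfg)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, version=__version__)
    for key in ("library", "fragments", "np_library"):
        manifest.input_digests[key] = _sha256(cfg[key])

    stage = "standardize"
    try:
        records = read_molecule_table(cfg["library"], cfg.get("library_format", "smiles-tsv"))
        manifest.counts["library_read"] = len(records)
        records = standardize_library(records, config)
        unique, n_dup = deduplicate(records)
        manifest.counts["library_duplicates"] = n_dup
        manifest.counts["library_deduplicated"] = len(unique)
        logger.info("standardize: %d read, %d duplicates", len(records), n_dup)

        stage = "catalog"
        frag_records = read_molecule_table(cfg["fragments"], "smiles-tsv")
        catalog = build_catalog([r.smiles_input for r in frag_records])
        manifest.counts["catalog_size"] = len(catalog)
        write_catalog(catalog, out_dir / "catalog.tsv")
        logger.info("catalog: %d fragments", len(catalog))

        stage = "np_reference"
        np_records = read_molecule_table(cfg["np_library"], cfg.get("np_library_format", "smiles-tsv"))
        np_records = standardize_library(np_records, config)
        np_unique, _ = deduplicate(np_records)
        reference = build_np_reference(np_unique, catalog, config)
        reference.save(out_dir / "np_ref.json")
        manifest.counts["np_library"] = len(np_unique)
        manifest.counts["np_signatures"] = len(reference.np_signatures)

        stage = "classify"
        analyzable = [r for r in unique if r.passed_filters and r.smiles_std]
        analyses = chunked_map(
            analyzable,
            lambda r: analyze_molecule(r.smiles_std, catalog, config.connection_cutoff),
            config,
        )
        fcgs_df = fcg_table(analyzable, analyses)
        fcgs_df.to_csv(out_dir / "fcg.tsv", sep="\t", index=False)

        stage = "status"
        status_by_key: dict[str, str] = {}
        for rec, analysis in zip(analyzable, analyses):
            if isinstance(analysis, ChunkFailure):
                rec.failure_reason = analysis.reason
                rec.status = "NonPNP"
            else:
                rec.status = classify_molecule(
                    rec, analysis.fcgs, reference, config.fcg_compare_level
                )
            status_by_key[rec.inchikey] = rec.status

        stage = "merge_back"
        for rec in records:
            rec.status = status_by_key.get(rec.inchikey, "NonPNP")
        write_molecule_table(records, out_dir / "status.tsv")
        for s in ("PNP", "NPL", "NP", "NonPNP"):
            manifest.counts[f"status_{s}"] = sum(1 for r in records if r.status == s)

        stage = "summarize"
        status_df = pd.DataFrame(
            {
                "inchikey": [r.inchikey for r in unique],
                "status": [status_by_key.get(r.inchikey, "NonPNP") for r in unique],
            }
        )
        summary = summarize_library(status_df, fcgs_df)
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(summary.to_dict(), fh, indent=1, sort_keys=True)
    except Exception:
        manifest.failed_stage = stage
        manifest.save(out_dir / "manifest.json")
        raise

    for name in ("status.tsv", "fcg.tsv", "catalog.tsv", "np_ref.json", "summary.json"):
        manifest.output_digests[name] = _sha256(out_dir / name)
    manifest.save(out_dir / "manifest.json")
    return manifest
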