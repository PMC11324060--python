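"""Library-level statistics and scaffold-based screening-subset selection.

Combination-type statistics follow the convention of reporting over PNP
molecules only: each pairwise combination string ``a:b:ctype`` of a PNP
molecule contributes one typed edge; type percentages are relative to all
typed edges and the ratio representation rescales so that the monopodal
connection (cm) reads 100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import FilterCatalog

from .catalog import murcko_scaffold
from .standardize import MoleculeRecord, standardize_structure

logger = logging.getLogger(__name__)


@dataclass
class LibrarySummary:
    status_counts: dict[str, int]
    ctype_percent: dict[str, float]
    ctype_ratio: dict[str, float]
    top_fragments: list[tuple[int, float]]
    top_combinations: list[tuple[str, float]]

    def to_dict(self) -> dict:
        return {
            "status_counts": self.status_counts,
            "ctype_percent": self.ctype_percent,
            "ctype_ratio": self.ctype_ratio,
            "top_fragments": [[int(f), p] for f, p in self.top_fragments],
            "top_combinations": [[s, p] for s, p in self.top_combinations],
        }


def summarize_library(
    status_table: pd.DataFrame, fcg_table: pd.DataFrame, top_n: int = 10
) -> LibrarySummary:
    """Aggregate statuses and PNP combination statistics.

    ``status_table`` needs columns ``inchikey`` and ``status`` (one row per
    deduplicated molecule); ``fcg_table`` needs ``inchikey`` and ``edges``
    (semicolon-joined ``a:b:ctype`` strings, one row per FCG).
    """
    if status_table.empty:
        logger.warning("empty status table; empty summary")
        return LibrarySummary({}, {}, {}, [], [])
    status_counts = status_table["status"].value_counts().to_dict()

    pnp_keys = set(status_table.loc[status_table["status"] == "PNP", "inchikey"])
    edge_strings: list[str] = []
    if not fcg_table.empty:
        for _, row in fcg_table.iterrows():
            if row["inchikey"] in pnp_keys and row["edges"]:
                edge_strings.extend(str(row["edges"]).split(";"))

    ctype_percent: dict[str, float] = {}
    ctype_ratio: dict[str, float] = {}
    top_fragments: list[tuple[int, float]] = []
    top_combinations: list[tuple[str, float]] = []
    if edge_strings:
        edges = pd.DataFrame(
            [s.rsplit(":", 1) + [s] for s in edge_strings],
            columns=["pair", "ctype", "combination"],
        )
        ct = edges["ctype"].value_counts()
        ctype_percent = (100.0 * ct / ct.sum()).round(6).to_dict()
        if "cm" in ct:
            ctype_ratio = (100.0 * ct / ct["cm"]).round(6).to_dict()
        frag_ids = pd.Series(
            [int(f) for pair in edges["pair"] for f in pair.split(":")]
        ).value_counts()
        frag_pct = 100.0 * frag_ids / len(edges)  # percent of all PNP combinations
        top_fragments = [(int(i), float(round(p, 4))) for i, p in frag_pct.head(top_n).items()]
        combo = edges["combination"].value_counts()
        combo_pct = 100.0 * combo / combo.sum()
        top_combinations = [(str(s), float(round(p, 4))) for s, p in combo_pct.head(top_n).items()]

    return LibrarySummary(
        status_counts={str(k): int(v) for k, v in status_counts.items()},
        ctype_percent={str(k): float(v) for k, v in ctype_percent.items()},
        ctype_ratio={str(k): float(v) for k, v in ctype_ratio.items()},
        top_fragments=top_fragments,
        top_combinations=top_combinations,
    )


# ---------------------------------------------------------------------------
# Scaffold-based subset selection for cell-painting screening


def scaffold_key(smiles_std: str) -> tuple[str | None, int]:
    """Racemic InChIKey and heavy-atom count of a molecule's Murcko scaffold."""
    scaffold = murcko_scaffold(smiles_std)
    if scaffold is None:
        return None, 0
    smiles, inchikey = standardize_structure(scaffold)
    return inchikey, Chem.MolFromSmiles(smiles).GetNumHeavyAtoms()


def select_cpa_subset(
    pnp_records: Sequence[MoleculeRecord],
    scaffold_heavy_atoms: int = 17,
    min_group: int = 4,
    n_scaffolds: int = 250,
    per_scaffold: int = 4,
    seed: int = 0,
) -> list[MoleculeRecord]:
    """Scaffold-diverse random subset of PNPs for screening.

    Records are grouped by the racemic InChIKey of their Murcko scaffold;
    only groups whose scaffold has exactly ``scaffold_heavy_atoms`` heavy
    atoms and at least ``min_group`` members qualify. ``n_scaffolds`` groups
    and then ``per_scaffold`` members per group are drawn uniformly without
    replacement; groups and members are pre-sorted so a seed maps to one
    selection on any platform.
    """
    groups: dict[str, list[MoleculeRecord]] = {}
    for rec in pnp_records:
        if rec.smiles_std is None:
            continue
        key, n_heavy = scaffold_key(rec.smiles_std)
        if key is None or n_heavy != scaffold_heavy_atoms:
            continue
        groups.setdefault(key, []).append(rec)
    qualifying = {k: v for k, v in groups.items() if len(v) >= min_group}
    if len(qualifying) < n_scaffolds:
        raise ValueError(
            f"only {len(qualifying)} qualifying scaffold groups; need {n_scaffolds}"
        )
    rng = np.random.default_rng(seed)
    keys = sorted(qualifying)
    chosen_keys = rng.choice(len(keys), size=n_scaffolds, replace=False)
    selected: list[MoleculeRecord] = []
    for ki in sorted(chosen_keys):
        members = sorted(qualifying[keys[ki]], key=lambda r: r.source_id)
        picks = rng.choice(len(members), size=per_scaffold, replace=False)
        selected.extend(members[i] for i in sorted(picks))
    return selected


# ---------------------------------------------------------------------------
# PAINS triage

_PAINS_CATALOG: FilterCatalog.FilterCatalog | None = None


def _pains_catalog() -> FilterCatalog.FilterCatalog:
    global _PAINS_CATALOG
    if _PAINS_CATALOG is None:
        params = FilterCatalog.FilterCatalogParams()
        params.AddCatalog(FilterCatalog.FilterCatalogParams.FilterCatalogs.PAINS)
        _PAINS_CATALOG = FilterCatalog.FilterCatalog(params)
    return _PAINS_CATALOG


def pains_filter(records: Sequence[MoleculeRecord]) -> list[MoleculeRecord]:
    """Remove records matching any public PAINS pattern; removals are logged."""
    catalog = _pains_catalog()
    kept: list[MoleculeRecord] = []
    for rec in records:
        smiles = rec.smiles_std or rec.smiles_input
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            kept.append(rec)
            continue
        match = catalog.GetFirstMatch(mol)
        if match is not None:
            logger.info("PAINS %s removed %s", match.GetDescription(), rec.source_id)
            continue
        kept.append(rec)
    return kept
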