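"""PNP / NPL / NP / NonPNP status assignment against an NP reference.

The reference holds the identities (racemic InChIKeys) of the natural-product
library and the set of all fragment-combination signatures observed in it.
A molecule is then:

* NP     — structurally identical to a reference NP (identity wins over any
           combination evidence);
* PNP    — carries at least one fragment combination not observed in any NP;
* NPL    — carries combinations, all of which occur in NPs;
* NonPNP — no classifiable combination (no hits, discarded pairs only,
           filter failure, or processing failure).

Comparison granularity is configurable: at the default ``edge`` level the
novelty test is per pairwise combination string; at ``graph`` level it is per
whole-FCG signature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .catalog import FragmentEntry
from .combinations import FCG, MoleculeAnalysis, analyze_molecule
from .standardize import MoleculeRecord, PipelineConfig

STATUSES = ("PNP", "NPL", "NP", "NonPNP")


@dataclass
class NPReference:
    np_inchikeys: set[str] = field(default_factory=set)
    np_signatures: set[str] = field(default_factory=set)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "np_inchikeys": sorted(self.np_inchikeys),
                    "np_signatures": sorted(self.np_signatures),
                },
                fh,
                indent=1,
            )

    @classmethod
    def load(cls, path: str | Path) -> "NPReference":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            np_inchikeys=set(data["np_inchikeys"]),
            np_signatures=set(data["np_signatures"]),
        )


def _comparison_keys(fcgs: Sequence[FCG], level: str) -> list[str]:
    """The signature keys a molecule contributes/compares at a given level."""
    if level == "graph":
        return [f.signature for f in fcgs]
    keys: list[str] = []
    for f in fcgs:
        keys.extend(f.edge_strings)
    return keys


def build_np_reference(
    np_library: Sequence[MoleculeRecord],
    catalog: list[FragmentEntry],
    config: PipelineConfig | None = None,
) -> NPReference:
    """Build the NP identity + signature reference from a standardized,
    filtered and deduplicated NP library."""
    if not np_library:
        raise ValueError("empty NP library")
    config = config or PipelineConfig()
    ref = NPReference()
    for rec in np_library:
        if rec.inchikey is None:
            continue
        ref.np_inchikeys.add(rec.inchikey)
        if not rec.passed_filters or rec.smiles_std is None:
            continue
        analysis = analyze_molecule(rec.smiles_std, catalog, config.connection_cutoff)
        ref.np_signatures.update(_comparison_keys(analysis.fcgs, config.fcg_compare_level))
    return ref


def classify_keys(
    inchikey: str | None,
    keys: Sequence[str],
    reference: NPReference,
    passed_filters: bool = True,
) -> str:
    """Status from an InChIKey and pre-extracted comparison signatures.

    Precedence: NP identity first; then any novel signature makes the
    molecule PNP even if it also carries known (NPL) combinations; all-known
    signatures give NPL; no signatures (or upstream failure) gives NonPNP.
    """
    if not passed_filters:
        return "NonPNP"
    if inchikey is not None and inchikey in reference.np_inchikeys:
        return "NP"
    if not keys:
        return "NonPNP"
    if any(k not in reference.np_signatures for k in keys):
        return "PNP"
    return "NPL"


def classify_molecule(
    record: MoleculeRecord,
    fcgs: Sequence[FCG],
    reference: NPReference,
    fcg_compare_level: str = "edge",
) -> str:
    """Assign one status to a deduplicated molecule (see classify_keys)."""
    return classify_keys(
        record.inchikey,
        _comparison_keys(fcgs, fcg_compare_level),
        reference,
        passed_filters=record.passed_filters,
    )
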