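"""Natural-product fragment catalog: Murcko scaffolding + racemic dedup.

The catalog entering fragment matching is built from an input fragment set by
taking each fragment's Murcko scaffold, standardizing and racemizing it,
deduplicating by InChIKey and deliberately excluding benzene (it would match
nearly everything and carries no NP information).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .standardize import StandardizationError, standardize_structure

logger = logging.getLogger(__name__)

BENZENE_INCHIKEY = Chem.MolToInchiKey(Chem.MolFromSmiles("c1ccccc1"))


@dataclass
class FragmentEntry:
    frag_id: int
    smiles: str
    inchikey: str
    num_heavy_atoms: int
    _mol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    @property
    def mol(self) -> Chem.Mol:
        """Cached RDKit molecule used as the substructure query."""
        if self._mol is None:
            self._mol = Chem.MolFromSmiles(self.smiles)
        return self._mol


def murcko_scaffold(smiles: str) -> str | None:
    """Return the canonical Murcko scaffold SMILES, or None for acyclic input.

    The scaffold keeps ring systems and the linkers between them; side chains
    are removed.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StandardizationError(f"unparseable SMILES: {smiles!r}")
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return None
    return Chem.MolToSmiles(scaffold)


def build_catalog(fragment_smiles: Sequence[str]) -> list[FragmentEntry]:
    """Build the fragment catalog from raw fragment SMILES.

    Per input: Murcko scaffold -> standardize/racemize -> dedup by InChIKey,
    benzene excluded. ``frag_id`` is assigned in first-seen order. Acyclic
    inputs are skipped (logged); an all-acyclic input set is an error.
    """
    if not fragment_smiles:
        raise ValueError("empty fragment set")
    entries: list[FragmentEntry] = []
    seen: set[str] = set()
    next_id = 0
    n_skipped = 0
    for smi in fragment_smiles:
        try:
            scaffold = murcko_scaffold(smi)
        except StandardizationError:
            n_skipped += 1
            logger.warning("fragment %r unparseable; skipped", smi)
            continue
        if scaffold is None:
            n_skipped += 1
            logger.info("fragment %r is acyclic; skipped", smi)
            continue
        smiles_std, inchikey = standardize_structure(scaffold)
        if inchikey == BENZENE_INCHIKEY:
            logger.info("benzene scaffold excluded (%r)", smi)
            continue
        if inchikey in seen:
            continue
        seen.add(inchikey)
        mol = Chem.MolFromSmiles(smiles_std)
        entries.append(
            FragmentEntry(
                frag_id=next_id,
                smiles=smiles_std,
                inchikey=inchikey,
                num_heavy_atoms=mol.GetNumHeavyAtoms(),
            )
        )
        next_id += 1
    if not entries:
        raise ValueError("no cyclic fragments in input set")
    return entries


def read_catalog(path: str | Path) -> list[FragmentEntry]:
    entries = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: header.index(name) for name in ("frag_id", "smiles", "inchikey", "num_heavy_atoms")}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            entries.append(
                FragmentEntry(
                    frag_id=int(parts[idx["frag_id"]]),
                    smiles=parts[idx["smiles"]],
                    inchikey=parts[idx["inchikey"]],
                    num_heavy_atoms=int(parts[idx["num_heavy_atoms"]]),
                )
            )
    return entries


def write_catalog(entries: Iterable[FragmentEntry], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("frag_id\tsmiles\tinchikey\tnum_heavy_atoms\n")
        for e in entries:
            fh.write(f"{e.frag_id}\t{e.smiles}\t{e.inchikey}\t{e.num_heavy_atoms}\n")
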