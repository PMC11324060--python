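"""Spatial complexity score (SPS) and its heavy-atom-normalized form (nSPS).

Each heavy atom contributes the product of four terms:

* hybridization: sp = 1, sp2 = 2, sp3 = 3, anything else = 4;
* stereo: 2 for atoms that are (potential) stereocenters or belong to a
  stereo double bond, else 1;
* ring: 2 for non-aromatic ring atoms (aromatic rings are not promoted),
  else 1;
* branching: the number of heavy-atom neighbors, squared.

SPS is the sum over heavy atoms; nSPS divides by the heavy-atom count and is
therefore a complexity density, comparable across molecule sizes. Potential
(unassigned) stereocenters count as stereogenic, so scores computed on
racemized structures match those of the corresponding stereo-annotated ones.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem
from rdkit.Chem import rdmolops

_HYBRIDIZATION_TERM = {
    Chem.HybridizationType.SP: 1,
    Chem.HybridizationType.SP2: 2,
    Chem.HybridizationType.SP3: 3,
}
_OTHER_HYBRIDIZATION_TERM = 4
_STEREO_TERM = 2
_RING_TERM = 2


@dataclass(frozen=True)
class ComplexityScore:
    sps: float
    nsps: float


def atom_spatial_score(
    hybridization: Chem.HybridizationType,
    is_stereo: bool,
    in_nonaromatic_ring: bool,
    n_heavy_neighbors: int,
) -> int:
    """Per-atom spatial score: hybridization x stereo x ring x neighbors^2."""
    h = _HYBRIDIZATION_TERM.get(hybridization, _OTHER_HYBRIDIZATION_TERM)
    s = _STEREO_TERM if is_stereo else 1
    r = _RING_TERM if in_nonaromatic_ring else 1
    return h * s * r * n_heavy_neighbors * n_heavy_neighbors


def _stereo_atom_indices(mol: Chem.Mol) -> set[int]:
    """Atoms counted as stereogenic: (potential) tetrahedral stereocenters
    plus both ends of double bonds with assigned or potential E/Z stereo."""
    stereo: set[int] = set()
    for idx, _label in Chem.FindMolChiralCenters(
        mol, includeUnassigned=True, includeCIP=False, useLegacyImplementation=False
    ):
        stereo.add(idx)
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.DOUBLE:
            continue
        if bond.GetStereo() != Chem.BondStereo.STEREONONE:
            stereo.add(bond.GetBeginAtomIdx())
            stereo.add(bond.GetEndAtomIdx())
    return stereo


def sps(mol: Chem.Mol) -> int:
    """Total spatial score of a molecule (integer; hydrogens implicit)."""
    if mol is None or mol.GetNumHeavyAtoms() == 0:
        raise ValueError("SPS requires a molecule with at least one heavy atom")
    work = Chem.Mol(mol)
    rdmolops.FindPotentialStereoBonds(work)
    stereo_atoms = _stereo_atom_indices(work)
    total = 0
    for atom in work.GetAtoms():
        total += atom_spatial_score(
            atom.GetHybridization(),
            atom.GetIdx() in stereo_atoms,
            atom.IsInRing() and not atom.GetIsAromatic(),
            atom.GetDegree(),
        )
    return total


def nsps(source: Chem.Mol | str) -> ComplexityScore:
    """SPS and nSPS for a molecule or SMILES string.

    Invariant to atom ordering and SMILES rendering: the score depends only
    on the molecular graph.
    """
    mol = Chem.MolFromSmiles(source) if isinstance(source, str) else source
    if mol is None:
        raise ValueError(f"unparseable structure: {source!r}")
    total = sps(mol)
    return ComplexityScore(sps=float(total), nsps=total / mol.GetNumHeavyAtoms())
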