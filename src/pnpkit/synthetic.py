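"""Ground-truth synthetic test worlds.

Real inputs to this kind of analysis (vendor catalogs, NP dictionaries,
screening profiles) are external and license-bound. This module builds small
synthetic stand-ins whose expected downstream results are certain by
construction:

* a toy fragment catalog of distinct non-benzene ring scaffolds;
* composed two-fragment molecules realizing each combination type (cm, fe,
  fs, fb, cbe) by explicit atom-index surgery, so the intended type is the
  ground truth — unrealizable requests are skipped loudly, never emitted
  wrong;
* a synthetic compound library plus NP reference with a known PNP / NPL /
  NP / NonPNP label per record;
* a scaffold-group library for subset-selection tests;
* morphological profiles with planted cluster structure.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .catalog import FragmentEntry, build_catalog
from .combinations import find_fragment_hits, resolve_containment
from .profiles import ClusterSubprofile, MorphProfile, compute_induction
from .standardize import MoleculeRecord, standardize_record

logger = logging.getLogger(__name__)

#: raw input for the toy catalog; benzene is included on purpose so that the
#: catalog builder's benzene exclusion is always exercised
TOY_FRAGMENT_SMILES = [
    "c1ccccc1",  # benzene: excluded by build_catalog
    "c1ccncc1",  # pyridine
    "C1CCNCC1",  # piperidine
    "C1CCNC1",  # pyrrolidine
    "C1COCCN1",  # morpholine
    "c1ccsc1",  # thiophene
    "c1ccoc1",  # furan
    "C1CCCC1",  # cyclopentane
    "C1CCOCC1",  # tetrahydropyran
    "c1ccc2[nH]ccc2c1",  # indole
    "c1ccc2ncccc2c1",  # quinoline
]

COMPOSE_TYPES = ("cm", "fe", "fs", "fb", "cbe")


def make_toy_catalog(seed: int = 0) -> list[FragmentEntry]:
    """Deterministic toy fragment catalog (>= 8 entries, benzene absent)."""
    return build_catalog(TOY_FRAGMENT_SMILES)


@dataclass
class ComposedMolecule:
    smiles: str
    frag_ids: tuple[int, int]
    true_ctype: str
    note: str


# ---------------------------------------------------------------------------
# Constructive composition


def _kekulized(mol: Chem.Mol) -> Chem.Mol:
    work = Chem.Mol(mol)
    Chem.Kekulize(work, clearAromaticFlags=True)
    return work


def _carbons_with_hs(mol: Chem.Mol, min_h: int, sp3_only: bool = False) -> list[int]:
    out = []
    for atom in mol.GetAtoms():
        if atom.GetSymbol() != "C" or atom.GetTotalNumHs() < min_h:
            continue
        if sp3_only and any(
            b.GetBondType() != Chem.BondType.SINGLE for b in atom.GetBonds()
        ):
            continue
        out.append(atom.GetIdx())
    return out


def _cc_bonds(mol: Chem.Mol, min_h: int) -> list[tuple[int, int]]:
    """Ring C-C bonds whose atoms each carry >= min_h hydrogens and no
    exocyclic substituents (degree 2)."""
    out = []
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if not bond.IsInRing():
            continue
        if a.GetSymbol() != "C" or b.GetSymbol() != "C":
            continue
        if a.GetTotalNumHs() < min_h or b.GetTotalNumHs() < min_h:
            continue
        if a.GetDegree() != 2 or b.GetDegree() != 2:
            continue
        out.append((a.GetIdx(), b.GetIdx()))
    return out


def _ring_triples(mol: Chem.Mol) -> list[tuple[int, int, int]]:
    """Consecutive all-carbon, all-single-bond, unsubstituted triples in
    non-fused rings."""
    triples = []
    ri = mol.GetRingInfo()
    for ring in ri.AtomRings():
        if any(ri.NumAtomRings(i) > 1 for i in ring):
            continue
        n = len(ring)
        for s in range(n):
            tri = (ring[s], ring[(s + 1) % n], ring[(s + 2) % n])
            atoms = [mol.GetAtomWithIdx(i) for i in tri]
            if any(a.GetSymbol() != "C" or a.GetDegree() != 2 for a in atoms):
                continue
            bonds = [
                mol.GetBondBetweenAtoms(tri[0], tri[1]),
                mol.GetBondBetweenAtoms(tri[1], tri[2]),
            ]
            if any(b.GetBondType() != Chem.BondType.SINGLE for b in bonds):
                continue
            triples.append(tri)
    return triples


def _try_sanitize(rw: Chem.RWMol) -> Chem.Mol | None:
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def _matches_at(mol: Chem.Mol, frag: FragmentEntry, atoms: frozenset[int]) -> bool:
    return any(
        frozenset(m) == atoms for m in mol.GetSubstructMatches(frag.mol, uniquify=True)
    )


def _candidate_surgeries(ma: Chem.Mol, mb: Chem.Mol, ctype: str, max_each: int = 6):
    """Yield (RWMol, intended_atoms_a, intended_atoms_b) candidates."""
    na = ma.GetNumAtoms()
    all_a = frozenset(range(na))

    def combined() -> Chem.RWMol:
        return Chem.RWMol(Chem.CombineMols(ma, mb))

    if ctype == "cm":
        for a_at, b_at in itertools.product(
            _carbons_with_hs(ma, 1)[:max_each], _carbons_with_hs(mb, 1)[:max_each]
        ):
            rw = combined()
            rw.AddBond(a_at, na + b_at, Chem.BondType.SINGLE)
            yield rw, all_a, frozenset(range(na, na + mb.GetNumAtoms()))

    elif ctype == "cbe":
        for (a1, a2), (b1, b2) in itertools.product(
            _cc_bonds(ma, 1)[:max_each], _cc_bonds(mb, 1)[:max_each]
        ):
            rw = combined()
            rw.AddBond(a1, na + b1, Chem.BondType.SINGLE)
            rw.AddBond(a2, na + b2, Chem.BondType.SINGLE)
            yield rw, all_a, frozenset(range(na, na + mb.GetNumAtoms()))

    elif ctype == "fs":
        for a_at, b_at in itertools.product(
            _carbons_with_hs(ma, 2, sp3_only=True)[:max_each],
            _carbons_with_hs(mb, 2, sp3_only=True)[:max_each],
        ):
            rw = combined()
            spiro_neighbors = [n.GetIdx() for n in mb.GetAtomWithIdx(b_at).GetNeighbors()]
            for nb in spiro_neighbors:
                rw.AddBond(a_at, na + nb, Chem.BondType.SINGLE)
            rw.RemoveAtom(na + b_at)
            intended_b = frozenset(
                _shifted(i, na, removed=(na + b_at,)) for i in range(na, na + mb.GetNumAtoms()) if i != na + b_at
            ) | {a_at}
            yield rw, all_a, intended_b

    elif ctype == "fe":
        for (u, v), (x, y) in itertools.product(
            _cc_bonds(ma, 1)[:max_each], _cc_bonds(mb, 1)[:max_each]
        ):
            for bx, by in ((x, y), (y, x)):
                rw = combined()
                mapping = {na + bx: u, na + by: v}
                ok = True
                for src, dst in mapping.items():
                    for j in [nb.GetIdx() for nb in rw.GetAtomWithIdx(src).GetNeighbors()]:
                        if j in mapping:
                            continue
                        bond = rw.GetBondBetweenAtoms(src, j)
                        if rw.GetBondBetweenAtoms(dst, j) is not None:
                            ok = False
                            break
                        rw.AddBond(dst, j, bond.GetBondType())
                    if not ok:
                        break
                if not ok:
                    continue
                removed = tuple(sorted(mapping, reverse=True))
                for idx in removed:
                    rw.RemoveAtom(idx)
                intended_b = frozenset(
                    _shifted(i, na, removed=removed)
                    for i in range(na, na + mb.GetNumAtoms())
                    if i not in mapping
                ) | {u, v}
                yield rw, all_a, intended_b

    elif ctype == "fb":
        for (p0, p1, p2), (q0, q1, q2) in itertools.product(
            _ring_triples(ma)[:max_each], _ring_triples(mb)[:max_each]
        ):
            for qs in ((q0, q1, q2), (q2, q1, q0)):
                rw = combined()
                mapping = {na + qs[0]: p0, na + qs[1]: p1, na + qs[2]: p2}
                ok = True
                for src, dst in mapping.items():
                    for j in [nb.GetIdx() for nb in rw.GetAtomWithIdx(src).GetNeighbors()]:
                        if j in mapping:
                            continue
                        bond = rw.GetBondBetweenAtoms(src, j)
                        if rw.GetBondBetweenAtoms(dst, j) is not None:
                            ok = False
                            break
                        rw.AddBond(dst, j, bond.GetBondType())
                    if not ok:
                        break
                if not ok:
                    continue
                removed = tuple(sorted(mapping, reverse=True))
                for idx in removed:
                    rw.RemoveAtom(idx)
                intended_b = frozenset(
                    _shifted(i, na, removed=removed)
                    for i in range(na, na + mb.GetNumAtoms())
                    if i not in mapping
                ) | {p0, p1, p2}
                yield rw, all_a, intended_b
    else:
        raise ValueError(f"unknown composition type: {ctype!r}")


def _shifted(idx: int, na: int, removed: tuple[int, ...]) -> int:
    """Atom index after removing ``removed`` (sorted desc) from an RWMol."""
    return idx - sum(1 for r in removed if r < idx)


def compose_molecule(
    frag_a: FragmentEntry, frag_b: FragmentEntry, ctype: str
) -> ComposedMolecule | None:
    """Compose two catalog fragments with the requested combination type.

    Returns None (an explicit skip) when the request is not chemically
    realizable for the pair: no valid attachment atoms, sanitization failure,
    or the fragments no longer match at their intended positions in any
    candidate product.
    """
    if ctype not in COMPOSE_TYPES:
        raise ValueError(f"composition type must be one of {COMPOSE_TYPES}")
    ma, mb = _kekulized(frag_a.mol), _kekulized(frag_b.mol)
    for rw, atoms_a, atoms_b in _candidate_surgeries(ma, mb, ctype):
        product = _try_sanitize(rw)
        if product is None:
            continue
        if not (_matches_at(product, frag_a, atoms_a) and _matches_at(product, frag_b, atoms_b)):
            continue
        return ComposedMolecule(
            smiles=Chem.MolToSmiles(product),
            frag_ids=(frag_a.frag_id, frag_b.frag_id),
            true_ctype=ctype,
            note=f"{frag_a.smiles}+{frag_b.smiles}:{ctype}",
        )
    logger.info(
        "skip: %s between %s and %s not realizable", ctype, frag_a.smiles, frag_b.smiles
    )
    return None


def _is_clean(smiles: str, catalog: list[FragmentEntry], frag_ids: tuple[int, int]) -> bool:
    """True when, after containment resolution, the molecule carries exactly
    the two intended fragment hits (so its single combination edge is the
    whole ground truth)."""
    mol = Chem.MolFromSmiles(smiles)
    hits = resolve_containment(find_fragment_hits(mol, catalog))
    return sorted(h.frag_id for h in hits) == sorted(frag_ids)


def enumerate_composites(
    catalog: list[FragmentEntry],
    ctypes: tuple[str, ...] = COMPOSE_TYPES,
    strict: bool = True,
) -> list[ComposedMolecule]:
    """All realizable (fragment pair, ctype) constructs from a catalog.

    With ``strict`` (default) constructs with incidental extra catalog hits
    are dropped, so each molecule's combination content is exactly one known
    edge.
    """
    out: list[ComposedMolecule] = []
    for i, frag_a in enumerate(catalog):
        for frag_b in catalog[i:]:
            for ctype in ctypes:
                composed = compose_molecule(frag_a, frag_b, ctype)
                if composed is None:
                    continue
                if strict and not _is_clean(composed.smiles, catalog, composed.frag_ids):
                    logger.info("skip (extra hits): %s", composed.note)
                    continue
                out.append(composed)
    return out


def _decorate(smiles: str, chain_len: int) -> str | None:
    """Append a linear alkyl chain at the first substitutable carbon."""
    mol = Chem.MolFromSmiles(smiles)
    sites = _carbons_with_hs(mol, 1)
    if not sites:
        return None
    rw = Chem.RWMol(mol)
    prev = sites[0]
    for _ in range(chain_len):
        idx = rw.AddAtom(Chem.Atom(6))
        rw.AddBond(prev, idx, Chem.BondType.SINGLE)
        prev = idx
    product = _try_sanitize(rw)
    return None if product is None else Chem.MolToSmiles(product)


# ---------------------------------------------------------------------------
# Synthetic library with known statuses


DECOY_SMILES = [
    ("decoy_benzene", "c1ccccc1", "no catalog hits (benzene excluded)"),
    ("decoy_cyclopropane", "C1CC1", "ring but no catalog hit"),
    ("decoy_acyclic", "CCCCCO", "fails ring filter"),
    ("decoy_heavy", "C1CCCCC1" + "C" * 70, "fails MW filter"),
    ("decoy_far_apart", "c1ccncc1CCCCCCc1ccncc1", "hits beyond connection cutoff"),
]


def make_synthetic_library(
    n: int, np_fraction: float = 0.2, seed: int = 0
) -> tuple[list[MoleculeRecord], list[MoleculeRecord], dict[str, str]]:
    """A compound library, an NP reference library, and true statuses.

    The library holds composed two-fragment molecules spanning all realizable
    (pair, ctype) constructs (decorated alkyl variants fill up to ``n``) plus
    fixed decoys. A random subset of combination signatures is designated
    "natural": the first molecule per chosen signature is copied into the NP
    library (true status NP), its variants become NPL, molecules with
    un-chosen signatures are PNP and the decoys NonPNP.

    Returns (library_records, np_library_records, truth) with ``truth``
    mapping source_id -> expected status.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    rng = np.random.default_rng(seed)
    catalog = make_toy_catalog()
    composites = enumerate_composites(catalog)
    n_members = max(n - len(DECOY_SMILES), 1)

    # cycle the composite pool with growing decorations; keep inchikeys unique
    members: list[tuple[str, str]] = []  # (smiles, signature)
    seen: set[str] = set()
    round_no = 0
    while len(members) < n_members and round_no < 12:
        for comp in composites:
            if len(members) >= n_members:
                break
            smiles = comp.smiles if round_no == 0 else _decorate(comp.smiles, round_no)
            if smiles is None:
                continue
            key = Chem.MolToInchiKey(Chem.MolFromSmiles(smiles))
            if key in seen:
                continue
            seen.add(key)
            a, b = sorted(comp.frag_ids)
            members.append((smiles, f"{a}:{b}:{comp.true_ctype}"))
        round_no += 1

    signatures = sorted({sig for _, sig in members})
    n_np = max(1, int(round(np_fraction * len(signatures))))
    np_signatures = set(
        np.array(signatures)[rng.choice(len(signatures), size=n_np, replace=False)]
    )

    library: list[MoleculeRecord] = []
    np_library: list[MoleculeRecord] = []
    truth: dict[str, str] = {}
    np_taken: set[str] = set()
    for i, (smiles, sig) in enumerate(members):
        source_id = f"syn_{i:04d}"
        library.append(MoleculeRecord(source_id=source_id, smiles_input=smiles))
        if sig in np_signatures:
            if sig not in np_taken:
                np_taken.add(sig)
                np_library.append(
                    MoleculeRecord(source_id=f"np_{i:04d}", smiles_input=smiles)
                )
                truth[source_id] = "NP"
            else:
                truth[source_id] = "NPL"
        else:
            truth[source_id] = "PNP"
    for decoy_id, smiles, _why in DECOY_SMILES:
        library.append(MoleculeRecord(source_id=decoy_id, smiles_input=smiles))
        truth[decoy_id] = "NonPNP"
    return library, np_library, truth


# ---------------------------------------------------------------------------
# Scaffold-group library for subset selection


_RING_TEMPLATES = [
    ("c1ccccc1", 6),
    ("c1ccncc1", 6),
    ("c1cccnc1", 6),
    ("c1ccsc1", 5),
    ("c1ccoc1", 5),
    ("C1CCCCC1", 6),
    ("C1CCCC1", 5),
    ("C1CCOCC1", 6),
]


def _linker_variants(length: int) -> list[str]:
    variants = ["C" * length]
    for hetero in "ONS":
        for pos in range(1, length - 1):
            variants.append("C" * pos + hetero + "C" * (length - pos - 1))
    return variants


def make_scaffold_library(
    n_groups: int = 300,
    scaffold_heavy_atoms: int = 17,
    seed: int = 0,
    n_undersized: int = 10,
    n_wrong_ha: int = 10,
) -> list[MoleculeRecord]:
    """Standardized records forming >= ``n_groups`` scaffold groups with
    exactly ``scaffold_heavy_atoms``-atom Murcko scaffolds and 4+ members,
    plus a few deliberately disqualified groups (too small, wrong scaffold
    size) that a correct selection must never pick."""
    rng = np.random.default_rng(seed)
    scaffolds: list[str] = []
    seen: set[str] = set()
    for (ra, sa), (rb, sb) in itertools.combinations_with_replacement(_RING_TEMPLATES, 2):
        length = scaffold_heavy_atoms - sa - sb
        if length < 3:
            continue
        for linker in _linker_variants(length):
            smi = f"{ra}{linker}{rb}"
            mol = Chem.MolFromSmiles(smi)
            if mol is None or mol.GetNumHeavyAtoms() != scaffold_heavy_atoms:
                continue
            key = Chem.MolToInchiKey(mol)
            if key in seen:
                continue
            seen.add(key)
            scaffolds.append(Chem.MolToSmiles(mol))
    if len(scaffolds) < n_groups + n_wrong_ha:
        raise ValueError(f"only {len(scaffolds)} scaffolds generated")

    records: list[MoleculeRecord] = []

    def add_group(scaffold: str, size: int, tag: str, gi: int) -> None:
        added = 0
        member_keys: set[str] = set()
        for chain_len in range(1, size + 6):
            smi = _decorate(scaffold, chain_len)
            if smi is None:
                continue
            key = Chem.MolToInchiKey(Chem.MolFromSmiles(smi))
            if key in member_keys:
                continue
            member_keys.add(key)
            rec = MoleculeRecord(source_id=f"{tag}_{gi:04d}_{added}", smiles_input=smi)
            standardize_record(rec, deglyco=False)
            records.append(rec)
            added += 1
            if added >= size:
                break

    for gi in range(n_groups):
        add_group(scaffolds[gi], int(rng.integers(4, 7)), "grp", gi)
    for gi in range(n_undersized):
        add_group(scaffolds[n_groups + gi], 3, "small", gi)
    # wrong scaffold size: drop one linker atom -> 16 heavy atoms
    wrong = 0
    for (ra, sa), (rb, sb) in itertools.combinations_with_replacement(_RING_TEMPLATES, 2):
        if wrong >= n_wrong_ha:
            break
        length = scaffold_heavy_atoms - 1 - sa - sb
        if length < 3:
            continue
        mol = Chem.MolFromSmiles(f"{ra}{'C' * length}{rb}")
        if mol is None or mol.GetNumHeavyAtoms() != scaffold_heavy_atoms - 1:
            continue
        add_group(Chem.MolToSmiles(mol), 5, "wrongha", wrong)
        wrong += 1
    return records


# ---------------------------------------------------------------------------
# Synthetic morphological profiles


def make_profiles(
    n_active: int,
    n_clusters: int,
    n_features: int = 579,
    seed: int = 0,
    subset_size: int = 40,
    novel_fraction: float = 0.3,
) -> tuple[list[MorphProfile], list[ClusterSubprofile], dict[str, str]]:
    """Active profiles with planted cluster structure.

    Each cluster owns a disjoint block of ``subset_size`` features with a
    strong reference vector; member profiles reproduce that vector (scaled,
    plus small noise) so their subprofile correlation is >= 0.9 and their
    induction >= 5%. Novel-activity profiles put their signal on a reserved
    feature block orthogonal to every cluster subset, so they stay
    unassigned. Returns (profiles, subprofiles, truth) with truth mapping
    compound_id -> cluster name or "novel".
    """
    if n_clusters > 13:
        raise ValueError("at most 13 clusters")
    if (n_clusters + 1) * subset_size > n_features:
        raise ValueError("feature blocks exceed profile length")
    rng = np.random.default_rng(seed)

    subprofiles: list[ClusterSubprofile] = []
    for c in range(n_clusters):
        idx = np.arange(c * subset_size, (c + 1) * subset_size)
        values = rng.uniform(4.5, 8.0, size=subset_size) * rng.choice([-1.0, 1.0], size=subset_size)
        subprofiles.append(
            ClusterSubprofile(cluster_name=f"cluster_{c:02d}", feature_subset=idx, values=values)
        )
    novel_block = np.arange(n_clusters * subset_size, (n_clusters + 1) * subset_size)
    novel_values = rng.uniform(4.5, 8.0, size=subset_size) * rng.choice([-1.0, 1.0], size=subset_size)

    n_novel = int(round(novel_fraction * n_active))
    profiles: list[MorphProfile] = []
    truth: dict[str, str] = {}
    for i in range(n_active):
        features = rng.normal(0.0, 0.3, size=n_features)
        if i < n_active - n_novel:
            cluster = subprofiles[i % n_clusters]
            scale = rng.uniform(0.85, 1.2)
            features[cluster.feature_subset] = cluster.values * scale + rng.normal(
                0.0, 0.3, size=subset_size
            )
            label = cluster.cluster_name
        else:
            scale = rng.uniform(0.85, 1.2)
            features[novel_block] = novel_values * scale + rng.normal(0.0, 0.3, size=subset_size)
            label = "novel"
        pid = f"cpd_{i:04d}"
        profile = MorphProfile(compound_id=pid, concentration=10.0, features=features)
        profile.induction = compute_induction(features, n_features=n_features)
        profiles.append(profile)
        truth[pid] = label
    return profiles, subprofiles, truth
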