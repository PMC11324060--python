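"""Fragment matching and the typed fragment-combination taxonomy.

Two catalog fragments matched onto one molecule combine in exactly one way,
decided from the overlap of their atom sets and, for disjoint sets, from the
short bridging paths between them:

fusion family (shared atoms, k = |A ∩ B|):
  * one hit contained in the other      -> ffs (the contained hit is a match
                                          artifact and is discarded globally)
  * k = 1                               -> fs  (spiro fusion)
  * k = 2, shared atoms bonded          -> fe  (edge fusion)
  * k = 3..5                            -> fb  (bridge fusion)
  * k = 2 non-bonded, or k > 5          -> ffo (overlap artifact, discarded)

connection family (k = 0; bridging paths run only through atoms external to
both hits, shortest path at most ``cutoff`` bonds):
  * no path within cutoff               -> cfc (too far apart, no edge)
  * 1 attachment-point pair             -> cm  (monopodal connection)
  * 2 pairs sharing an attachment atom  -> cbs (bipodal spiro)
  * 2 pairs, attachment atoms bonded
    within both fragments               -> cbe (bipodal edge)
  * 2 pairs otherwise                   -> cbb (bipodal bridge)
  * >= 3 pairs                          -> ct  (tripodal or higher)

Typed edges over the hits of one molecule form fragment-combination graphs
(FCGs): the connected components with at least one edge, each carrying a
canonical text signature.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import networkx as nx
from rdkit import Chem

from .catalog import FragmentEntry

#: combination types that appear in FCGs
TYPED = ("cm", "fe", "fb", "fs", "cbs", "cbe", "cbb", "ct")
#: internal discard codes; never appear in FCGs
DISCARD = ("ffs", "ffo", "cfc")


@dataclass(frozen=True)
class FragmentHit:
    """One substructure match of a catalog fragment onto a molecule."""

    frag_id: int
    occurrence: int
    atom_ids: frozenset[int]


@dataclass(frozen=True)
class CombinationEdge:
    hit_a: FragmentHit
    hit_b: FragmentHit
    ctype: str

    def edge_string(self) -> str:
        a, b = sorted((self.hit_a.frag_id, self.hit_b.frag_id))
        return f"{a}:{b}:{self.ctype}"


@dataclass
class FCG:
    """A connected fragment-combination graph with its canonical signature."""

    edges: list[CombinationEdge]
    signature: str = field(init=False)

    def __post_init__(self) -> None:
        self.signature = canonical_signature(self.edges)

    @property
    def edge_strings(self) -> list[str]:
        return sorted(e.edge_string() for e in self.edges)


def canonical_signature(edges: list[CombinationEdge]) -> str:
    """Order-independent text signature of an edge set.

    Each edge renders as ``min(frag_id):max(frag_id):ctype`` (occurrence
    indices dropped, so repeated identical combinations count once); edge
    strings are sorted and joined with ``|``.
    """
    return "|".join(sorted({e.edge_string() for e in edges}))


def find_fragment_hits(mol: Chem.Mol, catalog: list[FragmentEntry]) -> list[FragmentHit]:
    """All substructure matches of all catalog entries, as atom-id sets.

    Symmetry-equivalent matches onto the same atoms are collapsed; hits
    contained in a hit of another fragment are retained here and resolved by
    the containment (ffs) rule before FCG construction.
    """
    hits: list[FragmentHit] = []
    for entry in catalog:
        seen: set[frozenset[int]] = set()
        occurrence = 0
        for match in mol.GetSubstructMatches(entry.mol, uniquify=True, maxMatches=4096):
            atoms = frozenset(match)
            if atoms in seen:
                continue
            seen.add(atoms)
            hits.append(FragmentHit(entry.frag_id, occurrence, atoms))
            occurrence += 1
    return hits


def _attachment_pairs(
    mol: Chem.Mol, set_a: frozenset[int], set_b: frozenset[int], cutoff: int
) -> tuple[dict[tuple[int, int], int], int | None]:
    """Attachment-point pairs between two disjoint hits.

    A pair (a, b) is connected when a path of at most ``cutoff`` bonds leads
    from a ∈ A to b ∈ B through atoms external to both hits (a direct bond is
    a path of length 1). Returns the pairs within cutoff with their shortest
    lengths, plus the overall shortest bridging length found at any distance
    (None when the hits are not bridged at all, e.g. only via other hits'
    interiors beyond the search depth).
    """
    adjacency = {a.GetIdx(): [n.GetIdx() for n in a.GetNeighbors()] for a in mol.GetAtoms()}
    external = set(adjacency) - set_a - set_b
    pairs: dict[tuple[int, int], int] = {}
    shortest: int | None = None
    for a in set_a:
        # BFS from a over external atoms only, depth-limited by cutoff
        dist = {a: 0}
        queue = deque([a])
        while queue:
            x = queue.popleft()
            d = dist[x]
            if d >= cutoff:
                continue
            for y in adjacency[x]:
                if y in set_b:
                    key = (a, y)
                    if key not in pairs or d + 1 < pairs[key]:
                        pairs[key] = d + 1
                    if shortest is None or d + 1 < shortest:
                        shortest = d + 1
                elif y in external and y not in dist:
                    dist[y] = d + 1
                    queue.append(y)
    return pairs, shortest


def classify_pair(
    hit_a: FragmentHit, hit_b: FragmentHit, mol: Chem.Mol, cutoff: int = 3
) -> str:
    """Classify one unordered hit pair into the combination taxonomy.

    Symmetric in its first two arguments; returns one of the typed codes or a
    discard code (``ffs``/``ffo``/``cfc``).
    """
    set_a, set_b = hit_a.atom_ids, hit_b.atom_ids
    shared = set_a & set_b
    k = len(shared)
    if k > 0:
        if set_a < set_b or set_b < set_a or set_a == set_b:
            return "ffs"
        if k == 1:
            return "fs"
        if k == 2:
            i, j = sorted(shared)
            return "fe" if mol.GetBondBetweenAtoms(i, j) is not None else "ffo"
        if k <= 5:
            return "fb"
        return "ffo"
    pairs, _shortest = _attachment_pairs(mol, set_a, set_b, cutoff)
    if not pairs:
        return "cfc"
    if len(pairs) == 1:
        return "cm"
    if len(pairs) == 2:
        (a1, b1), (a2, b2) = sorted(pairs)
        if a1 == a2 or b1 == b2:
            return "cbs"
        if (
            mol.GetBondBetweenAtoms(a1, a2) is not None
            and mol.GetBondBetweenAtoms(b1, b2) is not None
        ):
            return "cbe"
        return "cbb"
    return "ct"


def resolve_containment(hits: list[FragmentHit]) -> list[FragmentHit]:
    """Drop hits wholly contained in a hit of a different fragment (ffs).

    A fragment sitting inside a larger matched fragment is a substructure
    artifact and must never generate combination edges. Ties on identical
    atom sets keep the lower ``frag_id``.
    """
    kept: list[FragmentHit] = []
    for h in hits:
        contained = False
        for other in hits:
            if other is h or other.frag_id == h.frag_id and other.occurrence == h.occurrence:
                continue
            if h.atom_ids < other.atom_ids:
                contained = True
                break
            if h.atom_ids == other.atom_ids and other.frag_id < h.frag_id:
                contained = True
                break
        if not contained:
            kept.append(h)
    return kept


def classify_all_pairs(
    hits: list[FragmentHit], mol: Chem.Mol, cutoff: int = 3
) -> list[CombinationEdge]:
    """Typed edges over all unordered hit pairs (discard codes excluded)."""
    edges: list[CombinationEdge] = []
    for i in range(len(hits)):
        for j in range(i + 1, len(hits)):
            ctype = classify_pair(hits[i], hits[j], mol, cutoff)
            if ctype in TYPED:
                edges.append(CombinationEdge(hits[i], hits[j], ctype))
    return edges


def build_fcgs(hits: list[FragmentHit], edges: list[CombinationEdge]) -> list[FCG]:
    """Connected components of the hit graph with >= 1 edge, as FCGs.

    Isolated hits yield no FCG. FCG order follows the smallest hit (frag_id,
    occurrence) in each component, so output is stable across runs.
    """
    if not edges:
        return []
    graph = nx.Graph()
    graph.add_nodes_from(hits)
    for e in edges:
        graph.add_edge(e.hit_a, e.hit_b)
    fcgs: list[FCG] = []
    for component in nx.connected_components(graph):
        if len(component) < 2:
            continue
        comp_edges = [e for e in edges if e.hit_a in component and e.hit_b in component]
        fcgs.append(FCG(edges=comp_edges))
    fcgs.sort(key=lambda f: min((e.hit_a.frag_id, e.hit_a.occurrence) for e in f.edges))
    return fcgs


@dataclass
class MoleculeAnalysis:
    """Fragment hits, typed edges and FCGs of one molecule."""

    hits: list[FragmentHit]
    edges: list[CombinationEdge]
    fcgs: list[FCG]

    @property
    def signatures(self) -> list[str]:
        return [f.signature for f in self.fcgs]

    @property
    def edge_strings(self) -> list[str]:
        return sorted({e.edge_string() for e in self.edges})


def analyze_molecule(
    smiles_std: str, catalog: list[FragmentEntry], cutoff: int = 3
) -> MoleculeAnalysis:
    """Full combination analysis of one standardized structure."""
    mol = Chem.MolFromSmiles(smiles_std)
    if mol is None:
        raise ValueError(f"unparseable standardized SMILES: {smiles_std!r}")
    hits = resolve_containment(find_fragment_hits(mol, catalog))
    edges = classify_all_pairs(hits, mol, cutoff)
    return MoleculeAnalysis(hits=hits, edges=edges, fcgs=build_fcgs(hits, edges))
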