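"""Structure standardization, filtering and deduplication of compound tables.

The preprocessing contract for every library entering the fragment-combination
analysis is identical: keep the largest organic component, neutralize charges,
strip all stereochemistry (tetrahedral and double-bond) so that downstream
deduplication operates on racemic InChIKeys, optionally remove terminal sugar
rings (deglycosylation), and apply the structural filters (at least one ring,
molecular weight below 1000 g/mol).
"""

from __future__ import annotations

import logging
import signal
import threading
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdMolDescriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

MW_LIMIT = 1000.0


class StandardizationError(ValueError):
    """Raised when a structure cannot be parsed or standardized."""

    def __init__(self, message: str, source_id: str | None = None):
        super().__init__(message)
        self.source_id = source_id


@dataclass
class MoleculeRecord:
    """One standardized library entry.

    ``status`` is one of ``PNP``/``NPL``/``NP``/``NonPNP`` once assigned;
    records that fail parsing, filtering or the per-record timeout carry a
    ``failure_reason`` and end up ``NonPNP``.
    """

    source_id: str
    smiles_input: str
    smiles_std: str | None = None
    inchikey: str | None = None
    mw: float | None = None
    num_rings: int | None = None
    num_heavy_atoms: int | None = None
    passed_filters: bool = False
    status: str | None = None
    failure_reason: str | None = None


@dataclass
class PipelineConfig:
    """Run-wide knobs shared by all pipeline stages."""

    chunk_size: int = 100
    timeout_s: float = 50.0
    random_seed: int = 0
    connection_cutoff: int = 3
    fcg_compare_level: str = "edge"  # or "graph"
    deglycosylate: bool = True

    def __post_init__(self) -> None:
        if self.timeout_s <= 0:
            raise ValueError("timeout_s must be positive")
        if self.chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")
        if self.fcg_compare_level not in ("edge", "graph"):
            raise ValueError("fcg_compare_level must be 'edge' or 'graph'")


_LARGEST = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)
_UNCHARGER = rdMolStandardize.Uncharger()


def _standardize_mol(mol: Chem.Mol) -> Chem.Mol:
    mol = rdMolStandardize.Cleanup(mol)
    mol = _LARGEST.choose(mol)
    mol = _UNCHARGER.uncharge(mol)
    Chem.RemoveStereochemistry(mol)
    # round-trip through SMILES so the output is independent of input atom order
    out = Chem.MolFromSmiles(Chem.MolToSmiles(mol))
    if out is None:  # pragma: no cover - Cleanup output always re-parses
        raise StandardizationError("standardized structure failed to re-parse")
    return out


def standardize_structure(smiles_input: str, source_id: str | None = None) -> tuple[str, str]:
    """Standardize one SMILES: salt stripping, neutralization, racemization.

    Returns the canonical racemic SMILES and its InChIKey.
    """
    mol = Chem.MolFromSmiles(smiles_input)
    if mol is None:
        raise StandardizationError(f"unparseable SMILES: {smiles_input!r}", source_id)
    mol = _standardize_mol(mol)
    return Chem.MolToSmiles(mol), Chem.MolToInchiKey(mol)


# ---------------------------------------------------------------------------
# Deglycosylation


def _terminal_sugar(mol: Chem.Mol) -> tuple[set[int], int] | None:
    """Locate one terminal sugar ring.

    A terminal sugar is a 5- or 6-membered ring with exactly one ring oxygen
    and carbon ring atoms, not fused to another ring, decorated only with
    hydroxyls and/or CH2OH groups, and attached to the remainder of the
    molecule through exactly one exocyclic O-glycosidic single bond.

    Returns the atom indices to delete (ring plus its OH/CH2OH substituents)
    and the index of the bridging oxygen (kept, becomes a hydroxyl on the
    aglycone), or None if no terminal sugar is present.
    """
    ri = mol.GetRingInfo()
    for ring in ri.AtomRings():
        if len(ring) not in (5, 6):
            continue
        ring_set = set(ring)
        ring_oxygens = [i for i in ring if mol.GetAtomWithIdx(i).GetSymbol() == "O"]
        if len(ring_oxygens) != 1:
            continue
        if any(mol.GetAtomWithIdx(i).GetSymbol() != "C" for i in ring if i != ring_oxygens[0]):
            continue
        if any(ri.NumAtomRings(i) > 1 for i in ring):
            continue
        if any(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            continue
        delete = set(ring_set)
        n_hydroxyl = 0
        bridges: list[int] = []
        ok = True
        for i in ring:
            for nb in mol.GetAtomWithIdx(i).GetNeighbors():
                j = nb.GetIdx()
                if j in ring_set:
                    continue
                bond = mol.GetBondBetweenAtoms(i, j)
                if bond.GetBondType() != Chem.BondType.SINGLE:
                    ok = False
                    break
                if nb.GetSymbol() == "O":
                    if nb.GetDegree() == 1:
                        n_hydroxyl += 1
                        delete.add(j)
                    else:
                        bridges.append(j)
                elif nb.GetSymbol() == "C":
                    # accept exocyclic CH2OH only
                    ext = [x for x in nb.GetNeighbors() if x.GetIdx() != i]
                    if (
                        nb.GetDegree() == 2
                        and len(ext) == 1
                        and ext[0].GetSymbol() == "O"
                        and ext[0].GetDegree() == 1
                    ):
                        n_hydroxyl += 1
                        delete.add(j)
                        delete.add(ext[0].GetIdx())
                    else:
                        ok = False
                        break
                else:
                    ok = False
                    break
            if not ok:
                break
        if ok and n_hydroxyl >= 2 and len(bridges) == 1:
            return delete, bridges[0]
    return None


def deglycosylate(smiles_std: str) -> str:
    """Iteratively remove terminal sugar rings; return the aglycone SMILES.

    Molecules without a glycosidic sugar are returned unchanged; if removal
    would leave an empty structure the input is returned unchanged.
    """
    mol = Chem.MolFromSmiles(smiles_std)
    if mol is None:
        raise StandardizationError(f"unparseable SMILES: {smiles_std!r}")
    while True:
        found = _terminal_sugar(mol)
        if found is None:
            break
        delete, _bridge = found
        if len(delete) >= mol.GetNumAtoms() - 1:
            logger.info("deglycosylation would empty %s; kept as is", smiles_std)
            break
        rw = Chem.RWMol(mol)
        for idx in sorted(delete, reverse=True):
            rw.RemoveAtom(idx)
        candidate = rw.GetMol()
        try:
            Chem.SanitizeMol(candidate)
        except Exception:  # sugar-like ring in an unexpected context: keep input
            logger.info("deglycosylation produced invalid structure for %s", smiles_std)
            break
        mol = candidate
    return Chem.MolToSmiles(mol)


# ---------------------------------------------------------------------------
# Filters, dedup, record-level pipeline


def apply_filters(record: MoleculeRecord) -> bool:
    """True iff the standardized structure has >0 rings and MW < 1000."""
    if record.num_rings is None or record.mw is None:
        raise ValueError("filters require num_rings and mw")
    return record.num_rings > 0 and record.mw < MW_LIMIT


def standardize_record(record: MoleculeRecord, deglyco: bool = True) -> MoleculeRecord:
    """Fill a record's standardized fields in place; failures are recorded."""
    try:
        smiles_std, _ = standardize_structure(record.smiles_input, record.source_id)
        if deglyco:
            smiles_std = deglycosylate(smiles_std)
        mol = Chem.MolFromSmiles(smiles_std)
        record.smiles_std = Chem.MolToSmiles(mol)
        record.inchikey = Chem.MolToInchiKey(mol)
        record.mw = Descriptors.MolWt(mol)
        record.num_rings = rdMolDescriptors.CalcNumRings(mol)
        record.num_heavy_atoms = mol.GetNumHeavyAtoms()
        record.passed_filters = apply_filters(record)
        if not record.passed_filters:
            record.failure_reason = "filtered"
    except StandardizationError as exc:
        record.failure_reason = f"standardization: {exc}"
        record.passed_filters = False
    return record


def deduplicate(records: Sequence[MoleculeRecord]) -> tuple[list[MoleculeRecord], int]:
    """Keep the first occurrence per InChIKey, preserving input order.

    Records without an InChIKey (failed standardization) are all kept; they
    never collide. Returns the unique records and the duplicate count.
    """
    seen: set[str] = set()
    unique: list[MoleculeRecord] = []
    n_dup = 0
    for rec in records:
        if rec.inchikey is not None and rec.inchikey in seen:
            n_dup += 1
            continue
        if rec.inchikey is not None:
            seen.add(rec.inchikey)
        unique.append(rec)
    return unique, n_dup


# ---------------------------------------------------------------------------
# Table I/O


def read_molecule_table(path: str | Path, format: str = "smiles-tsv") -> list[MoleculeRecord]:
    """Read a compound table (``smiles-tsv`` or ``sdf``) into raw records.

    Unparseable entries are logged and skipped; zero parseable records is an
    error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[MoleculeRecord] = []
    n_rejected = 0
    if format == "smiles-tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            try:
                id_col, smi_col = header.index("id"), header.index("smiles")
            except ValueError as exc:
                raise ValueError(f"{path}: header must contain 'id' and 'smiles'") from exc
            for lineno, line in enumerate(fh, start=2):
                parts = line.rstrip("\n").split("\t")
                if len(parts) <= max(id_col, smi_col):
                    n_rejected += 1
                    logger.warning("%s:%d: short row skipped", path, lineno)
                    continue
                source_id, smiles = parts[id_col], parts[smi_col]
                if Chem.MolFromSmiles(smiles) is None:
                    n_rejected += 1
                    logger.warning("%s:%d: unparseable SMILES %r", path, lineno, smiles)
                    continue
                records.append(MoleculeRecord(source_id=source_id, smiles_input=smiles))
    elif format == "sdf":
        supplier = Chem.SDMolSupplier(str(path))
        for i, mol in enumerate(supplier):
            if mol is None:
                n_rejected += 1
                logger.warning("%s: molecule %d unparseable", path, i)
                continue
            source_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol_{i}"
            records.append(MoleculeRecord(source_id=source_id, smiles_input=Chem.MolToSmiles(mol)))
    else:
        raise ValueError(f"unknown format: {format!r}")
    if not records:
        raise ValueError(f"{path}: no parseable records")
    if n_rejected:
        logger.info("%s: %d records read, %d rejected", path, len(records), n_rejected)
    return records


STATUS_COLUMNS = [
    "id",
    "smiles_std",
    "inchikey",
    "mw",
    "num_rings",
    "num_heavy_atoms",
    "passed_filters",
    "status",
    "failure_reason",
]


def write_molecule_table(records: Iterable[MoleculeRecord], path: str | Path) -> None:
    """Write standardized records as TSV with the standard column set."""
    with open(path, "w") as fh:
        fh.write("\t".join(STATUS_COLUMNS) + "\n")
        for rec in records:
            row = [
                rec.source_id,
                rec.smiles_std or "",
                rec.inchikey or "",
                "" if rec.mw is None else f"{rec.mw:.3f}",
                "" if rec.num_rings is None else str(rec.num_rings),
                "" if rec.num_heavy_atoms is None else str(rec.num_heavy_atoms),
                str(rec.passed_filters),
                rec.status or "",
                rec.failure_reason or "",
            ]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Chunked execution


@dataclass
class ChunkFailure:
    """Marker result for a record whose per-record computation failed."""

    reason: str


class _RecordTimeout(Exception):
    pass


def _call_with_timeout(operation: Callable, record, timeout_s: float | None):
    """Run ``operation(record)`` under a wall-clock alarm (main thread only)."""
    use_alarm = (
        timeout_s is not None
        and threading.current_thread() is threading.main_thread()
    )
    if not use_alarm:
        return operation(record)

    def _handler(signum, frame):
        raise _RecordTimeout()

    old = signal.signal(signal.SIGALRM, _handler)
    signal.setitimer(signal.ITIMER_REAL, timeout_s)
    try:
        return operation(record)
    finally:
        signal.setitimer(signal.ITIMER_REAL, 0.0)
        signal.signal(signal.SIGALRM, old)


def chunked_map(records: Sequence, operation: Callable, config: PipelineConfig) -> list:
    """Apply a pure per-record ``operation`` in chunks of ``config.chunk_size``.

    The result is element-for-element identical to a single-chunk run for any
    chunk size: no decision (deduplication, filtering, aggregation) is ever
    taken per chunk. A record exceeding ``config.timeout_s`` wall-clock
    seconds, or raising, yields a :class:`ChunkFailure` in its slot; the run
    continues.
    """
    results: list = []
    for start in range(0, len(records), config.chunk_size):
        for rec in records[start : start + config.chunk_size]:
            try:
                results.append(_call_with_timeout(operation, rec, config.timeout_s))
            except _RecordTimeout:
                logger.warning("record timed out after %.1fs", config.timeout_s)
                results.append(ChunkFailure(reason=f"timeout>{config.timeout_s:g}s"))
            except Exception as exc:
                results.append(ChunkFailure(reason=f"error: {exc}"))
    return results
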