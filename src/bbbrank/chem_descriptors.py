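"""Solute descriptors for blood-brain partition models.

The four partition models downstream consume the Abraham solute descriptors
(E, S, A, B, V), the octanol-water logP, the topological polar surface area
(PSA) and optionally a free energy of solvation (Gsolv).  Two of these are
cheap graph quantities this module computes itself:

* **V** — the McGowan characteristic volume, an additive volume built from
  per-element increments minus a fixed contribution per bond, reported on
  the Abraham scale of (cm3/mol)/100.
* **PSA** — the fragment-sum topological polar surface area in A^2.

The remaining descriptors (E, S, A, B, logP, Gsolv) depend on trained
fragment schemes or quantum chemistry and must be supplied in a table;
:func:`resolve_descriptors` merges supplied and computed values and records
the provenance of every field.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from rdkit import Chem
from rdkit.Chem import rdMolDescriptors
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

#: Elements the McGowan increment table below covers; parsing rejects others.
SUPPORTED_ELEMENTS = frozenset({"C", "H", "N", "O", "S", "P", "F", "Cl", "Br", "I"})

#: McGowan atomic increments in cm3/mol (Abraham & McGowan's standard table).
MCGOWAN_INCREMENTS = {
    "C": 16.35,
    "H": 8.71,
    "N": 14.39,
    "O": 12.43,
    "F": 10.48,
    "S": 22.91,
    "Cl": 20.95,
    "Br": 26.21,
    "I": 34.53,
    "P": 24.87,
}

#: Fixed volume removed per connection (bond), cm3/mol.  Counted over the
#: sigma framework: one deduction per bond regardless of bond order.
MCGOWAN_BOND_TERM = 6.56

#: Descriptor fields in canonical CSV order.
DESCRIPTOR_FIELDS = ("E", "S", "A", "B", "V", "logP", "PSA", "Gsolv")

#: CSV column headers for the descriptor table (Gsolv carries its unit).
_CSV_COLUMNS = ("compound_id", "E", "S", "A", "B", "V", "logP", "PSA", "Gsolv_kcal_mol")


class MoleculeParseError(ValueError):
    """Raised when a structure file cannot be parsed into valid records."""


@dataclass
class MoleculeRecord:
    """One compound: a label plus an RDKit molecule with explicit hydrogens."""

    id: str
    mol: Chem.Mol
    source: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise MoleculeParseError("molecule record with empty id")
        if self.mol.GetNumAtoms() < 1:
            raise MoleculeParseError(f"{self.id}: structure has no atoms")
        for atom in self.mol.GetAtoms():
            if atom.GetSymbol() not in SUPPORTED_ELEMENTS:
                raise MoleculeParseError(
                    f"{self.id}: unsupported element {atom.GetSymbol()!r}"
                )

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(Chem.RemoveHs(self.mol))


@dataclass
class DescriptorSet:
    """Complete per-compound descriptor record feeding the partition models.

    Units: E in (cm3/mol)/10; S, A, B unitless (Abraham scale); V in
    (cm3/mol)/100; logP unitless; PSA in A^2; Gsolv in kcal/mol.  Absent
    fields are ``None``; ``provenance`` maps each present field to either
    ``"computed"`` or ``"supplied"``.
    """

    compound_id: str
    E: Optional[float] = None
    S: Optional[float] = None
    A: Optional[float] = None
    B: Optional[float] = None
    V: Optional[float] = None
    logP: Optional[float] = None
    PSA: Optional[float] = None
    Gsolv: Optional[float] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.V is not None and not self.V > 0:
            raise ValueError(f"{self.compound_id}: V must be positive, got {self.V}")
        for name in ("PSA", "A", "B"):
            val = getattr(self, name)
            if val is not None and val < 0:
                raise ValueError(f"{self.compound_id}: {name} must be >= 0, got {val}")

    def get(self, name: str) -> Optional[float]:
        return getattr(self, name)

    def present(self) -> tuple:
        return tuple(f for f in DESCRIPTOR_FIELDS if getattr(self, f) is not None)


def _mol_from_smiles(smiles: str, label: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeParseError(f"{label}: unparsable SMILES {smiles!r}")
    return Chem.AddHs(mol)


def parse_molecules(path: str | Path, fmt: Optional[str] = None) -> list[MoleculeRecord]:
    """Read molecules from a ``.smi`` or SDF (V2000) file.

    SMILES files hold one ``SMILES whitespace ID`` per line; ``#`` starts a
    comment.  Hydrogens are made explicit on every record and input order is
    preserved.  Duplicate ids and unparsable blocks raise
    :class:`MoleculeParseError` naming the offending line or block.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "sdf" if path.suffix.lower() in {".sdf", ".mol"} else "smi"
    if fmt not in {"smi", "sdf"}:
        raise ValueError(f"unknown format {fmt!r}")

    records: list[MoleculeRecord] = []
    if fmt == "smi":
        for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise MoleculeParseError(
                    f"{path.name}:{lineno}: expected 'SMILES ID', got {raw!r}"
                )
            smiles, mol_id = parts[0], parts[1].strip()
            mol = _mol_from_smiles(smiles, f"{path.name}:{lineno} ({mol_id})")
            records.append(MoleculeRecord(id=mol_id, mol=mol, source=str(path)))
    else:
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        for block_no, mol in enumerate(supplier, start=1):
            if mol is None:
                raise MoleculeParseError(f"{path.name}: unparsable molblock #{block_no}")
            mol_id = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
            if not mol_id:
                mol_id = f"mol{block_no}"
            mol = Chem.AddHs(mol)
            records.append(MoleculeRecord(id=mol_id, mol=mol, source=str(path)))

    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise MoleculeParseError(f"duplicate molecule id {rec.id!r} in {path.name}")
        seen.add(rec.id)
    return records


def mcgowan_volume(mol: MoleculeRecord | Chem.Mol) -> float:
    """McGowan characteristic volume V in (cm3/mol)/100.

    V = (sum of atomic increments - 6.56 per bond) / 100, hydrogens included
    and every bond deducted once regardless of its order.  Additive over
    disconnected components since no bond joins them.
    """
    rdmol = mol.mol if isinstance(mol, MoleculeRecord) else Chem.AddHs(mol)
    total = 0.0
    for atom in rdmol.GetAtoms():
        sym = atom.GetSymbol()
        try:
            total += MCGOWAN_INCREMENTS[sym]
        except KeyError:
            raise ValueError(f"no McGowan increment for element {sym!r}") from None
    total -= MCGOWAN_BOND_TERM * rdmol.GetNumBonds()
    return total / 100.0


def topological_psa(mol: MoleculeRecord | Chem.Mol, include_sp: bool = False) -> float:
    """Fragment-sum topological polar surface area in A^2.

    Sums the published polar-fragment contributions over N/O environments;
    ``include_sp`` adds the S/P fragment contributions.  Pure hydrocarbons
    score 0.  Polar environments missing from the fragment table contribute
    0 (the underlying implementation's convention).
    """
    rdmol = mol.mol if isinstance(mol, MoleculeRecord) else mol
    return float(rdMolDescriptors.CalcTPSA(rdmol, includeSandP=include_sp))


def read_descriptor_table(path: str | Path) -> dict[str, dict]:
    """Load the descriptor CSV into ``{compound_id: {field: value}}``.

    Blank cells mean "absent".  Duplicate rows for one id that disagree on
    any field raise ``ValueError``.
    """
    path = Path(path)
    rows: dict[str, dict] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "compound_id" not in reader.fieldnames:
            raise ValueError(f"{path.name}: missing 'compound_id' column")
        for raw in reader:
            cid = (raw.get("compound_id") or "").strip()
            if not cid:
                continue
            parsed: dict = {}
            for col, fld in (
                ("E", "E"), ("S", "S"), ("A", "A"), ("B", "B"), ("V", "V"),
                ("logP", "logP"), ("PSA", "PSA"), ("Gsolv_kcal_mol", "Gsolv"),
            ):
                cell = (raw.get(col) or "").strip()
                if cell:
                    parsed[fld] = float(cell)
            if cid in rows:
                if rows[cid] != parsed:
                    raise ValueError(f"{path.name}: conflicting duplicate rows for {cid!r}")
            else:
                rows[cid] = parsed
    return rows


def resolve_descriptors(
    mol: MoleculeRecord,
    table_row: Optional[Mapping[str, float]] = None,
    include_sp: bool = False,
) -> DescriptorSet:
    """Merge computed (V, PSA) and supplied descriptors for one compound.

    A supplied value for any field — including V and PSA — overrides the
    computed one; provenance is recorded per field.  Fields neither computed
    nor supplied stay absent.  Idempotent: feeding a resolved set's values
    back reproduces it.
    """
    values: dict[str, float] = {
        "V": mcgowan_volume(mol),
        "PSA": topological_psa(mol, include_sp=include_sp),
    }
    provenance = {"V": "computed", "PSA": "computed"}
    if table_row:
        for fld in DESCRIPTOR_FIELDS:
            if fld in table_row and table_row[fld] is not None:
                values[fld] = float(table_row[fld])
                provenance[fld] = "supplied"
    return DescriptorSet(compound_id=mol.id, provenance=provenance, **values)


def write_descriptor_table(sets: Sequence[DescriptorSet], path: str | Path) -> None:
    """Write resolved descriptors to CSV (schema plus ``*_provenance`` columns)."""
    path = Path(path)
    prov_cols = [f"{c}_provenance" for c in _CSV_COLUMNS[1:]]
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(_CSV_COLUMNS) + prov_cols)
        for ds in sets:
            vals, provs = [], []
            for col in _CSV_COLUMNS[1:]:
                fld = "Gsolv" if col == "Gsolv_kcal_mol" else col
                v = ds.get(fld)
                vals.append("" if v is None else repr(v))
                provs.append(ds.provenance.get(fld, ""))
            writer.writerow([ds.compound_id] + vals + provs)


def resolve_all(
    molecules: Iterable[MoleculeRecord],
    table: Optional[Mapping[str, Mapping[str, float]]] = None,
    include_sp: bool = False,
) -> list[DescriptorSet]:
    """Resolve descriptors for every molecule against an optional table."""
    table = table or {}
    return [resolve_descriptors(m, table.get(m.id), include_sp=include_sp) for m in molecules]
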