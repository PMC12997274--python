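"""Structure and spectrum I/O plus graph-level chemistry facts.

Molecules are carried as :class:`MoleculeRecord`, a light wrapper around
an RDKit molecule with explicit hydrogens.  The record exposes exactly
the facts the scoring pipeline needs: the atom/bond lists, conformer
coordinates (Å), the canonical molecular formula, and the partition of
carbon atoms into symmetry-equivalence classes (the distinct ¹³C
environments, i.e. the expected peak multiplicity of the spectrum).

Equivalence is computed on the 2-D molecular graph (element, bond order,
canonical ranking) and is therefore conformer-independent, matching the
way peak counts are tabulated in practice.  Stereochemistry is retained
on the underlying RDKit molecule (it distinguishes diastereomers once
3-D conformers are generated) but does not influence the class
partition.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

logger = logging.getLogger(__name__)

__all__ = [
    "MoleculeRecord",
    "ShiftSpectrum",
    "read_structures",
    "write_structures",
    "read_spectrum",
    "write_spectrum",
    "carbon_equivalence",
    "molecule_from_smiles",
]


@dataclass
class ShiftSpectrum:
    """An ordered list of experimental ¹³C shifts in ppm.

    ``assignment`` maps peak index -> carbon equivalence-class index of
    the paired :class:`MoleculeRecord`; it is ``None`` for unassigned
    peak lists.
    """

    shifts: list[float]
    assignment: dict[int, int] | None = None

    def __post_init__(self):
        self.shifts = [float(s) for s in self.shifts]
        if not all(np.isfinite(self.shifts)):
            raise ValueError("shifts must be finite")
        if self.assignment is not None:
            self.assignment = {int(k): int(v) for k, v in self.assignment.items()}

    def __len__(self) -> int:
        return len(self.shifts)


class MoleculeRecord:
    """A single-molecule structure with optional 3-D conformers."""

    def __init__(self, rdmol: Chem.Mol, name: str = ""):
        if rdmol is None:
            raise ValueError("rdmol must not be None")
        # explicit hydrogens so conformer coordinates cover every atom
        if any(a.GetNumImplicitHs() or a.GetNumExplicitHs() for a in rdmol.GetAtoms()):
            rdmol = Chem.AddHs(rdmol, addCoords=rdmol.GetNumConformers() > 0)
        self.rdmol = rdmol
        self.name = name or (rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else "")
        self._classes: list[list[int]] | None = None

    # --- derived facts --------------------------------------------------
    @property
    def atoms(self) -> list[tuple[str, int]]:
        return [(a.GetSymbol(), a.GetIdx()) for a in self.rdmol.GetAtoms()]

    @property
    def bonds(self) -> list[tuple[int, int, float]]:
        return [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
            for b in self.rdmol.GetBonds()
        ]

    @property
    def conformers(self) -> list[np.ndarray]:
        return [np.array(c.GetPositions(), dtype=float) for c in self.rdmol.GetConformers()]

    @property
    def n_conformers(self) -> int:
        return self.rdmol.GetNumConformers()

    @property
    def formula(self) -> str:
        return rdMolDescriptors.CalcMolFormula(self.rdmol)

    @property
    def carbon_indices(self) -> list[int]:
        return [a.GetIdx() for a in self.rdmol.GetAtoms() if a.GetAtomicNum() == 6]

    @property
    def carbon_classes(self) -> list[list[int]]:
        if self._classes is None:
            self._classes = carbon_equivalence(self)
        return self._classes

    @property
    def n_fragments(self) -> int:
        return len(Chem.GetMolFrags(self.rdmol))

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(Chem.RemoveHs(self.rdmol))

    def class_of_atom(self) -> dict[int, int]:
        """Map carbon atom index -> equivalence-class index."""
        return {a: ci for ci, cls in enumerate(self.carbon_classes) for a in cls}

    def __repr__(self):  # pragma: no cover
        return f"MoleculeRecord({self.smiles!r}, conformers={self.n_conformers})"


def molecule_from_smiles(smiles: str, name: str = "") -> MoleculeRecord:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return MoleculeRecord(mol, name=name)


def carbon_equivalence(molecule: MoleculeRecord) -> list[list[int]]:
    """Partition carbon atoms into graph-symmetry equivalence classes.

    Carbons related by an automorphism of the H-explicit molecular graph
    (respecting element and bond order) fall in one class and contribute
    a single ¹³C peak.  Classes are returned sorted by their smallest
    member index, so the partition is deterministic for a fixed input.
    """
    carbons = molecule.carbon_indices
    if not carbons:
        raise ValueError("molecule has no carbon atoms")
    ranks = list(Chem.CanonicalRankAtoms(molecule.rdmol, breakTies=False))
    by_rank: dict[int, list[int]] = {}
    for idx in carbons:
        by_rank.setdefault(ranks[idx], []).append(idx)
    classes = [sorted(v) for v in by_rank.values()]
    classes.sort(key=lambda c: c[0])
    return classes


# --------------------------------------------------------------------------
# structure I/O
# --------------------------------------------------------------------------

def read_structures(path: str | Path, format: str | None = None) -> list[MoleculeRecord]:
    """Read molecules from an SDF (V2000) or SMILES file.

    Entries that fail to parse are skipped with a logged warning naming
    their position; an unreadable file raises.  SMILES inputs yield
    records with zero conformers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "sdf" if path.suffix.lower() in {".sdf", ".mol"} else "smiles"
    records: list[MoleculeRecord] = []
    if format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                logger.warning("skipping unparseable SDF record %d in %s", i, path)
                continue
            records.append(MoleculeRecord(mol))
    elif format == "smiles":
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line:
                continue
            parts = line.split(None, 1)
            mol = Chem.MolFromSmiles(parts[0])
            if mol is None:
                logger.warning("skipping unparseable SMILES on line %d in %s", i + 1, path)
                continue
            records.append(MoleculeRecord(mol, name=parts[1] if len(parts) > 1 else ""))
    else:
        raise ValueError(f"unknown format {format!r}")
    if not records:
        logger.warning("no parseable structures found in %s", path)
    return records


def write_structures(records: list[MoleculeRecord], path: str | Path) -> None:
    """Write records to SDF; each conformer becomes one entry."""
    path = Path(path)
    writer = Chem.SDWriter(str(path))
    try:
        for rec in records:
            mol = Chem.Mol(rec.rdmol)
            if rec.name:
                mol.SetProp("_Name", rec.name)
            if mol.GetNumConformers() == 0:
                writer.write(mol)
            else:
                for conf in mol.GetConformers():
                    writer.write(mol, confId=conf.GetId())
    finally:
        writer.close()


# --------------------------------------------------------------------------
# spectrum I/O
# --------------------------------------------------------------------------

def read_spectrum(path: str | Path) -> ShiftSpectrum:
    """Read a ¹³C peak list.

    Accepted formats: headerless CSV with one ppm value per line (an
    optional second column holds the assigned carbon-class index), or
    JSON ``{"shifts": [...], "assignment": {...}}``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        return ShiftSpectrum(
            shifts=data["shifts"],
            assignment=data.get("assignment"),
        )
    shifts: list[float] = []
    assignment: dict[int, int] = {}
    has_assignment = False
    with open(path, newline="") as fh:
        for row_no, row in enumerate(csv.reader(fh), start=1):
            if not row or not any(cell.strip() for cell in row):
                continue
            try:
                shifts.append(float(row[0]))
            except ValueError as exc:
                raise ValueError(
                    f"non-numeric shift {row[0]!r} at row {row_no} of {path}"
                ) from exc
            if len(row) > 1 and row[1].strip():
                assignment[len(shifts) - 1] = int(row[1])
                has_assignment = True
    return ShiftSpectrum(shifts=shifts, assignment=assignment if has_assignment else None)


def write_spectrum(spectrum: ShiftSpectrum, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload: dict = {"shifts": spectrum.shifts}
        if spectrum.assignment is not None:
            payload["assignment"] = {str(k): v for k, v in spectrum.assignment.items()}
        path.write_text(json.dumps(payload, indent=1))
        return
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for i, s in enumerate(spectrum.shifts):
            if spectrum.assignment is not None and i in spectrum.assignment:
                writer.writerow([s, spectrum.assignment[i]])
            else:
                writer.writerow([s])
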