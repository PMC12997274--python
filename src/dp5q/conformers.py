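"""Conformer ensembles for shift prediction.

Two backends are exposed through one contract:

* ``etkdg`` — distance-geometry embedding (ETKDGv3) followed by MMFF94
  force-field relaxation, both delegated to RDKit; deterministic under
  the request seed.
* ``passthrough`` — returns conformers already present on the record,
  for externally generated ensembles (e.g. a conformational search with
  DFT-refined geometries and energies supplied alongside).

Optional conformer energies (kcal/mol) can be converted to Boltzmann
weights for energy-weighted ensemble prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .chem_io import MoleculeRecord

__all__ = ["ConformerRequest", "generate", "boltzmann_weights", "GAS_CONSTANT_KCAL"]

GAS_CONSTANT_KCAL = 1.987204258640832e-3  # kcal / (mol K)


@dataclass
class ConformerRequest:
    molecule: MoleculeRecord
    n_conformers: int = 20
    seed: int = 42
    backend: str = "etkdg"
    energies: list[float] | None = None

    def __post_init__(self):
        if self.n_conformers < 1:
            raise ValueError("requested conformer count must be >= 1")
        if self.backend not in {"etkdg", "passthrough"}:
            raise ValueError(f"unknown backend {self.backend!r}")


def generate(request: ConformerRequest) -> MoleculeRecord:
    """Produce a record with ≥1 conformer; never silently empty."""
    rec = request.molecule
    if request.backend == "passthrough":
        if rec.n_conformers == 0:
            raise ValueError(
                f"passthrough backend but {rec.smiles} carries no conformers"
            )
        return rec
    mol = Chem.AddHs(Chem.Mol(rec.rdmol))
    mol.RemoveAllConformers()
    params = AllChem.ETKDGv3()
    params.randomSeed = int(request.seed)
    ids = AllChem.EmbedMultipleConfs(mol, numConfs=int(request.n_conformers), params=params)
    if len(ids) == 0:
        raise RuntimeError(f"conformer embedding failed for {rec.smiles}")
    AllChem.MMFFOptimizeMoleculeConfs(mol)
    return MoleculeRecord(mol, name=rec.name)


def write_ensemble(record: MoleculeRecord, path) -> None:
    """Write a conformer ensemble as a multi-entry SDF (one per conformer)."""
    from .chem_io import write_structures

    write_structures([record], path)


def read_ensemble(path) -> MoleculeRecord:
    """Read a multi-entry SDF of one molecule back into a single record.

    Consecutive entries must share the molecular graph (the layout
    :func:`write_ensemble` produces); their coordinates become the
    conformers of one record.
    """
    from rdkit.Chem import rdMolAlign  # noqa: F401  (keeps conformer API loaded)

    from .chem_io import read_structures

    records = read_structures(path)
    if not records:
        raise ValueError(f"no structures in {path}")
    first = records[0]
    smiles = first.smiles
    mol = Chem.Mol(first.rdmol)
    for other in records[1:]:
        if other.smiles != smiles:
            raise ValueError("ensemble file mixes different molecules")
        for conf in other.rdmol.GetConformers():
            mol.AddConformer(conf, assignId=True)
    return MoleculeRecord(mol, name=first.name)


def boltzmann_weights(energies, temperature: float = 298.15) -> np.ndarray:
    """Normalised weights w_i ∝ exp(−E_i / RT) for energies in kcal/mol."""
    e = np.asarray(energies, dtype=float)
    if e.size == 0:
        raise ValueError("need at least one energy")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    z = -(e - e.min()) / (GAS_CONSTANT_KCAL * temperature)
    w = np.exp(z)
    return w / w.sum()
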