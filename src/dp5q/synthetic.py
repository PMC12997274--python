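"""Synthetic molecules and simulated ¹³C spectra with known statistics.

Every downstream stage (curation, training, scoring, benchmarking) is
exercised against data whose generating process is fully known:

* :func:`fixture_molecules` decorates a built-in pool of small organic
  SMILES (all within the 11-element set H, B, C, N, O, F, P, S, Cl, Br,
  I) with valence-legal substituent edits, reproducibly under a seed.
* :class:`SurrogateShiftModel` assigns each carbon a Gaussian shift
  distribution whose mean and standard deviation depend only on a local
  environment key (hybridisation, aromaticity, ring membership, and the
  counts of attached carbon / oxygen / nitrogen / halogen neighbours
  plus β-heteroatoms).  The additive mean model mimics the empirical
  substituent-increment rules of ¹³C spectroscopy, so positional isomers
  receive distinct spectra — the property the structure-confirmation
  benchmark relies on.  Because the noise is Gaussian and independent
  across carbons, the true quantile function of every atom is available
  in closed form: mean + sigma * Phi^-1(tau).  That closed form is the
  ground truth against which the quantile network's calibration is
  verified.
* :func:`make_benchmark` builds the labelled correct/incorrect
  structure–spectrum pairs, restricting incorrect pairs to candidates
  with the same molecular formula.
* :func:`isomer_fixtures` generates many distinct constitutional
  isomers of a single saturated acyclic formula (random trees over the
  heavy atoms), giving the same-formula pool the benchmark needs.

The generator does not attempt to mimic real database accuracy, solvent
or temperature effects; it provides a controlled statistical testbed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.stats import norm

from .chem_io import MoleculeRecord, ShiftSpectrum, molecule_from_smiles

__all__ = [
    "ALLOWED_ELEMENTS",
    "BASE_SMILES",
    "SurrogateShiftModel",
    "fixture_molecules",
    "isomer_fixtures",
    "simulate_spectrum",
    "make_benchmark",
    "BenchmarkPair",
    "SurrogatePredictor",
]

ALLOWED_ELEMENTS = frozenset({"H", "B", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I"})

# ~50 small organics spanning sp3/sp2/sp carbons, rings, aromatics and
# the allowed heteroatoms.
BASE_SMILES: tuple[str, ...] = (
    "CC", "CCC", "CCCC", "CC(C)C", "CCCCC", "CC(C)CC", "CCCCCC",
    "CCO", "CC(C)O", "CCCO", "OCCO", "CCOC", "COC", "CCOCC",
    "CC=O", "CCC=O", "CC(C)=O", "CCC(C)=O", "CC(=O)O", "CCC(=O)O",
    "CC(=O)OC", "CCOC(C)=O", "CC(=O)N", "CCC(=O)NC",
    "CCN", "CCCN", "CN(C)C", "CCNCC",
    "CCCl", "CC(C)Cl", "CCBr", "CCCBr", "CCF", "CCCI",
    "CCS", "CCSC", "CCSCC",
    "C1CCCCC1", "C1CCCC1", "C1CCOC1", "C1CCNC1", "C1CCOCC1",
    "c1ccccc1", "Cc1ccccc1", "CCc1ccccc1", "Oc1ccccc1", "COc1ccccc1",
    "Nc1ccccc1", "Clc1ccccc1", "Cc1ccc(C)cc1", "Cc1cccc(O)c1",
    "c1ccncc1", "c1ccoc1", "c1ccsc1", "C#CC", "CC#N", "CC=C", "CC=CC",
)

# substituents used for valence-legal decoration of pool molecules
_SUBSTITUENTS = ("C", "O", "N", "F", "Cl", "Br")


@dataclass
class SurrogateShiftModel:
    """Environment-keyed Gaussian model of ¹³C shifts.

    ``base_table`` caches the mean shift per environment key; means are
    produced by an additive increment rule spanning roughly 0–220 ppm
    like real ¹³C spectra.  ``sigma`` is deterministic per key and lies
    in ``[sigma_min, sigma_max]`` ppm (heteroscedastic across
    environments, constant within one).
    """

    seed: int = 0
    sigma_min: float = 1.0
    sigma_max: float = 3.0
    base_table: dict = field(default_factory=dict)

    def environment_key(self, rdmol: Chem.Mol, atom_idx: int) -> tuple:
        atom = rdmol.GetAtomWithIdx(atom_idx)
        if atom.GetAtomicNum() != 6:
            raise ValueError(f"atom {atom_idx} is not carbon")
        hyb = str(atom.GetHybridization())
        n_c = n_o = n_n = n_x = beta = 0
        for nb in atom.GetNeighbors():
            z = nb.GetAtomicNum()
            if z == 6:
                n_c += 1
            elif z == 8:
                n_o += 1
            elif z == 7:
                n_n += 1
            elif z in (9, 17, 35, 53):
                n_x += 1
            for nb2 in nb.GetNeighbors():
                if nb2.GetIdx() != atom_idx and nb2.GetAtomicNum() in (7, 8, 9, 16, 17, 35, 53):
                    beta += 1
        return (hyb, atom.GetIsAromatic(), atom.IsInRing(), n_c, n_o, n_n, n_x, beta)

    def mean(self, key: tuple) -> float:
        if key not in self.base_table:
            hyb, arom, ring, n_c, n_o, n_n, n_x, beta = key
            if arom:
                mu = 126.0 + 7.0 * max(n_c - 2, 0) + 28.0 * n_o + 20.0 * n_n - 4.0 * n_x + 3.0 * beta
            elif hyb == "SP3":
                mu = (8.0 + 9.5 * n_c + 42.0 * n_o + 28.0 * n_n + 18.0 * n_x
                      + 7.0 * beta - (2.0 if ring else 0.0))
            elif hyb == "SP2":
                # carbonyl-like when oxygen is attached, alkene otherwise
                mu = (168.0 + 12.0 * n_o + 8.0 * n_c if n_o
                      else 118.0 + 9.0 * n_c + 14.0 * n_n + 5.0 * beta)
            elif hyb == "SP":
                mu = 76.0 + 14.0 * n_n + 6.0 * n_c + 4.0 * beta
            else:
                mu = 100.0
            self.base_table[key] = float(np.clip(mu, 0.0, 220.0))
        return self.base_table[key]

    def sigma(self, key: tuple) -> float:
        # deterministic, heteroscedastic: spread keys over [sigma_min, sigma_max]
        h = zlib.crc32(repr(key).encode()) % 101
        return float(self.sigma_min + (self.sigma_max - self.sigma_min) * h / 100.0)

    def class_params(self, molecule: MoleculeRecord) -> list[tuple[float, float]]:
        """(mean, sigma) per carbon equivalence class."""
        out = []
        for cls in molecule.carbon_classes:
            key = self.environment_key(molecule.rdmol, cls[0])
            out.append((self.mean(key), self.sigma(key)))
        return out

    def true_quantiles(self, molecule: MoleculeRecord, taus: np.ndarray) -> np.ndarray:
        """Closed-form quantile curves, one row per carbon class."""
        params = self.class_params(molecule)
        z = norm.ppf(np.asarray(taus, dtype=float))
        return np.array([[mu + sg * zi for zi in z] for mu, sg in params])


def _molecule_rng(model_seed: int, molecule: MoleculeRecord) -> np.random.Generator:
    # stable per-(seed, structure) stream so simulation is reproducible
    tag = zlib.crc32(molecule.smiles.encode())
    return np.random.default_rng(np.random.SeedSequence([model_seed, tag]))


def simulate_spectrum(
    molecule: MoleculeRecord,
    model: SurrogateShiftModel,
    rng: np.random.Generator | None = None,
) -> tuple[ShiftSpectrum, list[tuple[float, float]]]:
    """Draw one shift per carbon class from the surrogate Gaussians.

    Returns the spectrum (peak ``i`` assigned to class ``i``) together
    with the true ``(mean, sigma)`` per class, from which the exact
    quantile function is ``mean + sigma * Phi^-1(tau)``.
    """
    if not molecule.carbon_indices:
        raise ValueError("molecule has no carbon atoms")
    if rng is None:
        rng = _molecule_rng(model.seed, molecule)
    params = model.class_params(molecule)
    shifts = [float(mu + sg * rng.standard_normal()) for mu, sg in params]
    spectrum = ShiftSpectrum(shifts=shifts, assignment={i: i for i in range(len(shifts))})
    return spectrum, params


# --------------------------------------------------------------------------
# molecule generation
# --------------------------------------------------------------------------

def _decorate(mol: Chem.Mol, rng: np.random.Generator) -> Chem.Mol:
    """Attach 0–2 random substituents at carbons with free valence."""
    rw = Chem.RWMol(mol)
    for _ in range(int(rng.integers(0, 3))):
        sites = [
            a.GetIdx()
            for a in rw.GetAtoms()
            if a.GetAtomicNum() == 6 and a.GetTotalNumHs() > 0 and not a.GetIsAromatic()
        ]
        if not sites:
            break
        site = int(sites[rng.integers(len(sites))])
        sub = _SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))]
        new_idx = rw.AddAtom(Chem.Atom(sub))
        rw.AddBond(site, new_idx, Chem.BondType.SINGLE)
        try:
            Chem.SanitizeMol(rw)
        except Exception:
            rw.RemoveAtom(new_idx)
            Chem.SanitizeMol(rw)
    return rw.GetMol()


def fixture_molecules(n: int, seed: int = 0, decorate: bool = True) -> list[MoleculeRecord]:
    """Generate ``n`` single-fragment molecules from the embedded pool.

    Deterministic under ``seed``; all outputs stay within the allowed
    element set because both the pool and the decoration alphabet do.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[MoleculeRecord] = []
    i = 0
    while len(records) < n:
        smi = BASE_SMILES[i % len(BASE_SMILES)]
        mol = Chem.MolFromSmiles(smi)
        if decorate and i >= len(BASE_SMILES):
            mol = _decorate(mol, rng)
        records.append(MoleculeRecord(mol, name=f"fixture-{i}"))
        i += 1
    return records


def isomer_fixtures(
    n: int,
    seed: int = 0,
    n_carbons: int = 9,
    n_oxygens: int = 1,
    max_tries: int = 20000,
) -> list[MoleculeRecord]:
    """Generate ``n`` distinct constitutional isomers of one formula.

    Random labelled trees over the heavy atoms (via Prüfer sequences)
    are filtered for valence (C ≤ 4 bonds, O ≤ 2) and de-duplicated by
    canonical SMILES.  Every saturated acyclic tree over ``n_carbons``
    carbons and ``n_oxygens`` oxygens shares the formula
    C_nH_(2n+2-?)O_m, so the resulting pool is formula-homogeneous —
    exactly what the same-formula benchmark requires.
    """
    rng = np.random.default_rng(seed)
    heavy = ["C"] * n_carbons + ["O"] * n_oxygens
    k = len(heavy)
    seen: set[str] = set()
    out: list[MoleculeRecord] = []
    for _ in range(max_tries):
        if len(out) >= n:
            break
        prufer = rng.integers(0, k, size=k - 2)
        degree = np.ones(k, dtype=int)
        for p in prufer:
            degree[p] += 1
        max_deg = np.where(np.array(heavy) == "O", 2, 4)
        if np.any(degree > max_deg):
            continue
        edges = _prufer_to_edges(list(prufer), k)
        rw = Chem.RWMol()
        for el in heavy:
            rw.AddAtom(Chem.Atom(el))
        for a, b in edges:
            rw.AddBond(int(a), int(b), Chem.BondType.SINGLE)
        try:
            mol = rw.GetMol()
            Chem.SanitizeMol(mol)
        except Exception:
            continue
        canon = Chem.MolToSmiles(mol)
        if canon in seen:
            continue
        seen.add(canon)
        out.append(MoleculeRecord(mol, name=f"isomer-{len(out)}"))
    if len(out) < n:
        raise RuntimeError(
            f"only generated {len(out)}/{n} distinct isomers for C{n_carbons}O{n_oxygens}"
        )
    return out


def _prufer_to_edges(prufer: list[int], k: int) -> list[tuple[int, int]]:
    degree = [1] * k
    for p in prufer:
        degree[p] += 1
    edges = []
    import heapq

    leaves = [i for i in range(k) if degree[i] == 1]
    heapq.heapify(leaves)
    for p in prufer:
        leaf = heapq.heappop(leaves)
        edges.append((leaf, p))
        degree[p] -= 1
        if degree[p] == 1:
            heapq.heappush(leaves, p)
    u, v = heapq.heappop(leaves), heapq.heappop(leaves)
    edges.append((u, v))
    return edges


def embed_conformer(record: MoleculeRecord, seed: int = 42) -> MoleculeRecord:
    """Attach one ETKDG + MMFF-optimised conformer if none present."""
    if record.n_conformers > 0:
        return record
    mol = Chem.AddHs(Chem.Mol(record.rdmol))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise RuntimeError(f"conformer embedding failed for {record.smiles}")
    AllChem.MMFFOptimizeMolecule(mol)
    new = MoleculeRecord(mol, name=record.name)
    return new


# --------------------------------------------------------------------------
# benchmark construction
# --------------------------------------------------------------------------

@dataclass
class BenchmarkPair:
    molecule: MoleculeRecord
    spectrum: ShiftSpectrum
    label: str  # "correct" | "incorrect"
    molecule_index: int
    spectrum_index: int


def make_benchmark(
    pool: list[MoleculeRecord],
    model: SurrogateShiftModel,
) -> list[BenchmarkPair]:
    """Correct pairs plus all equal-formula incorrect cross pairs.

    A pool of size N yields N correct pairs and at most N² − N incorrect
    ones; the incorrect set is restricted to (molecule, spectrum)
    combinations whose molecular formulae match, because only those are
    plausible misassignments.  Cross-pair spectra carry no assignment
    (the peaks belong to a different structure).
    """
    if len(pool) < 2:
        raise ValueError("pool must contain at least 2 molecules")
    spectra = [simulate_spectrum(m, model)[0] for m in pool]
    formulae = [m.formula for m in pool]
    pairs: list[BenchmarkPair] = []
    for i, mol in enumerate(pool):
        pairs.append(BenchmarkPair(mol, spectra[i], "correct", i, i))
    for i, mol in enumerate(pool):
        for j in range(len(pool)):
            if i == j or formulae[i] != formulae[j]:
                continue
            unassigned = ShiftSpectrum(shifts=list(spectra[j].shifts), assignment=None)
            pairs.append(BenchmarkPair(mol, unassigned, "incorrect", i, j))
    return pairs


class SurrogatePredictor:
    """Oracle predictor returning the exact surrogate quantiles.

    Quacks like a fitted quantile regressor (``predict_molecule``) but
    reads the closed-form Gaussian quantiles straight from the surrogate
    model; used to test scoring and ranking independently of training.
    """

    def __init__(self, model: SurrogateShiftModel, taus: np.ndarray | None = None):
        self.model = model
        self.taus = np.round(np.arange(0.01, 1.0, 0.01), 2) if taus is None else np.asarray(taus)

    def predict_molecule(self, molecule: MoleculeRecord, conformer: int = 0) -> np.ndarray:
        """Per-carbon-atom quantile matrix (n_carbons, n_taus)."""
        class_q = self.model.true_quantiles(molecule, self.taus)
        atom_class = molecule.class_of_atom()
        carbons = molecule.carbon_indices
        return np.array([class_q[atom_class[a]] for a in carbons])
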