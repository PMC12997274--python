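"""DP5q confidence scoring from predicted shift distributions.

Given a per-atom quantile vector (the predicted inverse CDF of the
chemical shift) and an experimental shift ``y``, the error score is the
probability mass the predicted distribution places inside the symmetric
interval around the predicted median ``ŷ``:

    P = F(ŷ + |ŷ − y|) − F(ŷ − |ŷ − y|)

and the atomic confidence is ``DP5q = 1 − P``.  An experimental shift
close to the median leaves most of the mass outside the interval and
scores near 1; a shift far in the tail captures nearly all the mass and
scores near 0.  The molecular score is the geometric mean of the atomic
scores (computed in log space), and the molecular MAE compares class
median predictions with the assigned experimental shifts.

The predicted CDF is the piecewise-linear interpolant through the
(quantile value, τ) knots after a monotonic repair (sorting), with
linear tail ramps to exactly 0 and 1 whose widths equal the adjacent
inter-quantile gaps; a degenerate all-equal vector behaves as a step
function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem_io import MoleculeRecord, ShiftSpectrum
from .losses import QuantileGrid

__all__ = [
    "AtomScore",
    "DP5qResult",
    "repair_monotonic",
    "cdf",
    "error_score",
    "molecule_dp5q",
    "molecule_mae",
    "score_pair",
]


@dataclass
class AtomScore:
    """Scored comparison of one carbon class (or atom) with one peak."""

    atom_index: int
    predicted_median: float
    observed: float
    abs_error: float
    p: float
    dp5q: float


@dataclass
class DP5qResult:
    atom_scores: list[AtomScore]
    molecular_dp5q: float
    molecular_mae: float
    n_atoms: int


def repair_monotonic(quantile_vector: np.ndarray) -> np.ndarray:
    """Non-decreasing rearrangement of a quantile vector (a sort).

    The training penalty discourages but does not forbid quantile
    crossing; a valid CDF requires monotone knots, so residual
    crossings are repaired by sorting.  The value multiset is
    unchanged, and already-sorted input passes through identically.
    """
    v = np.asarray(quantile_vector, dtype=float)
    return np.sort(v, axis=-1)


def _knots(quantile_vector: np.ndarray, grid: QuantileGrid) -> tuple[np.ndarray, np.ndarray]:
    q = np.asarray(quantile_vector, dtype=float)
    taus = grid.array
    if q.shape[-1] != len(taus):
        raise ValueError("quantile vector length does not match grid")
    if np.any(np.diff(q) < 0):
        raise ValueError("quantile vector must be repaired (non-decreasing) first")
    # tail ramps: width = adjacent inter-quantile gap, reaching exactly 0/1
    lo_gap = q[1] - q[0] if len(q) > 1 else 0.0
    hi_gap = q[-1] - q[-2] if len(q) > 1 else 0.0
    xs = np.concatenate([[q[0] - lo_gap], q, [q[-1] + hi_gap]])
    ys = np.concatenate([[0.0], taus, [1.0]])
    return xs, ys


def cdf(quantile_vector: np.ndarray, grid: QuantileGrid, x) -> np.ndarray | float:
    """Predicted cumulative probability at shift ``x`` (ppm)."""
    xs, ys = _knots(quantile_vector, grid)
    out = np.interp(np.asarray(x, dtype=float), xs, ys)
    return float(out) if np.ndim(x) == 0 else out


def predicted_median(quantile_vector: np.ndarray, grid: QuantileGrid) -> float:
    """The τ = 0.5 entry, interpolated when 0.5 is absent from the grid."""
    q = np.asarray(quantile_vector, dtype=float)
    idx = grid.median_index
    if idx is not None:
        return float(q[idx])
    return float(np.interp(0.5, grid.array, q))


def error_score(quantile_vector: np.ndarray, grid: QuantileGrid, y: float) -> float:
    """Probability mass inside ``[ŷ − |ŷ−y|, ŷ + |ŷ−y|]``.

    The vector must already be non-decreasing.  A degenerate vector
    (all quantiles equal) yields P = 0 at ``y = ŷ`` and P = 1 anywhere
    else.
    """
    q = np.asarray(quantile_vector, dtype=float)
    med = predicted_median(q, grid)
    err = abs(med - float(y))
    if err == 0.0:
        return 0.0
    p = cdf(q, grid, med + err) - cdf(q, grid, med - err)
    return float(np.clip(p, 0.0, 1.0))


def molecule_dp5q(atom_scores: list[AtomScore] | np.ndarray) -> float:
    """Geometric mean of atomic DP5q scores, computed in log space."""
    if isinstance(atom_scores, np.ndarray) or (
        atom_scores and not isinstance(atom_scores[0], AtomScore)
    ):
        vals = np.asarray(atom_scores, dtype=float)
    else:
        vals = np.array([s.dp5q for s in atom_scores], dtype=float)
    if vals.size == 0:
        raise ValueError("no atom scores to aggregate")
    if np.any(vals < 0) or np.any(vals > 1):
        raise ValueError("atomic dp5q scores must lie in [0, 1]")
    if np.any(vals == 0.0):
        return 0.0
    return float(np.exp(np.mean(np.log(vals))))


def molecule_mae(
    class_medians: np.ndarray, spectrum: ShiftSpectrum
) -> float:
    """Mean |class median − observed| over assigned peaks, in ppm."""
    if spectrum.assignment is None:
        raise ValueError("spectrum has no assignment; run the assignment module first")
    errs = []
    for peak, cls in spectrum.assignment.items():
        errs.append(abs(float(class_medians[cls]) - spectrum.shifts[peak]))
    if not errs:
        raise ValueError("assignment is empty")
    return float(np.mean(errs))


def class_quantiles(
    molecule: MoleculeRecord, atom_quantiles: np.ndarray
) -> np.ndarray:
    """Average per-atom quantile vectors over each equivalence class.

    ``atom_quantiles`` has one row per carbon atom, ordered as
    ``molecule.carbon_indices``.  Returns one repaired row per class.
    """
    carbons = molecule.carbon_indices
    pos = {a: i for i, a in enumerate(carbons)}
    rows = []
    for cls in molecule.carbon_classes:
        rows.append(np.mean([atom_quantiles[pos[a]] for a in cls], axis=0))
    return repair_monotonic(np.asarray(rows))


def score_pair(
    molecule: MoleculeRecord,
    atom_quantiles: np.ndarray,
    spectrum: ShiftSpectrum,
    grid: QuantileGrid | None = None,
    assignment: dict[int, int] | None = None,
) -> DP5qResult:
    """Score one structure–spectrum pair.

    Scoring is per equivalence class: one experimental peak is compared
    with the class's averaged, repaired quantile vector.  When neither
    the spectrum nor the caller provides an assignment, peaks are
    matched to classes by minimum-cost matching (see
    :mod:`dp5q.assignment`).
    """
    grid = grid or QuantileGrid()
    cls_q = class_quantiles(molecule, atom_quantiles)
    medians = np.array([predicted_median(q, grid) for q in cls_q])
    if assignment is None:
        assignment = spectrum.assignment
    if assignment is None:
        from .assignment import assign

        assignment = assign(medians, spectrum.shifts).mapping
    scores: list[AtomScore] = []
    for peak, cls in sorted(assignment.items()):
        y = spectrum.shifts[peak]
        p = error_score(cls_q[cls], grid, y)
        med = medians[cls]
        scores.append(
            AtomScore(
                atom_index=molecule.carbon_classes[cls][0],
                predicted_median=float(med),
                observed=float(y),
                abs_error=abs(float(med) - float(y)),
                p=p,
                dp5q=1.0 - p,
            )
        )
    mol_score = molecule_dp5q(scores)
    mae = float(np.mean([s.abs_error for s in scores]))
    return DP5qResult(
        atom_scores=scores,
        molecular_dp5q=mol_score,
        molecular_mae=mae,
        n_atoms=len(scores),
    )
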