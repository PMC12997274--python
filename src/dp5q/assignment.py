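"""Peak-to-environment assignment by minimum-cost bipartite matching.

When a peak list arrives without an assignment, each experimental peak
is matched to a predicted carbon environment (equivalence class) so
that the total absolute shift deviation is minimal.  The matching is
solved exactly with the Hungarian algorithm
(:func:`scipy.optimize.linear_sum_assignment`).  When class and peak
counts differ, the smaller side is fully matched and surplus classes
are left unmatched and excluded from scoring (overlapping peaks are a
real feature of crowded spectra, so this is reported, not an error).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.optimize import linear_sum_assignment

from .chem_io import MoleculeRecord, ShiftSpectrum

__all__ = ["Assignment", "assign", "enumerate_pairs"]


@dataclass
class Assignment:
    """Peak index -> carbon class index, with the total matching cost."""

    mapping: dict[int, int]
    total_cost: float
    unmatched_classes: list[int] = field(default_factory=list)
    unmatched_peaks: list[int] = field(default_factory=list)


def assign(class_medians, observed_shifts) -> Assignment:
    """Optimal |Δδ| matching between predicted classes and peaks.

    Deterministic: scipy's Hungarian solver is itself deterministic and
    cost ties are broken towards the lexicographically smallest
    (peak index, class index) pairing by an infinitesimal index bias.
    """
    preds = np.asarray(class_medians, dtype=float)
    peaks = np.asarray(observed_shifts, dtype=float)
    if preds.size == 0 or peaks.size == 0:
        raise ValueError("assign requires at least one class and one peak")
    cost = np.abs(peaks[:, None] - preds[None, :])
    # deterministic tie-break favouring low (peak, class) indices
    tie = (np.arange(peaks.size)[:, None] * preds.size + np.arange(preds.size)[None, :])
    rows, cols = linear_sum_assignment(cost + 1e-12 * tie)
    mapping = {int(r): int(c) for r, c in zip(rows, cols)}
    total = float(sum(cost[r, c] for r, c in zip(rows, cols)))
    return Assignment(
        mapping=mapping,
        total_cost=total,
        unmatched_classes=sorted(set(range(preds.size)) - set(cols)),
        unmatched_peaks=sorted(set(range(peaks.size)) - set(rows)),
    )


def enumerate_pairs(
    corpus: list[tuple[MoleculeRecord, ShiftSpectrum]]
) -> list[tuple[MoleculeRecord, ShiftSpectrum, str, int, int]]:
    """All labelled (molecule, spectrum) cross pairs with equal formula.

    Each molecule with its own spectrum is a correct pair; paired with
    another molecule's spectrum of the same molecular formula it is an
    incorrect pair.  Tuples carry (molecule, spectrum, label,
    molecule_index, spectrum_index).
    """
    if len(corpus) < 2:
        raise ValueError("need at least two records to enumerate pairs")
    formulae = [mol.formula for mol, _ in corpus]
    out = []
    for i, (mol, spec) in enumerate(corpus):
        out.append((mol, spec, "correct", i, i))
    for i, j in product(range(len(corpus)), repeat=2):
        if i != j and formulae[i] == formulae[j]:
            mol = corpus[i][0]
            spec = ShiftSpectrum(shifts=list(corpus[j][1].shifts), assignment=None)
            out.append((mol, spec, "incorrect", i, j))
    return out
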