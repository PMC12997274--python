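"""Benchmark evaluation: score distributions, ratio surfaces, ranking.

Reproduces the evaluation designs of the structure-confirmation
workflow at desk scale:

* score every labelled correct/incorrect structure–spectrum pair with
  the molecular DP5q score and the MAE of class-median predictions;
* bin the scored pairs over (MAE, DP5q) and report the fraction of
  correct interpretations per bin — an empirical probability of correct
  interpretation given the two summary metrics;
* rank candidate structures for one spectrum, reporting both the DP5q
  ranking and the MAE ranking, with the display normalisation that
  divides scores by the candidate count;
* classify pairs with a DP5q threshold (default 0.2) into confusion
  counts, treating "correct pair" as the positive class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem_io import MoleculeRecord, ShiftSpectrum
from .losses import QuantileGrid
from .scoring import score_pair

logger = logging.getLogger(__name__)

__all__ = [
    "RankingReport",
    "RatioSurface",
    "score_benchmark",
    "ratio_surface",
    "rank_candidates",
    "threshold_classify",
    "DEFAULT_MAE_EDGES",
    "DEFAULT_DP5Q_EDGES",
]

DEFAULT_MAE_EDGES = np.arange(0.0, 10.5, 0.5)
DEFAULT_DP5Q_EDGES = np.arange(0.0, 1.05, 0.05)


@dataclass
class RatioSurface:
    mae_edges: np.ndarray
    dp5q_edges: np.ndarray
    n_pairs: np.ndarray  # (n_mae_bins, n_dp5q_bins)
    n_correct: np.ndarray
    ratio: np.ndarray  # NaN where a bin is empty


@dataclass
class RankingReport:
    table: pd.DataFrame  # candidate, dp5q, mae, dp5q_normalised
    winner: int  # index of the argmax-dp5q candidate
    winner_by_mae: int
    tie: bool


def _predictor_quantiles(model, molecule: MoleculeRecord, conformers=None) -> np.ndarray:
    """Per-atom quantile matrix from any predictor-shaped object."""
    if conformers is not None and hasattr(model, "predict_ensemble"):
        return model.predict_ensemble(molecule, conformers)
    return model.predict_molecule(molecule)


def _grid_of(model) -> QuantileGrid:
    taus = getattr(model, "grid_", None)
    if isinstance(taus, QuantileGrid):
        return taus
    taus = getattr(model, "taus", None)
    return QuantileGrid(tuple(np.asarray(taus))) if taus is not None else QuantileGrid()


def score_benchmark(pairs, model) -> pd.DataFrame:
    """One row (label, dp5q, mae) per scorable labelled pair.

    Pairs may be :class:`~dp5q.synthetic.BenchmarkPair` objects or
    (molecule, spectrum, label, i, j) tuples.  Unassigned spectra are
    assigned automatically inside scoring; pairs that fail to score are
    logged and excluded (their count is in ``df.attrs['excluded']``).
    """
    grid = _grid_of(model)
    rows = []
    excluded = 0
    for pair in pairs:
        if hasattr(pair, "molecule"):
            mol, spec, label = pair.molecule, pair.spectrum, pair.label
            i, j = pair.molecule_index, pair.spectrum_index
        else:
            mol, spec, label, i, j = pair
        try:
            q = _predictor_quantiles(model, mol)
            res = score_pair(mol, q, spec, grid)
        except Exception as exc:
            logger.warning("excluding pair (%s, %s): %s", i, j, exc)
            excluded += 1
            continue
        rows.append(
            {
                "molecule_index": i,
                "spectrum_index": j,
                "label": label,
                "dp5q": res.molecular_dp5q,
                "mae": res.molecular_mae,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["excluded"] = excluded
    return df


def ratio_surface(
    table: pd.DataFrame,
    mae_edges=DEFAULT_MAE_EDGES,
    dp5q_edges=DEFAULT_DP5Q_EDGES,
) -> RatioSurface:
    """Correct-interpretation fraction per (MAE, DP5q) bin.

    Bins are half-open [lo, hi) except the last, which is closed; empty
    bins carry NaN (undefined), not zero.  Values outside the edge
    range are dropped from the surface but the per-bin counts conserve
    every in-range pair.
    """
    if table.empty:
        raise ValueError("table must be non-empty")
    mae_edges = np.asarray(mae_edges, dtype=float)
    dp5q_edges = np.asarray(dp5q_edges, dtype=float)
    for edges in (mae_edges, dp5q_edges):
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
    nm, nd = len(mae_edges) - 1, len(dp5q_edges) - 1
    n_pairs = np.zeros((nm, nd), dtype=int)
    n_correct = np.zeros((nm, nd), dtype=int)

    def bin_index(v, edges):
        if v < edges[0] or v > edges[-1]:
            return None
        idx = int(np.searchsorted(edges, v, side="right")) - 1
        return min(idx, len(edges) - 2)  # last bin closed

    for _, row in table.iterrows():
        bi = bin_index(row["mae"], mae_edges)
        bj = bin_index(row["dp5q"], dp5q_edges)
        if bi is None or bj is None:
            continue
        n_pairs[bi, bj] += 1
        if row["label"] == "correct":
            n_correct[bi, bj] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(n_pairs > 0, n_correct / np.maximum(n_pairs, 1), np.nan)
    return RatioSurface(mae_edges, dp5q_edges, n_pairs, n_correct, ratio)


def rank_candidates(
    candidates: list[MoleculeRecord],
    spectrum: ShiftSpectrum,
    model,
    conformers: list[list[int]] | None = None,
) -> RankingReport:
    """Score each candidate against one spectrum and rank by DP5q.

    The normalised column divides each score by the candidate count
    (the display convention for diastereomer panels); ties on the top
    score are flagged rather than broken silently.
    """
    if len(candidates) < 2:
        raise ValueError("ranking requires at least two candidates")
    grid = _grid_of(model)
    rows = []
    for k, mol in enumerate(candidates):
        confs = conformers[k] if conformers is not None else None
        q = _predictor_quantiles(model, mol, confs)
        spec = ShiftSpectrum(shifts=list(spectrum.shifts), assignment=None)
        res = score_pair(mol, q, spec, grid)
        rows.append({"candidate": k, "dp5q": res.molecular_dp5q, "mae": res.molecular_mae})
    df = pd.DataFrame(rows)
    df["dp5q_normalised"] = df["dp5q"] / len(candidates)
    best = df["dp5q"].max()
    winners = df.index[np.isclose(df["dp5q"], best)].tolist()
    return RankingReport(
        table=df,
        winner=int(df["dp5q"].idxmax()),
        winner_by_mae=int(df["mae"].idxmin()),
        tie=len(winners) > 1,
    )


def threshold_classify(table: pd.DataFrame, threshold: float = 0.2) -> dict[str, int]:
    """Confusion counts when pairs with dp5q < threshold are discarded.

    Positive class = correct pair; predicted positive = dp5q ≥
    threshold.  The default threshold 0.2 is the recommended operating
    point for discarding incorrect proposals.
    """
    keep = table["dp5q"] >= threshold
    correct = table["label"] == "correct"
    return {
        "TP": int((keep & correct).sum()),
        "FP": int((keep & ~correct).sum()),
        "TN": int((~keep & ~correct).sum()),
        "FN": int((~keep & correct).sum()),
    }
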