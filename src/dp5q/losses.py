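"""Composite quantile-regression training objective.

The objective has two parts.  The prediction term applies, for every
quantile level τ on the grid, a modified Huber loss to the residual
``y − ŷ_τ`` weighted asymmetrically: weight τ for under-prediction
(``ŷ_τ < y``) and ``1 − τ`` for over-prediction.  The Huber smoothing
(scale δ, default 1e-4 ppm) keeps the gradient well-defined at zero
residual; as δ → 0 each term converges to the classical pinball loss
whose minimiser is the τ-quantile, and the deviation is bounded by δ/2.
At τ = 0.75 an under-prediction therefore costs three times an
over-prediction of the same size; at τ = 0.5 the two cost the same and
the model is guided to the median.

The regularisation term penalises quantile crossing: for consecutive
grid levels it adds ``max(0, ŷ_τk − ŷ_τk+1 + ε)``, zero only when each
successive quantile exceeds its predecessor by at least the margin ε
(default 1e-6).  The total loss is the per-atom mean of the prediction
sum plus ``mono_weight`` times the crossing penalty.

All functions accept numpy arrays (plain evaluation) or autodiff
tensors (training); see :mod:`dp5q.autodiff`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad

__all__ = [
    "QuantileGrid",
    "LossConfig",
    "huber",
    "quantile_loss",
    "multi_quantile_loss",
    "monotonicity_penalty",
    "total_loss",
    "pinball",
]


@dataclass(frozen=True)
class QuantileGrid:
    """Strictly increasing quantile levels in (0, 1).

    The default grid is the 99 percentiles 0.01, 0.02, …, 0.99; the 0th
    and 100th percentiles are excluded because they correspond to the
    extremes of the training data rather than a modelled quantity.
    """

    taus: tuple[float, ...] = field(
        default_factory=lambda: tuple(np.round(np.arange(1, 100) / 100.0, 2))
    )

    def __post_init__(self):
        t = np.asarray(self.taus, dtype=float)
        if t.ndim != 1 or len(t) == 0:
            raise ValueError("taus must be a non-empty 1-D sequence")
        if not (np.all(t > 0.0) and np.all(t < 1.0)):
            raise ValueError("taus must lie strictly inside (0, 1)")
        if not np.all(np.diff(t) > 0.0):
            raise ValueError("taus must be strictly increasing")
        object.__setattr__(self, "taus", tuple(float(x) for x in t))

    def __len__(self) -> int:
        return len(self.taus)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.taus, dtype=float)

    @property
    def median_index(self) -> int | None:
        t = self.array
        hits = np.flatnonzero(np.isclose(t, 0.5))
        return int(hits[0]) if hits.size else None


@dataclass
class LossConfig:
    delta: float = 1e-4
    epsilon: float = 1e-6
    mono_weight: float = 1.0
    grid: QuantileGrid = field(default_factory=QuantileGrid)

    def __post_init__(self):
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.mono_weight < 0:
            raise ValueError("mono_weight must be non-negative")


def huber(residual, delta: float = 1e-4):
    """Smoothed absolute error, C¹ everywhere.

    Quadratic ``r²/(2δ)`` for ``|r| ≤ δ``, linear ``|r| − δ/2`` beyond.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    return ad.huber_value(residual, delta)


def pinball(y, yhat, tau):
    """Classical pinball loss τ·max(y−ŷ, 0) + (1−τ)·max(ŷ−y, 0)."""
    r = np.asarray(y, dtype=float) - np.asarray(yhat, dtype=float)
    return np.where(r > 0, tau * r, (tau - 1.0) * r)


def quantile_loss(y, yhat, tau: float, delta: float = 1e-4):
    """Asymmetric Huber term for one quantile level."""
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must lie in (0, 1), got {tau}")
    if delta <= 0:
        raise ValueError("delta must be positive")
    if isinstance(yhat, ad.Tensor) or isinstance(y, ad.Tensor):
        residual = ad.add(y, ad.mul(yhat, -1.0)) if isinstance(yhat, ad.Tensor) else y - yhat
        return ad.quantile_huber(residual, tau, delta)
    return ad.quantile_huber(np.asarray(y, dtype=float) - np.asarray(yhat, dtype=float), tau, delta)


def multi_quantile_loss(y, yhat_vector, config: LossConfig | None = None):
    """Sum of the asymmetric Huber terms over the whole quantile grid.

    ``y`` is the observed shift (scalar per atom, broadcastable);
    ``yhat_vector`` has one column per grid entry.  Zero iff every
    entry equals ``y``.
    """
    config = config or LossConfig()
    taus = config.grid.array
    if isinstance(yhat_vector, ad.Tensor):
        if yhat_vector.v.shape[-1] != len(taus):
            raise ValueError("prediction vector length does not match the quantile grid")
        y_col = np.asarray(y, dtype=float).reshape(-1, 1) if np.ndim(y) else np.float64(y)
        residual = ad.add(y_col, ad.mul(yhat_vector, -1.0))
        return ad.total_sum(ad.quantile_huber(residual, taus, config.delta), axis=-1)
    yhat_vector = np.asarray(yhat_vector, dtype=float)
    if yhat_vector.shape[-1] != len(taus):
        raise ValueError("prediction vector length does not match the quantile grid")
    y_col = np.expand_dims(np.asarray(y, dtype=float), -1)
    return np.sum(ad.quantile_huber(y_col - yhat_vector, taus, config.delta), axis=-1)


def monotonicity_penalty(yhat_vector, epsilon: float = 1e-6):
    """Crossing penalty: Σ_k max(0, ŷ_τk − ŷ_τk+1 + ε) over adjacent pairs."""
    if isinstance(yhat_vector, ad.Tensor):
        if yhat_vector.v.shape[-1] < 2:
            raise ValueError("need at least two quantiles")
        lead = yhat_vector[..., :-1]
        lag = yhat_vector[..., 1:]
        gap = ad.add(ad.add(lead, ad.mul(lag, -1.0)), epsilon)
        return ad.total_sum(ad.relu(gap), axis=-1)
    v = np.asarray(yhat_vector, dtype=float)
    if v.shape[-1] < 2:
        raise ValueError("need at least two quantiles")
    gap = v[..., :-1] - v[..., 1:] + epsilon
    return np.sum(np.maximum(gap, 0.0), axis=-1)


def total_loss(y, yhat_matrix, config: LossConfig | None = None):
    """Mean over atoms of prediction sum + mono_weight × crossing penalty."""
    config = config or LossConfig()
    if isinstance(yhat_matrix, ad.Tensor):
        if yhat_matrix.v.shape[0] == 0:
            raise ValueError("empty batch")
        pred = multi_quantile_loss(y, yhat_matrix, config)
        pen = monotonicity_penalty(yhat_matrix, config.epsilon)
        return ad.mean(ad.add(pred, ad.mul(pen, config.mono_weight)))
    yhat_matrix = np.asarray(yhat_matrix, dtype=float)
    if yhat_matrix.shape[0] == 0:
        raise ValueError("empty batch")
    pred = multi_quantile_loss(y, yhat_matrix, config)
    pen = monotonicity_penalty(yhat_matrix, config.epsilon)
    return float(np.mean(pred + config.mono_weight * pen))
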