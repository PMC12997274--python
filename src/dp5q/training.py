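"""Training loop for the quantile network.

Adam with an initial learning rate of 5e-4 reduced by 4% every 100 000
optimiser steps, up to 1200 epochs, early stopping when the validation
loss has not strictly improved for 10 consecutive epochs, returning the
parameters of the best validation epoch.  The train/validation split is
by molecule.  Per-atom targets come from the assigned spectrum: every
carbon inherits the shift of its equivalence class; classes without an
assigned peak are excluded from the objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .chem_io import MoleculeRecord, ShiftSpectrum
from .losses import LossConfig, total_loss
from .model import Graph, ModelConfig, batch_graphs, featurize, forward, init_params

__all__ = ["TrainConfig", "split", "train", "train_loop", "learning_rate_at"]


@dataclass
class TrainConfig:
    max_epochs: int = 1200
    learning_rate: float = 5e-4
    lr_decay: float = 0.04
    decay_interval: int = 100_000
    optimizer: str = "adam"
    patience: int = 10
    val_fraction: float = 0.1
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if not 0.0 <= self.lr_decay < 1.0:
            raise ValueError("decay fraction must lie in [0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


def learning_rate_at(step: int, config: TrainConfig) -> float:
    """Stepwise-decayed rate: lr0 · (1 − decay)^(step // interval)."""
    k = step // config.decay_interval
    return config.learning_rate * (1.0 - config.lr_decay) ** k


def split(corpus: list, fraction: float, seed: int) -> tuple[list, list]:
    """Reproducible by-molecule split into (train, held-out).

    ``fraction`` is the training share; the two sides are disjoint and
    exhaustive.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly in (0, 1)")
    if len(corpus) < 2:
        raise ValueError("corpus must contain at least two molecules")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(corpus))
    n_train = int(round(fraction * len(corpus)))
    n_train = min(max(n_train, 1), len(corpus) - 1)
    train_idx = sorted(order[:n_train])
    val_idx = sorted(order[n_train:])
    return [corpus[i] for i in train_idx], [corpus[i] for i in val_idx]


def _targets_for(molecule: MoleculeRecord, spectrum: ShiftSpectrum) -> tuple[np.ndarray, np.ndarray]:
    """(carbon-row mask, per-carbon target shifts) for assigned classes."""
    if spectrum.assignment is None:
        raise ValueError(
            f"spectrum for {molecule.smiles} has no assignment; training needs assigned shifts"
        )
    class_shift = {cls: spectrum.shifts[peak] for peak, cls in spectrum.assignment.items()}
    atom_class = molecule.class_of_atom()
    carbons = molecule.carbon_indices
    mask = np.array([atom_class[a] in class_shift for a in carbons], dtype=bool)
    y = np.array([class_shift.get(atom_class[a], np.nan) for a in carbons], dtype=float)
    return mask, y


class _Adam:
    def __init__(self, params: dict[str, np.ndarray]):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray], lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)


def _prepare(molecules, spectra, model_config):
    items = []
    for mol, spec in zip(molecules, spectra):
        g = featurize(mol, 0, model_config)
        mask, y = _targets_for(mol, spec)
        if mask.sum() == 0:
            raise ValueError(f"molecule {mol.smiles} has no assigned carbon shifts")
        items.append((g, mask, y))
    return items


def _batch(items):
    g = batch_graphs([it[0] for it in items])
    mask = np.concatenate([it[1] for it in items])
    y = np.concatenate([it[2] for it in items])
    return g, mask, y[mask]


def _eval_loss(params, g: Graph, mask, y, model_config, loss_config, center, scale) -> float:
    pred = forward(params, g, model_config, center, scale)
    return float(total_loss(y, np.asarray(pred)[mask], loss_config))


def train_loop(
    molecules: list[MoleculeRecord],
    spectra: list[ShiftSpectrum],
    model_config: ModelConfig,
    train_config: TrainConfig,
    loss_config: LossConfig,
):
    """Fit the network; returns (params, history, best_epoch, center, scale)."""
    pairs = list(zip(molecules, spectra))
    train_set, val_set = split(pairs, 1.0 - train_config.val_fraction, train_config.seed)
    train_items = _prepare([p[0] for p in train_set], [p[1] for p in train_set], model_config)
    val_items = _prepare([p[0] for p in val_set], [p[1] for p in val_set], model_config)

    all_y = np.concatenate([it[2][it[1]] for it in train_items])
    center = float(np.mean(all_y))
    scale = float(np.std(all_y) + 1e-9)

    params = init_params(model_config)
    # start the head bias on a monotone Gaussian quantile shape (prior
    # width 2 ppm) so the spread is learned as a correction, not from zero
    from scipy.stats import norm

    params["b_out"] = norm.ppf(model_config.grid.array) * (2.0 / scale)
    opt = _Adam(params)
    rng = np.random.default_rng(train_config.seed)
    val_graph = _batch(val_items)

    best_loss = np.inf
    best_params = {k: v.copy() for k, v in params.items()}
    best_epoch = -1
    since_improvement = 0
    step = 0
    rows = []

    for epoch in range(train_config.max_epochs):
        order = rng.permutation(len(train_items))
        epoch_losses = []
        for start in range(0, len(order), train_config.batch_size):
            sel = order[start : start + train_config.batch_size]
            g, mask, y = _batch([train_items[i] for i in sel])
            tparams = {k: Tensor(v, requires_grad=True) for k, v in params.items()}
            pred = forward(tparams, g, model_config, center, scale)
            loss = total_loss(y, pred[mask], loss_config)
            if not np.isfinite(loss.v):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, step {step}"
                )
            loss.backward()
            grads = {k: tparams[k].grad for k in params}
            opt.step(params, grads, learning_rate_at(step, train_config))
            step += 1
            epoch_losses.append(float(loss.v))

        val_loss = _eval_loss(params, *val_graph, model_config, loss_config, center, scale)
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        rows.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(epoch_losses)),
                "val_loss": val_loss,
                "lr": learning_rate_at(step, train_config),
            }
        )
        if val_loss < best_loss:
            best_loss = val_loss
            best_params = {k: v.copy() for k, v in params.items()}
            best_epoch = epoch
            since_improvement = 0
        else:
            since_improvement += 1
            if since_improvement >= train_config.patience:
                break

    history = pd.DataFrame(rows)
    return best_params, history, best_epoch, center, scale


def train(
    molecules: list[MoleculeRecord],
    spectra: list[ShiftSpectrum],
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    loss_config: LossConfig | None = None,
):
    """Functional wrapper: build and fit a :class:`QuantileShiftRegressor`."""
    from .model import QuantileShiftRegressor

    mc = model_config or ModelConfig()
    tc = train_config or TrainConfig()
    lc = loss_config or LossConfig(grid=mc.grid)
    est = QuantileShiftRegressor(
        taus=mc.grid.taus,
        hidden_width=mc.hidden_width,
        n_steps=mc.n_steps,
        n_rbf=mc.n_rbf,
        cutoff=mc.cutoff,
        delta=lc.delta,
        epsilon=lc.epsilon,
        mono_weight=lc.mono_weight,
        learning_rate=tc.learning_rate,
        lr_decay=tc.lr_decay,
        decay_interval=tc.decay_interval,
        max_epochs=tc.max_epochs,
        patience=tc.patience,
        val_fraction=tc.val_fraction,
        batch_size=tc.batch_size,
        random_state=tc.seed,
    )
    est.fit(molecules, spectra)
    return est, est.history_
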