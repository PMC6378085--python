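"""Training protocol: Gaussian initialization, SGD with momentum and L2
weight decay, learning-rate halving against a frozen early baseline, and a
relative-change stopping rule.

The schedule works on the per-epoch mean training loss. The mean loss of the
first ten epochs is frozen as the *baseline*; afterwards, whenever the
improvement over the previous epoch falls below 1% of that baseline the
learning rate is halved. Training stops when the relative difference between
consecutive epoch losses drops below ``rel_tol`` (1e-4) or at the epoch cap
(150). Validation loss, when a validation set is supplied, only selects the
checkpoint that is restored at the end; it never drives the schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import losses as L
from .nn import SGD, Adam
from .model import Network


__all__ = [
    "TrainConfig",
    "TrainingState",
    "DivergenceError",
    "init_weights",
    "lr_schedule_step",
    "stopping_criterion",
    "train",
]


class DivergenceError(RuntimeError):
    """Raised when the objective stops being finite during optimization."""


@dataclass
class TrainConfig:
    lr0: float = 0.001
    momentum: float = 0.9
    weight_decay: float = L.DEFAULT_WEIGHT_DECAY   # 5e-4
    max_epochs: int = 150
    rel_tol: float = 1e-4          # stopping: relative loss change
    halving_frac: float = 0.01     # LR halves when improvement < this x baseline
    baseline_epochs: int = 10      # epochs averaged into the frozen baseline
    batch_size: int = 8
    seed: int = 0
    loss_terms: str = "s+c"        # ablation arm: wce | c | s | s+c
    band_width: int = L.DEFAULT_BAND_WIDTH
    pos_weight: float = 1.0
    optimizer: str = "sgd"         # sgd (protocol default) | adam

    def __post_init__(self):
        for name in ("lr0", "rel_tol", "halving_frac", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")
        if self.loss_terms not in L.LOSS_ARMS:
            raise ValueError(f"loss_terms must be one of {L.LOSS_ARMS}")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError("optimizer must be 'sgd' or 'adam'")


@dataclass
class TrainingState:
    epoch: int = 0
    lr: float = 0.001
    loss_history: list = field(default_factory=list)       # per-epoch mean L
    lr_history: list = field(default_factory=list)         # lr used each epoch
    val_history: list = field(default_factory=list)
    baseline: float | None = None
    baseline_epochs: int = 10
    halving_frac: float = 0.01
    stopped: bool = False
    stop_reason: str | None = None
    best_epoch: int | None = None


def init_weights(network: Network, seed: int = 0) -> Network:
    """Gaussian weight initialization, deterministic given the seed.

    Convolution kernels draw from N(0, 2 / fan_in) (He scaling, suited to the
    ReLU nonlinearities); biases start at zero, batch-norm gains at one, and
    running statistics are reset.
    """
    rng = np.random.default_rng(seed)
    for name, p in network.named_parameters():
        if p.data.ndim == 4:  # conv / deconv kernels
            fan_in = p.data.shape[1] * p.data.shape[2] * p.data.shape[3]
            p.data = rng.normal(0.0, np.sqrt(2.0 / fan_in), p.data.shape)
        elif name.endswith(".weight"):  # batch-norm gains
            p.data = np.ones_like(p.data)
        else:  # all biases
            p.data = np.zeros_like(p.data)
    for m in network.modules():
        if hasattr(m, "running_mean"):
            m.running_mean = np.zeros_like(m.running_mean)
            m.running_var = np.ones_like(m.running_var)
    return network


def lr_schedule_step(state: TrainingState, epoch_loss: float) -> TrainingState:
    """Record one epoch's mean loss and apply the halving rule.

    The baseline (mean of the first ``baseline_epochs`` losses) is frozen
    once formed; from the next epoch on, the learning rate is halved whenever
    ``previous_loss - epoch_loss < halving_frac * baseline``.
    """
    prev = state.loss_history[-1] if state.loss_history else None
    state.loss_history.append(float(epoch_loss))
    state.lr_history.append(state.lr)
    state.epoch = len(state.loss_history)
    n0 = state.baseline_epochs
    if state.baseline is None and len(state.loss_history) >= n0:
        state.baseline = float(np.mean(state.loss_history[:n0]))
        return state  # the baseline-forming epoch itself never halves
    if state.baseline is not None and prev is not None:
        if (prev - epoch_loss) < state.halving_frac * state.baseline:
            state.lr /= 2.0
    return state


def stopping_criterion(state: TrainingState, rel_tol: float = 1e-4,
                       max_epochs: int = 150) -> tuple[bool, str | None]:
    """Stop when consecutive epoch losses agree to ``rel_tol`` relatively,
    or at the epoch cap."""
    if len(state.loss_history) >= 2:
        prev, cur = state.loss_history[-2], state.loss_history[-1]
        rel = abs(prev - cur) / max(abs(prev), 1e-12)
        if rel < rel_tol:
            return True, "converged"
    if state.epoch >= max_epochs:
        return True, "max_epochs"
    return False, None


def _epoch_pass(network, images, masks, bands, order, config, optimizer):
    """One pass over the training patches; returns the mean batch loss."""
    total, nb = 0.0, 0
    bs = config.batch_size
    for start in range(0, len(order), bs):
        idx = order[start:start + bs]
        pred = network(images[idx])
        batch_bands = L.stack_bands([bands[i] for i in idx])
        br = L.total_objective(pred, masks[idx], batch_bands,
                               terms=config.loss_terms,
                               pos_weight=config.pos_weight)
        if not np.isfinite([br.L, br.L_wce, br.L_c, br.L_s]).all():
            bad = [n for n, v in
                   [("wce", br.L_wce), ("c", br.L_c), ("s", br.L_s)]
                   if not np.isfinite(v)]
            raise DivergenceError(f"non-finite loss term(s) {bad}")
        optimizer.zero_grad()
        br.tensor.backward()
        optimizer.step()
        total += br.L
        nb += 1
    return total / max(nb, 1)


def _mean_eval_loss(network, images, masks, bands, config) -> float:
    network.eval()
    pred = network(images)
    br = L.total_objective(pred, masks, L.stack_bands(bands),
                           terms=config.loss_terms,
                           pos_weight=config.pos_weight)
    network.train()
    return br.L


def train(network: Network, images: np.ndarray, masks: np.ndarray,
          config: TrainConfig, val_images: np.ndarray | None = None,
          val_masks: np.ndarray | None = None) -> tuple[Network, TrainingState]:
    """Optimize the network on patch arrays (images (N,1,S,S), masks (N,S,S)).

    Deterministic given the config seed: initialization, per-epoch shuffling
    and all kernels are seeded. When a validation set is given, the weights
    of the best-validation-loss epoch are restored at the end.
    """
    if len(images) == 0:
        raise ValueError("empty patch set")
    init_weights(network, config.seed)
    state = TrainingState(lr=config.lr0, baseline_epochs=config.baseline_epochs,
                          halving_frac=config.halving_frac)
    if config.max_epochs == 0:
        return network, state

    masks = np.asarray(masks, dtype=np.float64)
    bands = [L.compute_contour_bands(m, config.band_width) for m in masks]
    val_bands = ([L.compute_contour_bands(m, config.band_width)
                  for m in np.asarray(val_masks)]
                 if val_masks is not None else None)
    if config.optimizer == "adam":
        optimizer = Adam(network.parameters(), lr=config.lr0,
                         weight_decay=config.weight_decay)
    else:
        optimizer = SGD(network.parameters(), lr=config.lr0,
                        momentum=config.momentum, weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)
    network.train()
    best_val, best_state = np.inf, None

    for _ in range(config.max_epochs):
        order = rng.permutation(len(images))
        optimizer.lr = state.lr
        try:
            epoch_loss = _epoch_pass(network, images, masks, bands, order,
                                     config, optimizer)
        except DivergenceError as err:
            raise DivergenceError(f"epoch {state.epoch + 1}: {err}") from None
        if not np.isfinite(epoch_loss):
            raise DivergenceError(f"non-finite mean loss in epoch {state.epoch + 1}")
        lr_schedule_step(state, epoch_loss)
        if val_images is not None:
            vloss = _mean_eval_loss(network, val_images, np.asarray(val_masks,
                                    dtype=np.float64), val_bands, config)
            state.val_history.append(vloss)
            if vloss < best_val:
                best_val = vloss
                best_state = network.state_dict()
                state.best_epoch = state.epoch
        stop, reason = stopping_criterion(state, config.rel_tol, config.max_epochs)
        if stop:
            state.stopped = True
            state.stop_reason = reason
            break

    if best_state is not None:
        network.load_state_dict(best_state)
    network.eval()
    return network, state
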