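"""Autoencoder imputation of incomplete distance matrices.

An undercomplete autoencoder learns to reconstruct each taxon's row of the
distance matrix: encoder f and decoder g are trained so that g(f(x)) ~ x,
with capacity constrained by a bottleneck and aggressive dropout so the
network must learn salient structure rather than the identity map.

Architecture: input N -> three hidden ReLU layers (default widths
N, ceil(N/2), N) -> sigmoid output of width N.  Dropout (default rate
0.75) is applied to the hidden activations during training only.  Because
the output activation is a sigmoid, distances are scaled into [0, 1] by
1.05 x the largest observed entry and scaled back afterwards.

Training/imputation loop: missing cells are first filled with seeded
random values in the observed range; then each iteration takes one Adam
step on all rows as a batch, minimizing the reconstruction error

    L(R, R') = sum over non-missing cells of (R_i - R'_i)^2

(observed cells only — the network is never penalized against its own
guesses), and then blends the deterministic predictions p into the missing
cells:

    x' = (1 - w) x + w p          (default w = 0.5)

The loop stops when L < tol (default 1e-6) or after ``max_iter`` (default
10,000) iterations.  Observed entries are restored verbatim at the end and
the imputed cells are symmetrized by averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil, sqrt
from typing import Optional

import numpy as np

from .matrix import MaskedDistanceMatrix

__all__ = [
    "AEConfig",
    "AEModel",
    "scale_matrix",
    "masked_mse",
    "blend_update",
    "ae_impute",
    "ae_impute_with_model",
]


class AEDivergenceError(RuntimeError):
    """Reconstruction loss became non-finite during training."""


@dataclass(frozen=True)
class AEConfig:
    """Hyperparameters for autoencoder imputation.

    ``hidden_sizes=None`` selects the default (N, ceil(N/2), N) for an
    N-taxon matrix.  ``w`` is the blend weight of Eq. x' = (1-w)x + wp.
    """

    hidden_sizes: Optional[tuple[int, int, int]] = None
    dropout: float = 0.75
    w: float = 0.5
    max_iter: int = 10_000
    tol: float = 1e-6
    seed: int = 0
    learning_rate: float = 1e-3

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if not 0.0 < self.w <= 1.0:
            raise ValueError("blend weight w must be in (0, 1]")
        if self.hidden_sizes is not None:
            if len(self.hidden_sizes) != 3 or any(h < 1 for h in self.hidden_sizes):
                raise ValueError("hidden_sizes must be three positive integers")
        if self.tol <= 0 or self.max_iter < 1 or self.learning_rate <= 0:
            raise ValueError("tol, max_iter and learning_rate must be positive")


@dataclass
class AEModel:
    """Trained network (weights/biases per layer) plus the distance scale."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    dropout: float
    scale: float
    loss_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_iter(self) -> int:
        return len(self.loss_trace)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Deterministic (no-dropout) forward pass; rows are samples."""
        a = x
        for wgt, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.maximum(a @ wgt + b, 0.0)
        z = a @ self.weights[-1] + self.biases[-1]
        return 1.0 / (1.0 + np.exp(-z))


def scale_matrix(m: MaskedDistanceMatrix) -> tuple[np.ndarray, float]:
    """Map distances into [0, 1] for the sigmoid output layer.

    scale = 1.05 x the largest observed entry, so scaled values lie in
    [0, 1/1.05]; multiplying back by ``scale`` inverts exactly.  If every
    observed entry is zero the scale is undefined; unit scale is used with
    a warning.
    """
    obs = m.values[~m.mask]
    vmax = float(obs.max()) if obs.size else 0.0
    if vmax <= 0.0:
        warnings.warn("all observed entries are zero; using unit scale")
        return m.values.copy(), 1.0
    scale = vmax * 1.05
    return m.values / scale, scale


def masked_mse(r: np.ndarray, r_prime: np.ndarray, nm: np.ndarray) -> float:
    """Reconstruction error: sum of squared differences over non-missing cells.

    ``nm`` is a boolean array, ``True`` for cells that participate (the
    non-missing set; diagonal zeros are observed and included).  Written as
    a sum, which is what the stopping threshold is compared against.
    """
    if r.shape != r_prime.shape:
        raise ValueError("matrices differ in shape")
    if not nm.any():
        raise ValueError("empty non-missing set")
    diff = (r - r_prime)[nm]
    return float(diff @ diff)


def blend_update(x, p, w: float):
    """Convex blend x' = (1 - w) x + w p applied to missing cells."""
    if not 0.0 < w <= 1.0:
        raise ValueError("w must be in (0, 1]")
    return (1.0 - w) * x + w * p


def _init_layers(sizes: list[int], rng: np.random.Generator):
    """Glorot-uniform weights, zero biases."""
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        limit = sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


def ae_impute_with_model(
    m: MaskedDistanceMatrix, cfg: AEConfig = AEConfig()
) -> tuple[MaskedDistanceMatrix, Optional[AEModel]]:
    """Impute and also return the trained model (``None`` for complete input)."""
    if m.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if m.is_complete:
        return m.copy(), None
    if m.observed_count == 0:
        raise ValueError("matrix has no observed off-diagonal entries")

    n = m.n_taxa
    hidden = cfg.hidden_sizes or (n, ceil(n / 2), n)
    sizes = [n, *hidden, n]
    rng = np.random.default_rng(cfg.seed)
    weights, biases = _init_layers(sizes, rng)

    scaled, scale = scale_matrix(m)
    nm = ~m.mask  # non-missing cells, diagonal included
    target = scaled.copy()
    target[m.mask] = 0.0  # never used in the loss; keep finite

    # random initial fill in the observed (scaled) range
    obs_max = float(scaled[nm].max()) if nm.any() else 1.0
    current = scaled.copy()
    n_missing_cells = int(m.mask.sum())
    current[m.mask] = rng.random(n_missing_cells) * obs_max

    keep = 1.0 - cfg.dropout
    lr = cfg.learning_rate
    b1, b2, eps = 0.9, 0.999, 1e-8
    params = weights + biases
    adam_m = [np.zeros_like(p) for p in params]
    adam_v = [np.zeros_like(p) for p in params]
    trace = np.empty(cfg.max_iter)
    step = 0

    n_layers = len(weights)
    for it in range(cfg.max_iter):
        # training forward pass with inverted dropout on hidden activations
        acts = [current]
        preacts = []
        drop_masks = []
        a = current
        for li in range(n_layers - 1):
            z = a @ weights[li] + biases[li]
            a = np.maximum(z, 0.0)
            if keep < 1.0:
                dm = (rng.random(a.shape) < keep) / keep
                a = a * dm
            else:
                dm = np.ones_like(a)
            preacts.append(z)
            drop_masks.append(dm)
            acts.append(a)
        z_out = a @ weights[-1] + biases[-1]
        out = 1.0 / (1.0 + np.exp(-z_out))

        loss = masked_mse(target, out, nm)
        if not np.isfinite(loss):
            raise AEDivergenceError(
                f"non-finite reconstruction loss at iteration {it} "
                f"(seed={cfg.seed}, lr={lr}, dropout={cfg.dropout})"
            )
        trace[it] = loss
        step = it + 1
        if loss < cfg.tol:
            break

        # backprop of the masked squared-error sum
        d_out = np.where(nm, 2.0 * (out - target), 0.0)
        dz = d_out * out * (1.0 - out)
        grads_w = [np.empty(0)] * n_layers
        grads_b = [np.empty(0)] * n_layers
        grads_w[-1] = acts[-1].T @ dz
        grads_b[-1] = dz.sum(axis=0)
        da = dz @ weights[-1].T
        for li in range(n_layers - 2, -1, -1):
            da = da * drop_masks[li]
            dz = da * (preacts[li] > 0.0)
            grads_w[li] = acts[li].T @ dz
            grads_b[li] = dz.sum(axis=0)
            if li > 0:
                da = dz @ weights[li].T

        # Adam update
        t_adam = it + 1
        for p, g, mm, vv in zip(params, grads_w + grads_b, adam_m, adam_v):
            mm *= b1
            mm += (1 - b1) * g
            vv *= b2
            vv += (1 - b2) * g * g
            m_hat = mm / (1 - b1**t_adam)
            v_hat = vv / (1 - b2**t_adam)
            p -= lr * m_hat / (np.sqrt(v_hat) + eps)

        # blend deterministic predictions into the missing cells
        model = AEModel(weights, biases, cfg.dropout, scale)
        p_det = model.forward(current)
        current[m.mask] = blend_update(current[m.mask], p_det[m.mask], cfg.w)

    model = AEModel(weights, biases, cfg.dropout, scale, trace[:step].copy())

    values = current * scale
    # observed cells restored verbatim, imputed cells symmetrized by averaging
    values[nm] = m.values[nm]
    sym = (values + values.T) / 2.0
    values = np.where(m.mask, sym, values)
    np.fill_diagonal(values, 0.0)
    values = np.maximum(values, 0.0)
    values[nm] = m.values[nm]
    np.fill_diagonal(values, 0.0)
    return MaskedDistanceMatrix(m.labels, values), model


def ae_impute(
    m: MaskedDistanceMatrix, cfg: AEConfig = AEConfig()
) -> MaskedDistanceMatrix:
    """Complete matrix: observed entries verbatim, missing cells imputed by
    the trained autoencoder (see module docstring for the procedure)."""
    return ae_impute_with_model(m, cfg)[0]
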