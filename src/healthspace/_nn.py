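"""Compact numpy multilayer-perceptron machinery for the ordinal networks.

The networks here are tiny (tabular inputs with p <= ~10, two hidden
layers by default), so forward/backward passes and the Adam update are
written directly against numpy arrays. Parameters are kept as a flat list
of arrays: ``[W_1, b_1, ..., W_L, b_L, beta, alpha]`` where ``beta`` is
the shared coefficient vector of the last hidden representation and
``alpha`` the threshold intercepts.
"""

from __future__ import annotations

import numpy as np


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def softplus(z: np.ndarray) -> np.ndarray:
    # log(1 + e^z), stable for |z| up to overflow
    return np.logaddexp(0.0, z)


def init_params(
    p: int,
    hidden_widths: tuple[int, ...],
    n_thresholds: int,
    rng: np.random.Generator,
    alpha0: np.ndarray | None = None,
) -> list[np.ndarray]:
    """He-normal hidden layers; small-variance beta; alpha0 optionally set
    from empirical cumulative frequencies (a good convex-region start)."""
    params: list[np.ndarray] = []
    fan_in = p
    for width in hidden_widths:
        params.append(rng.standard_normal((fan_in, width)) * np.sqrt(2.0 / fan_in))
        params.append(np.zeros(width))
        fan_in = width
    params.append(rng.standard_normal(fan_in) / np.sqrt(fan_in))
    if alpha0 is None:
        alpha0 = np.linspace(1.0, -1.0, n_thresholds)
    params.append(np.asarray(alpha0, dtype=float).copy())
    return params


def forward_features(X: np.ndarray, params: list[np.ndarray]) -> np.ndarray:
    """W = f(X): ReLU hidden stack; identity when there are no hidden layers."""
    h = X
    for k in range(0, len(params) - 2, 2):
        h = np.maximum(h @ params[k] + params[k + 1], 0.0)
    return h


def forward_scores(X: np.ndarray, params: list[np.ndarray]) -> np.ndarray:
    """Shared linear score s_i = f(x_i)' beta (no intercept)."""
    return forward_features(X, params) @ params[-2]


def loss_and_grads(
    X: np.ndarray,
    targets: np.ndarray,
    params: list[np.ndarray],
) -> tuple[float, list[np.ndarray]]:
    """Mean-per-sample cumulative-logit cross-entropy and its gradients.

    ``targets`` is the n x (J-1) exceedance-indicator matrix I(y > j).
    The per-element loss is softplus(z) - z * t with z = s + alpha_j,
    which is the numerically stable form of the binary cross-entropy.
    """
    n = X.shape[0]
    # forward, caching activations for backprop
    acts = [X]
    h = X
    n_hidden = (len(params) - 2) // 2
    for k in range(n_hidden):
        h = np.maximum(h @ params[2 * k] + params[2 * k + 1], 0.0)
        acts.append(h)
    beta, alpha = params[-2], params[-1]
    s = h @ beta
    z = s[:, None] + alpha[None, :]
    loss = float(np.sum(softplus(z) - z * targets)) / n

    d_z = (sigmoid(z) - targets) / n
    d_alpha = d_z.sum(axis=0)
    d_s = d_z.sum(axis=1)
    d_beta = acts[-1].T @ d_s
    d_h = np.outer(d_s, beta)
    grads_hidden: list[np.ndarray] = []
    for k in range(n_hidden - 1, -1, -1):
        d_a = d_h * (acts[k + 1] > 0)
        grads_hidden.append(d_a.sum(axis=0))  # b_k
        grads_hidden.append(acts[k].T @ d_a)  # W_k
        if k > 0:
            d_h = d_a @ params[2 * k].T
    grads = grads_hidden[::-1] + [d_beta, d_alpha]
    return loss, grads


class Adam:
    """Standard Adam with bias correction over a flat parameter list."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 0.001,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)
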