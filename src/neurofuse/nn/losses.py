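"""Loss functions returning ``(value, gradient_wrt_input)`` pairs."""

from __future__ import annotations

import numpy as np


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def weighted_cross_entropy(
    logits: np.ndarray, labels: np.ndarray, class_weights: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Softmax cross-entropy with per-class weights.

    ``class_weights[c]`` rescales the negative log-likelihood of samples of
    class ``c``; the default (None) is uniform weight 1. The loss is the
    mean over the batch of ``w_y * (-log p_y)``.
    """
    n, k = logits.shape
    if labels.shape != (n,):
        raise ValueError(f"labels shape {labels.shape} does not match batch {n}")
    p = softmax(logits)
    if class_weights is None:
        class_weights = np.ones(k)
    w = class_weights[labels]
    nll = -np.log(np.clip(p[np.arange(n), labels], 1e-300, None))
    loss = float(np.mean(w * nll))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    grad *= (w / n)[:, None]
    return loss, grad


def lsgan_discriminator_loss(
    scores_real: np.ndarray, scores_fake: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares adversarial loss, discriminator side.

    ``mean[(D(real) - 1)^2] + mean[D(fake)^2]``; returns the loss and the
    gradients with respect to the real and fake score batches.
    """
    if scores_real.size == 0 or scores_fake.size == 0:
        raise ValueError("empty score batch")
    loss = float(np.mean((scores_real - 1.0) ** 2) + np.mean(scores_fake**2))
    g_real = 2.0 * (scores_real - 1.0) / scores_real.size
    g_fake = 2.0 * scores_fake / scores_fake.size
    return loss, g_real, g_fake


def lsgan_generator_loss(scores_fake: np.ndarray) -> tuple[float, np.ndarray]:
    """``mean[(D(fake) - 1)^2]`` and its gradient w.r.t. the fake scores."""
    if scores_fake.size == 0:
        raise ValueError("empty score batch")
    loss = float(np.mean((scores_fake - 1.0) ** 2))
    return loss, 2.0 * (scores_fake - 1.0) / scores_fake.size


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def bce_discriminator_loss(
    scores_real: np.ndarray, scores_fake: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Binary cross-entropy adversarial loss on raw scores (logits)."""
    if scores_real.size == 0 or scores_fake.size == 0:
        raise ValueError("empty score batch")
    pr, pf = _sigmoid(scores_real), _sigmoid(scores_fake)
    loss = float(
        -np.mean(np.log(np.clip(pr, 1e-300, None)))
        - np.mean(np.log(np.clip(1.0 - pf, 1e-300, None)))
    )
    return loss, (pr - 1.0) / scores_real.size, pf / scores_fake.size


def bce_generator_loss(scores_fake: np.ndarray) -> tuple[float, np.ndarray]:
    if scores_fake.size == 0:
        raise ValueError("empty score batch")
    pf = _sigmoid(scores_fake)
    loss = float(-np.mean(np.log(np.clip(pf, 1e-300, None))))
    return loss, (pf - 1.0) / scores_fake.size


def l1_loss(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute difference and its gradient with respect to ``x``."""
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    d = x - y
    return float(np.mean(np.abs(d))), np.sign(d) / d.size
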