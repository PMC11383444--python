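"""Composite training objective.

The total loss is

    L = L_e(yhat, y) + alpha * L_manifold + L_mask

where L_e is mean squared error (regression) or cross-entropy from logits
(classification); L_manifold = 1/2 sum_q sum_{j in N_q} ||h_q - h_j||^2 =
trace(H^T L H) smooths last-layer node embeddings over graph neighborhoods
(L is the unnormalized Laplacian of the *binary* adjacency support — the
only reading under which the double-sum and trace forms coincide); and
L_mask = lambda1 ||M||_1 + lambda2 ||M||_F^2 + lambda3 ||M M^T - I||_F
pushes the learned mask toward sparse, near-orthogonal rows.

Each loss ships with its analytic gradient; the gradients are checked
against finite differences in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossBreakdown",
    "binary_laplacian",
    "manifold_loss",
    "manifold_loss_grad",
    "mask_penalty",
    "mask_penalty_grad",
    "prediction_loss",
    "prediction_loss_grad",
    "total_loss",
    "softmax",
]


@dataclass
class LossBreakdown:
    """The three loss components and their exact affine combination."""

    prediction: float
    manifold: float
    mask: float
    alpha: float
    total: float

    @classmethod
    def combine(cls, prediction: float, manifold: float, mask: float,
                alpha: float) -> "LossBreakdown":
        return cls(prediction=prediction, manifold=manifold, mask=mask,
                   alpha=alpha, total=prediction + alpha * manifold + mask)


def binary_laplacian(adjacency: np.ndarray) -> np.ndarray:
    """Unnormalized Laplacian D - A of the binary support of an adjacency."""
    a = (np.asarray(adjacency) > 0).astype(float)
    np.fill_diagonal(a, 0.0)
    return np.diag(a.sum(axis=1)) - a


def manifold_loss(h: np.ndarray, adjacency: np.ndarray) -> float:
    """Smoothness of node embeddings over the graph: trace(H^T L H).

    ``h`` may be (Q, d) for one subject or (B, Q, d) for a batch with a
    matching (B, Q, Q) adjacency stack; the batch value is the mean over
    subjects.
    """
    h = np.asarray(h, dtype=float)
    a = np.asarray(adjacency, dtype=float)
    if h.ndim == 2:
        h, a = h[None], a[None]
    if a.ndim == 2:
        a = np.broadcast_to(a, (h.shape[0],) + a.shape)
    if h.shape[0] != a.shape[0] or h.shape[1] != a.shape[1]:
        raise ValueError("embedding and adjacency shapes are inconsistent")
    vals = np.empty(h.shape[0])
    for b in range(h.shape[0]):
        lap = binary_laplacian(a[b])
        vals[b] = np.trace(h[b].T @ lap @ h[b])
    return float(vals.mean())


def manifold_loss_grad(h: np.ndarray, adjacency: np.ndarray) -> np.ndarray:
    """Gradient of the batch-mean manifold loss w.r.t. the embeddings:
    2 L H / B per subject."""
    h = np.asarray(h, dtype=float)
    a = np.asarray(adjacency, dtype=float)
    squeeze = h.ndim == 2
    if squeeze:
        h, a = h[None], a[None]
    if a.ndim == 2:
        a = np.broadcast_to(a, (h.shape[0],) + a.shape)
    b = h.shape[0]
    out = np.empty_like(h)
    for i in range(b):
        out[i] = 2.0 * binary_laplacian(a[i]) @ h[i] / b
    return out[0] if squeeze else out


def mask_penalty(m: np.ndarray, lambda1: float, lambda2: float,
                 lambda3: float) -> float:
    """lambda1 ||M||_1 + lambda2 ||M||_F^2 + lambda3 ||M M^T - I||_F."""
    m = np.asarray(m, dtype=float)
    q = m.shape[0]
    l1 = np.abs(m).sum()
    fro2 = np.sum(m * m)
    ortho = np.linalg.norm(m @ m.T - np.eye(q), ord="fro")
    return float(lambda1 * l1 + lambda2 * fro2 + lambda3 * ortho)


def mask_penalty_grad(m: np.ndarray, lambda1: float, lambda2: float,
                      lambda3: float) -> np.ndarray:
    """Analytic gradient of :func:`mask_penalty` w.r.t. M.

    The (unsquared) orthonormality term ||E||_F with E = M M^T - I has
    gradient (E + E^T) M / ||E||_F; at the nondifferentiable point E = 0 the
    subgradient 0 is used.
    """
    m = np.asarray(m, dtype=float)
    q = m.shape[0]
    grad = lambda1 * np.sign(m) + 2.0 * lambda2 * m
    e = m @ m.T - np.eye(q)
    norm = np.linalg.norm(e, ord="fro")
    if norm > 0:
        grad = grad + lambda3 * (e + e.T) @ m / norm
    return grad


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    z = z - z.max(axis=axis, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=axis, keepdims=True)


def prediction_loss(yhat: np.ndarray, y: np.ndarray, task: str) -> float:
    """MSE over targets and batch (regression) or mean cross-entropy from
    logits (classification; labels are 0/1 integers)."""
    yhat = np.asarray(yhat, dtype=float)
    if task == "regression":
        y = np.asarray(y, dtype=float).reshape(yhat.shape)
        return float(np.mean((yhat - y) ** 2))
    if task == "classification":
        labels = np.asarray(y).astype(int).ravel()
        if np.any((labels < 0) | (labels >= yhat.shape[1])):
            raise ValueError("class label outside the class set")
        logz = yhat - yhat.max(axis=1, keepdims=True)
        log_prob = logz - np.log(np.exp(logz).sum(axis=1, keepdims=True))
        return float(-log_prob[np.arange(labels.size), labels].mean())
    raise ValueError(f"unknown task {task!r}")


def prediction_loss_grad(yhat: np.ndarray, y: np.ndarray, task: str) -> np.ndarray:
    """Gradient of :func:`prediction_loss` w.r.t. the model outputs."""
    yhat = np.asarray(yhat, dtype=float)
    n = yhat.shape[0]
    if task == "regression":
        y = np.asarray(y, dtype=float).reshape(yhat.shape)
        return 2.0 * (yhat - y) / yhat.size
    if task == "classification":
        labels = np.asarray(y).astype(int).ravel()
        p = softmax(yhat, axis=1)
        p[np.arange(n), labels] -= 1.0
        return p / n
    raise ValueError(f"unknown task {task!r}")


def total_loss(
    yhat: np.ndarray,
    y: np.ndarray,
    h_last: np.ndarray,
    adjacency: np.ndarray,
    m: np.ndarray,
    task: str,
    alpha: float,
    lambda1: float,
    lambda2: float,
    lambda3: float,
) -> LossBreakdown:
    """Assemble the full objective on one batch; the breakdown satisfies
    total == prediction + alpha * manifold + mask to machine precision."""
    return LossBreakdown.combine(
        prediction=prediction_loss(yhat, y, task),
        manifold=manifold_loss(h_last, adjacency),
        mask=mask_penalty(m, lambda1, lambda2, lambda3),
        alpha=alpha,
    )
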