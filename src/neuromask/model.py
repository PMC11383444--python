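"""The masked graph convolutional network.

A population-level edge mask M = sigmoid(V + V^T) — one free Q x Q matrix V
shared across layers and subjects — modulates message passing in an
otherwise standard two-layer GCN:

    H^{l+1} = phi( (M + I) ⊙ S  H^l  Theta^l ),    S = D~^{-1/2} A~ D~^{-1/2}

with A~ = A + I the self-loop-augmented adjacency and D~ its degree matrix.
The Hadamard product means the mask only reweights edges that exist in S;
the +I term guarantees an identity path so the filter cannot degenerate to
zero when M does.  After layer 1 the node embeddings are concatenated with
the per-region anatomical-statistics table C; after layer 2 the node axis is
pooled (mean by default) and a small dense readout produces the prediction
(real targets for regression, class logits for classification).

Everything here is plain numpy.  The backward pass is derived analytically
and is validated against central finite differences in the test suite; the
same machinery yields the gradients with respect to C used for Grad-RAM /
Grad-CAM attribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MaskGNN",
    "Adam",
    "normalized_structure",
    "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def normalized_structure(adjacency: np.ndarray) -> np.ndarray:
    """Symmetrically normalized self-loop-augmented adjacency
    S = D~^{-1/2} (A + I) D~^{-1/2}.

    Degrees are row sums of A + I, hence >= 1 even for isolated nodes, so the
    normalization is always defined.
    """
    a = np.asarray(adjacency, dtype=float)
    q = a.shape[0]
    a_tilde = a + np.eye(q)
    d = a_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return a_tilde * inv_sqrt[:, None] * inv_sqrt[None, :]


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


@dataclass
class _Cache:
    """Intermediate tensors of one batched forward pass."""

    s: np.ndarray  # (B, Q, Q)
    f: np.ndarray  # (B, Q, Q) masked filter
    h0: np.ndarray
    c: np.ndarray
    z1: np.ndarray
    h1: np.ndarray  # concat(relu(z1), C)
    z2: np.ndarray
    h2: np.ndarray
    pooled: np.ndarray  # (B, d2)
    z3: np.ndarray
    h3: np.ndarray
    y: np.ndarray  # (B, n_out)


class MaskGNN:
    """Two-layer masked GCN with mid-network AS fusion and dense readout.

    Parameters
    ----------
    q : number of graph nodes (ROIs).
    d0 : node input feature width (2Q for FC+SC profiles, Q for one modality).
    dc : width of the fused anatomical table (0 disables fusion).
    d1, d2 : hidden widths of the two graph layers.
    hidden : width of the dense readout's hidden layer.
    n_targets : output dimension for regression (ignored for classification,
        which always emits two class logits).
    task : "regression" | "classification".
    pooling : "mean" | "sum" | "max" node pooling.
    rng : numpy Generator for weight initialization.
    """

    PARAM_KEYS = ("V", "theta1", "theta2", "w3", "b3", "w4", "b4")

    def __init__(
        self,
        q: int,
        d0: int,
        dc: int = 0,
        d1: int = 64,
        d2: int = 64,
        hidden: int = 32,
        n_targets: int = 1,
        task: str = "regression",
        pooling: str = "mean",
        rng: np.random.Generator | None = None,
    ) -> None:
        if task not in ("regression", "classification"):
            raise ValueError(f"unknown task {task!r}")
        if pooling not in ("mean", "sum", "max"):
            raise ValueError(f"unknown pooling {pooling!r}")
        rng = rng if rng is not None else np.random.default_rng()
        self.q, self.d0, self.dc = q, d0, dc
        self.d1, self.d2, self.hidden = d1, d2, hidden
        self.task = task
        self.pooling = pooling
        self.n_out = 2 if task == "classification" else n_targets
        self.n_targets = n_targets

        def glorot(fan_in: int, fan_out: int) -> np.ndarray:
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=(fan_in, fan_out))

        self.params: dict[str, np.ndarray] = {
            "V": np.zeros((q, q)),  # mask starts flat at 0.5 everywhere
            "theta1": glorot(d0, d1),
            "theta2": glorot(d1 + dc, d2),
            "w3": glorot(d2, hidden),
            "b3": np.zeros(hidden),
            "w4": glorot(hidden, self.n_out),
            "b4": np.zeros(self.n_out),
        }

    # -- mask ---------------------------------------------------------------

    def mask(self) -> np.ndarray:
        """M = sigmoid(V + V^T): symmetric, entries strictly in (0, 1)."""
        v = self.params["V"]
        if not np.all(np.isfinite(v)):
            raise ValueError("mask parameters V contain non-finite values")
        return sigmoid(v + v.T)

    def dv_from_dm(self, dm: np.ndarray) -> np.ndarray:
        """Chain a gradient w.r.t. M back to V through sigmoid(V + V^T)."""
        m = self.mask()
        g = dm * m * (1.0 - m)
        return g + g.T

    # -- forward ------------------------------------------------------------

    def forward(
        self,
        s: np.ndarray,
        h0: np.ndarray,
        c: np.ndarray | None = None,
        return_cache: bool = False,
    ):
        """Batched forward pass.

        ``s`` is the stack of per-subject normalized structure matrices
        (B, Q, Q) from :func:`normalized_structure`; ``h0`` the node features
        (B, Q, d0); ``c`` the scaled AS tables (B, Q, dc) or None when
        ``dc == 0``.  Returns predictions (B, n_out), plus the cache when
        requested.
        """
        s = np.asarray(s, dtype=float)
        h0 = np.asarray(h0, dtype=float)
        if s.ndim == 2:
            s, h0 = s[None], h0[None]
            c = None if c is None else np.asarray(c, float)[None]
        b = s.shape[0]
        if c is None:
            c = np.zeros((b, self.q, self.dc))
        else:
            c = np.asarray(c, dtype=float)
            if c.ndim == 2:
                c = c[None]
        if s.shape[1:] != (self.q, self.q) or h0.shape != (b, self.q, self.d0):
            raise ValueError("input shapes inconsistent with model dimensions")
        if c.shape != (b, self.q, self.dc):
            raise ValueError("AS table shape inconsistent with model dimensions")
        if self.dc and (c.min() < -1e-9 or c.max() > 1 + 1e-9):
            import warnings

            warnings.warn("AS table entries outside [0, 1]; expected a scaled table")

        m = self.mask()
        f = (m + np.eye(self.q))[None, :, :] * s  # Hadamard: mask acts on existing edges only

        z1 = f @ (h0 @ self.params["theta1"])
        hhat1 = _relu(z1)
        h1 = np.concatenate([hhat1, c], axis=2)
        z2 = f @ (h1 @ self.params["theta2"])
        h2 = _relu(z2)

        if self.pooling == "mean":
            pooled = h2.mean(axis=1)
        elif self.pooling == "sum":
            pooled = h2.sum(axis=1)
        else:
            pooled = h2.max(axis=1)

        z3 = pooled @ self.params["w3"] + self.params["b3"]
        h3 = _relu(z3)
        y = h3 @ self.params["w4"] + self.params["b4"]

        if not return_cache:
            return y
        return y, _Cache(s=s, f=f, h0=h0, c=c, z1=z1, h1=h1, z2=z2, h2=h2,
                         pooled=pooled, z3=z3, h3=h3, y=y)

    # -- backward -----------------------------------------------------------

    def backward(
        self,
        cache: _Cache,
        dy: np.ndarray,
        dh2_extra: np.ndarray | None = None,
        dm_extra: np.ndarray | None = None,
        want_dc: bool = False,
    ):
        """Analytic gradients of sum_b <dy_b, y_b> (+ extra terms) w.r.t. all
        parameters.

        ``dy`` is the upstream gradient on the predictions (B, n_out); the
        caller folds in any 1/B batch-mean factors.  ``dh2_extra`` adds a
        gradient flowing directly into the last-layer embeddings (the
        manifold-smoothness term); ``dm_extra`` adds a gradient on the mask
        itself (the sparsity/orthonormality penalty).  With ``want_dc`` the
        gradient with respect to the fused AS block is returned as well —
        this is the Grad-RAM/Grad-CAM gradient matrix.
        """
        p = self.params
        b, q = cache.s.shape[0], self.q
        dy = np.asarray(dy, dtype=float).reshape(b, self.n_out)

        grads = {k: np.zeros_like(v) for k, v in p.items()}

        grads["w4"] = cache.h3.T @ dy
        grads["b4"] = dy.sum(axis=0)
        dh3 = dy @ p["w4"].T
        dz3 = dh3 * (cache.z3 > 0)
        grads["w3"] = cache.pooled.T @ dz3
        grads["b3"] = dz3.sum(axis=0)
        dpooled = dz3 @ p["w3"].T

        if self.pooling == "mean":
            dh2 = np.repeat(dpooled[:, None, :], q, axis=1) / q
        elif self.pooling == "sum":
            dh2 = np.repeat(dpooled[:, None, :], q, axis=1)
        else:  # max
            dh2 = np.zeros_like(cache.h2)
            arg = cache.h2.argmax(axis=1)  # (B, d2)
            bi = np.arange(b)[:, None]
            di = np.arange(self.d2)[None, :]
            dh2[bi, arg, di] = dpooled
        if dh2_extra is not None:
            dh2 = dh2 + dh2_extra

        dz2 = dh2 * (cache.z2 > 0)
        x2 = cache.h1 @ p["theta2"]
        ft = cache.f.transpose(0, 2, 1)
        g2 = ft @ dz2  # (B, Q, d2)
        grads["theta2"] = np.einsum("bqi,bqj->ij", cache.h1, g2)
        dh1 = g2 @ p["theta2"].T
        df = dz2 @ x2.transpose(0, 2, 1)

        dhhat1 = dh1[:, :, : self.d1]
        dc = dh1[:, :, self.d1 :]
        dz1 = dhhat1 * (cache.z1 > 0)
        x1 = cache.h0 @ p["theta1"]
        g1 = ft @ dz1
        grads["theta1"] = np.einsum("bqi,bqj->ij", cache.h0, g1)
        df += dz1 @ x1.transpose(0, 2, 1)

        dm = np.einsum("bij,bij->ij", df, cache.s)
        if dm_extra is not None:
            dm = dm + dm_extra
        grads["V"] = self.dv_from_dm(dm)

        if want_dc:
            return grads, dc
        return grads

    def grad_wrt_as(self, cache: _Cache, selector: int) -> np.ndarray:
        """d(selected output) / d(C) per subject: the attribution gradient.

        ``selector`` picks a regression target or a class logit.
        """
        if not 0 <= selector < self.n_out:
            raise ValueError(f"output selector {selector} out of range")
        b = cache.s.shape[0]
        dy = np.zeros((b, self.n_out))
        dy[:, selector] = 1.0
        _, dc = self.backward(cache, dy, want_dc=True)
        return dc

    # -- (de)serialization --------------------------------------------------

    def get_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for k in self.PARAM_KEYS:
            self.params[k] = np.array(state[k], dtype=float, copy=True)

    def meta(self) -> dict:
        return {
            "q": self.q, "d0": self.d0, "dc": self.dc, "d1": self.d1,
            "d2": self.d2, "hidden": self.hidden, "n_targets": self.n_targets,
            "task": self.task, "pooling": self.pooling, "format_version": 1,
        }

    def save(self, path) -> None:
        """Serialize parameters + architecture to a single .npz checkpoint."""
        np.savez(path, _meta=json.dumps(self.meta()), **self.params)

    @classmethod
    def load(cls, path) -> "MaskGNN":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["_meta"]))
            meta.pop("format_version", None)
            model = cls(**meta, rng=np.random.default_rng(0))
            model.set_state({k: data[k] for k in cls.PARAM_KEYS})
        return model


class Adam:
    """Adam optimizer with optional (coupled) L2 weight decay.

    Weight decay is applied to the layer and readout weights but not to the
    mask parameters V (which carry their own sparsity penalties) nor biases.
    """

    DECAY_KEYS = ("theta1", "theta2", "w3", "w4")

    def __init__(self, params: dict[str, np.ndarray], lr: float = 0.005,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0) -> None:
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            if self.weight_decay and k in self.DECAY_KEYS:
                g = g + self.weight_decay * params[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1 ** self.t)
            vhat = self.v[k] / (1 - self.beta2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
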