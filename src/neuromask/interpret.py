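"""Post-training interpretation: edges from the learned mask, node features
from gradient attribution.

* The learned mask M is thresholded for visualization: entries above the
  threshold (already on the (0, 1) sigmoid scale; typical thresholds sit
  just above the neutral 0.5) are retained, the rest zeroed.  The diagonal
  is excluded from reporting — the self-loop is architectural, not a
  finding.
* Grad-RAM (regression) / Grad-CAM (classification) attributes the fused
  anatomical features: per subject, the gradient G of the selected output
  with respect to the AS block C is combined as a = mean_q ReLU(G_q ⊙ C_q)
  and softmax-normalized over the feature axis; the cohort score is the
  subject mean.
* Retained edges can be aggregated to a functional-network-by-network
  table (mean retained weight and density per network pair).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import MaskGNN, sigmoid
from .objectives import softmax
from .training import Dataset, TrainResult

__all__ = [
    "ThresholdedMask",
    "threshold_mask",
    "activation_map",
    "grad_attribution",
    "network_aggregate",
    "edge_recovery_auc",
]


@dataclass
class ThresholdedMask:
    values: np.ndarray  # Q x Q; zero where below threshold; zero diagonal
    threshold: float
    n_edges: int  # retained undirected off-diagonal edges

    def edge_list(self) -> pd.DataFrame:
        """Retained edges (i < j) sorted by weight descending, ties broken
        lexicographically by (i, j)."""
        iu, ju = np.triu_indices(self.values.shape[0], k=1)
        w = self.values[iu, ju]
        keep = w > 0
        frame = pd.DataFrame({"roi_i": iu[keep], "roi_j": ju[keep],
                              "weight": w[keep]})
        return frame.sort_values(
            by=["weight", "roi_i", "roi_j"], ascending=[False, True, True]
        ).reset_index(drop=True)


def threshold_mask(m: np.ndarray, t: float,
                   double_sigmoid: bool = False) -> ThresholdedMask:
    """Zero out mask entries at or below the visualization threshold.

    ``m`` is the learned mask, already in (0, 1).  By default the
    comparison is ``m > t`` directly on that scale.  ``double_sigmoid``
    applies a second sigmoid before comparing (mapping (0,1) into
    (0.5, 0.731)), an alternative reading of the published rule; both keep
    the *retained values* equal to the original mask entries.
    """
    if not (0.0 < t < 1.0):
        raise ValueError("visualization threshold must lie in (0, 1)")
    m = np.asarray(m, dtype=float)
    crit = sigmoid(m) if double_sigmoid else m
    out = np.where(crit > t, m, 0.0)
    np.fill_diagonal(out, 0.0)
    n_edges = int(np.count_nonzero(np.triu(out, k=1)))
    return ThresholdedMask(values=out, threshold=t, n_edges=n_edges)


def activation_map(g: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Gradient-times-activation map per subject.

    ``g`` and ``c`` are (Q, d_c) or (B, Q, d_c): the gradient of the
    selected output with respect to the AS block and the AS block itself.
    Returns the softmax-normalized vector(s) a = softmax(mean_q ReLU(G ⊙ C)):
    only features with a positive influence survive the ReLU, and each
    subject's attribution sums to 1.
    """
    g = np.asarray(g, dtype=float)
    c = np.asarray(c, dtype=float)
    if g.shape != c.shape:
        raise ValueError("gradient and activation shapes differ")
    pre = np.maximum(g * c, 0.0).mean(axis=-2)
    return softmax(pre, axis=-1)


def grad_attribution(
    result: TrainResult | MaskGNN,
    data: Dataset,
    idx: np.ndarray | None = None,
    selector: int = 0,
    column_names: list[str] | None = None,
) -> dict:
    """Gradient-times-activation attribution of the fused AS columns.

    For each subject, G = d(selected output)/dC is computed by
    backpropagation; the activation map a = (1/Q) sum_q ReLU(G_q ⊙ C_q) is
    softmax-normalized over the d_c feature columns, and the cohort score
    is the mean over subjects.  ``selector`` picks the regression target
    (Grad-RAM) or the class logit (Grad-CAM).  For classification the
    per-group means (label 0 vs 1) are reported as well.

    Returns a dict with ``scores`` (length d_c, sums to 1), ``per_subject``
    (n x d_c) and, for classification, ``group_scores``.
    """
    model = result.model if isinstance(result, TrainResult) else result
    if model.dc == 0:
        raise ValueError("model was trained without AS fusion; nothing to attribute")
    if idx is None:
        idx = np.arange(data.n)
    idx = np.asarray(idx)
    _, cache = model.forward(data.s[idx], data.h0[idx], data.c[idx],
                             return_cache=True)
    g = model.grad_wrt_as(cache, selector)  # (B, Q, dc)
    per_subject = activation_map(g, cache.c)
    out = {
        "scores": per_subject.mean(axis=0),
        "per_subject": per_subject,
        "selector": selector,
    }
    if model.task == "classification":
        labels = np.asarray(data.y)[idx]
        out["group_scores"] = {
            int(cls): per_subject[labels == cls].mean(axis=0)
            for cls in np.unique(labels)
        }
    if column_names is not None:
        out["column_names"] = list(column_names)
    return out


def network_aggregate(mask: ThresholdedMask,
                      labels: list[str] | np.ndarray) -> dict[str, pd.DataFrame]:
    """Aggregate retained mask edges to network-by-network summaries.

    ``labels`` assigns each ROI to a functional network (unlabeled ROIs
    should carry "Others").  Returns two symmetric network x network
    DataFrames: ``mean_weight`` (mean weight over the *retained* edges of
    that network pair; 0 where nothing is retained) and ``density``
    (retained / possible edge count).
    """
    labels = np.asarray(labels, dtype=object)
    q = mask.values.shape[0]
    if labels.size != q:
        raise ValueError("label vector length does not match ROI count")
    nets = sorted(set(labels.tolist()))
    k = len(nets)
    pos = {n: i for i, n in enumerate(nets)}
    weight_sum = np.zeros((k, k))
    retained = np.zeros((k, k))
    possible = np.zeros((k, k))
    iu, ju = np.triu_indices(q, k=1)
    for i, j in zip(iu, ju):
        a, b = pos[labels[i]], pos[labels[j]]
        a, b = min(a, b), max(a, b)
        possible[a, b] += 1
        w = mask.values[i, j]
        if w > 0:
            retained[a, b] += 1
            weight_sum[a, b] += w
    mean_w = np.divide(weight_sum, retained, out=np.zeros_like(weight_sum),
                       where=retained > 0)
    dens = np.divide(retained, possible, out=np.zeros_like(retained),
                     where=possible > 0)
    mean_w = mean_w + np.triu(mean_w, 1).T
    dens = dens + np.triu(dens, 1).T
    return {
        "mean_weight": pd.DataFrame(mean_w, index=nets, columns=nets),
        "density": pd.DataFrame(dens, index=nets, columns=nets),
    }


def edge_recovery_auc(m: np.ndarray, planted_edges: np.ndarray) -> float:
    """Ranking AUC of a planted edge set under the learned mask.

    All off-diagonal ROI pairs are ranked by their mask weight; the AUC is
    the probability that a planted edge outranks a non-planted pair.
    """
    from sklearn.metrics import roc_auc_score

    m = np.asarray(m, dtype=float)
    q = m.shape[0]
    iu, ju = np.triu_indices(q, k=1)
    truth = np.zeros(iu.size, dtype=int)
    planted = {(min(i, j), max(i, j)) for i, j in np.asarray(planted_edges)}
    for e, (i, j) in enumerate(zip(iu, ju)):
        if (i, j) in planted:
            truth[e] = 1
    sym = (m + m.T) / 2.0
    return float(roc_auc_score(truth, sym[iu, ju]))
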