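"""Training loop, data splitting, metrics, bootstrap repetition, ablation.

The optimization protocol: Adam at an initial learning rate of 0.005 with
L2 weight decay 1e-6, batch size 32, up to 50 epochs, a
reduce-on-plateau schedule (factor 0.5, patience 10) driven by validation
loss, and best-validation checkpointing.  The manifold-smoothness term is
monitored against a floor: if the batch-mean manifold loss drops below it
(embeddings collapsing toward oversmoothing), its weight alpha is halved
and the event logged.  Regression targets are standardized on the training
split inside the loop and predictions mapped back, so reported errors are
on the original score scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.metrics import f1_score, roc_auc_score

from .features import derive_features
from .graph import build_graph
from .io import RunConfig, get_logger
from .model import Adam, MaskGNN, normalized_structure
from .objectives import (
    LossBreakdown,
    manifold_loss,
    manifold_loss_grad,
    mask_penalty,
    mask_penalty_grad,
    prediction_loss,
    prediction_loss_grad,
    total_loss,
)
from .synthetic import Subject, SyntheticCohort

__all__ = [
    "SplitPlan",
    "Dataset",
    "TrainResult",
    "make_splits",
    "prepare_inputs",
    "train",
    "evaluate",
    "bootstrap_runs",
    "welch_t_test",
    "ablate",
]


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    proportions: tuple[float, float, float]
    seed: int


def make_splits(
    n: int,
    proportions: tuple[float, float, float] = (0.70, 0.10, 0.20),
    seed: int = 0,
    labels: np.ndarray | None = None,
) -> SplitPlan:
    """Random train/validation/test split, stratified by label when given.

    Sizes match the proportions to rounding; any empty split raises.
    """
    if n < 10:
        raise ValueError("cohort too small to split (need >= 10 subjects)")
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError("split proportions must sum to 1")
    rng = np.random.default_rng(seed)

    def split_indices(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        idx = rng.permutation(idx)
        n_tr = int(round(proportions[0] * idx.size))
        n_val = int(round(proportions[1] * idx.size))
        return idx[:n_tr], idx[n_tr : n_tr + n_val], idx[n_tr + n_val :]

    if labels is None:
        tr, va, te = split_indices(np.arange(n))
    else:
        labels = np.asarray(labels)
        parts = [split_indices(np.flatnonzero(labels == c))
                 for c in np.unique(labels)]
        tr = np.concatenate([p[0] for p in parts])
        va = np.concatenate([p[1] for p in parts])
        te = np.concatenate([p[2] for p in parts])
    if min(tr.size, va.size, te.size) == 0:
        raise ValueError("a split would be empty with these proportions")
    return SplitPlan(train=np.sort(tr), val=np.sort(va), test=np.sort(te),
                     proportions=tuple(proportions), seed=seed)


# ---------------------------------------------------------------------------
# Featurized dataset
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """Stacked per-subject model inputs."""

    s: np.ndarray  # (n, Q, Q) normalized structure
    adjacency: np.ndarray  # (n, Q, Q) sparse graph (for the Laplacian)
    h0: np.ndarray  # (n, Q, d0)
    c: np.ndarray  # (n, Q, dc); dc = 0 when AS inactive
    y: np.ndarray  # (n, n_targets) regression targets or (n,) labels
    subject_ids: list[str]
    task: str

    @property
    def n(self) -> int:
        return self.s.shape[0]


def prepare_inputs(
    subjects: list[Subject] | SyntheticCohort,
    config: RunConfig,
) -> Dataset:
    """Derive features, build graphs and stack model inputs for a cohort.

    Honors ``config.modalities``: only the active modalities are derived
    and consumed.  For classification, subjects whose label is negative
    (outside the extreme groups) are dropped.
    """
    if isinstance(subjects, SyntheticCohort):
        subjects = subjects.subjects
    use_as = "AS" in config.modalities
    s_list, a_list, h_list, c_list, ys, labels, ids = [], [], [], [], [], [], []
    for subj in subjects:
        if config.task == "classification" and (subj.label is None or subj.label < 0):
            continue
        feats = subj.features
        if feats is None:
            feats = derive_features(
                subj.ts,
                subj.sc_raw if "SC" in config.modalities or use_as else None,
                subj.gm if "SC" in config.modalities or use_as else None,
                subj.morphology if use_as else None,
            )
        g = build_graph(
            feats.fc, feats.sc,
            modalities=tuple(m for m in config.modalities if m in ("FC", "SC")),
            k=config.k, threshold=config.threshold,
            binary=config.binary_adjacency,
        )
        s_list.append(normalized_structure(g.adjacency))
        a_list.append(g.adjacency)
        h_list.append(g.node_features)
        if use_as:
            if feats.as_table is None:
                raise ValueError(f"subject {subj.subject_id}: AS requested but unavailable")
            c_list.append(feats.as_table.values)
        ys.append(subj.y)
        labels.append(subj.label)
        ids.append(subj.subject_id)
    n = len(ids)
    if n == 0:
        raise ValueError("no usable subjects for this configuration")
    q = s_list[0].shape[0]
    c = np.stack(c_list) if use_as else np.zeros((n, q, 0))
    y = (np.asarray(labels, dtype=int) if config.task == "classification"
         else np.asarray(ys, dtype=float).reshape(n, config.n_targets))
    return Dataset(s=np.stack(s_list), adjacency=np.stack(a_list),
                   h0=np.stack(h_list), c=c, y=y, subject_ids=ids,
                   task=config.task)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    model: MaskGNN
    history: pd.DataFrame
    split: SplitPlan
    target_mean: np.ndarray  # standardization of regression targets
    target_sd: np.ndarray
    config: RunConfig
    events: list[str] = field(default_factory=list)


def _epoch_losses(model: MaskGNN, data: Dataset, idx: np.ndarray,
                  y_std: np.ndarray, config: RunConfig, alpha: float) -> LossBreakdown:
    yhat, cache = model.forward(data.s[idx], data.h0[idx],
                                data.c[idx] if model.dc else None,
                                return_cache=True)
    return total_loss(yhat, y_std[idx], cache.h2, data.adjacency[idx],
                      model.mask(), data.task, alpha,
                      config.lambda1, config.lambda2, config.lambda3)


def train(
    cohort: list[Subject] | SyntheticCohort | Dataset,
    config: RunConfig,
    split: SplitPlan | None = None,
) -> TrainResult:
    """Fit the masked GNN end to end on a cohort.

    Deterministic given the config seed.  Returns the best-validation
    checkpointed model plus the per-epoch loss table.
    """
    log = get_logger("train")
    data = cohort if isinstance(cohort, Dataset) else prepare_inputs(cohort, config)
    if split is None:
        split = make_splits(
            data.n, config.split_proportions, seed=config.seed,
            labels=data.y if config.task == "classification" else None,
        )

    # standardize regression targets on the training split
    if config.task == "regression":
        t_mean = data.y[split.train].mean(axis=0)
        t_sd = data.y[split.train].std(axis=0)
        t_sd = np.where(t_sd > 0, t_sd, 1.0)
        y_std = (data.y - t_mean) / t_sd
    else:
        t_mean = np.zeros(1)
        t_sd = np.ones(1)
        y_std = data.y

    rng = np.random.default_rng(config.seed)
    model = MaskGNN(
        q=data.s.shape[1], d0=data.h0.shape[2], dc=data.c.shape[2],
        d1=config.d1, d2=config.d2, hidden=config.hidden,
        n_targets=config.n_targets, task=config.task,
        pooling=config.pooling, rng=rng,
    )
    opt = Adam(model.params, lr=config.learning_rate,
               weight_decay=config.weight_decay)

    alpha = config.alpha
    events: list[str] = []
    best_val = np.inf
    best_state = model.get_state()
    lr_wait = 0
    history_rows = []

    for epoch in range(config.max_epochs):
        order = rng.permutation(split.train)
        epoch_manifold = []
        for start in range(0, order.size, config.batch_size):
            idx = order[start : start + config.batch_size]
            yhat, cache = model.forward(data.s[idx], data.h0[idx],
                                        data.c[idx] if model.dc else None,
                                        return_cache=True)
            m = model.mask()
            breakdown = total_loss(yhat, y_std[idx], cache.h2,
                                   data.adjacency[idx], m, data.task, alpha,
                                   config.lambda1, config.lambda2, config.lambda3)
            if not np.isfinite(breakdown.total):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={breakdown}"
                )
            epoch_manifold.append(breakdown.manifold)
            dy = prediction_loss_grad(yhat, y_std[idx], data.task)
            dh2 = alpha * manifold_loss_grad(cache.h2, data.adjacency[idx])
            dm = mask_penalty_grad(m, config.lambda1, config.lambda2,
                                   config.lambda3)
            grads = model.backward(cache, dy, dh2_extra=dh2, dm_extra=dm)
            opt.step(model.params, grads)

        # manifold monitor: guard against embedding collapse / oversmoothing
        mean_manifold = float(np.mean(epoch_manifold))
        if alpha > 0 and mean_manifold < config.manifold_floor:
            alpha *= 0.5
            events.append(f"epoch {epoch}: manifold {mean_manifold:.3g} below "
                          f"floor; alpha halved to {alpha:.3g}")
            log.info(events[-1])

        tr_loss = _epoch_losses(model, data, split.train, y_std, config, alpha)
        va_loss = _epoch_losses(model, data, split.val, y_std, config, alpha)
        history_rows.append({
            "epoch": epoch, "lr": opt.lr,
            "train_total": tr_loss.total, "train_prediction": tr_loss.prediction,
            "train_manifold": tr_loss.manifold, "train_mask": tr_loss.mask,
            "val_total": va_loss.total, "val_prediction": va_loss.prediction,
            "alpha": alpha,
        })

        if va_loss.total < best_val - 1e-12:
            best_val = va_loss.total
            best_state = model.get_state()
            lr_wait = 0
        else:
            lr_wait += 1
            if lr_wait > config.scheduler_patience:
                opt.lr *= config.scheduler_factor
                lr_wait = 0
                events.append(f"epoch {epoch}: plateau; lr reduced to {opt.lr:.3g}")
                log.info(events[-1])

    model.set_state(best_state)
    return TrainResult(model=model, history=pd.DataFrame(history_rows),
                       split=split, target_mean=np.atleast_1d(t_mean),
                       target_sd=np.atleast_1d(t_sd), config=config,
                       events=events)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def predict(result: TrainResult, data: Dataset, idx: np.ndarray) -> np.ndarray:
    """Model outputs on the original target scale (regression) or logits."""
    model = result.model
    yhat = model.forward(data.s[idx], data.h0[idx],
                         data.c[idx] if model.dc else None)
    if result.config.task == "regression":
        yhat = yhat * result.target_sd[None, :] + result.target_mean[None, :]
    return yhat


def evaluate(result: TrainResult, data: Dataset,
             idx: np.ndarray | None = None) -> dict[str, float]:
    """Held-out metrics: RMSE/MAE (regression) or accuracy/F1/AUC."""
    if idx is None:
        idx = result.split.test
    idx = np.asarray(idx)
    if idx.size == 0:
        raise ValueError("empty evaluation set")
    yhat = predict(result, data, idx)
    if result.config.task == "regression":
        y = data.y[idx]
        err = yhat - y
        rmse = float(np.sqrt(np.mean(err**2)))
        mae = float(np.mean(np.abs(err)))
        return {"rmse": rmse, "mae": mae}
    y = data.y[idx]
    scores = yhat[:, 1] - yhat[:, 0]
    pred = (scores > 0).astype(int)
    acc = float(np.mean(pred == y))
    f1 = float(f1_score(y, pred, zero_division=0))
    auc = float(roc_auc_score(y, scores)) if np.unique(y).size > 1 else np.nan
    return {"accuracy": acc, "f1": f1, "auc": auc}


# ---------------------------------------------------------------------------
# Bootstrap repetition and model comparison
# ---------------------------------------------------------------------------

def bootstrap_runs(
    cohort: list[Subject] | SyntheticCohort | Dataset,
    config: RunConfig,
    n_reps: int = 10,
) -> pd.DataFrame:
    """Repeat train/evaluate ``n_reps`` times with re-drawn splits and
    re-seeded training; returns the per-repetition metric table (the
    mean/sd summary is one ``.describe()`` away)."""
    if n_reps < 2:
        raise ValueError("need at least 2 repetitions")
    data = cohort if isinstance(cohort, Dataset) else prepare_inputs(cohort, config)
    rows = []
    for rep in range(n_reps):
        import dataclasses as _dc

        cfg = _dc.replace(config, seed=config.seed + 1000 * rep)
        result = train(data, cfg)
        metrics = evaluate(result, data)
        rows.append({"rep": rep, "seed": cfg.seed, **metrics})
    return pd.DataFrame(rows)


def welch_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch two-sample t-test (unequal variances); returns (t, p).  Used to
    compare per-repetition metrics between two models or settings."""
    res = sstats.ttest_ind(np.asarray(a, float), np.asarray(b, float),
                           equal_var=False)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Ablation harness
# ---------------------------------------------------------------------------

MODALITY_SUBSETS: tuple[tuple[str, ...], ...] = (
    ("FC",), ("SC",), ("FC", "SC"), ("FC", "SC", "AS"),
)
LOSS_SETTINGS: dict[str, dict[str, float]] = {
    "both": {},
    "manifold_only": {"lambda1": 0.0, "lambda2": 0.0, "lambda3": 0.0},
    "mask_only": {"alpha": 0.0},
    "neither": {"alpha": 0.0, "lambda1": 0.0, "lambda2": 0.0, "lambda3": 0.0},
}


def ablate(
    cohort: list[Subject] | SyntheticCohort,
    config: RunConfig,
    modality_subsets: tuple[tuple[str, ...], ...] = MODALITY_SUBSETS,
    loss_settings: tuple[str, ...] = ("both",),
    n_reps: int = 5,
) -> pd.DataFrame:
    """Grid over modality subsets and loss-term settings, each evaluated by
    bootstrap repetition; one summary row per grid cell."""
    import dataclasses as _dc

    rows = []
    for subset in modality_subsets:
        for setting in loss_settings:
            overrides = LOSS_SETTINGS[setting]
            cfg = _dc.replace(config, modalities=tuple(subset), **overrides)
            reps = bootstrap_runs(cohort, cfg, n_reps=n_reps)
            metric_cols = [c for c in reps.columns if c not in ("rep", "seed")]
            row = {"modalities": "+".join(subset), "loss_setting": setting}
            for mc in metric_cols:
                row[f"{mc}_mean"] = float(reps[mc].mean())
                row[f"{mc}_sd"] = float(reps[mc].std(ddof=1))
            rows.append(row)
    return pd.DataFrame(rows)
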