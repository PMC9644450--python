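"""Training loop, AUC, stratified k-fold splitting, and cross-validation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import Bag, PaddedBatch
from .model import ModelConfig, SparseAttentionMIL

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "CVResult",
    "auc",
    "kfold_split",
    "train",
    "cross_validate",
]


@dataclass
class TrainConfig:
    epochs: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 32
    seed: int = 0
    selection: str = "best_val_auc"  # or "last_epoch"
    val_fraction: float = 0.1
    pos_weight: float | None = None  # optional positive-class reweighting, off by default

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 <= self.val_fraction < 0.5:
            raise ValueError("val_fraction must lie in [0, 0.5)")
        if self.selection not in ("best_val_auc", "last_epoch"):
            raise ValueError(f"unknown selection rule {self.selection!r}")


@dataclass
class TrainHistory:
    losses: list[float] = field(default_factory=list)
    val_aucs: list[float] = field(default_factory=list)
    selected_epoch: int = -1


@dataclass
class CVResult:
    fold_aucs: list[float]
    mean_auc: float
    sd_auc: float
    predictions: pd.DataFrame  # columns: bag_id, fold, probability, label


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the Mann-Whitney statistic.

    Equals P(score+ > score-) + 0.5 * P(tie) over positive/negative pairs;
    ties are handled by midranks.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = stats.rankdata(scores)
    return float(
        (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


def kfold_split(
    labels: np.ndarray,
    k: int = 10,
    stratified: bool = True,
    seed: int = 0,
) -> list[np.ndarray]:
    """Seeded k-fold partition of indices; fold sizes differ by at most one.

    With stratification each fold preserves the class fractions to within one
    bag, which requires at least k members of each class.
    """
    labels = np.asarray(labels)
    n = labels.shape[0]
    if n < k:
        raise ValueError(f"cannot split {n} bags into {k} folds")
    rng = np.random.default_rng(seed)
    if not stratified:
        perm = rng.permutation(n)
        return [np.sort(chunk) for chunk in np.array_split(perm, k)]
    folds: list[list[int]] = [[] for _ in range(k)]
    # round-robin within each class over a shuffled fold order gives the
    # +/- 1 balance per class and overall
    offset = 0
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < k:
            raise ValueError(
                f"stratification impossible: class {cls} has {idx.size} < {k} bags"
            )
        idx = rng.permutation(idx)
        for j, i in enumerate(idx):
            folds[(j + offset) % k].append(int(i))
        offset += idx.size % k
    return [np.sort(np.array(f, dtype=int)) for f in folds]


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for key, g in grads.items():
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g**2
            params[key] -= self.lr * (self.m[key] / b1t) / (
                np.sqrt(self.v[key] / b2t) + self.eps
            )


def _stratified_holdout(
    labels: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Split indices into (train, val) keeping >= 1 bag per class in val."""
    val: list[int] = []
    for cls in (0, 1):
        idx = rng.permutation(np.flatnonzero(labels == cls))
        n_val = max(1, int(round(fraction * idx.size)))
        val.extend(idx[:n_val].tolist())
    val_idx = np.sort(np.array(val, dtype=int))
    train_idx = np.setdiff1d(np.arange(labels.size), val_idx)
    return train_idx, val_idx


def train(
    bags: list[Bag],
    model_config: ModelConfig,
    train_config: TrainConfig,
) -> tuple[SparseAttentionMIL, TrainHistory]:
    """Fit the network by Adam on binary cross-entropy.

    Runs for the configured number of epochs and returns the weights of the
    selected epoch: the one with the best held-out-validation AUC (a split
    carved from the training bags, never a test fold) or simply the last.
    Identical seeds give identical histories.
    """
    labels_all = np.array([b.label for b in bags])
    if len(np.unique(labels_all)) < 2:
        raise ValueError("degenerate training set: both classes are required")
    rng = np.random.default_rng(train_config.seed)
    batch = PaddedBatch.from_bags(bags, m_star=model_config.m_star)

    use_val = train_config.selection == "best_val_auc" and train_config.val_fraction > 0
    if use_val:
        tr_idx, val_idx = _stratified_holdout(labels_all, train_config.val_fraction, rng)
        val_batch = batch.subset(val_idx)
    else:
        tr_idx = np.arange(len(bags))
        val_batch = None
    tr_batch = batch.subset(tr_idx)

    model = SparseAttentionMIL(model_config, seed=train_config.seed)
    optimizer = _Adam(model.params, lr=train_config.learning_rate)
    history = TrainHistory()
    best_metric, best_state = -np.inf, None

    weight = None
    if train_config.pos_weight is not None:
        weight = np.where(tr_batch.labels == 1, train_config.pos_weight, 1.0)

    n_tr = tr_batch.n_bags
    tr_sizes = tr_batch.mask.sum(axis=1)
    if use_val:
        # padding is prefix-aligned and eval output padding-invariant: crop
        val_m = int(val_batch.mask.sum(axis=1).max())
        val_feat = val_batch.features[:, :val_m]
        val_mask = val_batch.mask[:, :val_m]
    for epoch in range(train_config.epochs):
        order = rng.permutation(n_tr)
        epoch_losses = []
        for start in range(0, n_tr, train_config.batch_size):
            sel = order[start : start + train_config.batch_size]
            m_batch = int(tr_sizes[sel].max())  # crop padding per minibatch
            loss, grads = model.loss_and_grads(
                tr_batch.features[sel, :m_batch],
                tr_batch.mask[sel, :m_batch],
                tr_batch.labels[sel],
                rng=rng,
                sample_weight=None if weight is None else weight[sel],
            )
            optimizer.step(model.params, grads)
            epoch_losses.append(loss)
        history.losses.append(float(np.mean(epoch_losses)))
        if use_val:
            probs = model.forward(val_feat, val_mask, training=False)["prob"]
            val_auc = auc(probs, val_batch.labels)
            history.val_aucs.append(val_auc)
            if val_auc > best_metric:
                best_metric, best_state = val_auc, model.state_dict()
                history.selected_epoch = epoch
    if use_val and best_state is not None:
        model.load_state_dict(best_state)
    else:
        history.selected_epoch = train_config.epochs - 1
    return model, history


def cross_validate(
    bags: list[Bag],
    model_config: ModelConfig,
    train_config: TrainConfig,
    k: int = 10,
    stratified: bool = True,
) -> CVResult:
    """Stratified k-fold cross-validation; test folds never touch training."""
    labels = np.array([b.label for b in bags])
    folds = kfold_split(labels, k=k, stratified=stratified, seed=train_config.seed)
    fold_aucs: list[float] = []
    rows = []
    for fold_no, test_idx in enumerate(folds):
        train_bags = [bags[i] for i in range(len(bags)) if i not in set(test_idx.tolist())]
        model, _ = train(train_bags, model_config, train_config)
        # eval output is padding-invariant, so the test capacity only matters
        # for truncation when m_star is fixed explicitly
        test_batch = PaddedBatch.from_bags(
            [bags[i] for i in test_idx], m_star=model_config.m_star
        )
        probs = model.predict_proba(test_batch)
        fold_aucs.append(auc(probs, test_batch.labels))
        for bag_id, prob, label in zip(test_batch.bag_ids, probs, test_batch.labels):
            rows.append((bag_id, fold_no, float(prob), int(label)))
    fold_arr = np.array(fold_aucs)
    return CVResult(
        fold_aucs=fold_aucs,
        mean_auc=float(fold_arr.mean()),
        sd_auc=float(fold_arr.std(ddof=1)),
        predictions=pd.DataFrame(rows, columns=["bag_id", "fold", "probability", "label"]),
    )
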