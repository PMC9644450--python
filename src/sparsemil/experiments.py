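"""Experiment protocols: ablation grid, capacity sweep, heatmaps, instance
selection, reference-distance comparison, and method-rank statistics."""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .data import Bag, PaddedBatch
from .model import ABLATION_VARIANTS, ModelConfig, SparseAttentionMIL, extract_features
from .train import CVResult, TrainConfig, cross_validate

logger = logging.getLogger(__name__)

__all__ = [
    "AblationRow",
    "MethodComparison",
    "run_ablation",
    "mstar_sensitivity",
    "attention_heatmap",
    "feature_heatmap",
    "label_primary_instances",
    "selection_recall",
    "reference_distance_report",
    "exact_signed_rank_p",
    "compare_methods",
]


@dataclass
class AblationRow:
    variant: str
    skip_on: bool
    sparse_on: bool
    mean_auc: float
    sd_auc: float


def run_ablation(
    bags: list[Bag],
    base_config: ModelConfig,
    train_config: TrainConfig,
    k: int = 10,
) -> tuple[list[AblationRow], dict[str, CVResult]]:
    """Cross-validate the 2x2 grid of {skip connection} x {sparse pooling}.

    All four variants share the same folds and seeds; only the two
    architecture switches differ.
    """
    rows, results = [], {}
    for variant, (use_skip, pooling) in ABLATION_VARIANTS.items():
        config = replace(base_config, use_skip=use_skip, pooling=pooling)
        cv = cross_validate(bags, config, train_config, k=k)
        results[variant] = cv
        rows.append(
            AblationRow(
                variant=variant,
                skip_on=use_skip,
                sparse_on=(pooling == "sparsemax"),
                mean_auc=cv.mean_auc,
                sd_auc=cv.sd_auc,
            )
        )
    return rows, results


def mstar_sensitivity(
    bags: list[Bag],
    grid: list[int],
    model_config: ModelConfig,
    train_config: TrainConfig,
    k: int = 10,
) -> pd.DataFrame:
    """One cross-validation per bag capacity value; folds/seeds held fixed."""
    rows = []
    for m_star in grid:
        if m_star < 1:
            raise ValueError("capacity values must be >= 1")
        cv = cross_validate(bags, replace(model_config, m_star=m_star), train_config, k=k)
        rows.append((m_star, cv.mean_auc, cv.sd_auc))
    return pd.DataFrame(rows, columns=["m_star", "mean_auc", "sd_auc"])


def attention_heatmap(
    model: SparseAttentionMIL, bags: list[Bag]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Attention weights per bag as an (n, m*) matrix, rows sorted by bag size.

    Returns (weights, mask, bag_ids); the mask flags real-instance cells so
    padded cells can be rendered distinctly (gray) rather than as zeros.
    Each row sums to 1 over its valid cells.
    """
    order = sorted(range(len(bags)), key=lambda i: bags[i].n_instances)
    ordered = [bags[i] for i in order]
    batch = PaddedBatch.from_bags(ordered, m_star=model.config.m_star)
    cache = model.forward(batch.features, batch.mask, training=False)
    return cache["alpha"], batch.mask, [b.bag_id for b in ordered]


def feature_heatmap(model: SparseAttentionMIL, bags: list[Bag]) -> np.ndarray:
    """Extracted (n, p) features, column-wise min-max normalized then log1p."""
    feats = extract_features(bags, model)
    lo = feats.min(axis=0)
    hi = feats.max(axis=0)
    span = hi - lo
    constant = span <= 0
    if constant.any():
        logger.warning(
            "feature_heatmap: %d constant column(s) set to 0", int(constant.sum())
        )
    span = np.where(constant, 1.0, span)
    scaled = np.where(constant, 0.0, (feats - lo) / span)
    return np.log1p(scaled)


def label_primary_instances(model: SparseAttentionMIL, bag: Bag) -> np.ndarray:
    """Flag the instances the model attends to: exact sparsemax support.

    Instances beyond the model capacity (truncated) are flagged False.  Only
    meaningful under sparsemax pooling; softmax never produces exact zeros.
    """
    if model.config.pooling != "sparsemax":
        raise ValueError(
            "primary-instance labeling requires sparsemax pooling (softmax has no exact zeros)"
        )
    m_star = model.config.m_star or bag.n_instances
    batch = PaddedBatch.from_bags([bag], m_star=m_star)
    alpha = model.forward(batch.features, batch.mask, training=False)["alpha"][0]
    flags = np.zeros(bag.n_instances, dtype=bool)
    keep = min(bag.n_instances, m_star)
    flags[:keep] = alpha[:keep] > 0
    return flags


def selection_recall(model: SparseAttentionMIL, bags: list[Bag]) -> float:
    """Recall of ground-truth primary instances by the attention support."""
    hit = total = 0
    for bag in bags:
        if bag.primary_flags is None or not bag.primary_flags.any():
            continue
        selected = label_primary_instances(model, bag)
        hit += int(np.sum(selected & bag.primary_flags))
        total += int(bag.primary_flags.sum())
    if total == 0:
        raise ValueError("no ground-truth primary instances available")
    return hit / total


def reference_distance_report(
    instance_embeddings: np.ndarray,
    primary_flags: np.ndarray,
    labels: np.ndarray,
    reference_embeddings: np.ndarray,
) -> pd.DataFrame:
    """Mean distance of each instance to a reference embedding cloud, by group.

    For every instance the mean Euclidean distance to all reference
    embeddings is computed; instances are grouped by (bag label) x
    (primary / non-primary) and a two-sided rank-sum test compares primary
    vs non-primary within each label.
    """
    X = np.atleast_2d(np.asarray(instance_embeddings, dtype=np.float64))
    R = np.atleast_2d(np.asarray(reference_embeddings, dtype=np.float64))
    if X.shape[1] != R.shape[1]:
        raise ValueError("instance and reference embeddings must share dimension")
    primary_flags = np.asarray(primary_flags, dtype=bool)
    labels = np.asarray(labels)
    mean_dist = cdist(X, R).mean(axis=1)

    rows = []
    for label in np.unique(labels):
        in_label = labels == label
        d_primary = mean_dist[in_label & primary_flags]
        d_other = mean_dist[in_label & ~primary_flags]
        if d_primary.size == 0 or d_other.size == 0:
            logger.warning("label %s: empty primary or non-primary group, skipped", label)
            p_value = np.nan
        else:
            p_value = float(stats.ranksums(d_primary, d_other).pvalue)
        for group, dist in (("primary", d_primary), ("non_primary", d_other)):
            rows.append(
                (
                    label,
                    group,
                    int(dist.size),
                    float(dist.mean()) if dist.size else np.nan,
                    p_value,
                )
            )
    return pd.DataFrame(
        rows, columns=["label", "group", "n", "mean_distance", "ranksum_p"]
    )


def exact_signed_rank_p(differences: np.ndarray) -> float:
    """Exact two-sided Wilcoxon signed-rank p over all sign patterns.

    Zero differences are dropped.  Ranks of |d| use midranks; the null
    distribution of W+ over the 2^n equiprobable sign assignments is built by
    convolution on doubled (integer) ranks, which handles ties exactly.
    """
    d = np.asarray(differences, dtype=np.float64)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks2 = np.round(2.0 * stats.rankdata(np.abs(d))).astype(int)
    w_plus2 = int(ranks2[d > 0].sum())
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: dist.size - r]
        dist = 0.5 * (dist + shifted)
    p_low = float(dist[: w_plus2 + 1].sum())
    p_high = float(dist[w_plus2:].sum())
    return min(1.0, 2.0 * min(p_low, p_high))


@dataclass
class MethodComparison:
    auc_table: pd.DataFrame  # methods x datasets
    ranks: pd.DataFrame      # per-dataset ranks, 1 = best, ties averaged
    avg_rank: pd.Series
    method_a: str
    method_b: str
    signed_rank_p: float


def compare_methods(
    auc_table: pd.DataFrame, method_a: str, method_b: str
) -> MethodComparison:
    """Rank methods per dataset and test a designated pair.

    Within each dataset (column) the methods are ranked by AUC (1 = best,
    average ranks on ties); the designated pair is compared by an exact
    two-sided Wilcoxon signed-rank test on the paired per-dataset ranks
    (normal approximation beyond 25 datasets).
    """
    if not isinstance(auc_table, pd.DataFrame):
        raise ValueError("auc_table must be a methods x datasets DataFrame")
    if auc_table.shape[0] < 2 or auc_table.shape[1] < 1:
        raise ValueError("need at least 2 methods and 1 dataset")
    for m in (method_a, method_b):
        if m not in auc_table.index:
            raise ValueError(f"method {m!r} not in table")
    ranks = pd.DataFrame(
        np.column_stack([stats.rankdata(-auc_table[c].to_numpy()) for c in auc_table]),
        index=auc_table.index,
        columns=auc_table.columns,
    )
    avg_rank = ranks.mean(axis=1)
    diffs = (ranks.loc[method_a] - ranks.loc[method_b]).to_numpy(dtype=float)
    nonzero = diffs[diffs != 0]
    if auc_table.shape[1] < 2 or nonzero.size < 1:
        logger.warning("signed-rank test degenerate (too few informative datasets)")
        p = np.nan
    elif nonzero.size <= 25:
        p = exact_signed_rank_p(diffs)
    else:
        p = float(stats.wilcoxon(nonzero, method="approx").pvalue)
    return MethodComparison(
        auc_table=auc_table,
        ranks=ranks,
        avg_rank=avg_rank,
        method_a=method_a,
        method_b=method_b,
        signed_rank_p=p,
    )
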