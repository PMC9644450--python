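"""Bag data model: padding/masking, tabular IO, and the synthetic generator.

A *bag* is one labeled sample holding a variable number of fixed-length
instance feature vectors.  Bags are serialized in long form (one row per
instance) as TSV/CSV with columns ``bag_id, label, instance_id, f1..fp``.
The synthetic generator emulates the primary-instance structure: positive
bags hide at least one signal ("primary") instance among background noise
instances, negative bags contain background only, and bag sizes follow a
heavy-tailed law under which most bags have fewer than five instances.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "Bag",
    "PaddedBatch",
    "NegativeBinomialSizes",
    "ShiftedPoissonCounts",
    "SyntheticSpec",
    "pad_truncate",
    "read_bags",
    "write_bags",
    "write_truth",
    "generate_synthetic",
]


@dataclass
class Bag:
    """One sample: a binary label and an (m_i, p) instance feature matrix."""

    bag_id: str
    label: int
    instances: np.ndarray
    instance_ids: list[str] | None = None
    primary_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.instances = np.asarray(self.instances, dtype=np.float64)
        if self.instances.ndim != 2 or self.instances.shape[0] < 1:
            raise ValueError(f"bag {self.bag_id}: instances must be a non-empty 2-D matrix")
        if not np.all(np.isfinite(self.instances)):
            raise ValueError(f"bag {self.bag_id}: non-finite feature values")
        if self.label not in (0, 1):
            raise ValueError(f"bag {self.bag_id}: label must be 0 or 1, got {self.label}")
        if self.instance_ids is not None and len(self.instance_ids) != self.n_instances:
            raise ValueError(f"bag {self.bag_id}: instance_ids length mismatch")
        if self.primary_flags is not None:
            self.primary_flags = np.asarray(self.primary_flags, dtype=bool)
            if self.primary_flags.shape != (self.n_instances,):
                raise ValueError(f"bag {self.bag_id}: primary_flags length mismatch")

    @property
    def n_instances(self) -> int:
        return self.instances.shape[0]

    @property
    def p(self) -> int:
        return self.instances.shape[1]


def pad_truncate(bag: Bag, m_star: int) -> tuple[np.ndarray, np.ndarray]:
    """Fit a bag into fixed capacity ``m_star``.

    Shorter bags are zero-padded with a false mask on the empty slots;
    oversized bags keep exactly their first ``m_star`` instances in original
    order.  Surviving instance values are never altered.
    """
    if m_star < 1:
        raise ValueError("m_star must be >= 1")
    m_i, p = bag.instances.shape
    features = np.zeros((m_star, p), dtype=np.float64)
    mask = np.zeros(m_star, dtype=bool)
    keep = min(m_i, m_star)
    features[:keep] = bag.instances[:keep]
    mask[:keep] = True
    return features, mask


@dataclass
class PaddedBatch:
    """Tensorized bags: (n, m*, p) features, (n, m*) validity mask, (n,) labels."""

    features: np.ndarray
    mask: np.ndarray
    labels: np.ndarray
    bag_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.features.ndim != 3 or self.mask.shape != self.features.shape[:2]:
            raise ValueError("features must be (n, m*, p) with matching (n, m*) mask")
        if not self.mask.any(axis=1).all():
            raise ValueError("every bag must have at least one valid instance")

    @classmethod
    def from_bags(cls, bags: list[Bag], m_star: int | None = None) -> "PaddedBatch":
        """Stack bags at capacity ``m_star`` (default: the largest bag size)."""
        if not bags:
            raise ValueError("no bags to batch")
        if m_star is None:
            m_star = max(b.n_instances for b in bags)
        pairs = [pad_truncate(b, m_star) for b in bags]
        return cls(
            features=np.stack([f for f, _ in pairs]),
            mask=np.stack([m for _, m in pairs]),
            labels=np.array([b.label for b in bags], dtype=np.float64),
            bag_ids=[b.bag_id for b in bags],
        )

    @property
    def n_bags(self) -> int:
        return self.features.shape[0]

    def subset(self, idx: np.ndarray) -> "PaddedBatch":
        idx = np.asarray(idx)
        return PaddedBatch(
            features=self.features[idx],
            mask=self.mask[idx],
            labels=self.labels[idx],
            bag_ids=[self.bag_ids[i] for i in idx],
        )


# ---------------------------------------------------------------------------
# tabular IO

_META_COLS = ["bag_id", "label", "instance_id"]


def write_bags(bags: list[Bag], path, sep: str = "\t") -> None:
    """Write bags in long form; full float precision so round-trips are exact."""
    if not bags:
        pd.DataFrame(columns=_META_COLS).to_csv(path, sep=sep, index=False)
        return
    p = bags[0].p
    frames = []
    for bag in bags:
        if bag.p != p:
            raise ValueError(f"bag {bag.bag_id}: feature dimension {bag.p} != {p}")
        ids = bag.instance_ids or [f"{bag.bag_id}_t{j}" for j in range(bag.n_instances)]
        df = pd.DataFrame(bag.instances, columns=[f"f{k + 1}" for k in range(p)])
        df.insert(0, "bag_id", bag.bag_id)
        df.insert(1, "label", bag.label)
        df.insert(2, "instance_id", ids)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep=sep, index=False, float_format="%.17g"
    )


def read_bags(path, sep: str = "\t") -> list[Bag]:
    """Read a long-form bag table, preserving bag and instance order."""
    df = pd.read_csv(path, sep=sep, dtype={"bag_id": str}, float_precision="round_trip")
    missing = [c for c in ("bag_id", "label") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if df.empty:
        logger.warning("%s: empty bag file", path)
        return []
    feat_cols = [c for c in df.columns if c not in _META_COLS]
    if not feat_cols:
        raise ValueError(f"{path}: no feature columns found")
    bad = df[~df["label"].isin((0, 1))]
    if len(bad):
        raise ValueError(
            f"{path}: non-binary label {bad['label'].iloc[0]!r} at row {bad.index[0] + 2}"
        )
    na_rows = df[feat_cols].isna().any(axis=1)
    if na_rows.any():
        row = int(np.flatnonzero(na_rows.to_numpy())[0])
        raise ValueError(f"{path}: missing/inconsistent feature values at row {row + 2}")
    has_ids = "instance_id" in df.columns
    bags = []
    for bag_id, grp in df.groupby("bag_id", sort=False):
        labels = grp["label"].unique()
        if len(labels) != 1:
            raise ValueError(f"{path}: bag {bag_id} has inconsistent labels {labels}")
        bags.append(
            Bag(
                bag_id=str(bag_id),
                label=int(labels[0]),
                instances=grp[feat_cols].to_numpy(dtype=np.float64),
                instance_ids=grp["instance_id"].astype(str).tolist() if has_ids else None,
            )
        )
    return bags


def write_truth(bags: list[Bag], path, sep: str = "\t") -> None:
    """Emit ground-truth primary flags (bag_id, instance_index, primary_flag)."""
    rows = []
    for bag in bags:
        flags = (
            bag.primary_flags
            if bag.primary_flags is not None
            else np.zeros(bag.n_instances, dtype=bool)
        )
        for j, fl in enumerate(flags):
            rows.append((bag.bag_id, j, int(fl)))
    pd.DataFrame(rows, columns=["bag_id", "instance_index", "primary_flag"]).to_csv(
        path, sep=sep, index=False
    )


# ---------------------------------------------------------------------------
# synthetic generator

@dataclass(frozen=True)
class NegativeBinomialSizes:
    """Shifted negative binomial bag-size law: size = minimum + NB(n, p).

    Defaults are tuned so ~75% of bags have at most 5 instances with a
    right tail reaching the low hundreds.
    """

    n: float = 0.35
    p: float = 0.09
    minimum: int = 1
    maximum: int | None = None

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        draws = self.minimum + rng.negative_binomial(self.n, self.p, size=size)
        if self.maximum is not None:
            while True:  # rejection keeps the truncated law exact
                over = draws > self.maximum
                if not over.any():
                    break
                draws[over] = self.minimum + rng.negative_binomial(
                    self.n, self.p, size=int(over.sum())
                )
        return draws

    def pmf(self, sizes: np.ndarray) -> np.ndarray:
        sizes = np.asarray(sizes)
        pm = stats.nbinom.pmf(sizes - self.minimum, self.n, self.p)
        if self.maximum is not None:
            pm = pm / stats.nbinom.cdf(self.maximum - self.minimum, self.n, self.p)
            pm = np.where(sizes > self.maximum, 0.0, pm)
        return np.where(sizes < self.minimum, 0.0, pm)


@dataclass(frozen=True)
class ShiftedPoissonCounts:
    """Primary-count law for positive bags: count = minimum + Poisson(lam)."""

    lam: float = 0.3
    minimum: int = 1

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return self.minimum + rng.poisson(self.lam, size=size)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic primary-instance benchmark generator."""

    n_bags: int = 400
    positive_fraction: float = 0.5
    p: int = 30
    bag_size_law: NegativeBinomialSizes = field(default_factory=NegativeBinomialSizes)
    primary_count_law: ShiftedPoissonCounts = field(default_factory=ShiftedPoissonCounts)
    signal_shift: float | np.ndarray = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def shift_vector(self) -> np.ndarray:
        shift = np.asarray(self.signal_shift, dtype=np.float64)
        return np.broadcast_to(shift, (self.p,)).copy()


def generate_synthetic(spec: SyntheticSpec) -> list[Bag]:
    """Draw seeded synthetic bags with the primary-instance structure.

    Background instances are N(0, noise_sd^2 I); primary instances are
    N(signal_shift, noise_sd^2 I).  Every positive bag receives at least one
    primary instance at random positions (count capped by bag size); negative
    bags are pure background.  Identical seeds give identical output.
    """
    n_pos = int(round(spec.n_bags * spec.positive_fraction))
    if n_pos < 1:
        raise ValueError(
            f"invalid spec: positive_fraction*n_bags = {spec.n_bags * spec.positive_fraction:.2f} < 1"
        )
    rng = np.random.default_rng(spec.seed)
    labels = np.zeros(spec.n_bags, dtype=int)
    labels[rng.permutation(spec.n_bags)[:n_pos]] = 1
    sizes = spec.bag_size_law.sample(rng, spec.n_bags)
    shift = spec.shift_vector()

    bags = []
    for i in range(spec.n_bags):
        m_i = int(sizes[i])
        X = rng.normal(0.0, spec.noise_sd, size=(m_i, spec.p))
        flags = np.zeros(m_i, dtype=bool)
        if labels[i] == 1:
            k = min(m_i, int(spec.primary_count_law.sample(rng, 1)[0]))
            pos = rng.choice(m_i, size=k, replace=False)
            X[pos] += shift
            flags[pos] = True
        bags.append(
            Bag(
                bag_id=f"bag{i:05d}",
                label=int(labels[i]),
                instances=X,
                instance_ids=[f"bag{i:05d}_t{j}" for j in range(m_i)],
                primary_flags=flags,
            )
        )
    return bags
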