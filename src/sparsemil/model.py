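"""Sparse-attention multiple-instance network, implemented in NumPy.

Architecture: a stack of instance-wise residual blocks (a fully-connected
p -> p map with weights shared across instances, ReLU, dropout, optional skip
connection), an attention scorer producing one scalar per instance, masked
sparsemax (or softmax) pooling into a single bag feature vector, batch
normalization, and a sigmoid classification head.  Forward and backward
passes are hand-written; :func:`sparsemax_jvp`'s centering rule supplies the
gradient through the simplex projection.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .data import Bag, PaddedBatch
from .sparsemax import masked_softmax_batch, masked_sparsemax_batch

__all__ = [
    "ModelConfig",
    "AttentionResult",
    "Prediction",
    "SparseAttentionMIL",
    "local_fc_forward",
    "residual_block",
    "attention_scores",
    "attention_pool",
    "extract_features",
    "ABLATION_VARIANTS",
]

# the 2x2 ablation grid: (use_skip, pooling)
ABLATION_VARIANTS: dict[str, tuple[bool, str]] = {
    "FC": (False, "softmax"),
    "Skip": (True, "softmax"),
    "Sparse": (False, "sparsemax"),
    "Proposed": (True, "sparsemax"),
}

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass
class ModelConfig:
    p: int = 30
    m_star: int | None = None  # bag capacity; None = largest bag size in data
    n_blocks: int = 4
    use_skip: bool = True
    pooling: str = "sparsemax"
    dropout_rate: float = 0.3
    scorer: str = "gated_tanh"
    scorer_hidden: int | None = None  # default: p

    def __post_init__(self) -> None:
        if self.p < 1 or self.n_blocks < 1:
            raise ValueError("p and n_blocks must be >= 1")
        if self.m_star is not None and self.m_star < 1:
            raise ValueError("m_star must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.pooling not in ("sparsemax", "softmax"):
            raise ValueError(f"unknown pooling {self.pooling!r}")
        if self.scorer not in ("linear", "gated_tanh"):
            raise ValueError(f"unknown scorer {self.scorer!r}")

    @property
    def hidden(self) -> int:
        return self.scorer_hidden or self.p


@dataclass
class AttentionResult:
    """Per-bag attention weights, their support, and the pooled features."""

    alpha: np.ndarray          # (m*,) simplex vector, zeros on padded slots
    pooled: np.ndarray         # (p,) weighted feature vector
    pooled_normalized: np.ndarray  # (p,) after batch normalization
    support: np.ndarray        # indices of instances with alpha > 0


@dataclass
class Prediction:
    probability: float
    attention: AttentionResult


def local_fc_forward(X: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Instance-wise fully-connected map: row j of the output is W @ X[j] + b.

    Weights are shared across instances; rows never mix.  Accepts any leading
    batch dimensions before the (m, p) instance axes.
    """
    X, W, b = np.asarray(X), np.asarray(W), np.asarray(b)
    if X.shape[-1] != W.shape[1] or W.shape[0] != b.shape[0]:
        raise ValueError(
            f"shape mismatch: X{X.shape} @ W{W.shape}.T + b{b.shape}"
        )
    # flatten leading axes so a single BLAS call handles batched input
    flat = X.reshape(-1, X.shape[-1]) @ W.T + b
    return flat.reshape(*X.shape[:-1], W.shape[0])


def residual_block(
    X: np.ndarray,
    W: np.ndarray,
    b: np.ndarray,
    use_skip: bool = True,
    dropout_rate: float = 0.0,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One block: F = dropout(relu(local_fc(X))); output X + F or F alone."""
    H = np.maximum(local_fc_forward(X, W, b), 0.0)
    if training and dropout_rate > 0.0:
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        keep = rng.random(H.shape) >= dropout_rate
        H = H * keep / (1.0 - dropout_rate)
    return X + H if use_skip else H


def attention_scores(
    Z: np.ndarray,
    mask: np.ndarray,
    params: dict[str, np.ndarray],
    scorer: str = "gated_tanh",
) -> np.ndarray:
    """One scalar score per instance; masked slots are scored but never used."""
    Z = np.asarray(Z)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty bag: mask has no valid entries")
    if scorer == "linear":
        return Z @ params["w_att"] + params["b_att"]
    return np.tanh(Z @ params["V"].T) @ params["w_att"]


def attention_pool(Z: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Convex combination of instance rows: sum_j alpha_j Z[j]."""
    Z, alpha = np.asarray(Z), np.asarray(alpha)
    if Z.shape[0] != alpha.shape[0]:
        raise ValueError(f"length mismatch: Z has {Z.shape[0]} rows, alpha {alpha.shape[0]}")
    return alpha @ Z


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


class SparseAttentionMIL:
    """The bag classifier; owns parameters, forward pass, and gradients."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        p, h = config.p, config.hidden
        he = lambda fan_in: np.sqrt(6.0 / fan_in)
        params: dict[str, np.ndarray] = {}
        for l in range(config.n_blocks):
            params[f"W{l}"] = rng.uniform(-he(p), he(p), size=(p, p))
            params[f"b{l}"] = np.zeros(p)
        if config.scorer == "linear":
            params["w_att"] = rng.uniform(-he(p), he(p), size=p)
            params["b_att"] = np.zeros(1)
        else:
            params["V"] = rng.uniform(-he(p), he(p), size=(h, p))
            params["w_att"] = rng.uniform(-he(h), he(h), size=h)
        params["gamma"] = np.ones(p)
        params["beta"] = np.zeros(p)
        params["u"] = rng.uniform(-he(p), he(p), size=p)
        params["c"] = np.zeros(1)
        self.params = params
        self.running_mean = np.zeros(p)
        self.running_var = np.ones(p)

    # -- forward ----------------------------------------------------------

    def forward(
        self,
        features: np.ndarray,
        mask: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> dict[str, np.ndarray]:
        """Run the full pipeline on a (B, m*, p) batch; returns the cache.

        In eval mode dropout is off and batch normalization uses running
        statistics, so the output is deterministic.
        """
        features = np.asarray(features, dtype=np.float64)
        mask = np.asarray(mask, dtype=bool)
        if features.ndim != 3 or mask.shape != features.shape[:2]:
            raise ValueError("expected (B, m*, p) features with (B, m*) mask")
        if not np.all(np.isfinite(features)):
            raise ValueError("non-finite values in features")
        if not mask.any(axis=1).all():
            raise ValueError("empty bag: a mask row has no valid instance")
        cfg = self.config
        cache: dict = {"mask": mask, "training": training}

        X = features
        xs, us, keeps = [], [], []
        for l in range(cfg.n_blocks):
            xs.append(X)
            U = local_fc_forward(X, self.params[f"W{l}"], self.params[f"b{l}"])
            us.append(U)
            H = np.maximum(U, 0.0)
            if training and cfg.dropout_rate > 0.0:
                if rng is None:
                    raise ValueError("training-mode forward needs an rng for dropout")
                keep = (rng.random(H.shape) >= cfg.dropout_rate) / (1.0 - cfg.dropout_rate)
                H = H * keep
                keeps.append(keep)
            else:
                keeps.append(None)
            X = X + H if cfg.use_skip else H
        Z = X
        cache.update(xs=xs, us=us, keeps=keeps, Z=Z)

        if cfg.scorer == "linear":
            scores = Z @ self.params["w_att"] + self.params["b_att"]
        else:
            A = Z @ self.params["V"].T
            T = np.tanh(A)
            scores = T @ self.params["w_att"]
            cache["T"] = T
        cache["scores"] = scores

        pool_fn = masked_sparsemax_batch if cfg.pooling == "sparsemax" else masked_softmax_batch
        alpha = pool_fn(scores, mask)
        pooled = (alpha[:, None, :] @ Z)[:, 0, :]
        cache.update(alpha=alpha, pooled=pooled)

        if training:
            mu = pooled.mean(axis=0)
            var = pooled.var(axis=0)
            self.running_mean = (1 - _BN_MOMENTUM) * self.running_mean + _BN_MOMENTUM * mu
            self.running_var = (1 - _BN_MOMENTUM) * self.running_var + _BN_MOMENTUM * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (pooled - mu) * inv_std
        pooled_norm = self.params["gamma"] * xhat + self.params["beta"]
        cache.update(mu=mu, var=var, inv_std=inv_std, xhat=xhat, pooled_norm=pooled_norm)

        logit = pooled_norm @ self.params["u"] + self.params["c"][0]
        cache["logit"] = logit
        cache["prob"] = _sigmoid(logit)
        return cache

    def predict_proba(self, batch: PaddedBatch) -> np.ndarray:
        return self.forward(batch.features, batch.mask, training=False)["prob"]

    def predict(self, batch: PaddedBatch) -> list[Prediction]:
        cache = self.forward(batch.features, batch.mask, training=False)
        preds = []
        for i in range(batch.n_bags):
            alpha = cache["alpha"][i]
            preds.append(
                Prediction(
                    probability=float(cache["prob"][i]),
                    attention=AttentionResult(
                        alpha=alpha,
                        pooled=cache["pooled"][i],
                        pooled_normalized=cache["pooled_norm"][i],
                        support=np.flatnonzero(alpha > 0),
                    ),
                )
            )
        return preds

    # -- backward ---------------------------------------------------------

    def loss_and_grads(
        self,
        features: np.ndarray,
        mask: np.ndarray,
        labels: np.ndarray,
        rng: np.random.Generator | None = None,
        sample_weight: np.ndarray | None = None,
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Mean binary cross-entropy and its gradient w.r.t. every parameter."""
        cfg = self.config
        cache = self.forward(features, mask, training=True, rng=rng)
        labels = np.asarray(labels, dtype=np.float64)
        B = labels.shape[0]
        logit = cache["logit"]
        w = np.ones(B) if sample_weight is None else np.asarray(sample_weight, float)
        # softplus(x) - y*x is BCE in a numerically stable form
        softplus = np.where(logit > 30, logit, np.log1p(np.exp(np.minimum(logit, 30))))
        loss = float(np.sum(w * (softplus - labels * logit)) / np.sum(w))

        grads: dict[str, np.ndarray] = {}
        dlogit = w * (cache["prob"] - labels) / np.sum(w)

        grads["u"] = cache["pooled_norm"].T @ dlogit
        grads["c"] = np.array([dlogit.sum()])
        dpn = dlogit[:, None] * self.params["u"]

        grads["gamma"] = np.sum(dpn * cache["xhat"], axis=0)
        grads["beta"] = np.sum(dpn, axis=0)
        dxhat = dpn * self.params["gamma"]
        # batch-norm backward over the batch axis (training statistics)
        xc = cache["pooled"] - cache["mu"]
        inv_std = cache["inv_std"]
        dvar = np.sum(dxhat * xc, axis=0) * (-0.5) * inv_std**3
        dmu = -np.sum(dxhat, axis=0) * inv_std - dvar * 2.0 * xc.mean(axis=0)
        dpooled = dxhat * inv_std + (2.0 / B) * dvar * xc + dmu / B

        alpha, Z = cache["alpha"], cache["Z"]
        dalpha = (Z @ dpooled[:, :, None])[:, :, 0]
        dZ = alpha[:, :, None] * dpooled[:, None, :]

        if cfg.pooling == "sparsemax":
            s = alpha > 0.0
            cnt = s.sum(axis=1)
            mean_v = np.sum(dalpha * s, axis=1) / cnt
            dscore = np.where(s, dalpha - mean_v[:, None], 0.0)
        else:
            inner = np.sum(alpha * dalpha, axis=1, keepdims=True)
            dscore = alpha * (dalpha - inner)

        p, h = cfg.p, cfg.hidden
        if cfg.scorer == "linear":
            grads["w_att"] = Z.reshape(-1, p).T @ dscore.reshape(-1)
            grads["b_att"] = np.array([dscore.sum()])
            dZ = dZ + dscore[:, :, None] * self.params["w_att"]
        else:
            T = cache["T"]
            grads["w_att"] = T.reshape(-1, h).T @ dscore.reshape(-1)
            dA = dscore[:, :, None] * self.params["w_att"] * (1.0 - T**2)
            grads["V"] = dA.reshape(-1, h).T @ Z.reshape(-1, p)
            dZ = dZ + (dA.reshape(-1, h) @ self.params["V"]).reshape(Z.shape)

        dX = dZ
        for l in reversed(range(cfg.n_blocks)):
            U, keep, Xin = cache["us"][l], cache["keeps"][l], cache["xs"][l]
            dH = dX if not cfg.use_skip else dX.copy()
            if keep is not None:
                dH = dH * keep
            dU = dH * (U > 0)
            dU_flat = dU.reshape(-1, p)
            grads[f"W{l}"] = dU_flat.T @ Xin.reshape(-1, p)
            grads[f"b{l}"] = dU_flat.sum(axis=0)
            dX = (dU_flat @ self.params[f"W{l}"]).reshape(Xin.shape) + (
                dX if cfg.use_skip else 0.0
            )
        return loss, grads

    # -- persistence ------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.copy() for k, v in self.params.items()}
        state["running_mean"] = self.running_mean.copy()
        state["running_var"] = self.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        self.running_mean = state["running_mean"].copy()
        self.running_var = state["running_var"].copy()
        self.params = {
            k: v.copy() for k, v in state.items() if k not in ("running_mean", "running_var")
        }

    def save(self, path: str | Path) -> None:
        """Write weights as .npz with a JSON sidecar holding the config."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.state_dict())
        path.with_suffix(".json").write_text(json.dumps(asdict(self.config), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SparseAttentionMIL":
        path = Path(path)
        config = ModelConfig(**json.loads(path.with_suffix(".json").read_text()))
        model = cls(config)
        with np.load(path.with_suffix(".npz")) as npz:
            model.load_state_dict({k: npz[k] for k in npz.files})
        return model


def extract_features(bags: list[Bag], model: SparseAttentionMIL) -> np.ndarray:
    """Eval-mode batch-normalized pooled features, one row per bag (n, p)."""
    batch = PaddedBatch.from_bags(bags, m_star=model.config.m_star)
    cache = model.forward(batch.features, batch.mask, training=False)
    return cache["pooled_norm"]
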