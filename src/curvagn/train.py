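"""Training loop (Adam), prediction, and evaluation.

The objective summed over a batch of complexes is

    L = sum |y_hat - y|  +  lambda * sum ||flatten(Z_tilde) - flatten(Z)||,

the second term tying the pairwise-pooling head to the ground-truth
atom-type interaction matrix.  Training is deterministic given the seed
(single-threaded numpy); the best state is selected by validation RMSE
with optional early stopping.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .dataset import GraphSample
from .metrics import MetricsReport, compute_metrics
from .nn.autodiff import Tensor
from .nn.model import ModelConfig, ModelState, forward, init_state, loss

logger = logging.getLogger(__name__)


class Adam:
    """Adam optimizer over a named-parameter state dict."""

    def __init__(
        self,
        state: ModelState,
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.state = state
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in state.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in state.items()}
        self.t = 0

    def step(self) -> None:
        """Apply one update from the gradients accumulated on the state."""
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.state.items():
            g = p.grad
            if g is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1**self.t)
            v_hat = self.v[k] / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.state.values():
            p.grad = None


def _batch_loss(
    batch: Sequence[GraphSample],
    config: ModelConfig,
    state: ModelState,
    training: bool,
    rng: Optional[np.random.Generator],
) -> Tensor:
    total: Optional[Tensor] = None
    for sample in batch:
        y_hat, z_tilde = forward(sample, config, state, training=training, rng=rng)
        item = loss(
            y_hat,
            sample.label,
            z_tilde,
            sample.interaction_matrix,
            config.lambda_tradeoff,
            norm=config.loss_norm,
        )
        total = item if total is None else total + item
    return total


def predict(
    samples: Sequence[GraphSample], config: ModelConfig, state: ModelState
) -> np.ndarray:
    """Deterministic (evaluation-mode) affinity predictions."""
    return np.array(
        [float(forward(s, config, state)[0].data) for s in samples]
    )


def training_mae(
    samples: Sequence[GraphSample], config: ModelConfig, state: ModelState
) -> float:
    labels = np.array([s.label for s in samples])
    return float(np.mean(np.abs(predict(samples, config, state) - labels)))


def train_steps(
    samples: Sequence[GraphSample],
    config: ModelConfig,
    state: ModelState,
    n_steps: int,
    lr: float = 1e-3,
    batch_size: int = 32,
    seed: int = 0,
) -> List[float]:
    """Run a fixed number of Adam steps on random batches; returns the
    per-step batch losses."""
    rng = np.random.default_rng(seed)
    opt = Adam(state, lr=lr)
    losses = []
    n = len(samples)
    for _ in range(n_steps):
        idx = rng.choice(n, size=min(batch_size, n), replace=False)
        opt.zero_grad()
        total = _batch_loss([samples[i] for i in idx], config, state, True, rng)
        if not np.isfinite(total.data):
            raise RuntimeError(f"training diverged: non-finite loss {total.data!r}")
        total.backward()
        opt.step()
        losses.append(float(total.data))
    return losses


@dataclass
class TrainResult:
    state: ModelState
    config: ModelConfig
    log: List[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_rmse: float = float("inf")


def train(
    train_samples: Sequence[GraphSample],
    config: ModelConfig,
    seed: int = 0,
    val_samples: Optional[Sequence[GraphSample]] = None,
    n_epochs: int = 30,
    lr: float = 1e-3,
    batch_size: int = 32,
    patience: int = 30,
    log_stream=None,
) -> TrainResult:
    """Epoch-based training with validation-RMSE model selection.

    With ``n_epochs == 0`` the freshly initialized state is returned
    unchanged.  Per-epoch records go to ``log_stream`` (default stderr)
    and to the returned ``log`` list.
    """
    if not train_samples:
        raise ValueError("training split is empty")
    stream = log_stream if log_stream is not None else sys.stderr
    rng = np.random.default_rng(seed)
    state = init_state(config, rng)
    result = TrainResult(state=state, config=config)
    if n_epochs == 0:
        return result

    opt = Adam(state, lr=lr)
    best_snapshot = {k: p.data.copy() for k, p in state.items()}
    stale = 0
    for epoch in range(n_epochs):
        order = rng.permutation(len(train_samples))
        epoch_loss = 0.0
        for start in range(0, len(order), batch_size):
            batch = [train_samples[i] for i in order[start : start + batch_size]]
            opt.zero_grad()
            total = _batch_loss(batch, config, state, True, rng)
            if not np.isfinite(total.data):
                raise RuntimeError("training diverged: non-finite loss")
            total.backward()
            opt.step()
            epoch_loss += float(total.data)
        record = {"epoch": epoch, "train_loss": epoch_loss / len(train_samples)}
        if val_samples:
            val_pred = predict(val_samples, config, state)
            val_labels = np.array([s.label for s in val_samples])
            val_rmse = float(np.sqrt(np.mean((val_pred - val_labels) ** 2)))
            record["val_rmse"] = val_rmse
            if val_rmse < result.best_val_rmse:
                result.best_val_rmse = val_rmse
                result.best_epoch = epoch
                best_snapshot = {k: p.data.copy() for k, p in state.items()}
                stale = 0
            else:
                stale += 1
        result.log.append(record)
        print(json.dumps(record), file=stream)
        if val_samples and stale > patience:
            break

    if val_samples:
        for k, p in state.items():
            p.data = best_snapshot[k]
    return result


def evaluate(
    state: ModelState,
    config: ModelConfig,
    samples: Sequence[GraphSample],
) -> Tuple[MetricsReport, List[dict]]:
    """Metrics plus a per-complex absolute-error table."""
    if not samples:
        raise ValueError("cannot evaluate on an empty dataset")
    preds = predict(samples, config, state)
    labels = np.array([s.label for s in samples])
    report = compute_metrics(preds, labels)
    table = [
        {
            "name": s.name,
            "label": float(l),
            "prediction": float(p),
            "abs_error": float(abs(p - l)),
        }
        for s, p, l in zip(samples, preds, labels)
    ]
    return report, table


# -- checkpoints ---------------------------------------------------------

CHECKPOINT_SCHEMA = "curvagn-checkpoint-v1"


def save_checkpoint(path, config: ModelConfig, state: ModelState) -> None:
    arrays = {f"param::{k}": p.data for k, p in state.items()}
    np.savez_compressed(
        path,
        schema=np.array(CHECKPOINT_SCHEMA),
        config=np.array(json.dumps(config.to_dict())),
        **arrays,
    )


def load_checkpoint(path) -> Tuple[ModelConfig, ModelState]:
    with np.load(path) as z:
        if str(z["schema"]) != CHECKPOINT_SCHEMA:
            raise ValueError(f"unknown checkpoint schema {z['schema']!r}")
        config = ModelConfig.from_dict(json.loads(str(z["config"])))
        state = {
            k[len("param::") :]: Tensor(z[k], requires_grad=True)
            for k in z.files
            if k.startswith("param::")
        }
    return config, state
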