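"""Three-branch multimodal network and its transfer-learning protocol.

The network fuses a recurrent (or transformer) encoding of the EHR day
sequence with a tabular omics vector through three prediction branches —
EHR-only, omics-only, and a joint branch over the concatenated latent state
and omics vector — combined by a final bias-free linear layer over the three
branch scores. Regression outputs the combined score directly (mean squared
error loss); classification passes it through a logistic link (binary
cross-entropy loss), with the branch heads producing raw scores.

The transfer protocol pretrains the encoder and EHR head on the large
EHR-only cohort, then copies the encoder weights into a fresh multimodal
network and freezes them; the EHR head is copied as initialization but
remains trainable, and the omics, joint and combiner weights start fresh.
Training uses adaptive moment estimation with a per-epoch multiplicative
learning-rate decay and early stopping when the held-out loss has not
improved for ``patience`` consecutive epochs, restoring the best epoch.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import GroupKFold, GroupShuffleSplit

from .nn import Tensor, concat, Module, Linear, MLP, GRU, Adam

logger = logging.getLogger(__name__)

__all__ = [
    "EHREncoderConfig", "TrainTrace", "EHROnlyNet", "OmicsOnlyNet",
    "MultimodalNet", "ModelData", "PredictionSet", "loss",
    "mse_loss", "bce_loss", "task_loss",
    "pretrain_ehr", "transfer_and_freeze", "train_multimodal",
    "train_simple", "grid_search", "save_checkpoint", "load_checkpoint",
]

BRANCHES = ("ehr", "omics", "joint")


@dataclass
class EHREncoderConfig:
    """Encoder and optimization hyperparameters.

    Reference-scale values are hidden_dim 400 / embedding 400 with batch
    sizes 512 (pretraining) and 16 (omics cohort); desk-scale experiments
    shrink the widths but keep the protocol.
    """

    n_layers: int = 2                  # grid: {2, 4}
    hidden_dim: int = 32
    dropout: float = 0.1
    learning_rate: float = 1e-2
    lr_decay: float = 1e-3             # per-epoch multiplicative decay
    batch_size_pretrain: int = 512
    batch_size_omics: int = 16
    max_epochs: int = 100
    patience: int = 5
    omics_hidden: int = 32             # classification omics head: {16, 32, 64}
    seed: int = 0

    def __post_init__(self):
        if self.hidden_dim < 1 or self.patience < 1:
            raise ValueError("hidden_dim and patience must be >= 1")


@dataclass
class TrainTrace:
    train_losses: list[float] = field(default_factory=list)
    test_losses: list[float] = field(default_factory=list)
    stop_epoch: int = 0
    snapshots: list[dict] = field(default_factory=list)


@dataclass
class ModelData:
    """Batched model inputs for one record set."""

    ehr: np.ndarray            # (B, L, d) summaries or (B, L) token ids
    mask: np.ndarray           # (B, L) valid positions
    omics: np.ndarray | None   # (B, P)
    y: np.ndarray              # (B,)
    record_ids: list[str]
    patient_ids: list[str]

    def subset(self, idx) -> "ModelData":
        idx = np.asarray(idx)
        return ModelData(
            ehr=self.ehr[idx], mask=self.mask[idx],
            omics=None if self.omics is None else self.omics[idx],
            y=self.y[idx],
            record_ids=[self.record_ids[i] for i in idx],
            patient_ids=[self.patient_ids[i] for i in idx])

    def __len__(self) -> int:
        return len(self.y)


# ---------------------------------------------------------------------------
# losses

@dataclass
class PredictionSet:
    y_true: np.ndarray
    y_pred: np.ndarray

    def __post_init__(self):
        self.y_true = np.asarray(self.y_true, float)
        self.y_pred = np.asarray(self.y_pred, float)
        if self.y_true.shape != self.y_pred.shape:
            raise ValueError("y_true and y_pred must have equal length")

    @property
    def n(self) -> int:
        return len(self.y_true)


def loss(preds: PredictionSet, task: str) -> float:
    """Task loss on a prediction set: MSE (regression) or clamped BCE."""
    return float(task_loss(Tensor(preds.y_pred), preds.y_true, task).data)


def mse_loss(pred: Tensor, y: np.ndarray) -> Tensor:
    diff = pred - Tensor(y)
    return (diff * diff).mean()

def bce_loss(pred: Tensor, y: np.ndarray, eps: float = 1e-7) -> Tensor:
    p = pred.clip(eps, 1.0 - eps)
    yt = Tensor(y)
    return -(yt * p.log() + (1.0 - yt) * (1.0 - p).log()).mean()

def task_loss(pred: Tensor, y: np.ndarray, task: str) -> Tensor:
    return mse_loss(pred, y) if task == "regression" else bce_loss(pred, y)


# ---------------------------------------------------------------------------
# networks

class EHROnlyNet(Module):
    """Encoder + affine head; the pretraining network and the EHR-only
    baseline."""

    def __init__(self, encoder: Module, hidden_dim: int, task: str,
                 rng: np.random.Generator):
        self.encoder = encoder
        self.head = Linear(hidden_dim, 1, rng)
        self.task = task

    def forward(self, data: ModelData, rng=None, training=False) -> Tensor:
        h = self.encoder(Tensor(data.ehr) if data.ehr.dtype != np.int64
                         else data.ehr, data.mask, rng=rng, training=training)
        raw = self.head(h).reshape(len(data))
        return raw.sigmoid() if self.task == "classification" else raw


class OmicsOnlyNet(Module):
    """The omics head alone, with its own output nonlinearity for
    classification."""

    def __init__(self, n_analytes: int, task: str, rng: np.random.Generator,
                 omics_hidden: int = 32):
        self.head = (Linear(n_analytes, 1, rng) if task == "regression"
                     else MLP(n_analytes, omics_hidden, 1, rng))
        self.task = task

    def forward(self, data: ModelData, rng=None, training=False) -> Tensor:
        raw = self.head(Tensor(data.omics)).reshape(len(data))
        return raw.sigmoid() if self.task == "classification" else raw


class MultimodalNet(Module):
    """The full three-branch fusion network."""

    def __init__(self, input_dim: int, n_analytes: int,
                 config: EHREncoderConfig, task: str,
                 rng: np.random.Generator, encoder: Module | None = None):
        self.task = task
        self.config = config
        H = config.hidden_dim
        self.encoder = encoder if encoder is not None else GRU(
            input_dim, H, config.n_layers, config.dropout, rng)
        self.ehr_head = Linear(H, 1, rng)
        self.omics_head = (Linear(n_analytes, 1, rng) if task == "regression"
                           else MLP(n_analytes, config.omics_hidden, 1, rng))
        self.joint_head = Linear(H + n_analytes, 1, rng)
        self.combiner = Linear(3, 1, rng, bias=False)

    def forward(self, data: ModelData, rng=None, training=False
                ) -> tuple[Tensor, Tensor, Tensor]:
        """Returns (prediction, branch scores (B,3), latent state (B,H))."""
        h = self.encoder(Tensor(data.ehr) if data.ehr.dtype != np.int64
                         else data.ehr, data.mask, rng=rng, training=training)
        return self.head_forward(h, data.omics, rng=rng, training=training)

    def head_forward(self, h: Tensor, omics: np.ndarray, rng=None,
                     training=False) -> tuple[Tensor, Tensor, Tensor]:
        """Branches and combiner on a given latent state (used directly when
        the encoder is frozen and its outputs can be cached). Dropout lives
        between recurrent layers inside the encoder, not on the latent
        state."""
        om = Tensor(omics)
        p_ehr = self.ehr_head(h)
        p_om = self.omics_head(om)
        p_joint = self.joint_head(concat([h, om], axis=1))
        branch = concat([p_ehr, p_om, p_joint], axis=1)
        raw = self.combiner(branch).reshape(h.shape[0])
        yhat = raw.sigmoid() if self.task == "classification" else raw
        return yhat, branch, h

    def predict(self, data: ModelData) -> np.ndarray:
        return self.forward(data)[0].data

    def branch_values(self, data: ModelData) -> np.ndarray:
        return self.forward(data)[1].data


# ---------------------------------------------------------------------------
# training loops

def _epoch_lr(config: EHREncoderConfig, epoch: int) -> float:
    return config.learning_rate * (1.0 - config.lr_decay) ** epoch


def _run_training(net: Module, forward_loss, train_n: int, eval_loss,
                  config: EHREncoderConfig, batch_size: int,
                  rng: np.random.Generator,
                  snapshot_fn=None) -> TrainTrace:
    """Generic loop: minibatch SGD epochs, early stopping on eval_loss with
    ``patience``, restore of the best-epoch weights."""
    opt = Adam(net.parameters(), lr=config.learning_rate)
    trace = TrainTrace()
    best_loss, best_state, since_best = np.inf, net.state_dict(), 0
    for epoch in range(config.max_epochs):
        opt.lr = _epoch_lr(config, epoch)
        order = rng.permutation(train_n)
        ep_losses = []
        for start in range(0, train_n, batch_size):
            idx = order[start:start + batch_size]
            opt.zero_grad()
            loss = forward_loss(idx, rng)
            loss.backward()
            opt.step()
            ep_losses.append(float(loss.data))
        test_loss = float(eval_loss())
        trace.train_losses.append(float(np.mean(ep_losses)))
        trace.test_losses.append(test_loss)
        if snapshot_fn is not None:
            trace.snapshots.append(snapshot_fn())
        if test_loss < best_loss - 1e-12:
            best_loss, best_state, since_best = test_loss, net.state_dict(), 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    trace.stop_epoch = len(trace.test_losses)
    net.load_state_dict(best_state)
    return trace


def pretrain_ehr(data: ModelData, config: EHREncoderConfig, task: str,
                 encoder: Module | None = None,
                 input_dim: int | None = None
                 ) -> tuple[EHROnlyNet, TrainTrace]:
    """Train encoder + EHR head on the pretraining cohort with a held-out
    20% (patient-grouped) test split for early stopping."""
    if len(data) == 0:
        raise ValueError("pretraining cohort is empty")
    if np.all(data.y == data.y[0]):
        logger.warning("all pretraining labels identical; degenerate task")
    rng = np.random.default_rng(config.seed)
    if encoder is None:
        if input_dim is None:
            input_dim = data.ehr.shape[-1]
        encoder = GRU(input_dim, config.hidden_dim, config.n_layers,
                      config.dropout, rng)
    net = EHROnlyNet(encoder, config.hidden_dim, task, rng)

    groups = np.asarray(data.patient_ids)
    if len(set(groups)) >= 2:
        split = GroupShuffleSplit(n_splits=1, test_size=0.2,
                                  random_state=config.seed)
        tr_idx, te_idx = next(split.split(np.zeros(len(data)), groups=groups))
    else:
        tr_idx = te_idx = np.arange(len(data))
    train, test = data.subset(tr_idx), data.subset(te_idx)

    def forward_loss(idx, rng_):
        batch = train.subset(idx)
        pred = net.forward(batch, rng=rng_, training=True)
        return task_loss(pred, batch.y, task)

    def eval_loss():
        return task_loss(net.forward(test), test.y, task).data

    trace = _run_training(net, forward_loss, len(train), eval_loss, config,
                          config.batch_size_pretrain, rng)
    return net, trace


def transfer_and_freeze(pretrained: EHROnlyNet, fresh: MultimodalNet
                        ) -> MultimodalNet:
    """Copy pretrained encoder weights into ``fresh`` and freeze them; the
    EHR head is copied as a trainable initialization."""
    src = pretrained.encoder.state_dict()
    dst = dict(fresh.encoder.named_parameters())
    mismatched = [k for k in src
                  if k not in dst or dst[k].data.shape != src[k].shape]
    if mismatched or set(src) != set(dst):
        raise ValueError(f"encoder transfer mismatch on: {sorted(mismatched) or sorted(set(src) ^ set(dst))}")
    fresh.encoder.load_state_dict(src)
    fresh.encoder.freeze(True)
    fresh.ehr_head.load_state_dict(pretrained.head.state_dict())
    return fresh


def train_multimodal(net, train: ModelData, test: ModelData,
                     config: EHREncoderConfig, task: str,
                     snapshot_params: bool = False,
                     seed: int | None = None) -> tuple[Module, TrainTrace]:
    """Fit any of the networks on the omics cohort, early-stopping on the
    test split; works for the full net and the single-branch baselines."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    is_multi = isinstance(net, MultimodalNet)

    # a fully frozen encoder yields constant latents: compute them once and
    # train only the heads on the cached states
    frozen_encoder = (is_multi
                      and all(p.frozen for p in net.encoder.parameters()))
    if frozen_encoder:
        h_train = net.forward(train)[2].data
        h_test = net.forward(test)[2].data

    def forward_loss(idx, rng_):
        batch = train.subset(idx)
        if frozen_encoder:
            out = net.head_forward(Tensor(h_train[np.asarray(idx)]),
                                   batch.omics, rng=rng_, training=True)
        else:
            out = net.forward(batch, rng=rng_, training=True)
        pred = out[0] if is_multi else out
        return task_loss(pred, batch.y, task)

    def eval_loss():
        if frozen_encoder:
            out = net.head_forward(Tensor(h_test), test.omics)
        else:
            out = net.forward(test)
        pred = out[0] if is_multi else out
        return task_loss(pred, test.y, task).data

    snap = net.state_dict if snapshot_params else None
    trace = _run_training(net, forward_loss, len(train), eval_loss, config,
                          config.batch_size_omics, rng, snapshot_fn=snap)
    return net, trace


def train_simple(net, train: ModelData, test: ModelData,
                 config: EHREncoderConfig, task: str,
                 seed: int | None = None):
    """Alias of :func:`train_multimodal` for single-branch baselines."""
    return train_multimodal(net, train, test, config, task, seed=seed)


def grid_search(grid: list[dict], fit_eval, groups: np.ndarray,
                seed: int = 0, n_folds: int = 3,
                maximize: bool = False) -> tuple[dict, list[float]]:
    """Grouped 3-fold cross-validated grid search.

    ``fit_eval(point, train_idx, stop_idx, val_idx) -> score`` trains a
    model for one grid point using ``stop_idx`` for early stopping and
    returns the validation score (a loss unless ``maximize``). 20% of each
    training fold (patient-grouped) is carved out as the early-stopping set.
    Ties keep the first grid point.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    groups = np.asarray(groups)
    n = len(groups)
    folds = list(GroupKFold(n_splits=n_folds).split(np.zeros(n), groups=groups))
    means = []
    for point in grid:
        scores = []
        for fold_i, (tr, val) in enumerate(folds):
            gss = GroupShuffleSplit(n_splits=1, test_size=0.2,
                                    random_state=seed + fold_i)
            sub_tr, sub_stop = next(gss.split(np.zeros(len(tr)),
                                              groups=groups[tr]))
            scores.append(fit_eval(point, tr[sub_tr], tr[sub_stop], val))
        means.append(float(np.mean(scores)))
    best = int(np.argmax(means) if maximize else np.argmin(means))
    return grid[best], means


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(net: Module, config: EHREncoderConfig, path,
                    extra: dict | None = None) -> None:
    state = net.state_dict()
    frozen = {name: p.frozen for name, p in net.named_parameters()}
    meta = {"config": asdict(config), "frozen": frozen,
            "class": type(net).__name__, **(extra or {})}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> tuple[dict[str, np.ndarray], dict]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k: z[k] for k in z.files if k != "__meta__"}
    return state, meta
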