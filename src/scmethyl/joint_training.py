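"""Multi-task heads, the masked objective, and the training protocol.

The full model predicts, for every target CpG site, one methylation
probability per cell (multi-task output).  Training minimises a masked
negative log-likelihood — unobserved site–cell pairs contribute exactly
nothing to the loss or its gradients — plus an L2 weight penalty:

    L(w) = NLL_w(ŷ, y) + λ2 ‖w‖²   (sum of squared weights, biases excluded)

Protocol: the DNA and CpG modules are first pre-trained independently, each
with its own per-cell sigmoid head (these remain usable as standalone
predictors).  The joint model is then assembled from the pre-trained
bodies, their parameters frozen, and only the joint hidden and output
layers are trained.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Tensor
from .cpg_net import CpgNet, CpgNetConfig
from .data_io import SiteDataset
from .dna_net import DnaNet, DnaNetConfig
from .nn import Adam, Dense, Module, Param

EPS = 1e-7


@dataclass
class TrainConfig:
    batch_size: int = 128
    learning_rate: float = 1e-4
    lr_decay_per_epoch: float = 0.95
    early_stop_patience_epochs: int = 10
    max_epochs: int = 200
    l2_lambda: float = 0.0
    l2_squared: bool = True
    seed: int = 0
    val_frac: float = 0.15  # used only when the split has no validation chroms

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not (0.0 < self.lr_decay_per_epoch <= 1.0):
            raise ValueError("lr_decay_per_epoch must be in (0, 1]")
        if self.early_stop_patience_epochs < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class PredictionSet:
    """Aligned probabilities, truth labels and observation mask."""

    sites: list[tuple[str, int]]
    y_hat: np.ndarray  # (N, T) in [0, 1]
    y: np.ndarray      # (N, T) binary
    o: np.ndarray      # (N, T) in {0, 1}

    def __post_init__(self):
        if not (self.y_hat.shape == self.y.shape == self.o.shape):
            raise ValueError("y_hat, y and o must have identical shapes")


@dataclass
class TrainLog:
    epochs: list[dict] = field(default_factory=list)
    trainable_groups: list[str] = field(default_factory=list)
    best_epoch: int = -1


# -- losses ---------------------------------------------------------------

def nll_loss(pred: PredictionSet) -> float:
    """Masked negative log-likelihood, summed over observed pairs."""
    p = np.clip(pred.y_hat, EPS, 1.0 - EPS)
    ll = pred.o * (pred.y * np.log(p) + (1.0 - pred.y) * np.log(1.0 - p))
    return float(-ll.sum())


def l2_penalty_t(params: dict[str, Param], squared: bool = True) -> Tensor:
    """Penalty over trainable non-bias weights (autodiff tensor)."""
    terms = [ad.tsum(p * p) for p in params.values()
             if p.trainable and not p.is_bias]
    if not terms:
        return Tensor(0.0)
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total if squared else total ** 0.5


def total_loss(pred: PredictionSet, params: dict[str, Param],
               l2_lambda: float, l2_squared: bool = True) -> float:
    return nll_loss(pred) + l2_lambda * float(
        l2_penalty_t(params, l2_squared).data)


def _nll_t(y_hat: Tensor, y: np.ndarray, o: np.ndarray) -> Tensor:
    p = ad.clip(y_hat, EPS, 1.0 - EPS)
    ll = Tensor(o) * (Tensor(y) * ad.log(p)
                      + Tensor(1.0 - y) * ad.log(Tensor(1.0) - p))
    return -ad.tsum(ll)


# -- models ---------------------------------------------------------------

class ModelBase(Module):
    """Common surface: forward to per-cell probabilities, predict, save."""

    kind = "base"

    def forward(self, windows: Tensor | None, contexts: Tensor | None,
                training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        raise NotImplementedError

    def predict(self, data: SiteDataset, batch_size: int = 512) -> np.ndarray:
        """Per-site, per-cell methylation probabilities (N, T)."""
        out = np.empty((data.n_sites, data.n_cells))
        for lo in range(0, data.n_sites, batch_size):
            hi = min(lo + batch_size, data.n_sites)
            w = Tensor(data.windows[lo:hi]) if self.uses_dna else None
            c = Tensor(data.contexts[lo:hi]) if self.uses_cpg else None
            out[lo:hi] = self.forward(w, c).data
        return out


class DnaModel(ModelBase):
    """DNA module plus a per-cell sigmoid head (sequence-only predictor)."""

    kind = "dna"
    uses_dna = True
    uses_cpg = False

    def __init__(self, rng: np.random.Generator, dna_cfg: DnaNetConfig,
                 L_win: int, n_cells: int):
        self.dna = DnaNet(rng, dna_cfg, L_win)
        self.head = Dense(rng, dna_cfg.fc_units, n_cells, "dna_head",
                          activation="sigmoid")
        self.n_cells = n_cells

    def forward(self, windows, contexts=None, training=False, rng=None):
        feat = self.dna.forward(windows, training=training, rng=rng)
        return self.head(feat)


class CpgModel(ModelBase):
    """CpG module plus a per-cell sigmoid head (neighbourhood-only predictor)."""

    kind = "cpg"
    uses_dna = False
    uses_cpg = True

    def __init__(self, rng: np.random.Generator, cpg_cfg: CpgNetConfig,
                 context_dim: int, n_cells: int):
        self.cpg = CpgNet(rng, cpg_cfg, context_dim)
        self.head = Dense(rng, 2 * cpg_cfg.hidden_units, n_cells, "cpg_head",
                          activation="sigmoid")
        self.n_cells = n_cells

    def forward(self, windows, contexts, training=False, rng=None):
        feat = self.cpg.forward(contexts, training=training, rng=rng)
        return self.head(feat)


class JointModel(ModelBase):
    """DNA + CpG bodies feeding a joint head of two FC ReLU layers.

    Feature order is fixed: [dna ; cpg].  The output layer has one sigmoid
    unit per cell.
    """

    kind = "joint"
    uses_dna = True
    uses_cpg = True

    def __init__(self, rng: np.random.Generator, dna: DnaNet, cpg: CpgNet,
                 n_cells: int, joint_units: int = 512,
                 dropout_rate: float = 0.0):
        self.dna = dna
        self.cpg = cpg
        in_dim = dna.cfg.fc_units + 2 * cpg.cfg.hidden_units
        self.fc1 = Dense(rng, in_dim, joint_units, "joint/fc1", activation="relu")
        self.fc2 = Dense(rng, joint_units, joint_units, "joint/fc2",
                         activation="relu")
        self.head = Dense(rng, joint_units, n_cells, "joint/head",
                          activation="sigmoid")
        self.n_cells = n_cells
        self.dropout_rate = dropout_rate

    def forward(self, windows, contexts, training=False, rng=None):
        feat = ad.concat([
            self.dna.forward(windows, training=training, rng=rng),
            self.cpg.forward(contexts, training=training, rng=rng),
        ], axis=1)
        h = self.fc1(feat)
        if training and self.dropout_rate > 0:
            h = ad.dropout(h, self.dropout_rate, rng)
        h = self.fc2(h)
        if training and self.dropout_rate > 0:
            h = ad.dropout(h, self.dropout_rate, rng)
        return self.head(h)


def joint_forward(dna_feat: np.ndarray, cpg_feat: np.ndarray,
                  model: JointModel) -> np.ndarray:
    """Joint head on pre-computed feature vectors (single site, inference)."""
    feat = Tensor(np.concatenate([dna_feat, cpg_feat])[None])
    h = model.fc2(model.fc1(feat))
    return model.head(h).data[0]


# -- training -------------------------------------------------------------

def _batch_loss(model: ModelBase, data: SiteDataset, idx: np.ndarray,
                l2_lambda: float, l2_squared: bool, training: bool,
                rng: np.random.Generator | None) -> Tensor:
    w = Tensor(data.windows[idx]) if model.uses_dna else None
    c = Tensor(data.contexts[idx]) if model.uses_cpg else None
    y_hat = model.forward(w, c, training=training, rng=rng)
    loss = _nll_t(y_hat, data.y[idx], data.o[idx])
    if l2_lambda > 0:
        loss = loss + Tensor(l2_lambda) * l2_penalty_t(model.params(), l2_squared)
    return loss


def evaluate_loss(model: ModelBase, data: SiteDataset, cfg: TrainConfig) -> float:
    """Total validation-style loss (NLL + L2) without dropout."""
    total = 0.0
    for lo in range(0, data.n_sites, 512):
        idx = np.arange(lo, min(lo + 512, data.n_sites))
        w = Tensor(data.windows[idx]) if model.uses_dna else None
        c = Tensor(data.contexts[idx]) if model.uses_cpg else None
        y_hat = model.forward(w, c).data
        total += nll_loss(PredictionSet([data.sites[i] for i in idx],
                                        y_hat, data.y[idx], data.o[idx]))
    if cfg.l2_lambda > 0:
        total += cfg.l2_lambda * float(
            l2_penalty_t(model.params(), cfg.l2_squared).data)
    return total


def train(model: ModelBase, train_data: SiteDataset, val_data: SiteDataset,
          cfg: TrainConfig,
          trainable: set[str] | None = None) -> TrainLog:
    """Mini-batch Adam with per-epoch learning-rate decay and early stopping.

    ``trainable``: restrict updates to parameters whose name starts with any
    of these prefixes (None = all).  Validation total loss is monitored;
    training stops after ``early_stop_patience_epochs`` epochs without
    improvement and the best-epoch parameters are restored.
    """
    if train_data.n_sites == 0:
        raise ValueError("empty training set")
    params = model.params()
    if trainable is not None:
        for name, p in params.items():
            p.trainable = any(name.startswith(pref) for pref in trainable)
    groups = sorted({n.split("/")[0] for n, p in params.items() if p.trainable})
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(params, lr=cfg.learning_rate)
    log = TrainLog(trainable_groups=groups)
    best_val = np.inf
    best_state = model.state_dict()
    since_improve = 0
    lr = cfg.learning_rate
    for epoch in range(cfg.max_epochs):
        opt.lr = lr
        order = rng.permutation(train_data.n_sites)
        train_loss = 0.0
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            opt.zero_grad()
            loss = _batch_loss(model, train_data, idx, cfg.l2_lambda,
                               cfg.l2_squared, True, rng)
            loss.backward()
            opt.step()
            train_loss += float(loss.data)
        val_loss = (evaluate_loss(model, val_data, cfg)
                    if val_data.n_sites > 0 else train_loss)
        log.epochs.append({"epoch": epoch, "train_loss": train_loss,
                           "val_loss": val_loss, "lr": lr})
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
            log.best_epoch = epoch
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= cfg.early_stop_patience_epochs:
                break
        lr *= cfg.lr_decay_per_epoch
    model.load_state_dict(best_state)
    return log


def split_train_val(data: SiteDataset, split, cfg: TrainConfig
                    ) -> tuple[SiteDataset, SiteDataset]:
    """Train/val datasets from a chromosome split.

    When the split has no validation chromosomes (tiny genomes), the last
    ``val_frac`` of each training chromosome — by position, not at random —
    is carved out instead.  The spatial blocking matters: a random-site
    validation set shares local sequence context with the training sites
    and cannot detect chromosome-specific overfitting.
    """
    train_data = data.chrom_subset(split.train_chroms)
    if split.val_chroms:
        val_data = data.chrom_subset(split.val_chroms)
        if val_data.n_sites > 0:
            return train_data, val_data
    per_chrom: dict[str, list[int]] = {}
    for i, (chrom, _pos) in enumerate(train_data.sites):
        per_chrom.setdefault(chrom, []).append(i)
    val_idx: list[int] = []
    for chrom, idx in per_chrom.items():  # sites are position-sorted per chrom
        n_val = max(1, int(round(cfg.val_frac * len(idx))))
        val_idx.extend(idx[-n_val:])
    val_set = set(val_idx)
    tr_idx = np.array([i for i in range(train_data.n_sites) if i not in val_set],
                      dtype=np.int64)
    return train_data.subset(tr_idx), train_data.subset(np.array(sorted(val_idx),
                                                                 dtype=np.int64))


def validation_auc(model: ModelBase, val_data: SiteDataset) -> float:
    """AUC over the observed validation pairs (0.5 when undefined)."""
    from sklearn.metrics import roc_auc_score

    y_hat = model.predict(val_data)
    obs = val_data.o.astype(bool)
    y = val_data.y[obs]
    if len(np.unique(y)) < 2:
        return 0.5
    return float(roc_auc_score(y, y_hat[obs]))


def train_with_restarts(model_factory, train_data: SiteDataset,
                        val_data: SiteDataset, cfg: TrainConfig,
                        n_restarts: int = 3,
                        trainable: set[str] | None = None
                        ) -> tuple[ModelBase, TrainLog]:
    """Train from several random initialisations; keep the best by val AUC.

    ``model_factory(rng)`` builds a fresh model.  Restart r uses seed
    ``cfg.seed + 1000·r`` for both initialisation and batching, so the whole
    procedure is deterministic in ``cfg.seed``.
    """
    best: tuple[float, ModelBase, TrainLog] | None = None
    for r in range(n_restarts):
        r_cfg = TrainConfig(**{**cfg.__dict__, "seed": cfg.seed + 1000 * r})
        model = model_factory(np.random.default_rng(r_cfg.seed))
        log = train(model, train_data, val_data, r_cfg, trainable=trainable)
        score = validation_auc(model, val_data)
        if best is None or score > best[0]:
            best = (score, model, log)
    return best[1], best[2]


def train_protocol(data: SiteDataset, split, cfg: TrainConfig,
                   dna_cfg: DnaNetConfig | None = None,
                   cpg_cfg: CpgNetConfig | None = None,
                   joint_units: int = 512,
                   ) -> tuple[dict[str, ModelBase], dict[str, TrainLog]]:
    """Three-stage protocol: pre-train DNA and CpG modules, then the joint head.

    Returns standalone DNA-only and CpG-only models plus the assembled joint
    model whose DNA/CpG parameters are frozen copies of the pre-trained ones.
    """
    dna_cfg = dna_cfg or DnaNetConfig()
    cpg_cfg = cpg_cfg or CpgNetConfig()
    train_data, val_data = split_train_val(data, split, cfg)
    T = data.n_cells
    logs: dict[str, TrainLog] = {}

    rng = np.random.default_rng(cfg.seed)
    dna_model = DnaModel(rng, dna_cfg, data.L_win, T)
    logs["dna"] = train(dna_model, train_data, val_data, cfg)

    rng = np.random.default_rng(cfg.seed + 7)
    cpg_model = CpgModel(rng, cpg_cfg, data.contexts.shape[2], T)
    logs["cpg"] = train(cpg_model, train_data, val_data, cfg)

    rng = np.random.default_rng(cfg.seed + 13)
    joint = JointModel(rng, copy.deepcopy(dna_model.dna),
                       copy.deepcopy(cpg_model.cpg), T,
                       joint_units=joint_units)
    logs["joint"] = train(joint, train_data, val_data, cfg,
                          trainable={"joint/"})
    models = {"dna": dna_model, "cpg": cpg_model, "joint": joint}
    return models, logs


# -- persistence ----------------------------------------------------------

def save_model(model: ModelBase, path, meta: dict | None = None) -> None:
    """Single-file model container: parameter arrays + JSON metadata.

    Written with numpy's pickle serialisation (deterministic bytes for
    identical contents, unlike zip-based containers).
    """
    params = model.params()
    payload = {
        "__meta__": json.dumps(_model_meta(model, meta), sort_keys=True),
        "__freeze__": json.dumps({n: bool(p.trainable) for n, p in params.items()},
                                 sort_keys=True),
    }
    for name, p in sorted(params.items()):
        payload[name] = np.ascontiguousarray(p.data)
    with open(path, "wb") as fh:
        np.save(fh, np.array(payload, dtype=object), allow_pickle=True)


def _model_meta(model: ModelBase, extra: dict | None) -> dict:
    meta = {"kind": model.kind, "n_cells": getattr(model, "n_cells", None)}
    if hasattr(model, "dna"):
        meta["dna_cfg"] = asdict(model.dna.cfg)
        meta["L_win"] = model.dna.L_win
    if hasattr(model, "cpg"):
        meta["cpg_cfg"] = asdict(model.cpg.cfg)
        meta["context_dim"] = model.cpg.embedding.W.data.shape[0]
    if isinstance(model, JointModel):
        meta["joint_units"] = model.fc1.W.data.shape[1]
    if extra:
        meta.update(extra)
    return meta


def load_model(path) -> tuple[ModelBase, dict]:
    """Rebuild a model from a container written by :func:`save_model`."""
    with open(path, "rb") as fh:
        payload = np.load(fh, allow_pickle=True).item()
    meta = json.loads(payload["__meta__"])
    freeze = json.loads(payload["__freeze__"])
    rng = np.random.default_rng(0)  # shapes only; weights overwritten below
    kind = meta["kind"]
    if kind == "dna":
        model = DnaModel(rng, DnaNetConfig(**meta["dna_cfg"]), meta["L_win"],
                         meta["n_cells"])
    elif kind == "cpg":
        model = CpgModel(rng, CpgNetConfig(**meta["cpg_cfg"]),
                         meta["context_dim"], meta["n_cells"])
    elif kind == "joint":
        dna = DnaNet(rng, DnaNetConfig(**meta["dna_cfg"]), meta["L_win"])
        cpg = CpgNet(rng, CpgNetConfig(**meta["cpg_cfg"]), meta["context_dim"])
        model = JointModel(rng, dna, cpg, meta["n_cells"],
                           joint_units=meta.get("joint_units", 512))
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    state = {k: v for k, v in payload.items() if not k.startswith("__")}
    model.load_state_dict(state)
    for name, p in model.params().items():
        if name in freeze:
            p.trainable = freeze[name]
    return model, meta


def predictions_to_tsv(pred: PredictionSet, cell_ids: list[str], path) -> None:
    """Long-format TSV: chrom, pos, cell_id, y_hat (observed-state column too)."""
    rows = []
    for i, (chrom, pos) in enumerate(pred.sites):
        for t, cell in enumerate(cell_ids):
            rows.append((chrom, pos, cell, pred.y_hat[i, t],
                         int(pred.y[i, t]) if pred.o[i, t] else ""))
    pd.DataFrame(rows, columns=["chrom", "pos", "cell_id", "y_hat",
                                "observed_state"]).to_csv(
        path, sep="\t", index=False, float_format="%.6f")
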