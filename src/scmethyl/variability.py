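"""Mean / cell-to-cell-variance prediction from DNA sequence.

Targets are computed per site and window scale s ∈ {1000, …, 5000} bp: each
cell's mean methylation m_nst over its observed sites in the window, the
across-cell mean m_ns and the population variance v_ns = mean_t (m_nst −
m_ns)².  Cells with no observation in a window are excluded (with the
divisor reduced accordingly); at least two included cells are required to
define a variance, otherwise the (site, scale) target is missing.

The predictor reuses the trained DNA module architecture and weights with
the output layer replaced by 2·|S| sigmoid units (mean and variance per
scale, multi-task).  Fine-tuning freezes the first-layer convolutional
filters — the motif detectors — and trains everything else against a
summed squared-error objective with the usual L2 penalty.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import autodiff as ad
from .autodiff import Tensor
from .data_io import MethylationProfile
from .joint_training import TrainConfig, l2_penalty_t
from .nn import Adam, Dense, Module, Param

DEFAULT_SCALES = (1000, 2000, 3000, 4000, 5000)


@dataclass
class WindowStats:
    """Mean / variance targets for one site across window scales."""

    scales: tuple[int, ...]
    m: np.ndarray        # (|S|,) across-cell mean, NaN when undefined
    v: np.ndarray        # (|S|,) across-cell variance, NaN when undefined
    m_per_cell: np.ndarray  # (|S|, T) per-cell means, NaN for excluded cells
    n_obs: np.ndarray    # (|S|, T) observed-site counts per cell


def window_targets(profiles: list[MethylationProfile], chrom: str, pos: int,
                   scales: tuple[int, ...] = DEFAULT_SCALES,
                   min_cells: int = 2) -> WindowStats:
    """Exact mean/variance targets for windows centred on ``pos``."""
    profiles = sorted(profiles, key=lambda p: p.cell_id)
    T = len(profiles)
    S = len(scales)
    m_ct = np.full((S, T), np.nan)
    n_obs = np.zeros((S, T), dtype=np.int64)
    for t, prof in enumerate(profiles):
        positions = prof.positions.get(chrom)
        if positions is None or len(positions) == 0:
            continue
        states = prof.states[chrom]
        for si, s in enumerate(scales):
            half = s // 2
            lo = np.searchsorted(positions, pos - half, side="left")
            hi = np.searchsorted(positions, pos + half, side="right")
            if hi > lo:
                m_ct[si, t] = float(states[lo:hi].mean())
                n_obs[si, t] = hi - lo
    m = np.full(S, np.nan)
    v = np.full(S, np.nan)
    for si in range(S):
        inc = ~np.isnan(m_ct[si])
        if inc.sum() >= min_cells:
            vals = m_ct[si, inc]
            m[si] = vals.mean()
            v[si] = float(((vals - vals.mean()) ** 2).mean())
    return WindowStats(tuple(scales), m, v, m_ct, n_obs)


def targets_matrix(profiles: list[MethylationProfile],
                   sites: list[tuple[str, int]],
                   scales: tuple[int, ...] = DEFAULT_SCALES
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stacked (N, |S|) mean and variance targets plus a defined-mask."""
    N, S = len(sites), len(scales)
    m = np.full((N, S), np.nan)
    v = np.full((N, S), np.nan)
    for i, (chrom, pos) in enumerate(sites):
        ws = window_targets(profiles, chrom, pos, scales)
        m[i], v[i] = ws.m, ws.v
    mask = (~np.isnan(m)) & (~np.isnan(v))
    return m, v, mask


# -- losses ---------------------------------------------------------------

def mse_loss(m_hat: np.ndarray, v_hat: np.ndarray, m: np.ndarray,
             v: np.ndarray, mask: np.ndarray,
             l2_lambda: float = 0.0, params: dict[str, Param] | None = None,
             l2_squared: bool = True) -> float:
    """Summed squared error over defined (site, scale) targets, plus L2."""
    se = ((m - m_hat) ** 2 + (v - v_hat) ** 2) * mask
    total = float(np.nansum(se))
    if l2_lambda > 0 and params is not None:
        total += l2_lambda * float(l2_penalty_t(params, l2_squared).data)
    return total


def _mse_t(out: Tensor, m: np.ndarray, v: np.ndarray, mask: np.ndarray) -> Tensor:
    S = m.shape[1]
    m_hat, v_hat = out[:, :S], out[:, S:]
    msk = Tensor(mask.astype(np.float64))
    m0 = np.nan_to_num(m)
    v0 = np.nan_to_num(v)
    dm = m_hat - Tensor(m0)
    dv = v_hat - Tensor(v0)
    return ad.tsum(msk * (dm * dm + dv * dv))


# -- the variance network -------------------------------------------------

class VarNet(Module):
    """DNA-module body with a 2·|S| sigmoid head (mean and variance per scale)."""

    def __init__(self, dna_net, scales: tuple[int, ...],
                 rng: np.random.Generator):
        self.dna = copy.deepcopy(dna_net)
        # re-namespace copied parameters so files stay unambiguous
        for p in self.dna.params().values():
            p.name = "var_" + p.name
        self.scales = tuple(scales)
        self.head = Dense(rng, self.dna.cfg.fc_units, 2 * len(scales),
                          "var_head", activation="sigmoid")

    def forward(self, windows: Tensor, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        return self.head(self.dna.forward(windows, training=training, rng=rng))

    def predict(self, windows: np.ndarray, batch_size: int = 512
                ) -> tuple[np.ndarray, np.ndarray]:
        S = len(self.scales)
        out = np.empty((len(windows), 2 * S))
        for lo in range(0, len(windows), batch_size):
            out[lo:lo + batch_size] = self.forward(
                Tensor(windows[lo:lo + batch_size])).data
        return out[:, :S], out[:, S:]


def finetune_varnet(dna_net, windows: np.ndarray, m: np.ndarray,
                    v: np.ndarray, mask: np.ndarray, cfg: TrainConfig,
                    val_windows: np.ndarray | None = None,
                    val_targets: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
                    scales: tuple[int, ...] = DEFAULT_SCALES) -> VarNet:
    """Fine-tune a copy of a trained DNA module on window mean/variance.

    The first convolutional layer (the motif filters) stays bitwise frozen;
    all other copied layers and the new head are trained with Adam under
    the summed-MSE + L2 objective, with early stopping on validation loss
    when a validation set is given.
    """
    rng = np.random.default_rng(cfg.seed)
    net = VarNet(dna_net, scales, rng)
    params = net.params()
    for name, p in params.items():
        p.trainable = not name.startswith("var_dna/conv0/")
    opt = Adam(params, lr=cfg.learning_rate)
    n = len(windows)
    best_val = np.inf
    best_state = net.state_dict()
    since_improve = 0
    lr = cfg.learning_rate

    def val_loss() -> float:
        if val_windows is None or val_targets is None:
            return np.nan
        vm, vv, vmask = val_targets
        mh, vh = net.predict(val_windows)
        return mse_loss(mh, vh, vm, vv, vmask, cfg.l2_lambda, params,
                        cfg.l2_squared)

    for epoch in range(cfg.max_epochs):
        opt.lr = lr
        order = rng.permutation(n)
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            opt.zero_grad()
            out = net.forward(Tensor(windows[idx]), training=True, rng=rng)
            loss = _mse_t(out, m[idx], v[idx], mask[idx])
            if cfg.l2_lambda > 0:
                loss = loss + Tensor(cfg.l2_lambda) * l2_penalty_t(
                    params, cfg.l2_squared)
            loss.backward()
            opt.step()
        vl = val_loss()
        if np.isnan(vl):
            continue
        if vl < best_val:
            best_val, best_state, since_improve = vl, net.state_dict(), 0
        else:
            since_improve += 1
            if since_improve >= cfg.early_stop_patience_epochs:
                break
        lr *= cfg.lr_decay_per_epoch
    if val_windows is not None:
        net.load_state_dict(best_state)
    return net


# -- motif classification by variance vs mean association -----------------

def variance_mean_classification(activity: np.ndarray, m_hat: np.ndarray,
                                 v_hat: np.ndarray,
                                 threshold: float = 0.25
                                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                            list[list[str]]]:
    """Label filters as variance- or mean-associated per scale.

    r^v_fs = cor_n(ā_nf, v̂_ns), r^m_fs likewise for m̂; the difference
    r^d_fs = |r^v_fs| − |r^m_fs| classifies a filter as variance-associated
    (> threshold), mean-associated (< −threshold) or neither; degenerate
    correlations give "undetermined".
    """
    n, F = activity.shape
    S = m_hat.shape[1]
    if n < 3:
        raise ValueError("need at least 3 sites")
    r_v = np.full((F, S), np.nan)
    r_m = np.full((F, S), np.nan)
    for f in range(F):
        af = activity[:, f]
        if af.std() == 0.0:
            continue
        for s in range(S):
            if v_hat[:, s].std() > 0.0:
                r_v[f, s] = stats.pearsonr(af, v_hat[:, s]).statistic
            if m_hat[:, s].std() > 0.0:
                r_m[f, s] = stats.pearsonr(af, m_hat[:, s]).statistic
    r_d = np.abs(r_v) - np.abs(r_m)
    labels: list[list[str]] = []
    for f in range(F):
        row = []
        for s in range(S):
            if np.isnan(r_d[f, s]):
                row.append("undetermined")
            elif r_d[f, s] > threshold:
                row.append("variance")
            elif r_d[f, s] < -threshold:
                row.append("mean")
            else:
                row.append("neither")
        labels.append(row)
    return r_v, r_m, r_d, labels
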