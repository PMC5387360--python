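"""Gradient-based single-nucleotide mutation effects on predicted methylation.

For a site n with one-hot window s and mean predicted methylation across
cells ŷ_n = mean_t ŷ_nt, the effect of substituting nucleotide d at window
position i is the first-order gradient with wild-type entries zeroed:

    e_nid = ∂ŷ_n/∂s_nid · (1 − s_nid)

The per-position score is e_ni = max_d |e_nid| and the dataset-level
profile e_i averages e_ni over sites — a distance-to-CpG saliency profile.
An exhaustive single-substitution re-prediction oracle is provided to bound
the first-order approximation error in tests.

The gradient is taken at the wild-type input; no re-normalisation of the
one-hot rows is applied for hypothetical substitutions.  Mutations hitting
the central CpG dinucleotide itself are still scored but flagged, since
they destroy the site whose methylation is being predicted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .data_io import BASES
from .joint_training import ModelBase


@dataclass
class EffectScores:
    e_nid: np.ndarray           # (L_win, 4): gradient effects, ATGC order
    e_ni: np.ndarray            # (L_win,): max_d |e_nid|
    center_cpg_flag: np.ndarray  # (L_win,) bool: position is the target C or G


def mutation_effects(model: ModelBase, window: np.ndarray,
                     contexts: np.ndarray | None = None) -> EffectScores:
    """Effect scores for one site from a single backward pass.

    ``window``: (L_win, 4) one-hot; ``contexts``: (T, 4K) for models with a
    CpG module (held fixed — only sequence effects are scored).
    """
    if not model.uses_dna:
        raise ValueError("model has no DNA module; sequence effects undefined")
    w = Tensor(window[None], requires_grad=True)
    c = Tensor(contexts[None]) if (model.uses_cpg and contexts is not None) else None
    if model.uses_cpg and c is None:
        raise ValueError("joint model requires neighbour contexts")
    y_hat = model.forward(w, c)          # (1, T)
    y_mean = ad.tmean(y_hat)             # scalar: mean over cells
    y_mean.backward()
    grad = w.grad[0]                     # (L_win, 4)
    e_nid = grad * (1.0 - window)
    e_ni = np.abs(e_nid).max(axis=1)
    L = window.shape[0]
    center = (L - 1) // 2
    flag = np.zeros(L, dtype=bool)
    flag[center] = True
    if center + 1 < L:
        flag[center + 1] = True
    return EffectScores(e_nid=e_nid, e_ni=e_ni, center_cpg_flag=flag)


def aggregate_effects(per_site: list[EffectScores]) -> np.ndarray:
    """Position-wise mean of e_ni over sites: the e_i saliency profile."""
    if not per_site:
        raise ValueError("need at least one site")
    return np.mean([e.e_ni for e in per_site], axis=0)


def substitution_oracle(model: ModelBase, window: np.ndarray,
                        contexts: np.ndarray | None, position: int,
                        base: str) -> float:
    """Exact Δŷ from re-predicting with one base substituted.

    Returns ŷ_mut − ŷ_wt of the cell-mean prediction.  Substituting the
    wild-type base by itself gives exactly 0.
    """
    d = BASES.index(base)
    mut = window.copy()
    mut[position] = 0.0
    mut[position, d] = 1.0
    c = Tensor(contexts[None]) if (model.uses_cpg and contexts is not None) else None
    y_wt = float(model.forward(Tensor(window[None]), c).data.mean())
    y_mut = float(model.forward(Tensor(mut[None]), c).data.mean())
    return y_mut - y_wt


def distance_matched_sampler(variant_positions: np.ndarray, center: int,
                             rng: np.random.Generator, L_win: int,
                             n_per_variant: int = 1) -> np.ndarray:
    """Random window positions distance-matched to given variants.

    For each variant, samples positions at the same absolute distance from
    the central CpG (left or right, uniformly), for use as a matched null
    when scoring user-supplied variant tables.
    """
    out = []
    for pos in variant_positions:
        dist = abs(int(pos) - center)
        for _ in range(n_per_variant):
            side = 1 if rng.random() < 0.5 else -1
            cand = center + side * dist
            if not 0 <= cand < L_win:
                cand = center - side * dist
            out.append(cand)
    return np.array(out, dtype=np.int64)


def effects_table(model: ModelBase, data, site_indices: np.ndarray
                  ) -> tuple[list[EffectScores], np.ndarray]:
    """Per-site effect scores and their aggregate profile for chosen sites."""
    scores = [
        mutation_effects(model, data.windows[i],
                         data.contexts[i] if model.uses_cpg else None)
        for i in site_indices
    ]
    return scores, aggregate_effects(scores)
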