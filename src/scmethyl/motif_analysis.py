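"""Interpretation of first-layer convolutional filters as sequence motifs.

Filters are summarised four ways: (i) seqlets — subsequences whose
activation exceeds half the filter's global maximum — aligned into a
position weight matrix; (ii) activity — a centre-weighted mean activation
per sequence window, a motif occurrence score; (iii) influence — the
correlation of activity with predicted methylation across sites;
(iv) structure — PCA and pairwise correlations of the activity matrix, and
correlation with per-site conservation scores.  PWMs are emitted in MEME
minimal format for downstream motif-database matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

PWM_ALPHABET = "ACGT"  # MEME column order
_PWM_INDEX = {b: i for i, b in enumerate(PWM_ALPHABET)}


@dataclass
class FilterMotif:
    filter_index: int
    pwm: np.ndarray | None      # (L, 4) column-stochastic, ACGT order
    n_seqlets: int
    seqlets: list[str] = field(default_factory=list)


@dataclass
class MotifReport:
    motifs: list[FilterMotif]
    activity: np.ndarray | None = None        # (n_sites, n_filters)
    influence_per_cell: np.ndarray | None = None  # (n_filters, n_cells)
    influence: np.ndarray | None = None       # (n_filters,)
    pca_components: np.ndarray | None = None
    pca_explained_variance: np.ndarray | None = None
    correlation_matrix: np.ndarray | None = None
    conservation_corr: np.ndarray | None = None


# -- seqlets and PWMs -----------------------------------------------------

def extract_seqlets(activations: np.ndarray, sequences: list[str], L: int,
                    threshold_frac: float = 0.5) -> list[str]:
    """Subsequences of length L wherever activation exceeds the threshold.

    ``activations``: (n_sequences, W_out) for one filter under a valid scan,
    so position i maps to sequence[i : i+L].  The threshold is
    ``threshold_frac`` times the global maximum activation; a filter that
    never activates (max = 0) yields no seqlets.
    """
    a = np.asarray(activations)
    peak = float(a.max()) if a.size else 0.0
    if peak <= 0.0:
        return []
    thr = threshold_frac * peak
    seqlets = []
    # threshold_frac = 1.0 keeps only argmax positions (>= at the peak)
    hits = np.argwhere(a >= thr if threshold_frac >= 1.0 else a > thr)
    for n, i in hits:
        if i + L <= len(sequences[n]):
            seqlets.append(sequences[n][i:i + L])
    return seqlets


def pwm_from_seqlets(seqlets: list[str], L: int,
                     pseudocount: float = 1.0) -> np.ndarray | None:
    """Column-stochastic PWM from aligned seqlets, +1 pseudocount per base."""
    if not seqlets:
        return None
    counts = np.full((L, 4), pseudocount, dtype=np.float64)
    for s in seqlets:
        for i, ch in enumerate(s[:L]):
            j = _PWM_INDEX.get(ch)
            if j is not None:
                counts[i, j] += 1.0
    return counts / counts.sum(axis=1, keepdims=True)


def build_filter_motifs(first_layer_activations: np.ndarray,
                        sequences: list[str], L: int,
                        threshold_frac: float = 0.5) -> list[FilterMotif]:
    """Seqlet PWMs for every filter from (B, W_out, F) activations."""
    n_filters = first_layer_activations.shape[2]
    motifs = []
    for f in range(n_filters):
        seqlets = extract_seqlets(first_layer_activations[:, :, f],
                                  sequences, L, threshold_frac)
        if not seqlets:
            warnings.warn(f"filter {f} never activates; no seqlets")
        motifs.append(FilterMotif(f, pwm_from_seqlets(seqlets, L),
                                  len(seqlets), seqlets))
    return motifs


# -- activity and influence ----------------------------------------------

def activity_weights(width: int) -> np.ndarray:
    """Normalised triangular weights over window positions.

    With 1-based position index i = 1..width and centre c = (width+1)/2,
    raw weight 1 − |i − c|/c decays linearly from the centre and stays
    positive at the edges; weights are normalised to sum to one, so uniform
    activations are a fixed point of the weighted mean.
    """
    i = np.arange(1, width + 1, dtype=np.float64)
    c = (width + 1) / 2.0
    raw = 1.0 - np.abs(i - c) / c
    return raw / raw.sum()


def filter_activity(activations: np.ndarray) -> np.ndarray:
    """Centre-weighted mean activity per sequence and filter.

    ``activations``: (B, W_out, F) ReLU first-layer activations;
    returns (B, F).
    """
    lam = activity_weights(activations.shape[1])
    return np.tensordot(activations, lam, axes=([1], [0]))


def filter_influence(activity: np.ndarray, y_hat: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of each filter's activity with predictions.

    ``activity``: (n_sites, F); ``y_hat``: (n_sites, T).  Returns per-cell
    correlations r_ft (F, T) and their mean over cells r_f (F,).  Degenerate
    (zero-variance) pairs give NaN with a warning.
    """
    n, F = activity.shape
    T = y_hat.shape[1]
    if n < 3:
        raise ValueError("need at least 3 sites")
    r_ft = np.full((F, T), np.nan)
    degenerate = False
    for f in range(F):
        af = activity[:, f]
        if af.std() == 0.0:
            degenerate = True
            continue
        for t in range(T):
            yt = y_hat[:, t]
            if yt.std() == 0.0:
                degenerate = True
                continue
            r_ft[f, t] = stats.pearsonr(af, yt).statistic
    if degenerate:
        warnings.warn("zero-variance activity or prediction; influence missing")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r_f = np.nanmean(r_ft, axis=1)
    return r_ft, r_f


def motif_cooccurrence(activity: np.ndarray, n_components: int | None = None
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """PCA and pairwise correlations of the site × filter activity matrix.

    Columns are centred before PCA; components are ordered by explained
    variance.  Returns (scores, loadings, explained_variance, corr_matrix).
    """
    n, F = activity.shape
    if F < 2 or n < 3:
        raise ValueError("need >= 2 filters and >= 3 sites")
    k = min(n_components or min(n, F), min(n, F))
    pca = PCA(n_components=k)
    scores = pca.fit_transform(activity)  # centres columns internally
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(activity, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    return scores, pca.components_, pca.explained_variance_, corr


def conservation_correlation(activity: np.ndarray,
                             site_scores: np.ndarray) -> np.ndarray:
    """Pearson correlation of each filter's activity with conservation.

    ``site_scores``: per-site mean conservation over the sequence window;
    NaN entries (unscored sites) are dropped.  Constant scores give NaN.
    """
    keep = ~np.isnan(site_scores)
    if keep.sum() < 3:
        warnings.warn("too few scored sites; conservation correlation missing")
        return np.full(activity.shape[1], np.nan)
    s = site_scores[keep]
    out = np.full(activity.shape[1], np.nan)
    if s.std() == 0.0:
        warnings.warn("constant conservation scores; correlation missing")
        return out
    for f in range(activity.shape[1]):
        af = activity[keep, f]
        if af.std() > 0.0:
            out[f] = stats.pearsonr(af, s).statistic
    return out


def read_conservation_track(path) -> dict[str, dict[int, float]]:
    """Read a per-base conservation track: TSV of (chrom, 1-based pos, score).

    Gzip-transparent; returns chrom → {pos: score}.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     compression="infer",
                     names=["chrom", "pos", "score"])
    out: dict[str, dict[int, float]] = {}
    for chrom, grp in df.groupby("chrom"):
        out[str(chrom)] = dict(zip(grp["pos"].astype(int),
                                   grp["score"].astype(float)))
    return out


def site_conservation(track: dict[str, dict[int, float]],
                      sites: list[tuple[str, int]], L_win: int) -> np.ndarray:
    """Mean conservation over each site's sequence window (NaN if unscored)."""
    half = (L_win - 1) // 2
    out = np.full(len(sites), np.nan)
    for i, (chrom, pos) in enumerate(sites):
        scores = track.get(chrom)
        if not scores:
            continue
        vals = [scores[p] for p in range(pos - half, pos + half + 1)
                if p in scores]
        if vals:
            out[i] = float(np.mean(vals))
    return out


# -- PWM comparison (planted-motif recovery) ------------------------------

def pwm_best_correlation(pwm_a: np.ndarray, pwm_b: np.ndarray,
                         min_overlap: int = 4) -> float:
    """Best column-wise Pearson correlation over all offset alignments."""
    best = -1.0
    La, Lb = len(pwm_a), len(pwm_b)
    for offset in range(-(Lb - min_overlap), La - min_overlap + 1):
        lo_a, hi_a = max(0, offset), min(La, offset + Lb)
        if hi_a - lo_a < min_overlap:
            continue
        a = pwm_a[lo_a:hi_a].ravel()
        b = pwm_b[lo_a - offset:hi_a - offset].ravel()
        if a.std() == 0.0 or b.std() == 0.0:
            continue
        best = max(best, float(stats.pearsonr(a, b).statistic))
    return best


# -- MEME minimal format --------------------------------------------------

def write_meme(motifs: list[FilterMotif], path,
               background: tuple[float, float, float, float] = (0.25,) * 4
               ) -> None:
    """Write PWMs in MEME minimal motif format (input for motif matchers)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: +\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A %.5f C %.5f G %.5f T %.5f\n\n" % background)
        for m in motifs:
            if m.pwm is None:
                continue
            fh.write(f"MOTIF filter_{m.filter_index}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {len(m.pwm)} "
                     f"nsites= {m.n_seqlets} E= 0\n")
            for row in m.pwm:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_meme(path) -> dict[str, np.ndarray]:
    """Re-parse a MEME minimal file back into name → PWM (round-trip check)."""
    pwms: dict[str, np.ndarray] = {}
    name, rows, expect = None, [], 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                name = line.split()[1]
            elif line.startswith("letter-probability"):
                expect = int(line.split("w=")[1].split()[0])
                rows = []
            elif name is not None and expect and line:
                rows.append([float(v) for v in line.split()])
                if len(rows) == expect:
                    pwms[name] = np.array(rows)
                    name, rows, expect = None, [], 0
    return pwms
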