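"""Comparison methods: window averaging, cross-cell averaging, random forests.

WinAvg imputes a site from the same cell's observed neighbours inside a
3001-bp window; CpGAvg from the other cells' observed states at the same
position; both fall back to the cell's genome-wide mean methylation rate
when no information is available.  The RF baseline trains one off-the-shelf
random forest per cell on neighbour-context features (4K) plus k-mer counts
of the sequence window (4^k), matching the neural model's inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .data_io import MethylationProfile, extract_neighbors, window_sequence

KMER_BASES = "ACGT"  # lexicographic feature order, independent of one-hot order


def win_avg(profile: MethylationProfile, chrom: str, pos: int,
            W: int = 3001) -> float:
    """Mean observed state of other sites within the W-bp window around pos.

    The target site's own state (k = 0) is excluded.  Falls back to the
    cell's genome-wide mean when no neighbour is observed in the window.
    """
    if W % 2 != 1:
        raise ValueError("W must be odd")
    half = W // 2  # |k| < W/2
    positions = profile.positions.get(chrom)
    if positions is not None and len(positions):
        lo = np.searchsorted(positions, pos - half, side="left")
        hi = np.searchsorted(positions, pos + half, side="right")
        states = profile.states[chrom][lo:hi]
        sel = positions[lo:hi] != pos
        if sel.any():
            return float(states[sel].mean())
    return profile.genome_wide_mean()


def cpg_avg(profiles: list[MethylationProfile], chrom: str, pos: int,
            cell_t: int) -> float:
    """Mean state at pos over the other cells with an observation there.

    Falls back to cell t's genome-wide mean methylation rate when no other
    cell observed the site (always, in a single-cell dataset).
    """
    if not profiles:
        raise ValueError("need at least one cell")
    states = [p.state_at(chrom, pos) for i, p in enumerate(profiles) if i != cell_t]
    states = [s for s in states if s is not None]
    if states:
        return float(np.mean(states))
    return profiles[cell_t].genome_wide_mean()


def kmer_counts(sequence: str, k: int = 4) -> np.ndarray:
    """Counts of each of the 4^k k-mers (lexicographic ACGT order).

    Window positions containing a non-ACGT character contribute nothing.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    index = {b: i for i, b in enumerate(KMER_BASES)}
    counts = np.zeros(4 ** k, dtype=np.int64)
    codes = np.fromiter((index.get(ch, -1) for ch in sequence), dtype=np.int64,
                        count=len(sequence))
    if len(codes) < k:
        return counts
    wins = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (wins >= 0).all(axis=1)
    if valid.any():
        powers = 4 ** np.arange(k - 1, -1, -1)
        np.add.at(counts, wins[valid] @ powers, 1)
    return counts


def kmer_feature_names(k: int = 4) -> list[str]:
    return ["".join(p) for p in product(KMER_BASES, repeat=k)]


@dataclass
class RfDataset:
    """Per-cell feature table for the random-forest baseline."""

    cell_id: str
    features: np.ndarray       # (n_sites, n_features)
    labels: np.ndarray         # (n_sites,)
    sites: list[tuple[str, int]]
    feature_names: list[str]


def rf_feature_names(K: int, k: int, variant: str = "full") -> list[str]:
    neigh = []
    for side, order in (("L", range(K, 0, -1)), ("R", range(1, K + 1))):
        for i in order:
            neigh += [f"nbr_{side}{i}_state", f"nbr_{side}{i}_dist"]
    kmers = [f"kmer_{s}" for s in kmer_feature_names(k)]
    if variant == "cpg":
        return neigh
    if variant == "dna":
        return kmers
    return neigh + kmers


def build_rf_dataset(profiles: list[MethylationProfile], genome: dict[str, str],
                     sites: list[tuple[str, int]], K: int = 25, k: int = 4,
                     L_win: int = 1001, max_dist: float = 25000.0,
                     variant: str = "full",
                     extra_features: dict[tuple[str, int], np.ndarray] | None = None,
                     ) -> list[RfDataset]:
    """One feature table per cell over that cell's observed sites.

    ``variant``: "full" (neighbour + k-mer blocks), "cpg" (neighbours only)
    or "dna" (k-mers only).  ``extra_features`` may add per-site columns
    (e.g. binary annotation overlaps) shared across cells.
    """
    if variant not in ("full", "cpg", "dna"):
        raise ValueError(f"unknown RF variant {variant!r}")
    kmer_cache: dict[tuple[str, int], np.ndarray] = {}
    names = rf_feature_names(K, k, variant)
    if extra_features:
        n_extra = len(next(iter(extra_features.values())))
        names = names + [f"extra_{i}" for i in range(n_extra)]
    tables = []
    for prof in sorted(profiles, key=lambda p: p.cell_id):
        rows, labels, kept = [], [], []
        for chrom, pos in sites:
            state = prof.state_at(chrom, pos)
            if state is None:
                continue
            blocks = []
            if variant in ("full", "cpg"):
                blocks.append(extract_neighbors(prof, chrom, pos, K, max_dist))
            if variant in ("full", "dna"):
                key = (chrom, pos)
                if key not in kmer_cache:
                    kmer_cache[key] = kmer_counts(
                        window_sequence(genome, chrom, pos, L_win), k)
                blocks.append(kmer_cache[key].astype(np.float64))
            if extra_features:
                blocks.append(np.asarray(extra_features[(chrom, pos)],
                                         dtype=np.float64))
            rows.append(np.concatenate(blocks))
            labels.append(state)
            kept.append((chrom, pos))
        if not rows:
            warnings.warn(f"cell {prof.cell_id}: no observed sites, skipped")
            continue
        tables.append(RfDataset(prof.cell_id, np.vstack(rows),
                                np.array(labels, dtype=np.int64), kept, names))
    return tables


def train_rf(table: RfDataset, n_trees: int = 100, max_depth: int | None = None,
             seed: int = 0) -> RandomForestClassifier:
    """Fit the per-cell random forest (standard scikit-learn implementation)."""
    clf = RandomForestClassifier(n_estimators=n_trees, max_depth=max_depth,
                                 random_state=seed, n_jobs=1)
    clf.fit(table.features, table.labels)
    return clf


def rf_predict_proba(clf: RandomForestClassifier, features: np.ndarray
                     ) -> np.ndarray:
    """P(methylated) per row, robust to single-class training labels."""
    proba = clf.predict_proba(features)
    if proba.shape[1] == 1:
        return np.full(len(features), float(clf.classes_[0]))
    return proba[:, list(clf.classes_).index(1)]
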