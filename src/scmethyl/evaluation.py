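"""Holdout evaluation: AUC, accuracy, F1 and MCC over observed site–cell pairs.

Metrics are computed on the pooled set of observed pairs (a per-cell
breakdown is also available); probabilities are thresholded at 0.5 with
ties going to the unmethylated class.  Metrics that are undefined on a
one-class truth vector (AUC, MCC, and F1 without positives) are reported as
missing (None) rather than imputed.

Context stratification converts 1-based CpG positions against 0-based
half-open BED intervals; a site belongs to a context iff its CpG
dinucleotide (positions pos and pos+1) overlaps any interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (accuracy_score, f1_score, matthews_corrcoef,
                             roc_auc_score)

from .data_io import FormatError, MethylationProfile
from .joint_training import PredictionSet


def binarize_predictions(y_hat: np.ndarray) -> np.ndarray:
    """1 iff probability strictly greater than 0.5 (0.5 itself rounds to 0)."""
    return (np.asarray(y_hat) > 0.5).astype(np.int64)


@dataclass
class EvalReport:
    rows: list[dict] = field(default_factory=list)

    def add(self, **kwargs) -> None:
        self.rows.append(kwargs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def compute_metrics(pred: PredictionSet, model: str = "model",
                    context: str = "All") -> dict:
    """Metric row over the observed pairs of a prediction set."""
    obs = pred.o.astype(bool)
    y = pred.y[obs].astype(np.int64)
    p = pred.y_hat[obs]
    row = {"model": model, "context": context,
           "n_sites": len(pred.sites), "n_observed": int(obs.sum()),
           "auc": None, "accuracy": None, "f1": None, "mcc": None}
    if len(y) == 0:
        warnings.warn("no observed pairs; all metrics missing")
        return row
    yb = binarize_predictions(p)
    row["accuracy"] = float(accuracy_score(y, yb))
    if len(np.unique(y)) < 2:
        warnings.warn("single-class truth; AUC and MCC undefined")
    else:
        row["auc"] = float(roc_auc_score(y, p))  # midrank tie handling
        row["mcc"] = float(matthews_corrcoef(y, yb))
    if y.sum() > 0 or yb.sum() > 0:
        row["f1"] = float(f1_score(y, yb, zero_division=0.0))
    return row


def per_cell_metrics(pred: PredictionSet, cell_ids: list[str],
                     model: str = "model") -> pd.DataFrame:
    """The same metrics computed separately within each cell."""
    rows = []
    for t, cell in enumerate(cell_ids):
        sub = PredictionSet(pred.sites, pred.y_hat[:, t:t + 1],
                            pred.y[:, t:t + 1], pred.o[:, t:t + 1])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            row = compute_metrics(sub, model=model)
        row["cell_id"] = cell
        rows.append(row)
    return pd.DataFrame(rows)


# -- stratification -------------------------------------------------------

def read_bed(path) -> dict[str, np.ndarray]:
    """Minimal BED reader: chrom → (n, 2) array of 0-based half-open intervals."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end < start:
                raise FormatError(f"{path}:{lineno}: end before start")
            intervals.setdefault(parts[0], []).append((start, end))
    return {c: np.array(sorted(iv), dtype=np.int64)
            for c, iv in intervals.items()}


def site_in_intervals(chrom: str, pos: int,
                      intervals: dict[str, np.ndarray]) -> bool:
    """Does the CpG dinucleotide [pos, pos+1] (1-based) overlap any interval?

    A 1-based dinucleotide covers 0-based positions pos−1 and pos, so it
    overlaps a half-open interval [start, end) iff start ≤ pos and end > pos − 1.
    """
    iv = intervals.get(chrom)
    if iv is None:
        return False
    return bool(np.any((iv[:, 0] <= pos) & (iv[:, 1] > pos - 1)))


def stratify(sites: list[tuple[str, int]],
             bed_annotations: dict[str, dict[str, np.ndarray]]
             ) -> dict[str, np.ndarray]:
    """Map context name → index array of member sites.

    ``bed_annotations``: context name → interval dict from :func:`read_bed`.
    Contexts may overlap; an "All" context covering every site is always
    present.
    """
    out = {"All": np.arange(len(sites), dtype=np.int64)}
    for name, intervals in bed_annotations.items():
        idx = [i for i, (c, p) in enumerate(sites)
               if site_in_intervals(c, p, intervals)]
        out[name] = np.array(idx, dtype=np.int64)
    return out


def coverage_strata(profiles: list[MethylationProfile],
                    sites: list[tuple[str, int]],
                    bin_edges: list[int]) -> dict[str, np.ndarray]:
    """Group sites by the number of cells observing them.

    ``bin_edges`` are ascending; bin i holds counts in
    [edges[i], edges[i+1]) — inclusive-left, exclusive-right — except the
    last bin, which also includes its right edge.
    """
    counts = np.array(
        [sum(p.state_at(c, pos) is not None for p in profiles)
         for c, pos in sites], dtype=np.int64)
    out: dict[str, np.ndarray] = {}
    for i in range(len(bin_edges) - 1):
        lo, hi = bin_edges[i], bin_edges[i + 1]
        last = i == len(bin_edges) - 2
        sel = (counts >= lo) & ((counts <= hi) if last else (counts < hi))
        out[f"[{lo},{hi}{']' if last else ')'}"] = np.flatnonzero(sel)
    return out


def evaluate_stratified(pred: PredictionSet, strata: dict[str, np.ndarray],
                        model: str = "model") -> EvalReport:
    report = EvalReport()
    for name, idx in strata.items():
        sub = PredictionSet([pred.sites[i] for i in idx], pred.y_hat[idx],
                            pred.y[idx], pred.o[idx])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report.add(**compute_metrics(sub, model=model, context=name))
    return report
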