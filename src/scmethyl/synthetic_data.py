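"""Synthetic genomes and sparse multi-cell methylomes with known ground truth.

The generator emulates the statistical structure the model exploits, at
desk scale:

* a random genome whose nucleotide frequencies are tuned to a target CpG
  density, with instances of planted position weight matrices embedded at
  recorded positions;
* a per-site methylation propensity on the logit scale: a base level, plus
  planted-motif match scores times effect weights, plus a spatially
  correlated Gaussian field (Ornstein–Uhlenbeck, i.e. exponential kernel —
  exact sequential simulation at the irregular CpG positions);
* cross-cell structure from mixing a shared latent field with independent
  per-cell fields (mixing weight = correlation knob), binary states drawn
  per cell, and observations masked independently at a per-cell coverage
  fraction in the single-cell bisulfite range.

Everything is driven by one seed and regenerates bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.special import expit

from .data_io import MethylationProfile, write_genome, write_profile

# A strong CpG-containing planted motif (consensus TGACGTCA).  The central
# CG guarantees a target site inside every instance, and the balanced G+C
# content keeps near-matches rare in the A/T-rich background that the CpG
# density tuning produces.
DEFAULT_PWM = np.array([
    [0.02, 0.02, 0.02, 0.94],  # T     (columns A, C, G, T)
    [0.02, 0.02, 0.94, 0.02],  # G
    [0.94, 0.02, 0.02, 0.02],  # A
    [0.02, 0.94, 0.02, 0.02],  # C
    [0.02, 0.02, 0.94, 0.02],  # G
    [0.02, 0.02, 0.02, 0.94],  # T
    [0.02, 0.94, 0.02, 0.02],  # C
    [0.94, 0.02, 0.02, 0.02],  # A
])

PWM_BASES = "ACGT"


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset."""

    n_chroms: int = 2
    chrom_length: int = 50_000
    n_cells: int = 5
    cpg_density: float = 0.02
    planted_pwms: list[tuple[np.ndarray, float]] = field(default_factory=list)
    n_motif_instances_per_chrom: int = 0
    motif_radius: int = 100          # bp within which a match affects a site
    base_logit: float = 0.0
    gp_sigma: float = 0.5            # spatial field std-dev on the logit scale
    gp_length_scale: float = 1000.0  # bp, exponential kernel
    cross_cell_corr: float = 0.5     # shared-field mixing weight rho
    coverage: float | tuple[float, float] = (0.05, 0.40)
    emit_counts: bool = False        # write the 4-column read-count dialect
    seed: int = 0

    def __post_init__(self):
        cov = self.coverage
        lo, hi = (cov, cov) if np.isscalar(cov) else cov
        if not (0.0 < lo <= 1.0 and 0.0 < hi <= 1.0):
            raise ValueError("coverage must lie in (0, 1]")
        if not (0.0 <= self.cross_cell_corr <= 1.0):
            raise ValueError("cross_cell_corr must lie in [0, 1]")


@dataclass
class SimulatedData:
    genome: dict[str, str]
    cpg_sites: list[tuple[str, int]]          # 1-based C positions
    motif_positions: dict[str, list[int]]     # planted instance starts (1-based)
    profiles: list[MethylationProfile]
    truth_states: np.ndarray                  # (N, T) full binary truth
    truth_probs: np.ndarray                   # (N, T) per-cell propensities
    config: SimConfig


def _sample_background(rng: np.random.Generator, length: int,
                       cpg_density: float) -> np.ndarray:
    """IID bases with C/G frequency tuned so P(CpG) ≈ cpg_density."""
    p_cg = np.sqrt(max(cpg_density, 0.0))
    p = np.array([(1 - 2 * p_cg) / 2, (1 - 2 * p_cg) / 2, p_cg, p_cg])
    return rng.choice(np.frombuffer(b"ATGC", dtype="S1"), size=length, p=p)


def _sample_pwm_instance(rng: np.random.Generator, pwm: np.ndarray) -> bytes:
    cols = [PWM_BASES[rng.choice(4, p=row / row.sum())] for row in pwm]
    return "".join(cols).encode()


def simulate_genome(cfg: SimConfig, rng: np.random.Generator | None = None
                    ) -> tuple[dict[str, str], list[tuple[str, int]],
                               dict[str, list[int]]]:
    """Genome, CpG index and planted-motif positions for a SimConfig."""
    rng = rng or np.random.default_rng(cfg.seed)
    genome: dict[str, str] = {}
    motif_positions: dict[str, list[int]] = {}
    for ci in range(cfg.n_chroms):
        chrom = str(ci + 1)
        arr = _sample_background(rng, cfg.chrom_length, cfg.cpg_density)
        starts: list[int] = []
        if cfg.planted_pwms and cfg.n_motif_instances_per_chrom > 0:
            for _ in range(cfg.n_motif_instances_per_chrom):
                pwm, _w = cfg.planted_pwms[rng.integers(len(cfg.planted_pwms))]
                L = len(pwm)
                start0 = int(rng.integers(0, cfg.chrom_length - L))
                inst = _sample_pwm_instance(rng, pwm)
                arr[start0:start0 + L] = np.frombuffer(inst, dtype="S1")
                starts.append(start0 + 1)
        genome[chrom] = b"".join(arr).decode()
        motif_positions[chrom] = sorted(starts)
    cpg_sites = [(chrom, i + 1)
                 for chrom in sorted(genome)
                 for i in range(len(genome[chrom]) - 1)
                 if genome[chrom][i:i + 2] == "CG"]
    return genome, cpg_sites, motif_positions


def _pwm_match_scores(seq: str, pwm: np.ndarray) -> np.ndarray:
    """Per-start log-odds of the PWM vs uniform background, rescaled to [0,1].

    1 corresponds to the consensus sequence, 0 to a score at or below the
    uniform-background expectation.
    """
    L = len(pwm)
    logp = np.log(pwm)
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate(PWM_BASES):
        lut[ord(b)] = i
    idx = lut[codes]
    n = len(seq) - L + 1
    if n <= 0:
        return np.zeros(0)
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for l in range(L):
        col = idx[l:l + n]
        ok = col >= 0
        valid &= ok
        scores[ok] += logp[l, col[ok]]
    max_score = float(np.log(pwm.max(axis=1)).sum())
    null = L * np.log(0.25)
    out = (scores - null) / (max_score - null)
    out[~valid] = 0.0
    return np.clip(out, 0.0, 1.0)


def _motif_effect(genome: dict[str, str], cpg_sites: list[tuple[str, int]],
                  cfg: SimConfig, match_threshold: float = 0.8) -> np.ndarray:
    """Logit contribution per site: Σ weights · thresholded best match nearby."""
    effect = np.zeros(len(cpg_sites))
    if not cfg.planted_pwms:
        return effect
    by_chrom: dict[str, list[int]] = {}
    for i, (c, _p) in enumerate(cpg_sites):
        by_chrom.setdefault(c, []).append(i)
    for chrom, site_idx in by_chrom.items():
        seq = genome[chrom]
        pos = np.array([cpg_sites[i][1] for i in site_idx])
        for pwm, weight in cfg.planted_pwms:
            scores = _pwm_match_scores(seq, pwm)
            if len(scores) == 0:
                continue
            rescaled = np.maximum(0.0, (scores - match_threshold)
                                  / (1.0 - match_threshold))
            hit_starts = np.flatnonzero(rescaled > 0)
            if len(hit_starts) == 0:
                continue
            hit_pos = hit_starts + 1  # 1-based instance start
            best = np.zeros(len(pos))
            for hs, hp in zip(rescaled[hit_starts], hit_pos):
                near = np.abs(pos - hp) <= cfg.motif_radius
                best[near] = np.maximum(best[near], hs)
            effect[site_idx] += weight * best
    return effect


def _ou_field(rng: np.random.Generator, positions: np.ndarray,
              length_scale: float) -> np.ndarray:
    """Unit-variance Ornstein–Uhlenbeck sample at irregular positions."""
    n = len(positions)
    z = np.empty(n)
    z[0] = rng.standard_normal()
    for i in range(1, n):
        phi = np.exp(-(positions[i] - positions[i - 1]) / length_scale)
        z[i] = phi * z[i - 1] + np.sqrt(1.0 - phi * phi) * rng.standard_normal()
    return z


def simulate_methylomes(genome: dict[str, str],
                        cpg_sites: list[tuple[str, int]],
                        cfg: SimConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[list[MethylationProfile], np.ndarray,
                                   np.ndarray]:
    """Per-cell sparse profiles plus the dense truth state/propensity matrices."""
    rng = rng or np.random.default_rng(cfg.seed + 1)
    N, T = len(cpg_sites), cfg.n_cells
    motif = _motif_effect(genome, cpg_sites, cfg)
    probs = np.empty((N, T))
    by_chrom: dict[str, list[int]] = {}
    for i, (c, _p) in enumerate(cpg_sites):
        by_chrom.setdefault(c, []).append(i)
    for chrom in sorted(by_chrom):
        idx = np.array(by_chrom[chrom])
        pos = np.array([cpg_sites[i][1] for i in idx], dtype=np.float64)
        shared = _ou_field(rng, pos, cfg.gp_length_scale)
        rho = cfg.cross_cell_corr
        for t in range(T):
            own = _ou_field(rng, pos, cfg.gp_length_scale)
            z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own
            probs[idx, t] = expit(cfg.base_logit + motif[idx] + cfg.gp_sigma * z)
    truth = (rng.random((N, T)) < probs).astype(np.uint8)

    cov = cfg.coverage
    cov_lo, cov_hi = (cov, cov) if np.isscalar(cov) else cov
    profiles = []
    for t in range(T):
        frac = float(rng.uniform(cov_lo, cov_hi)) if cov_lo != cov_hi else cov_lo
        observed = rng.random(N) < frac
        prof = MethylationProfile(cell_id=f"cell{t:02d}")
        for chrom in sorted(by_chrom):
            idx = np.array(by_chrom[chrom])
            sel = idx[observed[idx]]
            if len(sel) == 0:
                continue
            prof.positions[chrom] = np.array([cpg_sites[i][1] for i in sel],
                                             dtype=np.int64)
            prof.states[chrom] = truth[sel, t].astype(np.uint8)
            if cfg.emit_counts:
                total = 4 + rng.poisson(4, size=len(sel))
                min_meth = total // 2 + 1  # strict read-count majority
                meth = np.where(
                    truth[sel, t] == 1,
                    min_meth + rng.integers(0, total - min_meth + 1,
                                            size=len(sel)),
                    rng.integers(0, total // 2 + 1, size=len(sel)))
                prof.meth[chrom] = meth.astype(np.int64)
                prof.total[chrom] = total.astype(np.int64)
        profiles.append(prof)
    return profiles, truth, probs


def simulate(cfg: SimConfig) -> SimulatedData:
    """Full simulation from one seed: genome, CpG index, profiles, truth."""
    rng = np.random.default_rng(cfg.seed)
    genome, cpg_sites, motif_positions = simulate_genome(cfg, rng)
    profiles, truth, probs = simulate_methylomes(genome, cpg_sites, cfg, rng)
    return SimulatedData(genome, cpg_sites, motif_positions, profiles,
                         truth, probs, cfg)


def write_dataset(data: SimulatedData, out_dir) -> dict:
    """Write FASTA + per-cell TSVs + truth matrix + manifest; returns manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_genome(data.genome, out / "genome.fa")
    for prof in data.profiles:
        write_profile(prof, out / f"{prof.cell_id}.tsv")
    np.savetxt(out / "truth_states.tsv", data.truth_states, fmt="%d",
               delimiter="\t")
    cfg_dict = asdict(data.config)
    cfg_dict["planted_pwms"] = [
        {"pwm": np.asarray(p).tolist(), "weight": w}
        for p, w in data.config.planted_pwms]
    manifest = {
        "config": cfg_dict,
        "n_cpg_sites": len(data.cpg_sites),
        "n_cells": len(data.profiles),
        "cell_ids": [p.cell_id for p in data.profiles],
        "motif_positions": data.motif_positions,
        "cpg_sites": [[c, int(p)] for c, p in data.cpg_sites],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


# -- canned fixtures ------------------------------------------------------

def motif_fixture_config(seed: int = 0) -> SimConfig:
    """Strong planted-motif conditions: sequence drives methylation.

    Background sites sit near 8% methylation (base logit −2.5) and sites
    within 100 bp of a planted-motif match near 92% (logit effect +5); the
    spatial field is weak so the DNA sequence is the dominant signal.
    """
    return SimConfig(n_chroms=2, chrom_length=50_000, n_cells=5,
                     cpg_density=0.02,
                     planted_pwms=[(DEFAULT_PWM.copy(), 5.0)],
                     n_motif_instances_per_chrom=80, motif_radius=100,
                     base_logit=-2.5, gp_sigma=0.5, gp_length_scale=1000.0,
                     cross_cell_corr=0.5, coverage=0.3, seed=seed)


def neighbor_fixture_config(seed: int = 0) -> SimConfig:
    """High spatial and cross-cell correlation, no sequence signal.

    A strong short-range field (sigma 3, length scale 500 bp) makes nearby
    observed states highly informative, and a 0.85 shared-field weight
    couples cells; the methylation neighbourhood is the only usable signal.
    """
    return SimConfig(n_chroms=2, chrom_length=50_000, n_cells=8,
                     cpg_density=0.02, planted_pwms=[],
                     base_logit=0.0, gp_sigma=3.0, gp_length_scale=500.0,
                     cross_cell_corr=0.85, coverage=0.3, seed=seed)


def variance_fixture_config(seed: int = 0) -> SimConfig:
    """Conditions for the mean/variance prediction experiments.

    Sequence effects here operate at window scale rather than site scale:
    planted-motif influence extends 400 bp and lifts covered regions from
    8% background methylation towards ~73%, so both the regional mean and
    the cell-to-cell variance of window means respond to motif coverage
    (binomial sampling noise and the cross-cell field are both largest at
    intermediate rates).  Low cell coupling (rho 0.3) and 8 cells give
    genuinely variable window statistics.  The fixture is larger and more
    densely observed than the site-scale ones because its regression
    targets live at 1–5 kb scale: a 100 kb chromosome offers ~100
    independent window-scale examples where 50 kb would offer too few to
    identify the regression at all.
    """
    return SimConfig(n_chroms=2, chrom_length=100_000, n_cells=8,
                     cpg_density=0.02,
                     planted_pwms=[(DEFAULT_PWM.copy(), 3.5)],
                     n_motif_instances_per_chrom=80, motif_radius=400,
                     base_logit=-2.5, gp_sigma=1.0, gp_length_scale=1000.0,
                     cross_cell_corr=0.3, coverage=0.5, seed=seed)


def fixture_suite(out_dir=None, seed: int = 0) -> dict[str, SimulatedData]:
    """Deterministic micro datasets used across the test suite.

    ``micro3``: 2 × 20 kb, 3 cells, generic conditions — fast unit tests.
    ``motif``:  the planted-motif conditions (5 cells).
    ``neighbor``: the correlation-driven conditions (8 cells).
    """
    suite = {
        "micro3": SimConfig(n_chroms=2, chrom_length=20_000, n_cells=3,
                            cpg_density=0.02, base_logit=0.0, gp_sigma=1.5,
                            gp_length_scale=800.0, cross_cell_corr=0.6,
                            coverage=0.3, seed=seed),
        "motif": motif_fixture_config(seed),
        "neighbor": neighbor_fixture_config(seed),
    }
    out = {}
    for name, cfg in suite.items():
        data = simulate(cfg)
        if out_dir is not None:
            write_dataset(data, Path(out_dir) / name)
        out[name] = data
    return out
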