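"""Input handling: genomes, per-cell CpG profiles, model input construction.

Coordinate conventions used throughout the package: positions are 1-based on
the forward strand and denote the C of the CpG dinucleotide; profiles from
both strands are assumed pre-collapsed to forward-strand C positions (the
usual CpG-report convention).

One-hot channel order is A, T, G, C; unknown bases (N, IUPAC ambiguity
codes, window overhang past a chromosome end) encode as the all-zero row so
they contribute nothing to convolutional activations.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyfaidx import Fasta

BASES = "ATGC"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

DEFAULT_TRAIN_CHROMS = {"1", "3", "5", "7", "9", "11"}
DEFAULT_TEST_CHROMS = {"2", "4", "6", "8", "10", "12"}


class InputError(Exception):
    """Missing or unusable input file."""


class FormatError(Exception):
    """Malformed file contents."""


class ConfigError(Exception):
    """Inconsistent configuration."""


# -- domain types ---------------------------------------------------------

@dataclass
class MethylationProfile:
    """Sparse per-cell map from (chromosome, position) to binary state.

    Per chromosome, positions are kept sorted; ``meth`` / ``total`` read
    counts are retained when the source file carried them.
    """

    cell_id: str
    positions: dict[str, np.ndarray] = field(default_factory=dict)
    states: dict[str, np.ndarray] = field(default_factory=dict)
    meth: dict[str, np.ndarray] = field(default_factory=dict)
    total: dict[str, np.ndarray] = field(default_factory=dict)

    def chroms(self) -> list[str]:
        return sorted(self.positions)

    def n_sites(self) -> int:
        return sum(len(p) for p in self.positions.values())

    def genome_wide_mean(self) -> float:
        """Mean observed methylation state across all sites of this cell."""
        n = self.n_sites()
        if n == 0:
            return 0.5
        return sum(float(s.sum()) for s in self.states.values()) / n

    def state_at(self, chrom: str, pos: int) -> int | None:
        if chrom not in self.positions:
            return None
        idx = np.searchsorted(self.positions[chrom], pos)
        if idx < len(self.positions[chrom]) and self.positions[chrom][idx] == pos:
            return int(self.states[chrom][idx])
        return None


@dataclass(frozen=True)
class HoldoutSplit:
    """Chromosome-level train/validation/test partition."""

    train_chroms: frozenset[str]
    val_chroms: frozenset[str]
    test_chroms: frozenset[str]


@dataclass
class SiteDataset:
    """Model-ready arrays for a list of target CpG sites.

    windows:  (N, L_win, 4) one-hot DNA, channel order ATGC
    contexts: (N, T, 4K) neighbour vectors, cell order = sorted cell_ids
    y, o:     (N, T) binary labels and observation mask
    """

    sites: list[tuple[str, int]]
    windows: np.ndarray
    contexts: np.ndarray
    y: np.ndarray
    o: np.ndarray
    cell_ids: list[str]
    L_win: int
    K: int
    max_dist: float

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def subset(self, idx: np.ndarray) -> "SiteDataset":
        return SiteDataset(
            sites=[self.sites[i] for i in idx],
            windows=self.windows[idx],
            contexts=self.contexts[idx],
            y=self.y[idx],
            o=self.o[idx],
            cell_ids=self.cell_ids,
            L_win=self.L_win,
            K=self.K,
            max_dist=self.max_dist,
        )

    def chrom_subset(self, chroms: frozenset[str] | set[str]) -> "SiteDataset":
        idx = np.array([i for i, (c, _) in enumerate(self.sites) if c in chroms],
                       dtype=np.int64)
        return self.subset(idx)


# -- genome ---------------------------------------------------------------

def read_genome(fasta_path) -> dict[str, str]:
    """Read a FASTA file into a dict of uppercased sequences."""
    import pyfaidx

    try:
        fa = Fasta(str(fasta_path), rebuild=True, build_index=True)
    except (FileNotFoundError, pyfaidx.FastaNotFoundError,
            pyfaidx.FastaIndexingError) as exc:
        raise InputError(f"genome file not found or unreadable: "
                         f"{fasta_path}") from exc
    except ValueError as exc:
        msg = str(exc)
        if "Duplicate" in msg or "duplicate" in msg:
            raise FormatError(f"duplicate chromosome names in {fasta_path}") from exc
        raise InputError(f"cannot read FASTA {fasta_path}: {exc}") from exc
    genome = {name: str(fa[name][:]).upper() for name in fa.keys()}
    if not genome:
        raise InputError(f"empty FASTA: {fasta_path}")
    return genome


def write_genome(genome: dict[str, str], fasta_path, width: int = 80) -> None:
    with open(fasta_path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# -- methylation profiles -------------------------------------------------

def binarize(meth_reads: int, total_reads: int) -> int:
    """1 iff strictly more methylated than unmethylated reads; ties are 0."""
    return 1 if meth_reads > total_reads - meth_reads else 0


def read_profile(tsv_path, min_reads: int = 4, cell_id: str | None = None
                 ) -> MethylationProfile:
    """Read a per-cell profile TSV (gzip-transparent).

    Two dialects by column count: 4 columns (chrom, pos, meth_reads,
    total_reads) — sites under ``min_reads`` total coverage are dropped and
    states are called by read-count majority with ties unmethylated; or
    3 columns (chrom, pos, state) — states pass through, ``min_reads`` is
    ignored.
    """
    if min_reads < 1:
        raise ConfigError("min_reads must be >= 1")
    try:
        df = pd.read_csv(tsv_path, sep="\t", header=None, comment="#",
                         compression="infer")
    except FileNotFoundError as exc:
        raise InputError(f"profile not found: {tsv_path}") from exc
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"empty profile: {tsv_path}") from exc
    if cell_id is None:
        cell_id = _strip_suffixes(str(tsv_path))
    prof = MethylationProfile(cell_id=cell_id)
    if df.shape[1] == 4:
        df.columns = ["chrom", "pos", "meth", "total"]
        meth = df["meth"].to_numpy(dtype=np.int64)
        total = df["total"].to_numpy(dtype=np.int64)
        if np.any(meth > total):
            raise FormatError(f"{tsv_path}: meth_reads exceeds total_reads")
        if np.any(meth < 0) or np.any(total < 0):
            raise FormatError(f"{tsv_path}: negative read counts")
        keep = total >= min_reads
        df = df.loc[keep].copy()
        df["state"] = (df["meth"].to_numpy() * 2 > df["total"].to_numpy()).astype(np.uint8)
        has_counts = True
    elif df.shape[1] == 3:
        df.columns = ["chrom", "pos", "state"]
        states = df["state"].to_numpy()
        if not np.isin(states, [0, 1]).all():
            raise FormatError(f"{tsv_path}: states must be 0 or 1")
        has_counts = False
    else:
        raise FormatError(f"{tsv_path}: expected 3 or 4 columns, got {df.shape[1]}")

    for chrom, grp in df.groupby("chrom", sort=True):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy(dtype=np.int64)
        if len(np.unique(pos)) != len(pos):
            raise FormatError(f"{tsv_path}: duplicate positions on {chrom}")
        c = str(chrom)
        prof.positions[c] = pos
        prof.states[c] = grp["state"].to_numpy(dtype=np.uint8)
        if has_counts:
            prof.meth[c] = grp["meth"].to_numpy(dtype=np.int64)
            prof.total[c] = grp["total"].to_numpy(dtype=np.int64)
    return prof


def write_profile(profile: MethylationProfile, tsv_path) -> None:
    """Write the binary (chrom, pos, state) dialect; gzip if path ends .gz."""
    opener = gzip.open if str(tsv_path).endswith(".gz") else open
    with opener(tsv_path, "wt") as fh:
        for chrom in profile.chroms():
            for pos, state in zip(profile.positions[chrom], profile.states[chrom]):
                fh.write(f"{chrom}\t{pos}\t{state}\n")


def _strip_suffixes(path: str) -> str:
    name = path.rsplit("/", 1)[-1]
    for suf in (".gz", ".tsv", ".txt"):
        if name.endswith(suf):
            name = name[: -len(suf)]
    return name


# -- model inputs ---------------------------------------------------------

def one_hot(sequence: str) -> np.ndarray:
    """Encode DNA as an (L, 4) binary matrix, channel order ATGC.

    Any character outside ACGT maps to the all-zero row.
    """
    out = np.zeros((len(sequence), 4), dtype=np.float64)
    for i, base in enumerate(sequence):
        j = BASE_INDEX.get(base)
        if j is not None:
            out[i, j] = 1.0
    return out


def extract_window(genome: dict[str, str], chrom: str, pos: int,
                   L_win: int = 1001) -> np.ndarray:
    """One-hot window of odd length ``L_win`` centred on ``pos`` (1-based).

    Positions beyond the chromosome ends become all-zero (unknown) rows, so
    the output always has exactly ``L_win`` rows.
    """
    if L_win % 2 != 1:
        raise ConfigError("L_win must be odd")
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} not in genome")
    seq = genome[chrom]
    half = (L_win - 1) // 2
    lo = pos - half  # 1-based inclusive
    hi = pos + half
    left_pad = max(0, 1 - lo)
    right_pad = max(0, hi - len(seq))
    sub = seq[max(lo, 1) - 1: min(hi, len(seq))]
    mat = np.zeros((L_win, 4), dtype=np.float64)
    mat[left_pad:left_pad + len(sub)] = one_hot(sub)
    return mat


def window_sequence(genome: dict[str, str], chrom: str, pos: int,
                    L_win: int = 1001, pad_char: str = "N") -> str:
    """The raw sequence of the window, end-padded with ``pad_char``."""
    seq = genome[chrom]
    half = (L_win - 1) // 2
    lo, hi = pos - half, pos + half
    sub = seq[max(lo, 1) - 1: min(hi, len(seq))]
    return pad_char * max(0, 1 - lo) + sub + pad_char * max(0, hi - len(seq))


PAD_STATE = 0.5
PAD_DIST = 1.0


def extract_neighbors(profile: MethylationProfile, chrom: str, pos: int,
                      K: int = 25, max_dist: float = 25000.0) -> np.ndarray:
    """Neighbour-context vector of length 4K for one cell and target site.

    Layout: K left neighbours ordered farthest→nearest, then K right
    neighbours nearest→farthest, each contributing (state, relative
    distance).  Distances are clipped at ``max_dist`` and divided by it.
    Missing neighbours (sparse coverage, chromosome edge) are padded with
    state 0.5 and relative distance 1.0; the target site itself is excluded.
    """
    if K <= 0:
        raise ConfigError("K must be positive")
    out = np.empty(4 * K, dtype=np.float64)
    out[0::2] = PAD_STATE
    out[1::2] = PAD_DIST
    positions = profile.positions.get(chrom)
    if positions is None or len(positions) == 0:
        return out
    states = profile.states[chrom]
    idx = np.searchsorted(positions, pos)
    # left neighbours: positions[idx-1], idx-2, ... are nearest-first
    left_n = min(K, idx)
    for j in range(left_n):  # j = 0 is nearest
        p = positions[idx - 1 - j]
        slot = K - 1 - j  # nearest-last within the left block
        out[2 * slot] = states[idx - 1 - j]
        out[2 * slot + 1] = min(pos - p, max_dist) / max_dist
    # right neighbours: skip the target site itself if observed
    ridx = idx
    if ridx < len(positions) and positions[ridx] == pos:
        ridx += 1
    right_n = min(K, len(positions) - ridx)
    for j in range(right_n):
        p = positions[ridx + j]
        slot = K + j  # nearest-first within the right block
        out[2 * slot] = states[ridx + j]
        out[2 * slot + 1] = min(p - pos, max_dist) / max_dist
    return out


def compute_max_dist(profiles: list[MethylationProfile], K: int = 25,
                     chroms: set[str] | None = None) -> float:
    """Largest neighbour distance the context builder would collect.

    The maximum, over cells and chromosomes, of the distance from any
    observed site to its K-th nearest observed neighbour; stored once with
    the model and reused at prediction time.
    """
    best = 1.0
    for prof in profiles:
        for chrom, pos in prof.positions.items():
            if chroms is not None and chrom not in chroms:
                continue
            for k in range(1, min(K, len(pos) - 1) + 1):
                gaps = pos[k:] - pos[:-k]
                if len(gaps):
                    best = max(best, float(gaps.max()))
    return best


# -- holdout split --------------------------------------------------------

def _core_name(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def make_split(chromosomes, train=None, val=None, test=None) -> HoldoutSplit:
    """Chromosome holdout split.

    Defaults follow the odd/even convention: odd chromosomes 1–11 train,
    even chromosomes 2–12 test, everything else validation.  User-supplied
    sets override; any chromosome in none of them falls to validation.
    """
    chromosomes = list(chromosomes)
    if train is not None or test is not None:
        train = frozenset(train or ())
        test = frozenset(test or ())
        val = frozenset(val) if val is not None else frozenset(
            c for c in chromosomes if c not in train and c not in test)
        if train & test or train & val or test & val:
            raise ConfigError("split sets must be pairwise disjoint")
        return HoldoutSplit(train, val, test)
    tr, te, va = set(), set(), set()
    for c in chromosomes:
        core = _core_name(c)
        if core in DEFAULT_TRAIN_CHROMS:
            tr.add(c)
        elif core in DEFAULT_TEST_CHROMS:
            te.add(c)
        else:
            va.add(c)
    return HoldoutSplit(frozenset(tr), frozenset(va), frozenset(te))


# -- dataset assembly -----------------------------------------------------

def collect_sites(profiles: list[MethylationProfile]) -> list[tuple[str, int]]:
    """Union of observed positions across cells, sorted by (chrom, pos)."""
    per_chrom: dict[str, set[int]] = {}
    for prof in profiles:
        for chrom, pos in prof.positions.items():
            per_chrom.setdefault(chrom, set()).update(int(p) for p in pos)
    return [(c, p) for c in sorted(per_chrom) for p in sorted(per_chrom[c])]


def build_dataset(genome: dict[str, str], profiles: list[MethylationProfile],
                  sites: list[tuple[str, int]] | None = None,
                  L_win: int = 1001, K: int = 25,
                  max_dist: float | None = None) -> SiteDataset:
    """Assemble windows, neighbour contexts, labels and masks for sites.

    Cells are ordered by sorted ``cell_id`` (the fixed scan order of the
    recurrent module).  When ``max_dist`` is None it is computed from the
    given profiles via :func:`compute_max_dist`.
    """
    profiles = sorted(profiles, key=lambda p: p.cell_id)
    if sites is None:
        sites = collect_sites(profiles)
    if max_dist is None:
        max_dist = compute_max_dist(profiles, K=K)
    N, T = len(sites), len(profiles)
    # full-chromosome one-hot, sliced per site
    encoded = {c: one_hot(genome[c]) for c in {s[0] for s in sites}}
    half = (L_win - 1) // 2
    windows = np.zeros((N, L_win, 4), dtype=np.float64)
    contexts = np.zeros((N, T, 4 * K), dtype=np.float64)
    y = np.zeros((N, T), dtype=np.float64)
    o = np.zeros((N, T), dtype=np.float64)
    for i, (chrom, pos) in enumerate(sites):
        enc = encoded[chrom]
        lo, hi = pos - half, pos + half
        left_pad = max(0, 1 - lo)
        sub = enc[max(lo, 1) - 1: min(hi, len(enc))]
        windows[i, left_pad:left_pad + len(sub)] = sub
        for t, prof in enumerate(profiles):
            contexts[i, t] = extract_neighbors(prof, chrom, pos, K, max_dist)
            state = prof.state_at(chrom, pos)
            if state is not None:
                y[i, t] = state
                o[i, t] = 1.0
    return SiteDataset(sites=sites, windows=windows, contexts=contexts, y=y,
                       o=o, cell_ids=[p.cell_id for p in profiles],
                       L_win=L_win, K=K, max_dist=float(max_dist))
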