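"""Binding-energy matrices, PWM estimation, and motif-distortion metrics.

An additive binding-energy matrix (BEM) assigns each L-mer the sum of
per-position mismatch energies; matrices are normalised so every column
minimum is 0, making the consensus sequence's energy exactly 0 (higher
values = weaker sites).  PWMs are log2-odds count matrices with background
pseudocounts:

    W_ij = log2((N_ij + b_i) / (b_i (N + 1)))

where N_ij counts base i at position j over N aligned sites and b_i is the
background frequency of base i.  Motif distortion between two PWMs is the
per-position Kullback-Leibler divergence of their pseudocounted probability
columns, in bits; the symmetrised form (P vs Q averaged both ways) is the
default.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

from .rng import substream

__all__ = [
    "ALPHABET",
    "EnergyMatrix",
    "PWM",
    "DinucModel",
    "read_energy_matrix",
    "toy_matrix",
    "default_dinuc_model",
    "sequence_energy",
    "nearest_energy_sequence",
    "estimate_pwm",
    "kl_distance",
    "dinucleotide_sequences",
    "infer_motif_from_simulation",
    "single_mutation_energy_quantiles",
]

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_ENUM_MAX_L = 12  # exhaustive 4^L enumeration cap


@dataclass(frozen=True)
class EnergyMatrix:
    """4 x L additive mismatch-energy model (rows A, C, G, T; kBT units)."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != 4:
            raise ValueError(f"energy matrix must be 4 x L, got {v.shape}")
        object.__setattr__(self, "values", v - v.min(axis=0, keepdims=True))

    @property
    def length(self) -> int:
        return self.values.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in np.argmin(self.values, axis=0))

    def max_energy(self) -> float:
        return float(self.values.max(axis=0).sum())


def read_energy_matrix(path) -> EnergyMatrix:
    """Load a whitespace-delimited 4 x L energy matrix (rows A, C, G, T).

    An optional leading label in each row (as in BEEML-style files) is
    tolerated.  Columns are shifted so each minimum is 0.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith(">"):
                continue
            fields = line.split()
            if fields[0].rstrip(":").upper() in ("A", "C", "G", "T"):
                fields = fields[1:]
            try:
                rows.append([float(x) for x in fields])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed matrix row at line {lineno}") from exc
    if len(rows) != 4:
        raise ValueError(f"{path}: expected 4 rows (A, C, G, T), found {len(rows)}")
    return EnergyMatrix(np.array(rows))


def toy_matrix() -> EnergyMatrix:
    """The packaged synthetic 4 x 10 energy matrix (not a measured TF)."""
    ref = resources.files("chipsim") / "data" / "toy_energy_matrix.txt"
    with resources.as_file(ref) as path:
        return read_energy_matrix(path)


def sequence_energy(seq: str, matrix: EnergyMatrix) -> float:
    """Additive energy of an L-mer under the matrix."""
    if len(seq) != matrix.length:
        raise ValueError(f"sequence length {len(seq)} != matrix length {matrix.length}")
    try:
        idx = [_BASE_INDEX[b] for b in seq.upper()]
    except KeyError as exc:
        raise ValueError(f"invalid base in sequence {seq!r}") from exc
    return float(matrix.values[idx, np.arange(matrix.length)].sum())


@lru_cache(maxsize=8)
def _enumerated(matrix_key: tuple) -> tuple[np.ndarray, np.ndarray]:
    """(sorted energies, sequence codes) for all 4^L sequences, L <= 12."""
    values = np.array(matrix_key).reshape(4, -1)
    L = values.shape[1]
    energies = np.zeros(1)
    for j in range(L):
        energies = (energies[:, None] + values[:, j][None, :]).ravel()
    order = np.argsort(energies, kind="stable")
    return energies[order], order.astype(np.int64)


def _code_to_seq(code: int, L: int) -> str:
    # base-4 digits, most significant = position 0
    out = []
    for j in range(L - 1, -1, -1):
        out.append(ALPHABET[(code >> (2 * j)) & 3])
    return "".join(out)


def nearest_energy_sequence(
    target: float, matrix: EnergyMatrix, rng=None
) -> tuple[str, float]:
    """Sequence whose energy is closest to ``target``.

    Exhaustive over all 4^L sequences for L <= 12 (the enumeration is
    cached per matrix); greedy coordinate refinement with random restarts
    for longer matrices.  Ties resolve to the lower-energy sequence, then
    to the enumeration order, so the result is deterministic.
    """
    if target < 0:
        raise ValueError("target energy must be >= 0")
    L = matrix.length
    if L <= _ENUM_MAX_L:
        energies, codes = _enumerated(tuple(matrix.values.ravel()))
        i = int(np.searchsorted(energies, target))
        cands = [c for c in (i - 1, i) if 0 <= c < energies.size]
        best = min(cands, key=lambda c: (abs(energies[c] - target), energies[c]))
        return _code_to_seq(int(codes[best]), L), float(energies[best])
    return _greedy_nearest(target, matrix, rng)


def _greedy_nearest(target: float, matrix: EnergyMatrix, rng) -> tuple[str, float]:
    if not isinstance(rng, np.random.Generator):
        rng = substream(0 if rng is None else rng, "nearest-seq")
    best_seq, best_e = None, None
    for _ in range(8):
        idx = rng.integers(0, 4, size=matrix.length)
        e = float(matrix.values[idx, np.arange(matrix.length)].sum())
        improved = True
        while improved:
            improved = False
            for j in range(matrix.length):
                col = matrix.values[:, j]
                cur = col[idx[j]]
                for b in range(4):
                    cand = e - cur + col[b]
                    if abs(cand - target) < abs(e - target):
                        idx[j], e = b, cand
                        cur = col[b]
                        improved = True
        if best_e is None or abs(e - target) < abs(best_e - target):
            best_seq, best_e = idx.copy(), e
    seq = "".join(ALPHABET[i] for i in best_seq)
    return seq, float(best_e)


# ---------------------------------------------------------------------------
# PWMs


@dataclass(frozen=True)
class PWM:
    """Log2-odds weight matrix with its pseudocounted probability matrix."""

    weights: np.ndarray  # 4 x L
    probs: np.ndarray  # 4 x L, columns sum to 1
    background: np.ndarray  # length 4
    n_sequences: int = 0

    @property
    def length(self) -> int:
        return self.weights.shape[1]

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.weights, index=list(ALPHABET))
        df.to_csv(path, sep="\t")

    def to_meme(self, path, name: str = "motif_1") -> None:
        """Write MEME minimal motif format (probability matrix)."""
        with open(path, "w") as fh:
            fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
            bg = " ".join(f"{b} {f:.5f}" for b, f in zip(ALPHABET, self.background))
            fh.write(f"Background letter frequencies\n{bg}\n\n")
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {self.length} "
                f"nsites= {max(self.n_sequences, 1)}\n"
            )
            for col in self.probs.T:
                fh.write(" ".join(f"{x:.6f}" for x in col) + "\n")


def estimate_pwm(sequences, background=None) -> PWM:
    """Count PWM with background pseudocounts from aligned equal-length sites."""
    sequences = list(sequences)
    if not sequences:
        raise ValueError("no sequences to estimate a PWM from")
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        raise ValueError("sequences must have equal length")
    b = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    if b.shape != (4,) or np.any(b <= 0) or abs(b.sum() - 1) > 1e-9:
        raise ValueError("background must be 4 positive frequencies summing to 1")
    counts = np.zeros((4, L))
    for s in sequences:
        for j, base in enumerate(s.upper()):
            counts[_BASE_INDEX[base], j] += 1
    n = len(sequences)
    probs = (counts + b[:, None]) / (n + 1)
    weights = np.log2((counts + b[:, None]) / (b[:, None] * (n + 1)))
    return PWM(weights=weights, probs=probs, background=b, n_sequences=n)


def kl_distance(pwm_a: PWM, pwm_b: PWM, direction: str = "symmetric") -> float:
    """Mean per-position K-L divergence between two PWMs, in bits.

    ``direction``: 'symmetric' (default, 0.5 * [D(P||Q) + D(Q||P)]),
    'forward' (D(P||Q)), or 'reverse'.
    """
    if pwm_a.length != pwm_b.length:
        raise ValueError("PWM lengths differ")
    p, q = pwm_a.probs, pwm_b.probs
    d_pq = np.sum(p * np.log2(p / q), axis=0)
    d_qp = np.sum(q * np.log2(q / p), axis=0)
    per_pos = {"symmetric": 0.5 * (d_pq + d_qp), "forward": d_pq, "reverse": d_qp}[direction]
    return float(per_pos.mean())


# ---------------------------------------------------------------------------
# dinucleotide background model


@dataclass(frozen=True)
class DinucModel:
    """First-order Markov chain over bases (initial distribution + 4x4
    transitions, rows summing to 1)."""

    initial: np.ndarray
    transitions: np.ndarray

    def __post_init__(self):
        ini = np.asarray(self.initial, dtype=float)
        tr = np.asarray(self.transitions, dtype=float)
        if ini.shape != (4,) or tr.shape != (4, 4):
            raise ValueError("need a length-4 initial distribution and 4x4 transitions")
        if abs(ini.sum() - 1) > 1e-9 or np.any(np.abs(tr.sum(axis=1) - 1) > 1e-9):
            raise ValueError("distributions must sum to 1")
        object.__setattr__(self, "initial", ini)
        object.__setattr__(self, "transitions", tr)


def default_dinuc_model() -> DinucModel:
    """A synthetic AT-rich background model (yeast-like composition).

    This is a constructed fixture, not fitted to any real genome.
    """
    initial = np.array([0.31, 0.19, 0.19, 0.31])
    transitions = np.array(
        [
            [0.36, 0.17, 0.19, 0.28],
            [0.32, 0.19, 0.15, 0.34],
            [0.29, 0.21, 0.19, 0.31],
            [0.26, 0.19, 0.21, 0.34],
        ]
    )
    return DinucModel(initial, transitions)


def dinucleotide_sequences(model: DinucModel, length: int, n: int, rng=0) -> list[str]:
    """Generate ``n`` Markov-chain sequences of a given length."""
    if not isinstance(rng, np.random.Generator):
        rng = substream(rng, "dinuc")
    # cumulative transition rows for vectorised inverse-CDF stepping
    cum_tr = np.cumsum(model.transitions, axis=1)
    cum_ini = np.cumsum(model.initial)
    states = np.searchsorted(cum_ini, rng.random(n))
    cols = [states]
    for _ in range(length - 1):
        u = rng.random(n)
        states = np.array([np.searchsorted(cum_tr[s], x) for s, x in zip(states, u)])
        cols.append(states)
    mat = np.stack(cols, axis=1)
    lut = np.array(list(ALPHABET))
    return ["".join(row) for row in lut[mat]]


# ---------------------------------------------------------------------------
# motif inference from a simulated experiment


def infer_motif_from_simulation(
    locus_table: pd.DataFrame,
    site_sequences,
    top_fraction: float = 0.10,
    background=None,
) -> PWM:
    """PWM from the site sequences of the top-ranked loci by read-count ratio.

    ``site_sequences[i]`` is the sequence attributed to locus i: the target
    TF's planted site at directly/cooperatively bound loci, or the
    background-generated sequence at indirectly bound loci (what an
    experimenter would recover there).  Loci with undefined (NaN) ratios
    are excluded before ranking; ties break by locus order (stable sort).
    """
    ratios = np.asarray(locus_table["ratio"], dtype=float)
    site_sequences = list(site_sequences)
    if len(site_sequences) != ratios.size:
        raise ValueError("site_sequences length must match the locus table")
    defined = np.flatnonzero(np.isfinite(ratios))
    k = int(round(top_fraction * ratios.size))
    if k < 1 or defined.size < k:
        raise ValueError(
            f"need at least {k} defined ratios, have {defined.size}"
        )
    order = defined[np.argsort(-ratios[defined], kind="stable")]
    top = order[:k]
    return estimate_pwm([site_sequences[i] for i in top], background)


def single_mutation_energy_quantiles(
    matrices,
    baseline_energies=(2, 3, 4, 5, 6),
    quantiles=(0.25, 0.5),
) -> pd.DataFrame:
    """Distribution of |energy change| over all single-base mutants.

    For each matrix and each baseline energy: take the sequence nearest to
    that energy and enumerate its 3L single mutants, recording |delta E|.
    Differences are pooled across matrices; the table reports the requested
    quantiles per baseline energy.
    """
    records = {e: [] for e in baseline_energies}
    for matrix in matrices:
        L = matrix.length
        pos_idx = np.arange(L)
        for e0 in baseline_energies:
            seq, achieved = nearest_energy_sequence(float(e0), matrix)
            idx = np.array([_BASE_INDEX[b] for b in seq])
            base_contrib = matrix.values[idx, pos_idx]
            for j in range(L):
                for b in range(4):
                    if b == idx[j]:
                        continue
                    delta = matrix.values[b, j] - base_contrib[j]
                    records[e0].append(abs(delta))
    rows = []
    for e0 in baseline_energies:
        diffs = np.array(records[e0])
        rows.append(
            {"baseline_energy": e0, "n_mutants": diffs.size}
            | {f"q{q}": float(np.quantile(diffs, q)) for q in quantiles}
        )
    return pd.DataFrame(rows)
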