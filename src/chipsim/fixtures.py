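"""Synthetic inputs: toy genomes, interval sets with planted sites, and
DNase-like density tracks.

Everything here is generated from a seed, so the full pipeline can run with
no downloads.  The genome is i.i.d. random sequence at a requested GC
content — a deliberate stand-in for a real genome, adequate for exercising
read synthesis and motif recovery but not for composition-sensitive
analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .rng import substream

__all__ = [
    "make_genome",
    "write_fasta",
    "make_intervals_with_sites",
    "make_density_track",
]

_BASES = np.array(list("ACGT"))


def make_genome(length: int, gc: float = 0.4, rng=0, name: str = "chrS") -> tuple[str, str]:
    """Random genome sequence at the requested GC content.

    Returns (name, sequence).  ``rng`` is a Generator or an integer seed.
    """
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = substream(rng, "genome")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(rng.choice(_BASES, size=length, p=p))
    return name, seq


def write_fasta(path, contigs: dict[str, str], width: int = 70) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


@dataclass
class IntervalSet:
    """Planted-site intervals plus the genome carrying them."""

    chrom: str
    genome: str
    table: pd.DataFrame  # chrom, start, end, summit, energy, site_seq

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def make_intervals_with_sites(
    genome: tuple[str, str],
    n: int,
    matrix,
    energy_law,
    rng=0,
    interval_length: tuple[int, int] = (300, 500),
) -> IntervalSet:
    """Carve non-overlapping intervals and plant a binding site at each summit.

    For every interval an energy is drawn from ``energy_law``, the sequence
    whose matrix energy is nearest to that draw is planted starting at the
    summit, and the truth (locus, achieved energy, site sequence, summit)
    is recorded.  The achieved energy replaces the drawn one, mirroring how
    site sequences quantise the energy scale.
    """
    from .motif import nearest_energy_sequence

    if not isinstance(rng, np.random.Generator):
        rng = substream(rng, "intervals")
    chrom, seq = genome
    glen = len(seq)
    lo, hi = interval_length
    if n * hi > glen:
        raise ValueError("genome too short for the requested intervals")

    # evenly partition, then jitter interval bounds inside each slot
    slot = glen // n
    if slot < hi:
        raise ValueError("genome too short for non-overlapping intervals of this length")
    site_len = matrix.length
    starts, ends, summits, energies, sites = [], [], [], [], []
    seq_list = list(seq)
    targets = energy_law.sample(n, rng)
    for i in range(n):
        ilen = int(rng.integers(lo, hi + 1))
        b = i * slot + int(rng.integers(0, slot - ilen + 1))
        e = b + ilen
        s = int(rng.integers(b + site_len, e - site_len))
        site, achieved = nearest_energy_sequence(float(targets[i]), matrix)
        seq_list[s : s + site_len] = list(site)
        starts.append(b)
        ends.append(e)
        summits.append(s)
        energies.append(achieved)
        sites.append(site)

    table = pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": ends,
            "summit": summits,
            "energy": energies,
            "site_seq": sites,
        }
    )
    return IntervalSet(chrom=chrom, genome="".join(seq_list), table=table)


def make_density_track(n: int, rng=0, scale: float = 1.0, shape: float = 1.0) -> np.ndarray:
    """Long-tailed nonnegative per-locus read densities.

    Emulates windowed DNase read counts: a lognormal count per 150 bp
    window divided by the window length.  ``scale = 0`` yields all-zero
    densities (downstream accessibility 0.5 everywhere).
    """
    if not isinstance(rng, np.random.Generator):
        rng = substream(rng, "density")
    if scale == 0:
        return np.zeros(n)
    counts = scale * rng.lognormal(mean=0.0, sigma=shape, size=n) * 150.0
    return counts / 150.0
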