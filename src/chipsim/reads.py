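"""FASTQ synthesis from simulated per-locus read counts.

Unique fragments at a ChIP locus start at Gaussian positions around
summit - d/2 (sd = jitter); control-sample fragments start uniformly in the
interval.  Each unique fragment's start is repeated once per sampled PCR
copy, so duplicate reads share a start position by construction and carry a
duplicate flag in the read name.  Coordinates are 0-based half-open (BED
convention); draws are rounded to integers and clamped so fragments stay on
the contig.

Single-end reads take either strand with probability 1/2: plus-strand reads
are genome[a, a+l), minus-strand reads are the reverse complement of the
final l bases of the fragment, genome[a+d-l, a+d).  Paired mode emits both
reads per fragment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .rng import substream

__all__ = [
    "GenomicInterval",
    "FragmentLayout",
    "ReadRecord",
    "sample_fragment_starts",
    "fragments_to_reads",
    "write_fastq",
    "generate_fastq",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval with a binding summit inside it."""

    chrom: str
    start: int
    end: int
    summit: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("interval end must exceed start")
        if not self.start <= self.summit < self.end:
            raise ValueError("summit must lie inside the interval")


@dataclass(frozen=True)
class FragmentLayout:
    """Fragment geometry: length d, positional jitter j, read length l."""

    fragment_length: int = 200
    jitter: float = 50.0
    read_length: int = 50
    paired: bool = False
    quality_char: str = "K"  # Phred-33 Q=42

    def __post_init__(self):
        if self.read_length > self.fragment_length:
            raise ValueError("read length must not exceed fragment length")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")


@dataclass(frozen=True)
class ReadRecord:
    name: str
    sequence: str
    quality: str
    mate: int = 0  # 0 = single-end, 1/2 = paired mates


def sample_fragment_starts(
    interval: GenomicInterval,
    layout: FragmentLayout,
    copy_numbers,
    role: str,
    rng: np.random.Generator,
    contig_length: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-read fragment start positions for one locus.

    ``copy_numbers[j]`` is the sampled read count of the j-th unique
    fragment (>= 1); its start is drawn once and repeated that many times.
    Returns (starts per read, parent index per read).
    """
    copy_numbers = np.asarray(copy_numbers, dtype=np.int64)
    if np.any(copy_numbers < 1):
        raise ValueError("copy numbers must be >= 1")
    u = copy_numbers.size
    d = layout.fragment_length
    if role == "chip":
        starts = rng.normal(interval.summit - d / 2.0, layout.jitter, size=u)
        starts = np.rint(starts).astype(np.int64)
    elif role == "input":
        # floor keeps the draw inside the half-open interval [start, end)
        starts = np.floor(
            rng.uniform(interval.start, interval.end, size=u)
        ).astype(np.int64)
    else:
        raise ValueError("role must be 'chip' or 'input'")
    starts = np.clip(starts, 0, max(contig_length - d, 0))
    parent = np.repeat(np.arange(u), copy_numbers)
    return starts[parent], parent


def fragments_to_reads(
    starts,
    layout: FragmentLayout,
    genome: str,
    rng: np.random.Generator,
    name_prefix: str = "read",
    parent_ids=None,
) -> list[ReadRecord]:
    """Turn fragment start positions into read records.

    Single-end mode flips a fair coin per fragment for the strand; paired
    mode emits a plus-strand and a minus-strand read per fragment.  The
    strand stream is drawn before sequence extraction so positions and
    strands come from independent substreams of the caller's generator.
    """
    starts = np.asarray(starts, dtype=np.int64)
    d, l = layout.fragment_length, layout.read_length
    n = starts.size
    if parent_ids is None:
        parent_ids = np.zeros(n, dtype=np.int64)
    if n and (starts.min() < 0 or starts.max() + d > len(genome)):
        bad = int(np.flatnonzero((starts < 0) | (starts + d > len(genome)))[0])
        raise ValueError(f"fragment {bad} extends beyond the contig")
    qual = layout.quality_char * l
    seen: dict[int, int] = {}
    records: list[ReadRecord] = []
    strands = rng.random(n) < 0.5  # True = minus strand (single-end only)
    for k in range(n):
        a = int(starts[k])
        p = int(parent_ids[k])
        copy_idx = seen.get(p, 0)
        seen[p] = copy_idx + 1
        dup = "dup" if copy_idx > 0 else "uniq"
        name = f"{name_prefix}:frag{p}:copy{copy_idx}:{dup}"
        plus = genome[a : a + l]
        minus = reverse_complement(genome[a + d - l : a + d])
        if layout.paired:
            records.append(ReadRecord(name, plus, qual, mate=1))
            records.append(ReadRecord(name, minus, qual, mate=2))
        else:
            seq = minus if strands[k] else plus
            records.append(ReadRecord(name, seq, qual))
    return records


def write_fastq(records, path, mate: int | None = None) -> Path:
    """Write 4-line FASTQ; ``mate`` filters paired records (1 or 2)."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            if mate is not None and rec.mate != mate:
                continue
            suffix = f"/{rec.mate}" if rec.mate else ""
            fh.write(f"@{rec.name}{suffix}\n{rec.sequence}\n+\n{rec.quality}\n")
    return path


def generate_fastq(
    result,
    intervals: pd.DataFrame,
    genome: str,
    layout: FragmentLayout,
    out_prefix,
    seed: int = 0,
) -> dict[str, Path]:
    """Emit FASTQ (plus a read-name truth table) for ChIP and input samples.

    ``result`` is an ExperimentResult whose copy-number lists supply the
    per-parent sampled read counts; ``intervals`` needs columns start, end,
    summit aligned with the locus table.
    """
    out_prefix = Path(out_prefix)
    paths: dict[str, Path] = {}
    truth_rows = []
    for role, copy_lists in (("chip", result.chip_copy_numbers),
                             ("input", result.input_copy_numbers)):
        records: list[ReadRecord] = []
        for i, copies in enumerate(copy_lists):
            if copies.size == 0:
                continue
            row = intervals.iloc[i]
            interval = GenomicInterval(
                str(row["chrom"]), int(row["start"]), int(row["end"]), int(row["summit"])
            )
            rng_pos = substream(seed, "fastq-pos", role, str(i))
            rng_strand = substream(seed, "fastq-strand", role, str(i))
            starts, parents = sample_fragment_starts(
                interval, layout, copies, role, rng_pos, len(genome)
            )
            recs = fragments_to_reads(
                starts, layout, genome, rng_strand,
                name_prefix=f"{role}:locus{i}", parent_ids=parents,
            )
            records.extend(recs)
            for rec in recs if not layout.paired else recs[::2]:
                _, locus_tag, frag_tag, _, dup = (rec.name + ":").split(":")[:5]
                truth_rows.append(
                    {"read_name": rec.name, "sample": role, "locus": i,
                     "fragment": int(frag_tag[4:]), "duplicate": dup == "dup"}
                )
        if layout.paired:
            paths[f"{role}_R1"] = write_fastq(records, f"{out_prefix}_{role}_R1.fastq", mate=1)
            paths[f"{role}_R2"] = write_fastq(records, f"{out_prefix}_{role}_R2.fastq", mate=2)
        else:
            paths[role] = write_fastq(records, f"{out_prefix}_{role}.fastq")
    truth = pd.DataFrame(truth_rows)
    truth_path = Path(f"{out_prefix}_truth.tsv")
    truth.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    return paths
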