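"""Datasets for TFBS classification: peak extension, negative sampling,
train/test splitting, and one-hot sequence encoding.

Coordinates are 0-based half-open throughout (the BED convention); peaks
are re-centred on their summit (or midpoint) and extended by a fixed flank
on each side, giving 2*flank bp windows — 500 bp with the default
flank of 250.  Negatives are random genomic windows of the same length
that avoid an exclusion set (typically the positive peaks themselves).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_ONEHOT_ROWS = {
    "A": (1.0, 0.0, 0.0, 0.0),
    "C": (0.0, 1.0, 0.0, 0.0),
    "G": (0.0, 0.0, 1.0, 0.0),
    "T": (0.0, 0.0, 0.0, 1.0),
    "N": (0.0, 0.0, 0.0, 0.0),
}

_LUT = np.zeros((256, 4), dtype=np.float32)
for _ch, _row in _ONEHOT_ROWS.items():
    _LUT[ord(_ch)] = _row
    _LUT[ord(_ch.lower())] = _row
_VALID = np.zeros(256, dtype=bool)
for _ch in "ACGTNacgtn":
    _VALID[ord(_ch)] = True


@dataclass
class GenomicInterval:
    """0-based half-open span on a chromosome, with optional summit/strand."""

    chrom: str
    start: int
    end: int
    summit: int | None = None
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValueError(f"summit {self.summit} outside [{self.start}, {self.end})")

    @property
    def center(self) -> int:
        return self.summit if self.summit is not None else (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class SequenceSample:
    id: str
    sequence: str
    label: int
    source: GenomicInterval | str = "synthetic"

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


def one_hot(sequence: str) -> np.ndarray:
    """Encode A/C/G/T as unit rows in that channel order and N as a zero row.

    Case-insensitive; any other character raises with its position.
    """
    codes = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    bad = np.flatnonzero(~_VALID[codes])
    if bad.size:
        i = int(bad[0])
        raise ValueError(f"invalid character {sequence[i]!r} at position {i}")
    return _LUT[codes]


def decode_one_hot(matrix: np.ndarray) -> str:
    """Inverse of :func:`one_hot`; zero rows decode to N."""
    matrix = np.asarray(matrix)
    idx = matrix.argmax(axis=1)
    chars = np.array(list(ALPHABET))[idx]
    chars[matrix.sum(axis=1) == 0] = "N"
    return "".join(chars)


def encode_batch(sequences) -> np.ndarray:
    """Stack one-hot encodings of equal-length sequences into (n, L, 4)."""
    seqs = list(sequences)
    if not seqs:
        raise ValueError("no sequences given")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences have mixed lengths {sorted(lengths)}")
    return np.stack([one_hot(s) for s in seqs])


def extend_peaks(
    peaks, flank: int = 250, chrom_sizes: dict[str, int] | None = None
) -> list[GenomicInterval]:
    """Re-centre each peak on its summit (or midpoint) and take +/- flank bp.

    Windows that would run past a chromosome boundary are dropped with a
    logged warning; an unknown chromosome is an error.
    """
    out = []
    dropped = 0
    for p in peaks:
        if chrom_sizes is not None and p.chrom not in chrom_sizes:
            raise KeyError(f"unknown chromosome {p.chrom!r}")
        c = p.center
        start, end = c - flank, c + flank
        size = chrom_sizes.get(p.chrom) if chrom_sizes else None
        if start < 0 or (size is not None and end > size):
            dropped += 1
            continue
        out.append(GenomicInterval(p.chrom, start, end, summit=c, strand=p.strand))
    if dropped:
        logger.warning("extend_peaks: dropped %d peak(s) extending past chromosome bounds", dropped)
    return out


def sample_negatives(
    genome: dict[str, str],
    n: int,
    length: int,
    exclusions=(),
    seed: int | None = None,
    max_tries: int | None = None,
    max_n_fraction: float = 0.1,
) -> list[GenomicInterval]:
    """Draw n random windows of the given length avoiding the exclusion set.

    A candidate is rejected if it overlaps any exclusion interval by at
    least one base or contains more than ``max_n_fraction`` N bases.
    ``genome`` maps chromosome name to sequence (any str-like supporting
    slicing, e.g. a :class:`pyfaidx.FastaRecord`).
    """
    if n < 1 or length < 1:
        raise ValueError("n and length must be positive")
    if max_tries is None:
        max_tries = 50 * n
    rng = np.random.default_rng(seed)
    trees: dict[str, IntervalTree] = {}
    for iv in exclusions:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)

    chroms = [c for c in genome if len(genome[c]) >= length]
    if not chroms:
        raise ValueError(f"no chromosome is at least {length} bp long")
    weights = np.array([len(genome[c]) - length + 1 for c in chroms], dtype=float)
    weights /= weights.sum()

    placed: list[GenomicInterval] = []
    tries = 0
    while len(placed) < n and tries < max_tries:
        tries += 1
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        start = int(rng.integers(0, len(genome[chrom]) - length + 1))
        end = start + length
        if chrom in trees and trees[chrom].overlap(start, end):
            continue
        window = str(genome[chrom][start:end]).upper()
        if window.count("N") > max_n_fraction * length:
            continue
        placed.append(GenomicInterval(chrom, start, end))
    if len(placed) < n:
        raise RuntimeError(
            f"placed only {len(placed)}/{n} negative windows within {max_tries} tries"
        )
    return placed


def split_dataset(samples, train_frac: float = 0.8, seed: int | None = None):
    """Uniform random partition into train/test; |train| = round(frac * n)."""
    if not 0 < train_frac < 1:
        raise ValueError(f"train_frac must be in (0,1), got {train_frac}")
    samples = list(samples)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    n_train = int(round(train_frac * len(samples)))
    train = [samples[i] for i in sorted(order[:n_train])]
    test = [samples[i] for i in sorted(order[n_train:])]
    return train, test


def fetch_sequences(genome, intervals, label: int) -> list[SequenceSample]:
    """Extract interval sequences from a genome mapping into labelled samples."""
    out = []
    for i, iv in enumerate(intervals):
        seq = str(genome[iv.chrom][iv.start : iv.end]).upper()
        out.append(SequenceSample(f"{iv.chrom}:{iv.start}-{iv.end}", seq, label, source=iv))
    return out


# ---- file formats -------------------------------------------------------


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6 or narrowPeak; narrowPeak column 10 (>=0) is the summit
    offset relative to start."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            strand = f[5] if len(f) > 5 and f[5] in "+-" else "."
            summit = None
            if len(f) >= 10:  # narrowPeak
                off = int(f[9])
                if off >= 0:
                    summit = start + off
            out.append(GenomicInterval(chrom, start, end, summit=summit, strand=strand))
    return out


def write_bed(intervals, path) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tregion_{i}\t0\t{iv.strand}\n")


def write_fasta(samples, path) -> None:
    with open(path, "w") as fh:
        for s in samples:
            fh.write(f">{s.id}\n{s.sequence}\n")


def read_fasta(path) -> dict[str, str]:
    """Plain FASTA into an ordered name->sequence dict (whole file in memory)."""
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            else:
                if name is None:
                    raise ValueError(f"{path}: sequence data before first header")
                seqs[name].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


def write_labels(samples, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tlabel\n")
        for s in samples:
            fh.write(f"{s.id}\t{s.label}\n")
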