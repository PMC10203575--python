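"""Synthetic benchmarks with known ground truth.

Backgrounds are i.i.d. per-base sequences with a symmetric GC split
(P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2).  Positives carry a motif instance —
either a literal k-mer or a draw from a PWM — planted by replacement at a
uniform-random or fixed offset, and every plant is recorded in a truth
table so downstream localisation can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqdata import ALPHABET, SequenceSample


@dataclass
class TruthRow:
    sample_id: str
    planted: bool
    plant_start: int | None = None
    motif_instance: str = ""


@dataclass
class SyntheticConfig:
    """Study conditions for one benchmark: 2000+2000 samples of 500 bp by default."""

    n_pos: int = 2000
    n_neg: int = 2000
    seq_length: int = 500
    gc_content: float = 0.5
    motif: object = "GCACGTGC"  # literal k-mer or PWM (probs array / tfbsnet PWM)
    plant_fraction: float = 1.0
    plant_position: object = "uniform"  # "uniform" or fixed 0-based offset
    seed: int = 0

    def __post_init__(self):
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")
        if not 0.0 <= self.plant_fraction <= 1.0:
            raise ValueError("plant_fraction must be in [0, 1]")
        if self.seq_length < _motif_width(self.motif):
            raise ValueError("seq_length must be at least the motif width")


def _motif_width(motif) -> int:
    if isinstance(motif, str):
        return len(motif)
    probs = getattr(motif, "probs", motif)
    return int(np.asarray(probs).shape[0])


def _sample_motif_instance(motif, rng: np.random.Generator) -> str:
    if isinstance(motif, str):
        return motif.upper()
    probs = np.asarray(getattr(motif, "probs", motif), dtype=float)
    return "".join(ALPHABET[rng.choice(4, p=col / col.sum())] for col in probs)


def generate_background(n: int, length: int, gc: float = 0.5, seed: int | None = None):
    """n i.i.d. sequences of the given length and expected GC content."""
    if n < 1 or length < 1:
        raise ValueError("n and length must be positive")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alph = np.array(list(ALPHABET))
    draws = rng.choice(4, size=(n, length), p=p)
    return ["".join(row) for row in alph[draws]]


def plant_motif(backgrounds, motif, fraction: float = 1.0, position_rule="uniform", seed=None):
    """Replace bases with a motif instance in round(fraction * n) sequences.

    Returns (sequences, truth_rows); sequence ids are positional indices.
    """
    backgrounds = list(backgrounds)
    width = _motif_width(motif)
    for s in backgrounds:
        if width > len(s):
            raise ValueError(f"motif width {width} exceeds sequence length {len(s)}")
    rng = np.random.default_rng(seed)
    n_plant = int(round(fraction * len(backgrounds)))
    chosen = set(rng.choice(len(backgrounds), size=n_plant, replace=False)) if n_plant else set()
    out, truth = [], []
    for i, seq in enumerate(backgrounds):
        if i in chosen:
            inst = _sample_motif_instance(motif, rng)
            if position_rule == "uniform":
                start = int(rng.integers(0, len(seq) - width + 1))
            else:
                start = int(position_rule)
                if not 0 <= start <= len(seq) - width:
                    raise ValueError(f"fixed plant position {start} out of bounds")
            out.append(seq[:start] + inst + seq[start + width :])
            truth.append(TruthRow(str(i), True, start, inst))
        else:
            out.append(seq)
    return out, truth


def make_benchmark(config: SyntheticConfig):
    """Full labelled benchmark: planted positives (label 1) + fresh negatives (label 0).

    Returns (samples, truth_rows) where truth rows use the positive sample ids.
    """
    rng = np.random.default_rng(config.seed)
    seed_bg_pos, seed_plant, seed_bg_neg = rng.integers(0, 2**31 - 1, size=3)
    pos_bg = generate_background(
        config.n_pos, config.seq_length, config.gc_content, int(seed_bg_pos)
    )
    pos_seqs, truth = plant_motif(
        pos_bg, config.motif, config.plant_fraction, config.plant_position, int(seed_plant)
    )
    neg_seqs = generate_background(
        config.n_neg, config.seq_length, config.gc_content, int(seed_bg_neg)
    )
    samples = [
        SequenceSample(f"pos_{i}", s, 1, source="synthetic") for i, s in enumerate(pos_seqs)
    ] + [SequenceSample(f"neg_{i}", s, 0, source="synthetic") for i, s in enumerate(neg_seqs)]
    # re-key truth rows onto the sample ids actually emitted
    id_map = {str(i): f"pos_{i}" for i in range(config.n_pos)}
    for row in truth:
        row.sample_id = id_map[row.sample_id]
    return samples, truth


def write_truth_table(truth, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tplanted\tplant_start\tmotif_instance\n")
        for r in truth:
            start = "" if r.plant_start is None else r.plant_start
            fh.write(f"{r.sample_id}\t{int(r.planted)}\t{start}\t{r.motif_instance}\n")
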