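"""PWM scanning with exact p-value-calibrated log-odds thresholds,
MEME-style aggregation scores, and motif co-occurrence tables.

The score threshold for a requested p-value is derived from the exact
null distribution of the log-odds score of a random background-drawn
w-mer, computed by column-by-column convolution of per-column score
distributions (optionally discretized onto a fixed granularity for wide
motifs).  This mirrors the calibration used by matrix-scanning tools
such as motifmatchr/TFBSTools; the conventional cutoff in TFBS work is
p = 1e-5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .seqdata import ALPHABET

logger = logging.getLogger(__name__)

_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

SCHEMES = ("M1-SUM", "M1-MAX", "SUM-SUM", "MAX-SUM", "SUM-MAX", "MAX-MAX")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Probability matrix over A,C,G,T columns with background and pseudocount.

    Construct from raw counts or probabilities via :meth:`from_matrix`;
    the pseudocount (default 0.8, split by background frequency) is folded
    in at construction so every stored entry is strictly positive.
    """

    name: str
    probs: np.ndarray  # (width, 4), rows sum to 1
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise ValueError("probs must be a non-empty width x 4 matrix")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")
        if np.any(self.probs <= 0):
            raise ValueError("PWM entries must be strictly positive (apply a pseudocount)")

    @classmethod
    def from_matrix(cls, name, matrix, background=None, pseudocount: float = 0.8) -> "PWM":
        """Regularise a count or probability matrix into a PWM.

        Each column is treated as observations totalling its own sum
        (1 for probability input), to which ``pseudocount`` fictive
        observations distributed as the background are added.
        """
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if matrix.shape[0] == 4 and matrix.shape[1] != 4:
            matrix = matrix.T  # accept 4 x width layouts
        bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
        totals = matrix.sum(axis=1, keepdims=True)
        if np.any(totals <= 0):
            raise ValueError("every PWM column needs a positive total")
        probs = (matrix + pseudocount * bg) / (totals + pseudocount)
        return cls(name, probs, bg)

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def log_odds(self) -> np.ndarray:
        """(width, 4) matrix of log2(p / background) scores."""
        return np.log2(self.probs / self.background)

    def consensus(self) -> str:
        """Per-column argmax base; ties resolve in A<C<G<T order."""
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(self.name, self.probs[::-1, ::-1], self.background[::-1])


@dataclass
class MotifHit:
    sample_id: str
    start: int
    strand: str
    score: float
    pwm_name: str


@dataclass
class ScanConfig:
    p_cutoff: float = 1e-5
    both_strands: bool = True
    score_bins: int = 1000

    def __post_init__(self):
        if not 0 < self.p_cutoff < 1:
            raise ValueError("p_cutoff must be in (0, 1)")


@dataclass
class CooccurrenceTable:
    """Four-case cross-tabulation of two motifs' per-sample presence."""

    n_samples: int
    neither: int
    only_a: int
    only_b: int
    both: int

    def __post_init__(self):
        if self.neither + self.only_a + self.only_b + self.both != self.n_samples:
            raise ValueError("case counts must partition n_samples")

    @property
    def fractions(self) -> dict[str, float]:
        n = self.n_samples
        return {
            "neither": self.neither / n,
            "only_a": self.only_a / n,
            "only_b": self.only_b / n,
            "both": self.both / n,
        }

    @property
    def frac_a_total(self) -> float:
        """Fraction of samples containing motif A at all (only_a + both)."""
        return (self.only_a + self.both) / self.n_samples

    @property
    def frac_b_total(self) -> float:
        return (self.only_b + self.both) / self.n_samples


# ---- score distribution and thresholds ----------------------------------


def score_distribution(pwm: PWM, granularity: float | None = None):
    """Exact null distribution of the w-mer log-odds score under the background.

    Column-by-column convolution: after column i the dict maps each
    achievable partial score to its probability.  With ``granularity`` g,
    per-column scores are first rounded to multiples of g, bounding the
    support size at the cost of score resolution.

    Returns (scores, probabilities) sorted by ascending score.
    """
    lo = pwm.log_odds()
    bg = pwm.background
    if granularity is not None:
        lo = np.round(lo / granularity) * granularity
    dist = {0.0: 1.0}
    for i in range(pwm.width):
        nxt: dict[float, float] = {}
        for s, p in dist.items():
            for b in range(4):
                key = s + lo[i, b]
                nxt[key] = nxt.get(key, 0.0) + p * bg[b]
        dist = nxt
    scores = np.array(sorted(dist))
    probs = np.array([dist[s] for s in scores])
    return scores, probs


def threshold_from_pvalue(
    pwm: PWM, p_cutoff: float = 1e-5, score_bins: int = 1000, exact_max_width: int = 8
) -> float:
    """Smallest score t with P(score >= t) <= p_cutoff under the background.

    Exact convolution for widths up to ``exact_max_width``; wider motifs
    use per-column granularity (total score range / score_bins).  If even
    the maximum score is not rare enough, it is returned with a warning.
    """
    if pwm.width <= exact_max_width:
        scores, probs = score_distribution(pwm)
    else:
        lo = pwm.log_odds()
        span = float((lo.max(axis=1) - lo.min(axis=1)).sum())
        scores, probs = score_distribution(pwm, granularity=max(span, 1e-9) / score_bins)
    tail = np.cumsum(probs[::-1])[::-1]  # tail[i] = P(score >= scores[i])
    ok = np.flatnonzero(tail <= p_cutoff)
    if ok.size == 0:
        logger.warning(
            "p_cutoff=%g below the minimal achievable tail %g for %s; using max score",
            p_cutoff,
            tail[-1],
            pwm.name,
        )
        return float(scores[-1])
    return float(scores[ok[0]])


# ---- scanning -----------------------------------------------------------


def _encode_indices(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    idx = np.full(arr.shape, -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        idx[arr == ord(b)] = i
    return idx


def sliding_scores(seq: str, pwm: PWM) -> np.ndarray:
    """Log-odds score at every + strand offset; NaN where the window has N."""
    idx = _encode_indices(seq)
    w = pwm.width
    if len(idx) < w:
        return np.empty(0)
    lo = pwm.log_odds()
    n_win = len(idx) - w + 1
    scores = np.zeros(n_win)
    valid = np.ones(n_win, dtype=bool)
    for j in range(w):
        col = idx[j : j + n_win]
        bad = col < 0
        valid &= ~bad
        scores += lo[j, np.where(bad, 0, col)]
    scores[~valid] = np.nan
    return scores


def scan_sequence(
    seq: str,
    pwm: PWM,
    config: ScanConfig | None = None,
    sample_id: str = "",
    threshold: float | None = None,
) -> list[MotifHit]:
    """All offsets scoring at or above the calibrated threshold, both strands.

    Minus-strand hits are reported with their start in forward coordinates.
    Windows containing N are skipped.  Hits come back sorted by start.
    """
    config = config or ScanConfig()
    if len(seq) < pwm.width:
        return []
    if threshold is None:
        threshold = threshold_from_pvalue(pwm, config.p_cutoff, config.score_bins)
    hits = []
    fwd = sliding_scores(seq, pwm)
    for start in np.flatnonzero(fwd >= threshold):
        hits.append(MotifHit(sample_id, int(start), "+", float(fwd[start]), pwm.name))
    if config.both_strands:
        rev = sliding_scores(seq, pwm.reverse_complement())
        for start in np.flatnonzero(rev >= threshold):
            hits.append(MotifHit(sample_id, int(start), "-", float(rev[start]), pwm.name))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_samples(samples, pwm: PWM, config: ScanConfig | None = None) -> list[MotifHit]:
    """Scan many (id, sequence) pairs or SequenceSamples with one shared threshold."""
    config = config or ScanConfig()
    threshold = threshold_from_pvalue(pwm, config.p_cutoff, config.score_bins)
    hits = []
    for item in samples:
        sid, seq = (item.id, item.sequence) if hasattr(item, "sequence") else item
        hits.extend(scan_sequence(seq, pwm, config, sample_id=sid, threshold=threshold))
    return hits


# ---- aggregation (MEME-style scoring schemes) ---------------------------


def aggregate_scores(per_pwm_position_scores, scheme: str) -> float:
    """Reduce per-PWM, per-position scores by one of the six schemes.

    The first PWM is M1.  SUM/MAX before the dash is the across-motif
    reduction, after the dash the across-position reduction — except the
    M1-* schemes, which use only the first motif.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    mats = [np.asarray(s, dtype=float) for s in per_pwm_position_scores]
    if not mats:
        raise ValueError("need at least one PWM's scores")
    if scheme == "M1-SUM":
        return float(mats[0].sum())
    if scheme == "M1-MAX":
        return float(mats[0].max())
    if scheme == "SUM-SUM":
        return float(sum(m.sum() for m in mats))
    if scheme == "MAX-SUM":
        return float(sum(m.max() for m in mats))
    if scheme == "SUM-MAX":
        return float(max(m.sum() for m in mats))
    return float(max(m.max() for m in mats))  # MAX-MAX


# ---- co-occurrence ------------------------------------------------------


def cooccurrence(hits_a, hits_b, sample_ids) -> CooccurrenceTable:
    """Four-case presence table of two motifs over a fixed sample universe.

    A sample "contains" a motif if it has at least one hit.  ``sample_ids``
    is the full list of scanned samples (or an integer count, in which
    case hits must carry ids convertible to integers < n).
    """
    if isinstance(sample_ids, int):
        universe = {str(i) for i in range(sample_ids)}
    else:
        universe = {str(s) for s in sample_ids}
    set_a = {h.sample_id for h in hits_a}
    set_b = {h.sample_id for h in hits_b}
    for sid in set_a | set_b:
        if sid not in universe:
            raise ValueError(f"hit references unknown sample {sid!r}")
    n = len(universe)
    both = len(set_a & set_b)
    only_a = len(set_a - set_b)
    only_b = len(set_b - set_a)
    return CooccurrenceTable(n, n - only_a - only_b - both, only_a, only_b, both)


def cooccurrence_from_counts(
    n_samples: int, neither: int, only_a: int, only_b: int, both: int
) -> CooccurrenceTable:
    """Build the table directly from the four case counts."""
    return CooccurrenceTable(n_samples, neither, only_a, only_b, both)


# ---- motif file formats -------------------------------------------------


def read_jaspar(path, pseudocount: float = 0.8) -> list[PWM]:
    """JASPAR .jaspar / .pfm: '>' headers then 4 base rows, bracketed or bare."""
    pwms = []
    name = None
    rows: dict[str, list[float]] = {}
    order = []

    def flush():
        if name is None:
            return
        if set(rows) == set("ACGT"):
            matrix = np.array([rows[b] for b in ALPHABET]).T
        elif len(order) == 4:
            matrix = np.array(order).T
        else:
            raise ValueError(f"motif {name!r}: expected 4 matrix rows")
        pwms.append(PWM.from_matrix(name, matrix, pseudocount=pseudocount))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0]
                rows, order = {}, []
                continue
            parts = line.replace("[", " ").replace("]", " ").split()
            if parts and parts[0] in "ACGT" and len(parts) > 1:
                rows[parts[0]] = [float(v) for v in parts[1:]]
            else:
                order.append([float(v) for v in parts])
    flush()
    return pwms


def read_meme(path, pseudocount: float = 0.8) -> list[PWM]:
    """MEME minimal format: MOTIF blocks with letter-probability matrices."""
    pwms = []
    background = np.full(4, 0.25)
    with open(path) as fh:
        lines = iter(fh.read().splitlines())
    name = None
    matrix: list[list[float]] = []
    for line in lines:
        s = line.strip()
        if s.startswith("Background letter frequencies"):
            freq_line = next(lines).split()
            vals = {freq_line[i]: float(freq_line[i + 1]) for i in range(0, len(freq_line), 2)}
            background = np.array([vals.get(b, 0.25) for b in ALPHABET])
        elif s.startswith("MOTIF"):
            if name and matrix:
                pwms.append(
                    PWM.from_matrix(name, np.array(matrix), background, pseudocount)
                )
            name = s.split()[1]
            matrix = []
        elif name and s and s[0].isdigit() or (name and s.startswith("0.")):
            parts = s.split()
            if len(parts) == 4:
                matrix.append([float(v) for v in parts])
    if name and matrix:
        pwms.append(PWM.from_matrix(name, np.array(matrix), background, pseudocount))
    return pwms


def write_hits_tsv(hits, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tstart\tstrand\tscore\tpwm\n")
        for h in hits:
            fh.write(f"{h.sample_id}\t{h.start}\t{h.strand}\t{h.score:.4f}\t{h.pwm_name}\n")


def write_hits_bed(hits, width: int, path) -> None:
    """BED6 with the log-odds score min-max scaled onto [0, 1000]."""
    scores = np.array([h.score for h in hits]) if hits else np.empty(0)
    lo, hi = (scores.min(), scores.max()) if hits else (0.0, 1.0)
    span = (hi - lo) or 1.0
    with open(path, "w") as fh:
        for h in hits:
            scaled = int(round(1000 * (h.score - lo) / span))
            fh.write(
                f"{h.sample_id}\t{h.start}\t{h.start + width}\t{h.pwm_name}\t{scaled}\t{h.strand}\n"
            )
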