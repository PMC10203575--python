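"""PWM scoring, p-value calibration, scanning, aggregation, co-occurrence."""

from itertools import product

import numpy as np
import pytest

from tfbsnet.motifscan import (
    PWM,
    CooccurrenceTable,
    MotifHit,
    ScanConfig,
    aggregate_scores,
    cooccurrence,
    read_jaspar,
    read_meme,
    reverse_complement,
    scan_sequence,
    score_distribution,
    threshold_from_pvalue,
)


def strong_pwm(consensus: str, p: float = 0.97) -> PWM:
    probs = np.full((len(consensus), 4), (1 - p) / 3)
    for i, b in enumerate(consensus):
        probs[i, "ACGT".index(b)] = p
    return PWM("strong", probs)


def brute_force_tail(pwm: PWM, threshold: float) -> float:
    """P(score >= threshold) by exhaustive enumeration over all w-mers."""
    lo = pwm.log_odds()
    total = 0.0
    for word in product(range(4), repeat=pwm.width):
        sc = sum(lo[i, b] for i, b in enumerate(word))
        if sc >= threshold - 1e-12:
            total += np.prod([pwm.background[b] for b in word])
    return total


class TestPWM:
    def test_log_odds_values(self):
        pwm = PWM("m", np.array([[0.25, 0.25, 0.25, 0.25], [0.5, 0.25, 0.125, 0.125]]))
        lo = pwm.log_odds()
        assert lo[0, 0] == pytest.approx(0.0)  # p == background -> 0
        assert lo[1, 0] == pytest.approx(1.0)  # p = 2x background -> 1 bit

    def test_consensus_beats_any_single_mismatch(self):
        pwm = strong_pwm("GCACGTGC")
        lo = pwm.log_odds()
        cons_score = sum(lo[i, "ACGT".index(b)] for i, b in enumerate("GCACGTGC"))
        for i in range(8):
            for b in range(4):
                if b == "ACGT".index("GCACGTGC"[i]):
                    continue
                mut = cons_score - lo[i, "ACGT".index("GCACGTGC"[i])] + lo[i, b]
                assert mut < cons_score

    def test_from_matrix_counts_with_pseudocount(self):
        pwm = PWM.from_matrix("m", np.array([[10, 0, 0, 0]]), pseudocount=0.8)
        assert pwm.probs[0, 0] == pytest.approx((10 + 0.2) / 10.8)
        assert np.all(pwm.probs > 0)

    def test_column_sum_validation(self):
        with pytest.raises(ValueError):
            PWM("bad", np.array([[0.5, 0.5, 0.5, 0.5]]))

    def test_reverse_complement_involution(self, rng):
        counts = rng.integers(1, 20, size=(6, 4)).astype(float)
        pwm = PWM.from_matrix("m", counts)
        back = pwm.reverse_complement().reverse_complement()
        assert np.allclose(back.probs, pwm.probs)


class TestThresholdCalibration:
    def test_dp_distribution_matches_enumeration(self, rng):
        """Convolution DP equals the exhaustive 4^w enumeration oracle."""
        for _ in range(5):
            w = int(rng.integers(2, 6))
            pwm = PWM.from_matrix("m", rng.integers(1, 40, size=(w, 4)).astype(float))
            scores, probs = score_distribution(pwm)
            assert probs.sum() == pytest.approx(1.0, abs=1e-12)
            for q in (0.5, 0.05, 0.001):
                t = float(np.quantile(scores, 1 - q))
                dp_tail = probs[scores >= t - 1e-12].sum()
                assert dp_tail == pytest.approx(brute_force_tail(pwm, t), abs=1e-12)

    def test_p_cutoff_near_one_accepts_almost_everything(self, rng):
        pwm = PWM.from_matrix("m", rng.integers(1, 10, size=(3, 4)).astype(float))
        scores, probs = score_distribution(pwm)
        # The minimum score has tail probability exactly 1 > p_cutoff, so the
        # threshold lands on the next achievable score; only the minimum-score
        # words (probability mass probs[0]) are rejected.
        t = threshold_from_pvalue(pwm, 1 - 1e-12)
        assert t == pytest.approx(scores[1])
        assert probs[scores >= t - 1e-12].sum() == pytest.approx(1 - probs[0])

    def test_uniform_pwm_degenerate_warning_path(self, caplog):
        pwm = PWM("uniform", np.full((4, 4), 0.25))
        with caplog.at_level("WARNING"):
            t = threshold_from_pvalue(pwm, 0.5)
        assert t == pytest.approx(0.0)  # every word scores 0; max score returned
        assert "below the minimal achievable tail" in caplog.text

    def test_threshold_is_calibrated(self, rng):
        """The returned threshold's true tail probability respects the cutoff."""
        pwm = PWM.from_matrix("m", rng.integers(1, 60, size=(5, 4)).astype(float))
        for p_cut in (0.01, 1e-3):
            t = threshold_from_pvalue(pwm, p_cut)
            assert brute_force_tail(pwm, t) <= p_cut + 1e-12


class TestScanning:
    def test_planted_consensus_found_on_plus_strand(self, dna):
        pwm = strong_pwm("GCACGTGC")
        seq = dna(500)
        seq = seq[:100] + "GCACGTGC" + seq[108:]
        hits = scan_sequence(seq, pwm, ScanConfig())
        assert any(h.start == 100 and h.strand == "+" for h in hits)

    def test_strand_symmetry(self, dna):
        """Hits on the reverse complement are mirror images with equal scores."""
        pwm = strong_pwm("GATTACAA")
        seq = dna(300)
        seq = seq[:50] + "GATTACAA" + seq[58:]
        fwd_hits = scan_sequence(seq, pwm, ScanConfig(), sample_id="s")
        rc_hits = scan_sequence(reverse_complement(seq), pwm, ScanConfig(), sample_id="s")
        mirrored = sorted((300 - h.start - 8, h.strand, round(h.score, 6)) for h in rc_hits)
        original = sorted(
            (h.start, "+" if h.strand == "-" else "-", round(h.score, 6)) for h in fwd_hits
        )
        assert [(p, round(s, 6)) for p, _, s in mirrored] == [
            (p, round(s, 6)) for p, _, s in original
        ]

    def test_all_n_sequence_yields_no_hits(self):
        assert scan_sequence("N" * 100, strong_pwm("ACGTACGT"), ScanConfig()) == []

    def test_hits_sorted_by_start(self, dna):
        pwm = strong_pwm("TTGACCAA")
        seq = "TTGACCAA" + dna(84) + "TTGACCAA" + dna(50)
        hits = scan_sequence(seq, pwm, ScanConfig())
        starts = [h.start for h in hits]
        assert starts == sorted(starts)


class TestAggregation:
    def test_worked_arithmetic(self):
        assert aggregate_scores([[1, -2, 3]], "M1-SUM") == 2
        assert aggregate_scores([[1, -2, 3]], "M1-MAX") == 3
        assert aggregate_scores([[1, 2], [0, 5]], "SUM-SUM") == 8
        assert aggregate_scores([[1, 2], [0, 5]], "MAX-SUM") == 7
        assert aggregate_scores([[1, 2], [0, 5]], "SUM-MAX") == 5
        assert aggregate_scores([[1, 2], [0, 5]], "MAX-MAX") == 5

    def test_singleton_collapse(self, rng):
        """With one PWM all six schemes reduce to sum or max of its scores."""
        scores = [list(rng.normal(size=7))]
        total, peak = float(np.sum(scores[0])), float(np.max(scores[0]))
        for scheme in ("M1-SUM", "SUM-SUM", "SUM-MAX"):
            assert aggregate_scores(scores, scheme) == pytest.approx(total)
        for scheme in ("M1-MAX", "MAX-SUM", "MAX-MAX"):
            assert aggregate_scores(scores, scheme) == pytest.approx(peak)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="unknown scheme"):
            aggregate_scores([[1.0]], "MEAN-MAX")


class TestCooccurrence:
    def _hits(self, ids, name):
        return [MotifHit(str(i), 0, "+", 1.0, name) for i in ids]

    def test_counts_partition_samples(self):
        hits_a = self._hits([0, 1, 2, 5], "a")
        hits_b = self._hits([2, 3], "b")
        t = cooccurrence(hits_a, hits_b, 10)
        assert t.neither + t.only_a + t.only_b + t.both == 10
        assert (t.only_a, t.only_b, t.both) == (3, 1, 1)

    def test_multiple_hits_count_once(self):
        hits_a = self._hits([0, 0, 0], "a")
        t = cooccurrence(hits_a, [], 5)
        assert t.only_a == 1

    def test_no_hits_all_neither(self):
        t = cooccurrence([], [], 100)
        assert t.neither == 100
        assert t.fractions["both"] == 0.0

    def test_unknown_sample_rejected(self):
        with pytest.raises(ValueError, match="unknown sample"):
            cooccurrence(self._hits([11], "a"), [], 10)

    def test_partition_invariant_enforced(self):
        with pytest.raises(ValueError):
            CooccurrenceTable(10, 5, 5, 5, 5)


class TestMotifIO:
    def test_jaspar_bracketed(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(
            ">MA0001.1 TEST\n"
            "A  [ 4 19  0 ]\n"
            "C  [16  0 20 ]\n"
            "G  [ 0  1  0 ]\n"
            "T  [ 0  0  0 ]\n"
        )
        (pwm,) = read_jaspar(p)
        assert pwm.name == "MA0001.1"
        assert pwm.width == 3
        assert pwm.consensus() == "CAC"

    def test_meme_minimal(self, tmp_path):
        p = tmp_path / "m.meme"
        p.write_text(
            "MEME version 4\n\nALPHABET= ACGT\n\n"
            "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n"
            "MOTIF motif1\n"
            "letter-probability matrix: alength= 4 w= 2 nsites= 20 E= 0\n"
            "0.970000 0.010000 0.010000 0.010000\n"
            "0.010000 0.010000 0.970000 0.010000\n"
        )
        (pwm,) = read_meme(p)
        assert pwm.name == "motif1"
        assert pwm.consensus() == "AG"
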