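"""Interpretability stack: shuffling, attributions, deletion, mutagenesis, seqlets."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tfbsnet.interpret import (
    AttributionTrack,
    SeqletParams,
    contribution_scores,
    dinuc_shuffle,
    extract_seqlets,
    saturation_mutagenesis,
    tiling_deletion,
)
from tfbsnet.seqdata import one_hot

from conftest import AdditiveScorer, ConstantModel


def dinuc_counts(seq: str) -> Counter:
    return Counter(zip(seq, seq[1:]))


class TestDinucShuffle:
    @given(st.text(alphabet="ACGT", min_size=2, max_size=60))
    @settings(max_examples=60, deadline=None)
    def test_dinucleotide_counts_preserved(self, seq):
        assert dinuc_counts(dinuc_shuffle(seq, seed=0)) == dinuc_counts(seq)

    def test_homopolymer_is_forced(self):
        assert dinuc_shuffle("AAAA", seed=3) == "AAAA"

    def test_first_and_last_base_preserved(self, dna):
        seq = dna(200)
        for seed in range(5):
            sh = dinuc_shuffle(seq, seed)
            assert (sh[0], sh[-1]) == (seq[0], seq[-1])

    def test_deterministic_under_seed(self, dna):
        seq = dna(100)
        assert dinuc_shuffle(seq, 7) == dinuc_shuffle(seq, 7)

    def test_rejects_n(self):
        with pytest.raises(ValueError, match="N"):
            dinuc_shuffle("ACNGT", 0)

    def test_rejects_too_short(self):
        with pytest.raises(ValueError):
            dinuc_shuffle("A", 0)


class TestContributionScores:
    def test_constant_model_gives_zero_scores(self, dna):
        model = ConstantModel(0.5, input_length=80)
        track = contribution_scores(model, dna(80), seed=0)
        assert np.allclose(track.scores, 0.0)
        assert track.completeness_residual < 1e-9

    def test_linear_model_is_exactly_complete(self, rng, dna):
        """For a model linear in the one-hot, IG completeness is exact."""
        w = rng.normal(size=(60, 4))
        model = AdditiveScorer(w)
        track = contribution_scores(model, dna(60), n_references=5, seed=1)
        diff = track.prediction - track.mean_reference_prediction
        assert track.scores.sum() == pytest.approx(diff, abs=1e-8)

    def test_length_mismatch_rejected(self, dna):
        with pytest.raises(ValueError, match="length"):
            contribution_scores(ConstantModel(0.5, input_length=100), dna(80))


class TestTilingDeletion:
    def test_window_count_arithmetic(self, dna):
        prof = tiling_deletion(AdditiveScorer(np.zeros((500, 4))), dna(500))
        assert len(prof.deltas) == 491

    def test_constant_model_all_zero(self, dna):
        prof = tiling_deletion(ConstantModel(0.9, input_length=100), dna(100))
        assert np.allclose(prof.deltas, 0.0)

    def test_full_length_window_equals_all_n_difference(self, rng, dna):
        w = rng.normal(size=(50, 4))
        model = AdditiveScorer(w)
        seq = dna(50)
        prof = tiling_deletion(model, seq, window=50)
        assert len(prof.deltas) == 1
        p_wt = model.predict_scores(one_hot(seq)[None])[0]
        p_null = model.predict_scores(np.zeros((1, 50, 4)))[0]
        assert prof.deltas[0] == pytest.approx(p_wt - p_null, abs=1e-8)

    def test_window_longer_than_sequence_rejected(self, dna):
        with pytest.raises(ValueError):
            tiling_deletion(ConstantModel(0.5), dna(20), window=30)

    def test_deltas_match_additive_model_closed_form(self, rng, dna):
        w = rng.normal(size=(30, 4))
        model = AdditiveScorer(w)
        seq = dna(30)
        prof = tiling_deletion(model, seq, window=5)
        x = one_hot(seq)
        for s, delta in enumerate(prof.deltas):
            expected = np.einsum("lc,lc->", x[s : s + 5], w[s : s + 5])
            assert delta == pytest.approx(expected, abs=1e-6)


class TestSaturationMutagenesis:
    def test_reference_cells_zero_by_construction(self, dna):
        seq = dna(40)
        m = saturation_mutagenesis(AdditiveScorer(np.ones((40, 4))), seq)
        x = one_hot(seq)
        for i in range(40):
            assert m.deltas[i, x[i].argmax()] == 0.0

    def test_constant_model_all_zero(self, dna):
        m = saturation_mutagenesis(ConstantModel(0.5, input_length=30), dna(30))
        assert np.allclose(m.deltas, 0.0)

    def test_deltas_match_additive_model_closed_form(self, rng, dna):
        w = rng.normal(size=(25, 4))
        model = AdditiveScorer(w)
        seq = dna(25)
        m = saturation_mutagenesis(model, seq)
        x = one_hot(seq)
        for i in range(25):
            ref = int(x[i].argmax())
            for b in range(4):
                expected = 0.0 if b == ref else w[i, b] - w[i, ref]
                assert m.deltas[i, b] == pytest.approx(expected, abs=1e-6)


class TestSeqlets:
    def _track(self, scores):
        return AttributionTrack("A" * len(scores), np.asarray(scores, float), None, 1)

    def test_zero_track_yields_nothing(self):
        assert extract_seqlets(self._track(np.zeros(500))) == []

    def test_single_bump_covers_site_with_flanks(self):
        """A width-12 unit bump at 100 must produce one seqlet spanning it."""
        scores = np.zeros(500)
        scores[100:112] = 1.0
        seqlets = extract_seqlets(self._track(scores))
        assert len(seqlets) == 1
        q = seqlets[0]
        # bump +/- flank is [95, 117); smoothing can spread by < window/2 + flank
        assert q.start <= 95 and q.end >= 117
        assert q.start >= 100 - 7 - 5 and q.end <= 112 + 7 + 5

    def test_two_separated_bumps_sorted_by_mean_score(self):
        scores = np.zeros(500)
        scores[50:60] = 1.0
        scores[300:310] = 2.0
        seqlets = extract_seqlets(self._track(scores))
        assert len(seqlets) == 2
        assert seqlets[0].mean_score > seqlets[1].mean_score
        assert 300 - 12 <= seqlets[0].start <= 300

    def test_params_validation(self):
        with pytest.raises(ValueError):
            SeqletParams(score_quantile=1.5)
        with pytest.raises(ValueError):
            SeqletParams(sliding_window_size=0)
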