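"""Shared fixtures and stub models for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from tfbsnet.seqdata import one_hot


class ConstantModel:
    """Model that ignores its input; useful as a null for interpretability."""

    def __init__(self, value: float = 0.7, input_length: int | None = None):
        self.value = value
        self.input_length_ = input_length

    def predict_scores(self, X):
        return np.full(len(X), self.value)

    def probability_gradients(self, X):
        X = np.asarray(X)
        return np.full(len(X), self.value), np.zeros_like(X, dtype=float)


class AdditiveScorer:
    """Linear position-weight model: score = sum_i w[i, base_i] on the one-hot.

    Being exactly linear in the encoding, embedding effects have a closed
    form, which makes it the oracle for global-importance bookkeeping.
    """

    def __init__(self, weights: np.ndarray):
        self.weights = np.asarray(weights, dtype=float)
        self.input_length_ = self.weights.shape[0]

    def predict_scores(self, X):
        X = np.asarray(X, dtype=float)
        return np.einsum("nlc,lc->n", X, self.weights)

    def probability_gradients(self, X):
        X = np.asarray(X, dtype=float)
        return self.predict_scores(X), np.broadcast_to(self.weights, X.shape).copy()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def dna(rng):
    """Callable producing a random DNA string of a given length."""

    def _make(n: int) -> str:
        return "".join(rng.choice(list("ACGT"), size=n))

    return _make
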