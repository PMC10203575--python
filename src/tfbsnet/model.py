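"""DenseNet TFBS classifier with a scikit-learn estimator interface.

`DenseNetClassifier` wraps the NumPy network in :mod:`tfbsnet.nn`:
``fit`` trains with Adam on binary cross-entropy, holding out a validation
fraction for early stopping on validation loss (patience 5, best weights
restored); ``predict_proba`` returns binding probabilities.  Inputs may be
equal-length DNA strings or pre-encoded one-hot arrays of shape (n, L, 4).
"""

from __future__ import annotations

import json
import zipfile
from io import BytesIO

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .nn import Adam, DenseNet1D
from .seqdata import encode_batch


def _as_onehot(X) -> np.ndarray:
    if isinstance(X, np.ndarray) and X.ndim == 3:
        return X.astype(np.float32, copy=False)
    return encode_batch(X)


class DenseNetClassifier(BaseEstimator, ClassifierMixin):
    """Binary sequence classifier built on a 1-D DenseNet.

    Parameters
    ----------
    stem_filters, stem_kernel
        The two stem convolutions share this filter count (default 64)
        and kernel size (default 3); an average pool of stride 2 follows.
    block_layers
        Dense layers per block, four blocks (default (6, 12, 24, 16)).
    growth_rate
        Feature maps added by each dense layer (default 32).
    transition_compression
        Channel compression of the kernel-1 transition convolutions.
    learning_rate, max_epochs, batch_size
        Adam step size (default 1e-3), epoch cap (default 80) and
        minibatch size (default 64).
    validation_frac, patience
        Held-out fraction for early stopping and the number of epochs
        without validation-loss improvement tolerated before stopping.
    random_state
        Seeds weight initialisation, the validation split and batch order.
    """

    def __init__(
        self,
        stem_filters: int = 64,
        stem_kernel: int = 3,
        block_layers: tuple = (6, 12, 24, 16),
        growth_rate: int = 32,
        transition_compression: float = 0.5,
        learning_rate: float = 1e-3,
        max_epochs: int = 80,
        batch_size: int = 64,
        validation_frac: float = 0.1,
        patience: int = 5,
        random_state: int | None = None,
    ):
        self.stem_filters = stem_filters
        self.stem_kernel = stem_kernel
        self.block_layers = block_layers
        self.growth_rate = growth_rate
        self.transition_compression = transition_compression
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.validation_frac = validation_frac
        self.patience = patience
        self.random_state = random_state

    # ---- training -------------------------------------------------------

    def fit(self, X, y):
        Xe = _as_onehot(X)
        y = np.asarray(y, dtype=np.float64)
        if len(Xe) != len(y):
            raise ValueError("X and y have different lengths")
        if len(Xe) == 0:
            raise ValueError("empty training set")
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training data must contain both classes")
        if not set(classes) <= {0.0, 1.0}:
            raise ValueError("labels must be 0/1")
        self.classes_ = np.array([0, 1])
        self.input_length_ = Xe.shape[1]

        rng = np.random.default_rng(self.random_state)
        net = DenseNet1D(
            input_length=self.input_length_,
            stem_filters=self.stem_filters,
            stem_kernel=self.stem_kernel,
            block_layers=tuple(self.block_layers),
            growth_rate=self.growth_rate,
            transition_compression=self.transition_compression,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        opt = Adam(net.params(), lr=self.learning_rate)

        n = len(Xe)
        order = rng.permutation(n)
        n_val = max(1, int(round(self.validation_frac * n))) if self.validation_frac > 0 else 0
        val_idx, tr_idx = order[:n_val], order[n_val:]
        Xtr, ytr = Xe[tr_idx], y[tr_idx]
        Xval, yval = Xe[val_idx], y[val_idx]

        history = []
        best_val = np.inf
        best_state = None
        stale = 0
        for epoch in range(self.max_epochs):
            perm = rng.permutation(len(Xtr))
            losses = []
            for s in range(0, len(Xtr), self.batch_size):
                idx = perm[s : s + self.batch_size]
                if len(idx) < 2:
                    continue  # batch norm needs more than one sample
                losses.append(net.train_step(Xtr[idx], ytr[idx]))
                opt.step()
            rec = {"epoch": epoch, "train_loss": float(np.mean(losses))}
            if n_val:
                pv = net.predict_proba(Xval)
                eps = 1e-12
                val_loss = float(
                    -np.mean(yval * np.log(pv + eps) + (1 - yval) * np.log(1 - pv + eps))
                )
                rec["val_loss"] = val_loss
                if val_loss < best_val - 1e-6:
                    best_val = val_loss
                    best_state = {k: v.copy() for k, v in net.state_arrays().items()}
                    stale = 0
                else:
                    stale += 1
            history.append(rec)
            if n_val and stale >= self.patience:
                break
        if best_state is not None:
            net.load_state_arrays(best_state)
        self.net_ = net
        self.history_ = history
        self.best_val_loss_ = best_val if n_val else None
        return self

    # ---- inference ------------------------------------------------------

    def _check_input(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        Xe = _as_onehot(X)
        if Xe.shape[1] != self.input_length_:
            raise ValueError(
                f"expected sequences of length {self.input_length_}, got {Xe.shape[1]}"
            )
        return Xe

    def predict_proba(self, X) -> np.ndarray:
        """(n, 2) class probabilities; column 1 is the binding probability."""
        p1 = self.predict_scores(X)
        return np.column_stack([1 - p1, p1])

    def predict_scores(self, X) -> np.ndarray:
        """Binding probability per sequence (the sigmoid output)."""
        return self.net_.predict_proba(self._check_input(X))

    def predict(self, X) -> np.ndarray:
        return (self.predict_scores(X) >= 0.5).astype(int)

    def input_gradients(self, X) -> np.ndarray:
        """(n, L, 4) gradient of the output logit with respect to the one-hot input."""
        return self.net_.input_gradients(self._check_input(X))

    def probability_gradients(self, X):
        """(probabilities, gradients) of the sigmoid output w.r.t. the input."""
        return self.net_.probability_gradients(self._check_input(X))

    # ---- persistence ----------------------------------------------------

    def save(self, path) -> None:
        """Single-file checkpoint: weights (npz) + JSON architecture metadata."""
        check_is_fitted(self, "net_")
        buf = BytesIO()
        np.savez(buf, **self.net_.state_arrays())
        meta = {
            "params": self.get_params(),
            "input_length": int(self.input_length_),
            "channel_order": "ACGT",
        }
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("weights.npz", buf.getvalue())
            zf.writestr("meta.json", json.dumps(meta, default=list))

    @classmethod
    def load(cls, path) -> "DenseNetClassifier":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            with zf.open("weights.npz") as fh:
                state = dict(np.load(BytesIO(fh.read())))
        params = meta["params"]
        params["block_layers"] = tuple(params["block_layers"])
        est = cls(**params)
        est.classes_ = np.array([0, 1])
        est.input_length_ = meta["input_length"]
        rng = np.random.default_rng(0)
        net = DenseNet1D(
            input_length=est.input_length_,
            stem_filters=est.stem_filters,
            stem_kernel=est.stem_kernel,
            block_layers=tuple(est.block_layers),
            growth_rate=est.growth_rate,
            transition_compression=est.transition_compression,
            seed=0,
        )
        net.load_state_arrays(state)
        est.net_ = net
        est.history_ = []
        return est
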