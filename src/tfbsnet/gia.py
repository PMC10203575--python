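"""Global importance analysis (GIA).

A motif's population-level effect on a model is measured by embedding it
into many background sequences at a fixed set of offsets and averaging
the change in predicted binding probability.  By default the motif is
placed at the 70th, 170th, 270th, 370th and 470th bp (1-based starts) of
1000 background sequences of model length; the sign convention makes a
binding-promoting motif positive (embedded mean minus original).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqdata import ALPHABET, encode_batch, one_hot

DEFAULT_POSITIONS_1BASED = (70, 170, 270, 370, 470)


@dataclass
class GIAConfig:
    positions: tuple = DEFAULT_POSITIONS_1BASED
    positions_are_one_based: bool = True
    n_backgrounds: int = 1000
    seed: int | None = None

    def offsets(self) -> list[int]:
        """0-based embedding offsets."""
        shift = 1 if self.positions_are_one_based else 0
        return [int(p) - shift for p in self.positions]


@dataclass
class GIAResult:
    motif_sequence: str
    global_importance: float
    per_background_local_importance: np.ndarray
    per_position_mean: np.ndarray

    def __post_init__(self):
        assert np.isclose(
            self.global_importance, float(np.mean(self.per_background_local_importance))
        )


def top_affinity_kmer(pwm) -> str:
    """Highest-probability base per column; ties break in A<C<G<T order."""
    probs = np.asarray(getattr(pwm, "probs", pwm), dtype=float)
    if probs.size == 0:
        raise ValueError("empty PWM")
    return "".join(ALPHABET[i] for i in probs.argmax(axis=1))


def embed_motif(background: str, motif: str, position: int) -> str:
    """Replace bases [position, position+len(motif)) of the background."""
    if position < 0 or position + len(motif) > len(background):
        raise ValueError(
            f"cannot embed {len(motif)}-mer at {position} in {len(background)} bp background"
        )
    return background[:position] + motif + background[position + len(motif) :]


def _select_backgrounds(backgrounds, config: GIAConfig) -> list[str]:
    backgrounds = list(backgrounds)
    if not backgrounds:
        raise ValueError("no background sequences supplied")
    if len(backgrounds) > config.n_backgrounds:
        rng = np.random.default_rng(config.seed)
        idx = rng.choice(len(backgrounds), size=config.n_backgrounds, replace=False)
        backgrounds = [backgrounds[i] for i in sorted(idx)]
    return backgrounds


def _embedded_means(model, backgrounds: list[str], motif: str, offsets, batch_size: int = 512):
    """(n_bg, n_pos) predictions with the motif embedded at each offset."""
    preds = np.empty((len(backgrounds), len(offsets)))
    embedded = [
        embed_motif(bg, motif, off) for bg in backgrounds for off in offsets
    ]
    X = encode_batch(embedded)
    flat = np.empty(len(embedded))
    for s in range(0, len(embedded), batch_size):
        flat[s : s + batch_size] = model.predict_scores(X[s : s + batch_size])
    return flat.reshape(len(backgrounds), len(offsets))


def global_importance(model, motif: str, backgrounds, config: GIAConfig | None = None) -> GIAResult:
    """Mean over backgrounds of (mean embedded prediction - original prediction)."""
    config = config or GIAConfig()
    backgrounds = _select_backgrounds(backgrounds, config)
    offsets = config.offsets()
    for off in offsets:
        if off < 0 or off + len(motif) > len(backgrounds[0]):
            raise ValueError(f"embedding offset {off} out of bounds for motif {motif!r}")
    base = model.predict_scores(encode_batch(backgrounds))
    emb = _embedded_means(model, backgrounds, motif, offsets)
    local = emb.mean(axis=1) - base
    return GIAResult(
        motif_sequence=motif,
        global_importance=float(local.mean()),
        per_background_local_importance=local,
        per_position_mean=emb.mean(axis=0) - base.mean(),
    )


def gia_single_nt_map(
    model, motif: str, backgrounds, config: GIAConfig | None = None
) -> np.ndarray:
    """(width, 4) change in global importance for every single-nt mutant.

    Cell [i, b] is GIA(motif with base b at i) - GIA(motif); reference
    cells are 0 by construction.  The original-sequence baseline cancels
    in the difference, so only embedded predictions are computed.
    """
    config = config or GIAConfig()
    backgrounds = _select_backgrounds(backgrounds, config)
    offsets = config.offsets()
    ref_mean = _embedded_means(model, backgrounds, motif, offsets).mean()
    out = np.zeros((len(motif), 4))
    for i in range(len(motif)):
        for b, base in enumerate(ALPHABET):
            if base == motif[i]:
                continue
            mutant = motif[:i] + base + motif[i + 1 :]
            out[i, b] = _embedded_means(model, backgrounds, mutant, offsets).mean() - ref_mean
    return out
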