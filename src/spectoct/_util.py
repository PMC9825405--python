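"""Shared numerical helpers: sinogram mirror convention and seed substreams."""

from __future__ import annotations

import numpy as np

__all__ = ["mirror_columns", "substream"]


def mirror_columns(values: np.ndarray, axis: int = -1) -> np.ndarray:
    """Mirror a projection about the rotation axis.

    For a parallel beam, the projection at angle θ+180° is the mirror image
    of the one at θ.  The rotation axis sits at index ``n // 2`` (the
    convention of skimage's radon transform), so the mirror is a flip
    followed by a one-pixel roll; index 0 wraps around, which is harmless
    for objects inside the inscribed circle.
    """
    return np.roll(np.flip(values, axis=axis), 1, axis=axis)


def substream(seed: int, *key: int) -> np.random.Generator:
    """Independent, reproducible random stream for a (seed, key...) pair.

    All simulator randomness flows from one master seed; per-energy and
    per-angle substreams are derived with ``spawn_key`` so any subset of the
    acquisition can be re-simulated bit-identically.
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))
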