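"""Shared FFT helpers: mirror padding to power-of-two shapes.

Every FFT-based operator in the package (Fresnel propagator, Fourier
Laplacian, MBA filter, ramp filter) pads with mirrored (reflected) copies of
the field before transforming and crops back afterwards, so the implicit
periodization never places a hard jump at the frame border. Power-of-two
sizes keep the transforms fast and the padding amount deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = ["next_pow2", "pad_mirror"]


def next_pow2(n: int) -> int:
    """Smallest power of two >= n."""
    return 1 << (int(n) - 1).bit_length()


def pad_mirror(field: np.ndarray, min_factor: float = 1.0):
    """Mirror-pad a 2D field to the next power of two strictly above its size.

    Every axis is always extended (a frame already at a power of two is
    doubled): without real padding the DFT's implicit periodization places a
    hard jump at the frame border, which corrupts spectral derivatives and
    propagators of non-periodic data. Returns ``(padded, crop)`` where
    ``padded[crop]`` recovers the original region; padding is split as evenly
    as possible around the field.
    """
    field = np.asarray(field)
    targets = [
        next_pow2(max(int(np.ceil(min_factor * s)), s + 1)) for s in field.shape
    ]
    pads, crops = [], []
    for s, t in zip(field.shape, targets):
        before = (t - s) // 2
        after = t - s - before
        pads.append((before, after))
        crops.append(slice(before, before + s))
    padded = np.pad(field, pads, mode="reflect")
    return padded, tuple(crops)
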