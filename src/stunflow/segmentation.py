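"""Pig/background segmentation providers.

Downstream activity computation only needs, for every frame, the set of
pixels containing pigs (the animals are treated as a whole; individuals are
never separated).  Any callable mapping a frame stack to one boolean mask
per frame can act as a provider — e.g. an adapter around precomputed masks
from a learned segmenter.  The reference provider is a global intensity
threshold, exact on the synthetic scenes (bright animals, dark floor).
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .errors import ContractViolation, FormatError

__all__ = [
    "segment_pigs",
    "threshold_provider",
    "ground_truth_provider",
    "validate_masks",
    "MaskProvider",
]

#: A mask provider maps a frame stack to a same-length stack of boolean masks.
MaskProvider = Callable[[np.ndarray], np.ndarray]


def segment_pigs(frame: np.ndarray, threshold: float = 50) -> np.ndarray:
    """Boolean pig mask: pixels strictly brighter than ``threshold``.

    Raising the threshold can only shrink the mask (monotonicity), and an
    all-dark frame yields an empty mask.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise FormatError(f"expected a single-channel frame, got shape {frame.shape}")
    return frame > threshold


def threshold_provider(threshold: float = 50) -> MaskProvider:
    """Provider applying :func:`segment_pigs` frame by frame."""

    def provide(frames: np.ndarray) -> np.ndarray:
        return np.stack([segment_pigs(f, threshold) for f in frames])

    return provide


def ground_truth_provider(masks: np.ndarray) -> MaskProvider:
    """Provider returning precomputed (e.g. generator ground-truth) masks."""
    masks = np.asarray(masks, dtype=bool)

    def provide(frames: np.ndarray) -> np.ndarray:
        validate_masks(frames, masks)
        return masks

    return provide


def validate_masks(frames: np.ndarray | Sequence[np.ndarray], masks: np.ndarray) -> np.ndarray:
    """Enforce the provider contract: one dimension-matched mask per frame."""
    if len(masks) != len(frames):
        raise ContractViolation(f"provider returned {len(masks)} masks for {len(frames)} frames")
    for i, (f, m) in enumerate(zip(frames, masks)):
        if np.shape(m) != np.shape(f):
            raise ContractViolation(
                f"mask {i} shape {np.shape(m)} does not match frame shape {np.shape(f)}"
            )
    return np.asarray(masks, dtype=bool)
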