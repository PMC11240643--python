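"""Dense frame-to-frame motion and the per-frame activity level.

The activity level of a gondola is the mean optical-flow speed over the
pixels containing pigs, one value per consecutive frame pair.  The field's
learned flow estimators are deliberately out of scope here; the reference
backend is exhaustive integer block matching, which is exact on the
integer-translation scenes the synthetic generator produces.  Classical
dense estimators from scikit-image are registered as alternative backends
behind the same contract.

Conventions (fixed and relied on downstream):

* ``compute_flow(prev, cur)`` returns the displacement from ``prev`` to
  ``cur`` sampled on the grid of ``cur``: the content now at pixel ``p``
  came from ``p - (u, v)`` in the previous frame.
* The activity value indexed by frame ``t`` (``t >= 1``) uses the pair
  ``(t-1, t)`` and the pig mask of the *later* frame, so a series over an
  ``n``-frame video has length ``n - 1`` starting at frame index 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import (
    AnalysisError,
    ConfigurationError,
    ContractViolation,
    EmptyMaskError,
    FormatError,
)

__all__ = [
    "FlowField",
    "ActivitySeries",
    "compute_flow",
    "frame_activity",
    "activity_series",
    "register_backend",
    "available_backends",
]


@dataclass
class FlowField:
    """Per-pixel displacement (pixels/frame); ``u`` is x (columns), ``v`` is y (rows)."""

    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        if self.u.shape != self.v.shape:
            raise FormatError("u and v must have identical shapes")
        if not (np.isfinite(self.u).all() and np.isfinite(self.v).all()):
            raise FormatError("flow field contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape

    def speed(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


@dataclass
class ActivitySeries:
    """Mean pig-pixel speed per frame pair, indexed from the second frame."""

    gondola_id: str
    values: np.ndarray
    fps: float
    start_frame: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise FormatError("activity values must be one-dimensional")
        if not np.isfinite(self.values).all() or (self.values < 0).any():
            raise FormatError("activity values must be finite and non-negative")

    def __len__(self) -> int:
        return len(self.values)

    def window(self, t_start: int, t_end: int) -> np.ndarray:
        """Values for frame indices in the half-open window ``[t_start, t_end)``."""
        if t_start >= t_end:
            raise AnalysisError(f"empty window [{t_start}, {t_end})")
        lo = t_start - self.start_frame
        hi = t_end - self.start_frame
        if lo < 0 or hi > len(self.values):
            raise AnalysisError(
                f"window [{t_start}, {t_end}) outside series "
                f"[{self.start_frame}, {self.start_frame + len(self.values)})"
            )
        return self.values[lo:hi]


# ---------------------------------------------------------------------------
# backends

_BACKENDS: dict[str, Callable[..., FlowField]] = {}


def register_backend(name: str):
    def deco(fn: Callable[..., FlowField]):
        _BACKENDS[name] = fn
        return fn

    return deco


def available_backends() -> list[str]:
    return sorted(_BACKENDS)


def compute_flow(prev: np.ndarray, cur: np.ndarray, backend: str = "block", **params) -> FlowField:
    """Dense displacement field from ``prev`` to ``cur`` (see module notes)."""
    prev = np.asarray(prev)
    cur = np.asarray(cur)
    if prev.ndim != 2 or cur.ndim != 2:
        raise FormatError("frames must be single-channel 2-D arrays")
    if prev.shape != cur.shape:
        raise FormatError(f"frame shapes differ: {prev.shape} vs {cur.shape}")
    try:
        fn = _BACKENDS[backend]
    except KeyError:
        raise ConfigurationError(
            f"unknown flow backend {backend!r}; registered: {available_backends()}"
        ) from None
    return fn(prev, cur, **params)


def _shift(img: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Translate by (dx, dy) with zero fill: out[y, x] = img[y - dy, x - dx]."""
    out = np.zeros_like(img)
    h, w = img.shape
    xs_dst = slice(max(dx, 0), w + min(dx, 0))
    ys_dst = slice(max(dy, 0), h + min(dy, 0))
    xs_src = slice(max(-dx, 0), w + min(-dx, 0))
    ys_src = slice(max(-dy, 0), h + min(-dy, 0))
    out[ys_dst, xs_dst] = img[ys_src, xs_src]
    return out


def _boxsum(a: np.ndarray, size: int) -> np.ndarray:
    """Exact integer sum over a centred size x size window (zero padded)."""
    r = size // 2
    p = np.pad(a.astype(np.int64), r)
    c = p.cumsum(axis=0).cumsum(axis=1)
    c = np.pad(c, ((1, 0), (1, 0)))
    return c[size:, size:] - c[:-size, size:] - c[size:, :-size] + c[:-size, :-size]


@register_backend("block")
def block_matching_flow(
    prev: np.ndarray, cur: np.ndarray, block_size: int = 5, search_radius: int = 5
) -> FlowField:
    """Exhaustive integer block matching (the reference backend).

    For every pixel of ``cur`` the integer displacement minimising the sum
    of absolute differences between its centred block and the block at the
    back-shifted position in ``prev`` is selected.  Ties go to the smallest
    displacement magnitude, then to row-major candidate order, so a static
    scene yields an exactly zero field.
    """
    if block_size < 1 or block_size % 2 == 0:
        raise ConfigurationError("block_size must be an odd positive integer")
    if search_radius < 0:
        raise ConfigurationError("search_radius must be non-negative")
    prev_i = prev.astype(np.int16)
    cur_i = cur.astype(np.int16)
    r = search_radius
    candidates = [(dx, dy) for dy in range(-r, r + 1) for dx in range(-r, r + 1)]
    order = sorted(range(len(candidates)), key=lambda i: (candidates[i][0] ** 2 + candidates[i][1] ** 2, i))
    best = np.full(prev.shape, np.iinfo(np.int64).max, dtype=np.int64)
    u = np.zeros(prev.shape, dtype=np.int64)
    v = np.zeros(prev.shape, dtype=np.int64)
    for i in order:
        dx, dy = candidates[i]
        sad = _boxsum(np.abs(cur_i - _shift(prev_i, dx, dy)), block_size)
        better = sad < best
        best[better] = sad[better]
        u[better] = dx
        v[better] = dy
    return FlowField(u=u.astype(float), v=v.astype(float))


@register_backend("ilk")
def ilk_flow(prev: np.ndarray, cur: np.ndarray, **params) -> FlowField:
    """Iterative Lucas–Kanade dense flow (scikit-image).

    skimage returns (row, col) components already oriented prev -> cur.
    """
    from skimage.registration import optical_flow_ilk

    vr, uc = optical_flow_ilk(prev.astype(float), cur.astype(float), **params)
    return FlowField(u=uc, v=vr)


# ---------------------------------------------------------------------------
# activity

def frame_activity(flow: FlowField, mask: np.ndarray) -> float:
    """Mean speed over masked (pig) pixels for one frame pair."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != flow.shape:
        raise FormatError(f"mask shape {mask.shape} != flow shape {flow.shape}")
    if not mask.any():
        raise EmptyMaskError("no pig pixels in mask; frame is invalid for activity")
    return float(flow.speed()[mask].mean())


def activity_series(
    frames: np.ndarray | Sequence[np.ndarray],
    masks: np.ndarray | Sequence[np.ndarray],
    backend: str = "block",
    gondola_id: str = "",
    fps: float = 24.0,
    **params,
) -> ActivitySeries:
    """Per-frame activity for a whole video.

    ``masks`` must supply one mask per frame; the value for the pair
    ``(t-1, t)`` is averaged over the mask of frame ``t``.
    """
    n = len(frames)
    if len(masks) != n:
        raise ContractViolation(f"{len(masks)} masks for {n} frames")
    if n < 2:
        raise FormatError("need at least two frames for an activity series")
    values = np.empty(n - 1)
    for t in range(1, n):
        fl = compute_flow(frames[t - 1], frames[t], backend=backend, **params)
        values[t - 1] = frame_activity(fl, masks[t])
    return ActivitySeries(gondola_id=gondola_id, values=values, fps=fps)
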