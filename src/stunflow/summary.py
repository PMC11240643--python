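"""Per-gondola window statistics of the activity series.

Two windows are analysed per gondola, both starting at the manually
annotated first response: up to the first loss of posture (FLOP) and up to
the last (LLOP).  Windows are half-open ``[start, end)`` in frame indices,
so the collapse frame itself is excluded.  Two statistics are computed per
window: the mean activity, and the summed activity of "high-activity"
frames — frames whose activity exceeds the median over the pooled
first-response-to-LLOP frames of *all* gondolas in the dataset (a
dataset-relative threshold, recomputed per analysis).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import AnalysisError, DataError
from .flow import ActivitySeries

__all__ = [
    "GondolaRecord",
    "global_median_threshold",
    "mean_activity",
    "high_activity_sum",
    "summarize_gondola",
    "summarize_dataset",
]


@dataclass
class GondolaRecord:
    """Events and summary statistics for one gondola.

    Event fields are frame indices; ``lop_times`` (seconds from first
    response, one per pig) is attached only for gondolas where individual
    animals could be scored — the baseline subset.
    """

    gondola_id: str
    group_size: int
    t_first_response: int
    t_flop: int
    t_llop: int
    mean_activity_flop: float | None = None
    mean_activity_llop: float | None = None
    high_activity_sum_flop: float | None = None
    high_activity_sum_llop: float | None = None
    lop_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.t_first_response <= self.t_flop <= self.t_llop:
            raise DataError(
                f"{self.gondola_id}: event order violated "
                f"(fr={self.t_first_response}, flop={self.t_flop}, llop={self.t_llop})"
            )
        if self.lop_times is not None:
            self.lop_times = np.asarray(self.lop_times, dtype=float)
            if len(self.lop_times) != self.group_size:
                raise DataError(f"{self.gondola_id}: expected one LOP time per pig")


def global_median_threshold(
    series: Sequence[ActivitySeries], records: Sequence[GondolaRecord]
) -> float:
    """Median activity over the pooled ``[first response, LLOP)`` frames.

    This is the dataset-wide high-activity threshold; the even-count median
    is the mean of the central pair.
    """
    pooled = [s.window(r.t_first_response, r.t_llop) for s, r in zip(series, records, strict=True)]
    if not pooled:
        raise AnalysisError("no gondolas to pool an activity median over")
    return float(np.median(np.concatenate(pooled)))


def mean_activity(series: ActivitySeries, t_start: int, t_end: int) -> float:
    """Arithmetic mean activity over frames in ``[t_start, t_end)``."""
    return float(series.window(t_start, t_end).mean())


def high_activity_sum(series: ActivitySeries, t_start: int, t_end: int, threshold: float) -> float:
    """Sum of window activity values strictly above ``threshold``."""
    w = series.window(t_start, t_end)
    return float(w[w > threshold].sum())


def summarize_gondola(
    series: ActivitySeries, record: GondolaRecord, threshold: float
) -> GondolaRecord:
    """Fill the four window statistics of ``record`` in place and return it."""
    fr = record.t_first_response
    record.mean_activity_flop = mean_activity(series, fr, record.t_flop)
    record.mean_activity_llop = mean_activity(series, fr, record.t_llop)
    record.high_activity_sum_flop = high_activity_sum(series, fr, record.t_flop, threshold)
    record.high_activity_sum_llop = high_activity_sum(series, fr, record.t_llop, threshold)
    return record


def summarize_dataset(
    series: Sequence[ActivitySeries], records: Sequence[GondolaRecord]
) -> tuple[list[GondolaRecord], float]:
    """Threshold over the whole dataset, then per-gondola statistics."""
    thr = global_median_threshold(series, records)
    return [summarize_gondola(s, r, thr) for s, r in zip(series, records, strict=True)], thr
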