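"""Simulated expected time to last loss of posture (simLLOP).

Directly comparing the observed time until the *last* animal in a gondola
collapses (LLOP) across group sizes is biased: the expected maximum of k
draws grows with k even when individuals are unaffected by group size.  The
reference distribution is therefore simulated from a baseline of
individually scored LOP times (collected in sparsely stocked gondolas):
for each observed gondola of size k, draw k baseline times and keep their
maximum.  The observed LLOP sample is then compared to the simulated one
with a Mann–Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, ParameterError
from .stats import TestResult, mann_whitney_u

__all__ = ["BaselineLOP", "SimLLOPResult", "simulate_llop", "compare_llop"]


@dataclass
class BaselineLOP:
    """Individual times (s) from first response to loss of posture."""

    times: np.ndarray
    source_group_sizes: tuple[int, ...] = (3, 4)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size == 0:
            raise DataError("baseline is empty")
        if (self.times <= 0).any():
            raise DataError("baseline LOP times must be positive")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class SimLLOPResult:
    """Simulated LLOP values for one group size (one per observed gondola)."""

    group_size: int
    simulated: np.ndarray
    n_observed: int
    seed: int

    def __post_init__(self) -> None:
        self.simulated = np.asarray(self.simulated, dtype=float)
        if len(self.simulated) != self.n_observed:
            raise DataError("one simulated value per observed gondola is required")


def simulate_llop(
    baseline: BaselineLOP,
    group_size: int,
    n_observed: int,
    seed: int = 0,
    replace: bool = True,
) -> SimLLOPResult:
    """Bootstrap the distribution of the within-gondola maximum.

    Each replicate draws ``group_size`` baseline times uniformly (with
    replacement by default) and records the maximum; ``n_observed``
    replicates match the size of the observed LLOP sample.
    """
    if group_size < 1:
        raise ParameterError("group_size must be >= 1")
    if n_observed < 1:
        raise ParameterError("n_observed must be >= 1")
    if not replace and group_size > len(baseline):
        raise ParameterError("cannot draw without replacement beyond the baseline size")
    rng = np.random.default_rng(seed)
    if replace:
        draws = rng.choice(baseline.times, size=(n_observed, group_size), replace=True)
    else:
        draws = np.stack(
            [rng.choice(baseline.times, size=group_size, replace=False) for _ in range(n_observed)]
        )
    return SimLLOPResult(
        group_size=group_size,
        simulated=draws.max(axis=1),
        n_observed=n_observed,
        seed=seed,
    )


def compare_llop(
    observed: np.ndarray, result: SimLLOPResult, alternative: str = "two-sided"
) -> TestResult:
    """Mann–Whitney U test of observed LLOP against the simulated sample."""
    observed = np.asarray(observed, dtype=float)
    return mann_whitney_u(observed, result.simulated, alternative=alternative)
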