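"""Simulation experiments validating the statistical pipeline.

Two experiments, both over many independently seeded synthetic datasets in
the fast kinematic mode:

* **Type-I calibration** — under the null model (no density effect) the
  LLOP-vs-simLLOP tests and the pairwise activity tests should reject at
  the nominal 5% level.  The pairwise family is evaluated on the
  FLOP-window mean activity: that is the one window statistic whose
  distribution is group-size invariant under the null (LLOP-window
  statistics mix induction and post-collapse phases in group-size-dependent
  proportions and are *expected* to differ across group sizes even without
  a density effect).
* **Pattern recovery** — with a configured stocking-density effect on the
  large groups, the analysis should reproduce the study's significance
  pattern: observed LLOP exceeding simLLOP only for groups of 7 and 8, and
  both activity statistics separating 7/8 from 3/4 while 3 vs 4 stays
  non-significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .flow import ActivitySeries
from .llop import BaselineLOP, compare_llop, simulate_llop
from .pipeline import records_from_samples
from .stats import pairwise_comparisons
from .summary import mean_activity, summarize_dataset
from .synthetic import ScenarioConfig, generate_dataset

__all__ = [
    "DENSITY_EFFECT_DEMO",
    "CALIBRATION_COUNTS",
    "type_i_calibration",
    "pattern_recovery",
]

#: Stocking-density effect used in the recovery experiment: pigs in densely
#: stocked gondolas take 5 s longer to lose posture and move 1.5x faster
#: during induction.  The magnitudes are chosen a priori to represent the
#: strong effects the study reports (p < 0.001 at its sample sizes): the
#: LOP shift is ~1.3 baseline SDs and the activity gain is far larger than
#: between-gondola variation in mean activity.
DENSITY_EFFECT_DEMO: dict[int, dict[str, float]] = {
    7: {"density_lop_shift": 5.0, "density_activity_gain": 1.5},
    8: {"density_lop_shift": 5.0, "density_activity_gain": 1.5},
}

#: Reduced-scale design for calibration runs: ten gondolas per group size.
CALIBRATION_COUNTS: dict[int, int] = {3: 10, 4: 10, 7: 10, 8: 10}


def _llop_and_pairwise(samples, seed: int, alpha: float):
    """Raw p-values of the two test families for one dataset."""
    series = [s.truth.activity_series(s.gondola_id) for s in samples]
    records = records_from_samples(samples)
    for r, s in zip(records, series):
        r.mean_activity_flop = mean_activity(s, r.t_first_response, r.t_flop)
    fps = samples[0].config.fps
    baseline = BaselineLOP(
        np.concatenate([r.lop_times for r in records if r.group_size in (3, 4)])
    )
    group_sizes = sorted({r.group_size for r in records})
    root = np.random.SeedSequence(seed)
    llop_p = {}
    for k in group_sizes:
        observed = np.array(
            [(r.t_llop - r.t_first_response) / fps for r in records if r.group_size == k]
        )
        sim_seed = int(root.spawn(1)[0].generate_state(1)[0] % (2**31))
        sim = simulate_llop(baseline, k, n_observed=len(observed), seed=sim_seed)
        llop_p[k] = compare_llop(observed, sim).p_raw
    pair = pairwise_comparisons(records, metric="mean", window="flop")
    pair_p = {p: t.p_raw for p, t in zip(pair.pairs, pair.tests)}
    return llop_p, pair_p


@dataclass
class CalibrationResult:
    n_replicates: int
    alpha: float
    llop_rejections: int = 0
    llop_tests: int = 0
    pairwise_rejections: int = 0
    pairwise_tests: int = 0

    @property
    def llop_rate(self) -> float:
        return self.llop_rejections / self.llop_tests

    @property
    def pairwise_rate(self) -> float:
        return self.pairwise_rejections / self.pairwise_tests


def type_i_calibration(
    n_replicates: int = 1000,
    counts: Mapping[int, int] | None = None,
    template: ScenarioConfig | None = None,
    alpha: float = 0.05,
    seed: int = 0,
) -> CalibrationResult:
    """Null rejection rates of both test families at level ``alpha``."""
    counts = dict(counts or CALIBRATION_COUNTS)
    template = template or ScenarioConfig()
    root = np.random.SeedSequence(seed)
    out = CalibrationResult(n_replicates=n_replicates, alpha=alpha)
    for _ in range(n_replicates):
        rep_seed = int(root.spawn(1)[0].generate_state(1)[0] % (2**31))
        samples = generate_dataset(counts, template, seed=rep_seed, mode="kinematic")
        llop_p, pair_p = _llop_and_pairwise(samples, rep_seed, alpha)
        out.llop_tests += len(llop_p)
        out.llop_rejections += sum(p < alpha for p in llop_p.values())
        out.pairwise_tests += len(pair_p)
        out.pairwise_rejections += sum(p < alpha for p in pair_p.values())
    return out


def _replicate_pattern(samples, seed: int, alpha: float) -> bool:
    """Does one dataset reproduce the study's significance pattern?

    Checked: LLOP > simLLOP significant (raw p) for groups 7 and 8 only;
    for both activity statistics on the FLOP window (Bonferroni adjusted
    over the six pairs), every 3/4-vs-7/8 pair significant and 3-vs-4 not.
    """
    series = [s.truth.activity_series(s.gondola_id) for s in samples]
    records = records_from_samples(samples)
    records, _thr = summarize_dataset(series, records)
    fps = samples[0].config.fps
    baseline = BaselineLOP(
        np.concatenate([r.lop_times for r in records if r.group_size in (3, 4)])
    )
    root = np.random.SeedSequence(seed)
    llop_sig = {}
    for k in sorted({r.group_size for r in records}):
        observed = np.array(
            [(r.t_llop - r.t_first_response) / fps for r in records if r.group_size == k]
        )
        sim_seed = int(root.spawn(1)[0].generate_state(1)[0] % (2**31))
        sim = simulate_llop(baseline, k, n_observed=len(observed), seed=sim_seed)
        llop_sig[k] = compare_llop(observed, sim).p_raw < alpha
    if not (llop_sig[7] and llop_sig[8] and not llop_sig[3] and not llop_sig[4]):
        return False
    cross = [(3, 7), (3, 8), (4, 7), (4, 8)]
    for metric in ("mean", "high_sum"):
        pair = pairwise_comparisons(records, metric=metric, window="flop")
        padj = {p: t.p_adjusted for p, t in zip(pair.pairs, pair.tests)}
        if padj[(3, 4)] < alpha:
            return False
        if any(padj[p] >= alpha for p in cross):
            return False
    return True


def pattern_recovery(
    n_replicates: int = 50,
    counts: Mapping[int, int] | None = None,
    template: ScenarioConfig | None = None,
    effect: Mapping[int, Mapping[str, float]] | None = None,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of replicate datasets reproducing the significance pattern."""
    counts = dict(counts or CALIBRATION_COUNTS)
    template = template or ScenarioConfig()
    effect = effect or DENSITY_EFFECT_DEMO
    root = np.random.SeedSequence(seed)
    hits = 0
    for _ in range(n_replicates):
        rep_seed = int(root.spawn(1)[0].generate_state(1)[0] % (2**31))
        samples = generate_dataset(
            counts, template, seed=rep_seed, mode="kinematic", group_overrides=effect
        )
        hits += _replicate_pattern(samples, rep_seed, alpha)
    return hits / n_replicates
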