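"""End-to-end orchestration: simulate → segment → flow → summarise → compare.

The in-memory entry point is :func:`analyze_samples`, which the analysis
scripts, the test-suite and the disk-based runner all share.  Events (first
response, FLOP, LLOP) always enter as annotations — on synthetic data they
come from the generator's ground truth; the pipeline never infers them from
video.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as sfio
from .errors import AnalysisError, ConfigurationError, DataError
from .flow import ActivitySeries, activity_series
from .llop import BaselineLOP, SimLLOPResult, compare_llop, simulate_llop
from .segmentation import threshold_provider, validate_masks
from .stats import TestResult, comparison_table, pairwise_comparisons
from .summary import GondolaRecord, summarize_dataset
from .synthetic import (
    STUDY_GROUP_COUNTS,
    GondolaSample,
    ScenarioConfig,
    generate_dataset,
)

log = logging.getLogger("stunflow")

__all__ = [
    "RunConfig",
    "AnalysisResult",
    "records_from_samples",
    "analyze_samples",
    "run_simulate",
    "run_analyze",
]


@dataclass
class RunConfig:
    """Declarative configuration of a full run."""

    out_dir: str = "runs/demo"
    counts: dict[int, int] = field(default_factory=lambda: dict(STUDY_GROUP_COUNTS))
    scenario: dict = field(default_factory=dict)
    density_effect: dict[int, dict[str, float]] = field(default_factory=dict)
    backend: str = "block"
    backend_params: dict = field(default_factory=dict)
    segmentation_threshold: float = 50
    use_ground_truth_masks: bool = False
    baseline_sizes: tuple[int, ...] = (3, 4)
    family_size: int | None = None
    seed: int = 0
    plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.counts = {int(k): int(v) for k, v in cfg.counts.items()}
        cfg.density_effect = {int(k): dict(v) for k, v in cfg.density_effect.items()}
        return cfg

    def scenario_config(self) -> ScenarioConfig:
        return ScenarioConfig(**self.scenario)

    def parameter_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class AnalysisResult:
    """Everything one analysed dataset yields."""

    records: list[GondolaRecord]
    high_activity_threshold: float
    baseline: BaselineLOP
    llop_observed: dict[int, np.ndarray]
    llop_simulated: dict[int, SimLLOPResult]
    llop_tests: dict[int, TestResult]
    tables: dict[str, pd.DataFrame]

    def records_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gondola_id": [r.gondola_id for r in self.records],
                "group_size": [r.group_size for r in self.records],
                "t_first_response_frame": [r.t_first_response for r in self.records],
                "t_flop_frame": [r.t_flop for r in self.records],
                "t_llop_frame": [r.t_llop for r in self.records],
                "mean_activity_flop": [r.mean_activity_flop for r in self.records],
                "mean_activity_llop": [r.mean_activity_llop for r in self.records],
                "high_sum_flop": [r.high_activity_sum_flop for r in self.records],
                "high_sum_llop": [r.high_activity_sum_llop for r in self.records],
            }
        )


def records_from_samples(samples: Sequence[GondolaSample]) -> list[GondolaRecord]:
    """Ground-truth annotations of synthetic gondolas as analysis records."""
    return [
        GondolaRecord(
            gondola_id=s.gondola_id,
            group_size=s.group_size,
            t_first_response=s.truth.t_first_response,
            t_flop=s.truth.flop_frame,
            t_llop=s.truth.llop_frame,
            lop_times=s.truth.lop_times,
        )
        for s in samples
    ]


def _series_for_sample(
    sample: GondolaSample,
    backend: str,
    backend_params: Mapping,
    segmentation_threshold: float,
    use_ground_truth_masks: bool,
) -> ActivitySeries:
    if sample.frames is None:
        return sample.truth.activity_series(sample.gondola_id)
    if use_ground_truth_masks:
        masks = validate_masks(sample.frames, sample.truth.masks)
    else:
        masks = threshold_provider(segmentation_threshold)(sample.frames)
    return activity_series(
        sample.frames,
        masks,
        backend=backend,
        gondola_id=sample.gondola_id,
        fps=sample.config.fps,
        **backend_params,
    )


def analyze_samples(
    samples: Sequence[GondolaSample],
    backend: str = "block",
    backend_params: Mapping | None = None,
    segmentation_threshold: float = 50,
    use_ground_truth_masks: bool = False,
    baseline_sizes: Sequence[int] = (3, 4),
    family_size: int | None = None,
    seed: int = 0,
) -> AnalysisResult:
    """Run the full analysis on generated gondolas.

    Rendered samples go through segmentation and optical flow; unrendered
    (kinematic) samples use their ground-truth activity directly.  The
    baseline for the simLLOP comparison pools the individual LOP times of
    the small-group gondolas (default sizes 3 and 4), and one simulated
    LLOP sample of matching size is generated per observed group size.
    """
    if not samples:
        raise DataError("no gondolas to analyze")
    backend_params = dict(backend_params or {})
    series = [
        _series_for_sample(
            s, backend, backend_params, segmentation_threshold, use_ground_truth_masks
        )
        for s in samples
    ]
    records = records_from_samples(samples)
    records, threshold = summarize_dataset(series, records)
    log.info("summarised %d gondolas; high-activity threshold %.4f", len(records), threshold)

    baseline_times = np.concatenate(
        [r.lop_times for r in records if r.group_size in tuple(baseline_sizes)]
        or [np.empty(0)]
    )
    baseline = BaselineLOP(times=baseline_times, source_group_sizes=tuple(baseline_sizes))

    group_sizes = sorted({r.group_size for r in records})
    fps = samples[0].config.fps
    observed = {
        k: np.array(
            [(r.t_llop - r.t_first_response) / fps for r in records if r.group_size == k]
        )
        for k in group_sizes
    }
    root = np.random.SeedSequence(seed)
    llop_sim: dict[int, SimLLOPResult] = {}
    llop_tests: dict[int, TestResult] = {}
    for k in group_sizes:
        sim_seed = int(root.spawn(1)[0].generate_state(1)[0] % (2**31))
        llop_sim[k] = simulate_llop(baseline, k, n_observed=len(observed[k]), seed=sim_seed)
        llop_tests[k] = compare_llop(observed[k], llop_sim[k])

    tables = {
        metric: comparison_table(records, metric=metric, family_size=family_size)
        for metric in ("mean", "high_sum")
    }
    return AnalysisResult(
        records=records,
        high_activity_threshold=threshold,
        baseline=baseline,
        llop_observed=observed,
        llop_simulated=llop_sim,
        llop_tests=llop_tests,
        tables=tables,
    )


# ---------------------------------------------------------------------------
# disk-based runs

def run_simulate(config: RunConfig, mode: str = "frames") -> Path:
    """Generate a dataset and write it under ``config.out_dir``.

    Writes per-gondola frame and mask PNG sequences (when rendered), the
    annotations CSV, the baseline CSV of individual LOP times from the
    small-group gondolas, and a manifest with seeds and a parameter hash.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples = generate_dataset(
        config.counts,
        template=config.scenario_config(),
        seed=config.seed,
        mode=mode,
        group_overrides=config.density_effect or None,
    )
    ann_rows, base_rows = [], []
    for s in samples:
        if s.frames is not None:
            gdir = out / "gondolas" / s.gondola_id
            sfio.write_image_sequence(gdir / "frames", s.frames)
            sfio.write_image_sequence(gdir / "masks", s.truth.masks, prefix="mask")
        ann_rows.append(
            dict(
                gondola_id=s.gondola_id,
                group_size=s.group_size,
                t_first_response_frame=s.truth.t_first_response,
                t_flop_frame=s.truth.flop_frame,
                t_llop_frame=s.truth.llop_frame,
            )
        )
        if s.group_size in config.baseline_sizes:
            for j, t in enumerate(s.truth.lop_times):
                base_rows.append(
                    dict(pig_id=f"{s.gondola_id}_p{j}", gondola_id=s.gondola_id, lop_seconds=t)
                )
    sfio.write_table(
        out / "annotations.csv",
        pd.DataFrame(ann_rows, columns=sfio.SCHEMAS["annotations"]),
        "annotations",
        config.seed,
    )
    sfio.write_table(
        out / "baseline.csv",
        pd.DataFrame(base_rows, columns=sfio.SCHEMAS["baseline"]),
        "baseline",
        config.seed,
    )
    manifest = {
        "schema_version": sfio.SCHEMA_VERSION,
        "seed": config.seed,
        "parameter_hash": config.parameter_hash(),
        "mode": mode,
        "counts": {str(k): v for k, v in sorted(config.counts.items())},
        "n_gondolas": len(samples),
        "n_pigs": int(sum(s.group_size for s in samples)),
        "gondola_seeds": {s.gondola_id: s.config.seed for s in samples},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("simulated %d gondolas (%d pigs) into %s", len(samples), manifest["n_pigs"], out)
    return out


def run_analyze(config: RunConfig) -> AnalysisResult:
    """Analyse a dataset previously written by :func:`run_simulate`."""
    out = Path(config.out_dir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise ConfigurationError(f"no manifest.json under {out}; run simulate first")
    manifest = json.loads(manifest_path.read_text())
    ann = sfio.read_table(out / "annotations.csv", "annotations")
    base = sfio.read_table(out / "baseline.csv", "baseline")
    if ann.empty:
        raise DataError("dataset contains no gondolas")

    fps = config.scenario_config().fps
    series_list, records = [], []
    for row in ann.itertuples(index=False):
        gdir = out / "gondolas" / row.gondola_id
        if not (gdir / "frames").exists():
            warnings.warn(f"{row.gondola_id}: frames missing; gondola skipped")
            continue
        frames = sfio.read_image_sequence(gdir / "frames")
        if config.use_ground_truth_masks:
            masks = sfio.read_image_sequence(gdir / "masks", prefix="mask", as_mask=True)
        else:
            masks = threshold_provider(config.segmentation_threshold)(frames)
        series_list.append(
            activity_series(
                frames,
                masks,
                backend=config.backend,
                gondola_id=row.gondola_id,
                fps=fps,
                **config.backend_params,
            )
        )
        records.append(
            GondolaRecord(
                gondola_id=row.gondola_id,
                group_size=int(row.group_size),
                t_first_response=int(row.t_first_response_frame),
                t_flop=int(row.t_flop_frame),
                t_llop=int(row.t_llop_frame),
            )
        )
    if not records:
        raise DataError("no analysable gondolas found")
    records, threshold = summarize_dataset(series_list, records)

    baseline = BaselineLOP(times=base["lop_seconds"].to_numpy())
    group_sizes = sorted({r.group_size for r in records})
    observed = {
        k: np.array(
            [(r.t_llop - r.t_first_response) / fps for r in records if r.group_size == k]
        )
        for k in group_sizes
    }
    root = np.random.SeedSequence(config.seed)
    llop_sim, llop_tests = {}, {}
    sim_rows = []
    for k in group_sizes:
        sim_seed = int(root.spawn(1)[0].generate_state(1)[0] % (2**31))
        llop_sim[k] = simulate_llop(baseline, k, n_observed=len(observed[k]), seed=sim_seed)
        llop_tests[k] = compare_llop(observed[k], llop_sim[k])
        for j, v in enumerate(llop_sim[k].simulated):
            sim_rows.append(
                dict(group_size=k, replicate=j, sim_llop_seconds=v, seed=sim_seed)
            )

    result = AnalysisResult(
        records=records,
        high_activity_threshold=threshold,
        baseline=baseline,
        llop_observed=observed,
        llop_simulated=llop_sim,
        llop_tests=llop_tests,
        tables={
            m: comparison_table(records, metric=m, family_size=config.family_size)
            for m in ("mean", "high_sum")
        },
    )
    sfio.write_table(out / "records.csv", result.records_frame(), "records", config.seed)
    sfio.write_table(out / "simllop.csv", pd.DataFrame(sim_rows), "simllop", config.seed)
    for metric, tbl in result.tables.items():
        sfio.write_table(out / f"comparisons_{metric}.csv", tbl, "comparisons", config.seed)
    act_rows = pd.concat(
        [
            pd.DataFrame(
                {
                    "gondola_id": s.gondola_id,
                    "frame_idx": np.arange(s.start_frame, s.start_frame + len(s)),
                    "activity_px_per_frame": s.values,
                }
            )
            for s in series_list
        ],
        ignore_index=True,
    )
    sfio.write_table(out / "activity.csv", act_rows, "activity", config.seed)
    if config.plots:
        from . import report

        report.write_report(result, out / "report")
    return result
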