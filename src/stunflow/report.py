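"""Box-plot report of an analysed dataset.

Three figures: observed LLOP against its simulated expectation per group
size, mean activity per group size (both windows), and the sum of high
activity per group size (both windows), annotated with significance
letters.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .pipeline import AnalysisResult
from .stats import pairwise_comparisons

__all__ = ["write_report"]


def _letters_for(result: AnalysisResult, metric: str, window: str) -> dict[int, str]:
    return pairwise_comparisons(result.records, metric=metric, window=window).letters


def _boxgrid(result: AnalysisResult, metric: str, attr_flop: str, attr_llop: str, title: str):
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5), sharey=True)
    groups = sorted({r.group_size for r in result.records})
    for ax, window, attr in zip(axes, ("flop", "llop"), (attr_flop, attr_llop)):
        data = [
            [getattr(r, attr) for r in result.records if r.group_size == g] for g in groups
        ]
        ax.boxplot(data, tick_labels=[str(g) for g in groups])
        letters = _letters_for(result, metric, window)
        top = max(max(d) for d in data if d)
        for i, g in enumerate(groups, start=1):
            ax.text(i, top * 1.04, letters[g], ha="center", fontsize=9)
        ax.set_xlabel("pigs per gondola")
        ax.set_title(window.upper())
    axes[0].set_ylabel(title)
    fig.tight_layout()
    return fig


def write_report(result: AnalysisResult, out_dir: str | Path) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    groups = sorted(result.llop_observed)
    fig, ax = plt.subplots(figsize=(6, 3.5))
    data, labels = [], []
    for g in groups:
        data.append(result.llop_simulated[g].simulated)
        labels.append(f"sim {g}")
        data.append(result.llop_observed[g])
        labels.append(f"obs {g}")
    ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel("time to last LOP (s)")
    for i, g in enumerate(groups):
        p = result.llop_tests[g].p_raw
        ax.text(2 * i + 1.5, ax.get_ylim()[1] * 0.97, f"p={p:.3g}", ha="center", fontsize=8)
    fig.tight_layout()
    path = out / "llop_vs_simllop.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    for metric, (a_f, a_l), title, name in [
        ("mean", ("mean_activity_flop", "mean_activity_llop"), "mean activity (px/frame)", "mean_activity.png"),
        ("high_sum", ("high_activity_sum_flop", "high_activity_sum_llop"), "sum of high activity", "high_activity.png"),
    ]:
        fig = _boxgrid(result, metric, a_f, a_l, title)
        path = out / name
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
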