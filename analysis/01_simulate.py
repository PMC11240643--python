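#!/usr/bin/env python
"""Generate the synthetic datasets the downstream analyses consume.

Two artifacts:

* the study-scale bookkeeping dataset — 10/57/59/77 gondolas of
  3/4/7/8 pigs (203 gondolas, 1287 pigs), events only; its manifest is the
  record of the experimental design;
* a small rendered demo (two gondolas per group size, 64 x 64 px arena)
  whose PNG frames and masks feed the video pipeline in the next script.

Rendered image data goes under scratch/ (it is bulky and reproducible);
manifests and annotation tables go under results/.
"""

import json
import shutil
from pathlib import Path

from stunflow.pipeline import RunConfig, run_simulate

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

DEMO_SCENARIO = dict(arena_width=64, arena_height=64, pig_axes=(6, 4))


def main() -> None:
    RESULTS.mkdir(exist_ok=True)

    full = RunConfig(out_dir=str(SCRATCH / "study_scale"), seed=0)
    run_simulate(full, mode="events")
    manifest = json.loads((SCRATCH / "study_scale" / "manifest.json").read_text())
    (RESULTS / "study_scale_manifest.json").write_text(json.dumps(manifest, indent=2))
    print(f"study-scale dataset: {manifest['n_gondolas']} gondolas, "
          f"{manifest['n_pigs']} pigs")

    demo = RunConfig(
        out_dir=str(SCRATCH / "video_demo"),
        counts={3: 2, 4: 2, 7: 2, 8: 2},
        scenario=DEMO_SCENARIO,
        seed=1,
    )
    out = run_simulate(demo, mode="frames")
    for name in ("annotations.csv", "baseline.csv", "manifest.json"):
        shutil.copy(out / name, RESULTS / f"video_demo_{name}")
    print(f"rendered demo: 8 gondolas under {out}")


if __name__ == "__main__":
    main()
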