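"""File formats: PNG image sequences and schema-checked CSV tables.

The canonical on-disk interchange is deliberately plain: gray-8 PNG
sequences with zero-padded frame numbers for video and masks, and CSV for
everything tabular.  Every CSV starts with comment lines recording the
schema version and the seed of the run that produced it.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import DataError, SchemaError

SCHEMA_VERSION = "1"

SCHEMAS: dict[str, list[str]] = {
    "annotations": [
        "gondola_id", "group_size",
        "t_first_response_frame", "t_flop_frame", "t_llop_frame",
    ],
    "records": [
        "gondola_id", "group_size",
        "t_first_response_frame", "t_flop_frame", "t_llop_frame",
        "mean_activity_flop", "mean_activity_llop",
        "high_sum_flop", "high_sum_llop",
    ],
    "baseline": ["pig_id", "gondola_id", "lop_seconds"],
    "activity": ["gondola_id", "frame_idx", "activity_px_per_frame"],
    "simllop": ["group_size", "replicate", "sim_llop_seconds", "seed"],
    "comparisons": ["group_a", "group_b", "p_flop", "p_llop", "method"],
}


# ---------------------------------------------------------------------------
# image sequences

def write_image_sequence(directory: str | Path, stack: np.ndarray, prefix: str = "frame") -> None:
    """Write a (n, h, w) uint8/bool stack as zero-padded gray-8 PNGs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, img in enumerate(stack):
        arr = (img.astype(np.uint8) * 255) if img.dtype == bool else img.astype(np.uint8)
        iio.imwrite(directory / f"{prefix}_{i:06d}.png", arr)


def read_image_sequence(directory: str | Path, prefix: str = "frame", as_mask: bool = False) -> np.ndarray:
    directory = Path(directory)
    paths = sorted(directory.glob(f"{prefix}_*.png"))
    if not paths:
        raise DataError(f"no {prefix}_*.png files in {directory}")
    stack = np.stack([iio.imread(p) for p in paths])
    return stack > 127 if as_mask else stack


# ---------------------------------------------------------------------------
# CSV tables

def write_table(path: str | Path, df: pd.DataFrame, schema: str, seed: int | None = None) -> None:
    columns = SCHEMAS[schema]
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing} for schema {schema!r}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# schema={schema} version={SCHEMA_VERSION} seed={seed}\n")
        df.to_csv(fh, index=False, columns=columns)


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    columns = SCHEMAS[schema]
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # malformed CSV
        raise SchemaError(f"{path}: cannot parse as CSV ({exc})") from exc
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    _validate_rows(df, schema, path)
    return df[columns]


def _validate_rows(df: pd.DataFrame, schema: str, path) -> None:
    def fail(mask: pd.Series, message: str) -> None:
        if mask.any():
            row = int(df.index[mask][0]) + 1  # 1-based data row
            raise SchemaError(f"{path}: row {row}: {message}")

    if schema == "baseline":
        fail(~(df["lop_seconds"] > 0), "lop_seconds must be positive")
    if schema in ("annotations", "records"):
        fail(~(df["group_size"] >= 1), "group_size must be >= 1")
        fail(
            ~(
                (df["t_first_response_frame"] <= df["t_flop_frame"])
                & (df["t_flop_frame"] <= df["t_llop_frame"])
            ),
            "event order must be first response <= FLOP <= LLOP",
        )
    if schema == "activity":
        fail(~(df["activity_px_per_frame"] >= 0), "activity must be non-negative")
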