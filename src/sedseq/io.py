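"""File-format helpers: TSV tables, TIFF images, JSON sidecars.

All inter-stage communication in the pipeline goes through these plain
formats so that stages can be rerun and inspected independently.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

COUNT_COLUMNS = ["transcript_id", "total", "sup", "pellet"]


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_counts(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"count table {path} is missing columns {missing}")
    return df


def write_image(image: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(image))
    return path


def read_image(path: str | Path) -> np.ndarray:
    img = tifffile.imread(path)
    if img.ndim == 3:  # project z-stacks: the statistics operate on 2-D planes
        img = img.max(axis=0)
    return img


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify) + "\n")
    return path


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
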