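"""Plain-text table formats used across the pipeline.

Histories travel as wide CSV (cell_id, then one ``t=<hours>`` column per
timepoint), detections and tracks as TSV, lineages and reports as JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_histories", "read_histories",
    "write_detections", "read_detections",
    "write_json", "read_json", "file_checksum",
]


def write_histories(histories: pd.DataFrame, path):
    out = histories.copy()
    out.columns = [f"t={float(c):g}" for c in out.columns]
    out.to_csv(path, index_label="cell_id")


def read_histories(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="cell_id")
    df.columns = [float(str(c).split("=", 1)[1]) for c in df.columns]
    return df


def write_detections(detections: pd.DataFrame, path):
    detections.to_csv(path, sep="\t", index=False)


def read_detections(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_json(obj, path):
    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
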