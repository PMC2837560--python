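"""Plain-text readers and writers for the pipeline's tabular formats.

Expression matrices travel as TSV with probes in rows and a header row of
sample IDs; sample annotations as two-column TSV (sample_id, group); models
and summaries as JSON. Long-format qPCR tables live in :mod:`sigrev.ddct`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

PROBE_INDEX_NAME = "probe_id"


class InputError(ValueError):
    """Raised when an on-disk input violates the format contract."""


def validate_matrix(m: pd.DataFrame) -> pd.DataFrame:
    """Check the expression-matrix invariants: finite values, unique IDs."""
    if m.shape[0] == 0 or m.shape[1] == 0:
        raise InputError("expression matrix is empty")
    if not m.index.is_unique:
        raise InputError("duplicate probe IDs in expression matrix")
    if not m.columns.is_unique:
        raise InputError("duplicate sample IDs in expression matrix")
    if not np.isfinite(m.to_numpy(dtype=float)).all():
        raise InputError("expression matrix contains non-finite values")
    return m


def read_matrix(path: str | Path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t", index_col=0)
    m.index.name = PROBE_INDEX_NAME
    return validate_matrix(m.astype(float))


def write_matrix(m: pd.DataFrame, path: str | Path) -> None:
    out = m.copy()
    out.index.name = PROBE_INDEX_NAME
    out.to_csv(path, sep="\t")


def read_annotation(path: str | Path) -> pd.Series:
    ann = pd.read_csv(path, sep="\t", index_col=0).iloc[:, 0]
    ann.index.name = "sample_id"
    ann.name = "group"
    if not ann.index.is_unique:
        raise InputError("duplicate sample IDs in annotation")
    return ann.astype(str)


def write_annotation(ann: pd.Series, path: str | Path) -> None:
    out = ann.rename("group")
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def check_annotation(m: pd.DataFrame, ann: pd.Series, min_group_size: int = 2) -> None:
    """Every matrix sample must carry exactly one group label."""
    missing = [s for s in m.columns if s not in ann.index]
    if missing:
        raise InputError(f"samples without group label: {missing}")
    counts = ann.loc[list(m.columns)].value_counts()
    small = counts[counts < min_group_size]
    if len(small):
        raise InputError(
            f"groups below the minimum size of {min_group_size}: "
            f"{dict(small)}"
        )


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
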