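"""Delimited-text I/O for cell tables and summaries.

Cell tables are UTF-8 CSV with a header row; metadata (seed, config hash,
package version) travels in ``#``-prefixed comment lines at the top of the
file so a table remains a single self-describing artifact.
"""

from __future__ import annotations

import hashlib
from typing import Mapping, Optional

import pandas as pd
import yaml

from . import __version__

_BOOLEAN_COLS = ["glyt2_positive", "chat_positive", "lhx1_positive",
                 "is_motoneuron"]


def config_hash(config_dict: Mapping) -> str:
    """Stable short hash of a configuration mapping."""
    canon = yaml.safe_dump(config_dict, sort_keys=True)
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()[:12]


def write_cells(cells: pd.DataFrame, path,
                metadata: Optional[Mapping[str, object]] = None) -> None:
    """Write a cell table as CSV with comment-line metadata."""
    meta = {"divtrace": __version__}
    if metadata:
        meta.update(metadata)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}={value}\n")
        cells.to_csv(fh, index=False)


def read_cells(path) -> pd.DataFrame:
    """Read a cell table written by :func:`write_cells` (or any CSV with
    the same columns); metadata lines are skipped and boolean/tri-state
    columns restored to nullable boolean dtype."""
    df = pd.read_csv(path, comment="#")
    for col in _BOOLEAN_COLS:
        if col in df.columns:
            df[col] = df[col].astype("boolean")
    if "is_motoneuron" in df.columns:
        df["is_motoneuron"] = df["is_motoneuron"].fillna(False).astype(bool)
    return df


def read_metadata(path) -> dict[str, str]:
    """Recover the ``key=value`` comment metadata from a table file."""
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta
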