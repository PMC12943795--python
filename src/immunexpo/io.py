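"""Delimited-table I/O conventions: TSV, header row, ``NA`` missing marker."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

NA_MARKER = "NA"


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    """Read a sample-by-feature TSV with ``NA`` as the missing marker."""
    return pd.read_csv(path, sep="\t", index_col=index_col,
                       na_values=[NA_MARKER], keep_default_na=False)


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", na_rep=NA_MARKER, index=True,
              index_label=df.index.name or "id")
    return path


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_coerce))
    return path


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def _coerce(o):
    try:
        return o.item()  # numpy scalars
    except AttributeError:
        if hasattr(o, "tolist"):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
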