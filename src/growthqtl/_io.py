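"""CSV read/write helpers with ``# key: value`` metadata headers.

All tabular outputs of the pipeline carry a small metadata block of
comment lines (seed, stage, thresholds) before the CSV header so that
every file is self-describing and reruns are auditable.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = ["write_table", "read_table", "read_metadata"]


def write_table(df: pd.DataFrame, path: str | Path, meta: Mapping[str, object] | None = None) -> None:
    """Write *df* as CSV, preceded by ``# key: value`` metadata lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = io.StringIO()
    for key, val in (meta or {}).items():
        buf.write(f"# {key}: {val}\n")
    df.to_csv(buf, index=False)
    path.write_text(buf.getvalue())


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` (metadata lines skipped)."""
    return pd.read_csv(path, comment="#", **kwargs)


def read_metadata(path: str | Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                key, val = body.split(":", 1)
                meta[key.strip()] = val.strip()
    return meta
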