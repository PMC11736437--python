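"""Tabular I/O with provenance headers and schema validation.

All command-line outputs are plain CSV with ``#``-prefixed comment lines
carrying provenance (package version, command configuration, seed), so
files stay grep-able, spreadsheet-safe and self-describing. Reading
validates column names and reports malformed rows with line numbers.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__

__all__ = ["write_table", "read_table", "SchemaError"]


class SchemaError(ValueError):
    """Raised when a table does not match the expected column schema."""


def write_table(df: pd.DataFrame, path, config: Optional[dict] = None) -> None:
    """Write a CSV atomically with a provenance comment header."""
    path = Path(path)
    header_lines = [f"# rmdyn version {__version__}"]
    if config:
        header_lines.append("# config " + json.dumps(config, sort_keys=True, default=str))
    tmp_fd, tmp_name = tempfile.mkstemp(dir=path.parent or Path("."), suffix=".tmp")
    try:
        with os.fdopen(tmp_fd, "w") as fh:
            for line in header_lines:
                fh.write(line + "\n")
            df.to_csv(fh, index=False)
        os.replace(tmp_name, path)
    except BaseException:
        if os.path.exists(tmp_name):
            os.unlink(tmp_name)
        raise


def read_table(path, required_columns: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Read a provenance-headered CSV, validating the expected columns."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file, no data rows") from None
    except pd.errors.ParserError as exc:
        raise SchemaError(f"{path}: malformed CSV: {exc}") from None
    if df.empty:
        raise SchemaError(f"{path}: table has no data rows")
    if required_columns is not None:
        missing = [c for c in required_columns if c not in df.columns]
        if missing:
            raise SchemaError(
                f"{path}: missing columns {missing}; expected {list(required_columns)}, "
                f"found {list(df.columns)}"
            )
    return df
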