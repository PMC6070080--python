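"""Delimited-text file formats with a versioned schema header line.

Every file this package writes starts with a ``# rdipw <kind> v1`` comment
line followed by an ordinary CSV with a header row; missing values are
empty fields. Times are in months from entry into care.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "write_table",
    "read_table",
    "write_fit_report",
    "read_fit_report",
    "SchemaError",
]

_SCHEMA_PREFIX = "# rdipw"


class SchemaError(ValueError):
    """File does not carry the expected schema header."""


def write_table(df: pd.DataFrame, path, kind: str) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"{_SCHEMA_PREFIX} {kind} v1\n")
        df.to_csv(fh, index=False)


def read_table(path, kind: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith(_SCHEMA_PREFIX):
            raise SchemaError(f"{path} lacks the '{_SCHEMA_PREFIX} ...' schema header")
        if kind is not None and f" {kind} " not in first:
            raise SchemaError(f"{path} is not an rdipw {kind} file: {first.strip()}")
        return pd.read_csv(fh)


def write_fit_report(report: dict, path, human_path=None) -> None:
    """Write a fit as a machine-readable key-value file (tab-separated),
    optionally also as an aligned human-readable text block."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{_SCHEMA_PREFIX} fit v1\n")
        for k, v in report.items():
            fh.write(f"{k}\t{v}\n")
    if human_path is not None:
        width = max(len(str(k)) for k in report)
        with open(human_path, "w", encoding="utf-8") as fh:
            for k, v in report.items():
                fh.write(f"{str(k):<{width}}  {v}\n")


def read_fit_report(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    out: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith(_SCHEMA_PREFIX):
            raise SchemaError(f"{path} lacks the schema header")
        for line in fh:
            if not line.strip():
                continue
            k, _, v = line.rstrip("\n").partition("\t")
            out[k] = v
    return out
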