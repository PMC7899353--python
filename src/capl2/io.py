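"""Tabular import and export (XLSX, CSV, optional SPSS SAV)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["import_table", "export_table"]

_FORMATS = ("xlsx", "csv", "sav")


def import_table(path: str | Path, sheet: str | None = None) -> pd.DataFrame:
    """Read a raw-data table from an XLSX workbook or CSV file.

    The header row supplies variable names.  Values are imported as-is;
    type coercion (numeric strings, clock strings) happens later inside the
    quiet validators, not at import time.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    suffix = path.suffix.lower().lstrip(".")
    if suffix == "csv":
        return pd.read_csv(path)
    if suffix == "xlsx":
        try:
            return pd.read_excel(path, sheet_name=sheet if sheet is not None else 0)
        except ValueError as exc:
            raise ValueError(f"cannot read sheet {sheet!r} from {path}: {exc}") from exc
    raise ValueError(f"unsupported input format {suffix!r} for {path}; expected csv or xlsx")


def export_table(table: pd.DataFrame, path: str | Path, format: str | None = None) -> Path:
    """Write a table to disk as xlsx, csv, or (optionally) SPSS sav.

    SAV export needs the optional ``pyreadstat`` dependency.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported export format {fmt!r}; expected one of {_FORMATS}")
    if fmt == "csv":
        table.to_csv(path, index=False)
    elif fmt == "xlsx":
        table.to_excel(path, index=False)
    else:
        try:
            import pyreadstat
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise RuntimeError(
                "SAV export requires the optional 'pyreadstat' dependency "
                "(pip install capl2[sav])"
            ) from exc
        pyreadstat.write_sav(table, str(path))
    return path
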