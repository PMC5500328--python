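"""Named append-only result tables plus a key/value variable store.

Tile processing steps are independent by design, so cross-tile state
(running totals, per-tile measurements, values another step will read
back) lives in a :class:`ResultsStore`: any number of named tables whose
rows are appended in processing order, and a variable store for scalars
and lists.  The store persists to plain text — one RFC 4180 CSV per
table and a JSON sidecar for variables — and survives across runs, so a
second pass (e.g. re-opening the most interesting tile) can read what a
first pass recorded.

Cell values are numbers or strings; a column missing from some rows
yields empty cells there.  The CSV header is the first-seen-order union
of row keys.  Round-tripping is lossless for strings, integers and
floats (full ``repr`` precision).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Any, Union

from .errors import MissingVariableError

__all__ = ["ResultsStore"]

Cell = Union[int, float, str]

VARIABLES_FILE = "_variables.json"

# File-name-safe, invertible table-name escaping: keep [A-Za-z0-9_-],
# percent-encode everything else (and '%' itself) as %XX.
_SAFE = set("abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789_-")


def _escape_table_name(name: str) -> str:
    out = []
    for ch in name:
        if ch in _SAFE:
            out.append(ch)
        else:
            out.extend(f"%{b:02X}" for b in ch.encode("utf-8"))
    return "".join(out)


def _unescape_table_name(escaped: str) -> str:
    raw = bytearray()
    i = 0
    while i < len(escaped):
        if escaped[i] == "%":
            raw.append(int(escaped[i + 1 : i + 3], 16))
            i += 3
        else:
            raw.append(ord(escaped[i]))
            i += 1
    return raw.decode("utf-8")


def _format_cell(value: Cell) -> str:
    if isinstance(value, bool):  # bools stored as ints to stay numeric
        return str(int(value))
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _parse_cell(text: str) -> Cell:
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        pass
    return text


class ResultsStore:
    """Append-only tables + variables, persisted under one folder."""

    def __init__(self, root: Union[str, Path]):
        self.root = Path(root)
        self.tables: dict[str, list[dict[str, Cell]]] = {}
        self.variables: dict[str, Any] = {}

    # -- tables ---------------------------------------------------------

    def append_row(self, table: str, row: dict[str, Cell]) -> None:
        """Append one row to ``table``, creating the table on first use.

        Earlier rows are never mutated; row order is append order.
        """
        if not table:
            raise ValueError("table name must be non-empty")
        if not row:
            raise ValueError("row must be non-empty")
        self.tables.setdefault(table, []).append(dict(row))

    def rows(self, table: str) -> list[dict[str, Cell]]:
        """All rows of ``table`` in append order ([] if absent)."""
        return [dict(r) for r in self.tables.get(table, [])]

    def n_rows(self, table: str) -> int:
        return len(self.tables.get(table, []))

    # -- variables ------------------------------------------------------

    def set_var(self, name: str, value: Any) -> None:
        """Set a scalar or list variable (overwrites any previous value)."""
        if not name:
            raise ValueError("variable name must be non-empty")
        self.variables[name] = value

    def get_var(self, name: str) -> Any:
        if name not in self.variables:
            raise MissingVariableError(f"variable not set: {name!r}")
        return self.variables[name]

    def has_var(self, name: str) -> bool:
        return name in self.variables

    # -- persistence ----------------------------------------------------

    def save(self) -> None:
        """Write every table as ``<name>.csv`` plus the variables sidecar.

        Headers are the first-seen-order union of row keys; cells missing
        from a row are written empty.
        """
        self.root.mkdir(parents=True, exist_ok=True)
        for name, rows in self.tables.items():
            columns: list[str] = []
            for row in rows:
                for key in row:
                    if key not in columns:
                        columns.append(key)
            path = self.root / f"{_escape_table_name(name)}.csv"
            with open(path, "w", newline="", encoding="utf-8") as fh:
                writer = csv.writer(fh)
                writer.writerow(columns)
                for row in rows:
                    writer.writerow(
                        [_format_cell(row[c]) if c in row else "" for c in columns]
                    )
        with open(self.root / VARIABLES_FILE, "w", encoding="utf-8") as fh:
            json.dump(self.variables, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, root: Union[str, Path]) -> "ResultsStore":
        """Load a store previously written by :meth:`save`.

        ``load(save(s))`` observationally equals ``s``: same tables, row
        order, cell values (numbers re-typed int/float), and variables.
        A missing folder yields an empty store rooted there.
        """
        store = cls(root)
        if not store.root.is_dir():
            return store
        for path in sorted(store.root.glob("*.csv")):
            name = _unescape_table_name(path.stem)
            with open(path, newline="", encoding="utf-8") as fh:
                reader = csv.reader(fh)
                try:
                    columns = next(reader)
                except StopIteration:
                    continue
                rows = []
                for record in reader:
                    row = {
                        c: _parse_cell(v)
                        for c, v in zip(columns, record)
                        if v != ""
                    }
                    rows.append(row)
            store.tables[name] = rows
        var_path = store.root / VARIABLES_FILE
        if var_path.exists():
            with open(var_path, encoding="utf-8") as fh:
                store.variables = json.load(fh)
        return store
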