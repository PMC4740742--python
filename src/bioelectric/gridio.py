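"""Delimited-text potential maps with commented metadata headers.

Snapshot files are plain whitespace-delimited matrices preceded by
``# key = value`` header lines (time, grid shape, parameters, a
parameter hash).  Values round-trip losslessly at full float precision.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np

__all__ = ["write_grid", "read_grid", "GridParseError", "parameter_hash"]


class GridParseError(ValueError):
    """Malformed snapshot file; carries the offending line number."""

    def __init__(self, path: Path | str, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.line_no = line_no


def parameter_hash(metadata: dict[str, Any]) -> str:
    """Short stable hash of a metadata mapping, for provenance headers."""
    payload = json.dumps(metadata, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_grid(path: Path | str, grid: np.ndarray, metadata: dict[str, Any] | None = None) -> Path:
    """Write a 2-D array as text with a commented header, full precision."""
    grid = np.atleast_2d(np.asarray(grid, dtype=float))
    if grid.ndim != 2:
        raise ValueError(f"grid must be 2-D, got ndim={grid.ndim}")
    path = Path(path)
    meta = dict(metadata or {})
    meta.setdefault("rows", grid.shape[0])
    meta.setdefault("cols", grid.shape[1])
    lines = [f"# {k} = {json.dumps(v, default=str)}" for k, v in meta.items()]
    body = "\n".join(" ".join(format(x, ".17g") for x in row) for row in grid)
    path.write_text("\n".join(lines) + "\n" + body + "\n")
    return path


def read_grid(path: Path | str) -> tuple[np.ndarray, dict[str, Any]]:
    """Read a grid file back into (array, metadata); inverse of write_grid."""
    path = Path(path)
    meta: dict[str, Any] = {}
    rows: list[list[float]] = []
    width: int | None = None
    for line_no, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if rows:
                raise GridParseError(path, line_no, "header line after data began")
            body = line.lstrip("#").strip()
            if "=" not in body:
                raise GridParseError(path, line_no, f"header line without '=': {raw!r}")
            key, _, value = body.partition("=")
            try:
                meta[key.strip()] = json.loads(value.strip())
            except json.JSONDecodeError:
                meta[key.strip()] = value.strip()
            continue
        try:
            row = [float(tok) for tok in line.split()]
        except ValueError as exc:
            raise GridParseError(path, line_no, f"non-numeric data: {exc}") from None
        if width is None:
            width = len(row)
        elif len(row) != width:
            raise GridParseError(path, line_no, f"ragged row: expected {width} values, got {len(row)}")
        rows.append(row)
    if not rows:
        raise GridParseError(path, 1, "file contains no data rows")
    return np.array(rows, dtype=float), meta
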