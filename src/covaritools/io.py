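"""Matrix and result I/O: CSV (optional single header row), NPY and JSON."""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

__all__ = ["read_matrix", "write_matrix", "write_json", "read_json"]


def read_matrix(path) -> np.ndarray:
    """Read a dense matrix from ``.npy`` or CSV.

    CSV may carry one optional header row; rows must be rectangular — a
    ragged row raises :class:`ValueError` naming the 1-based line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    if path.suffix == ".npy":
        return np.asarray(np.load(path), dtype=float)
    rows = []
    width = None
    start_line = 1
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    lines = [(i + 1, ln) for i, ln in enumerate(lines) if ln]
    if not lines:
        raise ValueError(f"{path} is empty")
    # optional header: first row that does not parse as numbers
    first_vals = lines[0][1].split(",")
    try:
        [float(v) for v in first_vals]
    except ValueError:
        lines = lines[1:]
        start_line = 2
        if not lines:
            raise ValueError(f"{path} holds a header but no data")
    for lineno, ln in lines:
        vals = ln.split(",")
        if width is None:
            width = len(vals)
        elif len(vals) != width:
            raise ValueError(
                f"malformed CSV {path}: line {lineno} has {len(vals)} "
                f"fields, expected {width}"
            )
        try:
            rows.append([float(v) for v in vals])
        except ValueError as err:
            raise ValueError(f"malformed CSV {path}: line {lineno}: {err}") from err
    return np.asarray(rows, dtype=float)


def write_matrix(path, M, header=None) -> None:
    path = Path(path)
    M = np.asarray(M)
    if path.suffix == ".npy":
        np.save(path, M)
        return
    with open(path, "w") as fh:
        if header:
            fh.write(",".join(header) + "\n")
        for row in np.atleast_2d(M):
            fh.write(",".join(f"{v:.17g}" for v in row) + "\n")


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        if math.isinf(v) or math.isnan(v):
            return None  # JSON has no inf/nan; used for unscored entries
        return v
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json(path, obj) -> None:
    """Write a JSON result file; floats keep full (round-trip) precision."""
    with open(path, "w") as fh:
        json.dump(_jsonify(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
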