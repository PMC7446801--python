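"""Delimited-text matrix I/O, JSON reports, YAML/JSON configs, provenance."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "read_matrix",
    "write_matrix",
    "write_report",
    "read_config",
    "write_config",
    "write_series",
]


def read_matrix(path) -> np.ndarray:
    """Read a comma-separated matrix (one row per line, no header)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"matrix file not found: {path}")
    try:
        m = np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError as err:
        raise ValueError(f"malformed matrix file {path}: {err}") from err
    return m


def write_matrix(path, matrix) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, np.atleast_2d(np.asarray(matrix, dtype=float)), delimiter=",")


def write_report(path, report) -> None:
    """Serialise a CertificateReport (or plain dict) to JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = report.to_dict() if hasattr(report, "to_dict") else report
    path.write_text(json.dumps(payload, indent=2) + "\n")


def read_config(path) -> dict:
    """Load a YAML or JSON run config."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def write_config(path, config: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".json":
        path.write_text(json.dumps(config, indent=2, default=_jsonable) + "\n")
    else:
        path.write_text(yaml.safe_dump(config, sort_keys=False))


def _jsonable(v):
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    raise TypeError(f"not JSON-serialisable: {type(v)}")


def write_series(path, times, columns: dict) -> None:
    """Write a time series as delimited text with a header row.

    ``columns`` maps column name -> 1-d array (or (T, m) array, expanded to
    ``name_0 .. name_{m-1}``).
    """
    names = ["time"]
    arrays = [np.asarray(times, dtype=float)]
    for name, arr in columns.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 1:
            names.append(name)
            arrays.append(arr)
        else:
            for j in range(arr.shape[1]):
                names.append(f"{name}_{j}")
                arrays.append(arr[:, j])
    data = np.column_stack(arrays)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, data, delimiter=",", header=",".join(names), comments="")
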