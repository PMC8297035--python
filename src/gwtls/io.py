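"""Reading and writing the delimited station tables and result files.

The station table is a comma-separated file with one row per sample:
``station_id, u, v, y, <feature>..., <feature>__var...`` where ``u, v`` are
projected planar coordinates in meters and every feature column has a
matching ``__var`` column holding its measurement variance (or a global
default is configured).  An optional ``date`` column is carried through but
ignored by the estimators.

All files written by the package start with ``#``-prefixed provenance
lines (version, seed, config hash); readers skip them.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "read_station_table",
    "write_station_table",
    "feature_columns",
    "write_table",
    "provenance_lines",
]

REQUIRED = ("station_id", "u", "v", "y")
IGNORED = ("date",)


def feature_columns(frame: pd.DataFrame) -> list:
    """Feature column names: everything except the required, variance and ignored columns."""
    return [
        c
        for c in frame.columns
        if c not in REQUIRED and c not in IGNORED and not c.endswith("__var")
    ]


def read_station_table(path, default_variance: float | None = None) -> pd.DataFrame:
    """Read and validate a station table.

    Every feature needs a ``<feature>__var`` column unless
    ``default_variance`` is given, in which case missing variance columns
    are filled with it.  Raises :class:`SchemaError` listing any missing
    columns, and :class:`ValidationError` for non-numeric coordinates or
    negative variances (with the offending row index).
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED if c not in frame.columns]
    if missing:
        raise SchemaError(f"station table missing required columns: {missing}")

    for col in ("u", "v", "y"):
        try:
            frame[col] = frame[col].astype(float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"column {col!r} is not numeric: {exc}") from None

    feats = feature_columns(frame)
    if not feats:
        raise SchemaError("station table has no feature columns")
    missing_var = [f for f in feats if f"{f}__var" not in frame.columns]
    if missing_var and default_variance is None:
        raise SchemaError(
            "missing measurement-variance columns (and no default configured): "
            + ", ".join(f"{f}__var" for f in missing_var)
        )
    for f in missing_var:
        frame[f"{f}__var"] = float(default_variance)
    for f in feats:
        var = frame[f"{f}__var"].astype(float)
        bad = np.flatnonzero(var.to_numpy() < 0)
        if bad.size:
            raise ValidationError(
                f"negative variance in column {f}__var at row index {int(bad[0])}"
            )
    return frame


def provenance_lines(**meta) -> list:
    """Provenance header: package version, then any extra key/value pairs."""
    from . import __version__

    items = {"gwtls_version": __version__, **meta}
    if "config" in items:
        cfg = items.pop("config")
        digest = hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
        items["config_sha256"] = digest
    return [f"# {k}: {v}" for k, v in items.items()]


def write_table(frame: pd.DataFrame, path, **meta) -> None:
    """Write a CSV with a provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in provenance_lines(**meta):
            fh.write(line + "\n")
        frame.to_csv(fh, index=False)


def write_station_table(frame: pd.DataFrame, path, **meta) -> None:
    missing = [c for c in REQUIRED if c not in frame.columns]
    if missing:
        raise SchemaError(f"cannot write station table without columns: {missing}")
    write_table(frame, path, **meta)
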