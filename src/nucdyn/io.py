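"""CSV readers/writers for the package's table dialects, and report output.

Dialect: comma separator, ``.`` decimal, UTF-8, mandatory header; metadata
lines prefixed ``#`` as ``# key: value`` pairs (captured into a dict).
Reports are written as JSON (full float precision) or CSV (6 significant
digits) with a provenance block (package version + the configuration that
produced the result) so reruns are byte-identical for identical inputs.
"""

from __future__ import annotations

import dataclasses
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__

__all__ = ["SCHEMAS", "SchemaError", "read_table", "write_table", "write_report"]


class SchemaError(ValueError):
    """Input table does not match the expected schema."""


#: required columns and their numeric-ness per logical table type
SCHEMAS = {
    "titration": {
        "columns": ["x_molar", "y", "replicate", "channel"],
        "numeric": ["x_molar", "y"],
    },
    "trace": {
        "columns": ["time_s", "extension_nm", "force_pN"],
        "numeric": ["time_s", "extension_nm", "force_pN"],
    },
    "digestion": {
        "columns": ["site", "time_min", "condition", "intensity", "replicate"],
        "numeric": ["time_min", "intensity"],
    },
    "elution": {
        "columns": ["salt_molar", "fraction", "intensity", "strain", "replicate"],
        "numeric": ["salt_molar", "intensity"],
    },
}


def _read_metadata(path: Path):
    meta, body = {}, []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line.lstrip("#").strip()
                if ":" in stripped:
                    key, value = stripped.split(":", 1)
                    meta[key.strip()] = value.strip()
            else:
                body.append(line)
    return meta, "".join(body)


def read_table(path, schema_name: str):
    """Read and validate a CSV table; returns (DataFrame, metadata dict).

    Raises :class:`SchemaError` naming the missing column, or a parse
    error naming the offending row for non-numeric cells.  Row order is
    preserved.
    """
    if schema_name not in SCHEMAS:
        raise ValueError(f"unknown schema {schema_name!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    schema = SCHEMAS[schema_name]
    meta, body = _read_metadata(path)
    df = pd.read_csv(_io.StringIO(body), dtype=str, skipinitialspace=True)
    missing = [c for c in schema["columns"] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s): {', '.join(missing)}"
        )
    for col in schema["numeric"]:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path.name}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r} at data row {row + 1}"
            )
        df[col] = converted
    return df, meta


def write_table(df: pd.DataFrame, path, metadata: dict | None = None):
    """Write a CSV table with optional ``# key: value`` metadata lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False, lineterminator="\n")
    return path


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and not np.isfinite(obj):
        return repr(obj)
    return obj


def write_report(results, path, fmt: str = "json", config: dict | None = None):
    """Write an analysis result with a provenance block.

    JSON keeps full float precision under ``"results"`` with
    ``"_provenance"`` alongside; CSV formats floats at 6 significant
    digits with provenance as ``#`` header lines.  ``results`` may be a
    dataclass, dict, list of dataclasses, or DataFrame.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    provenance = {"package": "nucdyn", "version": __version__}
    if config:
        provenance["config"] = _jsonable(config)
    if fmt == "json":
        payload = {"_provenance": provenance, "results": _jsonable(results)}
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif fmt == "csv":
        if dataclasses.is_dataclass(results) and not isinstance(results, type):
            results = [results]
        if isinstance(results, list):
            df = pd.DataFrame([_jsonable(r) for r in results])
        elif isinstance(results, dict):
            df = pd.DataFrame([_jsonable(results)])
        elif isinstance(results, pd.DataFrame):
            df = results
        else:
            raise TypeError("unsupported results type for CSV output")
        meta = {"package": "nucdyn", "version": __version__}
        if config:
            meta["config"] = json.dumps(_jsonable(config), sort_keys=True)
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for key, value in meta.items():
                fh.write(f"# {key}: {value}\n")
            df.to_csv(fh, index=False, float_format="%.6g", lineterminator="\n")
    else:
        raise ValueError("fmt must be 'json' or 'csv'")
    return path
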