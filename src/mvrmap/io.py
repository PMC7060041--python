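"""Table and report I/O dialects used by the pipeline.

Event, site and pair tables travel as TSV (tab default; commas are
auto-detected by header sniffing). Reports are JSON documents validated
against a minimal embedded schema before writing.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import SchemaError

__all__ = [
    "EVENT_TABLE_MANDATORY",
    "read_event_table",
    "write_event_table",
    "read_frame_stack",
    "REPORT_SCHEMA_VERSION",
    "REPORT_REQUIRED_KEYS",
    "validate_report",
    "write_report",
    "read_report",
]

EVENT_TABLE_MANDATORY = ["bouton_id", "stimulus_index", "x_nm", "y_nm", "amplitude"]

REPORT_SCHEMA_VERSION = "1"
REPORT_REQUIRED_KEYS = [
    "schema_version", "provenance", "counts", "boutons", "sites", "pairs",
    "quantal", "tests",
]


def _sniff_sep(path) -> str:
    with open(path, "r") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_event_table(path) -> pd.DataFrame:
    """Read an event table (TSV or CSV), checking mandatory columns.

    Unknown columns are preserved untouched; a missing mandatory column
    raises :class:`SchemaError` naming it.
    """
    df = pd.read_csv(path, sep=_sniff_sep(path))
    missing = [c for c in EVENT_TABLE_MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(
            f"event table {path} lacks mandatory column(s): {', '.join(missing)}"
        )
    return df


def write_event_table(events: pd.DataFrame, path, sep: str = "\t") -> None:
    events.to_csv(path, sep=sep, index=False)


def read_frame_stack(path):
    """Read a multi-page TIFF stack written by synthkit (pre/post interleaved)."""
    import tifffile

    try:
        return tifffile.imread(path).astype(float)
    except Exception as exc:  # pragma: no cover - error-path plumbing
        raise SchemaError(f"unreadable TIFF stack {path}: {exc}") from exc


def validate_report(report: dict) -> None:
    missing = [k for k in REPORT_REQUIRED_KEYS if k not in report]
    if missing:
        raise SchemaError(f"report lacks required key(s): {', '.join(missing)}")
    for t in report["tests"].values():
        for k in ("test_name", "statistic", "p_value", "n"):
            if k not in t:
                raise SchemaError(f"test result lacks required field {k!r}")


def write_report(report: dict, path) -> None:
    """Schema-validate and write the run report as JSON."""
    validate_report(report)
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True,
                                     default=_json_default))


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
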