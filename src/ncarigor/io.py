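"""Tabular ingestion and the JSON run report."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .core import BivariateSample, DataError

__all__ = ["read_xy_table", "load_xy_table", "sample_from_frame", "RunReport"]

logger = logging.getLogger("ncarigor")


def _infer_delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def sample_from_frame(
    data: pd.DataFrame, x_col: str, y_col: str
) -> tuple[BivariateSample, int]:
    """Extract a listwise-complete :class:`BivariateSample` from a DataFrame.

    Returns the sample and the number of rows dropped for missingness.
    Non-numeric cells (other than genuine missing values) raise a
    :class:`DataError` naming the offending row.
    """
    for col in (x_col, y_col):
        if col not in data.columns:
            raise DataError(
                f"column {col!r} not found; table has columns {list(data.columns)}"
            )
    pair = data[[x_col, y_col]].copy()
    for col in (x_col, y_col):
        raw = pair[col]
        numeric = pd.to_numeric(raw, errors="coerce")
        bad = numeric.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            row = int(bad.idxmax())
            raise DataError(
                f"non-numeric value {raw[bad].iloc[0]!r} in column {col!r} at row {row}"
            )
        pair[col] = numeric
    complete = pair.dropna()
    n_dropped = len(pair) - len(complete)
    if len(complete) < 2:
        raise DataError(
            f"fewer than 2 complete (x, y) rows after listwise deletion "
            f"({len(complete)} usable, {n_dropped} dropped)"
        )
    sample = BivariateSample(complete[x_col].to_numpy(), complete[y_col].to_numpy())
    return sample, n_dropped


def load_xy_table(
    path, x_col: str, y_col: str, delimiter: str | None = None
) -> tuple[BivariateSample, int]:
    """Read a CSV/TSV table and return ``(sample, rows_dropped)``.

    The delimiter is inferred from the file extension (``.tsv``/``.tab`` mean
    tab) unless given explicitly.  Decimal parsing is locale-independent
    (period separator only).
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    delim = delimiter or _infer_delimiter(path)
    frame = pd.read_csv(path, sep=delim, dtype=str, skipinitialspace=True)
    return sample_from_frame(frame, x_col, y_col)


def read_xy_table(
    path, x_col: str, y_col: str, delimiter: str | None = None
) -> BivariateSample:
    """Read paired (x, y) data from a delimited text table.

    Convenience wrapper around :func:`load_xy_table` that logs the number of
    rows dropped by listwise deletion instead of returning it.
    """
    sample, n_dropped = load_xy_table(path, x_col, y_col, delimiter=delimiter)
    if n_dropped:
        logger.warning("%d row(s) dropped for missing values", n_dropped)
    return sample


@dataclass
class RunReport:
    """Self-describing record of one command invocation.

    Serialises losslessly to JSON; every stochastic result echoes the seed
    that produced it, so any report can be replayed from its own ``inputs``.
    """

    command: str
    inputs: dict
    results: dict
    warnings: list = field(default_factory=list)
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "command": self.command,
            "inputs": self.inputs,
            "results": self.results,
            "warnings": list(self.warnings),
            "version": self.version,
        }

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        obj = json.loads(text)
        return cls(
            command=obj["command"],
            inputs=obj["inputs"],
            results=obj["results"],
            warnings=obj.get("warnings", []),
            version=obj.get("version", __version__),
        )
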