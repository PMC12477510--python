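"""Reading and writing country tables and result tables.

All tables are UTF-8 CSV with a header row.  Missing values are accepted as
empty cells or the token ``NA`` on read and written back as empty cells —
never as 0.  Lines starting with ``#`` are comments (the pipeline stamps a
run-manifest digest there) and are skipped on read.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._util import is_missing
from .catalog import RESERVED_COLUMNS, CountryRecord, IndicatorCatalog, resolve_region

logger = logging.getLogger(__name__)

_NA_TOKENS = ["", "NA"]


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        comment="#",
        na_values=_NA_TOKENS,
        keep_default_na=False,
        skip_blank_lines=True,
    )


def load_country_table(path, catalog: IndicatorCatalog) -> list[CountryRecord]:
    """Parse a country CSV into records, validating columns against the catalog.

    Every non-reserved column must be an indicator id known to the catalog
    (unknown columns are a hard error naming the column, to catch typos
    early).  Unparseable numeric cells become missing with a logged warning;
    row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_csv(path)

    if "country_id" not in df.columns:
        raise ValueError(f"{path}: required column 'country_id' not found")
    if "region" not in df.columns:
        raise ValueError(f"{path}: required column 'region' not found")
    known = set(catalog.indicator_ids)
    for col in df.columns:
        if col not in RESERVED_COLUMNS and col not in known:
            raise ValueError(
                f"{path}: unknown indicator column {col!r} (not in catalog and not reserved)"
            )

    numeric_cols = [c for c in df.columns if c not in ("country_id", "region")]
    for col in numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & coerced.isna()
        if bad.any():
            for idx in df.index[bad]:
                logger.warning(
                    "%s: unparseable value %r in column %r, row %d; treated as missing",
                    path,
                    df.at[idx, col],
                    col,
                    idx,
                )
        df[col] = coerced

    records = []
    for _, row in df.iterrows():
        raw = {
            ind: (None if is_missing(row.get(ind)) else float(row[ind]))
            for ind in catalog.indicator_ids
            if ind in df.columns
        }
        records.append(
            CountryRecord(
                country_id=str(row["country_id"]),
                region=resolve_region(row["region"], catalog.region_aliases),
                raw_indicators=raw,
                health_expenditure=None
                if "health_expenditure" not in df.columns or is_missing(row["health_expenditure"])
                else float(row["health_expenditure"]),
                performance_index=None
                if "performance_index" not in df.columns or is_missing(row["performance_index"])
                else float(row["performance_index"]),
            )
        )
    return records


def _flatten(obj) -> dict:
    """Flatten a result dataclass into one CSV row; dict-valued fields are
    expanded into ``field.key`` columns, None stays None (→ empty cell)."""
    out: dict = {}
    for f in dataclasses.fields(obj):
        value = getattr(obj, f.name)
        if isinstance(value, dict):
            for k, v in value.items():
                out[f"{f.name}.{k}"] = v
        elif isinstance(value, (list, tuple, np.ndarray)):
            continue  # per-country vectors are written by their own writers
        else:
            out[f.name] = value
    return out


def write_results_table(records: Sequence, path, comment: Optional[str] = None) -> Path:
    """Write homogeneous result records (dataclasses or a DataFrame) as CSV.

    Missing values are serialized as empty cells so that a round-trip
    through :func:`read_table` reproduces them as missing, never as 0.
    """
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        if records.empty:
            raise ValueError("refusing to write an empty results table")
        df = records
    else:
        if len(records) == 0:
            raise ValueError("refusing to write an empty results table")
        first_type = type(records[0])
        if not all(type(r) is first_type for r in records):
            raise TypeError("records must be homogeneous")
        if not dataclasses.is_dataclass(records[0]):
            raise TypeError(f"cannot serialize records of type {first_type.__name__}")
        df = pd.DataFrame([_flatten(r) for r in records])
    try:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            if comment:
                for line in comment.splitlines():
                    fh.write(f"# {line}\n")
            df.to_csv(fh, index=False, na_rep="")
    except OSError as exc:
        raise OSError(f"cannot write results table to {path}: {exc}") from exc
    return path


def read_table(path) -> pd.DataFrame:
    """Read a results CSV back, restoring empty cells and ``NA`` to NaN."""
    return _read_csv(path)
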