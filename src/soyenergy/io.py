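"""CSV reading/writing for the trial tables.

Dialect: comma-separated, UTF-8, "." decimal, missing values as empty
cells. Each table maps 1:1 onto a record type in :mod:`soyenergy.records`;
amino-acid concentrations travel as ``aa_<name>`` columns of samples.csv.
Reading validates every row and reports all failing rows at once.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence, Type

import pandas as pd
from pydantic import ValidationError

from .records import (
    CollectionRecord,
    DietSpec,
    PigRecord,
    ProcessingRecord,
    SampleAssay,
)

__all__ = ["SCHEMAS", "TableValidationError", "read_table", "write_table"]

#: table name -> record type
SCHEMAS: dict[str, type] = {
    "samples": SampleAssay,
    "processing": ProcessingRecord,
    "diets": DietSpec,
    "pigs": PigRecord,
    "collection": CollectionRecord,
}

_STR_FIELDS = {
    "sample_id", "plant_id", "diet_id", "experiment_id",
    "reference_diet_id", "pig_id", "block_id",
}
_BOOL_FIELDS = {"dehulled"}


class TableValidationError(ValueError):
    """One or more rows of a table failed validation.

    ``failures`` is a list of ``(row_number, field, message)`` tuples with
    1-based data row numbers (header excluded).
    """

    def __init__(self, table: str, failures: list[tuple[int, str, str]]):
        self.table = table
        self.failures = failures
        lines = [f"{table}: {len(failures)} invalid value(s)"]
        lines += [f"  row {r}, field '{f}': {m}" for r, f, m in failures]
        super().__init__("\n".join(lines))


def _coerce(model: Type, row: dict) -> dict:
    out: dict = {}
    aa: dict[str, float] = {}
    for key, val in row.items():
        missing = val is None or (isinstance(val, float) and math.isnan(val)) \
            or (isinstance(val, str) and val.strip() == "")
        if key.startswith("aa_"):
            if not missing:
                aa[key[3:]] = float(val)
            continue
        if missing:
            continue
        if key in _STR_FIELDS:
            out[key] = str(val)
        elif key in _BOOL_FIELDS:
            if isinstance(val, str):
                out[key] = val.strip().lower() in ("true", "1", "yes")
            else:
                out[key] = bool(val)
        else:
            out[key] = val
    if aa and model is SampleAssay:
        out["amino_acids"] = aa
    return out


def read_table(path: str | Path, table: str) -> list:
    """Read and validate one CSV table.

    Returns a list of validated records of the type registered for
    ``table`` in :data:`SCHEMAS`. Raises :class:`TableValidationError`
    naming every failing row and field, or ``ValueError`` on a missing
    required column.
    """
    if table not in SCHEMAS:
        raise ValueError(f"unknown table '{table}'; known: {sorted(SCHEMAS)}")
    model = SCHEMAS[table]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{table} table not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)

    required = {
        name for name, f in model.model_fields.items()
        if f.is_required() and name != "amino_acids"
    }
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(
            f"{table}: missing required column(s): {sorted(missing_cols)}")

    records = []
    failures: list[tuple[int, str, str]] = []
    for i, row in enumerate(df.to_dict(orient="records"), start=1):
        try:
            records.append(model(**_coerce(model, row)))
        except ValidationError as exc:
            for err in exc.errors():
                loc = ".".join(str(p) for p in err["loc"]) or "<record>"
                failures.append((i, loc, err["msg"]))
        except (TypeError, ValueError) as exc:  # non-numeric cell
            failures.append((i, "<row>", str(exc)))
    if failures:
        raise TableValidationError(table, failures)
    return records


def write_table(records: Sequence, path: str | Path, table: str | None = None) -> Path:
    """Write validated records to CSV so that ``read_table`` round-trips.

    An empty collection needs an explicit ``table`` name and yields a
    header-only file. Optional fields that are absent in every record
    (e.g. amino acids) are omitted from the output.
    """
    path = Path(path)
    if not records:
        if table is None:
            raise ValueError("empty collection: pass table= to emit a header")
        cols = [c for c in SCHEMAS[table].model_fields if c != "amino_acids"]
        pd.DataFrame(columns=cols).to_csv(path, index=False)
        return path

    model = type(records[0])
    rows = []
    for rec in records:
        d = rec.model_dump()
        aa = d.pop("amino_acids", None)
        if aa:
            d.update({f"aa_{k}": v for k, v in aa.items()})
        rows.append(d)
    df = pd.DataFrame(rows)
    df = df.dropna(axis=1, how="all")
    df.to_csv(path, index=False)
    return path
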