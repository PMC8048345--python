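"""CSV / JSON readers and writers for the long-format tables used across the package.

A *long expression table* is a pandas DataFrame with columns
``patient_id, day, gene_id, value`` — one row per measured gene per blood draw.
A *survival table* is handled by :class:`trajsurv.survival.SurvivalTable`.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

EXPRESSION_COLUMNS = ("patient_id", "day", "gene_id", "value")


def validate_expression(table: pd.DataFrame) -> pd.DataFrame:
    """Check column names/dtypes of a long expression table; return it untouched."""
    missing = set(EXPRESSION_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    if table["value"].isna().any():
        raise ValueError("expression table contains NaN values; missingness is "
                         "encoded by absent rows, not NaN")
    return table


def read_expression_csv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"patient_id": str, "gene_id": str})
    table["day"] = table["day"].astype(int)
    return validate_expression(table)


def write_expression_csv(table: pd.DataFrame, path: str | Path) -> None:
    validate_expression(table)
    table.to_csv(path, index=False, columns=list(EXPRESSION_COLUMNS))


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
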