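"""Reading and writing the environmental-table CSV schema."""

from __future__ import annotations

import datetime as _dt
import warnings

import pandas as pd

from .synthetic_data import ABUNDANCE_COLUMNS, COLUMNS

__all__ = ["read_env_table", "write_env_table", "EnvTableError"]

_NUMERIC = [c for c in COLUMNS if c not in ("station", "date")]
_POSITIVE = ["depth_m", "chl_a_ug_l", *ABUNDANCE_COLUMNS.values(),
             "prokaryotes_1e5_ml", "viruses_1e6_ml"]


class EnvTableError(ValueError):
    """Schema violation in an environmental table file."""


def write_env_table(table: pd.DataFrame, path) -> None:
    out = table[COLUMNS].copy()
    out["date"] = [d.isoformat() for d in out["date"]]
    out.to_csv(path, index=False, float_format="%.12g")


def read_env_table(path) -> pd.DataFrame:
    """Read and validate an EnvTable CSV.

    Missing columns, non-numeric cells and non-positive abundances raise
    :class:`EnvTableError` naming the offending cell; additivity of the
    sum columns is checked to 1e-6 with a warning on violation.
    """
    table = pd.read_csv(path, dtype={"station": str})
    missing = [c for c in COLUMNS if c not in table.columns]
    if missing:
        raise EnvTableError(f"missing column(s): {', '.join(missing)}")
    for c in _NUMERIC:
        coerced = pd.to_numeric(table[c], errors="coerce")
        bad = coerced.isna() & table[c].notna()
        if bad.any() or table[c].isna().any():
            row = int((coerced.isna()).idxmax())
            raise EnvTableError(f"non-numeric cell at row {row}, column {c!r}")
        table[c] = coerced
    for c in _POSITIVE:
        if (table[c] <= 0).any():
            row = int((table[c] <= 0).idxmax())
            raise EnvTableError(f"non-positive value at row {row}, column {c!r}")
    table["date"] = [_dt.date.fromisoformat(s) for s in table["date"]]
    for total, (a, b) in (
        ("prokaryotes_1e5_ml", ("hna_1e5_ml", "lna_1e5_ml")),
        ("viruses_1e6_ml", ("v1_1e6_ml", "v2_1e6_ml")),
    ):
        gap = (table[total] - table[a] - table[b]).abs()
        if (gap > 1e-6).any():
            warnings.warn(
                f"additivity violated: {total} != {a}+{b} "
                f"(max gap {gap.max():.3g})",
                stacklevel=2,
            )
    return table[COLUMNS]
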