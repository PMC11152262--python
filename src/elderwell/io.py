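"""Reading and writing survey tables.

Survey data travel as RFC-4180 CSV with a header row.  Missing values are an
empty cell on disk and pandas ``NA`` in memory — never a magic number.  Every
cell is validated against the codebook on the way in; out-of-range or
undeclared values raise, nothing is silently coerced.
"""

from __future__ import annotations

import numbers

import numpy as np
import pandas as pd

from .codebook import Codebook, FieldSpec, SchemaError, ValidationError, default_codebook

MISSING_SENTINEL = ""


def _parse_item(raw: str, spec: FieldSpec, m: float, M: float, row, name: str) -> float:
    try:
        val = float(raw)
    except ValueError:
        if spec.labels and raw in spec.labels:
            # verbal anchor -> equally spaced integer grid m..M, worst first
            val = m + spec.labels.index(raw) * (M - m) / (len(spec.labels) - 1)
        else:
            raise ValidationError(f"row {row}, field {name!r}: unparseable value {raw!r}")
    if not (m <= val <= M):
        raise ValidationError(
            f"row {row}, field {name!r}: value {val} outside bounds [{m}, {M}]"
        )
    return val


def read_survey(path, codebook: Codebook | None = None) -> pd.DataFrame:
    """Read and validate a respondent-level survey CSV.

    Parameters
    ----------
    path : path-like or buffer
        Delimited text with a header row matching the codebook columns.
    codebook : Codebook, optional
        Defaults to :func:`~elderwell.codebook.default_codebook`.

    Returns
    -------
    pandas.DataFrame
        One row per respondent; item/count/flag columns are floats (NaN for
        missing), categorical columns are pandas ``category``.

    Raises
    ------
    SchemaError
        A declared column is absent from the file.
    ValidationError
        A cell violates its declaration (bounds, levels, duplicates).
    """
    cb = codebook or default_codebook()
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    missing_cols = [c for c in cb.columns if c not in raw.columns]
    if missing_cols:
        raise SchemaError(f"missing column(s): {missing_cols}")

    out = pd.DataFrame(index=raw.index)
    ids = raw[cb.id_field].astype(str)
    if ids.duplicated().any():
        dupes = ids[ids.duplicated()].tolist()
        raise ValidationError(f"duplicate respondent_id(s): {dupes}")
    out[cb.id_field] = ids

    for name, spec in cb.fields.items():
        col = raw[name].str.strip()
        is_missing = col == MISSING_SENTINEL
        if is_missing.any() and not (spec.allow_missing or spec.kind == "item"):
            rows = list(raw.index[is_missing])
            raise ValidationError(f"field {name!r}: missing not allowed (rows {rows})")
        if spec.kind == "item":
            m, M, _ = cb.bounds(name)
            vals = np.full(len(col), np.nan)
            for i, v in col.items():
                if not is_missing.iloc[i]:
                    vals[i] = _parse_item(v, spec, m, M, i, name)
            out[name] = vals
        elif spec.kind in ("ordinal", "nominal"):
            bad = ~is_missing & ~col.isin(spec.levels)
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValidationError(
                    f"row {i}, field {name!r}: value {col.iloc[i]!r} not in {spec.levels}"
                )
            out[name] = pd.Categorical(col.where(~is_missing), categories=spec.levels)
        elif spec.kind == "count":
            vals = np.full(len(col), np.nan)
            for i, v in col.items():
                if is_missing.iloc[i]:
                    continue
                try:
                    x = float(v)
                except ValueError:
                    raise ValidationError(f"row {i}, field {name!r}: non-numeric {v!r}")
                if x < 0 or x != int(x):
                    raise ValidationError(
                        f"row {i}, field {name!r}: {v!r} is not a non-negative integer"
                    )
                vals[i] = x
            out[name] = vals
        elif spec.kind == "flag":
            mapped = col.map({"0": 0.0, "1": 1.0, "no": 0.0, "yes": 1.0})
            bad = ~is_missing & mapped.isna()
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValidationError(
                    f"row {i}, field {name!r}: {col.iloc[i]!r} is not a 0/1 flag"
                )
            out[name] = mapped.astype(float)
        else:  # pragma: no cover - codebook construction forbids this
            raise SchemaError(f"field {name!r}: unknown kind {spec.kind!r}")
    return out


def write_table(table: pd.DataFrame, path) -> None:
    """Write any tabular result as CSV; missing cells become empty fields.

    ``read_survey(write_table(T))`` is the identity on a valid survey table
    up to column order and dtype.  Refuses to write an empty table.
    """
    if table is None or len(table) == 0:
        raise ValueError("refusing to write an empty table")
    df = table.copy()
    for c in df.columns:
        if pd.api.types.is_float_dtype(df[c]):
            # render integral floats without the trailing .0
            vals = df[c]
            if vals.dropna().mod(1).eq(0).all():
                df[c] = vals.map(lambda v: "" if pd.isna(v) else str(int(v)))
    df.to_csv(path, index=False, na_rep=MISSING_SENTINEL)
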