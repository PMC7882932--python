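"""CSV ingestion and export with configurable dialects.

Trait tables arrive as CSV files whose column headings use the canonical
trait abbreviations (H, SSD, LA, LMA, Nmass, SM — exact, case-sensitive
match), values in natural units with no prior transformation; any other
column is preserved verbatim as an extra column.  The separator, decimal
character and missing-value marker are configurable because trait tables come
from spreadsheets in many locales.

Exported coordinate files prepend "#"-prefixed metadata lines naming the
traits of the space and the number of reference entities used to fit it,
then repeat the uploaded table with the component coordinates appended as
extra columns (excluded entities keep their row, coordinates left missing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reference_data import CANONICAL_TRAITS


@dataclass(frozen=True)
class CsvDialect:
    separator: str = ","
    decimal: str = "."
    encoding: str = "utf-8"
    missing: str = "NA"

    def validate(self) -> None:
        if self.separator == self.decimal:
            raise ValueError(
                f"ambiguous dialect: separator and decimal are both {self.separator!r}"
            )


def read_entities_csv(path, dialect: CsvDialect | None = None) -> pd.DataFrame:
    """Read an entity table under the given dialect.

    Canonical trait columns are parsed as numbers (the missing marker becomes
    NaN); unparseable numeric cells are reported with their row and column.
    All non-trait columns are kept as-is.  A table with no recognized trait
    column is rejected — the headings probably do not match the canonical
    abbreviations.
    """
    if dialect is None:
        dialect = CsvDialect()
    dialect.validate()
    table = pd.read_csv(
        path,
        sep=dialect.separator,
        decimal=dialect.decimal,
        encoding=dialect.encoding,
        na_values=[dialect.missing],
        keep_default_na=False,
        comment="#",
        dtype=str,
        skipinitialspace=False,
    )
    table.columns = [c.strip() for c in table.columns]
    traits = [t for t in CANONICAL_TRAITS if t in table.columns]
    if not traits:
        raise ValueError(
            f"no canonical trait columns found in {path}; headings must match "
            f"{CANONICAL_TRAITS} exactly (case-sensitive)"
        )
    for t in traits:
        raw = table[t]
        # the dialect's decimal was already normalized by read_csv only for
        # numeric dtypes; with dtype=str we convert explicitly
        norm = raw.str.replace(dialect.decimal, ".", regex=False) if dialect.decimal != "." else raw
        parsed = pd.to_numeric(norm, errors="coerce")
        bad = parsed.isna() & raw.notna()
        if bad.any():
            row = int(table.index[bad][0])
            raise ValueError(
                f"unparseable numeric value {raw[bad].iloc[0]!r} in column {t}, row {row + 2} "
                f"(expected decimal character {dialect.decimal!r} or the missing marker "
                f"{dialect.missing!r})"
            )
        table[t] = parsed
    return table


def _format_number(x, dialect: CsvDialect) -> str:
    if pd.isna(x):
        return dialect.missing
    s = f"{float(x):.15g}"
    if dialect.decimal != ".":
        s = s.replace(".", dialect.decimal)
    return s


def _format_frame(table: pd.DataFrame, dialect: CsvDialect) -> pd.DataFrame:
    out = table.copy()
    for c in out.columns:
        if pd.api.types.is_float_dtype(out[c]):
            out[c] = out[c].map(lambda v: _format_number(v, dialect))
        else:
            out[c] = out[c].map(lambda v: dialect.missing if pd.isna(v) else str(v))
    return out


def write_entities_csv(table: pd.DataFrame, path, dialect: CsvDialect | None = None) -> None:
    """Write an entity table under the given dialect (15 significant digits)."""
    if dialect is None:
        dialect = CsvDialect()
    dialect.validate()
    _format_frame(table, dialect).to_csv(
        path, sep=dialect.separator, index=False, encoding=dialect.encoding
    )


def write_coordinates_csv(result, original: pd.DataFrame, space, path,
                          dialect: CsvDialect | None = None) -> None:
    """Write projected coordinates appended to the originally uploaded table.

    Leading "#" lines record the traits of the space and the number of
    reference entities used to fit it.  Every input row appears, in input
    order; rows excluded from the projection keep missing coordinate cells.
    """
    if dialect is None:
        dialect = CsvDialect()
    dialect.validate()

    pc_cols = [f"PC{k + 1}" for k in range(space.n_components)]
    coords = pd.DataFrame(np.nan, index=original.index, columns=pc_cols)
    coords.loc[result.coordinates.index, pc_cols] = result.coordinates[pc_cols].to_numpy()
    combined = pd.concat([original, coords], axis=1)

    header = (
        f"# traits used in the PCA: {', '.join(space.traits)}\n"
        f"# reference entities used to run the PCA: {space.stats.n_used}\n"
    )
    body = _format_frame(combined, dialect).to_csv(
        sep=dialect.separator, index=False
    )
    with open(path, "w", encoding=dialect.encoding) as fh:
        fh.write(header)
        fh.write(body)


__all__ = [
    "CsvDialect",
    "read_entities_csv",
    "write_entities_csv",
    "write_coordinates_csv",
]
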