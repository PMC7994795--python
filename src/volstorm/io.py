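"""Reading and writing localization tables.

Two text dialects are supported:

``canonical_csv``
    Comma-separated with a mandatory named header row.  Distances carry a
    ``_nm`` suffix: ``x_nm, y_nm, z_nm (optional), frame, movie_id,
    intensity, background, width_x_nm, width_y_nm, channel``.

``rapidstorm``
    Whitespace-separated values preceded by a single XML-like header
    comment line that declares column identities and units, as emitted by
    the rapidSTORM localizer's text output, e.g.::

        # <localizations><field identifier="Position-0-0" unit="nanometer" />
          <field identifier="Position-1-0" unit="nanometer" /> ... >

    Recognized identifiers: ``Position-0-0/1-0/2-0`` (x/y/z),
    ``ImageNumber-0-0`` (frame), ``Amplitude-0-0`` (intensity),
    ``PSFWidth-0-0/1-0`` (width_x/width_y), ``LocalBackground-0-0``
    (background).  Units ``nanometer``/``micrometer``/``pixel`` are
    converted to nm on read (pixels via the table's ``pixel_size``).
    Unknown identifiers are carried through as opaque extra columns.

Malformed rows abort the read with the offending line number: the
pipeline's product is quantitative counting, and silently skipping rows
would corrupt it.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError
from .table import LocalizationTable, MANDATORY_COLUMNS

DIALECTS = ("canonical_csv", "rapidstorm")

_CSV_RENAME = {
    "x_nm": "x", "y_nm": "y", "z_nm": "z",
    "width_x_nm": "width_x", "width_y_nm": "width_y",
}
_CSV_NAMES = {v: k for k, v in _CSV_RENAME.items()}

_RS_IDENTIFIERS = {
    "Position-0-0": "x",
    "Position-1-0": "y",
    "Position-2-0": "z",
    "ImageNumber-0-0": "frame",
    "Amplitude-0-0": "intensity",
    "PSFWidth-0-0": "width_x",
    "PSFWidth-1-0": "width_y",
    "LocalBackground-0-0": "background",
}
_RS_NAMES = {v: k for k, v in _RS_IDENTIFIERS.items()}

_LENGTH_COLUMNS = ("x", "y", "z", "width_x", "width_y")

_FIELD_RE = re.compile(r"<field\s+([^>]*?)/?>")
_ATTR_RE = re.compile(r'(\w+)="([^"]*)"')

_INT_COLUMNS = ("frame", "movie_id")
_FLOAT_FORMAT = "%.2f"  # 0.01 nm declared precision


def _unit_factor(unit: str, pixel_size: float) -> float:
    if unit in ("nanometer", "nm", ""):
        return 1.0
    if unit in ("micrometer", "um"):
        return 1000.0
    if unit in ("pixel", "px"):
        return float(pixel_size)
    raise FormatError(f"unsupported unit {unit!r} in rapidSTORM header")


def _to_numeric(df: pd.DataFrame, columns, n_header_lines: int) -> pd.DataFrame:
    """Convert string columns to numbers; abort naming the first bad line."""
    out = {}
    for col in df.columns:
        if col not in columns:
            out[col] = df[col]
            continue
        raw = df[col]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            line_no = row + n_header_lines + 1  # 1-based file line
            raise FormatError(
                f"non-numeric value {raw.iloc[row]!r} in column {col!r} "
                f"at line {line_no}")
        out[col] = num
    return pd.DataFrame(out)


def read_localizations(path, dialect: str = "canonical_csv",
                       pixel_size: float = 126.0,
                       field_of_view: tuple[float, float] = (25_000.0, 25_000.0),
                       ) -> LocalizationTable:
    """Read a localization table from ``path`` in the given dialect.

    All positions are converted to nanometres.  The returned table's
    metadata records the dialect, the source path and the row count.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ParameterError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    if dialect == "canonical_csv":
        df = pd.read_csv(path, dtype=str, skipinitialspace=True)
        df = df.rename(columns=_CSV_RENAME)
        numeric = [c for c in df.columns if c != "channel"]
        df = _to_numeric(df, numeric, n_header_lines=1)
    else:
        with open(path) as fh:
            header = fh.readline()
        if not header.lstrip().startswith("#"):
            raise FormatError("rapidSTORM file must start with a '#' header "
                              "comment declaring column identities")
        columns, factors = [], []
        for m in _FIELD_RE.finditer(header):
            attrs = dict(_ATTR_RE.findall(m.group(1)))
            ident = attrs.get("identifier", "")
            name = _RS_IDENTIFIERS.get(ident, ident or "unknown")
            columns.append(name)
            unit = attrs.get("unit", "")
            if name in _LENGTH_COLUMNS:
                factors.append(_unit_factor(unit, pixel_size))
            else:
                factors.append(1.0)
        if not columns:
            raise FormatError("rapidSTORM header declares no <field> entries")
        df = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                         names=columns, dtype=str)
        df = _to_numeric(df, columns, n_header_lines=1)
        for name, fac in zip(columns, factors):
            if fac != 1.0:
                df[name] = df[name] * fac
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s) {missing} in {path.name}")
    for col in _INT_COLUMNS:
        if col in df.columns:
            df[col] = df[col].astype(np.int64)
    extra = [c for c in df.columns
             if c not in set(_RS_NAMES) | {"movie_id", "channel"}]
    meta = {"dialect": dialect, "source": str(path), "n_rows": len(df)}
    if extra:
        meta["extra_columns"] = extra
    return LocalizationTable(df=df, field_of_view=field_of_view,
                             pixel_size=pixel_size, metadata=meta)


def write_localizations(table: LocalizationTable, path,
                        dialect: str = "canonical_csv",
                        allow_empty: bool = False) -> None:
    """Write ``table`` to ``path``; round-trips numeric fields to 0.01 nm.

    The ``z`` column is emitted only when present in the table.  Writing
    an empty table is refused unless ``allow_empty`` is set, so that an
    accidentally emptied pipeline stage fails loudly.
    """
    if dialect not in DIALECTS:
        raise ParameterError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    if len(table) == 0 and not allow_empty:
        raise ParameterError("refusing to write an empty table "
                             "(pass allow_empty=True to override)")
    df = table.df
    path = Path(path)
    if dialect == "canonical_csv":
        ordered = [c for c in ("x", "y", "z", "frame", "movie_id", "intensity",
                               "background", "width_x", "width_y", "channel")
                   if c in df.columns]
        ordered += [c for c in df.columns if c not in ordered]
        out = df[ordered].rename(columns=_CSV_NAMES)
        out.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
    else:
        ordered = [c for c in ("x", "y", "z", "frame", "intensity",
                               "width_x", "width_y", "background")
                   if c in df.columns]
        fields = "".join(
            f'<field identifier="{_RS_NAMES[c]}" unit="'
            + ("nanometer" if c in _LENGTH_COLUMNS else "au" if c in
               ("intensity", "background") else "frame") + '" />'
            for c in ordered)
        with open(path, "w") as fh:
            fh.write(f"# <localizations>{fields}</localizations>\n")
            cols = []
            for c in ordered:
                v = df[c]
                if c in _INT_COLUMNS:
                    cols.append(v.astype(np.int64).astype(str))
                else:
                    cols.append(v.map(lambda x: _FLOAT_FORMAT % x))
            body = pd.concat(cols, axis=1)
            body.to_csv(fh, sep=" ", header=False, index=False)
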