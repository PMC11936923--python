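"""A normalized on-disk store: one CSV per table with ISO dates.

``ingest`` writes deduplication-ready tables once so that the analysis
subcommands need not re-parse the quarterly ASCII files.  Dates are
serialized as (partial) ISO strings — ``2022-03-15``, ``2022-03`` or
``2022`` — and round-trip through the internal padded-integer +
precision representation.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Union

import pandas as pd

from ._dates import DAY, MONTH, YEAR, PartialDate
from .faers_io import RawQuarter

_STORE_TABLES = ("DEMO", "DRUG", "REAC", "THER", "INDI", "OUTC", "RPSR")
_DATE_COLS = {"DEMO": [("fda_dt", None), ("event_dt", "event_dt_prec")],
              "THER": [("start_dt", "start_dt_prec")]}


def _int_to_iso(value, prec) -> str:
    if pd.isna(value):
        return ""
    return PartialDate(int(value), DAY if prec is None or pd.isna(prec) else str(prec)).isoformat()


def _iso_to_int(s: str):
    s = str(s).strip()
    if not s or s == "nan":
        return pd.NA, pd.NA
    parts = s.split("-")
    if len(parts) == 3:
        return int(parts[0]) * 10000 + int(parts[1]) * 100 + int(parts[2]), DAY
    if len(parts) == 2:
        return int(parts[0]) * 10000 + int(parts[1]) * 100 + 1, MONTH
    return int(parts[0]) * 10000 + 101, YEAR


def write_store(raw: RawQuarter, path: Union[str, Path]) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for table, df in raw.tables.items():
        out = df.copy()
        for col, prec_col in _DATE_COLS.get(table, []):
            if col not in out.columns:
                continue
            precs = out[prec_col] if prec_col and prec_col in out.columns else pd.Series(None, index=out.index)
            out[col] = [_int_to_iso(v, p) for v, p in zip(out[col], precs)]
            if prec_col and prec_col in out.columns:
                out = out.drop(columns=prec_col)
        out.to_csv(path / f"{table.lower()}.csv", index=False, lineterminator="\n")
    with open(path / "meta.json", "w") as fh:
        json.dump({"quarter": raw.quarter, "log": raw.log}, fh, indent=1, default=str)


def load_store(path: Union[str, Path]) -> RawQuarter:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    tables: Dict[str, pd.DataFrame] = {}
    for table in _STORE_TABLES:
        f = path / f"{table.lower()}.csv"
        if not f.exists():
            continue
        df = pd.read_csv(f, dtype=str, keep_default_na=False).replace("", pd.NA)
        for col, prec_col in _DATE_COLS.get(table, []):
            if col not in df.columns:
                continue
            pairs = [_iso_to_int(v) if not pd.isna(v) else (pd.NA, pd.NA) for v in df[col]]
            df[col] = pd.array([p[0] for p in pairs], dtype="Int64")
            if prec_col:
                df[prec_col] = [p[1] for p in pairs]
        tables[table] = df
    if "DEMO" in tables:
        tables["DEMO"]["fda_dt"] = tables["DEMO"]["fda_dt"].astype("int64")
        tables["DEMO"]["rept_yr"] = tables["DEMO"]["fda_dt"] // 10000
    return RawQuarter(quarter=meta.get("quarter", "store"), tables=tables, log=meta.get("log", {}))
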