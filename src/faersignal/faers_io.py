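"""Reading, deduplicating and filtering FAERS-style quarterly ASCII files.

The FDA publishes FAERS as quarterly sets of "$"-delimited text tables
(DEMO, DRUG, REAC, THER, INDI, OUTC, RPSR).  This module parses those
tables into :class:`pandas.DataFrame` objects with lower-cased column
names, applies the FDA-recommended case-level deduplication (latest
FDA_DT per CASEID, ties broken by the highest PRIMARYID), and selects
the reports on which a target drug is recorded with a given role code
(typically PS, primary suspect).

Only the post-2012Q4 ASCII layout is supported; unknown extra columns
are carried through untouched.
"""
from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set

import pandas as pd

from ._dates import parse_partial_date

logger = logging.getLogger(__name__)

REQUIRED_TABLES = ("DEMO", "DRUG", "REAC")
OPTIONAL_TABLES = ("THER", "INDI", "OUTC", "RPSR")
ALL_TABLES = REQUIRED_TABLES + OPTIONAL_TABLES

ROLE_CODES = frozenset({"PS", "SS", "C", "I"})


@dataclass
class RawQuarter:
    """One or more FAERS quarters held as a dict of record tables.

    ``tables`` maps upper-case table names to DataFrames whose columns are
    lower-cased.  ``log`` collects non-fatal parse anomalies: counts of
    malformed rows per table, DEMO rows dropped for an invalid FDA_DT, and
    child-table primaryids with no DEMO parent (logged, never fatal).
    """

    quarter: str
    tables: Dict[str, pd.DataFrame]
    log: Dict[str, object] = field(default_factory=dict)

    @property
    def demo(self) -> pd.DataFrame:
        return self.tables["DEMO"]

    @property
    def drug(self) -> pd.DataFrame:
        return self.tables["DRUG"]

    @property
    def reac(self) -> pd.DataFrame:
        return self.tables["REAC"]

    @property
    def ther(self) -> pd.DataFrame:
        return self.tables.get("THER", pd.DataFrame(columns=["primaryid"]))


def _find_table_file(path: Path, table: str, quarter: str = "") -> Optional[Path]:
    """Locate a table's file; a quarter-tagged name (``DEMO22Q1.txt`` for
    2022Q1) wins over a bare prefix match, so one directory can hold
    several quarters."""
    if len(quarter) == 6:  # e.g. 2022Q1
        tagged = re.compile(
            rf"^{table}{quarter[2:4]}Q{quarter[5]}\.(txt|TXT)$", re.IGNORECASE
        )
        hits = sorted(p for p in path.iterdir() if p.is_file() and tagged.match(p.name))
        if hits:
            return hits[0]
    pat = re.compile(rf"^{table}.*\.(txt|TXT)$", re.IGNORECASE)
    hits = sorted(p for p in path.iterdir() if p.is_file() and pat.match(p.name))
    return hits[0] if hits else None


def _read_dollar_file(path: Path) -> tuple[pd.DataFrame, int]:
    """Read one "$"-delimited FAERS table; returns (frame, n_bad_rows).

    FAERS files have no quoting dialect; a row whose field count does not
    match the header is counted and dropped.
    """
    bad = [0]

    def _on_bad(row: List[str]):
        bad[0] += 1
        return None

    df = pd.read_csv(
        path,
        sep="$",
        dtype=str,
        engine="python",
        quoting=csv.QUOTE_NONE,
        on_bad_lines=_on_bad,
        keep_default_na=False,
    )
    df.columns = [c.strip().lower() for c in df.columns]
    # blank-out pure-whitespace fields so downstream "absent" checks are uniform
    df = df.apply(lambda s: s.str.strip())
    df = df.replace("", pd.NA)
    return df, bad[0]


def read_quarter(path: str | Path, quarter: str) -> RawQuarter:
    """Parse one quarterly directory of FAERS ASCII files.

    Parameters
    ----------
    path:
        Directory holding one file per table (e.g. ``DEMO22Q1.txt``); file
        names are matched case-insensitively on the table-name prefix.
    quarter:
        Label recorded on the result, e.g. ``"2022Q1"``.

    Raises
    ------
    FileNotFoundError
        If any of the required DEMO/DRUG/REAC files is missing; the message
        names the missing table.
    """
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"quarter directory not found: {path}")
    tables: Dict[str, pd.DataFrame] = {}
    log: Dict[str, object] = {"bad_rows": {}, "invalid_fda_dt": 0, "orphans": {}}
    for table in ALL_TABLES:
        f = _find_table_file(path, table, quarter)
        if f is None:
            if table in REQUIRED_TABLES:
                raise FileNotFoundError(
                    f"required FAERS table {table} has no file in {path}"
                )
            continue
        df, n_bad = _read_dollar_file(f)
        if n_bad:
            log["bad_rows"][table] = n_bad
            logger.warning("%s: dropped %d malformed rows in %s", quarter, n_bad, table)
        tables[table] = df

    demo = tables["DEMO"]
    if "primaryid" not in demo.columns or "caseid" not in demo.columns:
        raise ValueError("DEMO file lacks primaryid/caseid columns")

    # fda_dt must be a full valid date; rows violating that are unusable for
    # deduplication and are dropped with a trace.
    fda = demo.get("fda_dt", pd.Series(pd.NA, index=demo.index))
    parsed = fda.map(parse_partial_date)
    ok = parsed.map(lambda d: d is not None and d.precision == "day")
    n_bad_fda = int((~ok).sum())
    if n_bad_fda:
        log["invalid_fda_dt"] = n_bad_fda
        logger.warning("%s: dropped %d DEMO rows with invalid fda_dt", quarter, n_bad_fda)
    demo = demo.loc[ok].copy()
    demo["fda_dt"] = parsed.loc[ok].map(lambda d: d.value).astype("int64")
    # event_dt may be partial; keep the padded value plus a precision tag
    ev = demo.get("event_dt", pd.Series(pd.NA, index=demo.index)).map(parse_partial_date)
    demo["event_dt"] = ev.map(lambda d: d.value if d else pd.NA).astype("Int64")
    demo["event_dt_prec"] = ev.map(lambda d: d.precision if d else pd.NA)
    demo["rept_yr"] = (demo["fda_dt"] // 10000).astype("int64")
    tables["DEMO"] = demo

    if "THER" in tables:
        ther = tables["THER"]
        st = ther.get("start_dt", pd.Series(pd.NA, index=ther.index)).map(parse_partial_date)
        ther = ther.copy()
        ther["start_dt"] = st.map(lambda d: d.value if d else pd.NA).astype("Int64")
        ther["start_dt_prec"] = st.map(lambda d: d.precision if d else pd.NA)
        tables["THER"] = ther

    # referential check: child rows must point at a DEMO primaryid
    known = set(demo["primaryid"])
    for table, df in tables.items():
        if table == "DEMO" or "primaryid" not in df.columns:
            continue
        orphans = int((~df["primaryid"].isin(known)).sum())
        if orphans:
            log["orphans"][table] = orphans
            logger.warning("%s: %d %s rows reference unknown primaryids", quarter, orphans, table)

    for table in tables:
        tables[table]["quarter"] = quarter
    return RawQuarter(quarter=quarter, tables=tables, log=log)


def concat_quarters(quarters: Sequence[RawQuarter]) -> RawQuarter:
    """Row-wise union of several quarters; no implicit deduplication.

    Every quarter must present the same column set per table (optional
    tables may be absent from some quarters); a mismatch is fatal and the
    error names the differing columns.
    """
    if not quarters:
        raise ValueError("concat_quarters needs at least one quarter")
    if len(quarters) == 1:
        return quarters[0]
    names = sorted({t for q in quarters for t in q.tables})
    tables: Dict[str, pd.DataFrame] = {}
    for table in names:
        frames = [q.tables[table] for q in quarters if table in q.tables]
        cols0 = set(frames[0].columns)
        for f in frames[1:]:
            if set(f.columns) != cols0:
                diff = cols0.symmetric_difference(f.columns)
                raise ValueError(
                    f"inconsistent {table} columns across quarters: {sorted(diff)}"
                )
        tables[table] = pd.concat(frames, ignore_index=True)
    label = f"{quarters[0].quarter}-{quarters[-1].quarter}"
    log = {"per_quarter": {q.quarter: q.log for q in quarters}}
    return RawQuarter(quarter=label, tables=tables, log=log)


def _primaryid_sort_key(pids: pd.Series) -> pd.Series:
    """Key under which lexicographic order matches numeric order for
    all-digit primaryids: digit strings are zero-padded to a common width,
    other strings compare as-is."""
    width = int(pids.str.len().max() or 0)
    width = max(width, 1)
    is_num = pids.str.fullmatch(r"\d+").fillna(False)
    return pids.where(~is_num, pids.str.zfill(width))


def deduplicate(demo: pd.DataFrame) -> pd.DataFrame:
    """Keep one report version per case, per the FDA-recommended rule.

    For each CASEID the row with the maximal FDA_DT wins; ties are broken
    by the highest PRIMARYID (numeric comparison when the ids are digit
    strings).  Output is sorted by caseid, so the result is deterministic
    and the operation idempotent.
    """
    if demo["fda_dt"].isna().any():
        raise ValueError("deduplicate requires fda_dt on every row")
    key = _primaryid_sort_key(demo["primaryid"].astype(str))
    out = (
        demo.assign(_pidkey=key)
        .sort_values(["caseid", "fda_dt", "_pidkey"], kind="mergesort")
        .groupby("caseid", sort=False)
        .tail(1)
        .drop(columns="_pidkey")
        .sort_values("caseid", kind="mergesort")
        .reset_index(drop=True)
    )
    return out


def normalize_name(name: object) -> str:
    """Upper-case and collapse internal whitespace (FAERS drugname entry
    is free text)."""
    return re.sub(r"\s+", " ", str(name).strip()).upper()


def match_drug_rows(
    drug: pd.DataFrame,
    names: Iterable[str],
    role: str = "PS",
    substring: bool = False,
) -> pd.DataFrame:
    """Rows of the DRUG table naming any of ``names`` with the given role.

    A row matches if its ``drugname`` OR ``prod_ai`` equals (default) or
    contains (``substring=True``) any pattern after normalization.
    """
    patterns = [normalize_name(n) for n in names]
    if not patterns:
        raise ValueError("empty drug-name pattern list")
    if role not in ROLE_CODES:
        raise ValueError(f"unknown role code {role!r}; expected one of {sorted(ROLE_CODES)}")
    if drug.empty:
        return drug

    def _col(colname: str) -> pd.Series:
        if colname not in drug.columns:
            return pd.Series(False, index=drug.index)
        vals = drug[colname].fillna("").map(normalize_name)
        if substring:
            hit = pd.Series(False, index=drug.index)
            for p in patterns:
                hit |= vals.str.contains(re.escape(p), regex=True)
            return hit
        return vals.isin(patterns)

    name_hit = _col("drugname") | _col("prod_ai")
    role_hit = drug.get("role_cod", pd.Series(pd.NA, index=drug.index)).fillna("") == role
    return drug.loc[name_hit & role_hit]


def select_primary_suspect(
    drug: pd.DataFrame,
    names: Iterable[str],
    role: str = "PS",
    substring: bool = False,
) -> Set[str]:
    """Primaryids of reports where any named drug carries the given role."""
    return set(match_drug_rows(drug, names, role=role, substring=substring)["primaryid"])
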