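"""Drug–event record enumeration and 2×2 contingency tables.

Disproportionality statistics compare how often an event is reported
with the target drug against how often it is reported with everything
else.  The counting unit throughout is the *(deduplicated report,
distinct preferred term)* record — one report listing three distinct
PTs contributes three records — which is why a drug's record total can
exceed its case total.  For a term ``t`` and drug ``g``::

                 event t    other events
    drug g          a            b          a+b  (g's record total)
    other drugs     c            d          c+d
                   a+c          b+d          N

SOC-level tables count the same records after mapping each PT to its
(single, primary) system organ class; several same-SOC PTs on one
report still contribute one record each.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Sequence

import pandas as pd

from .cohort import CaseRecord

logger = logging.getLogger(__name__)

UNMAPPED_SOC = "unmapped"

RECORD_COLUMNS = ["primaryid", "drug", "pt"]


@dataclass(frozen=True)
class ContingencyTable:
    """Cell counts a, b, c, d of the 2×2 reporting table.

    Cells are floats so that tables reconstructed from published
    statistics (real-valued solutions) share the type; observed tables
    hold integral values.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValueError(f"negative cell {name}")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def cells(self) -> tuple:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class MeddraMap:
    """PT → (primary) SOC mapping, case-normalized.

    MedDRA itself is licensed, so the mapping is supplied by the user as
    a two-column ``pt,soc`` CSV (or built in code); synthetic runs use
    the generator's bundled mini-ontology.
    """

    pt_to_soc: Mapping[str, str]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple]) -> "MeddraMap":
        m: Dict[str, str] = {}
        for pt, soc in pairs:
            key = str(pt).strip().lower()
            val = str(soc).strip().lower()
            if key in m and m[key] != val:
                raise ValueError(f"PT {key!r} mapped to two SOCs: {m[key]!r}, {val!r}")
            m[key] = val
        return cls(pt_to_soc=m)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MeddraMap":
        df = pd.read_csv(path, dtype=str)
        cols = [c.strip().lower() for c in df.columns]
        df.columns = cols
        if "pt" not in cols or "soc" not in cols:
            raise ValueError("MedDRA map CSV needs 'pt' and 'soc' columns")
        return cls.from_pairs(zip(df["pt"], df["soc"]))

    def soc_of(self, pt: str) -> str:
        return self.pt_to_soc.get(str(pt).strip().lower(), UNMAPPED_SOC)

    @property
    def socs(self) -> set:
        return set(self.pt_to_soc.values())


def enumerate_records(cases: Mapping[str, Sequence[CaseRecord]]) -> pd.DataFrame:
    """Expand cohorts into the drug–event record table.

    ``cases`` maps a drug label to its (deduplicated) case records; the
    result has one row per (report, distinct PT) with columns
    ``primaryid, drug, pt``.
    """
    rows = []
    for drug, cohort in cases.items():
        for case in cohort:
            for pt in sorted(case.pts):
                rows.append((case.primaryid, drug, pt))
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def _check_records(records: pd.DataFrame) -> None:
    missing = set(RECORD_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"record table lacks columns {sorted(missing)}")


def build_pt_table(records: pd.DataFrame, drug: str, pt: str) -> ContingencyTable:
    """2×2 table for one (drug, preferred term) pair.

    A term absent from the whole dataset yields a valid table with
    a = c = 0 (flagged by the statistics layer, not an error here).
    """
    _check_records(records)
    is_drug = records["drug"] == drug
    is_pt = records["pt"] == pt
    a = int((is_drug & is_pt).sum())
    b = int((is_drug & ~is_pt).sum())
    c = int((~is_drug & is_pt).sum())
    d = int(len(records) - a - b - c)
    if a == 0 and c == 0:
        logger.info("term %r absent from dataset", pt)
    return ContingencyTable(a, b, c, d)


def map_to_soc(records: pd.DataFrame, mmap: MeddraMap) -> pd.DataFrame:
    """Attach the SOC of each record's PT; unmapped PTs get the
    ``unmapped`` pseudo-SOC (logged)."""
    if not mmap.pt_to_soc:
        raise ValueError("empty MedDRA map")
    out = records.copy()
    out["soc"] = out["pt"].map(mmap.soc_of)
    n_unmapped = int((out["soc"] == UNMAPPED_SOC).sum())
    if n_unmapped:
        logger.warning("%d records carry PTs absent from the SOC map", n_unmapped)
    return out


def build_soc_table(
    records: pd.DataFrame, drug: str, soc: str, mmap: MeddraMap
) -> ContingencyTable:
    """2×2 table for one (drug, system organ class) pair, counting each
    (report, PT) record once even when several PTs of one report share
    the SOC."""
    mapped = map_to_soc(records, mmap)
    is_drug = mapped["drug"] == drug
    is_soc = mapped["soc"] == str(soc).strip().lower()
    a = int((is_drug & is_soc).sum())
    b = int((is_drug & ~is_soc).sum())
    c = int((~is_drug & is_soc).sum())
    d = int(len(mapped) - a - b - c)
    return ContingencyTable(a, b, c, d)


def all_term_tables(
    records: pd.DataFrame,
    drug: str,
    level: str = "pt",
    mmap: Optional[MeddraMap] = None,
    min_n: int = 1,
) -> Dict[str, ContingencyTable]:
    """All 2×2 tables for one drug at PT or SOC level, vectorized.

    Only terms with ``a >= min_n`` for the drug are returned (the drug's
    other terms still contribute to the b/d margins, of course).
    """
    _check_records(records)
    if level not in {"pt", "soc"}:
        raise ValueError("level must be 'pt' or 'soc'")
    if level == "soc":
        if mmap is None:
            raise ValueError("SOC level requires a MedDRA map")
        records = map_to_soc(records, mmap)
    col = level
    total = len(records)
    is_drug = records["drug"] == drug
    drug_total = int(is_drug.sum())
    by_term_drug = records.loc[is_drug, col].value_counts()
    by_term_all = records[col].value_counts()
    out: Dict[str, ContingencyTable] = {}
    for term, a in by_term_drug.items():
        if a < min_n:
            continue
        a = int(a)
        c = int(by_term_all[term]) - a
        b = drug_total - a
        d = total - a - b - c
        out[str(term)] = ContingencyTable(a, b, c, d)
    return out
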