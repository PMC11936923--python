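"""Case-level cohort assembly and demographic descriptives.

A *case* is one deduplicated report joined across DEMO (demographics,
onset date), REAC (the set of distinct preferred terms on the report)
and THER (therapy start dates for the target drug).  Reports with no
coded reaction carry no analyzable information and are excluded with a
count.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from ._dates import PartialDate
from .faers_io import RawQuarter

logger = logging.getLogger(__name__)

# FAERS age unit codes -> factor converting the value to years
AGE_UNIT_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.18,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

# reporter occupation code -> category used in descriptive tables
OCCUPATION_CATEGORY = {
    "MD": "Physician",
    "CN": "Consumer",
    "HP": "Health professionals",
    "OT": "Health professionals",
    "PH": "Pharmacist",
}

MISSING = "Miss"
AGE_BIN_LABELS = ("<18", "18-65", "65-85", ">85", MISSING)
SEX_LABELS = ("Male", "Female", MISSING)


@dataclass(frozen=True)
class CaseRecord:
    """One deduplicated report, joined and normalized."""

    primaryid: str
    caseid: str
    age_years: Optional[float]
    sex: Optional[str]
    occupation: Optional[str]
    country: Optional[str]
    rept_yr: int
    event_dt: Optional[PartialDate]
    pts: FrozenSet[str]
    therapy_starts: Tuple[Tuple[str, PartialDate], ...] = ()


@dataclass
class DemographicSummary:
    """Counts and percentages mirroring a standard characteristics table.

    Every categorization (sex, age bin, reporter, year) partitions the
    cohort, so each block's counts sum to ``n_cases``.
    """

    n_cases: int
    sex: Dict[str, int]
    age: Dict[str, int]
    countries: Dict[str, int]  # top-k plus "Other"/"Miss"
    reporter: Dict[str, int]
    years: Dict[int, int]

    def percent(self, block: str, key) -> float:
        counts: Mapping = getattr(self, block)
        return pct(counts[key], self.n_cases)

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for block in ("sex", "age", "countries", "reporter", "years"):
            for key, n in getattr(self, block).items():
                rows.append((block, str(key), n, pct(n, self.n_cases)))
        return pd.DataFrame(rows, columns=["block", "category", "count", "percent"])


def pct(count: int, total: int, decimals: int = 1) -> float:
    """Percentage rounded half-up (so 39.55 -> 39.6, matching table style)."""
    if total <= 0:
        raise ValueError("total must be positive")
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(count) * 100 / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP)
    )


def normalize_age(value, code) -> Optional[float]:
    """Convert a FAERS (age, age_cod) pair to years.

    An absent unit code is treated as years; negative or unparseable
    values are returned as absent with a warning.
    """
    if value is None or (isinstance(value, float) and pd.isna(value)) or pd.isna(value):
        return None
    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    if v < 0:
        logger.warning("negative age %r discarded", value)
        return None
    c = None if code is None or pd.isna(code) else str(code).strip().upper()
    if not c:
        return v
    factor = AGE_UNIT_TO_YEARS.get(c)
    if factor is None:
        logger.warning("unknown age unit %r; treating value as missing", code)
        return None
    return v * factor


def _partial(value, prec) -> Optional[PartialDate]:
    if pd.isna(value):
        return None
    return PartialDate(int(value), str(prec))


def build_cohort(
    raw: RawQuarter,
    ids: Set[str],
    drug_seqs: Optional[Mapping[str, Set[str]]] = None,
) -> Tuple[List[CaseRecord], Dict[str, int]]:
    """Assemble one :class:`CaseRecord` per primaryid in ``ids``.

    ``raw.demo`` must already be deduplicated.  ``drug_seqs`` maps each
    primaryid to the DRUG-table sequence numbers of the target drug; when
    given, therapy start dates are restricted to those sequences.

    Returns the cohort plus an exclusion log; ids without any REAC row
    are excluded and counted under ``"no_reactions"``.
    """
    demo = raw.demo
    demo = demo[demo["primaryid"].isin(ids)]
    reac = raw.reac[raw.reac["primaryid"].isin(ids)]
    pts_by_id: Dict[str, Set[str]] = {}
    for pid, pt in zip(reac["primaryid"], reac.get("pt", pd.Series(dtype=str))):
        if pd.isna(pt):
            continue
        label = str(pt).strip().lower()
        if label:
            pts_by_id.setdefault(pid, set()).add(label)

    ther = raw.ther
    starts_by_id: Dict[str, List[Tuple[str, PartialDate]]] = {}
    if not ther.empty and "start_dt" in ther.columns:
        seq_col = "dsg_drug_seq" if "dsg_drug_seq" in ther.columns else None
        sub = ther[ther["primaryid"].isin(ids)]
        for _, row in sub.iterrows():
            d = _partial(row["start_dt"], row.get("start_dt_prec"))
            if d is None:
                continue
            seq = str(row[seq_col]) if seq_col else ""
            if drug_seqs is not None:
                allowed = drug_seqs.get(row["primaryid"], set())
                if seq not in {str(s) for s in allowed}:
                    continue
            starts_by_id.setdefault(row["primaryid"], []).append((seq, d))

    cases: List[CaseRecord] = []
    excluded = Counter()
    for _, row in demo.iterrows():
        pid = row["primaryid"]
        pts = pts_by_id.get(pid)
        if not pts:
            excluded["no_reactions"] += 1
            continue
        sex = row.get("sex")
        occ = row.get("occp_cod")
        country = row.get("occr_country")
        cases.append(
            CaseRecord(
                primaryid=pid,
                caseid=row["caseid"],
                age_years=normalize_age(row.get("age"), row.get("age_cod")),
                sex=None if pd.isna(sex) else str(sex).strip().upper() or None,
                occupation=None if pd.isna(occ) else str(occ).strip().upper() or None,
                country=None if pd.isna(country) else str(country).strip().upper() or None,
                rept_yr=int(row["rept_yr"]),
                event_dt=_partial(row.get("event_dt"), row.get("event_dt_prec")),
                pts=frozenset(pts),
                therapy_starts=tuple(starts_by_id.get(pid, ())),
            )
        )
    if excluded:
        logger.info("build_cohort exclusions: %s", dict(excluded))
    return cases, dict(excluded)


def _age_bin(age: Optional[float]) -> str:
    # bins partition: [0,18), [18,65), [65,85], (85,inf)
    if age is None:
        return MISSING
    if age < 18:
        return "<18"
    if age < 65:
        return "18-65"
    if age <= 85:
        return "65-85"
    return ">85"


def summarize_demographics(cohort: Sequence[CaseRecord], top_k_countries: int = 5) -> DemographicSummary:
    """Tabulate sex, age bins, top reporting countries, reporter category
    and reporting year over the cohort.  Fatal on an empty cohort."""
    if not cohort:
        raise ValueError("cannot summarize an empty cohort")
    n = len(cohort)
    sex = {k: 0 for k in SEX_LABELS}
    for c in cohort:
        if c.sex == "M":
            sex["Male"] += 1
        elif c.sex == "F":
            sex["Female"] += 1
        else:
            sex[MISSING] += 1  # UNK and absent both count as missing

    age = {k: 0 for k in AGE_BIN_LABELS}
    for c in cohort:
        age[_age_bin(c.age_years)] += 1

    country_counts = Counter(c.country if c.country else MISSING for c in cohort)
    top = country_counts.most_common()
    top_named = [kv for kv in top if kv[0] != MISSING][:top_k_countries]
    countries = dict(top_named)
    rest = n - sum(countries.values()) - country_counts.get(MISSING, 0)
    countries["Other"] = rest
    countries[MISSING] = country_counts.get(MISSING, 0)

    reporter = Counter()
    for c in cohort:
        reporter[OCCUPATION_CATEGORY.get(c.occupation or "", MISSING)] += 1

    years = Counter(c.rept_yr for c in cohort)
    return DemographicSummary(
        n_cases=n,
        sex=sex,
        age=age,
        countries=countries,
        reporter=dict(reporter),
        years=dict(sorted(years.items())),
    )
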