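"""The four disproportionality statistics and their decision rules.

Implemented exactly as commonly printed in FAERS pharmacovigilance
studies, on the 2×2 table (a, b, c, d) with N = a+b+c+d:

* ROR  = (a·d)/(b·c), with the lognormal 95% CI
  ``exp(ln ROR ± 1.96·sqrt(1/a + 1/b + 1/c + 1/d))``.
* PRR  = a(c+d) / (c(a+b)), with the Pearson chi-squared statistic
  ``(ad − bc)²·N / ((a+b)(c+d)(a+c)(b+d))`` (no continuity correction).
* IC   = log₂( a·N / ((a+c)(a+b)) ), the information component of the
  BCPNN family; IC025 = IC − 2·sqrt(V(IC)).  Two variance modes are
  offered: a fixed offset (2·sqrt(V) = 1.67, matching the near-constant
  gap between IC and IC025 in published tables of this form) and a
  delta-method variance ``(1/ln2)²·(1/a − 1/(a+b) + 1/(a+c) − 1/N)``.
* EBGM = a·N / ((a+c)(a+b)) — the raw relative reporting ratio, as this
  family of studies prints it (NOT the shrinkage estimator of the true
  multi-item gamma Poisson shrinker; see docs/methods.md) — with the
  same lognormal CI form as the ROR.

Note the exact identity IC = log₂(EBGM) under these definitions.

An event is flagged per algorithm (ROR CI low > 1 & n ≥ 3; PRR ≥ 2 &
χ² ≥ 4 & n ≥ 3; IC025 > 0; EBGM05 > 2) and called an adverse *reaction*
only when all four flag it.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .contingency import ContingencyTable, MeddraMap, all_term_tables

Z95 = 1.96
FIXED_IC_OFFSET = 1.67  # 2·sqrt(V(IC)) under the fixed-offset mode
ALGORITHMS = ("ror", "prr", "bcpnn", "mgps")


@dataclass(frozen=True)
class SignalThresholds:
    """Positivity criteria, individually overridable."""

    ror_ci_low: float = 1.0
    ror_min_n: int = 3
    prr_min: float = 2.0
    chi2_min: float = 4.0
    prr_min_n: int = 3
    ic025_min: float = 0.0
    ebgm05_min: float = 2.0

    def __post_init__(self):
        for f in ("ror_ci_low", "prr_min", "chi2_min", "ebgm05_min"):
            if getattr(self, f) <= 0:
                raise ValueError(f"threshold {f} must be strictly positive")


DEFAULT_THRESHOLDS = SignalThresholds()


@dataclass(frozen=True)
class SignalResult:
    """All four statistics, their lower bounds and flags for one term."""

    term: str
    level: str  # "pt" | "soc"
    n: int  # = a
    ror: float
    ror_ci95: Tuple[float, float]
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    flags: Dict[str, bool]
    combined: bool
    zero_cell_corrected: bool = False
    computable: bool = True


def _haldane(t: ContingencyTable) -> Tuple[ContingencyTable, bool]:
    """Haldane–Anscombe correction: +0.5 to every cell when any of
    b, c, d is zero (and a ≥ 1), so ratios and CIs stay finite."""
    if t.a >= 1 and (t.b == 0 or t.c == 0 or t.d == 0):
        return ContingencyTable(t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5), True
    return t, False


def _lognormal_ci(point: float, t: ContingencyTable) -> Tuple[float, float]:
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return (point * math.exp(-Z95 * se), point * math.exp(Z95 * se))


def compute_ror(t: ContingencyTable) -> Tuple[float, Tuple[float, float]]:
    """Reporting odds ratio with its lognormal 95% CI."""
    t, _ = _haldane(t)
    if t.a == 0 or t.b * t.c == 0:
        return math.nan, (math.nan, math.nan)
    ror = (t.a * t.d) / (t.b * t.c)
    return ror, _lognormal_ci(ror, t)


def compute_prr(t: ContingencyTable) -> Tuple[float, float]:
    """Proportional reporting ratio and the Pearson chi-squared statistic
    (no continuity correction)."""
    t, _ = _haldane(t)
    if t.a == 0 or t.c == 0:
        return math.nan, math.nan
    prr = (t.a * (t.c + t.d)) / (t.c * (t.a + t.b))
    num = (t.a * t.d - t.b * t.c) ** 2 * t.n
    den = (t.a + t.b) * (t.c + t.d) * (t.a + t.c) * (t.b + t.d)
    return prr, num / den


def compute_ic(
    t: ContingencyTable, mode: str = "fixed_offset"
) -> Tuple[float, float]:
    """Information component and its lower 95% bound IC025.

    ``mode="fixed_offset"`` subtracts the constant 1.67;
    ``mode="delta"`` uses the delta-method variance of log₂ of the
    relative reporting ratio.
    """
    t, _ = _haldane(t)
    if t.a == 0:
        return math.nan, math.nan
    rrr = t.a * t.n / ((t.a + t.c) * (t.a + t.b))
    ic = math.log2(rrr)
    if mode == "fixed_offset":
        return ic, ic - FIXED_IC_OFFSET
    if mode == "delta":
        v = (1 / math.log(2)) ** 2 * (
            1 / t.a - 1 / (t.a + t.b) + 1 / (t.a + t.c) - 1 / t.n
        )
        return ic, ic - 2 * math.sqrt(max(v, 0.0))
    raise ValueError(f"unknown IC variance mode {mode!r}")


def compute_ebgm(t: ContingencyTable) -> Tuple[float, float]:
    """Relative reporting ratio ("EBGM" in this table style — no
    gamma-Poisson shrinkage) and its lognormal lower 95% bound."""
    t, _ = _haldane(t)
    if t.a == 0:
        return math.nan, math.nan
    ebgm = t.a * t.n / ((t.a + t.c) * (t.a + t.b))
    lo, _hi = _lognormal_ci(ebgm, t)
    return ebgm, lo


def evaluate_signal(
    t: ContingencyTable,
    thresholds: SignalThresholds = DEFAULT_THRESHOLDS,
    term: str = "",
    level: str = "pt",
    ic_mode: str = "fixed_offset",
) -> SignalResult:
    """Compute all four statistics on one table and apply the thresholds.

    A table with a = 0 is returned as not-computable with every flag
    false rather than raising, so bulk scans stay total.
    """
    corrected_t, corrected = _haldane(t)
    n = int(round(t.a))
    if t.a == 0:
        nan = math.nan
        return SignalResult(
            term=term, level=level, n=0, ror=nan, ror_ci95=(nan, nan),
            prr=nan, chi2=nan, ic=nan, ic025=nan, ebgm=nan, ebgm05=nan,
            flags={k: False for k in ALGORITHMS}, combined=False,
            zero_cell_corrected=False, computable=False,
        )
    ror, ror_ci = compute_ror(corrected_t)
    prr, chi2 = compute_prr(corrected_t)
    ic, ic025 = compute_ic(corrected_t, mode=ic_mode)
    ebgm, ebgm05 = compute_ebgm(corrected_t)
    flags = {
        "ror": bool(ror_ci[0] > thresholds.ror_ci_low and n >= thresholds.ror_min_n),
        "prr": bool(
            prr >= thresholds.prr_min
            and chi2 >= thresholds.chi2_min
            and n >= thresholds.prr_min_n
        ),
        "bcpnn": bool(ic025 > thresholds.ic025_min),
        "mgps": bool(ebgm05 > thresholds.ebgm05_min),
    }
    return SignalResult(
        term=term, level=level, n=n, ror=ror, ror_ci95=ror_ci, prr=prr,
        chi2=chi2, ic=ic, ic025=ic025, ebgm=ebgm, ebgm05=ebgm05,
        flags=flags, combined=all(flags.values()),
        zero_cell_corrected=corrected,
    )


def evaluate_all(
    records: pd.DataFrame,
    drug: str,
    level: str = "pt",
    mmap: Optional[MeddraMap] = None,
    thresholds: SignalThresholds = DEFAULT_THRESHOLDS,
    ic_mode: str = "fixed_offset",
    min_n: int = 1,
) -> List[SignalResult]:
    """Evaluate every term reported with the drug at the given level."""
    tables = all_term_tables(records, drug, level=level, mmap=mmap, min_n=min_n)
    results = [
        evaluate_signal(t, thresholds, term=term, level=level, ic_mode=ic_mode)
        for term, t in sorted(tables.items())
    ]
    results.sort(key=lambda r: (-r.n, r.term))
    return results


@dataclass(frozen=True)
class IntersectionSummary:
    """Per-algorithm positive term sets and their overlap structure
    (the numbers behind a four-set Venn diagram)."""

    positive: Dict[str, FrozenSet[str]]
    fourway: FrozenSet[str]
    region_sizes: Dict[FrozenSet[str], int]


def intersect_positive(results: Sequence[SignalResult]) -> IntersectionSummary:
    """Intersect the four per-algorithm positive sets.

    ``region_sizes`` maps each non-empty algorithm combination to the
    number of terms positive on exactly that combination.
    """
    levels = {r.level for r in results}
    if len(levels) > 1:
        raise ValueError(f"results mix levels {sorted(levels)}")
    positive = {
        algo: frozenset(r.term for r in results if r.flags[algo]) for algo in ALGORITHMS
    }
    regions: Dict[FrozenSet[str], int] = {}
    for r in results:
        combo = frozenset(a for a in ALGORITHMS if r.flags[a])
        if combo:
            regions[combo] = regions.get(combo, 0) + 1
    fourway = frozenset(set.intersection(*(set(s) for s in positive.values())))
    return IntersectionSummary(positive=positive, fourway=fourway, region_sizes=regions)


NR = "NR"  # "not report": the drug has no record of the term


def compare_drugs(
    records: pd.DataFrame, drugs: Sequence[str], terms: Sequence[str]
) -> pd.DataFrame:
    """ROR-based head-to-head comparison across drugs for chosen terms.

    Each drug is compared against *all other* records in the dataset
    (the same contrast its own signal scan uses).  Rows where the drug
    never reported the term carry n = 0 and NR in place of the ROR.
    """
    if len(drugs) < 2:
        raise ValueError("compare_drugs needs at least two drugs")
    rows = []
    for drug in drugs:
        tables = all_term_tables(records, drug, level="pt", min_n=0)
        for term in terms:
            t = tables.get(term)
            if t is None or t.a == 0:
                rows.append((term, drug, 0, NR, NR, NR))
                continue
            ror, (lo, hi) = compute_ror(t)
            rows.append((term, drug, int(t.a), ror, lo, hi))
    return pd.DataFrame(rows, columns=["pt", "drug", "n", "ror", "ror_lo", "ror_hi"])


def reconstruct_counts(
    a: float, drug_total: float, ror: float, ebgm: float
) -> Tuple[ContingencyTable, Dict[str, float]]:
    """Complete a 2×2 table from published (a, drug total, ROR, EBGM).

    Validation utility: published tables print a, the drug's record
    total (a+b), the ROR and the relative reporting ratio; those four
    numbers determine real-valued c and d.  With b = drug_total − a and
    r = c/d = (a/b)/ROR, the relative-reporting-ratio equation
    ``ebgm = a·N/((a+c)(a+b))`` is linear in d::

        d = a·(a+b)·(1 − ebgm) / (ebgm·r·(a+b) − a·(1 + r))

    Returns the (non-rounded) table plus a consistency report
    re-evaluating all four statistics on it.
    """
    if ror <= 0 or ebgm <= 0:
        raise ValueError("ror and ebgm must be positive")
    if drug_total <= a:
        raise ValueError("drug_total must exceed a")
    b = drug_total - a
    r = (a / b) / ror
    denom = ebgm * r * (a + b) - a * (1 + r)
    numer = a * (a + b) * (1 - ebgm)
    if denom == 0:
        raise ValueError("inconsistent published statistics (degenerate system)")
    d = numer / denom
    c = r * d
    if c <= 0 or d <= 0:
        raise ValueError("inconsistent published statistics (no positive solution)")
    t = ContingencyTable(float(a), float(b), float(c), float(d))
    ror2, (lo, hi) = compute_ror(t)
    prr2, chi2 = compute_prr(t)
    ic2, _ = compute_ic(t)
    ebgm2, ebgm05 = compute_ebgm(t)
    report = {
        "ror": ror2, "ror_lo": lo, "ror_hi": hi,
        "prr": prr2, "chi2": chi2, "ic": ic2,
        "ebgm": ebgm2, "ebgm05": ebgm05,
    }
    return t, report


def results_to_frame(results: Sequence[SignalResult], decimals: int = 2) -> pd.DataFrame:
    """Flatten results to the standard signal-table CSV layout; statistics
    are rounded for presentation (full precision lives on the objects)."""
    rows = []
    for r in results:
        rows.append(
            dict(
                term=r.term, level=r.level, n=r.n,
                ror=round(r.ror, decimals) if not math.isnan(r.ror) else math.nan,
                ror_lo=round(r.ror_ci95[0], decimals) if not math.isnan(r.ror_ci95[0]) else math.nan,
                ror_hi=round(r.ror_ci95[1], decimals) if not math.isnan(r.ror_ci95[1]) else math.nan,
                prr=round(r.prr, decimals) if not math.isnan(r.prr) else math.nan,
                chi2=round(r.chi2, decimals) if not math.isnan(r.chi2) else math.nan,
                ic=round(r.ic, decimals) if not math.isnan(r.ic) else math.nan,
                ic025=round(r.ic025, decimals) if not math.isnan(r.ic025) else math.nan,
                ebgm=round(r.ebgm, decimals) if not math.isnan(r.ebgm) else math.nan,
                ebgm05=round(r.ebgm05, decimals) if not math.isnan(r.ebgm05) else math.nan,
                flag_ror=r.flags["ror"], flag_prr=r.flags["prr"],
                flag_bcpnn=r.flags["bcpnn"], flag_mgps=r.flags["mgps"],
                combined=r.combined,
            )
        )
    return pd.DataFrame(rows)
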