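"""Synthetic FAERS-style quarterly files with controlled signal structure.

The generator emulates the features of spontaneous-report data that the
analysis pipeline depends on: "$"-delimited DEMO/DRUG/REAC/THER files
split by quarter, follow-up report versions (the same CASEID re-filed
under a new PRIMARYID with a later FDA_DT), drug role codes, free-text
drug names in mixed case, MedDRA-like preferred terms with a bundled
PT→SOC mini-ontology, missing demographics, and Weibull-distributed
onset intervals.  Everything is reproducible from a single seed.

Generative model for reactions (chosen for a closed-form oracle): for a
report on drug g, each catalog PT *i* is included independently with
probability ``pi_i = m_g · w_i / Σ w``, where ``w_i = p_i · RR(g, i)``
multiplies the background frequency by the configured relative risk,
and reports with no PT are rejected and redrawn.  Because a report with
PT *i* is never empty, the conditional expectation is exact::

    E[a_i] = n_cases · pi_i / (1 − P0),   P0 = Π_j (1 − pi_j),

which :func:`expected_tables` evaluates; the per-drug intensity ``m_g``
is solved so that the *realized* mean number of distinct PTs per report
matches the configured target.
"""
from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .contingency import ContingencyTable, MeddraMap

# ---------------------------------------------------------------------------
# bundled mini-ontology: invented PT labels grouped into SOC-like classes.
# Structure (a flat PT -> single primary class map) resembles, but does not
# reproduce, the licensed MedDRA hierarchy.
# ---------------------------------------------------------------------------
MINI_ONTOLOGY: Tuple[Tuple[str, str], ...] = tuple(
    (pt, soc)
    for soc, pts in {
        "eye disorders": [
            "intraocular inflammation", "vision haze", "eye ache",
            "retinal vessel blockage", "retinal bleed", "vitreous specks",
            "lens clouding", "ocular pressure rise", "tear overproduction",
            "light sensitivity", "macular distortion", "eye surface dryness",
            "conjunctival redness", "anterior chamber cells", "sudden vision loss",
        ],
        "general and administration site conditions": [
            "injection site ache", "treatment ineffective", "fatigue feeling",
            "general malaise", "fever episode", "chills episode",
            "product taste complaint", "therapy discontinued effect",
        ],
        "injury and procedural complications": [
            "procedural pain", "wrong dose administered", "device handling issue",
            "accidental exposure", "post procedural swelling", "fall at home",
        ],
        "nervous system disorders": [
            "head pain", "dizzy spell", "brain ischemic event",
            "tremor episode", "numb limb", "taste loss", "sleepiness",
        ],
        "cardiac disorders": [
            "heart rhythm irregular", "chest tightness", "heart attack event",
            "palpitation episode", "heart failure worsening", "slow heart rate",
        ],
        "gastrointestinal disorders": [
            "stomach upset", "loose stools", "constipated bowel",
            "mouth dryness", "abdominal cramp", "queasy feeling",
        ],
        "infections and infestations": [
            "eye infection", "lung infection", "urinary infection",
            "skin infection", "sinus infection", "bloodstream infection",
        ],
        "skin and subcutaneous disorders": [
            "skin rash", "itchy skin", "hive outbreak",
            "skin peeling", "bruise marks", "hair thinning",
        ],
    }.items()
    for pt in pts
)

DEFAULT_QUARTERS: Tuple[str, ...] = (
    "2022Q1", "2022Q2", "2022Q3", "2022Q4",
    "2023Q1", "2023Q2", "2023Q3", "2023Q4",
    "2024Q1", "2024Q2",
)

# demographic mixes typical of an ophthalmology spontaneous-report cohort
DEFAULT_SEX_PROBS = {"M": 0.355, "F": 0.396, None: 0.249}
DEFAULT_AGE_BIN_PROBS = {"<18": 0.020, "18-65": 0.170, "65-85": 0.321, ">85": 0.066, None: 0.423}
DEFAULT_COUNTRY_PROBS = {
    "US": 0.556, "JP": 0.077, "CA": 0.049, "GB": 0.046, "IN": 0.046,
    "FR": 0.050, "DE": 0.050, "BR": 0.040, "AU": 0.040, None: 0.046,
}
DEFAULT_OCCP_PROBS = {"MD": 0.613, "CN": 0.296, "HP": 0.050, "OT": 0.021, "PH": 0.018, None: 0.002}


@dataclass
class DrugSpec:
    """Per-drug generation settings: cohort size and the probability that
    the drug is filed as primary suspect on its own reports."""

    n_cases: int
    ps_prob: float = 1.0

    def __post_init__(self):
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if not 0.0 <= self.ps_prob <= 1.0:
            raise ValueError("ps_prob must be in [0, 1]")


@dataclass
class SimConfig:
    """Full parameterization of the synthetic report generator.

    Defaults emulate the study conditions of a single-drug FAERS scan:
    a target cohort of 2,735 reports averaging ~2.08 distinct PTs each
    (≈5,691 drug–event records), onset intervals from a
    Weibull(scale 133.72 d, shape 0.80) with ~16.5% of reports carrying
    full therapy-start and onset dates (≈450 analyzable intervals), and
    demographic mixes with realistic missingness.  Background cohort
    sizes for the comparator and pooled-other drugs are fixed synthetic
    choices (see docs/methods.md).
    """

    seed: int
    drugs: Dict[str, DrugSpec] = field(
        default_factory=lambda: {
            "FARICIMAB": DrugSpec(2735),
            "RANIBIZUMAB": DrugSpec(6000),
            "AFLIBERCEPT": DrugSpec(5000),
            "OTHERDRUG": DrugSpec(15000),
        }
    )
    pt_catalog: Tuple[Tuple[str, str], ...] = MINI_ONTOLOGY
    background_freq: Optional[Sequence[float]] = None  # uniform when None
    signals: Tuple[Tuple[str, str, float], ...] = (
        ("FARICIMAB", "intraocular inflammation", 20.0),
        ("FARICIMAB", "retinal vessel blockage", 12.0),
        ("FARICIMAB", "ocular pressure rise", 10.0),
        ("FARICIMAB", "vitreous specks", 8.0),
        ("FARICIMAB", "sudden vision loss", 6.0),
    )
    mean_pts_per_case: float = 2.08  # realized mean distinct PTs per report
    duplicate_rate: float = 0.2
    concomitant_prob: float = 0.3
    sex_probs: Mapping[Optional[str], float] = field(default_factory=lambda: dict(DEFAULT_SEX_PROBS))
    age_bin_probs: Mapping[Optional[str], float] = field(default_factory=lambda: dict(DEFAULT_AGE_BIN_PROBS))
    country_probs: Mapping[Optional[str], float] = field(default_factory=lambda: dict(DEFAULT_COUNTRY_PROBS))
    occp_probs: Mapping[Optional[str], float] = field(default_factory=lambda: dict(DEFAULT_OCCP_PROBS))
    tto_alpha: float = 133.72
    tto_beta: float = 0.80
    tto_full_date_fraction: float = 0.165
    quarters: Tuple[str, ...] = DEFAULT_QUARTERS

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name, spec in list(self.drugs.items()):
            if isinstance(spec, int):
                self.drugs[name] = DrugSpec(spec)
            elif isinstance(spec, dict):
                self.drugs[name] = DrugSpec(**spec)
        for probs in (self.sex_probs, self.age_bin_probs, self.country_probs, self.occp_probs):
            if not math.isclose(sum(probs.values()), 1.0, abs_tol=1e-9):
                raise ValueError("probability vectors must sum to 1")
        for _, _, rr in self.signals:
            if rr < 0:
                raise ValueError("relative risks must be >= 0")
        if not 0.0 <= self.duplicate_rate <= 1.0:
            raise ValueError("duplicate_rate must be in [0, 1]")
        if self.background_freq is not None and len(self.background_freq) != len(self.pt_catalog):
            raise ValueError("background_freq length must match pt_catalog")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "signals" in raw:
            raw["signals"] = tuple(tuple(s) for s in raw["signals"])
        if "pt_catalog" in raw:
            raw["pt_catalog"] = tuple(tuple(p) for p in raw["pt_catalog"])
        return cls(**raw)

    @property
    def pts(self) -> List[str]:
        return [pt for pt, _ in self.pt_catalog]

    def meddra_map(self) -> MeddraMap:
        return MeddraMap.from_pairs(self.pt_catalog)

    def rr_matrix(self) -> Dict[str, np.ndarray]:
        """Per-drug relative-risk multiplier over the PT catalog."""
        idx = {pt: i for i, pt in enumerate(self.pts)}
        out = {}
        for drug in self.drugs:
            rr = np.ones(len(idx))
            for d, pt, val in self.signals:
                if d == drug:
                    if pt not in idx:
                        raise ValueError(f"signal PT {pt!r} not in catalog")
                    rr[idx[pt]] = val
            out[drug] = rr
        return out


# ---------------------------------------------------------------------------
# closed-form expectations (the oracle the end-to-end tests compare against)
# ---------------------------------------------------------------------------

def _solve_intensity(w_norm: np.ndarray, target_mean: float) -> float:
    """Find m with m / (1 − Π(1 − m·w̃_i)) == target realized PT mean."""
    def realized(m: float) -> float:
        p0 = float(np.prod(1.0 - m * w_norm))
        return m / (1.0 - p0)

    lo, hi = 1e-9, target_mean
    if realized(hi) < target_mean:  # cannot happen for target > 1, guard anyway
        return hi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if realized(mid) < target_mean:
            lo = mid
        else:
            hi = mid
    m = 0.5 * (lo + hi)
    if np.any(m * w_norm >= 1.0):
        raise ValueError("PT inclusion probability reaches 1; lower the RR or mean PTs")
    return m


@dataclass
class ExpectedTables:
    """Analytic expected contingency cells per (drug, PT) under the model."""

    drugs: List[str]
    pts: List[str]
    exp_a: Dict[str, np.ndarray]  # E[a] per PT, per drug

    @property
    def drug_totals(self) -> Dict[str, float]:
        return {d: float(self.exp_a[d].sum()) for d in self.drugs}

    @property
    def grand_total(self) -> float:
        return float(sum(self.drug_totals.values()))

    def table(self, drug: str, pt: str) -> ContingencyTable:
        i = self.pts.index(pt)
        a = float(self.exp_a[drug][i])
        b = self.drug_totals[drug] - a
        c = float(sum(self.exp_a[d][i] for d in self.drugs if d != drug))
        d = self.grand_total - a - b - c
        return ContingencyTable(a, b, c, d)

    def ror(self, drug: str, pt: str) -> float:
        t = self.table(drug, pt)
        return (t.a * t.d) / (t.b * t.c)


def expected_tables(config: SimConfig) -> ExpectedTables:
    p = (
        np.asarray(config.background_freq, dtype=float)
        if config.background_freq is not None
        else np.ones(len(config.pt_catalog))
    )
    p = p / p.sum()
    rr = config.rr_matrix()
    exp_a: Dict[str, np.ndarray] = {}
    for drug, spec in config.drugs.items():
        w = p * rr[drug]
        w_norm = w / w.sum()
        m = _solve_intensity(w_norm, config.mean_pts_per_case)
        pi = m * w_norm
        p0 = float(np.prod(1.0 - pi))
        exp_a[drug] = spec.n_cases * pi / (1.0 - p0)
    return ExpectedTables(drugs=list(config.drugs), pts=list(config.pts), exp_a=exp_a)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _quarter_bounds(label: str) -> Tuple[_dt.date, _dt.date]:
    year, q = int(label[:4]), int(label[-1])
    start = _dt.date(year, 3 * (q - 1) + 1, 1)
    end_month = 3 * q
    if end_month == 12:
        end = _dt.date(year, 12, 31)
    else:
        end = _dt.date(year, end_month + 1, 1) - _dt.timedelta(days=1)
    return start, end


def quarter_of(date: _dt.date) -> str:
    return f"{date.year}Q{(date.month - 1) // 3 + 1}"


def _yyyymmdd(date: _dt.date) -> int:
    return date.year * 10000 + date.month * 100 + date.day


def _sample_categorical(rng: np.random.Generator, probs: Mapping, size: int) -> np.ndarray:
    keys = list(probs.keys())
    pvals = np.array([probs[k] for k in keys], dtype=float)
    pvals = pvals / pvals.sum()
    idx = rng.choice(len(keys), size=size, p=pvals)
    return np.array([keys[i] for i in idx], dtype=object)


_AGE_BIN_RANGES = {"<18": (1, 17), "18-65": (18, 64), "65-85": (65, 85), ">85": (86, 99)}


def _draw_pt_sets(
    rng: np.random.Generator, n: int, pi: np.ndarray
) -> List[np.ndarray]:
    """Independent per-PT Bernoulli inclusion, empty rows redrawn."""
    incl = rng.random((n, pi.size)) < pi
    empty = ~incl.any(axis=1)
    while empty.any():
        incl[empty] = rng.random((int(empty.sum()), pi.size)) < pi
        empty = ~incl.any(axis=1)
    return [np.flatnonzero(row) for row in incl]


def _style_name(rng: np.random.Generator, name: str) -> str:
    k = rng.integers(3)
    return [name.upper(), name.lower(), name.title()][k]


def generate(config: SimConfig, outdir: Union[str, Path]) -> Dict:
    """Write quarterly FAERS-style files plus ground truth to ``outdir``.

    Emits ``DEMO<yy>Q<q>.txt`` (and DRUG/REAC/THER) per quarter in the
    "$"-delimited dialect :func:`faersignal.faers_io.read_quarter`
    accepts, a ``pt_soc_map.csv``, and ``manifest.json`` recording the
    ground truth: per-signal expected cells, duplicate case groups, and
    the true Weibull onset parameters.  Returns the manifest.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise OSError(f"cannot create output directory {outdir}: {exc}") from exc

    rng = np.random.default_rng(config.seed)
    pts = config.pts
    exp = expected_tables(config)

    span_start, _ = _quarter_bounds(config.quarters[0])
    _, span_end = _quarter_bounds(config.quarters[-1])
    span_days = (span_end - span_start).days

    p = (
        np.asarray(config.background_freq, dtype=float)
        if config.background_freq is not None
        else np.ones(len(pts))
    )
    p = p / p.sum()
    rr = config.rr_matrix()

    demo_rows: List[tuple] = []
    drug_rows: List[tuple] = []
    reac_rows: List[tuple] = []
    ther_rows: List[tuple] = []
    duplicate_groups: Dict[str, List[str]] = {}

    pid_counter = 10_000_000
    case_counter = 0
    drug_names = list(config.drugs)

    for drug, spec in config.drugs.items():
        n = spec.n_cases
        w = p * rr[drug]
        w_norm = w / w.sum()
        m = _solve_intensity(w_norm, config.mean_pts_per_case)
        pt_sets = _draw_pt_sets(rng, n, m * w_norm)

        sex = _sample_categorical(rng, config.sex_probs, n)
        age_bin = _sample_categorical(rng, config.age_bin_probs, n)
        country = _sample_categorical(rng, config.country_probs, n)
        occp = _sample_categorical(rng, config.occp_probs, n)
        fda_offset = rng.integers(0, span_days + 1, size=n)
        n_versions = np.where(
            rng.random(n) < config.duplicate_rate, rng.integers(2, 4, size=n), 1
        )
        has_tto = rng.random(n) < config.tto_full_date_fraction
        tto_days = config.tto_alpha * rng.weibull(config.tto_beta, size=n)
        role = np.where(rng.random(n) < spec.ps_prob, "PS", "SS")
        has_conc = rng.random(n) < config.concomitant_prob

        for i in range(n):
            case_counter += 1
            caseid = f"C{case_counter:08d}"
            first_fda = span_start + _dt.timedelta(days=int(fda_offset[i]))

            # demographics shared by all versions of the case
            if age_bin[i] is None:
                age_val, age_cod = "", ""
            else:
                lo_a, hi_a = _AGE_BIN_RANGES[age_bin[i]]
                years = int(rng.integers(lo_a, hi_a + 1))
                style = rng.integers(10)
                if style < 1 and years % 10 == 0:
                    age_val, age_cod = str(years // 10), "DEC"
                elif style < 2:
                    age_val, age_cod = str(years * 12), "MON"
                else:
                    age_val, age_cod = str(years), "YR"

            # onset dates: full precision only for the TTO subset
            if has_tto[i]:
                start_date = span_start + _dt.timedelta(days=int(rng.integers(0, max(span_days - 30, 1))))
                event_date = start_date + _dt.timedelta(days=int(round(tto_days[i])))
                start_s = str(_yyyymmdd(start_date))
                event_s = str(_yyyymmdd(event_date))
            else:
                u = rng.random()
                event_s = "" if u < 0.5 else str(_yyyymmdd(first_fda))[:6]  # month precision
                start_s = ""

            versions = int(n_versions[i])
            pids = []
            fda = first_fda
            for v in range(versions):
                pid_counter += 1
                pid = str(pid_counter)
                pids.append(pid)
                if v > 0:
                    fda = min(fda + _dt.timedelta(days=int(rng.integers(1, 91))), span_end)
                demo_rows.append(
                    (
                        pid, caseid, event_s, str(_yyyymmdd(fda)), age_val, age_cod,
                        "" if sex[i] is None else sex[i],
                        "" if occp[i] is None else occp[i],
                        "" if country[i] is None else country[i],
                    )
                )
                drug_rows.append(
                    (pid, caseid, "1", role[i], _style_name(rng, drug), drug)
                )
                if has_conc[i] and len(drug_names) > 1:
                    other = drug_names[int(rng.integers(len(drug_names)))]
                    if other != drug:
                        drug_rows.append(
                            (pid, caseid, "2", "C", _style_name(rng, other), other)
                        )
                for j in pt_sets[i]:
                    reac_rows.append((pid, caseid, pts[j].title()))
                if start_s:
                    ther_rows.append((pid, caseid, "1", start_s))
            if versions > 1:
                duplicate_groups[caseid] = pids

    demo = pd.DataFrame(
        demo_rows,
        columns=["primaryid", "caseid", "event_dt", "fda_dt", "age", "age_cod", "sex", "occp_cod", "occr_country"],
    )
    drugf = pd.DataFrame(
        drug_rows, columns=["primaryid", "caseid", "drug_seq", "role_cod", "drugname", "prod_ai"]
    )
    reac = pd.DataFrame(reac_rows, columns=["primaryid", "caseid", "pt"])
    ther = pd.DataFrame(ther_rows, columns=["primaryid", "caseid", "dsg_drug_seq", "start_dt"])

    demo["_q"] = demo["fda_dt"].map(lambda s: quarter_of(_dt.date(int(s[:4]), int(s[4:6]), int(s[6:8]))))
    q_of_pid = dict(zip(demo["primaryid"], demo["_q"]))
    for frame in (drugf, reac, ther):
        frame["_q"] = frame["primaryid"].map(q_of_pid)

    for label in config.quarters:
        yy, qn = label[2:4], label[5]
        for name, frame in (("DEMO", demo), ("DRUG", drugf), ("REAC", reac), ("THER", ther)):
            sub = frame[frame["_q"] == label].drop(columns="_q")
            sub.to_csv(outdir / f"{name}{yy}Q{qn}.txt", sep="$", index=False, lineterminator="\n")

    pd.DataFrame(config.pt_catalog, columns=["pt", "soc"]).to_csv(
        outdir / "pt_soc_map.csv", index=False, lineterminator="\n"
    )

    manifest = {
        "seed": config.seed,
        "quarters": list(config.quarters),
        "n_cases": {d: s.n_cases for d, s in config.drugs.items()},
        "n_reports_emitted": int(len(demo)),
        "duplicate_groups": duplicate_groups,
        "tto": {"alpha": config.tto_alpha, "beta": config.tto_beta,
                "full_date_fraction": config.tto_full_date_fraction},
        "signals": [
            {
                "drug": d, "pt": pt, "rr": rrv,
                "expected_cells": dict(zip("abcd", exp.table(d, pt).cells())),
                "expected_ror": exp.ror(d, pt),
            }
            for d, pt, rrv in config.signals
        ],
        "expected_drug_record_totals": exp.drug_totals,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
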