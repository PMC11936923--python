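"""End-to-end signal-detection pipeline with stage-level provenance.

Ties ingestion → deduplication → primary-suspect filtering → cohort
descriptives → contingency building → four-algorithm evaluation →
time-to-onset modelling into one deterministic run that writes every
table as CSV/JSON plus a manifest of counts at each stage (the numbers
a screening flowchart would report).  All randomness lives in the
synthetic generator; given the same inputs the pipeline's outputs are
identical.
"""
from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Union

import pandas as pd

from . import __version__
from .cohort import build_cohort, summarize_demographics
from .contingency import MeddraMap, RECORD_COLUMNS
from .faers_io import (
    RawQuarter,
    concat_quarters,
    deduplicate,
    match_drug_rows,
    normalize_name,
    read_quarter,
)
from .signal_stats import (
    DEFAULT_THRESHOLDS,
    SignalThresholds,
    compare_drugs,
    evaluate_all,
    intersect_positive,
    results_to_frame,
)
from .tto_weibull import cumulative_curve, extract_tto, fit_weibull, summarize_tto

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the manifest so far."""

    def __init__(self, stage: str, message: str, manifest: Optional[dict] = None):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage
        self.manifest = manifest or {}


@dataclass
class PipelineConfig:
    """What to analyze: where the quarters live, which drug is the target
    (with its free-text name patterns), optional comparators, the PT→SOC
    map, and the decision thresholds."""

    data_dir: Union[str, Path]
    quarters: Sequence[str]
    target: str
    target_patterns: Sequence[str]
    comparators: Mapping[str, Sequence[str]] = field(default_factory=dict)
    compare_terms: Sequence[str] = ()
    meddra_map: Optional[Union[str, Path, MeddraMap]] = None
    thresholds: SignalThresholds = DEFAULT_THRESHOLDS
    ic_mode: str = "fixed_offset"
    min_n: int = 1
    substring_match: bool = False


def quarter_range(start: str, end: str) -> List[str]:
    """Inclusive list of quarter labels, e.g. 2023Q3..2024Q2."""
    y0, q0 = int(start[:4]), int(start[5])
    y1, q1 = int(end[:4]), int(end[5])
    out = []
    y, q = y0, q0
    while (y, q) <= (y1, q1):
        out.append(f"{y}Q{q}")
        q += 1
        if q == 5:
            y, q = y + 1, 1
    return out


def build_records(
    dedup_demo: pd.DataFrame,
    drug_table: pd.DataFrame,
    reac_table: pd.DataFrame,
    name_groups: Mapping[str, Sequence[str]],
    substring: bool = False,
) -> pd.DataFrame:
    """Drug–event records over *all* deduplicated reports.

    Each record is one (report, distinct PT) pair labelled with the
    report's primary-suspect drug.  Reports whose PS drug matches one of
    ``name_groups``'s pattern lists receive that canonical label; every
    other report keeps its normalized free-text name and forms the
    comparison background.
    """
    kept = set(dedup_demo["primaryid"])
    role = (
        drug_table["role_cod"]
        if "role_cod" in drug_table.columns
        else pd.Series(pd.NA, index=drug_table.index)
    )
    ps = drug_table[
        (role.fillna("") == "PS") & drug_table["primaryid"].isin(kept)
    ].copy()
    base = ps.get("prod_ai", pd.Series(pd.NA, index=ps.index))
    fallback = ps.get("drugname", pd.Series(pd.NA, index=ps.index))
    label = base.fillna(fallback).fillna("").map(normalize_name)
    ps["drug"] = label
    for canonical, patterns in name_groups.items():
        hit = match_drug_rows(ps, patterns, role="PS", substring=substring)
        ps.loc[hit.index, "drug"] = canonical
    pairs = ps[["primaryid", "drug"]].drop_duplicates()

    reac = reac_table[reac_table["primaryid"].isin(kept)].copy()
    reac["pt"] = reac["pt"].fillna("").map(lambda s: str(s).strip().lower())
    reac = reac[reac["pt"] != ""][["primaryid", "pt"]].drop_duplicates()
    records = pairs.merge(reac, on="primaryid", how="inner")
    return records[RECORD_COLUMNS].reset_index(drop=True)


def run_pipeline(config: PipelineConfig, outdir: Union[str, Path]) -> dict:
    """Execute the full analysis and write all artifacts to ``outdir``.

    Returns the run manifest.  Any stage failure raises
    :class:`PipelineError` naming the stage, after writing the manifest
    accumulated so far.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "software": {"name": "faersignal", "version": __version__},
        "timestamp": _dt.datetime.now().isoformat(timespec="seconds"),
        "inputs": {"data_dir": str(config.data_dir), "quarters": list(config.quarters)},
        "target": {"name": config.target, "patterns": list(config.target_patterns)},
        "thresholds": vars(config.thresholds),
        "ic_mode": config.ic_mode,
        "counts": {},
    }

    def _fail(stage: str, message: str):
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        raise PipelineError(stage, message, manifest)

    # -- ingest -------------------------------------------------------------
    try:
        raw = concat_quarters(
            [read_quarter(config.data_dir, q) for q in config.quarters]
        )
    except (OSError, ValueError) as exc:
        _fail("ingest", str(exc))
    manifest["counts"]["reports_in"] = int(len(raw.demo))

    # -- deduplicate --------------------------------------------------------
    demo_d = deduplicate(raw.demo)
    manifest["counts"]["after_dedup"] = int(len(demo_d))
    dedup_raw = RawQuarter(raw.quarter, {**raw.tables, "DEMO": demo_d}, raw.log)

    # -- primary-suspect filter --------------------------------------------
    groups = {config.target: list(config.target_patterns), **{k: list(v) for k, v in config.comparators.items()}}
    target_rows = match_drug_rows(
        raw.drug, config.target_patterns, role="PS", substring=config.substring_match
    )
    target_ids = set(target_rows["primaryid"]) & set(demo_d["primaryid"])
    if not target_ids:
        _fail(
            "select",
            f"no deduplicated report names {config.target_patterns!r} as primary suspect",
        )
    manifest["counts"]["ps_cases"] = len(target_ids)

    # -- cohort + demographics ---------------------------------------------
    seq_col = "drug_seq" if "drug_seq" in target_rows.columns else None
    drug_seqs: Dict[str, set] = {}
    if seq_col:
        for pid, seq in zip(target_rows["primaryid"], target_rows[seq_col]):
            drug_seqs.setdefault(pid, set()).add(str(seq))
    cohort, excl = build_cohort(dedup_raw, target_ids, drug_seqs or None)
    manifest["counts"]["cohort_cases"] = len(cohort)
    manifest["counts"]["excluded_no_reactions"] = excl.get("no_reactions", 0)
    if not cohort:
        _fail("cohort", "every selected report lacked coded reactions")
    demo_summary = summarize_demographics(cohort)
    demo_summary.as_frame().to_csv(outdir / "demographics.csv", index=False)

    # -- records + signals --------------------------------------------------
    records = build_records(
        demo_d, raw.drug, raw.reac, groups, substring=config.substring_match
    )
    manifest["counts"]["total_records"] = int(len(records))
    manifest["counts"]["drug_event_records"] = int((records["drug"] == config.target).sum())

    mmap: Optional[MeddraMap] = None
    if isinstance(config.meddra_map, MeddraMap):
        mmap = config.meddra_map
    elif config.meddra_map is not None:
        mmap = MeddraMap.from_csv(config.meddra_map)

    pt_results = evaluate_all(
        records, config.target, level="pt",
        thresholds=config.thresholds, ic_mode=config.ic_mode, min_n=config.min_n,
    )
    results_to_frame(pt_results).to_csv(outdir / "signals_pt.csv", index=False)
    inter = intersect_positive(pt_results)
    with open(outdir / "intersections.json", "w") as fh:
        json.dump(
            {
                "positive": {k: sorted(v) for k, v in inter.positive.items()},
                "fourway": sorted(inter.fourway),
                "region_sizes": {"+".join(sorted(k)): v for k, v in inter.region_sizes.items()},
            },
            fh, indent=1,
        )
    manifest["counts"]["pt_terms_evaluated"] = len(pt_results)
    manifest["counts"]["pt_fourway_positive"] = len(inter.fourway)

    if mmap is not None:
        soc_results = evaluate_all(
            records, config.target, level="soc", mmap=mmap,
            thresholds=config.thresholds, ic_mode=config.ic_mode, min_n=config.min_n,
        )
        results_to_frame(soc_results).to_csv(outdir / "signals_soc.csv", index=False)
        manifest["counts"]["soc_terms_evaluated"] = len(soc_results)

    # -- time to onset -------------------------------------------------------
    ttos, tto_excl = extract_tto(cohort)
    manifest["counts"]["tto_records"] = len(ttos)
    tto_out: dict = {"n": len(ttos), "exclusions": tto_excl}
    if ttos:
        pd.DataFrame(
            {"primaryid": [r.primaryid for r in ttos], "tto_days": [r.tto_days for r in ttos]}
        ).to_csv(outdir / "tto_records.csv", index=False)
        summary = summarize_tto(ttos)
        tto_out.update(median=summary["median"], q1=summary["q1"], q3=summary["q3"])
        if len(ttos) >= 10:
            try:
                fit = fit_weibull(ttos)
            except (ValueError, RuntimeError) as exc:
                _fail("tto", str(exc))
            tto_out.update(
                alpha=fit.scale, alpha_ci95=list(fit.scale_ci95),
                beta=fit.shape, beta_ci95=list(fit.shape_ci95),
                log_likelihood=fit.log_likelihood,
                failure_class=fit.failure_class,
            )
            cumulative_curve(ttos, fit).to_csv(outdir / "cumulative_incidence.csv", index=False)
    with open(outdir / "tto_summary.json", "w") as fh:
        json.dump(tto_out, fh, indent=1)

    # -- drug comparison -----------------------------------------------------
    if config.comparators:
        terms = list(config.compare_terms)
        if not terms:
            terms = [r.term for r in pt_results if r.combined][:25]
        comparison = compare_drugs(
            records, [config.target, *config.comparators], terms
        )
        comparison.to_csv(outdir / "comparison.csv", index=False)
        manifest["counts"]["compared_terms"] = len(terms)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    logger.info("pipeline complete: %s", manifest["counts"])
    return manifest
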