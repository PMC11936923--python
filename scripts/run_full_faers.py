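#!/usr/bin/env python
"""Optional integration run against a real FAERS quarterly download.

The headline full-database figures (thousands of cases, >100 four-way
positive PTs, month-scale onset medians) require the actual FAERS ASCII
files, which are not bundled; download the quarterly ASCII packages
from the FDA site, unpack each quarter's ``*.txt`` tables into one
directory, and point this script at it::

    python scripts/run_full_faers.py --quarters /path/to/faers \
        --from 2022Q1 --to 2024Q2 --map /path/to/pt_soc_map.csv --out results/full

A PT->SOC mapping CSV must be supplied by the user (MedDRA is licensed).
"""
from __future__ import annotations

import argparse
import json

from faersignal.pipeline import PipelineConfig, quarter_range, run_pipeline

FARICIMAB_TERMS = [
    "VABYSMO",
    "FARICIMAB",
    "Vascular Endothelial Growth Factor Inhibitors Faricimab",
    "Blinded Faricimab",
]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--quarters", required=True)
    parser.add_argument("--from", dest="start", default="2022Q1")
    parser.add_argument("--to", dest="end", default="2024Q2")
    parser.add_argument("--map", dest="map_path", default=None)
    parser.add_argument("--out", required=True)
    args = parser.parse_args()

    config = PipelineConfig(
        data_dir=args.quarters,
        quarters=quarter_range(args.start, args.end),
        target="FARICIMAB",
        target_patterns=FARICIMAB_TERMS,
        comparators={"RANIBIZUMAB": ["RANIBIZUMAB"], "AFLIBERCEPT": ["AFLIBERCEPT"]},
        meddra_map=args.map_path,
    )
    manifest = run_pipeline(config, args.out)
    print(json.dumps(manifest["counts"], indent=1))


if __name__ == "__main__":
    main()
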