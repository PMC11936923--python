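import numpy as np
import pandas as pd
import pytest

from faersignal.cohort import CaseRecord
from faersignal.contingency import RECORD_COLUMNS


def write_quarter(path, demo=None, drug=None, reac=None, ther=None, tag="22Q1"):
    """Write "$"-delimited fixture files into ``path``; each argument is a
    list of lines (header first) or None to omit the table."""
    for name, lines in (("DEMO", demo), ("DRUG", drug), ("REAC", reac), ("THER", ther)):
        if lines is None:
            continue
        (path / f"{name}{tag}.txt").write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def quarter_dir(tmp_path):
    """A minimal well-formed quarter: two reports for one drug."""
    return write_quarter(
        tmp_path,
        demo=[
            "primaryid$caseid$event_dt$fda_dt$age$age_cod$sex$occp_cod$occr_country",
            "1001$C1001$20221215$20230105$72$YR$F$MD$US",
            "1002$C1002$202211$20230120$$$M$CN$JP",
        ],
        drug=[
            "primaryid$caseid$drug_seq$role_cod$drugname$prod_ai",
            "1001$C1001$1$PS$Vabysmo$FARICIMAB",
            "1002$C1002$1$PS$faricimab$FARICIMAB",
            "1002$C1002$2$C$Aspirin$ASPIRIN",
        ],
        reac=[
            "primaryid$caseid$pt",
            "1001$C1001$Uveitis",
            "1001$C1001$Eye pain",
            "1002$C1002$UVEITIS",
        ],
        ther=[
            "primaryid$caseid$dsg_drug_seq$start_dt",
            "1001$C1001$1$20221201",
        ],
    )


def make_records(spec):
    """Build a drug-event record table from (drug, pt, count) triples,
    assigning one synthetic report per record (the margins only depend
    on the counts)."""
    rows = []
    i = 0
    for drug, pt, count in spec:
        for _ in range(count):
            i += 1
            rows.append((str(i), drug, pt))
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


@pytest.fixture
def toy_records():
    """Hand-countable fixture with a=10, b=20, c=30, d=240 for ('X','p')."""
    return make_records(
        [("X", "p", 10), ("X", "q", 20), ("Y", "p", 30), ("Y", "r", 240)]
    )


def make_case(primaryid="1", caseid=None, pts=("headache",), event=None, starts=(),
              age=None, sex=None, occ=None, country=None, year=2023):
    from faersignal._dates import PartialDate

    return CaseRecord(
        primaryid=primaryid,
        caseid=caseid or f"C{primaryid}",
        age_years=age,
        sex=sex,
        occupation=occ,
        country=country,
        rept_yr=year,
        event_dt=event,
        pts=frozenset(pts),
        therapy_starts=tuple(starts),
    )
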