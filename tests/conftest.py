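"""Shared fixtures: a hand-written miniature quarter and small synthetic runs."""

import textwrap

import pandas as pd
import pytest

from faersig import faers_io


def _write(path, text):
    path.write_text(textwrap.dedent(text).strip() + "\n")
    return path


@pytest.fixture
def tiny_quarter(tmp_path):
    """Seven-table fixture: 5 reports, one duplicated case, mixed units.

    Reports 101-104 are distinct cases; 105 is an older version of case
    C4 (same caseid as 104, earlier fda_dt). Vonoprazan is primary
    suspect on 101, 102 and 104(105); on 103 it is only concomitant.
    """
    paths = {}
    paths["demo"] = _write(tmp_path / "demo.txt", """
        primaryid$caseid$fda_dt$event_dt$sex$age$age_cod$wt$wt_cod$reporter_country$occp_cod
        101$C1$20240105$20240103$F$5$DEC$154$LBS$US$CN
        102$C2$20240110$20240108$M$30$YR$70$KG$JP$MD
        103$C3$20240201$$F$400$YR$$$US$HP
        104$C4$20240301$20240210$$$$$$BR$PH
        105$C4$20240101$20240210$M$40$YR$80$KG$BR$PH
    """)
    paths["drug"] = _write(tmp_path / "drug.txt", """
        primaryid$drug_seq$role_cod$drugname
        101$1$PS$Voquezna® (vonoprazan)
        101$2$C$Aspirin
        102$1$PS$VONOPRAZAN FUMARATE
        102$2$SS$Warfarin
        103$1$PS$OMEPRAZOLE
        103$2$C$vonoprazan
        104$1$PS$VONOPRAZAN
        104$2$I$Clarithromycin
        105$1$PS$VONOPRAZAN
    """)
    paths["reac"] = _write(tmp_path / "reac.txt", """
        primaryid$pt
        101$NAUSEA
        101$NAUSEA
        101$HEADACHE
        102$DIARRHOEA
        103$NAUSEA
        104$RENAL IMPAIRMENT
        105$RENAL IMPAIRMENT
    """)
    paths["outc"] = _write(tmp_path / "outc.txt", """
        primaryid$outc_cod
        101$OT
        102$HO
        104$DE
        104$HO
    """)
    paths["ther"] = _write(tmp_path / "ther.txt", """
        primaryid$dsg_drug_seq$start_dt
        101$1$20240101
        102$1$20240101
        104$1$20240201
    """)
    paths["indi"] = _write(tmp_path / "indi.txt", """
        primaryid$indi_pt
        101$GASTROOESOPHAGEAL REFLUX DISEASE
    """)
    paths["rpsr"] = _write(tmp_path / "rpsr.txt", """
        primaryid$rpsr_cod
        101$CSM
    """)
    return paths


@pytest.fixture
def tiny_standardized(tiny_quarter):
    bundle = faers_io.parse_quarter(tiny_quarter)
    return faers_io.standardize(bundle)


@pytest.fixture
def tiny_cases(tiny_standardized):
    cases = faers_io.build_cases(tiny_standardized)
    deduped, _ = faers_io.deduplicate(cases)
    return deduped


def make_cases_frame(rows):
    """Build a minimal cases frame from (primaryid, caseid, fda_dt) tuples."""
    df = pd.DataFrame(rows, columns=["primaryid", "caseid", "fda_dt"])
    df["fda_date"] = pd.to_datetime(df["fda_dt"], format="%Y%m%d",
                                    errors="coerce")
    df["fda_date_order"] = df["fda_date"]
    return df
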