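"""2x2 contingency tables for drug-event disproportionality.

The counting unit is the unique deduplicated report. For a focal-drug
cohort F inside a database of N reports, the table for event label L is

    a = reports in F with L        b = reports in F without L
    c = reports outside F with L   d = reports outside F without L

so a+b is the cohort size and a+c the event margin, both within the
stratum being analysed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .faers_io import SIGNAL_AGE_BANDS, assign_age_band


@dataclass(frozen=True)
class ContingencyTable:
    """Cell counts for one drug-event (or serious/non-serious) 2x2 table."""

    a: float
    b: float
    c: float
    d: float
    label: str = ""
    stratum: str | None = None

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative cell in table {self.label!r}")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def expected_a(self) -> float:
        """Expected a-cell under row/column independence."""
        return (self.a + self.b) * (self.a + self.c) / self.n

    def cells(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


def build_pt_tables(
    case_ids: Iterable[str],
    reactions: pd.DataFrame,
    focal_ids: Iterable[str],
    stratum: str | None = None,
) -> dict[str, ContingencyTable]:
    """One table per preferred term observed anywhere in the database.

    ``reactions`` must already be PT-deduplicated per report (one row per
    (primaryid, pt)); rows whose report is not in ``case_ids`` (e.g.
    removed duplicates) are ignored.
    """
    ids = set(map(str, case_ids))
    focal = set(map(str, focal_ids))
    if not focal <= ids:
        raise ValueError("focal ids are not a subset of the case ids")
    n_total = len(ids)
    n_focal = len(focal)
    reac = reactions[reactions["primaryid"].astype(str).isin(ids)]
    pid = reac["primaryid"].astype(str)
    is_focal = pid.isin(focal)
    counts = (
        pd.DataFrame({"pt": reac["pt"], "focal": is_focal})
        .groupby("pt")["focal"]
        .agg(a="sum", total="count")
    )
    tables: dict[str, ContingencyTable] = {}
    for pt, row in counts.iterrows():
        a = int(row["a"])
        c = int(row["total"]) - a
        tables[str(pt)] = ContingencyTable(
            a=a, b=n_focal - a, c=c, d=(n_total - n_focal) - c,
            label=str(pt), stratum=stratum,
        )
    return tables


def build_soc_tables(
    reactions: pd.DataFrame,
    pt_to_soc: Mapping[str, str],
    case_ids: Iterable[str],
    focal_ids: Iterable[str],
    per_report: bool = True,
    stratum: str | None = None,
) -> dict[str, ContingencyTable]:
    """One table per system organ class.

    With ``per_report=True`` (default) the counting unit is the report: a
    report counts once per SOC even when several of its PTs map there, and
    the margins are report counts. With ``per_report=False`` the unit is
    the (report, PT) occurrence: SOC a-cells sum their PT a-cells and the
    margins are occurrence totals. PTs absent from the mapping are
    collected under ``"UNMAPPED"`` and tallied in a warning.
    """
    ids = set(map(str, case_ids))
    focal = set(map(str, focal_ids))
    if not focal <= ids:
        raise ValueError("focal ids are not a subset of the case ids")
    reac = reactions[reactions["primaryid"].astype(str).isin(ids)].copy()
    mapping = {str(k).upper(): str(v) for k, v in pt_to_soc.items()}
    soc = reac["pt"].astype(str).str.upper().map(mapping)
    n_unmapped = int(soc.isna().sum())
    if n_unmapped:
        warnings.warn(
            f"{n_unmapped} reaction rows with PTs missing from the SOC map; "
            "collected under UNMAPPED", stacklevel=2,
        )
    reac["soc"] = soc.fillna("UNMAPPED")
    is_focal = reac["primaryid"].astype(str).isin(focal)
    if per_report:
        keep = ~reac.duplicated(subset=["primaryid", "soc"])
        reac, is_focal = reac[keep], is_focal[keep]
        n_total, n_focal = len(ids), len(focal)
    else:
        # occurrence counting: margins are (report, PT) pair totals
        n_total, n_focal = len(reac), int(is_focal.sum())
    counts = (
        pd.DataFrame({"soc": reac["soc"], "focal": is_focal})
        .groupby("soc")["focal"]
        .agg(a="sum", total="count")
    )
    tables = {}
    for soc_name, row in counts.iterrows():
        a = int(row["a"])
        c = int(row["total"]) - a
        tables[str(soc_name)] = ContingencyTable(
            a=a, b=n_focal - a, c=c, d=(n_total - n_focal) - c,
            label=str(soc_name), stratum=stratum,
        )
    return tables


def stratify(cases: pd.DataFrame, by: str) -> dict[str, pd.DataFrame]:
    """Partition deduplicated cases by sex or signal age band.

    Missing values form an explicit ``"missing"`` stratum, which callers
    exclude from stratified signal statistics. Every report lands in
    exactly one stratum.
    """
    if by == "sex":
        key = cases["sex"].where(
            cases["sex"].isin(["female", "male"]), "missing"
        )
    elif by == "age_band":
        key = assign_age_band(cases["age_years"], bands=SIGNAL_AGE_BANDS)
    else:
        raise ValueError(f"unknown stratification variable {by!r}")
    out: dict[str, pd.DataFrame] = {}
    for label, sub in cases.groupby(key, sort=True):
        out[str(label)] = sub.reset_index(drop=True)
    for label in out:
        if len(out[label]) == 0:
            warnings.warn(f"stratum {label} is empty", stacklevel=2)
    return out


def tables_to_frame(tables: Mapping[str, ContingencyTable]) -> pd.DataFrame:
    """Flatten a table dict to a tidy frame (label, stratum, a, b, c, d)."""
    rows = [
        {"label": t.label, "stratum": t.stratum, "a": t.a, "b": t.b,
         "c": t.c, "d": t.d}
        for t in tables.values()
    ]
    return pd.DataFrame(rows, columns=["label", "stratum", "a", "b", "c", "d"])
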