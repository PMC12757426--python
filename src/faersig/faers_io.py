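"""Parsing, standardization and deduplication of FAERS-style quarterly tables.

FAERS distributes spontaneous adverse-event reports as '$'-delimited ASCII
tables (DEMO, DRUG, REAC, OUTC, THER, INDI, RPSR), one header line each.
This module turns a quarter's files into analysis-ready pandas DataFrames:
units are normalized (age to years, weight to kilograms), drug names are
canonicalized, duplicate report versions are collapsed to one record per
patient case, and the focal-drug cohort is selected by primary-suspect role.

Missing values are represented as pandas NA / NaN throughout; the empty
string in an input file means missing.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TABLE_NAMES = ("demo", "drug", "reac", "outc", "ther", "indi", "rpsr")

#: FAERS drug role codes -> analysis role labels
ROLE_CODES = {
    "PS": "primary_suspect",
    "SS": "secondary_suspect",
    "C": "concomitant",
    "I": "interacting",
}

#: FAERS outcome codes; every code except OT marks a report as serious
SERIOUS_OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI"})
OUTCOME_CODES = SERIOUS_OUTCOME_CODES | {"OT"}

OUTCOME_LABELS = {
    "DE": "death",
    "LT": "life_threatening",
    "HO": "hospitalization",
    "DS": "disability",
    "CA": "congenital_anomaly",
    "RI": "required_intervention",
    "OT": "other",
}

SEX_CODES = {"F": "female", "M": "male"}

REPORTER_CODES = {
    "CN": "consumer",
    "MD": "physician",
    "HP": "health professional",
    "OT": "health professional",
    "PH": "pharmacist",
}

# age-unit code -> factor converting to years
AGE_UNIT_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1775,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

# weight-unit code -> factor converting to kilograms
WEIGHT_UNIT_TO_KG = {
    "KG": 1.0,
    "LBS": 0.45359237,
    "GMS": 1.0 / 1000.0,
}

AGE_BOUNDS_YEARS = (0.0, 120.0)
WEIGHT_BOUNDS_KG = (1.0, 500.0)

_DRUG_NAME_KEEP = re.compile(r"[^A-Z0-9 ]+")
_WS = re.compile(r"\s+")

#: descriptive age bands (years): label -> [low, high)
DESCRIPTIVE_AGE_BANDS = (
    ("<18", 0.0, 18.0),
    ("18-64.9", 18.0, 65.0),
    ("65-85", 65.0, 85.0),
    (">=85", 85.0, np.inf),
)

#: coarser bands used for stratified signal analysis
SIGNAL_AGE_BANDS = (
    ("<18", 0.0, 18.0),
    ("18-64.9", 18.0, 65.0),
    (">=65", 65.0, np.inf),
)


class MissingColumnError(ValueError):
    """A mandatory column is absent from an input table."""


@dataclass
class CleaningLog:
    """Counters accumulated while standardizing a quarter."""

    rows_parsed: dict[str, int] = field(default_factory=dict)
    age_out_of_bounds: int = 0
    weight_out_of_bounds: int = 0
    unknown_age_units: dict[str, int] = field(default_factory=dict)
    unknown_weight_units: dict[str, int] = field(default_factory=dict)
    duplicate_reports_removed: int = 0
    reac_rows_collapsed: int = 0

    def as_dict(self) -> dict:
        return {
            "rows_parsed": dict(self.rows_parsed),
            "age_out_of_bounds": self.age_out_of_bounds,
            "weight_out_of_bounds": self.weight_out_of_bounds,
            "unknown_age_units": dict(self.unknown_age_units),
            "unknown_weight_units": dict(self.unknown_weight_units),
            "duplicate_reports_removed": self.duplicate_reports_removed,
            "reac_rows_collapsed": self.reac_rows_collapsed,
        }


def _read_table(path: Path, delimiter: str) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep=delimiter,
        dtype=str,
        keep_default_na=False,
        engine="python",
    )
    df.columns = [c.strip().lower() for c in df.columns]
    # empty string means missing in FAERS ASCII
    return df.replace("", pd.NA)


def parse_quarter(
    paths: Mapping[str, str | Path], delimiter: str = "$"
) -> dict[str, pd.DataFrame]:
    """Read one quarter's tables into string-typed DataFrames.

    Parameters
    ----------
    paths
        Mapping from table name (``demo``, ``drug``, ``reac``, ``outc``,
        ``ther``, ``indi``, ``rpsr``; case-insensitive) to file path.
        Tables not supplied come back as empty frames.
    delimiter
        Field separator; ``'$'`` is the FAERS ASCII convention, ``','``
        is accepted for fixtures.

    Returns
    -------
    dict mapping each of the seven table names to a DataFrame with
    lower-cased columns. Every supplied table must contain a
    ``primaryid`` column.
    """
    bundle: dict[str, pd.DataFrame] = {}
    supplied = {k.lower(): Path(v) for k, v in paths.items()}
    unknown = set(supplied) - set(TABLE_NAMES)
    if unknown:
        raise ValueError(f"unknown table names: {sorted(unknown)}")
    for name in TABLE_NAMES:
        if name not in supplied:
            bundle[name] = pd.DataFrame(columns=["primaryid"])
            continue
        path = supplied[name]
        if not path.exists():
            raise FileNotFoundError(f"{name} table not found: {path}")
        df = _read_table(path, delimiter)
        if len(df.columns) == 0 or len(df) == 0:
            warnings.warn(f"{name} table {path} is empty", stacklevel=2)
            if "primaryid" not in df.columns:
                df = pd.DataFrame(columns=["primaryid"])
        if "primaryid" not in df.columns:
            raise MissingColumnError(
                f"table {name} ({path}) lacks mandatory column PRIMARYID"
            )
        bundle[name] = df
        logger.info("parsed %s: %d rows", name, len(df))
    return bundle


def normalize_drug_name(name: str | None) -> str | None:
    """Uppercase, strip characters outside [A-Z0-9 ], collapse whitespace."""
    if name is None or (isinstance(name, float) and np.isnan(name)) or name is pd.NA:
        return None
    up = str(name).upper()
    up = _DRUG_NAME_KEEP.sub(" ", up)
    up = _WS.sub(" ", up).strip()
    return up or None


def _convert_units(
    values: pd.Series,
    codes: pd.Series,
    factors: Mapping[str, float],
    bounds: tuple[float, float],
    unknown_tally: dict[str, int],
) -> tuple[pd.Series, int]:
    vals = pd.to_numeric(values, errors="coerce")
    code = codes.fillna("").astype(str).str.strip().str.upper()
    factor = code.map(factors)
    unknown = code[(factor.isna()) & (code != "") & vals.notna()]
    for c, n in unknown.value_counts().items():
        unknown_tally[c] = unknown_tally.get(c, 0) + int(n)
    out = vals * factor.astype(float)
    lo, hi = bounds
    oob = out.notna() & ((out < lo) | (out > hi))
    out[oob] = np.nan
    return out, int(oob.sum())


def parse_date(series: pd.Series) -> pd.Series:
    """Parse 8-digit YYYYMMDD strings to datetimes; partial dates -> NaT."""
    s = series.astype("string").str.strip()
    full = s.str.fullmatch(r"\d{8}", na=False)
    out = pd.to_datetime(s.where(full), format="%Y%m%d", errors="coerce")
    return out


def pad_partial_date(series: pd.Series) -> pd.Series:
    """Zero-pad YYYY / YYYYMM to the first day, for ordering only."""
    s = series.astype("string").str.strip()
    s = s.where(~s.str.fullmatch(r"\d{4}", na=False), s + "0101")
    s = s.where(~s.str.fullmatch(r"\d{6}", na=False), s + "01")
    return pd.to_datetime(s.where(s.str.fullmatch(r"\d{8}", na=False)),
                          format="%Y%m%d", errors="coerce")


@dataclass
class StandardizedTables:
    """Cleaned per-table frames plus the counters produced along the way."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    ther: pd.DataFrame
    log: CleaningLog


def standardize(bundle: Mapping[str, pd.DataFrame]) -> StandardizedTables:
    """Normalize units, codes and names across the parsed bundle.

    Age is converted to years (DEC x10, MON /12, WK /52.1775, DY /365.25,
    HR /8766), weight to kg (LBS x0.45359237, GMS /1000); values outside
    plausibility bounds (age 0-120 y, weight 1-500 kg) and values with
    unknown unit codes become missing and are counted. Drug names are
    normalized to uppercase [A-Z0-9 ]. Reaction rows are de-duplicated to
    one per (report, preferred term).
    """
    log = CleaningLog()
    for name in TABLE_NAMES:
        log.rows_parsed[name] = len(bundle.get(name, ()))

    demo = bundle["demo"].copy()
    if len(demo):
        if "age" in demo.columns:
            demo["age_years"], n_oob = _convert_units(
                demo["age"], demo.get("age_cod", pd.Series("YR", index=demo.index)),
                AGE_UNIT_TO_YEARS, AGE_BOUNDS_YEARS, log.unknown_age_units,
            )
            log.age_out_of_bounds = n_oob
        else:
            demo["age_years"] = np.nan
        if "wt" in demo.columns:
            demo["weight_kg"], n_oob = _convert_units(
                demo["wt"], demo.get("wt_cod", pd.Series("KG", index=demo.index)),
                WEIGHT_UNIT_TO_KG, WEIGHT_BOUNDS_KG, log.unknown_weight_units,
            )
            log.weight_out_of_bounds = n_oob
        else:
            demo["weight_kg"] = np.nan
        sex_raw = demo.get("sex", pd.Series(pd.NA, index=demo.index))
        demo["sex"] = (
            sex_raw.astype("string").str.strip().str.upper().map(SEX_CODES)
            .fillna("unknown")
        )
        occp = demo.get("occp_cod", pd.Series(pd.NA, index=demo.index))
        demo["reporter_type"] = (
            occp.astype("string").str.strip().str.upper().map(REPORTER_CODES)
            .fillna("unknown")
        )
        demo["fda_date"] = parse_date(demo.get("fda_dt", pd.Series(pd.NA, index=demo.index)))
        demo["fda_date_order"] = pad_partial_date(
            demo.get("fda_dt", pd.Series(pd.NA, index=demo.index))
        )
        demo["event_date"] = parse_date(
            demo.get("event_dt", pd.Series(pd.NA, index=demo.index))
        )
        demo["country"] = demo.get(
            "reporter_country", pd.Series(pd.NA, index=demo.index)
        )
    else:
        demo = pd.DataFrame(
            columns=["primaryid", "caseid", "age_years", "weight_kg", "sex",
                     "reporter_type", "fda_date", "fda_date_order",
                     "event_date", "country"]
        )

    drug = bundle["drug"].copy()
    if len(drug):
        drug["drug_name"] = drug.get(
            "drugname", pd.Series(pd.NA, index=drug.index)
        ).map(normalize_drug_name)
        drug["role"] = (
            drug.get("role_cod", pd.Series(pd.NA, index=drug.index))
            .astype("string").str.strip().str.upper().map(ROLE_CODES)
        )
    else:
        drug = pd.DataFrame(columns=["primaryid", "drug_name", "role", "drug_seq"])

    reac = bundle["reac"].copy()
    if len(reac):
        reac["pt"] = reac.get("pt", pd.Series(pd.NA, index=reac.index)).astype(
            "string"
        ).str.strip().str.upper()
        reac = reac[reac["pt"].notna() & (reac["pt"] != "")]
        before = len(reac)
        reac = reac.drop_duplicates(subset=["primaryid", "pt"]).reset_index(drop=True)
        log.reac_rows_collapsed = before - len(reac)
    else:
        reac = pd.DataFrame(columns=["primaryid", "pt"])

    outc = bundle["outc"].copy()
    if len(outc):
        outc["outc_cod"] = outc.get(
            "outc_cod", pd.Series(pd.NA, index=outc.index)
        ).astype("string").str.strip().str.upper()
        outc = outc[outc["outc_cod"].isin(OUTCOME_CODES)]
    else:
        outc = pd.DataFrame(columns=["primaryid", "outc_cod"])

    ther = bundle["ther"].copy()
    if len(ther):
        ther["start_date"] = parse_date(
            ther.get("start_dt", pd.Series(pd.NA, index=ther.index))
        )
    else:
        ther = pd.DataFrame(columns=["primaryid", "start_date", "dsg_drug_seq"])

    return StandardizedTables(demo=demo, drug=drug, reac=reac, outc=outc,
                              ther=ther, log=log)


def build_cases(std: StandardizedTables, quarter: str | None = None) -> pd.DataFrame:
    """Assemble one row per report with demographics, outcomes, seriousness.

    ``serious`` is true iff the report carries at least one outcome in
    {DE, LT, HO, DS, CA, RI}; OT alone is non-serious.
    """
    demo = std.demo
    cases = demo[
        ["primaryid", "caseid", "fda_date", "fda_date_order", "event_date",
         "sex", "age_years", "weight_kg", "country", "reporter_type"]
    ].copy() if len(demo) else pd.DataFrame(
        columns=["primaryid", "caseid", "fda_date", "fda_date_order",
                 "event_date", "sex", "age_years", "weight_kg", "country",
                 "reporter_type"]
    )
    if len(std.outc):
        grouped = std.outc.groupby("primaryid")["outc_cod"].agg(
            lambda s: frozenset(s.dropna())
        )
        cases["outcomes"] = cases["primaryid"].map(grouped)
    else:
        cases["outcomes"] = None
    cases["outcomes"] = cases["outcomes"].apply(
        lambda s: s if isinstance(s, frozenset) else frozenset()
    )
    cases["serious"] = cases["outcomes"].apply(
        lambda s: bool(s & SERIOUS_OUTCOME_CODES)
    )
    if quarter is not None:
        cases["quarter"] = quarter
    return cases


def deduplicate(cases: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Collapse report versions: keep, per case id, the latest FDA date.

    Ties on (caseid, fda_date) are broken by the largest numeric primaryid.
    Records lacking a caseid are retained as their own group. Output is
    sorted by caseid (then primaryid) so repeated runs are identical.

    Returns the deduplicated frame and the number of rows removed.
    """
    if len(cases) == 0:
        return cases.copy(), 0
    df = cases.copy()
    df["_pid_num"] = pd.to_numeric(df["primaryid"], errors="coerce")
    missing_case = df["caseid"].isna()
    if missing_case.any():
        warnings.warn(
            f"{int(missing_case.sum())} records lack a caseid; kept as singletons",
            stacklevel=2,
        )
    # orderable date: full-precision if present, zero-padded partial otherwise
    order_date = df["fda_date"]
    if "fda_date_order" in df.columns:
        order_date = order_date.fillna(df["fda_date_order"])
    df["_order_date"] = order_date
    df["_group"] = df["caseid"].astype("string")
    df.loc[missing_case, "_group"] = "\x00MISSING\x00" + df.loc[
        missing_case, "primaryid"
    ].astype(str)
    df = df.sort_values(
        ["_group", "_order_date", "_pid_num"],
        kind="mergesort", na_position="first",
    )
    keep = df.drop_duplicates(subset=["_group"], keep="last")
    n_removed = len(df) - len(keep)
    keep = keep.sort_values(
        ["_group", "_pid_num"], kind="mergesort"
    ).drop(columns=["_pid_num", "_order_date", "_group"]).reset_index(drop=True)
    return keep, n_removed


def select_primary_suspect(
    drug: pd.DataFrame,
    targets: Iterable[str],
    mode: str = "substring",
) -> set[str]:
    """Report ids whose primary-suspect drug matches any target name.

    ``substring`` mode (default) matches a target as a whitespace-token
    substring of the normalized name, so salt forms such as
    "VONOPRAZAN FUMARATE" match target "VONOPRAZAN". ``exact`` requires
    the full normalized name.
    """
    target_list = [t for t in (normalize_drug_name(t) for t in targets) if t]
    if not target_list:
        raise ValueError("target drug-name set is empty")
    ps = drug[(drug["role"] == "primary_suspect") & drug["drug_name"].notna()]
    if mode == "exact":
        hit = ps["drug_name"].isin(target_list)
    elif mode == "substring":
        def _match(name: str) -> bool:
            tokens = name.split()
            for t in target_list:
                t_tokens = t.split()
                n = len(t_tokens)
                if any(tokens[i:i + n] == t_tokens
                       for i in range(len(tokens) - n + 1)):
                    return True
            return False
        hit = ps["drug_name"].map(_match)
    else:
        raise ValueError(f"unknown match mode {mode!r}")
    return set(ps.loc[hit, "primaryid"].astype(str))


def assign_age_band(
    age_years: pd.Series, bands=DESCRIPTIVE_AGE_BANDS
) -> pd.Series:
    """Label ages by band; missing ages -> 'missing'. Bands are [low, high)."""
    out = pd.Series("missing", index=age_years.index, dtype=object)
    for label, lo, hi in bands:
        mask = age_years.notna() & (age_years >= lo) & (age_years < hi)
        out[mask] = label
    return out


def impute_weight(
    cases: pd.DataFrame, missing_threshold: float = 0.10
) -> tuple[pd.DataFrame, dict]:
    """Median-impute weight within (sex, descriptive age band) cells.

    Imputation only runs when the missing fraction is below
    ``missing_threshold`` (default 10%); above it the data are returned
    unchanged with ``performed=False`` — at the missingness levels typical
    of spontaneous reports (~80%) the rule never triggers. Cells with no
    observed weights stay missing. Imputed rows are flagged in
    ``weight_imputed``.
    """
    df = cases.copy()
    df["weight_imputed"] = False
    n = len(df)
    if n == 0:
        return df, {"performed": False, "missing_fraction": 0.0, "n_imputed": 0}
    missing = df["weight_kg"].isna()
    frac = float(missing.sum()) / n
    info = {"performed": False, "missing_fraction": frac, "n_imputed": 0}
    if frac >= missing_threshold or not missing.any():
        return df, info
    band = assign_age_band(df["age_years"])
    medians = df.groupby([df["sex"], band])["weight_kg"].transform("median")
    fill = missing & medians.notna()
    n_empty_cells = int((missing & medians.isna()).sum())
    if n_empty_cells:
        warnings.warn(
            f"{n_empty_cells} missing weights in cells with no observed "
            "weight; left missing", stacklevel=2,
        )
    df.loc[fill, "weight_kg"] = medians[fill]
    df.loc[fill, "weight_imputed"] = True
    info.update(performed=True, n_imputed=int(fill.sum()))
    return df, info
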