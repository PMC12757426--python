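"""Synthetic spontaneous-report database with known ground truth.

Emulates the statistical structure of a FAERS quarter around one focal
drug: each report is assigned a primary-suspect drug (the focal drug with
probability ``focal_drug_share``, otherwise a background drug), and each
preferred term (PT) occurs independently with its background probability,
multiplied by a planted relative reporting ratio when the report's suspect
drug is the focal one. Onset intervals for focal-drug reports follow a
Weibull law in days; demographics, outcome seriousness, duplicates and
partial dates are injected at configured rates so the cleaning stages have
something to clean.

The generator writes the same '$'-delimited DEMO/DRUG/REAC/OUTC/THER
schema that :mod:`faersig.faers_io` parses, and a truth table giving, for
every PT, the generating ratio and the expected 2x2 cell probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: default PT panel: (pt, soc, background probability per report)
DEFAULT_BACKGROUND_PTS: tuple[tuple[str, str, float], ...] = (
    ("NAUSEA", "GASTROINTESTINAL DISORDERS", 0.040),
    ("DIARRHOEA", "GASTROINTESTINAL DISORDERS", 0.030),
    ("VOMITING", "GASTROINTESTINAL DISORDERS", 0.025),
    ("ABDOMINAL PAIN UPPER", "GASTROINTESTINAL DISORDERS", 0.012),
    ("ABDOMINAL DISTENSION", "GASTROINTESTINAL DISORDERS", 0.008),
    ("DYSPEPSIA", "GASTROINTESTINAL DISORDERS", 0.007),
    ("GASTROOESOPHAGEAL REFLUX DISEASE", "GASTROINTESTINAL DISORDERS", 0.006),
    ("ABDOMINAL DISCOMFORT", "GASTROINTESTINAL DISORDERS", 0.009),
    ("FLATULENCE", "GASTROINTESTINAL DISORDERS", 0.005),
    ("HAEMATEMESIS", "GASTROINTESTINAL DISORDERS", 0.002),
    ("GASTRIC POLYPS", "GASTROINTESTINAL DISORDERS", 0.0015),
    ("COLITIS MICROSCOPIC", "GASTROINTESTINAL DISORDERS", 0.0012),
    ("HEADACHE", "NERVOUS SYSTEM DISORDERS", 0.035),
    ("DIZZINESS", "NERVOUS SYSTEM DISORDERS", 0.030),
    ("FACIAL PARALYSIS", "NERVOUS SYSTEM DISORDERS", 0.0015),
    ("FATIGUE", "GENERAL DISORDERS AND ADMINISTRATION SITE CONDITIONS", 0.040),
    ("ASTHENIA", "GENERAL DISORDERS AND ADMINISTRATION SITE CONDITIONS", 0.020),
    ("THIRST", "GENERAL DISORDERS AND ADMINISTRATION SITE CONDITIONS", 0.003),
    ("RASH", "SKIN AND SUBCUTANEOUS TISSUE DISORDERS", 0.025),
    ("PRURITUS", "SKIN AND SUBCUTANEOUS TISSUE DISORDERS", 0.018),
    ("RENAL IMPAIRMENT", "RENAL AND URINARY DISORDERS", 0.004),
    ("BLOOD GASTRIN INCREASED", "INVESTIGATIONS", 0.0008),
    ("BLOOD PRESSURE DECREASED", "INVESTIGATIONS", 0.004),
    ("WEIGHT INCREASED", "INVESTIGATIONS", 0.008),
    ("PALPITATIONS", "CARDIAC DISORDERS", 0.010),
    ("DYSPNOEA", "RESPIRATORY, THORACIC AND MEDIASTINAL DISORDERS", 0.020),
    ("THROAT IRRITATION", "RESPIRATORY, THORACIC AND MEDIASTINAL DISORDERS", 0.003),
    ("CHOLECYSTITIS", "HEPATOBILIARY DISORDERS", 0.0012),
    ("ARTHRALGIA", "MUSCULOSKELETAL AND CONNECTIVE TISSUE DISORDERS", 0.018),
    ("INSOMNIA", "PSYCHIATRIC DISORDERS", 0.015),
)

#: default planted elevations on the focal drug:
#: (pt, relative reporting ratio, serious probability, sex bias, age>=65 bias)
DEFAULT_PLANTED_SIGNALS: tuple[tuple[str, float, float, float, float], ...] = (
    ("GASTROOESOPHAGEAL REFLUX DISEASE", 10.0, 0.2, 1.0, 1.0),
    ("ABDOMINAL DISTENSION", 5.0, 0.15, 1.0, 1.0),
    ("BLOOD GASTRIN INCREASED", 10.0, 0.3, 1.0, 1.0),
    ("GASTRIC POLYPS", 5.0, 0.3, 1.0, 1.0),
    ("RENAL IMPAIRMENT", 2.0, 0.8, 1.0, 1.0),
)

DEFAULT_SEX_MIX = {"F": 0.62, "M": 0.296, "": 0.084}
DEFAULT_AGE_BAND_MIX = {
    "<18": 0.081, "18-64.9": 0.366, "65-85": 0.253, ">=85": 0.028,
    "missing": 0.272,
}
_AGE_BAND_RANGES = {
    "<18": (1.0, 18.0), "18-64.9": (18.0, 65.0),
    "65-85": (65.0, 85.0), ">=85": (85.0, 100.0),
}

DEFAULT_COUNTRY_MIX = {"US": 0.684, "JP": 0.243, "BR": 0.058, "CN": 0.015}
DEFAULT_REPORTER_MIX = {"CN": 0.648, "MD": 0.194, "HP": 0.097, "PH": 0.057,
                        "": 0.004}

#: outcome-code mix among serious reports (a serious report draws one code)
DEFAULT_SERIOUS_OUTCOME_MIX = {"HO": 0.65, "DE": 0.12, "LT": 0.06, "DS": 0.03,
                               "RI": 0.14}


@dataclass
class SyntheticConfig:
    """Generating conditions for one synthetic reporting database."""

    n_reports: int = 20_000
    focal_drug_share: float = 0.05
    focal_drug_name: str = "VONOPRAZAN"
    background_pts: Sequence[tuple[str, str, float]] = DEFAULT_BACKGROUND_PTS
    planted_signals: Sequence[tuple[str, float, float, float, float]] = (
        DEFAULT_PLANTED_SIGNALS
    )
    onset_shape_beta: float = 0.49
    onset_scale_alpha: float = 19.73
    sex_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SEX_MIX))
    age_band_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_BAND_MIX))
    country_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COUNTRY_MIX))
    reporter_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REPORTER_MIX))
    baseline_serious_prob: float = 0.343
    serious_outcome_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SERIOUS_OUTCOME_MIX))
    weight_missing_prob: float = 0.80
    duplicate_rate: float = 0.05
    partial_date_rate: float = 0.05
    n_background_drugs: int = 200
    n_comedications_mean: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports < 0:
            raise ValueError("n_reports must be non-negative")
        if not 0.0 <= self.focal_drug_share <= 1.0:
            raise ValueError("focal_drug_share must be in [0, 1]")
        if self.onset_shape_beta <= 0 or self.onset_scale_alpha <= 0:
            raise ValueError("Weibull onset parameters must be positive")
        for mix_name in ("sex_mix", "age_band_mix", "country_mix",
                         "reporter_mix", "serious_outcome_mix"):
            mix = getattr(self, mix_name)
            if any(p < 0 for p in mix.values()):
                raise ValueError(f"{mix_name} has a negative probability")
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{mix_name} must sum to 1")
        for pt, ratio, *_ in self.planted_signals:
            if ratio <= 0:
                raise ValueError(f"planted ratio for {pt} must be positive")
        bg = {p for p, _, _ in self.background_pts}
        missing = {p for p, *_ in self.planted_signals} - bg
        if missing:
            raise ValueError(f"planted PTs absent from background panel: {missing}")


def _choice(rng: np.random.Generator, mix: dict[str, float], n: int) -> np.ndarray:
    keys = list(mix)
    return rng.choice(keys, size=n, p=[mix[k] for k in keys])


def generate(config: SyntheticConfig) -> dict[str, pd.DataFrame]:
    """Draw one database; reproducible given ``config.seed``.

    Returns string-typed DEMO/DRUG/REAC/OUTC/THER frames in the FAERS
    ASCII schema (plus empty INDI/RPSR placeholders), ready either for
    :func:`write_tables` or for direct standardization.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    if n == 0:
        return _empty_bundle()

    primaryid = np.arange(100_000_001, 100_000_001 + n)
    caseid = np.arange(50_000_001, 50_000_001 + n)
    focal = rng.random(n) < config.focal_drug_share

    sex = _choice(rng, config.sex_mix, n)
    band = _choice(rng, config.age_band_mix, n)
    age = np.full(n, np.nan)
    for b, (lo, hi) in _AGE_BAND_RANGES.items():
        m = band == b
        age[m] = rng.uniform(lo, hi, m.sum())
    weight = np.round(rng.normal(72.0, 15.0, n).clip(35, 180), 1)
    weight_missing = rng.random(n) < config.weight_missing_prob
    country = _choice(rng, config.country_mix, n)
    reporter = _choice(rng, config.reporter_mix, n)

    window_start = np.datetime64("2023-01-01")
    window_days = 820  # ~nine quarters
    start_offset = rng.integers(0, window_days, n)
    start_date = window_start + start_offset.astype("timedelta64[D]")

    # PT occurrence: independent Bernoulli per (report, PT)
    planted = {pt: (ratio, sp, sexb, ageb)
               for pt, ratio, sp, sexb, ageb in config.planted_signals}
    is_male = sex == "M"
    is_elderly = np.where(np.isnan(age), False, age >= 65.0)
    pt_hits: dict[str, np.ndarray] = {}
    for pt, _soc, bg_p in config.background_pts:
        p = np.full(n, bg_p)
        if pt in planted:
            ratio, _sp, sex_bias, age_bias = planted[pt]
            mult = np.where(focal, ratio, 1.0)
            if sex_bias != 1.0:
                mult = mult * np.where(focal & is_male, sex_bias, 1.0)
            if age_bias != 1.0:
                mult = mult * np.where(focal & is_elderly, age_bias, 1.0)
            p = p * mult
            if np.any(p > 1.0):
                warnings.warn(
                    f"capped occurrence probability >1 for ({pt}, ratio {ratio})",
                    stacklevel=2,
                )
                p = np.clip(p, 0.0, 1.0)
        pt_hits[pt] = rng.random(n) < p

    # seriousness: planted serious probability if a planted PT occurred on a
    # focal report, else the baseline rate
    serious_p = np.full(n, config.baseline_serious_prob)
    for pt, (ratio, sp, *_bias) in planted.items():
        m = focal & pt_hits[pt]
        serious_p[m] = np.maximum(serious_p[m], sp)
    serious = rng.random(n) < serious_p
    outcome = np.where(serious, _choice(rng, config.serious_outcome_mix, n), "OT")

    # onset: event date = start + Weibull days for focal reports, uniform lag
    # for the background
    tto = np.where(
        focal,
        np.round(config.onset_scale_alpha *
                 rng.weibull(config.onset_shape_beta, n)),
        rng.integers(0, 90, n).astype(float),
    ).astype(int)
    event_date = start_date + tto.astype("timedelta64[D]")
    fda_date = event_date + rng.integers(1, 60, n).astype("timedelta64[D]")

    def fmt(dates: np.ndarray) -> np.ndarray:
        return np.datetime_as_string(dates, unit="D")

    def compact(dates: np.ndarray) -> np.ndarray:
        return np.char.replace(fmt(dates), "-", "")

    start_dt = compact(start_date)
    event_dt = compact(event_date)
    fda_dt = compact(fda_date)

    # partial-date injection (start/event dates truncated to YYYYMM)
    partial = rng.random(n) < config.partial_date_rate
    start_dt = start_dt.astype("<U8").copy()
    event_dt = event_dt.astype("<U8").copy()
    start_dt[partial] = [s[:6] for s in start_dt[partial]]
    partial_ev = rng.random(n) < config.partial_date_rate
    event_dt[partial_ev] = [s[:6] for s in event_dt[partial_ev]]

    pid_str = primaryid.astype(str)
    demo = pd.DataFrame({
        "primaryid": pid_str,
        "caseid": caseid.astype(str),
        "fda_dt": fda_dt,
        "event_dt": event_dt,
        "sex": sex,
        "age": np.where(np.isnan(age), "", np.round(age, 1).astype(str)),
        "age_cod": np.where(np.isnan(age), "", "YR"),
        "wt": np.where(weight_missing, "", weight.astype(str)),
        "wt_cod": np.where(weight_missing, "", "KG"),
        "reporter_country": country,
        "occp_cod": reporter,
    })

    # DRUG/THER: one primary-suspect row per report plus concomitants
    bg_names = np.array([f"BACKGROUND DRUG {i:03d}"
                         for i in range(config.n_background_drugs)])
    suspect = np.where(focal, config.focal_drug_name,
                       bg_names[rng.integers(0, len(bg_names), n)])
    n_comed = rng.poisson(config.n_comedications_mean, n)
    comed_pid = np.repeat(pid_str, n_comed)
    comed_name = bg_names[rng.integers(0, len(bg_names), int(n_comed.sum()))]
    drug = pd.DataFrame({
        "primaryid": np.concatenate([pid_str, np.asarray(comed_pid, dtype=object)]),
        "drug_seq": (["1"] * n) + ["2"] * len(comed_pid),
        "role_cod": (["PS"] * n) + ["C"] * len(comed_pid),
        "drugname": np.concatenate([suspect, np.asarray(comed_name, dtype=object)]),
    })
    ther = pd.DataFrame({
        "primaryid": pid_str,
        "dsg_drug_seq": "1",
        "start_dt": start_dt,
    })

    reac_pid, reac_pt = [], []
    for pt, _soc, _p in config.background_pts:
        hits = np.nonzero(pt_hits[pt])[0]
        reac_pid.append(pid_str[hits])
        reac_pt.extend([pt] * len(hits))
    reac = pd.DataFrame({
        "primaryid": np.concatenate(reac_pid) if reac_pid else np.array([], str),
        "pt": reac_pt,
    }).sort_values(["primaryid", "pt"], kind="mergesort").reset_index(drop=True)

    outc = pd.DataFrame({"primaryid": pid_str, "outc_cod": outcome})

    bundle = {"demo": demo, "drug": drug, "reac": reac, "outc": outc,
              "ther": ther,
              "indi": pd.DataFrame(columns=["primaryid", "indi_pt"]),
              "rpsr": pd.DataFrame(columns=["primaryid", "rpsr_cod"])}
    bundle = _inject_duplicates(bundle, config, rng)
    return bundle


def _inject_duplicates(
    bundle: dict[str, pd.DataFrame], config: SyntheticConfig,
    rng: np.random.Generator,
) -> dict[str, pd.DataFrame]:
    """Append stale versions of a sample of cases (earlier fda_dt, smaller
    primaryid), exercising the latest-FDA-date dedup branch."""
    demo = bundle["demo"]
    n_dup = int(round(config.duplicate_rate * len(demo)))
    if n_dup == 0:
        return bundle
    pick = rng.choice(len(demo), size=n_dup, replace=False)
    dup = demo.iloc[pick].copy()
    # earlier submission under a smaller primaryid
    dup["primaryid"] = (90_000_001 + np.arange(n_dup)).astype(str)
    fd = pd.to_datetime(dup["fda_dt"], format="%Y%m%d") - pd.Timedelta(days=30)
    dup["fda_dt"] = fd.dt.strftime("%Y%m%d")
    bundle = dict(bundle)
    bundle["demo"] = pd.concat([demo, dup], ignore_index=True)
    # carry the duplicate's rows in the child tables under the new primaryid
    old_new = dict(zip(demo.iloc[pick]["primaryid"], dup["primaryid"]))
    for name in ("drug", "reac", "outc", "ther"):
        tab = bundle[name]
        extra = tab[tab["primaryid"].isin(old_new)].copy()
        extra["primaryid"] = extra["primaryid"].map(old_new)
        bundle[name] = pd.concat([tab, extra], ignore_index=True)
    return bundle


def _empty_bundle() -> dict[str, pd.DataFrame]:
    return {
        "demo": pd.DataFrame(columns=["primaryid", "caseid", "fda_dt",
                                      "event_dt", "sex", "age", "age_cod",
                                      "wt", "wt_cod", "reporter_country",
                                      "occp_cod"]),
        "drug": pd.DataFrame(columns=["primaryid", "drug_seq", "role_cod",
                                      "drugname"]),
        "reac": pd.DataFrame(columns=["primaryid", "pt"]),
        "outc": pd.DataFrame(columns=["primaryid", "outc_cod"]),
        "ther": pd.DataFrame(columns=["primaryid", "dsg_drug_seq",
                                      "start_dt"]),
        "indi": pd.DataFrame(columns=["primaryid", "indi_pt"]),
        "rpsr": pd.DataFrame(columns=["primaryid", "rpsr_cod"]),
    }


def truth_table(config: SyntheticConfig) -> pd.DataFrame:
    """Per-PT generating truth: ratio and expected 2x2 cell probabilities.

    Cell probabilities ignore the optional sex/age biases (documented as
    tilts around these marginals) and probability capping:
    ``p_a = focal_share * bg_p * ratio`` is the probability that a report
    is focal and carries the PT.
    """
    planted = {pt: ratio for pt, ratio, *_ in config.planted_signals}
    rows = []
    share = config.focal_drug_share
    for pt, soc, bg_p in config.background_pts:
        ratio = planted.get(pt, 1.0)
        p_focal_event = min(bg_p * ratio, 1.0)
        rows.append({
            "pt": pt,
            "soc": soc,
            "background_probability": bg_p,
            "relative_reporting_ratio": ratio,
            "p_a": share * p_focal_event,
            "p_b": share * (1 - p_focal_event),
            "p_c": (1 - share) * bg_p,
            "p_d": (1 - share) * (1 - bg_p),
            "onset_scale_alpha": config.onset_scale_alpha,
            "onset_shape_beta": config.onset_shape_beta,
        })
    return pd.DataFrame(rows)


def write_tables(
    bundle: dict[str, pd.DataFrame], outdir: str | Path, delimiter: str = "$"
) -> dict[str, Path]:
    """Write the bundle as FAERS-style delimited text; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in bundle.items():
        path = outdir / f"{name}.txt"
        df.to_csv(path, sep=delimiter, index=False)
        paths[name] = path
    return paths
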