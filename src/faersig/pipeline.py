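"""End-to-end orchestration: ingest -> dedup -> cohort -> signals ->
severity -> strata -> onset -> reports.

A run is driven by one :class:`RunConfig` and writes a bundle of TSV
report tables plus a machine-readable JSON manifest (config hash, seed,
report counts at every stage). All randomness flows from the single run
seed, and no output carries a timestamp, so a repeated run with the same
config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from . import contingency, faers_io, onset, severity, signals
from .synthetic import SyntheticConfig, generate, truth_table

WEIGHT_BANDS = (("<50", 0.0, 50.0), ("50-100", 50.0, 100.0),
                (">=100", 100.0, np.inf))


class ConfigError(ValueError):
    """The run configuration is invalid."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything a run needs; exactly one of input_paths / synthetic."""

    input_paths: dict[str, str] | None = None
    synthetic: dict | None = None
    delimiter: str = "$"
    target_drugs: tuple[str, ...] = ("VONOPRAZAN",)
    match_mode: str = "substring"
    ror_rule: str = "point"
    ror_threshold: float = 3.0
    ic_mode: str = "noren"
    fdr_method: str = "bh"
    soc_map_path: str | None = None
    labeled_pts_path: str | None = None
    onset_offset: float = 0.5
    onset_ci_method: str = "wald"
    n_boot: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_paths is None) == (self.synthetic is None):
            raise ConfigError(
                "exactly one of input_paths / synthetic must be supplied")
        if self.ror_threshold <= 0:
            raise ConfigError("ror_threshold must be positive")
        if not self.target_drugs:
            raise ConfigError("target_drugs must be non-empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "target_drugs" in raw:
            raw["target_drugs"] = tuple(raw["target_drugs"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def default_soc_map() -> dict[str, str]:
    path = resources.files("faersig.data") / "pt_soc_map.tsv"
    return signals.load_pt_soc_map(path)


def default_labeled_pts() -> set[str]:
    path = resources.files("faersig.data") / "labeled_pts_synthetic.tsv"
    return signals.load_labeled_pts(path)


def tabulate_comedications(
    drug: pd.DataFrame, focal_ids: Iterable[str],
    target_names: Iterable[str] = (),
) -> pd.DataFrame:
    """Concomitant-drug frequency among focal reports.

    Counts distinct non-focal normalized drug names once per report,
    ranked by descending count with alphabetical tie-break.
    """
    focal = set(map(str, focal_ids))
    targets = {faers_io.normalize_drug_name(t) for t in target_names}
    sub = drug[drug["primaryid"].astype(str).isin(focal)
               & drug["drug_name"].notna()]
    sub = sub[~sub["drug_name"].isin(targets)]
    pairs = sub[["primaryid", "drug_name"]].drop_duplicates()
    counts = pairs.groupby("drug_name").size().reset_index(name="n_reports")
    return counts.sort_values(
        ["n_reports", "drug_name"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def _band_series(values: pd.Series, bands) -> pd.Series:
    out = pd.Series("missing", index=values.index, dtype=object)
    for label, lo, hi in bands:
        out[values.notna() & (values >= lo) & (values < hi)] = label
    return out


def descriptive_table(cases: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages by seriousness for demographics, outcomes,
    country, reporter type and submission year."""
    serious = cases["serious"]
    groups = {"serious": cases[serious], "non_serious": cases[~serious],
              "overall": cases}

    def block(var: str, labeller) -> list[dict]:
        rows = []
        labels = {g: labeller(df) for g, df in groups.items()}
        seen = pd.unique(pd.concat(list(labels.values()), ignore_index=True))
        for value in sorted(map(str, seen)):
            row = {"variable": var, "value": value}
            for g, df in groups.items():
                lab = labels[g]
                n = int((lab.astype(str) == value).sum())
                denom = len(df)
                row[f"{g}_n"] = n
                row[f"{g}_pct"] = round(100.0 * n / denom, 1) if denom else 0.0
            rows.append(row)
        return rows

    rows: list[dict] = []
    rows += block("sex", lambda d: d["sex"])
    rows += block("age_band", lambda d: faers_io.assign_age_band(d["age_years"]))
    rows += block("weight_band", lambda d: _band_series(d["weight_kg"],
                                                        WEIGHT_BANDS))
    rows += block("outcome", lambda d: d["outcomes"].apply(
        lambda s: "/".join(sorted(faers_io.OUTCOME_LABELS[c] for c in s))
        if s else "none"))
    rows += block("country", lambda d: d["country"].fillna("missing"))
    rows += block("reporter_type", lambda d: d["reporter_type"])
    rows += block("year", lambda d: d["fda_date"].dt.year.astype("Int64")
                  .astype(str).replace("<NA>", "missing"))
    return pd.DataFrame(rows)


def _severity_counts(
    cases: pd.DataFrame, reactions: pd.DataFrame, focal_ids: set[str]
) -> pd.DataFrame:
    """Per-PT occurrence counts among serious / non-serious focal reports."""
    focal_cases = cases[cases["primaryid"].astype(str).isin(focal_ids)]
    serious_ids = set(focal_cases.loc[focal_cases["serious"],
                                      "primaryid"].astype(str))
    nonserious_ids = set(focal_cases.loc[~focal_cases["serious"],
                                         "primaryid"].astype(str))
    reac = reactions[reactions["primaryid"].astype(str).isin(focal_ids)]
    pid = reac["primaryid"].astype(str)
    df = pd.DataFrame({
        "pt": reac["pt"],
        "serious": pid.isin(serious_ids),
        "nonserious": pid.isin(nonserious_ids),
    })
    counts = df.groupby("pt").agg(
        serious_events=("serious", "sum"),
        nonserious_events=("nonserious", "sum"),
    ).reset_index()
    return counts.sort_values("pt", kind="mergesort").reset_index(drop=True)


def run(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full analysis; returns the manifest dict.

    Writes to ``outdir``: cleaned_cases.tsv, descriptive.tsv, signals.tsv,
    signals_by_cases.tsv / signals_by_ror.tsv, soc_signals.tsv,
    unlisted_signals.tsv, severity.tsv, comedications.tsv, stratified
    signal tables, onset_summary.tsv, onset_curve*.tsv, manifest.json
    (and truth.tsv for synthetic runs).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash(),
                      "seed": config.seed, "stages": {}}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as err:  # abort with stage name + partial manifest
                manifest["failed_stage"] = name
                (outdir / "manifest.json").write_text(
                    json.dumps(manifest, indent=2, sort_keys=True, default=str))
                raise StageError(name, err) from err
        return deco

    @stage("ingest")
    def bundle():
        if config.synthetic is not None:
            syn = SyntheticConfig(**{**config.synthetic,
                                     "seed": config.synthetic.get(
                                         "seed", config.seed)})
            b = generate(syn)
            truth_table(syn).to_csv(outdir / "truth.tsv", sep="\t",
                                    index=False)
            manifest["synthetic"] = True
            return b
        paths = {k: v for k, v in config.input_paths.items()}
        manifest["synthetic"] = False
        return faers_io.parse_quarter(paths, delimiter=config.delimiter)

    @stage("standardize")
    def std():
        s = faers_io.standardize(bundle)
        manifest["stages"]["parsed_rows"] = s.log.rows_parsed
        return s

    @stage("deduplicate")
    def cases():
        c = faers_io.build_cases(std)
        deduped, n_removed = faers_io.deduplicate(c)
        deduped, impute_info = faers_io.impute_weight(deduped)
        manifest["stages"]["reports_in"] = len(c)
        manifest["stages"]["duplicates_removed"] = n_removed
        manifest["stages"]["reports_deduplicated"] = len(deduped)
        manifest["stages"]["weight_imputation"] = impute_info
        assert len(c) == len(deduped) + n_removed
        return deduped

    @stage("cohort")
    def focal_ids():
        ids = faers_io.select_primary_suspect(
            std.drug, config.target_drugs, mode=config.match_mode)
        ids &= set(cases["primaryid"].astype(str))
        if not ids:
            raise ValueError("no reports with the target drug as primary suspect")
        manifest["stages"]["focal_reports"] = len(ids)
        return ids

    case_ids = set(cases["primaryid"].astype(str))
    reac = std.reac[std.reac["primaryid"].astype(str).isin(case_ids)]

    @stage("descriptive")
    def _descriptive():
        focal_cases = cases[cases["primaryid"].astype(str).isin(focal_ids)]
        desc = descriptive_table(focal_cases)
        desc.to_csv(outdir / "descriptive.tsv", sep="\t", index=False)
        manifest["stages"]["focal_serious"] = int(focal_cases["serious"].sum())
        return desc

    soc_map = (signals.load_pt_soc_map(config.soc_map_path)
               if config.soc_map_path else default_soc_map())
    labeled = (signals.load_labeled_pts(config.labeled_pts_path)
               if config.labeled_pts_path else default_labeled_pts())

    @stage("signals")
    def signal_df():
        tables = contingency.build_pt_tables(case_ids, reac, focal_ids)
        df = signals.evaluate_signals(
            tables, ror_rule=config.ror_rule,
            ror_threshold=config.ror_threshold, ic_mode=config.ic_mode,
            fdr_method=config.fdr_method)
        df.insert(0, "soc", df["label"].map(
            {k: v for k, v in soc_map.items()}).fillna("UNMAPPED"))
        df.to_csv(outdir / "signals.tsv", sep="\t", index=False)
        df.sort_values(["n_cases", "label"], ascending=[False, True],
                       kind="mergesort").head(50).to_csv(
            outdir / "signals_by_cases.tsv", sep="\t", index=False)
        df.sort_values(["ror", "label"], ascending=[False, True],
                       kind="mergesort").head(50).to_csv(
            outdir / "signals_by_ror.tsv", sep="\t", index=False)
        soc_tables = contingency.build_soc_tables(
            reac, soc_map, case_ids, focal_ids)
        signals.evaluate_signals(soc_tables, ror_rule=config.ror_rule,
                                 ror_threshold=config.ror_threshold,
                                 ic_mode=config.ic_mode,
                                 fdr_method=config.fdr_method).to_csv(
            outdir / "soc_signals.tsv", sep="\t", index=False)
        unlisted = signals.compare_to_label(df, labeled)
        unlisted.to_csv(outdir / "unlisted_signals.tsv", sep="\t", index=False)
        manifest["stages"]["pts_tested"] = len(df)
        manifest["stages"]["cross_validated_signals"] = int(
            (df["tier"] == "cross_validated").sum())
        manifest["stages"]["unlisted_positive_signals"] = len(unlisted)
        return df

    @stage("severity")
    def _severity():
        counts = _severity_counts(cases, reac, focal_ids)
        out = severity.compare_severity(counts)
        out.to_csv(outdir / "severity.tsv", sep="\t", index=False)
        return out

    @stage("strata")
    def _strata():
        focal_cases_mask = cases["primaryid"].astype(str).isin(focal_ids)
        for by in ("sex", "age_band"):
            parts = contingency.stratify(cases, by=by)
            for label, sub in parts.items():
                if label == "missing" or len(sub) == 0:
                    continue
                sub_ids = set(sub["primaryid"].astype(str))
                sub_focal = sub_ids & focal_ids
                if not sub_focal:
                    continue
                sub_reac = reac[reac["primaryid"].astype(str).isin(sub_ids)]
                tables = contingency.build_pt_tables(
                    sub_ids, sub_reac, sub_focal, stratum=label)
                if not tables:
                    continue
                df = signals.evaluate_signals(
                    tables, ror_rule=config.ror_rule,
                    ror_threshold=config.ror_threshold,
                    ic_mode=config.ic_mode, fdr_method=config.fdr_method)
                safe = label.replace("<", "lt").replace(">=", "ge").replace(
                    ".", "_")
                df.to_csv(outdir / f"signals_{by}_{safe}.tsv", sep="\t",
                          index=False)
        del focal_cases_mask

    @stage("comedications")
    def _comed():
        comed = tabulate_comedications(std.drug, focal_ids,
                                       config.target_drugs)
        comed.to_csv(outdir / "comedications.tsv", sep="\t", index=False)
        return comed

    @stage("onset")
    def _onset():
        focal_ther = std.ther[std.ther["primaryid"].astype(str).isin(focal_ids)]
        focal_demo = std.demo[std.demo["primaryid"].astype(str).isin(focal_ids)]
        sex_map = dict(zip(
            cases["primaryid"].astype(str),
            cases["sex"].where(cases["sex"].isin(["female", "male"])),
        ))
        records, excl = onset.compute_tto(
            focal_ther[["primaryid", "start_date"]],
            focal_demo[["primaryid", "event_date"]].rename(
                columns={"event_date": "event_date"}),
            sex=sex_map,
        )
        manifest["stages"]["onset_exclusions"] = excl
        rows = []
        if len(records):
            med, q1, q3 = onset.summarize_tto(records["tto_days"])
            row = {"group": "all", "n": len(records), "median": med,
                   "q1": q1, "q3": q3}
            if len(records) >= 10 and records["tto_days"].nunique() > 1:
                fit = onset.weibull_fit(
                    records["tto_days"], offset=config.onset_offset,
                    ci_method=config.onset_ci_method, n_boot=config.n_boot,
                    seed=config.seed)
                row.update(scale_alpha=fit.scale_alpha,
                           scale_lo=fit.scale_ci[0], scale_hi=fit.scale_ci[1],
                           shape_beta=fit.shape_beta,
                           shape_lo=fit.shape_ci[0], shape_hi=fit.shape_ci[1],
                           failure_type=fit.failure_type)
            rows.append(row)
            onset.cumulative_onset(records).to_csv(
                outdir / "onset_curve.tsv", sep="\t", index=False)
            sexed = records.dropna(subset=["sex"]) if "sex" in records else \
                records.iloc[0:0]
            if len(sexed) and sexed["sex"].nunique() == 2 and \
                    sexed.groupby("sex").size().min() >= 1:
                for g, sub in sexed.groupby("sex"):
                    m, a, b = onset.summarize_tto(sub["tto_days"])
                    rows.append({"group": str(g), "n": len(sub), "median": m,
                                 "q1": a, "q3": b})
                stat, p = onset.logrank(sexed, group="sex")
                manifest["stages"]["logrank_sex"] = {"statistic": stat, "p": p}
                onset.cumulative_onset(sexed, by="sex").to_csv(
                    outdir / "onset_curve_by_sex.tsv", sep="\t", index=False)
        pd.DataFrame(rows).to_csv(outdir / "onset_summary.tsv", sep="\t",
                                  index=False)

    cleaned = cases.copy()
    cleaned["outcomes"] = cleaned["outcomes"].apply(
        lambda s: "/".join(sorted(s)))
    cleaned.to_csv(outdir / "cleaned_cases.tsv", sep="\t", index=False)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest
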