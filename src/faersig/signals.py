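"""Disproportionality statistics and signal classification.

Four algorithms are computed per 2x2 table (a, b, c, d; N = a+b+c+d,
E = (a+b)(a+c)/N the expected a-cell under independence):

* ROR  = (a·d)/(b·c), 95% CI exp(ln ROR ± 1.96·sqrt(1/a+1/b+1/c+1/d));
  positive when the point estimate is at least ``ror_threshold`` (default
  3) and the CI lower bound exceeds 1.
* PRR  = [a/(a+b)] / [c/(c+d)] with the uncorrected Pearson chi-square on
  the same table; positive when PRR >= 2, chi2 >= 4 and a >= 3.
* IC   = log2((a+0.5)/(E+0.5)) with the closed-form lower credible bound
  IC025 = IC - 3.3(a+0.5)^(-1/2) - 2(a+0.5)^(-3/2); positive when
  IC025 > 0. An ``ic_from_ebgm`` mode (IC = log2 EBGM) mirrors the
  convention some published signal tables use.
* EBGM under DuMouchel's two-component gamma-mixture empirical Bayes
  ("gamma-Poisson shrinker"): a ~ Poisson(lambda·E) with
  lambda ~ P·Gamma(a1, b1) + (1-P)·Gamma(a2, b2) fitted by marginal
  maximum likelihood over all tables; EBGM = 2^{E[log2 lambda | a]},
  EBGM05 the 5th posterior percentile; positive when EBGM05 > 2 (the
  companion condition EBGM > 0 always holds and is recorded as such).

Tables with any zero cell receive the Haldane-Anscombe correction (0.5
added to all four cells) for the ratio estimates and are flagged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .contingency import ContingencyTable

Z975 = 1.959963984540054


@dataclass(frozen=True)
class RorResult:
    estimate: float
    ci_low: float
    ci_high: float
    flag: bool
    corrected: bool


@dataclass(frozen=True)
class PrrResult:
    estimate: float
    chi2: float
    p_value: float
    flag: bool
    corrected: bool


@dataclass(frozen=True)
class IcResult:
    ic: float
    ic025: float
    flag: bool


@dataclass(frozen=True)
class EbgmResult:
    ebgm: float
    ebgm05: float
    flag: bool


@dataclass(frozen=True)
class MgpsPrior:
    """Fitted two-component gamma mixture prior for the reporting ratio."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    mixture_weight: float
    log_marginal: float

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma parameters must be strictly positive")
        if not 0.0 <= self.mixture_weight <= 1.0:
            raise ValueError("mixture weight must lie in [0, 1]")

    @property
    def mean(self) -> float:
        """Prior mean reporting ratio."""
        p = self.mixture_weight
        return p * self.alpha1 / self.beta1 + (1 - p) * self.alpha2 / self.beta2


DUMOUCHEL_START = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


def _haldane(table: ContingencyTable) -> tuple[ContingencyTable, bool]:
    if min(table.cells()) == 0:
        a, b, c, d = table.cells()
        return (
            ContingencyTable(a + 0.5, b + 0.5, c + 0.5, d + 0.5,
                             label=table.label, stratum=table.stratum),
            True,
        )
    return table, False


def ror(
    table: ContingencyTable,
    point_threshold: float = 3.0,
    ci_low_threshold: float = 1.0,
    rule: str = "point",
    min_cases: int = 3,
) -> RorResult:
    """Reporting odds ratio with Wald 95% CI on the log scale.

    ``rule="point"`` flags estimate >= point_threshold AND CI lower >
    ci_low_threshold; ``rule="cases"`` uses the conventional a >= min_cases
    AND CI lower > ci_low_threshold instead.
    """
    a_raw = table.a
    t, corrected = _haldane(table)
    a, b, c, d = t.cells()
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = est * math.exp(-Z975 * se)
    hi = est * math.exp(Z975 * se)
    if rule == "point":
        flag = est >= point_threshold and lo > ci_low_threshold
    elif rule == "cases":
        flag = a_raw >= min_cases and lo > ci_low_threshold
    else:
        raise ValueError(f"unknown ROR rule {rule!r}")
    return RorResult(est, lo, hi, bool(flag), corrected)


def _pearson_chi2(a: float, b: float, c: float, d: float) -> float:
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return float("nan")
    return n * (a * d - b * c) ** 2 / denom


def prr(
    table: ContingencyTable,
    prr_threshold: float = 2.0,
    chi2_threshold: float = 4.0,
    min_cases: int = 3,
) -> PrrResult:
    """Proportional reporting ratio with the uncorrected Pearson chi2.

    The chi-square and its 1-df p-value are computed on the raw cells;
    the ratio falls back to Haldane-corrected cells when a zero cell
    would make it undefined or infinite.
    """
    if table.a + table.b == 0 or table.c + table.d == 0:
        raise ValueError("PRR undefined: an exposure margin is empty")
    a, b, c, d = table.cells()
    corrected = False
    if c == 0 or (a + b) == 0:
        (a, b, c, d), corrected = _haldane(table)[0].cells(), True
    est = (a / (a + b)) / (c / (c + d))
    chi2 = _pearson_chi2(*table.cells())
    p = float(stats.chi2.sf(chi2, df=1)) if math.isfinite(chi2) else float("nan")
    flag = (est >= prr_threshold and chi2 >= chi2_threshold
            and table.a >= min_cases)
    return PrrResult(est, chi2, p, bool(flag), corrected)


def bcpnn_ic(table: ContingencyTable, mode: str = "noren",
             ebgm_value: float | None = None) -> IcResult:
    """Information component with closed-form shrinkage and credible bound.

    ``mode="noren"`` (default) uses IC = log2((a+0.5)/(E+0.5));
    ``mode="ic_from_ebgm"`` takes IC = log2(EBGM) (pass ``ebgm_value``),
    keeping the same credible-bound approximation.
    """
    if table.n <= 0:
        raise ValueError("empty table")
    a = table.a
    e = table.expected_a
    if mode == "noren":
        ic = math.log2((a + 0.5) / (e + 0.5))
    elif mode == "ic_from_ebgm":
        if ebgm_value is None or ebgm_value <= 0:
            raise ValueError("ic_from_ebgm mode requires a positive EBGM")
        ic = math.log2(ebgm_value)
    else:
        raise ValueError(f"unknown IC mode {mode!r}")
    ic025 = ic - 3.3 * (a + 0.5) ** -0.5 - 2.0 * (a + 0.5) ** -1.5
    return IcResult(ic, ic025, bool(ic025 > 0))


# ---------------------------------------------------------------------------
# MGPS empirical Bayes


def _log_nb(a: np.ndarray, e: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """Log marginal P(a | alpha, beta, E): negative binomial from a
    Gamma(alpha, rate beta) mixing law on the Poisson mean lambda·E."""
    return (
        special.gammaln(alpha + a) - special.gammaln(alpha)
        - special.gammaln(a + 1.0)
        + alpha * (np.log(beta) - np.log(beta + e))
        + a * (np.log(e) - np.log(beta + e))
    )


def _neg_log_marginal(params: np.ndarray, a: np.ndarray, e: np.ndarray) -> float:
    la1, lb1, la2, lb2, logit_p = params
    a1, b1, a2, b2 = np.exp([la1, lb1, la2, lb2])
    p = special.expit(logit_p)
    l1 = _log_nb(a, e, a1, b1) + np.log(p + 1e-300)
    l2 = _log_nb(a, e, a2, b2) + np.log(1 - p + 1e-300)
    return -float(np.sum(np.logaddexp(l1, l2)))


def fit_mgps_prior(
    tables: Iterable[ContingencyTable] | Sequence[tuple[float, float]],
    n_starts: int = 4,
    seed: int = 0,
) -> MgpsPrior:
    """Fit the gamma-mixture prior by marginal maximum likelihood.

    Accepts contingency tables (a and E are extracted) or raw (a, E)
    pairs. Optimization is bounded quasi-Newton (L-BFGS-B) on log/logit
    parameters, multi-started from the DuMouchel default
    (0.2, 0.1, 2.0, 4.0, 1/3) plus ``n_starts - 1`` seeded perturbations;
    the best converged iterate wins. The marginal likelihood is a product
    over cells, so the fit is invariant to cell order.
    """
    pairs = []
    for t in tables:
        if isinstance(t, ContingencyTable):
            pairs.append((t.a, t.expected_a))
        else:
            pairs.append((float(t[0]), float(t[1])))
    arr = np.asarray(pairs, dtype=float)
    arr = arr[arr[:, 1] > 0]
    # canonical cell order: the likelihood is a product over cells, and
    # sorting makes the floating-point sum permutation-invariant too
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    if len(arr) == 0:
        raise ValueError("no cells with positive expected count")
    if len(arr) < 50:
        warnings.warn(
            f"only {len(arr)} drug-event cells; the mixture prior may be "
            "poorly identified", stacklevel=2,
        )
    a, e = arr[:, 0], arr[:, 1]

    d = DUMOUCHEL_START
    x0 = np.array([math.log(d[0]), math.log(d[1]), math.log(d[2]),
                   math.log(d[3]), special.logit(d[4])])
    rng = np.random.default_rng(seed)
    starts = [x0] + [x0 + rng.normal(0, 0.5, 5) for _ in range(n_starts - 1)]
    bounds = [(-10, 10)] * 4 + [(-12, 12)]

    best = None
    diagnostics = []
    for s in starts:
        res = optimize.minimize(
            _neg_log_marginal, s, args=(a, e), method="L-BFGS-B",
            bounds=bounds,
        )
        diagnostics.append(res)
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        fallback = min(diagnostics, key=lambda r: r.fun)
        raise RuntimeError(
            "MGPS prior fit failed to converge from all starts; best "
            f"iterate {fallback.x} with gradient norm "
            f"{np.linalg.norm(fallback.jac):.3g}"
        )
    la1, lb1, la2, lb2, logit_p = best.x
    return MgpsPrior(
        alpha1=float(np.exp(la1)), beta1=float(np.exp(lb1)),
        alpha2=float(np.exp(la2)), beta2=float(np.exp(lb2)),
        mixture_weight=float(special.expit(logit_p)),
        log_marginal=-float(best.fun),
    )


def ebgm(
    table: ContingencyTable,
    prior: MgpsPrior,
    ebgm05_threshold: float = 2.0,
    quantile_tol: float = 1e-8,
) -> EbgmResult:
    """Posterior geometric mean and 5th percentile of the reporting ratio.

    The posterior given a is again a two-component gamma mixture with
    components (alpha_k + a, beta_k + E) and weights proportional to the
    component marginal likelihoods of a.
    """
    a, e = table.a, table.expected_a
    if e <= 0:
        raise ValueError("expected count must be positive")
    p = prior.mixture_weight
    a_arr = np.array([a], dtype=float)
    e_arr = np.array([e], dtype=float)
    l1 = _log_nb(a_arr, e_arr, prior.alpha1, prior.beta1)[0] + math.log(p + 1e-300)
    l2 = _log_nb(a_arr, e_arr, prior.alpha2, prior.beta2)[0] + math.log(1 - p + 1e-300)
    m = max(l1, l2)
    w1 = math.exp(l1 - m)
    w2 = math.exp(l2 - m)
    q1 = w1 / (w1 + w2)
    shapes = (prior.alpha1 + a, prior.alpha2 + a)
    rates = (prior.beta1 + e, prior.beta2 + e)
    weights = (q1, 1 - q1)

    mean_log = sum(
        w * (special.digamma(s) - math.log(r))
        for w, s, r in zip(weights, shapes, rates)
    )
    ebgm_val = math.exp(mean_log)

    def cdf(x: float) -> float:
        return sum(
            w * stats.gamma.cdf(x, s, scale=1.0 / r)
            for w, s, r in zip(weights, shapes, rates)
        )

    lo, hi = 1e-12, 1.0
    if cdf(lo) >= 0.05:
        # posterior mass collapses toward zero (degenerate prior component
        # with a ~ 0): the 5th percentile is numerically zero
        return EbgmResult(ebgm_val, 0.0, False)
    while cdf(hi) < 0.05:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError(
                f"EBGM05 bracket failure for {table.label!r}: "
                f"cdf({hi:.3g}) = {cdf(hi):.3g}"
            )
    ebgm05 = float(optimize.brentq(lambda x: cdf(x) - 0.05, lo, hi,
                                   xtol=1e-12, rtol=8.9e-16))
    if abs(cdf(ebgm05) - 0.05) > quantile_tol:
        raise RuntimeError(
            f"EBGM05 quantile solve for {table.label!r} did not reach "
            f"|CDF-0.05| < {quantile_tol}"
        )
    # the companion conjunct "EBGM > 0" holds for every gamma posterior
    flag = ebgm05 > ebgm05_threshold and ebgm_val > 0
    return EbgmResult(ebgm_val, ebgm05, bool(flag))


def adjust_fdr(p_values: Sequence[float], method: str = "bh") -> np.ndarray:
    """Multiplicity adjustment: Benjamini-Hochberg step-up (default) or
    Bonferroni; input order is preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    name = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if name is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=name)[1]


TIERS = ("cross_validated", "hypothesis_generating", "negative")


def classify_signal(ror_flag: bool, prr_flag: bool, ic_flag: bool,
                    ebgm_flag: bool) -> str:
    """Tier a PT by how many algorithm families support it.

    ``cross_validated``: all four criteria met; ``hypothesis_generating``:
    at least one criterion met but not all four (including a single family
    firing alone); ``negative`` otherwise.
    """
    flags = (ror_flag, prr_flag, ic_flag, ebgm_flag)
    if all(flags):
        return "cross_validated"
    if any(flags):
        return "hypothesis_generating"
    return "negative"


def evaluate_signals(
    tables: Mapping[str, ContingencyTable],
    prior: MgpsPrior | None = None,
    ror_rule: str = "point",
    ror_threshold: float = 3.0,
    ic_mode: str = "noren",
    fdr_method: str = "bh",
    min_cases_fdr: int = 3,
) -> pd.DataFrame:
    """All four algorithms plus tiering and FDR for a set of PT tables.

    The multiplicity family is the PTs with at least ``min_cases_fdr``
    focal cases (adjusted on the PRR chi-square p-values); PTs outside
    the family get NaN adjusted p. Returns one row per label, sorted by
    descending case count then label.
    """
    if prior is None:
        prior = fit_mgps_prior(tables.values())
    rows = []
    for label, t in tables.items():
        r = ror(t, point_threshold=ror_threshold, rule=ror_rule)
        pr = prr(t)
        eb = ebgm(t, prior)
        ic = bcpnn_ic(t, mode=ic_mode,
                      ebgm_value=eb.ebgm if ic_mode == "ic_from_ebgm" else None)
        rows.append({
            "label": label, "stratum": t.stratum, "n_cases": t.a,
            "expected": t.expected_a,
            "ror": r.estimate, "ror_ci_low": r.ci_low, "ror_ci_high": r.ci_high,
            "ror_flag": r.flag, "ror_corrected": r.corrected,
            "prr": pr.estimate, "chi2": pr.chi2, "p_value": pr.p_value,
            "prr_flag": pr.flag,
            "ic": ic.ic, "ic025": ic.ic025, "ic_flag": ic.flag,
            "ebgm": eb.ebgm, "ebgm05": eb.ebgm05, "ebgm_flag": eb.flag,
        })
    df = pd.DataFrame(rows)
    if len(df) == 0:
        return df
    df["tier"] = [
        classify_signal(r, p, i, e)
        for r, p, i, e in zip(df["ror_flag"], df["prr_flag"], df["ic_flag"],
                              df["ebgm_flag"])
    ]
    df["p_adjusted"] = np.nan
    family = df["n_cases"] >= min_cases_fdr
    if family.any():
        fam_p = df.loc[family, "p_value"].fillna(1.0)
        df.loc[family, "p_adjusted"] = adjust_fdr(fam_p, method=fdr_method)
    df = df.sort_values(["n_cases", "label"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    return df


def compare_to_label(
    signals: pd.DataFrame, labeled_pts: Iterable[str]
) -> pd.DataFrame:
    """Positive-tier signals whose PT is absent from the product label.

    Matching is case-insensitive exact on the PT string. An empty label
    list triggers a warning (every positive signal comes back unlisted).
    """
    labeled = {str(p).strip().upper() for p in labeled_pts}
    if not labeled:
        warnings.warn("empty labeled-event list: all signals reported as "
                      "unlisted", stacklevel=2)
    positive = signals[signals["tier"].isin(
        ["cross_validated", "hypothesis_generating"]
    )]
    mask = ~positive["label"].astype(str).str.upper().isin(labeled)
    return positive[mask].reset_index(drop=True)


def load_labeled_pts(path) -> set[str]:
    """Read a one/two-column TSV of labeled preferred terms (first column)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return set(df.iloc[:, 0].dropna().str.strip().str.upper())


def load_pt_soc_map(path) -> dict[str, str]:
    """Read a two-column TSV mapping preferred term -> system organ class."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = df.columns[:2]
    return {
        str(r[cols[0]]).strip().upper(): str(r[cols[1]]).strip().upper()
        for _, r in df.iterrows()
    }
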