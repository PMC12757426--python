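"""Time-to-onset analysis and Weibull shape-parameter modelling.

The time to onset (TTO) of an adverse event is the whole-day interval
from the earliest focal-drug start date to the event date. Reports with
an event before the start, or with either date missing/partial, are
excluded (and accounted for). The onset sample is summarized by median
and IQR, modelled with a two-parameter Weibull whose shape governs the
hazard trend — shape < 1 means a decreasing hazard ("early failure"),
shape ~ 1 constant ("random failure"), shape > 1 increasing ("wear-out")
— and compared between groups with the log-rank test, every observation
being an event (spontaneous reports carry no at-risk denominator, so no
censoring is modelled).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy import optimize, stats

Z975 = 1.959963984540054


@dataclass(frozen=True)
class WeibullFit:
    """Maximum-likelihood Weibull fit with Wald or bootstrap 95% CIs."""

    scale_alpha: float
    scale_ci: tuple[float, float]
    shape_beta: float
    shape_ci: tuple[float, float]
    n: int
    failure_type: str
    log_likelihood: float

    @property
    def median_days(self) -> float:
        return self.scale_alpha * math.log(2.0) ** (1.0 / self.shape_beta)


def compute_tto(
    starts: pd.DataFrame,
    events: pd.DataFrame,
    sex: pd.Series | dict | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Onset records per report, with an exclusion tally.

    ``starts``: columns ``primaryid``, ``start_date`` (datetime; the
    earliest non-missing start per report is used). ``events``: columns
    ``primaryid``, ``event_date`` (earliest non-missing per report).
    Same-day onset (0 days) is retained; only a strictly earlier event
    date excludes a record.
    """
    s = starts.dropna(subset=["start_date"]).groupby("primaryid")[
        "start_date"].min()
    e = events.dropna(subset=["event_date"]).groupby("primaryid")[
        "event_date"].min()
    all_ids = pd.Index(
        pd.unique(pd.concat([starts["primaryid"], events["primaryid"]]))
    )
    merged = pd.DataFrame(index=all_ids)
    merged["start"] = s
    merged["event"] = e
    excl = {
        "missing_start": int(merged["start"].isna().sum()),
        "missing_event": int(
            (merged["start"].notna() & merged["event"].isna()).sum()),
    }
    ok = merged.dropna()
    days = (ok["event"] - ok["start"]).dt.days
    excl["negative"] = int((days < 0).sum())
    keep = days >= 0
    out = pd.DataFrame({
        "primaryid": ok.index[keep].astype(str),
        "tto_days": days[keep].astype(int).values,
    })
    if sex is not None:
        sex_map = sex if isinstance(sex, dict) else dict(
            zip(sex.index.astype(str), sex.values))
        out["sex"] = out["primaryid"].map(sex_map)
    excl["records_used"] = len(out)
    return out.reset_index(drop=True), excl


def summarize_tto(days) -> tuple[float, float, float]:
    """(median, Q1, Q3) by linear interpolation."""
    arr = np.asarray(days, dtype=float)
    if arr.size == 0:
        raise ValueError("no onset records to summarize")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return float(med), float(q1), float(q3)


def _weibull_nll(log_params: np.ndarray, x: np.ndarray) -> float:
    log_scale, log_shape = log_params
    scale, shape = math.exp(log_scale), math.exp(log_shape)
    z = x / scale
    return -float(np.sum(
        math.log(shape) - math.log(scale) + (shape - 1) * np.log(z)
        - z ** shape
    ))


def weibull_fit(
    days,
    offset: float = 0.5,
    ci_method: str = "wald",
    n_boot: int = 1000,
    seed: int = 0,
) -> WeibullFit:
    """Two-parameter Weibull MLE on onset days.

    The Weibull support is positive, so day counts are shifted by
    ``offset`` (default half a day, keeping same-day events in the
    sample; pass 0 to fit raw positive days). CIs are Wald intervals from
    the observed information on the log-parameter scale (default) or
    percentile bootstrap (``ci_method="bootstrap"``, seeded).

    Failure type is read off the shape CI: entirely below 1 ->
    ``early_failure``, entirely above -> ``wear_out``, else
    ``random_failure``.
    """
    x = np.asarray(days, dtype=float) + offset
    n = x.size
    if n < 2 or np.all(x == x[0]):
        raise ValueError("need at least two distinct onset values")
    if np.any(x <= 0):
        raise ValueError("onset values must be positive after the offset")
    if n < 10:
        warnings.warn(f"only {n} onset records; the fit will be unstable",
                      stacklevel=2)

    x0 = np.array([math.log(np.median(x) + 1e-9), 0.0])
    res = optimize.minimize(_weibull_nll, x0, args=(x,), method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12,
                                     "maxiter": 5000})
    res = optimize.minimize(_weibull_nll, res.x, args=(x,), method="BFGS")
    log_scale, log_shape = res.x
    scale, shape = math.exp(log_scale), math.exp(log_shape)

    if ci_method == "wald":
        hess = _numeric_hessian(lambda p: _weibull_nll(p, x), res.x)
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.diag(cov))
        scale_ci = (scale * math.exp(-Z975 * se[0]),
                    scale * math.exp(Z975 * se[0]))
        shape_ci = (shape * math.exp(-Z975 * se[1]),
                    shape * math.exp(Z975 * se[1]))
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = np.empty((n_boot, 2))
        for i in range(n_boot):
            xb = rng.choice(x, size=n, replace=True)
            if np.all(xb == xb[0]):
                boots[i] = (scale, shape)
                continue
            rb = optimize.minimize(_weibull_nll, res.x, args=(xb,),
                                   method="Nelder-Mead")
            boots[i] = np.exp(rb.x)
        scale_ci = tuple(np.percentile(boots[:, 0], [2.5, 97.5]))
        shape_ci = tuple(np.percentile(boots[:, 1], [2.5, 97.5]))
    else:
        raise ValueError(f"unknown CI method {ci_method!r}")

    if shape_ci[1] < 1.0:
        failure_type = "early_failure"
    elif shape_ci[0] > 1.0:
        failure_type = "wear_out"
    else:
        failure_type = "random_failure"
    return WeibullFit(
        scale_alpha=scale, scale_ci=(float(scale_ci[0]), float(scale_ci[1])),
        shape_beta=shape, shape_ci=(float(shape_ci[0]), float(shape_ci[1])),
        n=n, failure_type=failure_type, log_likelihood=-float(res.fun),
    )


def _numeric_hessian(f, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian (2 parameters)."""
    k = len(x)
    hess = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            hess[i, j] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej)
                + f(x - ei - ej)
            ) / (4 * h * h)
    return (hess + hess.T) / 2


def cumulative_onset(
    records: pd.DataFrame, by: str | None = None
) -> pd.DataFrame:
    """Empirical cumulative onset fraction vs day, optionally per group.

    Every record is an event; the curve steps from 0 to 1 at the ordered
    onset days. Returns columns ``day``, ``cumulative_fraction`` (and the
    group column when ``by`` is given).
    """
    def _ecdf(days: np.ndarray) -> pd.DataFrame:
        ds, counts = np.unique(days, return_counts=True)
        frac = np.cumsum(counts) / counts.sum()
        return pd.DataFrame({"day": ds, "cumulative_fraction": frac})

    if by is None:
        if len(records) == 0:
            raise ValueError("no onset records")
        return _ecdf(records["tto_days"].to_numpy())
    frames = []
    for g, sub in records.groupby(by, sort=True):
        if len(sub) == 0:
            continue
        e = _ecdf(sub["tto_days"].to_numpy())
        e[by] = g
        frames.append(e)
    return pd.concat(frames, ignore_index=True)


def logrank(
    records: pd.DataFrame, group: str = "sex"
) -> tuple[float, float]:
    """Log-rank comparison of onset-time distributions between two groups.

    All observations are events (no censoring). Returns (statistic, p) on
    one degree of freedom.
    """
    groups = [g for g, sub in records.groupby(group) if len(sub) > 0]
    if len(groups) != 2:
        raise ValueError(
            f"log-rank needs exactly two non-empty groups, got {groups}")
    g1 = records.loc[records[group] == groups[0], "tto_days"]
    g2 = records.loc[records[group] == groups[1], "tto_days"]
    res = logrank_test(g1, g2, event_observed_A=np.ones(len(g1)),
                       event_observed_B=np.ones(len(g2)))
    return float(res.test_statistic), float(res.p_value)
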