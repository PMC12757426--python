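"""Serious versus non-serious event-frequency comparison per preferred term.

Each PT yields a 2x2 table whose rows are the serious and non-serious
report groups and whose margins are the groups' total PT occurrences (not
case counts). The test is the continuity-corrected (Yates) chi-square
unless any expected cell falls below 5, in which case Fisher's exact test
(two-sided, sum-of-small-p convention) is used instead — the selection
rule standard for sparse 2x2 tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .contingency import ContingencyTable

EXPECTED_COUNT_THRESHOLD = 5.0


@dataclass(frozen=True)
class SeverityComparison:
    pt: str
    a: int  #: serious reports with the event
    b: int  #: serious without
    c: int  #: non-serious with the event
    d: int  #: non-serious without
    test_used: str
    statistic: float | None
    p_value: float


def severity_table(
    pt: str,
    serious_events: int,
    serious_total: int,
    nonserious_events: int,
    nonserious_total: int,
) -> ContingencyTable:
    """Build the serious/non-serious 2x2 for one PT from group margins."""
    if serious_events > serious_total or nonserious_events > nonserious_total:
        raise ValueError(f"{pt}: event count exceeds its group total")
    if min(serious_events, nonserious_events) < 0:
        raise ValueError(f"{pt}: negative event count")
    return ContingencyTable(
        a=serious_events, b=serious_total - serious_events,
        c=nonserious_events, d=nonserious_total - nonserious_events,
        label=pt,
    )


def expected_cells(table: ContingencyTable) -> np.ndarray:
    """Expected counts under independence, cellwise (2x2)."""
    a, b, c, d = table.cells()
    n = table.n
    rows = np.array([a + b, c + d])
    cols = np.array([a + c, b + d])
    return np.outer(rows, cols) / n


def select_test(table: ContingencyTable) -> str:
    """``fisher_exact`` iff the minimum expected cell count is below 5."""
    if float(expected_cells(table).min()) < EXPECTED_COUNT_THRESHOLD:
        return "fisher_exact"
    return "chi_square"


def chi_square_yates(table: ContingencyTable) -> tuple[float, float]:
    """Continuity-corrected Pearson chi-square on a 2x2 table.

    statistic = N(|ad-bc| - N/2)^2 / [(a+b)(c+d)(a+c)(b+d)], clamped to 0
    when |ad-bc| <= N/2; two-sided p on 1 df.
    """
    a, b, c, d = table.cells()
    n = table.n
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        raise ValueError(f"degenerate table for {table.label!r}: zero margin")
    num = max(abs(a * d - b * c) - n / 2.0, 0.0)
    statistic = n * num * num / denom
    p = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), p


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p (sum of hypergeometric probabilities no
    larger than the observed table's)."""
    a, b, c, d = (int(round(x)) for x in table.cells())
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)


def compare_pt(
    pt: str,
    serious_events: int,
    serious_total: int,
    nonserious_events: int,
    nonserious_total: int,
) -> SeverityComparison:
    """Full comparison for one PT: build, select, test."""
    t = severity_table(pt, serious_events, serious_total,
                       nonserious_events, nonserious_total)
    test = select_test(t)
    if test == "chi_square":
        statistic, p = chi_square_yates(t)
    else:
        statistic, p = None, fisher_exact(t)
    return SeverityComparison(
        pt=pt, a=int(t.a), b=int(t.b), c=int(t.c), d=int(t.d),
        test_used=test, statistic=statistic, p_value=p,
    )


def compare_severity(
    pt_counts: pd.DataFrame,
    serious_total: int | None = None,
    nonserious_total: int | None = None,
) -> pd.DataFrame:
    """Run the comparison for every PT.

    ``pt_counts`` needs columns ``pt``, ``serious_events``,
    ``nonserious_events``. Group totals default to the summed PT
    occurrences per group (the occurrence margins).
    """
    st = serious_total if serious_total is not None else int(
        pt_counts["serious_events"].sum())
    nt = nonserious_total if nonserious_total is not None else int(
        pt_counts["nonserious_events"].sum())
    rows = []
    for _, r in pt_counts.iterrows():
        se, ne = int(r["serious_events"]), int(r["nonserious_events"])
        if se == 0 and ne == 0:
            rows.append({
                "pt": r["pt"], "serious_events": 0, "nonserious_events": 0,
                "serious_pct": 0.0, "nonserious_pct": 0.0,
                "test": "none", "statistic": np.nan, "p_value": np.nan,
                "degenerate": True,
            })
            continue
        comp = compare_pt(str(r["pt"]), se, st, ne, nt)
        rows.append({
            "pt": comp.pt,
            "serious_events": comp.a, "nonserious_events": comp.c,
            "serious_pct": 100.0 * comp.a / st if st else np.nan,
            "nonserious_pct": 100.0 * comp.c / nt if nt else np.nan,
            "test": comp.test_used,
            "statistic": np.nan if comp.statistic is None else comp.statistic,
            "p_value": comp.p_value,
            "degenerate": False,
        })
    return pd.DataFrame(rows)
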