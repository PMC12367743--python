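"""Exact and classical two-group statistics for small clinical tables.

Everything here is implemented from first principles on top of plain
arithmetic; only distribution tail functions (Student t, chi-square,
normal) come from :mod:`scipy.stats`.

* :func:`fisher_exact_2x2` - two-sided Fisher's exact test using the
  point-probability rule (sums all fixed-margin tables whose
  hypergeometric point probability is <= the observed table's), computed
  exactly in integer arithmetic.
* :func:`chi_square` - Pearson chi-square without continuity correction.
* :func:`mann_whitney_u` - exact two-sided p by enumeration of the null
  U distribution for small untied samples, normal approximation with tie
  correction otherwise.
* :func:`welch_t` - Welch's unequal-variance t with Satterthwaite dof.
* :func:`logrank_two_group` - the standard two-group log-rank test with
  the simultaneous-event (hypergeometric variance) tie handling.
* :func:`table2_report` - a baseline-characteristics comparison table:
  continuous rows get Mann-Whitney (plus Welch) p-values, categorical
  rows Fisher (2x2) or chi-square (r x c), survival a log-rank p.
"""

from __future__ import annotations

import math
from fractions import Fraction
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "fisher_exact_2x2",
    "chi_square",
    "mann_whitney_u",
    "welch_t",
    "logrank_two_group",
    "kaplan_meier",
    "table2_report",
]


def _as_2x2(table) -> tuple[int, int, int, int]:
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float)
        if np.any(arr < 0) or np.any(arr != np.rint(arr)):
            raise ValueError("table cells must be nonnegative integers")
        arr = arr.astype(int)
    return int(arr[0, 0]), int(arr[0, 1]), int(arr[1, 0]), int(arr[1, 1])


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table (point-probability rule).

    Sums the hypergeometric point probabilities of every table with the
    observed margins whose probability does not exceed the observed
    table's. Computed with exact integer arithmetic.
    """
    a, b, c, d = _as_2x2(table)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        raise ValueError("table has no observations")
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    # integer weights proportional to the hypergeometric pmf
    weights = {x: math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)}
    observed = weights[a]
    total = math.comb(n, c1)
    num = sum(w for w in weights.values() if w <= observed)
    return float(Fraction(num, total))


def chi_square(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence for an r x c table.

    Returns ``(statistic, dof, p)``. No continuity correction. A zero
    expected cell (i.e. a zero margin) is rejected with advice to use
    Fisher's exact test.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or min(arr.shape) < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if np.any(arr < 0):
        raise ValueError("table cells must be nonnegative")
    total = arr.sum()
    if total == 0:
        raise ValueError("table has no observations")
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / total
    if np.any(expected == 0):
        raise ValueError(
            "zero expected count (empty margin); use Fisher's exact test"
        )
    statistic = float(((arr - expected) ** 2 / expected).sum())
    dof = (arr.shape[0] - 1) * (arr.shape[1] - 1)
    p = float(stats.chi2.sf(statistic, dof))
    return statistic, dof, p


@lru_cache(maxsize=None)
def _u_counts(n_x: int, n_y: int) -> tuple[int, ...]:
    """Number of rank assignments giving each U value, U = 0..n_x*n_y.

    Standard recurrence: c(u; n, m) = c(u - m; n - 1, m) + c(u; n, m - 1).
    """
    if n_x == 0 or n_y == 0:
        return (1,)
    max_u = n_x * n_y
    prev = _u_counts(n_x - 1, n_y)  # c(.; n_x-1, n_y)
    side = _u_counts(n_x, n_y - 1)  # c(.; n_x, n_y-1)
    out = []
    for u in range(max_u + 1):
        total = 0
        if 0 <= u - n_y < len(prev):
            total += prev[u - n_y]
        if u < len(side):
            total += side[u]
        out.append(total)
    return tuple(out)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, str]:
    """Mann-Whitney U test; returns ``(U, two-sided p, method)``.

    ``U`` counts pairs where x > y (ties count 0.5). The exact two-sided
    p enumerates the null U distribution when ``n_x + n_y <= 12`` and no
    ties are present; otherwise the normal approximation with tie
    correction is used. ``method`` is ``"exact"`` or ``"normal"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n_x, n_y = x.size, y.size
    greater = (x[:, None] > y[None, :]).sum()
    ties = (x[:, None] == y[None, :]).sum()
    u = float(greater) + 0.5 * float(ties)

    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size

    if not has_ties and n_x + n_y <= 12:
        counts = _u_counts(n_x, n_y)
        total = sum(counts)
        u_int = int(round(u))
        mean = n_x * n_y / 2
        # symmetric null: two-sided p = P(U <= u_min) + P(U >= n_x n_y - u_min)
        u_min = min(u_int, n_x * n_y - u_int)
        lower = sum(counts[: u_min + 1])
        upper = sum(counts[n_x * n_y - u_min :])
        p = min(1.0, float(Fraction(lower + upper, total)))
        if u == mean:
            p = 1.0
        return u, p, "exact"

    n = n_x + n_y
    mean = n_x * n_y / 2
    # tie correction over pooled value multiplicities
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n_x * n_y / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:
        return u, 1.0, "normal"
    z = (u - mean) / math.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z)))
    return u, min(1.0, p), "normal"


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns ``(t, dof, two-sided p)``.

    Requires at least two observations per sample. If both variances are
    zero: equal means give ``t = 0, p = 1`` by convention, unequal means
    are an error (no variance estimate exists).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(x.size + y.size - 2), 1.0
        raise ValueError("both samples have zero variance and different means")
    sx = vx / x.size
    sy = vy / y.size
    t = (x.mean() - y.mean()) / math.sqrt(sx + sy)
    dof = (sx + sy) ** 2 / (
        sx**2 / (x.size - 1) + sy**2 / (y.size - 1)
    )
    p = float(2 * stats.t.sf(abs(t), dof))
    return float(t), float(dof), p


def logrank_two_group(records: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test; returns ``(chi-square statistic, p)``.

    *records* needs columns ``time_months`` (> 0), ``event`` (1 = death,
    0 = censored) and ``group`` (exactly two levels). At each distinct
    event time, observed group-1 events are compared with their
    hypergeometric expectation; ties are handled with the standard
    simultaneous-event variance term.
    """
    times = records["time_months"].to_numpy(dtype=float)
    events = records["event"].to_numpy(dtype=int)
    groups = records["group"].to_numpy()
    levels = sorted(set(groups))
    if len(levels) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, found {levels}")
    if events.sum() == 0:
        raise ValueError("no events observed")
    in1 = groups == levels[0]
    obs_total = 0.0
    exp_total = 0.0
    var_total = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & in1).sum())
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & in1).sum())
        obs_total += d1
        exp_total += d * n1 / n
        if n > 1:
            var_total += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var_total == 0:
        return 0.0, 1.0
    statistic = (obs_total - exp_total) ** 2 / var_total
    p = float(stats.chi2.sf(statistic, 1))
    return float(statistic), p


def kaplan_meier(records: pd.DataFrame, group: str) -> pd.DataFrame:
    """Kaplan-Meier step function for one group (plotting convenience)."""
    sub = records[records["group"] == group]
    times = sub["time_months"].to_numpy(dtype=float)
    events = sub["event"].to_numpy(dtype=int)
    rows = [{"time_months": 0.0, "survival": 1.0}]
    surv = 1.0
    for t in sorted(set(times[events == 1])):
        n = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        surv *= 1 - d / n
        rows.append({"time_months": float(t), "survival": surv})
    return pd.DataFrame(rows)


def table2_report(
    clinical: pd.DataFrame,
    survival: pd.DataFrame | None = None,
    group_col: str = "arm",
    continuous: Sequence[str] | None = None,
    categorical: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Baseline-characteristics comparison between two groups.

    Continuous variables are summarised as mean +/- sd per group with a
    Mann-Whitney p (Welch p as an extra column); categorical variables as
    counts per level with a Fisher p for 2x2 shapes and a chi-square p
    otherwise. Rows with missing values drop those patients for that
    variable only. Variables observed at a single level get no p-value,
    with a note. When *survival* is given, a log-rank row is prepended.
    """
    levels = sorted(clinical[group_col].dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups in {group_col!r}, found {levels}")
    g1, g2 = levels
    if continuous is None:
        continuous = [
            c
            for c in clinical.columns
            if c not in (group_col, "patient_id", "outcome")
            and pd.api.types.is_numeric_dtype(clinical[c])
            and clinical[c].dropna().nunique() > 2
        ]
    if categorical is None:
        exclude = set(continuous) | {group_col, "patient_id"}
        categorical = [c for c in clinical.columns if c not in exclude]

    rows = []
    if survival is not None:
        stat, p = logrank_two_group(survival)
        rows.append(
            {
                "variable": "survival (log-rank)",
                "type": "survival",
                g1: "",
                g2: "",
                "p_value": p,
                "test": "logrank",
                "note": "",
            }
        )
    for var in continuous:
        sub = clinical[[group_col, var]].dropna()
        xs = sub.loc[sub[group_col] == g1, var].to_numpy(dtype=float)
        ys = sub.loc[sub[group_col] == g2, var].to_numpy(dtype=float)
        row = {
            "variable": var,
            "type": "continuous",
            g1: f"{xs.mean():.1f} ± {xs.std(ddof=1):.1f}" if xs.size > 1 else "na",
            g2: f"{ys.mean():.1f} ± {ys.std(ddof=1):.1f}" if ys.size > 1 else "na",
            "test": "mann-whitney",
            "note": "",
        }
        try:
            _, p, _ = mann_whitney_u(xs, ys)
            row["p_value"] = p
            _, _, row["welch_p"] = welch_t(xs, ys)
        except ValueError as exc:
            row["p_value"] = np.nan
            row["note"] = str(exc)
        rows.append(row)
    for var in categorical:
        sub = clinical[[group_col, var]].dropna()
        tab = pd.crosstab(sub[group_col], sub[var])
        tab = tab.reindex([g1, g2]).fillna(0).astype(int)
        counts1 = "/".join(f"{lvl}:{tab.loc[g1, lvl]}" for lvl in tab.columns)
        counts2 = "/".join(f"{lvl}:{tab.loc[g2, lvl]}" for lvl in tab.columns)
        row = {
            "variable": var,
            "type": "categorical",
            g1: counts1,
            g2: counts2,
            "note": "",
        }
        if tab.shape[1] < 2:
            row["p_value"] = np.nan
            row["test"] = ""
            row["note"] = "single observed level; p omitted"
        elif tab.shape[1] == 2:
            row["p_value"] = fisher_exact_2x2(tab.to_numpy())
            row["test"] = "fisher"
        else:
            try:
                _, _, row["p_value"] = chi_square(tab.to_numpy())
                row["test"] = "chi-square"
            except ValueError as exc:
                row["p_value"] = np.nan
                row["test"] = "chi-square"
                row["note"] = str(exc)
        rows.append(row)
    report = pd.DataFrame(rows)
    cols = ["variable", "type", g1, g2, "p_value", "welch_p", "test", "note"]
    for c in cols:
        if c not in report.columns:
            report[c] = np.nan
    return report[cols]
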