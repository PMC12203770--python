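"""Statistical comparisons between decoder groups.

Thin, explicit contracts around the comparisons used in decoder
evaluation: paired and two-sample t-tests (alpha 0.01, one- or two-tailed),
a pooled two-proportion z-test for orbiting rates, and a nested two-way
ANOVA (day, run-within-day) for online stability analyses.  No
multiple-testing correction is applied by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_ALPHA = 0.01

_TAILS = ("two-sided", "greater", "less")


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    p_value: float
    tail: str
    alpha: float
    n: tuple[int, ...]
    significant: bool
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p value outside [0, 1]")


def _check_tail(tail: str) -> None:
    if tail not in _TAILS:
        raise ValueError(f"tail must be one of {_TAILS}")


def paired_ttest(
    a: np.ndarray, b: np.ndarray, tail: str = "two-sided",
    alpha: float = DEFAULT_ALPHA,
) -> ComparisonResult:
    """Paired t-test on a - b differences."""
    _check_tail(tail)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diffs = a - b
    if np.std(diffs) == 0.0:
        # Zero-variance differences: decide by sign, flag as degenerate.
        mean = diffs.mean()
        if mean == 0.0:
            p = 1.0
        elif tail == "two-sided":
            p = 0.0
        elif tail == "greater":
            p = 0.0 if mean > 0 else 1.0
        else:
            p = 0.0 if mean < 0 else 1.0
        return ComparisonResult(
            "paired_t", np.inf if diffs.mean() else 0.0, p, tail, alpha,
            (len(a),), p < alpha, degenerate=True,
        )
    res = sps.ttest_rel(a, b, alternative=tail)
    return ComparisonResult(
        "paired_t", float(res.statistic), float(res.pvalue), tail, alpha,
        (len(a),), res.pvalue < alpha,
    )


def two_sample_ttest(
    a: np.ndarray, b: np.ndarray, tail: str = "two-sided",
    alpha: float = DEFAULT_ALPHA, welch: bool = False,
) -> ComparisonResult:
    """Pooled-variance (Student) two-sample t-test; Welch by flag."""
    _check_tail(tail)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    res = sps.ttest_ind(a, b, equal_var=not welch, alternative=tail)
    return ComparisonResult(
        "two_sample_t", float(res.statistic), float(res.pvalue), tail, alpha,
        (len(a), len(b)), res.pvalue < alpha,
    )


def diff_of_proportions(
    k1: int, n1: int, k2: int, n2: int, tail: str = "two-sided",
    alpha: float = DEFAULT_ALPHA,
) -> ComparisonResult:
    """Two-proportion z-test with pooled proportion."""
    _check_tail(tail)
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0:
            raise ValueError("sample sizes must be positive")
        if not (0 <= k <= n):
            raise ValueError("counts must satisfy 0 <= k <= n")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0.0:
        return ComparisonResult(
            "diff_of_proportions", 0.0, 1.0, tail, alpha, (n1, n2), False,
            degenerate=True,
        )
    z = (p1 - p2) / se
    if tail == "two-sided":
        p = 2.0 * sps.norm.sf(abs(z))
    elif tail == "greater":
        p = float(sps.norm.sf(z))
    else:
        p = float(sps.norm.cdf(z))
    return ComparisonResult(
        "diff_of_proportions", float(z), float(min(p, 1.0)), tail, alpha,
        (n1, n2), p < alpha,
    )


# --------------------------------------------------------------------------
# Nested two-way ANOVA
# --------------------------------------------------------------------------


def _group_means(values: np.ndarray, codes: np.ndarray, n_groups: int):
    counts = np.bincount(codes, minlength=n_groups)
    sums = np.bincount(codes, weights=values, minlength=n_groups)
    with np.errstate(invalid="ignore"):
        means = sums / counts
    return means, counts


def nested_anova(
    values: np.ndarray,
    day: np.ndarray,
    run: np.ndarray,
    crossed: bool = False,
) -> pd.DataFrame:
    """Two-way ANOVA with run nested within day.

    Decomposes the total sum of squares into a day effect, a
    run-within-day effect, and residual; F statistics test each mean
    square against the residual.  With ``crossed=True`` the run factor is
    instead treated as crossed with day and a day x run interaction term
    is reported (requires run labels shared across days).

    Returns a table with one row per effect: sum_sq, df, F, p.  Degenerate
    layouts (all values identical) are reported with NaN F and p.
    """
    values = np.asarray(values, dtype=float)
    day = np.asarray(day)
    run = np.asarray(run)
    if not (len(values) == len(day) == len(run)):
        raise ValueError("values and factors must align")
    day_codes, day_labels = pd.factorize(day)
    n_days = len(day_labels)
    if n_days < 2:
        raise ValueError("need >= 2 days")

    grand = values.mean()
    ss_total = float(np.sum((values - grand) ** 2))
    day_means, day_counts = _group_means(values, day_codes, n_days)
    ss_day = float(np.sum(day_counts * (day_means - grand) ** 2))
    df_day = n_days - 1

    if not crossed:
        # Cell = (day, run) combination; nested SS pools within-day
        # run-mean spread.
        cell_codes, _ = pd.factorize(
            pd.Series(day).astype(str) + "\x00" + pd.Series(run).astype(str)
        )
        n_cells = cell_codes.max() + 1
        cell_means, cell_counts = _group_means(values, cell_codes, n_cells)
        # runs per day
        runs_per_day = np.zeros(n_days, dtype=int)
        cell_day = np.full(n_cells, -1, dtype=int)
        for c, d in zip(cell_codes, day_codes):
            cell_day[c] = d
        for d in range(n_days):
            runs_per_day[d] = int(np.sum(cell_day == d))
        single_run_days = [
            str(day_labels[d]) for d in range(n_days) if runs_per_day[d] < 2
        ]
        if single_run_days:
            warnings.warn(
                "day(s) with a single run contribute no nested term: "
                + ", ".join(single_run_days),
                stacklevel=2,
            )
        ss_run = float(
            np.sum(cell_counts * (cell_means - day_means[cell_day]) ** 2)
        )
        df_run = int(np.sum(runs_per_day - 1))
        ss_res = ss_total - ss_day - ss_run
        df_res = len(values) - int(runs_per_day.sum())
        rows = [
            ("day", ss_day, df_day),
            ("run(day)", ss_run, df_run),
            ("residual", ss_res, df_res),
        ]
    else:
        run_codes, run_labels = pd.factorize(run)
        n_runs = len(run_labels)
        run_means, run_counts = _group_means(values, run_codes, n_runs)
        ss_run = float(np.sum(run_counts * (run_means - grand) ** 2))
        df_run = n_runs - 1
        cell_codes = day_codes * n_runs + run_codes
        cell_means, cell_counts = _group_means(values, cell_codes, n_days * n_runs)
        ss_cells = float(
            np.nansum(cell_counts * (np.nan_to_num(cell_means) - grand) ** 2)
        )
        ss_int = ss_cells - ss_day - ss_run
        df_int = df_day * df_run
        ss_res = ss_total - ss_cells
        df_res = len(values) - int((cell_counts > 0).sum())
        rows = [
            ("day", ss_day, df_day),
            ("run", ss_run, df_run),
            ("day:run", ss_int, df_int),
            ("residual", ss_res, df_res),
        ]

    ms_res = rows[-1][1] / rows[-1][2] if rows[-1][2] > 0 else np.nan
    out = []
    for name, ss, df in rows:
        if name == "residual":
            out.append({"effect": name, "sum_sq": ss, "df": df,
                        "F": np.nan, "p": np.nan})
            continue
        if df <= 0 or not np.isfinite(ms_res) or ms_res <= 0:
            f = p = np.nan
        else:
            f = (ss / df) / ms_res
            p = float(sps.f.sf(f, df, rows[-1][2]))
        out.append({"effect": name, "sum_sq": ss, "df": df, "F": f, "p": p})
    return pd.DataFrame(out)
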