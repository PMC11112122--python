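"""Group comparison and reporting.

Mirrors the statistical workflow used for per-axon / per-AIS metrics:
normality is screened per group (D'Agostino-Pearson); two groups are
compared with Student's t-test or Mann-Whitney, three or more with one-way
ANOVA or Kruskal-Wallis followed by Dunn's post-hoc test; descriptives are
the median with a distribution-free 95% confidence interval from order
statistics. Dunn's test is implemented here directly (rank sums from the
pooled Kruskal-Wallis ranking, tie-corrected z statistics) with a
configurable multiple-comparison correction.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError, InsufficientDataError, ParameterError

__all__ = [
    "ComparisonResult",
    "median_ci",
    "dunn_test",
    "compare_groups",
    "two_way_anova",
    "build_report",
]

NORMALITY_ALPHA = 0.05
MIN_N_FOR_NORMALTEST = 8  # below this the D'Agostino-Pearson test is undefined


@dataclass
class ComparisonResult:
    metric: str
    test_name: str
    statistic: float
    p_value: float
    group_medians: dict[str, tuple[float, float, float]]  # (median, lo, hi)
    posthoc: dict[tuple[str, str], float] = field(default_factory=dict)
    normality_p: dict[str, float] = field(default_factory=dict)
    choice_log: str = ""


def median_ci(values: Sequence[float], level: float = 0.95) -> tuple[float, float, float]:
    """Median with a distribution-free confidence interval.

    Uses the binomial order-statistic method: the interval
    [x_(j), x_(n+1-j)] in 1-based order statistics, with j the largest
    index such that the Bin(n, 1/2) tail P(X <= j-1) stays within
    (1-level)/2, giving coverage >= ``level``. For samples too small for
    any such interval a seeded bootstrap percentile interval is used.
    """
    x = np.sort(np.asarray(values, dtype=np.float64))
    n = len(x)
    if n < 3:
        raise InsufficientDataError("need >= 3 values for a median CI")
    med = float(np.median(x))
    alpha = 1.0 - level
    # smallest j with cdf(j) >= alpha/2 has cdf(j-1) < alpha/2, so the
    # interval [x_(j), x_(n+1-j)] covers with probability 1 - 2 cdf(j-1)
    j = int(sps.binom.ppf(alpha / 2, n, 0.5))
    while j >= 1 and sps.binom.cdf(j - 1, n, 0.5) >= alpha / 2:
        j -= 1
    if j < 1:
        rng = np.random.default_rng(0)
        boots = np.median(rng.choice(x, size=(10000, n), replace=True), axis=1)
        lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
        return med, float(lo), float(hi)
    return med, float(x[j - 1]), float(x[n - j])


def _tie_correction(pooled_ranks_source: np.ndarray) -> float:
    """Sum of (t^3 - t) over tie groups in the pooled sample."""
    _, counts = np.unique(pooled_ranks_source, return_counts=True)
    return float(np.sum(counts.astype(np.float64) ** 3 - counts))


def dunn_test(
    groups: dict[str, np.ndarray],
    comparisons: Sequence[tuple[str, str]] | None = None,
    p_adjust: Literal["holm", "bonferroni", "none"] = "holm",
) -> dict[tuple[str, str], float]:
    """Dunn's post-hoc test on the pooled Kruskal-Wallis ranking.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))
    with T the tie correction sum of (t^3 - t). ``comparisons`` defaults to
    all pairs; pass a many-to-one list to compare each group against a
    reference. Two-sided p-values, adjusted per ``p_adjust``.
    """
    names = list(groups)
    pooled = np.concatenate([np.asarray(groups[g], dtype=np.float64) for g in names])
    ranks = sps.rankdata(pooled)
    N = len(pooled)
    mean_ranks: dict[str, float] = {}
    sizes: dict[str, int] = {}
    i = 0
    for g in names:
        n = len(groups[g])
        mean_ranks[g] = float(ranks[i : i + n].mean())
        sizes[g] = n
        i += n
    T = _tie_correction(pooled)
    var_term = N * (N + 1) / 12.0 - T / (12.0 * (N - 1))
    if comparisons is None:
        comparisons = list(itertools.combinations(names, 2))
    raw = {}
    for g1, g2 in comparisons:
        if var_term <= 0:  # every pooled value tied: no evidence of difference
            raw[(g1, g2)] = 1.0
            continue
        se = np.sqrt(var_term * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se
        raw[(g1, g2)] = 2.0 * sps.norm.sf(abs(z))
    m = len(raw)
    if p_adjust == "bonferroni":
        return {k: min(1.0, v * m) for k, v in raw.items()}
    if p_adjust == "holm":
        items = sorted(raw.items(), key=lambda kv: kv[1])
        out: dict[tuple[str, str], float] = {}
        running = 0.0
        for rank, (k, v) in enumerate(items):
            adj = min(1.0, (m - rank) * v)
            running = max(running, adj)
            out[k] = running
        return out
    return raw


def compare_groups(
    table: pd.DataFrame,
    value_col: str = "value",
    group_col: str = "group",
    metric: str = "",
    reference: str | None = None,
    posthoc_adjust: Literal["holm", "bonferroni", "none"] = "holm",
) -> ComparisonResult:
    """Normality-screened comparison of >= 2 groups.

    Each group needs n >= 3. All groups Gaussian (D'Agostino-Pearson
    p > 0.05, n >= 8) selects the parametric branch (t-test / one-way
    ANOVA); otherwise Mann-Whitney / Kruskal-Wallis with Dunn's post-hoc.
    With ``reference`` given, post-hoc comparisons are many-to-one against
    it; otherwise all pairs. The branch taken is recorded in
    ``choice_log``.
    """
    # sorted within groups so results are bit-identical under row permutation
    groups: dict[str, np.ndarray] = {
        str(g): np.sort(np.asarray(sub[value_col], dtype=np.float64))
        for g, sub in table.groupby(group_col, sort=True)
    }
    if len(groups) < 2:
        raise InputError("need >= 2 groups to compare")
    for g, v in groups.items():
        if len(v) < 3:
            raise InsufficientDataError(f"group {g!r} has n={len(v)} < 3")
        if np.any(~np.isfinite(v)):
            raise InputError(f"group {g!r} contains missing values")

    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0:
        # all values identical across every group: nothing to test
        return ComparisonResult(
            metric=metric,
            test_name="degenerate (all values identical)",
            statistic=0.0,
            p_value=1.0,
            group_medians={g: median_ci(v) for g, v in groups.items()},
            choice_log="constant data; comparison skipped",
        )

    normality_p: dict[str, float] = {}
    normal = True
    for g, v in groups.items():
        if len(v) < MIN_N_FOR_NORMALTEST:
            normality_p[g] = float("nan")
            normal = False
        else:
            pval = float(sps.normaltest(v).pvalue)
            normality_p[g] = pval
            normal = normal and pval > NORMALITY_ALPHA

    medians = {g: median_ci(v) for g, v in groups.items()}
    names = list(groups)
    posthoc: dict[tuple[str, str], float] = {}
    if len(groups) == 2:
        a, b = groups[names[0]], groups[names[1]]
        if normal:
            stat, p = sps.ttest_ind(a, b)
            test = "t-test (unpaired, two-tailed)"
        else:
            stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
            test = "Mann-Whitney U"
        log = f"2 groups; all-normal={normal} -> {test}"
    else:
        if normal:
            stat, p = sps.f_oneway(*groups.values())
            test = "one-way ANOVA"
        else:
            stat, p = sps.kruskal(*groups.values())
            test = "Kruskal-Wallis"
            comps = (
                [(g, reference) for g in names if g != reference]
                if reference is not None
                else None
            )
            posthoc = dunn_test(groups, comparisons=comps, p_adjust=posthoc_adjust)
        log = f"{len(groups)} groups; all-normal={normal} -> {test}"
    return ComparisonResult(
        metric=metric,
        test_name=test,
        statistic=float(stat),
        p_value=float(p),
        group_medians=medians,
        posthoc=posthoc,
        normality_p=normality_p,
        choice_log=log,
    )


def two_way_anova(
    table: pd.DataFrame, value_col: str, factor_a: str, factor_b: str
) -> pd.DataFrame:
    """Two-factor ANOVA with interaction (used for per-culture percentage
    outcomes crossed by genotype); returns the statsmodels ANOVA table."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = table.rename(
        columns={value_col: "_y", factor_a: "_fa", factor_b: "_fb"}
    )[["_y", "_fa", "_fb"]]
    model = ols("_y ~ C(_fa) * C(_fb)", data=df).fit()
    return sm.stats.anova_lm(model, typ=2)


def build_report(
    table: pd.DataFrame,
    metrics: Sequence[str],
    group_col: str = "group",
    reference: str | None = None,
    out_dir: str | Path | None = None,
    config_echo: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-metric group comparison over a tidy table of per-axon (or per-AIS)
    values.

    Returns a tidy summary DataFrame and a JSON-ready dict (config echo,
    per-metric tests, post-hoc p-values). A single group yields
    descriptives only. Output is invariant to row order. If ``out_dir`` is
    given, writes ``report.csv`` and ``report.json`` there.
    """
    for m in metrics:
        if m not in table.columns:
            raise ParameterError(f"unknown metric column {m!r}")
    n_groups = table[group_col].nunique()
    rows = []
    tests: dict[str, dict] = {}
    for m in metrics:
        sub = table[[group_col, m]].dropna().rename(columns={m: "value"})
        for g, gsub in sub.groupby(group_col, sort=True):
            med, lo, hi = median_ci(gsub["value"].to_numpy())
            rows.append(
                {"metric": m, "group": g, "n": len(gsub), "median": med,
                 "ci_lo": lo, "ci_hi": hi}
            )
        if n_groups >= 2:
            res = compare_groups(sub, metric=m, reference=reference)
            tests[m] = {
                "test": res.test_name,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "posthoc": {f"{a} vs {b}": p for (a, b), p in res.posthoc.items()},
                "choice": res.choice_log,
            }
    summary = pd.DataFrame(rows).sort_values(["metric", "group"]).reset_index(drop=True)
    report = {"config": config_echo or {}, "tests": tests}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "report.csv", index=False)
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return summary, report
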