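"""Group-comparison workflow: ROUT outlier screening, Welch's t-test,
two-way and nested ANOVA with multiplicity-adjusted post hoc tests.

The workflow mirrors common practice in small-cohort imaging studies:

* per-group screening of each metric with the ROUT procedure (robust fit +
  false-discovery-rate test on scaled residuals) before any parametric
  comparison;
* unpaired two-group comparisons by Welch's t-test (no equal-variance
  assumption);
* factorial designs by fixed-effects two-way ANOVA with Šídák or Tukey HSD
  post hoc comparisons;
* hierarchical (measurements within animals) designs by nested one-way
  ANOVA, testing the condition against the between-animal mean square so
  that within-animal pseudo-replication cannot inflate significance.

For a univariate sample the ROUT "regression model" degenerates to a
robust location fit: centre = median, scale = the robust standard
deviation of the residuals (RSDR), estimated as the 68.27th percentile of
the absolute residuals with the small-sample correction ``n / (n - K)``
(K = 1 parameter).  Candidates are then tested largest-residual-first
against a t-based threshold whose level steps down as
``(Q / 100) * (n - i + 1) / n`` for the i-th largest residual, stopping at
the first non-significant candidate — a step-down false-discovery-rate
control at rate Q (percent, default 1).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "welch_t_test",
    "rout_outliers",
    "sidak_adjust",
    "two_way_anova",
    "nested_anova",
    "compare_conditions",
]

DEFAULT_ROUT_Q = 1.0  # FDR, percent


@dataclass
class TestResult:
    """One comparison's outcome with its multiplicity bookkeeping."""

    comparison: str
    statistic: float
    df: float
    p_raw: float
    p_adjusted: float
    adjust_method: str = "none"
    outliers_removed: list = field(default_factory=list)
    n_per_group: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("p_raw", "p_adjusted"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0 or math.isnan(p)):
                raise ValueError(f"{name}={p} outside [0, 1]")
        if not math.isnan(self.p_adjusted) and self.p_adjusted < self.p_raw - 1e-15:
            raise ValueError("p_adjusted must be >= p_raw")


def welch_t_test(x, y, comparison: str = "x vs y") -> TestResult:
    """Unpaired two-sided t-test with Welch's correction.

    t = (mean(x) - mean(y)) / sqrt(sx²/nx + sy²/ny), with
    Welch–Satterthwaite degrees of freedom.  If both samples have zero
    variance and equal means the test is vacuous and p = 1 by convention;
    zero variance with unequal means gives p = 0.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("values must be finite")
    nx, ny = x.size, y.size
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    diff = x.mean() - y.mean()
    se2 = vx / nx + vy / ny
    if se2 == 0.0:
        t = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
        df = float(nx + ny - 2)
        p = 1.0 if diff == 0.0 else 0.0
    else:
        t = diff / math.sqrt(se2)
        df = se2**2 / (
            (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
        )
        p = 2.0 * float(stats.t.sf(abs(t), df))
    return TestResult(
        comparison=comparison,
        statistic=float(t),
        df=float(df),
        p_raw=min(p, 1.0),
        p_adjusted=min(p, 1.0),
        adjust_method="none",
        n_per_group={"x": int(nx), "y": int(ny)},
    )


def rout_outliers(
    values, q: float = DEFAULT_ROUT_Q
) -> tuple[np.ndarray, np.ndarray]:
    """Flag outliers in a univariate sample by the ROUT procedure.

    ``q`` is the false-discovery rate in percent (default 1).  Returns
    ``(kept_values, outlier_flags)`` with flags aligned to the input order.
    The procedure is equivariant under affine transformation of the data.
    """
    values = np.asarray(values, dtype=np.float64)
    n = values.size
    if n < 3:
        raise ValueError("ROUT needs at least 3 values")
    if not (0.0 < q <= 10.0):
        raise ValueError("Q must be in (0, 10] percent")
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")

    flags = np.zeros(n, dtype=bool)
    residuals = values - np.median(values)
    abs_res = np.abs(residuals)
    if not abs_res.any():  # all values identical
        return values.copy(), flags

    k_params = 1  # location-only model
    rsdr = np.percentile(abs_res, 68.27) * n / (n - k_params)
    df = n - k_params
    order = np.argsort(abs_res)[::-1]
    if rsdr == 0.0:
        # majority of points exactly at the median: any deviation is infinitely
        # many robust SDs away
        flags[abs_res > 0] = True
        return values[~flags], flags

    p_values = 2.0 * stats.t.sf(abs_res / rsdr, df)
    alpha = q / 100.0
    for rank, idx in enumerate(order, start=1):
        threshold = alpha * (n - (rank - 1)) / n
        if p_values[idx] < threshold:
            flags[idx] = True
        else:
            break
    return values[~flags], flags


def sidak_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Šídák multiplicity adjustment: 1 - (1 - p)^m, clipped at 1.

    ``m`` defaults to the number of p-values and must be at least that
    many.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1 or m < p.size:
        raise ValueError("m must be >= max(1, number of p-values)")
    with np.errstate(divide="ignore"):
        adjusted = -np.expm1(m * np.log1p(-p))
    return np.where(p >= 1.0, 1.0, np.minimum(1.0, adjusted))


def _f_or_zero(ss_term: float, df_term: float, mse: float, df_resid: float):
    """F and p for an ANOVA term, defining F = 0 (p = 1) for a zero SS term."""
    if ss_term <= 0.0:
        return 0.0, 1.0
    if mse == 0.0:
        return math.inf, 0.0
    f = (ss_term / df_term) / mse
    return f, float(stats.f.sf(f, df_term, df_resid))


def two_way_anova(
    table: pd.DataFrame,
    factor_a: str,
    factor_b: str,
    value: str,
    posthoc: str = "sidak",
) -> list[TestResult]:
    """Fixed-effects two-way ANOVA with condition-within-level post hoc tests.

    ``table`` is long-format with one observation per row.  The ANOVA table
    (main effects + interaction; type-II sums of squares, identical to
    type I/III on balanced data) is computed with statsmodels OLS.  Post
    hoc, the levels of ``factor_a`` are compared pairwise within each level
    of ``factor_b`` using the residual mean square, adjusted either by
    Šídák (m = number of comparisons) or by Tukey HSD on the studentized
    range with the whole family of cell means (Tukey–Kramer form, harmonic
    n for imbalance).

    Returns the three ANOVA terms followed by the post hoc comparisons.
    Empty design cells raise, naming the cell.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    if posthoc not in ("sidak", "tukey", "none"):
        raise ValueError(f"unknown posthoc {posthoc!r}")
    df = table[[factor_a, factor_b, value]].copy()
    if df[value].isna().any():
        raise ValueError("missing values in the response column")
    a_levels = sorted(df[factor_a].astype(str).unique())
    b_levels = sorted(df[factor_b].astype(str).unique())
    if len(a_levels) < 2 or len(b_levels) < 2:
        raise ValueError("each factor needs at least 2 levels")
    counts = df.groupby([factor_a, factor_b], sort=True).size()
    for a in a_levels:
        for b in b_levels:
            n_cell = counts.get((a, b), 0)
            if n_cell == 0:
                raise ValueError(f"empty design cell ({factor_a}={a}, {factor_b}={b})")
            if n_cell < 2:
                raise ValueError(
                    f"cell ({factor_a}={a}, {factor_b}={b}) has a single "
                    "replicate; the interaction term is not estimable"
                )

    df = df.rename(columns={factor_a: "_a", factor_b: "_b", value: "_y"})
    fit = smf.ols("_y ~ C(_a) * C(_b)", data=df).fit()
    anova = anova_lm(fit, typ=2)
    ss_resid = float(anova.loc["Residual", "sum_sq"])
    df_resid = float(anova.loc["Residual", "df"])
    # absorb floating-point fuzz from the OLS decomposition on (near-)constant data
    ss_tol = 1e-12 * max(float(np.square(df["_y"] - df["_y"].mean()).sum()), 1.0)
    if ss_resid <= ss_tol:
        ss_resid = 0.0
    mse = ss_resid / df_resid if df_resid > 0 else 0.0

    term_names = {"C(_a)": factor_a, "C(_b)": factor_b, "C(_a):C(_b)": "interaction"}
    results = []
    for term, label in term_names.items():
        ss_t = float(anova.loc[term, "sum_sq"])
        if ss_t <= ss_tol:
            ss_t = 0.0
        df_t = float(anova.loc[term, "df"])
        f, p = _f_or_zero(ss_t, df_t, mse, df_resid)
        results.append(
            TestResult(
                comparison=f"anova:{label}",
                statistic=f,
                df=df_t,
                p_raw=p,
                p_adjusted=p,
                adjust_method="none",
                extra={"df_resid": df_resid, "ss": ss_t},
            )
        )

    if posthoc == "none":
        return results

    cells = df.groupby(["_a", "_b"])["_y"].agg(["mean", "count"])
    comparisons = []
    for b in b_levels:
        for a1, a2 in itertools.combinations(a_levels, 2):
            m1, n1 = cells.loc[(a1, b), "mean"], cells.loc[(a1, b), "count"]
            m2, n2 = cells.loc[(a2, b), "mean"], cells.loc[(a2, b), "count"]
            comparisons.append((b, a1, a2, m1 - m2, int(n1), int(n2)))

    posthoc_results = []
    if posthoc == "sidak":
        m_comp = len(comparisons)
        for b, a1, a2, diff, n1, n2 in comparisons:
            se = math.sqrt(mse * (1.0 / n1 + 1.0 / n2))
            t = diff / se if se > 0 else (0.0 if diff == 0 else math.copysign(math.inf, diff))
            p = 2.0 * float(stats.t.sf(abs(t), df_resid)) if se > 0 else (1.0 if diff == 0 else 0.0)
            p_adj = float(sidak_adjust([p], m_comp)[0])
            posthoc_results.append(
                TestResult(
                    comparison=f"{a1} vs {a2} @ {factor_b}={b}",
                    statistic=t,
                    df=df_resid,
                    p_raw=min(p, 1.0),
                    p_adjusted=p_adj,
                    adjust_method="sidak",
                    n_per_group={a1: n1, a2: n2},
                    extra={"mean_difference": diff, "m": m_comp},
                )
            )
    else:  # tukey
        k = len(a_levels) * len(b_levels)  # family of all cell means
        for b, a1, a2, diff, n1, n2 in comparisons:
            se_tk = math.sqrt((mse / 2.0) * (1.0 / n1 + 1.0 / n2))
            if se_tk == 0:
                q_stat, p = (0.0, 1.0) if diff == 0 else (math.inf, 0.0)
            else:
                q_stat = abs(diff) / se_tk
                p = float(stats.studentized_range.sf(q_stat, k, df_resid))
            t_equiv = q_stat / math.sqrt(2.0)
            p_unadj = 2.0 * float(stats.t.sf(t_equiv, df_resid)) if se_tk > 0 else p
            posthoc_results.append(
                TestResult(
                    comparison=f"{a1} vs {a2} @ {factor_b}={b}",
                    statistic=q_stat if diff >= 0 else -q_stat,
                    df=df_resid,
                    p_raw=min(p_unadj, p, 1.0),
                    p_adjusted=min(p, 1.0),
                    adjust_method="tukey",
                    n_per_group={a1: n1, a2: n2},
                    extra={"mean_difference": diff, "k": k},
                )
            )
    return results + posthoc_results


def nested_anova(
    table: pd.DataFrame,
    condition: str,
    animal: str,
    value: str,
    posthoc: str = "tukey",
) -> list[TestResult]:
    """One-way ANOVA with animals nested in conditions.

    The condition effect is tested against the between-animal
    (within-condition) mean square, so duplicating every animal's
    measurements leaves F unchanged — within-animal replicates carry no
    extra degrees of freedom for the group comparison.  The optional Tukey
    HSD post hoc compares conditions on animal-level means
    (Tukey–Kramer studentized range, df = n_animals - n_conditions).

    Requires at least 2 animals per condition.
    """
    if posthoc not in ("tukey", "none"):
        raise ValueError(f"unknown posthoc {posthoc!r}")
    df = table[[condition, animal, value]].copy()
    if df[value].isna().any():
        raise ValueError("missing values in the response column")
    cond_levels = sorted(df[condition].astype(str).unique())
    if len(cond_levels) < 2:
        raise ValueError("need at least 2 conditions")
    animals_per_cond = df.groupby(condition)[animal].nunique()
    single = animals_per_cond[animals_per_cond < 2]
    if len(single):
        raise ValueError(
            f"condition(s) with a single animal: {list(single.index)}; "
            "the between-animal mean square is not estimable"
        )

    grand = df[value].mean()
    ss_cond = 0.0
    ss_animal = 0.0
    n_animals_total = 0
    animal_means: dict[str, list[float]] = {}
    for cond, g in df.groupby(condition, sort=True):
        cond_mean = g[value].mean()
        ss_cond += len(g) * (cond_mean - grand) ** 2
        means = []
        for _, ga in g.groupby(animal, sort=True):
            m = ga[value].mean()
            ss_animal += len(ga) * (m - cond_mean) ** 2
            means.append(float(m))
            n_animals_total += 1
        animal_means[str(cond)] = means

    a = len(cond_levels)
    df_cond = a - 1
    df_animal = n_animals_total - a
    ms_animal = ss_animal / df_animal if df_animal > 0 else 0.0
    if ss_cond <= 0.0:
        f, p = 0.0, 1.0
    elif ms_animal == 0.0:
        f, p = math.inf, 0.0
    else:
        f = (ss_cond / df_cond) / ms_animal
        p = float(stats.f.sf(f, df_cond, df_animal))
    results = [
        TestResult(
            comparison="nested-anova:condition",
            statistic=f,
            df=float(df_cond),
            p_raw=p,
            p_adjusted=p,
            adjust_method="none",
            n_per_group={c: len(m) for c, m in animal_means.items()},
            extra={"df_animal": float(df_animal), "ms_animal": ms_animal},
        )
    ]

    if posthoc == "none":
        return results

    # Tukey on animal-level means with pooled within-condition variance
    k = a
    pooled_num = sum(
        (len(m) - 1) * np.var(m, ddof=1) for m in animal_means.values() if len(m) > 1
    )
    df_w = sum(len(m) - 1 for m in animal_means.values())
    msw = pooled_num / df_w if df_w > 0 else 0.0
    for c1, c2 in itertools.combinations(cond_levels, 2):
        m1, m2 = animal_means[c1], animal_means[c2]
        diff = float(np.mean(m1) - np.mean(m2))
        se_tk = math.sqrt((msw / 2.0) * (1.0 / len(m1) + 1.0 / len(m2)))
        if se_tk == 0:
            q_stat, p_adj = (0.0, 1.0) if diff == 0 else (math.inf, 0.0)
        else:
            q_stat = abs(diff) / se_tk
            p_adj = float(stats.studentized_range.sf(q_stat, k, df_w))
        t_equiv = q_stat / math.sqrt(2.0)
        p_unadj = 2.0 * float(stats.t.sf(t_equiv, df_w)) if se_tk > 0 else p_adj
        results.append(
            TestResult(
                comparison=f"{c1} vs {c2} (animal means)",
                statistic=q_stat if diff >= 0 else -q_stat,
                df=float(df_w),
                p_raw=min(p_unadj, p_adj, 1.0),
                p_adjusted=min(p_adj, 1.0),
                adjust_method="tukey",
                n_per_group={c1: len(m1), c2: len(m2)},
                extra={"mean_difference": diff, "k": k},
            )
        )
    return results


def compare_conditions(
    metrics_table: pd.DataFrame,
    metric: str,
    rois: list[str],
    conditions: tuple[str, str] = ("sham", "tbi"),
    q: float | None = DEFAULT_ROUT_Q,
    adjust: str = "sidak",
) -> list[TestResult]:
    """Per-ROI two-group comparison of a kinetic metric.

    For each ROI: censored values are excluded (with counts recorded),
    each condition is screened with ROUT at FDR ``q`` percent (skipped when
    ``q`` is None), then the groups are compared by Welch's t-test.  Both
    raw and Šídák-adjusted (across the ROIs tested) p-values are reported.
    A comparison whose post-screening group size drops below 2 is reported
    as not computable (NaN statistic) rather than silently dropped.

    The statistic sign follows ``conditions[0] - conditions[1]``
    (sham - tbi by default).
    """
    if adjust not in ("sidak", "none"):
        raise ValueError(f"unknown adjust {adjust!r}")
    results = []
    for roi in rois:
        sub = metrics_table[metrics_table["roi_name"] == roi]
        groups = {}
        removed: dict[str, list] = {}
        censored_counts = {}
        for cond in conditions:
            g = sub[sub["condition"] == cond]
            values = pd.to_numeric(g[metric], errors="coerce")
            censored = values.isna()
            if "censored" in g.columns and metric == "appearance_time":
                censored = censored | g["censored"].astype(bool)
            censored_counts[cond] = int(censored.sum())
            kept_ids = g.loc[~censored, "animal_id"].to_numpy()
            kept = values[~censored].to_numpy(dtype=float)
            if q is not None and kept.size >= 3:
                _, flags = rout_outliers(kept, q)
                removed[cond] = [str(i) for i in kept_ids[flags]]
                kept = kept[~flags]
            else:
                removed[cond] = []
            groups[cond] = kept
        label = f"{metric} {roi}: {conditions[0]} vs {conditions[1]}"
        x, y = groups[conditions[0]], groups[conditions[1]]
        if x.size < 2 or y.size < 2:
            results.append(
                TestResult(
                    comparison=label,
                    statistic=math.nan,
                    df=math.nan,
                    p_raw=math.nan,
                    p_adjusted=math.nan,
                    adjust_method="none",
                    outliers_removed=removed[conditions[0]] + removed[conditions[1]],
                    n_per_group={c: int(groups[c].size) for c in conditions},
                    extra={
                        "roi": roi,
                        "status": "not computable: fewer than 2 values per group",
                        "censored": censored_counts,
                    },
                )
            )
            continue
        res = welch_t_test(x, y, comparison=label)
        res.outliers_removed = removed[conditions[0]] + removed[conditions[1]]
        res.n_per_group = {c: int(groups[c].size) for c in conditions}
        res.extra = {
            "roi": roi,
            "censored": censored_counts,
            "mean_difference": float(x.mean() - y.mean()),
            "group_means": {c: float(groups[c].mean()) for c in conditions},
        }
        results.append(res)

    if adjust == "sidak":
        computable = [r for r in results if not math.isnan(r.p_raw)]
        if computable:
            adjusted = sidak_adjust([r.p_raw for r in computable], len(computable))
            for r, p_adj in zip(computable, adjusted):
                r.p_adjusted = float(p_adj)
                r.adjust_method = "sidak"
    return results
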