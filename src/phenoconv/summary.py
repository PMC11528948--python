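"""Cohort-level summaries: inclusion filtering, phenotype frequency tables,
phenoconversion metrics, sex-stratified conversion rates, and the
between-group test battery (Kruskal-Wallis, Dunn, Fisher / chi-square,
Bonferroni).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alleles import Phenotype

__all__ = [
    "ConversionMetrics",
    "TestResult",
    "apply_inclusion_filter",
    "phenotype_frequency_table",
    "conversion_metrics",
    "stratified_conversion",
    "kruskal_wallis",
    "dunn_posthoc",
    "categorical_association",
    "bonferroni_adjust",
]

PHENOTYPE_ORDER = ["PM", "IM", "NM", "UM"]

# inclusion window for the chlorpromazine-equivalent dose of the main
# treatment drug, mg/day
DOSE_MIN = 25.0
DOSE_MAX = 1000.0


def apply_inclusion_filter(
    cohort: pd.DataFrame,
    dose_min: float = DOSE_MIN,
    dose_max: float = DOSE_MAX,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the study inclusion criteria and log every exclusion.

    Retained patients have a main treatment drug, a known (non-UNKNOWN)
    genotype-predicted phenotype, and a chlorpromazine-equivalent dose inside
    [dose_min, dose_max] mg/day.  Returns ``(included, exclusion_log)`` where
    the log has columns ``patient_id`` and ``reason``.
    """
    reasons: list[tuple[str, str]] = []
    keep = np.ones(len(cohort), dtype=bool)
    for i, (_, row) in enumerate(cohort.iterrows()):
        pid = str(row.get("patient_id", i))
        drug = row.get("main_drug")
        if drug is None or (isinstance(drug, float) and pd.isna(drug)) or str(drug).strip() == "":
            reasons.append((pid, "no_main_treatment_drug"))
            keep[i] = False
            continue
        gpt = row.get("gPT")
        if gpt is None or (isinstance(gpt, float) and pd.isna(gpt)) or str(gpt).strip().upper() == "UNKNOWN":
            reasons.append((pid, "unknown_phenotype"))
            keep[i] = False
            continue
        dose = row.get("cpz_equivalent_dose")
        if dose is None or pd.isna(dose):
            reasons.append((pid, "missing_dose"))
            keep[i] = False
        elif dose < dose_min:
            reasons.append((pid, "dose_below_minimum"))
            keep[i] = False
        elif dose > dose_max:
            reasons.append((pid, "dose_above_maximum"))
            keep[i] = False
    log = pd.DataFrame(reasons, columns=["patient_id", "reason"])
    return cohort.loc[keep].copy(), log


def phenotype_frequency_table(
    cohort: pd.DataFrame, basis: str = "gPT", stratum: str | None = None
) -> pd.DataFrame:
    """Counts and percentages per metabolizer category on the chosen basis.

    ``basis`` is ``"gPT"`` or ``"pPT"``; an optional ``stratum`` column (e.g.
    ``sex`` or ``main_drug``) yields one row block per stratum level.
    Percentages are within-stratum and sum to 100 up to rounding.
    """
    if len(cohort) == 0:
        raise ValueError("cannot tabulate an empty cohort")
    if basis not in cohort.columns:
        raise ValueError(f"basis column {basis!r} not present in cohort")

    def _one(df: pd.DataFrame, label) -> pd.DataFrame:
        counts = df[basis].value_counts()
        cats = [c for c in PHENOTYPE_ORDER if c in counts.index]
        n = len(df)
        rows = [
            {
                "stratum": label,
                "category": c,
                "count": int(counts[c]),
                "pct": round(100.0 * counts[c] / n, 1),
            }
            for c in cats
        ]
        return pd.DataFrame(rows)

    if stratum is None:
        table = _one(cohort, "all")
    else:
        blocks = [
            _one(sub, level) for level, sub in cohort.groupby(stratum, observed=True)
        ]
        table = pd.concat(blocks, ignore_index=True)
    table.attrs["basis"] = basis
    return table


@dataclass(frozen=True)
class ConversionMetrics:
    """Cohort-level phenoconversion summary.

    ``pct_increase_PM`` and ``fold_PM`` are None when there were no
    genotype-predicted PMs to take as the baseline.
    """

    n: int
    n_converted: int
    pct_of_sample: float
    gPM_before: int
    pPM_after: int
    pct_increase_PM: float | None
    fold_PM: float | None


def conversion_metrics(cohort: pd.DataFrame) -> ConversionMetrics:
    """Phenoconversion counts and percentages for an annotated cohort.

    Percent of sample is reported to one decimal; percent increase in PM to
    the nearest integer.
    """
    for col in ("gPT", "pPT"):
        if col not in cohort.columns:
            raise ValueError(f"annotated cohort required: missing column {col!r}")
    n = len(cohort)
    if n == 0:
        raise ValueError("cannot compute conversion metrics for an empty cohort")
    converted = int((cohort["gPT"] != cohort["pPT"]).sum())
    g_pm = int((cohort["gPT"] == "PM").sum())
    p_pm = int((cohort["pPT"] == "PM").sum())
    if g_pm > 0:
        pct_increase = float(round(100.0 * (p_pm - g_pm) / g_pm))
        fold = p_pm / g_pm
    else:
        pct_increase = None
        fold = None
    return ConversionMetrics(
        n=n,
        n_converted=converted,
        pct_of_sample=round(100.0 * converted / n, 1),
        gPM_before=g_pm,
        pPM_after=p_pm,
        pct_increase_PM=pct_increase,
        fold_PM=fold,
    )


def stratified_conversion(cohort: pd.DataFrame, stratum: str = "sex") -> dict:
    """Per-stratum conversion rates, pPM shares, and the between-level risk ratio.

    Returns a dict with a ``levels`` table (one row per stratum level with
    ``n``, ``n_converted``, ``rate_pct``, ``pPM_share_pct``) and, for the
    pair of levels with highest/lowest conversion rate, ``risk_ratio``
    (higher / lower, one decimal) plus which levels those are.
    """
    if stratum not in cohort.columns:
        raise ValueError(f"stratum column {stratum!r} not present")
    rows = []
    for level, sub in cohort.groupby(stratum, observed=True):
        size = len(sub)
        if size == 0:
            raise ValueError(f"stratum level {level!r} is empty")
        conv = int((sub["gPT"] != sub["pPT"]).sum())
        rows.append(
            {
                "level": level,
                "n": size,
                "n_converted": conv,
                "rate_pct": round(100.0 * conv / size, 1),
                "pPM_share_pct": round(100.0 * (sub["pPT"] == "PM").sum() / size, 1),
            }
        )
    if len(rows) < 2:
        raise ValueError(f"stratum {stratum!r} must have at least two non-empty levels")
    levels = pd.DataFrame(rows)
    hi = levels.loc[levels["rate_pct"].idxmax()]
    lo = levels.loc[levels["rate_pct"].idxmin()]
    if lo["n_converted"] == 0:
        ratio = None
    else:
        ratio = round(
            (hi["n_converted"] / hi["n"]) / (lo["n_converted"] / lo["n"]), 1
        )
    return {
        "levels": levels,
        "risk_ratio": ratio,
        "higher_level": hi["level"],
        "lower_level": lo["level"],
    }


@dataclass(frozen=True)
class TestResult:
    """A single hypothesis-test outcome with its Bonferroni-adjusted p-value."""

    statistic: float
    p_value: float
    p_adjusted: float
    method: str
    groups: tuple = ()


def _kw_statistic(groups: Sequence[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H for pre-split samples."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - (counts**3 - counts).sum() / (n**3 - n)
    if tie == 0:
        return 0.0
    return h / tie


def kruskal_wallis(
    groups: Sequence[Iterable[float]],
    family_size: int = 1,
    p_method: str = "asymptotic",
) -> TestResult:
    """Kruskal-Wallis rank-sum test across two or more samples.

    ``p_method="asymptotic"`` uses the chi-square reference with k-1 degrees
    of freedom; ``"exact"`` enumerates every assignment of the pooled values
    to groups (feasible only for small samples) and reports the proportion
    with H at least as large as observed.
    """
    arrays = [np.asarray(list(g), dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("kruskal_wallis requires at least two groups")
    for g in arrays:
        if len(g) == 0:
            raise ValueError("each group must be non-empty")
    h = _kw_statistic(arrays)
    if p_method == "asymptotic":
        p = float(stats.chi2.sf(h, df=len(arrays) - 1))
        if h == 0.0:
            p = 1.0
    elif p_method == "exact":
        p = _kw_exact_p(arrays, h)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return TestResult(
        statistic=float(h),
        p_value=p,
        p_adjusted=min(1.0, family_size * p),
        method=f"kruskal-wallis ({p_method})",
        groups=tuple(range(len(arrays))),
    )


def _kw_exact_p(arrays: Sequence[np.ndarray], h_obs: float) -> float:
    """Exhaustive-permutation p-value: enumerate all splits of the pooled data."""
    pooled = np.concatenate(arrays)
    sizes = [len(g) for g in arrays]
    n = len(pooled)
    if n > 12:
        raise ValueError("exact Kruskal-Wallis enumeration is limited to n <= 12")
    idx = list(range(n))
    count = 0
    total = 0
    for assignment in _assignments(idx, sizes):
        split = [pooled[list(part)] for part in assignment]
        total += 1
        if _kw_statistic(split) >= h_obs - 1e-12:
            count += 1
    return count / total


def _assignments(indices: list[int], sizes: list[int]):
    """Yield all ways to partition *indices* into ordered blocks of the given sizes."""
    if len(sizes) == 1:
        yield (tuple(indices),)
        return
    for first in itertools.combinations(indices, sizes[0]):
        rest = [i for i in indices if i not in set(first)]
        for tail in _assignments(rest, sizes[1:]):
            yield (first,) + tail


def dunn_posthoc(
    groups: Sequence[Iterable[float]], adjustment: str = "bonferroni"
) -> list[TestResult]:
    """Dunn's pairwise z-tests on pooled tied ranks after a Kruskal-Wallis test.

    Each pair's p-value is two-sided normal; Bonferroni family size is the
    number of pairs, k(k-1)/2.
    """
    arrays = [np.asarray(list(g), dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("dunn_posthoc requires at least two groups")
    for g in arrays:
        if len(g) == 0:
            raise ValueError("each group must be non-empty")
    if adjustment not in ("bonferroni", "none"):
        raise ValueError(f"unsupported adjustment {adjustment!r}")
    pooled = np.concatenate(arrays)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    means = []
    start = 0
    for g in arrays:
        means.append(ranks[start : start + len(g)].mean())
        start += len(g)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1))
    var_core = n * (n + 1) / 12.0 - tie_term
    k = len(arrays)
    m = k * (k - 1) // 2
    family = m if adjustment == "bonferroni" else 1
    results = []
    for i, j in itertools.combinations(range(k), 2):
        se = math.sqrt(var_core * (1.0 / len(arrays[i]) + 1.0 / len(arrays[j])))
        z = 0.0 if se == 0 else (means[i] - means[j]) / se
        p = float(2 * stats.norm.sf(abs(z)))
        results.append(
            TestResult(
                statistic=float(z),
                p_value=p,
                p_adjusted=min(1.0, family * p),
                method="dunn",
                groups=(i, j),
            )
        )
    return results


def categorical_association(
    table: Sequence[Sequence[int]] | np.ndarray,
    family_size: int = 1,
    n_resamples: int = 20000,
    seed: int = 0,
) -> TestResult:
    """Association test for a contingency table, choosing the method the way
    an analyst would: Fisher's exact test when any expected cell is below 5
    (2x2 exactly via the hypergeometric; larger tables by Monte-Carlo over
    fixed-margin tables), otherwise Pearson's chi-square.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("contingency table must be two-dimensional")
    if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
        raise ValueError("contingency table cells must be non-negative integers")
    obs = obs.astype(int)
    row_m = obs.sum(axis=1)
    col_m = obs.sum(axis=0)
    if (row_m == 0).any() or (col_m == 0).any():
        raise ValueError("degenerate contingency table: zero row or column margin")
    expected = np.outer(row_m, col_m) / obs.sum()
    if (expected < 5).any():
        if obs.shape == (2, 2):
            stat, p = stats.fisher_exact(obs)
            method = "fisher_exact"
        else:
            stat, p = _monte_carlo_chi2(obs, n_resamples=n_resamples, seed=seed)
            method = "chi2_monte_carlo"
    else:
        stat, p, _, _ = stats.chi2_contingency(obs, correction=False)
        method = "pearson_chi2"
    p = float(p)
    return TestResult(
        statistic=float(stat),
        p_value=p,
        p_adjusted=min(1.0, family_size * p),
        method=method,
    )


def _monte_carlo_chi2(obs: np.ndarray, n_resamples: int, seed: int) -> tuple[float, float]:
    """Chi-square statistic with a fixed-margin Monte-Carlo p-value."""
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    rng = np.random.default_rng(seed)
    dist = stats.random_table(obs.sum(axis=1), obs.sum(axis=0))
    samples = dist.rvs(n_resamples, random_state=rng)
    sims = ((samples - expected) ** 2 / expected).sum(axis=(-2, -1))
    # add-one correction keeps the Monte-Carlo p valid
    p = (np.sum(sims >= stat - 1e-12) + 1) / (n_resamples + 1)
    return stat, float(p)


def bonferroni_adjust(p_values: Iterable[float], family_size: int | None = None) -> list[float]:
    """Bonferroni correction: min(1, m * p) elementwise; m defaults to len(p)."""
    ps = list(p_values)
    for p in ps:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {p}")
    m = len(ps) if family_size is None else family_size
    if m < 1:
        raise ValueError("family size must be >= 1")
    return [min(1.0, m * p) for p in ps]
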