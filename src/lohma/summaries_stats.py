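"""Per-environment aggregation and significance testing.

Aggregates per-line LOH summaries into an environment table (mean/median
LOH count, % genome covered, tract sizes, % SNPs fixed, per-generation
rate, and the size-class / extent / mechanism proportions) and runs the
study's tests: two-sided Wilcoxon rank-sum for continuous per-line
metrics against the control environment and chi-square for categorical
proportions, both with Bonferroni correction over the family of
environment-vs-control comparisons for one metric.

Exact rank-sum p-values are used for group sizes up to 15 (no ties),
normal approximation with continuity correction otherwise.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .loh_detection import (
    Extent,
    GENOME_SIZE_BP,
    LineSummary,
    LohTract,
    Mechanism,
    SizeClass,
)

EXACT_MAX_N = 15

STAR_LEVELS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    """Figure-legend stars: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    if np.isnan(p):
        return "NA"
    for cut, stars in STAR_LEVELS:
        if p < cut:
            return stars
    return "ns"


@dataclass
class EnvironmentSummary:
    """Environment-level twin of the per-line summaries."""

    environment: str
    n_lines: int
    mean_loh_count: float
    median_loh_count: float
    mean_pct_genome_covered: float
    median_pct_genome_covered: float
    mean_tract_size: float  # bp, pooled over tracts
    median_tract_size: float
    mean_pct_snps_fixed: float
    mean_loh_rate: float
    size_class_proportions: dict[str, float]
    extent_proportions: dict[str, float]
    mechanism_proportions: dict[str, float]


def _proportions(counter: Counter, keys: list[str]) -> dict[str, float]:
    total = sum(counter[k] for k in keys)
    if total == 0:
        return {k: float("nan") for k in keys}
    return {k: counter[k] / total for k in keys}


def environment_summary(
    environment: str,
    line_summaries: list[LineSummary],
    tracts: list[LohTract],
) -> EnvironmentSummary:
    """Aggregate per-line summaries and pooled tract classifications."""
    if not line_summaries:
        raise ValueError("need at least one line")
    counts = np.array([s.n_tracts for s in line_summaries], dtype=float)
    cov = np.array([s.pct_genome_covered for s in line_summaries])
    fixed = np.array([s.pct_snps_fixed for s in line_summaries])
    rates = np.array([s.loh_rate_per_generation for s in line_summaries])
    sizes = np.array([t.size for t in tracts], dtype=float)

    size_counter: Counter = Counter(
        t.size_class.value for t in tracts if t.size_class is not None
    )
    extent_counter: Counter = Counter(
        t.extent.value for t in tracts if t.extent is not None
    )
    mech_counter: Counter = Counter(
        t.mechanism.value
        for t in tracts
        if t.mechanism is not None and t.mechanism != Mechanism.UNCLASSIFIED
    )
    return EnvironmentSummary(
        environment=environment,
        n_lines=len(line_summaries),
        mean_loh_count=float(counts.mean()),
        median_loh_count=float(np.median(counts)),
        mean_pct_genome_covered=float(cov.mean()),
        median_pct_genome_covered=float(np.median(cov)),
        mean_tract_size=float(sizes.mean()) if sizes.size else 0.0,
        median_tract_size=float(np.median(sizes)) if sizes.size else 0.0,
        mean_pct_snps_fixed=float(fixed.mean()),
        mean_loh_rate=float(rates.mean()),
        size_class_proportions=_proportions(size_counter, [c.value for c in SizeClass]),
        extent_proportions=_proportions(extent_counter, [e.value for e in Extent]),
        mechanism_proportions=_proportions(
            mech_counter, [Mechanism.RECOMBINATION.value, Mechanism.DELETION.value]
        ),
    )


# ---------------------------------------------------------------------------
# Significance tests
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    environment: str
    statistic: float
    p_raw: float
    p_adjusted: float
    stars: str


def rank_sum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) statistic and p-value.

    Exact distribution for n <= 15 per group without ties; normal
    approximation with continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    exact = (
        len(x) <= EXACT_MAX_N
        and len(y) <= EXACT_MAX_N
        and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    )
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def compare_to_control(
    values_by_env: dict[str, np.ndarray], control: str = "YPD"
) -> dict[str, ComparisonResult]:
    """Wilcoxon rank-sum of every environment against the control, Bonferroni
    over the number of environment-vs-control comparisons.

    Groups with fewer than two values yield NaN p-values with a warning-
    level star label of "NA".
    """
    if control not in values_by_env:
        raise KeyError(f"control environment {control!r} missing")
    envs = [e for e in values_by_env if e != control]
    if not envs:
        raise ValueError("need at least one non-control environment")
    m = len(envs)
    ctrl = np.asarray(values_by_env[control], dtype=float)
    out: dict[str, ComparisonResult] = {}
    for env in envs:
        vals = np.asarray(values_by_env[env], dtype=float)
        if len(vals) < 2 or len(ctrl) < 2:
            out[env] = ComparisonResult(env, float("nan"), float("nan"), float("nan"), "NA")
            continue
        stat, p = rank_sum_p(vals, ctrl)
        p_adj = min(1.0, p * m)
        out[env] = ComparisonResult(env, stat, p, p_adj, significance_stars(p_adj))
    return out


def compare_proportions(
    counts_by_env: dict[str, dict[str, int] | list[int]], control: str = "YPD"
) -> dict[str, ComparisonResult]:
    """Chi-square test of each environment's category counts vs the control.

    Pearson chi-square without continuity correction on the 2 x k table of
    (environment counts, control counts); Bonferroni over the comparisons.
    Degenerate tables (all-zero rows or a single non-empty category) give
    NaN.
    """
    if control not in counts_by_env:
        raise KeyError(f"control environment {control!r} missing")

    def _vec(v) -> np.ndarray:
        if isinstance(v, dict):
            return np.array(list(v.values()), dtype=float)
        return np.asarray(v, dtype=float)

    envs = [e for e in counts_by_env if e != control]
    if not envs:
        raise ValueError("need at least one non-control environment")
    m = len(envs)
    ctrl = _vec(counts_by_env[control])
    out: dict[str, ComparisonResult] = {}
    for env in envs:
        vals = _vec(counts_by_env[env])
        table = np.vstack([vals, ctrl])
        col_ok = table.sum(axis=0) > 0
        table = table[:, col_ok]
        if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
            out[env] = ComparisonResult(env, float("nan"), float("nan"), float("nan"), "NA")
            continue
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        p_adj = min(1.0, p * m)
        out[env] = ComparisonResult(env, float(chi2), float(p), p_adj, significance_stars(p_adj))
    return out
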