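"""Nonparametric statistical battery for method comparison.

Pose-error distributions are heavily right-skewed, so the battery is
nonparametric throughout: a Shapiro-Wilk normality gate (consulted, but
the pipeline defaults to rank tests regardless), the Wilcoxon
signed-rank test for paired camera-view comparisons, the Mann-Whitney U
test for unpaired trial-type comparisons, Cliff's delta as the effect
size, Pearson correlation for the agreement scatter, a nonparametric
Bland-Altman summary (median bias and 2.5/97.5 percentile limits of
agreement), and the visibility-bin / temporal-phase aggregations.

Raw p-values are reported without multiple-testing correction; the
report metadata says so.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

__all__ = [
    "StatsConfig",
    "TestResult",
    "normality_gate",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "cliffs_delta",
    "pearson_r",
    "bland_altman_nonparametric",
    "bin_by_visibility",
    "phase_aggregate",
    "PHASE_LABELS",
]

PHASE_LABELS = {0: "pre-impact", 20: "impact"}  # >= 40 ms -> post-impact


def phase_of(t_ms: float) -> str:
    """Temporal phase of a 20 ms-grid time step."""
    if t_ms in PHASE_LABELS:
        return PHASE_LABELS[t_ms]
    return "post-impact"


@dataclass(frozen=True)
class StatsConfig:
    """Significance level, visibility-bin edges, and phase time points."""

    alpha: float = 0.05
    visibility_bins: tuple = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    phase_times_ms: tuple = (0, 20, 40, 60, 80, 100)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        edges = np.asarray(self.visibility_bins, float)
        if np.any(np.diff(edges) <= 0) or edges[0] != 0.0 or edges[-1] != 1.0:
            raise ValueError("visibility bin edges must ascend and cover [0, 1]")


class TestResult(NamedTuple):
    statistic: float
    p_value: float
    n: int
    effect_size: float | None
    method: str
    degenerate: bool = False


def normality_gate(sample: Sequence[float], alpha: float = 0.05) -> tuple[float, bool]:
    """Shapiro-Wilk normality check.

    Returns ``(p_value, use_nonparametric)``; the flag is True when the
    sample deviates from normality at ``alpha``.  A constant sample is
    degenerate and flagged nonparametric with a warning.
    """
    sample = np.asarray(sample, dtype=float)
    if len(sample) < 3:
        raise ValueError("normality check needs at least 3 observations")
    if np.ptp(sample) == 0:
        warnings.warn("constant sample: normality undefined; flagged nonparametric")
        return 0.0, True
    with warnings.catch_warnings():
        # Shapiro-Wilk p-values are approximate above n=5000; fine for a gate
        warnings.simplefilter("ignore")
        _, p = sp_stats.shapiro(sample)
    return float(p), bool(p < alpha)


def wilcoxon_signed_rank(paired_a: Sequence[float], paired_b: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped, ties mid-ranked; the null distribution
    is exact for n <= 25 zero-free differences and a tie-corrected
    normal approximation above.  The effect size reported is the median
    paired difference (a - b), the quantity of applied interest.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diffs = a - b
    nonzero = diffs[diffs != 0]
    if len(nonzero) == 0:
        return TestResult(0.0, 1.0, 0, 0.0, "wilcoxon-signed-rank", degenerate=True)
    if len(nonzero) < 5:
        raise ValueError("need at least 5 nonzero differences for a meaningful test")
    has_ties = len(np.unique(np.abs(nonzero))) < len(nonzero)
    method = "exact" if (len(nonzero) <= 25 and not has_ties) else "approx"
    res = sp_stats.wilcoxon(nonzero, alternative="two-sided", method=method, correction=False)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=int(len(nonzero)),
        effect_size=float(np.median(diffs)),
        method="wilcoxon-signed-rank",
    )


def mann_whitney_u(sample_a: Sequence[float], sample_b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test for independent samples.

    Ties are mid-ranked; the exact null distribution is used when
    ``n_a * n_b <= 400`` and the samples are tie-free, a tie-corrected
    normal approximation otherwise.  The statistic reported is U_a, the
    number of (a, b) pairs with a > b plus half the ties.  Cliff's delta
    accompanies it as the effect size.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each sample needs at least 3 observations")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) * len(b) <= 400 and not has_ties) else "asymptotic"
    res = sp_stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=int(len(a) + len(b)),
        effect_size=cliffs_delta(a, b),
        method="mann-whitney-u",
    )


def cliffs_delta(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """Cliff's delta: (#{a > b} - #{a < b}) / (n_a n_b), computed exactly."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("samples must be non-empty")
    diff = a[:, None] - b[None, :]
    return float((np.sum(diff > 0) - np.sum(diff < 0)) / (len(a) * len(b)))


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need equal-length samples of at least 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(sp_stats.pearsonr(x, y).statistic)


def bland_altman_nonparametric(
    predicted: Sequence[float], reference: Sequence[float]
) -> tuple[float, float, float]:
    """Median bias and nonparametric 95% limits of agreement.

    Differences are predicted - reference; the limits are the 2.5th and
    97.5th percentiles under the linear-interpolation percentile
    definition (numpy's default), which is the documented rule here.
    Fewer than 40 pairs makes the tail percentiles unstable; a warning
    is emitted rather than an error.
    """
    p = np.asarray(predicted, dtype=float)
    r = np.asarray(reference, dtype=float)
    if p.shape != r.shape:
        raise ValueError("samples must have equal length")
    if len(p) < 40:
        warnings.warn("fewer than 40 pairs: 2.5/97.5 percentile limits are unstable")
    d = p - r
    return (
        float(np.median(d)),
        float(np.percentile(d, 2.5)),
        float(np.percentile(d, 97.5)),
    )


def bin_by_visibility(
    errors: Sequence[float],
    visibility: Sequence[float],
    edges: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
) -> pd.DataFrame:
    """Mean and standard error of an error series per visibility bin.

    Bins are half-open [e_k, e_{k+1}) with the final bin closed so a
    ratio of exactly 1 is counted.  NaN visibility (no face box) is
    excluded; empty bins appear with n = 0 and NaN mean.  Bin counts
    always sum to the number of non-missing frames.
    """
    err = np.asarray(errors, dtype=float)
    vis = np.asarray(visibility, dtype=float)
    if err.shape != vis.shape:
        raise ValueError("errors and visibility must have equal length")
    edges = np.asarray(edges, dtype=float)
    ok = ~np.isnan(vis) & ~np.isnan(err)
    err, vis = err[ok], vis[ok]
    idx = np.digitize(vis, edges, right=False) - 1
    idx[vis == edges[-1]] = len(edges) - 2  # close the last bin
    rows = []
    for k in range(len(edges) - 1):
        sel = err[idx == k]
        n = len(sel)
        rows.append(
            {
                "bin_low": edges[k],
                "bin_high": edges[k + 1],
                "n": n,
                "mean": float(np.mean(sel)) if n else np.nan,
                "se": float(np.std(sel, ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def phase_aggregate(
    times_ms: Sequence[float],
    values: Sequence[float],
    config: StatsConfig | None = None,
) -> pd.DataFrame:
    """Mean and standard error per 20 ms time step, with phase labels.

    Times must sit on the configured 20 ms grid (off-grid times are an
    error, not silently rounded).  Values may be GE, IGE (indexed by the
    later frame) or visibility.
    """
    config = config or StatsConfig()
    t = np.asarray(times_ms, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape:
        raise ValueError("times and values must have equal length")
    grid = np.asarray(config.phase_times_ms, dtype=float)
    on_grid = np.isclose(t[:, None], grid[None, :], atol=1e-6).any(axis=1)
    if not on_grid.all():
        raise ValueError(f"times off the 20 ms grid: {np.unique(t[~on_grid])}")
    rows = []
    for step in grid:
        sel = v[np.isclose(t, step) & ~np.isnan(v)]
        n = len(sel)
        rows.append(
            {
                "t_ms": step,
                "phase": phase_of(step),
                "n": n,
                "mean": float(np.mean(sel)) if n else np.nan,
                "se": float(np.std(sel, ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)
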