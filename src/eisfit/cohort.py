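"""Cross-electrode cohort summaries and comparisons.

Disposable screen-printed electrodes show large device-to-device spread in
the fitted charge-transfer resistance; these helpers provide the
box-whisker five-number summaries, Welch mean comparisons and
age-stability regressions used to characterise that spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "RctCohort",
    "BoxWhiskerSummary",
    "AgeTrend",
    "box_whisker_summary",
    "welch_t_test",
    "age_trend",
    "kde_export",
]


@dataclass
class RctCohort:
    """A labelled collection of fitted R_ct values (Ω), one per electrode.

    ``ages`` optionally records the age (days) of the conjugate solution
    each electrode was modified with.
    """

    label: str
    values: np.ndarray
    ages: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("cohort must contain at least one value")
        if np.any(self.values <= 0):
            raise ValueError("R_ct values must be > 0")
        if self.ages is not None:
            self.ages = np.asarray(self.ages, dtype=float)
            if self.ages.shape != self.values.shape:
                raise ValueError("ages must match values in length")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class BoxWhiskerSummary:
    p5: float
    p25: float
    median: float
    p75: float
    p95: float
    mean: float


@dataclass(frozen=True)
class AgeTrend:
    slope: float  # Ω / day
    correlation: float
    stable: bool


def box_whisker_summary(cohort: RctCohort) -> BoxWhiskerSummary:
    """5th/25th/50th/75th/95th percentiles plus the arithmetic mean.

    Percentiles use linear interpolation between closest ranks (numpy's
    default, the common "type 7" rule).
    """
    v = cohort.values
    p5, p25, p50, p75, p95 = np.percentile(v, [5, 25, 50, 75, 95])
    return BoxWhiskerSummary(
        p5=float(p5),
        p25=float(p25),
        median=float(p50),
        p75=float(p75),
        p95=float(p95),
        mean=float(v.mean()),
    )


def welch_t_test(cohort_a: RctCohort, cohort_b: RctCohort) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test, two-sided.

    Returns ``(t, degrees_of_freedom, p_value)`` with Welch-Satterthwaite
    degrees of freedom.
    """
    if len(cohort_a) < 2 or len(cohort_b) < 2:
        raise ValueError("each cohort needs at least 2 values")
    result = stats.ttest_ind(cohort_a.values, cohort_b.values, equal_var=False)
    return float(result.statistic), float(result.df), float(result.pvalue)


def age_trend(cohort: RctCohort, stability_threshold: float = 0.3) -> AgeTrend:
    """OLS slope of R_ct vs conjugate age plus the Pearson correlation.

    The cohort is flagged "stable" when |correlation| is below the
    threshold, operationalizing "no correlation over time".  A constant
    R_ct gives slope 0 and correlation defined as 0.
    """
    if cohort.ages is None:
        raise ValueError("cohort has no age information")
    if len(cohort) < 3:
        raise ValueError("at least 3 aged points are required")
    ages = cohort.ages
    values = cohort.values
    if np.ptp(ages) == 0:
        raise ValueError("all ages equal: slope undefined")
    if np.ptp(values) == 0:
        return AgeTrend(slope=0.0, correlation=0.0, stable=True)
    fit = stats.linregress(ages, values)
    corr = float(fit.rvalue)
    return AgeTrend(
        slope=float(fit.slope), correlation=corr, stable=abs(corr) < stability_threshold
    )


def kde_export(
    cohort: RctCohort, grid_size: int = 256
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sorted values plus a Gaussian-kernel density on a fixed grid.

    Bandwidth by Silverman's rule; purely a plotting-parity export for
    distribution comparisons.  Returns ``(sorted_values, grid, density)``.
    """
    v = np.sort(cohort.values)
    if v.size < 2 or np.ptp(v) == 0:
        grid = np.linspace(v[0] * 0.9, v[0] * 1.1, grid_size)
        density = np.zeros(grid_size)
        return v, grid, density
    kde = stats.gaussian_kde(v, bw_method="silverman")
    pad = 0.1 * np.ptp(v)
    grid = np.linspace(v[0] - pad, v[-1] + pad, grid_size)
    return v, grid, kde(grid)
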