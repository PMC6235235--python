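"""Cohort-level descriptive statistics of per-fish neutrophil records.

Covers the quantities a neutrophil abundance study reports: group mean ±
sample SD and the SD/mean variability ratio, the OLS regression of total
fluorescence intensity on cell count (weak correlation means bulk
brightness is a poor proxy for cell number), the pooled anterior-posterior
position histogram, control-vs-treated fold change with propagated and
bootstrap uncertainty, and the 2D-projection / 3D count ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .grids import DataError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class FishRecord:
    """One fish: neutrophil count plus optional intensity, group, positions."""

    fish_id: str
    count: float
    total_intensity: float | None = None
    group: str | None = None
    ap_positions: list[float] | None = None

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValidationError(f"count must be >= 0, got {self.count}")
        if self.total_intensity is not None and self.total_intensity < 0:
            raise ValidationError("total_intensity must be >= 0")


@dataclass
class GroupSummary:
    """n, mean ± sample SD (n−1 denominator), and SD/mean.

    With a single fish the SD is undefined: ``sd_defined`` is False and
    sd / sd_over_mean are NaN rather than zero.
    """

    n: int
    mean: float
    sd: float
    sd_over_mean: float
    sd_defined: bool = True


@dataclass
class RegressionResult:
    """OLS fit of total intensity on count."""

    slope: float
    intercept: float
    r_squared: float
    n: int


@dataclass
class APHistogram:
    """Pooled anterior-posterior histogram; half-open bins [edge, edge+width)."""

    bin_edges: np.ndarray
    counts: np.ndarray


@dataclass
class GroupComparison:
    """Control vs treated group summaries and mean fold change.

    ``fold_se`` is the first-order propagation of the two standard errors of
    the mean; (``fold_ci_low``, ``fold_ci_high``) is a seeded percentile
    bootstrap interval as a cross-check.
    """

    control: GroupSummary
    treated: GroupSummary
    fold: float
    fold_se: float
    fold_ci_low: float
    fold_ci_high: float
    n_bootstrap: int


def summarize_counts(records: list[FishRecord]) -> GroupSummary:
    """Sample mean, sample SD and SD/mean of the per-fish counts."""
    if not records:
        raise ValidationError("no records to summarize")
    counts = np.asarray([r.count for r in records], dtype=np.float64)
    n = counts.size
    mean = float(counts.mean())
    if n == 1:
        return GroupSummary(n=1, mean=mean, sd=math.nan, sd_over_mean=math.nan, sd_defined=False)
    sd = float(counts.std(ddof=1))
    som = sd / mean if mean != 0 else math.nan
    return GroupSummary(n=n, mean=mean, sd=sd, sd_over_mean=som)


def regress_intensity_on_count(records: list[FishRecord]) -> RegressionResult:
    """OLS (with intercept) of per-fish total intensity on neutrophil count.

    R² = 1 − SS_res/SS_tot quantifies how well bulk fluorescence predicts
    the actual cell number.
    """
    pairs = [(r.count, r.total_intensity) for r in records if r.total_intensity is not None]
    if len(pairs) < 3:
        raise ValidationError("need at least 3 records with both count and intensity")
    x = np.asarray([p[0] for p in pairs], dtype=np.float64)
    y = np.asarray([p[1] for p in pairs], dtype=np.float64)
    if np.ptp(x) == 0:
        raise DataError("count has zero variance: regression undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        n=len(pairs),
    )


def ap_histogram(records: list[FishRecord], bin_width: float = 50.0, extent: float | None = None) -> APHistogram:
    """Histogram of anterior-posterior cell positions pooled over all fish.

    Bins are half-open [edge, edge+width) starting at 0; the range covers
    ``extent`` μm if given, else the largest observed position.  Every
    supplied position lands in exactly one bin.
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    positions = np.concatenate(
        [np.asarray(r.ap_positions, dtype=np.float64) for r in records if r.ap_positions]
        or [np.empty(0)]
    )
    if positions.size and positions.min() < 0:
        raise ValidationError("anterior-posterior positions must be >= 0")
    top = extent if extent is not None else (positions.max() if positions.size else bin_width)
    n_bins = max(1, int(np.floor(top / bin_width)) + 1)
    idx = np.floor(positions / bin_width).astype(int)
    if positions.size and idx.max() >= n_bins:
        n_bins = idx.max() + 1
    counts = np.bincount(idx, minlength=n_bins) if positions.size else np.zeros(n_bins, dtype=int)
    edges = np.arange(n_bins + 1) * bin_width
    return APHistogram(bin_edges=edges, counts=counts)


def compare_groups(
    control: list[FishRecord],
    treated: list[FishRecord],
    n_bootstrap: int = 10_000,
    seed: int = 0,
) -> GroupComparison:
    """Fold change of mean count, treated / control, with uncertainty.

    First-order propagation: SE(fold) = fold·√((SEM_c/mean_c)² + (SEM_t/mean_t)²);
    a seeded percentile bootstrap (resampling fish within each group)
    provides a distribution-free cross-check.
    """
    if len(control) < 2 or len(treated) < 2:
        raise ValidationError("both groups need at least 2 fish")
    cs = summarize_counts(control)
    ts = summarize_counts(treated)
    if cs.mean == 0:
        raise DataError("control mean is zero: fold change undefined")
    fold = ts.mean / cs.mean
    sem_c = cs.sd / math.sqrt(cs.n)
    sem_t = ts.sd / math.sqrt(ts.n)
    fold_se = fold * math.sqrt((sem_c / cs.mean) ** 2 + (sem_t / ts.mean) ** 2)
    rng = np.random.default_rng(seed)
    c = np.asarray([r.count for r in control], dtype=np.float64)
    t = np.asarray([r.count for r in treated], dtype=np.float64)
    cm = rng.choice(c, size=(n_bootstrap, c.size), replace=True).mean(axis=1)
    tm = rng.choice(t, size=(n_bootstrap, t.size), replace=True).mean(axis=1)
    valid = cm != 0
    folds = tm[valid] / cm[valid]
    lo, hi = np.percentile(folds, [2.5, 97.5])
    return GroupComparison(
        control=cs,
        treated=ts,
        fold=float(fold),
        fold_se=float(fold_se),
        fold_ci_low=float(lo),
        fold_ci_high=float(hi),
        n_bootstrap=n_bootstrap,
    )


def projection_ratio(pairs: list[tuple[float, float]]) -> tuple[float, float]:
    """Mean ± SEM of per-fish (2D projection count) / (3D count) ratios.

    Pairs with a zero 3D count are excluded (and logged): the ratio is
    undefined for them.
    """
    ratios = []
    for count2d, count3d in pairs:
        if count3d == 0:
            logger.warning("excluding pair with zero 3D count (2D count %s)", count2d)
            continue
        ratios.append(count2d / count3d)
    if not ratios:
        raise DataError("no pairs with a nonzero 3D count")
    r = np.asarray(ratios, dtype=np.float64)
    mean = float(r.mean())
    sem = float(r.std(ddof=1) / math.sqrt(r.size)) if r.size > 1 else math.nan
    return mean, sem
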