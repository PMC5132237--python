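"""Population-level lifespan statistics.

Everything that relates per-cell features to replicative lifespan at the
cohort level: Pearson screens across replicative ages, median splits with
Kaplan-Meier / log-rank survival comparison, rank-sum tests of time-to-age
distributions, fluorescence accounting (average intensity ~ concentration,
intensity x area ~ total amount), and conditional analyses on long-lived
subsets.

Feature extraction is decoupled from the statistics: a *feature map* is a
dict ``cell_id -> 1-D array`` of per-age values (index 0 = age 1).  The
factories below build the standard ones (fold increase, raw size, fitted
concentration) so every screen shares one code path.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats as sps

from .lifehistory import CellLifeHistory, LifeHistoryDataset
from .trajectories import SepResult, fit_cell, normalize_to_start, sep_for_cell

__all__ = [
    "AgeCorrelationSeries",
    "SurvivalCurve",
    "GroupSplit",
    "TestResult",
    "pearson_r",
    "feature_fold_increase",
    "feature_raw_size",
    "feature_fitted_size",
    "feature_concentration",
    "sep_ages_for",
    "per_age_lifespan_correlation",
    "conditional_age_correlation",
    "median_split_at_age",
    "km_estimate",
    "logrank_test",
    "ranksum_test",
    "percent_median_difference",
    "total_fluorescence",
    "concentration_size_relation",
]

DEFAULT_MIN_N = 10  # smallest per-age sample for which a correlation is reported


@dataclass
class AgeCorrelationSeries:
    """Per-age sample sizes and Pearson correlations of a feature with RLS."""

    ages: np.ndarray
    n: np.ndarray
    r: np.ndarray
    feature: str = ""

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.n = np.asarray(self.n, dtype=int)
        self.r = np.asarray(self.r, dtype=float)

    def at(self, age: int) -> float:
        idx = np.flatnonzero(self.ages == age)
        if idx.size == 0:
            raise KeyError(f"age {age} not in series")
        return float(self.r[idx[0]])


@dataclass
class SurvivalCurve:
    """Kaplan-Meier estimate of survival over replicative age."""

    ages: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        self.at_risk = np.asarray(self.at_risk, dtype=int)


@dataclass
class GroupSplit:
    """Median split of a cohort on a per-age feature value."""

    threshold: float
    split_age: int
    below_ids: list[str] = field(default_factory=list)
    above_ids: list[str] = field(default_factory=list)
    degenerate: bool = False


@dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


# ---------------------------------------------------------------------------
# Correlation primitives


def pearson_r(x, y) -> float:
    """Sample Pearson product-moment correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant series")
    return float(sps.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# Feature maps


def feature_fold_increase(dataset: LifeHistoryDataset, spar: float = 0.5) -> dict[str, np.ndarray]:
    """Spline-fitted size normalized to each cell's first-G1 size (fold, starts at 1)."""
    return {
        c.cell_id: normalize_to_start(fit_cell(c, spar=spar)).values for c in dataset.cells
    }


def feature_raw_size(dataset: LifeHistoryDataset) -> dict[str, np.ndarray]:
    """Unsmoothed cross-sectional area (μm²) per age."""
    return {c.cell_id: c.sizes.copy() for c in dataset.cells}


def feature_fitted_size(dataset: LifeHistoryDataset, spar: float = 0.5) -> dict[str, np.ndarray]:
    """Spline-fitted cross-sectional area (μm²) per age."""
    return {c.cell_id: fit_cell(c, spar=spar).values for c in dataset.cells}


def feature_concentration(dataset: LifeHistoryDataset, spar: float = 0.5) -> dict[str, np.ndarray]:
    """Spline-fitted average fluorescence intensity (AU ~ reporter concentration)."""
    if not dataset.has_fluor:
        raise ValueError("dataset has no fluorescence channel")
    return {
        c.cell_id: fit_cell(c, spar=spar, channel="fluor").values for c in dataset.cells
    }


def sep_ages_for(dataset: LifeHistoryDataset, epsilon: float | None = None) -> dict[str, int | None]:
    """SEP age per cell (None where no elbow is detectable)."""
    kw = {} if epsilon is None else {"epsilon": epsilon}
    return {c.cell_id: sep_for_cell(c, **kw).sep_age for c in dataset.cells}


# ---------------------------------------------------------------------------
# Per-age correlation screen


def per_age_lifespan_correlation(
    dataset: LifeHistoryDataset,
    feature: dict[str, np.ndarray],
    *,
    min_n: int = DEFAULT_MIN_N,
    exclude_post_sep: bool = False,
    sep_ages: dict[str, int | None] | None = None,
    feature_name: str = "",
) -> AgeCorrelationSeries:
    """Pearson correlation of a per-age feature with lifespan, age by age.

    At each replicative age ``a`` the feature value of every cell still
    alive at ``a`` (RLS >= a) is correlated with that cell's final RLS.
    With ``exclude_post_sep`` a cell contributes at age ``a`` only while
    still pre-SEP (its SEP age exceeds ``a``); cells without a detected
    SEP are pre-SEP throughout.  Ages with fewer than ``min_n`` cells, or
    with a degenerate (constant) feature or lifespan vector, are omitted.
    """
    if exclude_post_sep and sep_ages is None:
        sep_ages = sep_ages_for(dataset)
    max_age = int(dataset.lifespans().max())
    ages, ns, rs = [], [], []
    for a in range(1, max_age + 1):
        xs, ys = [], []
        for c in dataset.cells:
            if c.rls < a:
                continue
            if exclude_post_sep:
                s = sep_ages.get(c.cell_id)
                if s is not None and a >= s:
                    continue
            xs.append(feature[c.cell_id][a - 1])
            ys.append(c.rls)
        if len(xs) < max(min_n, 3):
            continue
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            continue
        ages.append(a)
        ns.append(len(xs))
        rs.append(pearson_r(xs, ys))
    return AgeCorrelationSeries(
        ages=np.array(ages), n=np.array(ns), r=np.array(rs), feature=feature_name
    )


def conditional_age_correlation(
    dataset: LifeHistoryDataset,
    feature: dict[str, np.ndarray],
    min_rls: int,
    *,
    min_n: int = DEFAULT_MIN_N,
    feature_name: str = "",
) -> AgeCorrelationSeries:
    """Per-age correlation restricted to cells with RLS >= ``min_rls``.

    Used to ask whether an association holds among long-lived cells once
    short-lived cells are removed from the cohort.
    """
    keep = [c for c in dataset.cells if c.rls >= min_rls]
    if not keep:
        raise ValueError(f"no cells with RLS >= {min_rls}")
    sub = LifeHistoryDataset(cells=keep, name=f"{dataset.name}|rls>={min_rls}", source=dataset.source)
    return per_age_lifespan_correlation(
        sub, feature, min_n=min_n, feature_name=feature_name or f"rls>={min_rls}"
    )


# ---------------------------------------------------------------------------
# Median split and survival


def median_split_at_age(
    dataset: LifeHistoryDataset, age: int, feature: dict[str, np.ndarray]
) -> GroupSplit:
    """Split the cells alive at ``age`` at the population median of a feature.

    Cells strictly below the median go to the *below* group, cells at or
    above it to the *above* group (ties side with "above"; with an odd
    number of cells the median cell itself therefore lands above, giving
    the familiar (n-1)/2 vs (n+1)/2 partition).  A constant feature yields
    a degenerate split, flagged rather than raised.
    """
    alive = [c for c in dataset.cells if c.rls >= age]
    if not alive:
        raise ValueError(f"no cell reaches age {age}")
    vals = np.array([feature[c.cell_id][age - 1] for c in alive])
    thr = float(np.median(vals))
    below = [c.cell_id for c, v in zip(alive, vals) if v < thr]
    above = [c.cell_id for c, v in zip(alive, vals) if v >= thr]
    return GroupSplit(
        threshold=thr,
        split_age=age,
        below_ids=below,
        above_ids=above,
        degenerate=(np.ptp(vals) == 0),
    )


def km_estimate(lifespans, death_observed=None) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate over replicative age.

    The median is the smallest age at which survival drops to 0.5 or
    below; with no censoring this is the lower sample median of the
    lifespans.
    """
    t = np.asarray(lifespans, dtype=float)
    if t.size == 0:
        raise ValueError("need at least one observation")
    e = np.ones_like(t, dtype=bool) if death_observed is None else np.asarray(death_observed, dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    ages = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = np.array([kmf.event_table.loc[a, "at_risk"] for a in ages], dtype=int)
    below = np.flatnonzero(surv <= 0.5)
    median = float(ages[below[0]]) if below.size else float("inf")
    return SurvivalCurve(ages=ages, survival=surv, at_risk=at_risk, median=median)


def logrank_test(
    lifespans_a, lifespans_b, events_a=None, events_b=None
) -> TestResult:
    """Two-group log-rank test (1-df chi-square, two-sided p)."""
    ta = np.asarray(lifespans_a, dtype=float)
    tb = np.asarray(lifespans_b, dtype=float)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    ea = np.ones_like(ta, dtype=bool) if events_a is None else np.asarray(events_a, dtype=bool)
    eb = np.ones_like(tb, dtype=bool) if events_b is None else np.asarray(events_b, dtype=bool)
    if ea.sum() == 0 or eb.sum() == 0:
        raise ValueError("log-rank needs at least one event in each group")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return TestResult(method="logrank", statistic=float(res.test_statistic), p_value=float(res.p_value))


# ---------------------------------------------------------------------------
# Rank-sum


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating rank assignments.

    Valid for untied samples; cost C(n+m, n) evaluations, intended for
    n+m <= 10.
    """
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n = len(x)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2.0
    mean_u = n * len(y) / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        u = ranks[list(combo)].sum() - n * (n + 1) / 2.0
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return u_obs, count / total


def ranksum_test(x, y, *, exact_max: int = 10) -> TestResult:
    """Two-sided Wilcoxon rank-sum / Mann-Whitney U test.

    Small untied samples (n+m <= ``exact_max``) use the exact permutation
    distribution; otherwise the normal approximation with tie correction
    (and continuity correction) is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    no_ties = len(np.unique(np.concatenate([x, y]))) == x.size + y.size
    if no_ties and x.size + y.size <= exact_max:
        u, p = _exact_ranksum_p(x, y)
        return TestResult(method="mannwhitney-exact", statistic=float(u), p_value=float(p))
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return TestResult(method="mannwhitney-normal", statistic=float(res.statistic), p_value=float(res.pvalue))


def percent_median_difference(median_a: float, median_b: float) -> int:
    """Percent difference of two medians, 100·(a − b)/b, rounded for reporting."""
    if median_b == 0:
        raise ZeroDivisionError("reference median is zero")
    return int(round(100.0 * (median_a - median_b) / median_b))


# ---------------------------------------------------------------------------
# Fluorescence accounting


def total_fluorescence(avg_intensity, area):
    """Total reporter amount: average intensity (AU) x cross-sectional area (μm²)."""
    avg_intensity = np.asarray(avg_intensity, dtype=float)
    area = np.asarray(area, dtype=float)
    if np.any(avg_intensity < 0) or np.any(area < 0):
        raise ValueError("intensity and area must be non-negative")
    out = avg_intensity * area
    return float(out) if out.ndim == 0 else out


def concentration_size_relation(
    dataset: LifeHistoryDataset, age: int, *, spar: float = 0.5, min_n: int = DEFAULT_MIN_N
) -> tuple[float, float, int]:
    """Cross-sectional concentration-vs-size relation at one age.

    Returns (Pearson r, OLS slope in AU per μm², n) across the cells alive
    at ``age``, using spline-fitted values of both channels.  Negative r
    means larger cells carry lower reporter concentration (dilution).
    """
    if not dataset.has_fluor:
        raise ValueError("dataset has no fluorescence channel")
    sizes = feature_fitted_size(dataset, spar=spar)
    concs = feature_concentration(dataset, spar=spar)
    xs, ys = [], []
    for c in dataset.cells:
        if c.rls >= age:
            xs.append(sizes[c.cell_id][age - 1])
            ys.append(concs[c.cell_id][age - 1])
    if len(xs) < max(min_n, 3):
        raise ValueError(f"only {len(xs)} cells alive at age {age} (need {min_n})")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("constant inputs: relation undefined")
    reg = sps.linregress(xs, ys)
    return float(reg.rvalue), float(reg.slope), len(xs)
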