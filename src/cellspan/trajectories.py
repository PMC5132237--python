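"""Per-cell trajectory smoothing and senescence-entry detection.

Longitudinal series (size or fluorescence against replicative age) are
smoothed with a penalized natural cubic smoothing spline using R-style
``spar`` semantics, then resampled at the original integer ages.  Division
durations (first differences of the G1 times) feed an elbow detector that
locates the Senescence Entry Point (SEP): the age at which the cell-cycle
duration profile bends upward, found as the point farthest above the chord
joining the first and last ages after rescaling both axes to the unit
square.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solveh_banded

from .lifehistory import CellLifeHistory

__all__ = [
    "FittedTrajectory",
    "DivisionProfile",
    "SepResult",
    "spar_to_lambda",
    "fit_smoothing_spline",
    "fit_cell",
    "normalize_to_start",
    "division_durations",
    "time_to_age",
    "detect_sep",
    "sep_for_cell",
    "split_pre_post_sep",
]

MIN_POINTS_FOR_FIT = 4
MIN_PROFILE_FOR_SEP = 3
SEP_EPSILON = 0.02  # scaled-unit tolerance: below this the profile is called linear


@dataclass
class FittedTrajectory:
    """Spline-smoothed values resampled at integer replicative ages.

    ``fitted`` is False when the series was too short to smooth (fewer than
    four points); the raw values are then passed through unchanged.
    """

    ages: np.ndarray
    values: np.ndarray
    spar: float
    fitted: bool = True

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.ages) != len(self.values):
            raise ValueError("ages and values must have equal length")
        if len(self.ages) > 1 and np.any(np.diff(self.ages) <= 0):
            raise ValueError("ages must be strictly increasing")


@dataclass
class DivisionProfile:
    """Hours per division at ages 1..K−1 (duration of the k-th cell cycle)."""

    ages: np.ndarray
    durations: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.durations = np.asarray(self.durations, dtype=float)
        if len(self.ages) != len(self.durations):
            raise ValueError("ages and durations must have equal length")
        if np.any(self.durations <= 0):
            raise ValueError("durations must be positive")


@dataclass
class SepResult:
    """Elbow location in a division profile, or none when the profile is linear."""

    sep_age: int | None
    chord_distance: float = 0.0


# ---------------------------------------------------------------------------
# Smoothing spline


def _penalty_bands(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Δ (second-difference) and W (overlap) matrices of the natural-spline
    roughness penalty on knots ``u``, in dense form.

    For a natural cubic spline f interpolating (u, f), the integrated
    squared second derivative equals fᵀ ΔᵀW⁻¹Δ f.
    """
    n = len(u)
    h = np.diff(u)
    delta = np.zeros((n - 2, n))
    w = np.zeros((n - 2, n - 2))
    for i in range(n - 2):
        delta[i, i] = 1.0 / h[i]
        delta[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        delta[i, i + 2] = 1.0 / h[i + 1]
        w[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < n - 2:
            w[i, i + 1] = w[i + 1, i] = h[i + 1] / 6.0
    return delta, w


def spar_to_lambda(ages: np.ndarray, spar: float) -> float:
    """Map an R-convention smoothing parameter to the roughness penalty λ.

    The abscissa is rescaled to [0, 1]; λ = r · 256^(3·spar − 1) where the
    trace ratio r = tr(I)/tr(K) balances the fidelity and roughness terms
    (K is the penalty matrix in the fitted-value basis).  spar = 0 is close
    to interpolation, spar = 1 close to a straight-line fit.
    """
    x = np.asarray(ages, dtype=float)
    u = (x - x[0]) / (x[-1] - x[0])
    delta, w = _penalty_bands(u)
    K = delta.T @ np.linalg.solve(w, delta)
    r = len(u) / np.trace(K)
    return float(r * 256.0 ** (3.0 * spar - 1.0))


def fit_smoothing_spline(ages, values, spar: float = 0.5) -> FittedTrajectory:
    """Penalized natural cubic smoothing spline evaluated at the input ages.

    Solves min Σ(y − f)² + λ ∫ f″(u)² du over all twice-differentiable f,
    whose minimizer is a natural cubic spline with knots at the data; the
    fitted values come from the Reinsch banded system
    (W + λ Δ Δᵀ) γ = Δ y,  f = y − λ Δᵀ γ.

    Series with fewer than four points are returned unfitted (raw values).
    """
    x = np.asarray(ages, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(x) != len(y):
        raise ValueError("ages and values must have equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite input to spline fit")
    if not 0.0 <= spar <= 1.0:
        raise ValueError("spar must lie in [0, 1]")
    if len(x) < MIN_POINTS_FOR_FIT:
        return FittedTrajectory(ages=x, values=y, spar=spar, fitted=False)

    lam = spar_to_lambda(x, spar)
    u = (x - x[0]) / (x[-1] - x[0])
    n = len(u)
    h = np.diff(u)
    # banded symmetric system (W + λ Δ Δᵀ), bandwidth 2, order n−2
    delta, w = _penalty_bands(u)
    A = w + lam * (delta @ delta.T)
    # pack into solveh_banded upper form
    ab = np.zeros((3, n - 2))
    ab[2, :] = np.diag(A)
    if n - 2 > 1:
        ab[1, 1:] = np.diag(A, 1)
    if n - 2 > 2:
        ab[0, 2:] = np.diag(A, 2)
    gamma = solveh_banded(ab, delta @ y)
    f = y - lam * (delta.T @ gamma)
    return FittedTrajectory(ages=x, values=f, spar=spar, fitted=True)


def fit_cell(cell: CellLifeHistory, spar: float = 0.5, channel: str = "sizes") -> FittedTrajectory:
    """Smooth one cell's size (or fluorescence) series against replicative age."""
    y = getattr(cell, "avg_fluor" if channel in ("fluor", "avg_fluor") else "sizes")
    if y is None:
        raise ValueError(f"cell {cell.cell_id!r} has no fluorescence channel")
    ages = np.arange(1, cell.rls + 1)
    return fit_smoothing_spline(ages, y, spar)


def normalize_to_start(fitted: FittedTrajectory) -> FittedTrajectory:
    """Fold-increase trajectory: values divided by the value at the first age.

    The first element becomes exactly 1; subsequent entries give the
    relative enlargement of the cell since its first G1.
    """
    v0 = fitted.values[0]
    if v0 <= 0:
        raise ValueError("cannot normalize: first fitted value is not positive")
    vals = fitted.values / v0
    vals[0] = 1.0
    return FittedTrajectory(ages=fitted.ages, values=vals, spar=fitted.spar, fitted=fitted.fitted)


# ---------------------------------------------------------------------------
# Division timing


def division_durations(cell: CellLifeHistory) -> DivisionProfile:
    """Duration of each cell cycle in hours: first differences of the G1 times."""
    if cell.rls < 2:
        raise ValueError(f"cell {cell.cell_id!r}: need at least 2 entries for durations")
    dur = np.diff(cell.times)
    return DivisionProfile(ages=np.arange(1, cell.rls), durations=dur)


def time_to_age(cell: CellLifeHistory, n: int) -> float:
    """Hours from the first observed G1 to the n-th recorded G1."""
    if not 1 <= n <= cell.rls:
        raise ValueError(f"cell {cell.cell_id!r}: age {n} outside 1..{cell.rls}")
    return float(cell.times[n - 1])


# ---------------------------------------------------------------------------
# Senescence Entry Point


def detect_sep(profile: DivisionProfile, epsilon: float = SEP_EPSILON) -> SepResult:
    """Locate the elbow of a division-duration profile.

    Both axes are rescaled to [0, 1] over the profile's range (hours and
    divisions are incommensurable).  The SEP is the interior point with the
    largest perpendicular distance from the chord joining the first and
    last points, on the convex side (durations *below* the chord): a
    senescent slowdown bends the profile upward at the end, so the early
    flat cycles sag under the chord and the point of maximum sag is the
    breakpoint where lengthening begins.  Ties break to the earliest age;
    profiles within ``epsilon`` of their chord (straight-line duration
    trends) have no SEP.
    """
    ages = profile.ages
    dur = profile.durations
    if len(ages) < MIN_PROFILE_FOR_SEP:
        raise ValueError("need at least 3 points to detect an elbow")
    x = (ages - ages[0]) / (ages[-1] - ages[0])
    rng = dur.max() - dur.min()
    if rng == 0:
        return SepResult(sep_age=None, chord_distance=0.0)
    y = (dur - dur.min()) / rng
    # chord from (x0,y0) to (x1,y1); cross-product distance, positive when
    # the point sags below the line (dx > 0 since x increases left to right)
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    norm = np.hypot(dx, dy)
    signed = (dy * (x - x[0]) - dx * (y - y[0])) / norm
    interior = slice(1, len(ages) - 1)
    d = signed[interior]
    if d.size == 0 or d.max() <= epsilon:
        return SepResult(sep_age=None, chord_distance=float(max(d.max(), 0.0)) if d.size else 0.0)
    idx = int(np.argmax(d))  # argmax returns the first maximum: earliest-age tie-break
    return SepResult(sep_age=int(ages[interior][idx]), chord_distance=float(d[idx]))


def sep_for_cell(cell: CellLifeHistory, epsilon: float = SEP_EPSILON) -> SepResult:
    """SEP of one cell from its raw division durations.

    Cells with fewer than four entries (profile shorter than three
    divisions) cannot support elbow detection and get no SEP.
    """
    if cell.rls < MIN_PROFILE_FOR_SEP + 1:
        return SepResult(sep_age=None, chord_distance=0.0)
    return detect_sep(division_durations(cell), epsilon=epsilon)


def split_pre_post_sep(cell: CellLifeHistory, sep: SepResult) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks over replicative ages 1..K: (pre-SEP, post-SEP).

    Pre covers ages strictly before the SEP age; post covers the SEP age
    onward.  A cell with no SEP is entirely pre-SEP.  The two masks always
    partition the ages.
    """
    ages = np.arange(1, cell.rls + 1)
    if sep.sep_age is None:
        pre = np.ones_like(ages, dtype=bool)
    else:
        pre = ages < sep.sep_age
    return pre, ~pre
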