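"""Independent reference implementations used only to cross-check the package.

Each oracle recomputes a result by a different route than the library:
the smoothing spline via a dense smoother matrix assembled from natural
cubic interpolants of unit vectors, the elbow detector via exhaustive
distance evaluation, and the rank-sum p-value via full enumeration of
rank assignments.
"""

from itertools import combinations

import numpy as np
from scipy.interpolate import CubicSpline


def dense_spline_oracle(ages, values, spar):
    """Penalized smoothing spline by direct dense linear algebra.

    The roughness matrix K is built column by column: K[i, j] equals the
    integral of the product of second derivatives of the natural cubic
    interpolants of the i-th and j-th unit vectors.  Second derivatives of
    cubics are piecewise linear, so Simpson's rule on each knot interval
    integrates their product exactly.  The fit solves (I + lam K) f = y
    with lam = (n / tr K) * 256**(3*spar - 1) on the [0, 1]-rescaled axis.
    """
    x = np.asarray(ages, dtype=float)
    y = np.asarray(values, dtype=float)
    n = len(x)
    u = (x - x[0]) / (x[-1] - x[0])

    splines = []
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        splines.append(CubicSpline(u, e, bc_type="natural"))

    K = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            total = 0.0
            for a, b in zip(u[:-1], u[1:]):
                mid = 0.5 * (a + b)
                fa = splines[i](a, 2) * splines[j](a, 2)
                fm = splines[i](mid, 2) * splines[j](mid, 2)
                fb = splines[i](b, 2) * splines[j](b, 2)
                total += (b - a) / 6.0 * (fa + 4.0 * fm + fb)
            K[i, j] = K[j, i] = total

    lam = (n / np.trace(K)) * 256.0 ** (3.0 * spar - 1.0)
    return np.linalg.solve(np.eye(n) + lam * K, y)


def brute_force_sep(ages, durations, epsilon=0.02):
    """Exhaustive max-distance elbow search on the unit-rescaled profile.

    Evaluates the perpendicular distance of every interior point from the
    first-to-last chord and returns the age of the largest distance on the
    sagging (below-chord) side, or None if nothing exceeds epsilon.
    """
    ages = np.asarray(ages, dtype=float)
    durations = np.asarray(durations, dtype=float)
    rng = durations.max() - durations.min()
    if rng == 0:
        return None
    x = (ages - ages[0]) / (ages[-1] - ages[0])
    y = (durations - durations.min()) / rng
    p0 = np.array([x[0], y[0]])
    p1 = np.array([x[-1], y[-1]])
    chord = p1 - p0
    norm = np.linalg.norm(chord)
    best_age, best_d = None, epsilon
    for i in range(1, len(ages) - 1):
        v = np.array([x[i], y[i]]) - p0
        cross = chord[0] * v[1] - chord[1] * v[0]  # >0 above, <0 below
        d = -cross / norm
        if d > best_d:
            best_age, best_d = int(ages[i]), d
    return best_age


def exact_ranksum_pvalue(x, y):
    """Two-sided Mann-Whitney p by enumerating all rank assignments.

    Assumes no ties; the p-value is the fraction of assignments whose U is
    at least as far from its mean as the observed one.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    order = pooled.argsort()
    ranks = np.empty(len(pooled))
    ranks[order] = np.arange(1, len(pooled) + 1)
    n = len(x)
    mean_u = n * len(y) / 2.0
    u_obs = ranks[:n].sum() - n * (n + 1) / 2.0
    hits = total = 0
    for combo in combinations(range(len(pooled)), n):
        u = ranks[list(combo)].sum() - n * (n + 1) / 2.0
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            hits += 1
    return hits / total
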