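"""Independent brute-force oracles used to validate the package's operations.

Each function here deliberately avoids the implementation path it checks:
chord scanning instead of conic algebra, exhaustive sign enumeration instead
of the rank-sum DP, Pearson-on-ranks instead of the library Spearman.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats as sps


def truncated_normal_mean(mean: float, sd: float) -> float:
    """Closed-form mean of Normal(mean, sd) truncated below at zero."""
    if sd == 0:
        return mean
    alpha = mean / sd
    return mean + sd * sps.norm.pdf(alpha) / sps.norm.cdf(alpha)


def _conic(center, semi_axes, rotation):
    (x0, y0), (a, b) = center, semi_axes
    ct, st = np.cos(rotation), np.sin(rotation)
    A = ct**2 / a**2 + st**2 / b**2
    C = st**2 / a**2 + ct**2 / b**2
    B = 2 * ct * st * (1 / a**2 - 1 / b**2)
    D = -(2 * A * x0 + B * y0)
    E = -(B * x0 + 2 * C * y0)
    F = A * x0**2 + B * x0 * y0 + C * y0**2 - 1.0
    return A, B, C, D, E, F


def _parabola_vertex(f, t0: float, h: float = 1.0) -> float:
    """Exact maximizer of a quadratic from three function samples."""
    fm, f0, fp = f(t0 - h), f(t0), f(t0 + h)
    denom = fm - 2 * f0 + fp
    if denom == 0:
        return t0
    return t0 + h * 0.5 * (fm - fp) / denom


def longest_chord_intersection(center, semi_axes, rotation):
    """Intersection of the longest horizontal and vertical chords of an ellipse.

    The squared horizontal chord length at height y is proportional to the
    quadratic discriminant of the conic restricted to that row, so a coarse
    grid scan followed by exact parabolic interpolation recovers the
    maximizing row/column to machine precision.
    """
    A, B, C, D, E, F = _conic(center, semi_axes, rotation)

    def disc_h(y):  # squared-length surrogate of the horizontal chord at y
        return (B * y + D) ** 2 - 4 * A * (C * y**2 + E * y + F)

    def disc_v(x):
        return (B * x + E) ** 2 - 4 * C * (A * x**2 + D * x + F)

    ext = max(semi_axes)
    ys = np.linspace(center[1] - ext, center[1] + ext, 501)
    y_star = _parabola_vertex(disc_h, float(ys[np.argmax(disc_h(ys))]))
    xs = np.linspace(center[0] - ext, center[0] + ext, 501)
    x_star = _parabola_vertex(disc_v, float(xs[np.argmax(disc_v(xs))]))
    # longest horizontal chord lies on y = y_star, longest vertical on x = x_star
    return x_star, y_star


def wilcoxon_enumeration_p(d: np.ndarray) -> float:
    """Exact two-sided signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array([
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ])
    eps = 1e-9
    lower = np.mean(ws <= w_obs + eps)
    upper = np.mean(ws >= w_obs - eps)
    return float(min(1.0, 2.0 * min(lower, upper)))


def pearson_on_average_ranks(a, b) -> tuple[float, float]:
    """Spearman r and t-approximation p computed from first principles."""
    ra = sps.rankdata(a, method="average")
    rb = sps.rankdata(b, method="average")
    r = float(np.corrcoef(ra, rb)[0, 1])
    n = len(ra)
    t = r * np.sqrt((n - 2) / max(1e-300, 1.0 - r * r))
    p = float(2 * sps.t.sf(abs(t), df=n - 2))
    return r, min(1.0, p)
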