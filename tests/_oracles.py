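"""Independent brute-force oracles used by the test suite.

Everything here is implemented directly from the defining formulas with
plain numpy, deliberately sharing no code with the package: closed-form
re-evaluations for the Wald / adjusted-Wald / Wilson / square-and-add
intervals, a vectorized grid search over the hypothesized difference for
the score-type intervals, and a likelihood grid for the constrained MLE.
"""

from __future__ import annotations

import numpy as np

Z95 = 1.959964  # pinned two-sided 95% quantile


def wald_oracle(x1, n1, x2, n2, z=Z95):
    p1, p2 = x1 / n1, x2 / n2
    d = p1 - p2
    se = np.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    return max(-1.0, d - z * se), min(1.0, d + z * se)


def agresti_caffo_oracle(x1, n1, x2, n2, z=Z95):
    return wald_oracle(x1 + 1, n1 + 2, x2 + 1, n2 + 2, z)


def wilson_oracle(x, n, z=Z95):
    p = x / n
    denom = 1 + z * z / n
    center = p + z * z / (2 * n)
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n))
    return max(0.0, (center - half) / denom), min(1.0, (center + half) / denom)


def newcombe_oracle(x1, n1, x2, n2, z=Z95):
    p1, p2 = x1 / n1, x2 / n2
    l1, u1 = wilson_oracle(x1, n1, z)
    l2, u2 = wilson_oracle(x2, n2, z)
    d = p1 - p2
    lower = d - np.sqrt((p1 - l1) ** 2 + (u2 - p2) ** 2)
    upper = d + np.sqrt((u1 - p1) ** 2 + (p2 - l2) ** 2)
    return max(-1.0, lower), min(1.0, upper)


def rmle_grid(x1, n1, x2, n2, d):
    """Constrained MLE (p1, p2) for a vector of differences d, via the cubic."""
    d = np.asarray(d, dtype=float)
    n = n1 + n2
    l3 = float(n)
    l2 = (n1 + 2 * n2) * d - n - (x1 + x2)
    l1 = (n2 * d - n - 2 * x2) * d + x1 + x2
    l0 = x2 * d * (1 - d)
    q = l2**3 / (3 * l3) ** 3 - l1 * l2 / (6 * l3**2) + l0 / (2 * l3)
    disc = np.maximum(l2**2 / (3 * l3) ** 2 - l1 / (3 * l3), 0.0)
    s = np.where(q >= 0, 1.0, -1.0)
    p = s * np.sqrt(disc)
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = np.clip(q / p**3, -1.0, 1.0)
    a = (np.pi + np.arccos(arg)) / 3.0
    p2 = 2 * p * np.cos(a) - l2 / (3 * l3)
    # degenerate cubic: solve by brute likelihood grid at those points
    bad = ~np.isfinite(p2) | (np.abs(p**3) < 1e-300)
    if np.any(bad):
        for i in np.flatnonzero(bad):
            p2[i] = _loglik_argmax(x1, n1, x2, n2, float(d[i]))
    p2 = np.clip(p2, np.maximum(0.0, -d), np.minimum(1.0, 1.0 - d))
    return p2 + d, p2


def loglik(x1, n1, x2, n2, p1, p2):
    out = np.zeros(np.broadcast(p1, p2).shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        for x, n, p in ((x1, n1, p1), (x2, n2, p2)):
            if x > 0:
                out = out + x * np.log(p)
            if x < n:
                out = out + (n - x) * np.log1p(-p)
    return out


def _loglik_argmax(x1, n1, x2, n2, d, points=200001):
    p2 = np.linspace(max(0.0, -d), min(1.0, 1.0 - d), points)
    ll = loglik(x1, n1, x2, n2, p2 + d, p2)
    return float(p2[np.nanargmax(ll)])


def _score_stat_grid(x1, n1, x2, n2, d, skew):
    p1, p2 = rmle_grid(x1, n1, x2, n2, d)
    n = n1 + n2
    v = (p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2) * n / (n - 1)
    num = (x1 / n1 - x2 / n2) - d
    with np.errstate(divide="ignore", invalid="ignore"):
        z = num / np.sqrt(v)
        if skew:
            mu3 = (
                p1 * (1 - p1) * (1 - 2 * p1) / n1**2
                - p2 * (1 - p2) * (1 - 2 * p2) / n2**2
            )
            gamma = mu3 / (6 * v**1.5)
            stat = z - gamma * (z * z - 1)
        else:
            stat = z
    stat = np.where(v <= 0, np.where(num == 0, 0.0, np.sign(num) * np.inf), stat)
    return stat


def score_grid_ci(x1, n1, x2, n2, z=Z95, skew=False, step=1e-5):
    """Grid search locating the sign changes of the (possibly skew-corrected)
    score statistic against +/-z, nearest to the point estimate."""
    d = np.arange(-1.0 + step, 1.0, step)
    stat = _score_stat_grid(x1, n1, x2, n2, d, skew)
    dhat = x1 / n1 - x2 / n2

    def crossing(target, side, boundary):
        # only decreasing crossings on the correct side of the point
        # estimate count: the zero-variance spike of degenerate tables
        # produces upward and wrong-side crossings that are not limits
        f = stat - target
        down = np.flatnonzero((f[:-1] > 0) & (f[1:] < 0))
        mids = 0.5 * (d[down] + d[down + 1])
        mids = mids[mids <= dhat + step] if side == "lower" else mids[mids >= dhat - step]
        if mids.size == 0:
            return boundary
        return float(mids[np.argmin(np.abs(mids - dhat))])

    return crossing(z, "lower", -1.0), crossing(-z, "upper", 1.0)


def quantile_oracle(values, q):
    """Sort-based quantile with linear interpolation between order statistics."""
    v = sorted(values)
    if len(v) == 1:
        return v[0]
    pos = q * (len(v) - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, len(v) - 1)
    frac = pos - lo
    return v[lo] * (1 - frac) + v[hi] * frac
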