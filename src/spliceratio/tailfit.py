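"""Continuous power-law tail fitting and tail significance.

The srd score of an unchanged splicing event sits near 1; genuinely changed
events produce large scores in the right tail.  The tail is modelled as a
continuous power law ``p(x) ~ x**(-alpha)`` for ``x >= xmin``.  Fitting
follows the standard Clauset procedure: for each candidate cutoff ``xmin``
the exponent is estimated by maximum likelihood,

    alpha = 1 + n / sum(log(x_i / xmin)),   x_i >= xmin,

and the cutoff minimising the Kolmogorov-Smirnov distance between the
empirical tail and the fitted model is kept.  Tail significance of a score
is the fitted complementary CDF, ``P(X >= x) = (x / xmin)**(1 - alpha)``,
clamped to 1 below the cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["PowerLawFit", "PowerLawFitError", "fit_power_law", "significance"]


class PowerLawFitError(ValueError):
    """Raised when the data admit no power-law tail fit."""


@dataclass(frozen=True, slots=True)
class PowerLawFit:
    """Fitted tail: exponent, lower cutoff, KS goodness-of-fit, tail size."""

    alpha: float
    xmin: float
    ks_distance: float
    n_tail: int


def fit_power_law(
    values,
    min_tail: int = 10,
    max_xmin_candidates: int = 256,
) -> PowerLawFit:
    """Fit a continuous power-law tail to positive values.

    Parameters
    ----------
    values
        Observations; only strictly positive values lie in the support of
        the model and are used.
    min_tail
        Minimum number of points at/above ``xmin`` for a candidate cutoff.
    max_xmin_candidates
        Cap on the number of candidate cutoffs scanned (evenly spaced over
        the unique values); keeps the scan near-linear on large samples.

    Raises
    ------
    PowerLawFitError
        If fewer than ``min_tail`` positive values exist, or all candidate
        tails are degenerate (all values equal).
    """
    x = np.asarray(values, dtype=float)
    x = np.sort(x[np.isfinite(x) & (x > 0)])
    if x.size < min_tail:
        raise PowerLawFitError(
            f"need >= {min_tail} positive values, got {x.size}"
        )
    uniq = np.unique(x)
    if uniq.size < 2:
        raise PowerLawFitError("degenerate data: all values identical")
    # candidate cutoffs: unique values whose tail keeps >= min_tail points
    last_ok = np.searchsorted(x, uniq, side="left") <= x.size - min_tail
    candidates = uniq[last_ok]
    if candidates.size == 0:
        raise PowerLawFitError(f"no cutoff leaves a tail of >= {min_tail} points")
    if candidates.size > max_xmin_candidates:
        idx = np.unique(
            np.linspace(0, candidates.size - 1, max_xmin_candidates).round().astype(int)
        )
        candidates = candidates[idx]

    logx = np.log(x)
    fits: list[tuple[float, float, float, int]] = []
    for xmin in candidates:
        i = np.searchsorted(x, xmin, side="left")
        tail = x[i:]
        n = tail.size
        s = np.sum(logx[i:] - np.log(xmin))
        if s <= 0:  # all tail values equal to xmin
            continue
        alpha = 1.0 + n / s
        # KS distance between the empirical tail CDF and the fitted CDF
        cdf = 1.0 - (tail / xmin) ** (1.0 - alpha)
        ecdf_hi = np.arange(1, n + 1) / n
        ecdf_lo = np.arange(0, n) / n
        ks = max(np.max(np.abs(ecdf_hi - cdf)), np.max(np.abs(ecdf_lo - cdf)))
        fits.append((alpha, float(xmin), float(ks), n))
    if not fits:
        raise PowerLawFitError("degenerate data: no non-trivial tail found")
    # The raw KS minimum is noisy: for data that follow the model down to a
    # cutoff, sampling noise of order 1/sqrt(n_tail) can favour an interior
    # cutoff and discard valid tail data.  Among candidates whose KS lies
    # within that noise band of the minimum, keep the smallest cutoff.
    ks_min = min(f[2] for f in fits)
    admissible = [f for f in fits if f[2] <= ks_min + 0.5 / math.sqrt(f[3])]
    best = min(admissible, key=lambda f: f[1])
    return PowerLawFit(alpha=best[0], xmin=best[1], ks_distance=best[2], n_tail=best[3])


def significance(srd, fit: PowerLawFit):
    """Tail significance ``P(X >= srd)`` under a fitted power law.

    Returns 1 below the cutoff ``xmin`` (the score is not in the modelled
    tail, hence unremarkable).  Accepts scalars or arrays.
    """
    srd_arr = np.asarray(srd, dtype=float)
    p = np.ones_like(srd_arr)
    in_tail = srd_arr >= fit.xmin
    p[in_tail] = (srd_arr[in_tail] / fit.xmin) ** (1.0 - fit.alpha)
    if np.ndim(srd) == 0:
        return float(p)
    return p
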