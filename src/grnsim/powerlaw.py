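"""Discrete power-law tail fitting by maximum likelihood.

Implements the standard discrete MLE with Hurwitz-zeta normalisation and
Kolmogorov-Smirnov selection of the tail cutoff ``xmin``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import zeta

__all__ = ["PowerLawFit", "fit_discrete_powerlaw"]


@dataclass(frozen=True)
class PowerLawFit:
    """Result of a discrete power-law tail fit."""

    alpha: float
    xmin: int
    ks_distance: float
    n_tail: int
    converged: bool
    method: str = "discrete-mle-ks"


def _neg_loglik(alpha: float, xmin: int, n: int, sum_log: float) -> float:
    return n * np.log(zeta(alpha, xmin)) + alpha * sum_log


def _fit_alpha(tail: np.ndarray, xmin: int, bounds: tuple[float, float]):
    n = tail.size
    sum_log = float(np.log(tail).sum())
    res = minimize_scalar(
        _neg_loglik,
        bounds=bounds,
        args=(xmin, n, sum_log),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x), bool(res.success)


def _ks_distance(tail: np.ndarray, xmin: int, alpha: float) -> float:
    kmax = int(tail.max())
    ks = np.arange(xmin, kmax + 1, dtype=float)
    pmf = ks ** (-alpha) / zeta(alpha, xmin)
    model_cdf = np.cumsum(pmf)
    ecdf = np.searchsorted(np.sort(tail), ks, side="right") / tail.size
    return float(np.max(np.abs(ecdf - model_cdf)))


def fit_discrete_powerlaw(
    values,
    xmin: int | None = None,
    alpha_bounds: tuple[float, float] = (1.01, 6.0),
    min_tail: int = 5,
    max_xmin_candidates: int = 50,
) -> PowerLawFit:
    """Fit ``P(k) ~ k^-alpha`` for ``k >= xmin`` to integer-valued data.

    When ``xmin`` is not given it is chosen among observed values so that the
    Kolmogorov-Smirnov distance between the fitted model and the empirical
    tail distribution is minimal.  Degenerate inputs (fewer than ``min_tail``
    usable points, or an all-equal sample) yield ``converged=False``.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals) & (vals >= 1)]
    vals = vals.astype(np.int64)
    if vals.size < min_tail or np.unique(vals).size < 2:
        return PowerLawFit(np.nan, xmin or 0, np.nan, int(vals.size), False)

    if xmin is not None:
        candidates = [int(xmin)]
    else:
        uniq = np.unique(vals)
        # the largest values leave too few tail points for a stable fit
        candidates = [
            int(x) for x in uniq if np.count_nonzero(vals >= x) >= min_tail
        ][:max_xmin_candidates]
        if not candidates:
            return PowerLawFit(np.nan, 0, np.nan, int(vals.size), False)

    best: PowerLawFit | None = None
    for cand in candidates:
        tail = vals[vals >= cand]
        if tail.size < 2 or np.unique(tail).size < 2:
            continue
        alpha, ok = _fit_alpha(tail, cand, alpha_bounds)
        if not ok:
            continue
        interior = alpha_bounds[0] + 1e-4 < alpha < alpha_bounds[1] - 1e-4
        ks = _ks_distance(tail, cand, alpha)
        fit = PowerLawFit(alpha, cand, ks, int(tail.size), interior)
        if best is None or ks < best.ks_distance:
            best = fit
    if best is None:
        return PowerLawFit(np.nan, 0, np.nan, int(vals.size), False)
    return best
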