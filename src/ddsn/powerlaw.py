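"""Maximum-likelihood power-law tail fitting with KS-minimizing cutoff.

Fits p(x) ~ x^(-alpha) for x >= x_min in the Clauset-Shalizi-Newman style:
for each candidate cutoff the exponent is estimated by MLE (continuous
closed form, or discrete via the Hurwitz-zeta likelihood), and the cutoff
minimizing the Kolmogorov-Smirnov distance between the empirical tail and
the fitted CDF is selected.  Centrality distributions of drug-drug
similarity networks are fat-tailed, so the tail exponent summarizes how
extreme the top-ranked drugs are.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special


@dataclass(frozen=True)
class PowerLawFit:
    """Fitted tail: exponent alpha, cutoff x_min, KS distance, tail size."""

    alpha: float
    xmin: float
    ks: float
    n_tail: int
    discrete: bool

    def __post_init__(self) -> None:
        if not self.alpha > 1:
            raise ValueError("power-law exponent must exceed 1")
        if self.n_tail < 2:
            raise ValueError("tail must contain at least 2 points")


def _fit_continuous(tail: np.ndarray, xmin: float) -> float:
    return 1.0 + tail.size / np.log(tail / xmin).sum()


def _discrete_nll(alpha: float, tail: np.ndarray, xmin: float) -> float:
    return tail.size * np.log(special.zeta(alpha, xmin)) + alpha * np.log(tail).sum()


def _fit_discrete(tail: np.ndarray, xmin: float) -> float:
    res = optimize.minimize_scalar(
        _discrete_nll, bounds=(1.0001, 12.0), args=(tail, xmin), method="bounded"
    )
    return float(res.x)


def _ks_distance(tail: np.ndarray, alpha: float, xmin: float, discrete: bool) -> float:
    # compare CDFs at unique values, matching right values with right values
    # and left limits with left limits (both CDFs jump at discrete points)
    uniq, counts = np.unique(tail, return_counts=True)
    n = tail.size
    emp_hi = np.cumsum(counts) / n
    emp_lo = emp_hi - counts / n
    if discrete:
        z = special.zeta(alpha, xmin)
        fit_hi = 1.0 - special.zeta(alpha, uniq + 1) / z
        fit_lo = 1.0 - special.zeta(alpha, uniq) / z
    else:
        fit_hi = 1.0 - (uniq / xmin) ** (1.0 - alpha)
        fit_lo = fit_hi
    return float(np.maximum(np.abs(emp_hi - fit_hi), np.abs(emp_lo - fit_lo)).max())


def fit_power_law(
    values,
    discrete: bool | None = None,
    xmin: float | None = None,
    min_tail: int = 10,
    max_candidates: int = 50,
) -> PowerLawFit:
    """Fit a power-law tail to positive values.

    ``discrete`` defaults to auto-detection (all values integral).  When
    ``xmin`` is given only the exponent is estimated; otherwise candidate
    cutoffs (up to ``max_candidates`` quantile-spaced unique values keeping
    at least ``min_tail`` tail points) are scanned and the KS-minimizing one
    wins.  Raises on degenerate input (fewer than 2 distinct values).
    """
    x = np.asarray(list(values), dtype=float)
    x = x[x > 0]
    if x.size < 2 or np.unique(x).size < 2:
        raise ValueError("degenerate input: need at least 2 distinct positive values")
    if discrete is None:
        discrete = bool(np.all(x == np.round(x)))

    def fit_at(x0: float) -> PowerLawFit | None:
        tail = x[x >= x0]
        if tail.size < 2 or np.unique(tail).size < 2:
            return None
        alpha = _fit_discrete(tail, x0) if discrete else _fit_continuous(tail, x0)
        if not alpha > 1:
            return None
        return PowerLawFit(
            alpha=float(alpha),
            xmin=float(x0),
            ks=_ks_distance(tail, alpha, x0, discrete),
            n_tail=int(tail.size),
            discrete=discrete,
        )

    if xmin is not None:
        fit = fit_at(float(xmin))
        if fit is None:
            raise ValueError(f"tail above xmin={xmin} is degenerate")
        return fit

    uniq = np.unique(x)
    # candidates must keep a usable tail
    candidates = [u for u in uniq if (x >= u).sum() >= max(min_tail, 2)]
    if not candidates:
        candidates = [uniq[0]]
    if len(candidates) > max_candidates:
        idx = np.unique(np.linspace(0, len(candidates) - 1, max_candidates).astype(int))
        candidates = [candidates[i] for i in idx]
    fits = [f for f in (fit_at(float(c)) for c in candidates) if f is not None]
    if not fits:
        raise ValueError("no viable power-law tail found")
    return min(fits, key=lambda f: (f.ks, f.xmin))


def sample_power_law(
    alpha: float,
    xmin: float = 1.0,
    size: int = 1,
    rng: np.random.Generator | int | None = None,
    discrete: bool = True,
    support_cap: int = 10**6,
) -> np.ndarray:
    """Draw samples from a power law (exact inverse-CDF for the discrete case).

    Discrete sampling normalizes x^(-alpha) over 1..support_cap above x_min
    (the truncated mass beyond the cap is negligible for alpha > 1.5).
    """
    if alpha <= 1:
        raise ValueError("alpha must exceed 1")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    if not discrete:
        u = rng.random(size)
        return xmin * (1.0 - u) ** (-1.0 / (alpha - 1.0))
    support = np.arange(int(xmin), support_cap + 1, dtype=float)
    pmf = support**-alpha
    cdf = np.cumsum(pmf / pmf.sum())
    u = rng.random(size)
    return support[np.searchsorted(cdf, u, side="left")]
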