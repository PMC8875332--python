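"""Many-to-one (Dunnett) inference, significance stars and volcano categories.

Dunnett's procedure compares k treatment groups against a shared
control using the pooled within-group standard deviation.  The k
t-statistics

    T_i = (mean_i - mean_0) / (S * sqrt(1/n_i + 1/n_0))

are jointly multivariate-t with product correlation
``r_ij = b_i b_j``, ``b_i = sqrt(n_i / (n_i + n_0))`` — this is the
general unbalanced structure; equal group sizes make it
equicorrelated.  The two-sided adjusted p for contrast i is

    p_i = 1 - P(max_j |T_j| <= |t_i|),

evaluated here by deterministic quadrature: conditioning on the shared
control variate Z (Gauss-Hermite) and on the pooled-SD chi variable
(Gauss-Legendre on the probability scale) factorises the joint
probability into a product of univariate normal interval
probabilities.  For k = 1 the integral reduces analytically to the
classical two-sided pooled t-test, which is returned exactly.  A
seeded Monte-Carlo evaluation of the same rejection probability is
provided as an independent validation oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import ndtr

_N_Z = 80   # Gauss-Hermite nodes for the shared control variate
_N_S = 96   # Gauss-Legendre nodes for the pooled-SD chi variable


class InsufficientDataError(ValueError):
    """A group with fewer than two observations."""


class DegenerateVarianceError(ValueError):
    """Pooled within-group variance is zero."""


@lru_cache(maxsize=None)
def _hermite_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    # probabilists' Hermite: integrates against the standard normal density
    x, w = np.polynomial.hermite_e.hermegauss(n)
    return x, w / np.sqrt(2.0 * np.pi)


@lru_cache(maxsize=None)
def _s_nodes(df: int, n: int = _N_S) -> tuple[np.ndarray, np.ndarray]:
    # map Legendre nodes on (0,1) through the chi quantile of S/sigma
    u, w = np.polynomial.legendre.leggauss(n)
    u = 0.5 * (u + 1.0)
    w = 0.5 * w
    s = np.sqrt(sps.chi2.ppf(u, df) / df)
    return s, w


def prob_max_abs_le(t: float, b: Sequence[float], df: int) -> float:
    """P(max_i |T_i| <= t) for Dunnett statistics with loadings *b*.

    *b* are the control loadings ``b_i = sqrt(n_i/(n_i+n_0))``; *df*
    the pooled-variance degrees of freedom.
    """
    if t <= 0:
        return 0.0
    b = np.asarray(b, dtype=float)
    c = np.sqrt(1.0 - b * b)
    z, wz = _hermite_nodes(_N_Z)
    s, ws = _s_nodes(int(df))
    ts = t * s  # (Ns,)
    # shape (Ns, Nz, k)
    upper = (ts[:, None, None] - b[None, None, :] * z[None, :, None]) / c[None, None, :]
    lower = (-ts[:, None, None] - b[None, None, :] * z[None, :, None]) / c[None, None, :]
    probs = np.prod(ndtr(upper) - ndtr(lower), axis=2)  # (Ns, Nz)
    val = float(ws @ (probs @ wz))
    return min(max(val, 0.0), 1.0)


@dataclass(frozen=True)
class DunnettResult:
    """Per-treatment statistics and two-sided Dunnett-adjusted p-values."""

    statistic: np.ndarray
    pvalue: np.ndarray
    df: int
    b: np.ndarray  # control loadings defining the correlation structure


def dunnett_test(control: Sequence[float], treatments: Sequence[Sequence[float]]) -> DunnettResult:
    """Two-sided many-to-one comparisons of each treatment vs the control.

    Raises :class:`InsufficientDataError` for any group with fewer than
    two observations and :class:`DegenerateVarianceError` when the
    pooled within-group variance is zero.
    """
    x0 = np.asarray(control, dtype=float)
    groups = [np.asarray(g, dtype=float) for g in treatments]
    if not groups:
        raise ValueError("at least one treatment group required")
    if len(x0) < 2 or any(len(g) < 2 for g in groups):
        raise InsufficientDataError("every group needs at least two observations")

    n0 = len(x0)
    ns = np.array([len(g) for g in groups])
    df = int(n0 - 1 + np.sum(ns - 1))
    ss = float(np.sum((x0 - x0.mean()) ** 2) + sum(np.sum((g - g.mean()) ** 2) for g in groups))
    if ss == 0.0:
        raise DegenerateVarianceError("pooled within-group variance is zero")
    s2 = ss / df

    means = np.array([g.mean() for g in groups])
    tstat = (means - x0.mean()) / np.sqrt(s2 * (1.0 / ns + 1.0 / n0))
    b = np.sqrt(ns / (ns + n0))

    if len(groups) == 1:
        # analytic reduction: Dunnett with one contrast IS the pooled t-test
        pvals = np.array([2.0 * sps.t.sf(abs(tstat[0]), df)])
    else:
        pvals = np.array(
            [1.0 - prob_max_abs_le(abs(t), tuple(b), df) for t in tstat]
        )
    return DunnettResult(statistic=tstat, pvalue=np.clip(pvals, 0.0, 1.0), df=df, b=b)


def monte_carlo_max_abs_sf(
    t: float,
    ns: Sequence[int],
    n0: int,
    n_draws: int = 10**6,
    seed: int = 0,
) -> float:
    """Seeded Monte-Carlo estimate of P(max_i |T_i| > t).

    Independent validation oracle for :func:`prob_max_abs_le`: draws
    the shared control variate, the per-group variates and the pooled
    chi scale directly and counts exceedances.
    """
    ns = np.asarray(ns, dtype=int)
    df = int(n0 - 1 + np.sum(ns - 1))
    b = np.sqrt(ns / (ns + n0))
    c = np.sqrt(1.0 - b * b)
    rng = np.random.default_rng(seed)
    out = 0
    chunk = 200_000
    done = 0
    while done < n_draws:
        m = min(chunk, n_draws - done)
        z0 = rng.standard_normal(m)
        zi = rng.standard_normal((m, len(ns)))
        s = np.sqrt(rng.chisquare(df, m) / df)
        tmax = np.max(np.abs(b[None, :] * z0[:, None] + c[None, :] * zi), axis=1) / s
        out += int(np.sum(tmax > t))
        done += m
    return out / n_draws


def significance_stars(p: float) -> str:
    """``***`` for p<=0.001, ``**`` for p<=0.01, ``*`` for p<=0.05, else ''."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value must lie in [0, 1], got {p}")
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


#: The eight volcano cells plus the exact-100% sentinel.
VOLCANO_CATEGORIES = tuple(
    f"{sig}_{direction}_{mag}"
    for sig in ("significant", "nonsignificant")
    for direction in ("increase", "decrease")
    for mag in ("beyond_sd", "within_sd")
) + ("no_change",)


def volcano_categorize(effect_pct: float, p_adjusted: float, sd_threshold: float) -> str:
    """Assign one of the eight volcano cells.

    Direction comes from the sign of (effect - 100), the magnitude flag
    from |effect - 100| > sd_threshold, the significance flag from
    p <= 0.05.  An effect of exactly 100 % gets the ``no_change``
    sentinel rather than an arbitrary direction.
    """
    if not (sd_threshold > 0):
        raise ValueError(f"sd_threshold must be > 0, got {sd_threshold}")
    if not (0.0 <= p_adjusted <= 1.0):
        raise ValueError(f"p-value must lie in [0, 1], got {p_adjusted}")
    delta = effect_pct - 100.0
    if delta == 0.0:
        return "no_change"
    sig = "significant" if p_adjusted <= 0.05 else "nonsignificant"
    direction = "increase" if delta > 0 else "decrease"
    mag = "beyond_sd" if abs(delta) > sd_threshold else "within_sd"
    return f"{sig}_{direction}_{mag}"
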