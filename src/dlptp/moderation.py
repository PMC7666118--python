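"""Empirical Bayes moderation of residual variances.

Each protein's alternative-model residual variance s_i^2 = RSS1_i / d2_i
is shrunk towards a common value estimated across proteins with a
similar number of observations.  The prior is a scaled inverse
chi-squared distribution on the true variances,

    1 / sigma_i^2  ~  chi^2_{d0} / (d0 * s0^2),

under which marginally s_i^2 ~ s0^2 * F(d2_i, d0) and the posterior mean
of sigma_i^2 given s_i^2 is the precision-weighted average

    s~_i^2 = (d0 * s0^2 + d2 * s_i^2) / (d0 + d2).

The hyperparameters (d0, s0^2) are estimated by moment matching on
log variances: for z = log s^2, E[log F(d2, d0)] and Var[log F(d2, d0)]
have closed forms in digamma/trigamma, and the trigamma equation for d0
is solved by monotone root finding.  Under-dispersed variances yield
d0 = +inf, in which case every s~^2 equals s0^2.

The moderated F-statistic replaces the residual variance in the nested
F-test denominator:  F~ = (RSS0 - RSS1) / (s~^2 * d1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import digamma, polygamma

logger = logging.getLogger("dlptp")


def _trigamma(x):
    return polygamma(1, x)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (y > 0)."""
    if y <= 0:
        return np.inf
    # trigamma(x) ~ 1/x + 1/(2x^2); bracket around that seed
    x0 = 0.5 + 1.0 / y
    lo, hi = x0, x0
    while _trigamma(lo) < y:
        lo /= 2.0
    while _trigamma(hi) > y:
        hi *= 2.0
    return brentq(lambda x: _trigamma(x) - y, lo, hi, xtol=1e-10, rtol=1e-12)


@dataclass
class ModerationParams:
    """Estimated prior df and prior variance for one stratum of proteins."""

    d0: float
    s0_sq: float
    stratum: int = 0
    n_proteins: int = 0

    def __post_init__(self):
        if not (self.d0 > 0):
            raise ValueError("d0 must be positive (possibly inf)")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be positive")


def estimate_prior(s_sq: np.ndarray, d2: np.ndarray, stratum: int = 0) -> ModerationParams:
    """Fit the scaled-F model s^2 ~ s0^2 * F(d2, d0) by log-moment matching.

    Returns d0 = +inf when the observed log-variances are no more
    dispersed than the chi-squared sampling variability alone (including
    the degenerate case of identical variances).
    """
    s_sq = np.asarray(s_sq, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    ok = np.isfinite(s_sq) & (s_sq > 0) & (d2 > 0)
    s_sq, d2 = s_sq[ok], d2[ok]
    n = s_sq.size
    if n < 2:
        raise ValueError("need at least two positive variances to estimate the prior")
    z = np.log(s_sq)
    e = z - digamma(d2 / 2.0) + np.log(d2 / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(np.mean(_trigamma(d2 / 2.0)))
    if e_var <= 0:
        # under-dispersed: all true variances equal; the arithmetic mean of
        # the observed variances is then the natural common-value estimate
        d0 = np.inf
        s0_sq = float(np.mean(s_sq))
    else:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return ModerationParams(d0=d0, s0_sq=s0_sq, stratum=stratum, n_proteins=n)


def squeeze_variance(s_sq, d2, params: ModerationParams):
    """Posterior-mean shrinkage of s^2 towards the prior variance.

    The d0 -> 0 limit returns s^2 unchanged; d0 = +inf returns s0^2.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if np.isinf(params.d0):
        return np.full_like(s_sq, params.s0_sq)
    return (params.d0 * params.s0_sq + d2 * s_sq) / (params.d0 + d2)


def moderated_f(rss0, rss1, d1, s_tilde_sq):
    """Moderated F-statistic (RSS0 - RSS1) / (s~^2 * d1).

    Equals the plain F-statistic whenever s~^2 = RSS1/d2.
    """
    rss0 = np.asarray(rss0, dtype=float)
    rss1 = np.asarray(rss1, dtype=float)
    s_tilde_sq = np.asarray(s_tilde_sq, dtype=float)
    out = np.maximum(rss0 - rss1, 0.0) / (s_tilde_sq * np.asarray(d1, dtype=float))
    out = np.where(s_tilde_sq <= 0, np.inf, out)
    return out if out.ndim else float(out)


def merge_small_strata(labels: np.ndarray, min_size: int) -> np.ndarray:
    """Merge strata with fewer than ``min_size`` members into the nearest stratum.

    Labels are integer group indices on an ordered scale (number of
    measurements / 10); "nearest" is by label distance, ties towards the
    larger-sample side.  Merging repeats until all strata are large
    enough or only one remains.
    """
    labels = np.asarray(labels).copy()
    while True:
        uniq, counts = np.unique(labels, return_counts=True)
        if uniq.size <= 1:
            break
        small = uniq[counts < min_size]
        if small.size == 0:
            break
        g = small[np.argmin(counts[np.isin(uniq, small)])]
        others = uniq[uniq != g]
        target = others[np.lexsort((-others, np.abs(others - g)))][0]
        labels[labels == g] = target
    return labels


def moderate_stats(table: pd.DataFrame, strata: np.ndarray | None = None,
                   min_stratum_size: int = 10) -> tuple[pd.DataFrame, list[ModerationParams]]:
    """Attach moderated statistics to a per-protein fit table.

    ``table`` must have columns rss0, rss1, d1, d2.  ``strata`` are
    integer group labels (default: a single stratum); strata smaller
    than ``min_stratum_size`` are merged with their nearest neighbour
    before prior estimation.  Returns the augmented table (columns
    s_sq, s_tilde_sq, f_mod, stratum) and the per-stratum parameters.
    """
    out = table.copy()
    n = len(out)
    if strata is None:
        strata = np.zeros(n, dtype=int)
    strata = merge_small_strata(np.asarray(strata, dtype=int), min_stratum_size)
    out["stratum"] = strata
    s_sq = out["rss1"].to_numpy() / out["d2"].to_numpy()
    out["s_sq"] = s_sq
    s_tilde = np.empty(n)
    params: list[ModerationParams] = []
    for g in np.unique(strata):
        idx = strata == g
        par = estimate_prior(s_sq[idx], out.loc[idx, "d2"].to_numpy(), stratum=int(g))
        params.append(par)
        s_tilde[idx] = squeeze_variance(s_sq[idx], out.loc[idx, "d2"].to_numpy(), par)
    out["s_tilde_sq"] = s_tilde
    out["f_mod"] = moderated_f(out["rss0"].to_numpy(), out["rss1"].to_numpy(),
                               out["d1"].to_numpy(), s_tilde)
    return out, params


def moderation_report(params: list[ModerationParams]) -> pd.DataFrame:
    return pd.DataFrame([{"stratum": p.stratum, "n_proteins": p.n_proteins,
                          "d0": p.d0, "s0_sq": p.s0_sq} for p in params])
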