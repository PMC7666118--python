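"""Nested dose-response models for 2D-TPP protein profiles.

For each protein the null model describes the log2 abundance as a
per-temperature baseline,

    y_jk = beta_j + eps_jk,

while the alternative model adds a shared sigmoid response in log10
concentration whose amplitude varies with temperature,

    y_jk = beta_j + alpha_j * delta / (1 + exp(-kappa * (c_k - zeta(T_j)))) + eps_jk,
    zeta(T) = zeta0 + a * T.

``delta`` is the maximal absolute stabilization over the temperature
range (log2 units), ``alpha_j in [0, 1]`` the fraction of it realised at
temperature ``T_j``, ``kappa`` a slope shared across temperatures whose
sign encodes direction (positive = stabilized, negative = destabilized),
and the inflection ``zeta`` (the pEC50 in -log10 M, negated) drifts
linearly with temperature.  The models are nested: with ``alpha = 0``
the alternative collapses to the null, so the residual sum of squares
satisfies RSS1 <= RSS0 at the optimum.

Model comparison uses the F-statistic

    F = (RSS0 - RSS1) / RSS1 * d2 / d1,

with d1 = nu1 - nu0 = m + 4 and d2 = p - nu1 = p - (2 m + 4) for a
protein observed at ``m`` temperatures with ``p`` non-missing values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .data import TwoDDataset

logger = logging.getLogger("dlptp")


@dataclass
class ModelConfig:
    """Optimizer settings for the alternative-model fit.

    kappa_max bounds |kappa| (per log10-concentration unit); a_max
    bounds the inflection drift (log10 units per degree C); zeta_margin
    widens the allowed inflection intercept beyond the tested
    concentration range (decades).
    """

    kappa_max: float = 500.0
    a_max: float = 1.0
    zeta_margin: float = 2.0
    tol: float = 1e-9
    max_iter: int = 300
    n_restarts: int = 3
    seed: int = 0


@dataclass
class ProfileData:
    """Compiled non-missing measurements of one protein."""

    protein_id: str
    y: np.ndarray            # log2 intensities, shape (p,)
    c: np.ndarray            # log10 concentration per row
    temp: np.ndarray         # temperature (deg C) per row
    temp_code: np.ndarray    # index into `temps` per row
    temps: np.ndarray        # unique observed temperatures, ascending
    run_code: np.ndarray     # MS-run index per row
    runs: np.ndarray         # unique run labels

    @property
    def p_obs(self) -> int:
        return self.y.size

    @property
    def m_temps(self) -> int:
        return self.temps.size


@dataclass
class NullFit:
    beta0: np.ndarray       # per-temperature least-squares baseline
    rss0: float
    nu0: int
    fitted: np.ndarray      # fitted value per row


@dataclass
class AltFit:
    beta1: np.ndarray
    alpha: np.ndarray
    delta: float
    kappa: float
    zeta0: float
    a_slope: float
    rss1: float
    nu1: int
    converged: bool
    n_restarts: int
    fitted: np.ndarray
    residuals: np.ndarray


@dataclass
class ProteinFitResult:
    protein_id: str
    p_obs: int
    m_temps: int
    null_fit: NullFit
    alt_fit: AltFit
    d1: int
    d2: int
    f_stat: float
    effect_size: float
    pec50: float
    t_ref: float
    degenerate: bool = False


def compile_profiles(ds: TwoDDataset) -> list[ProfileData]:
    """Split a dataset into per-protein compiled arrays (missing rows dropped)."""
    df = ds.df.dropna(subset=["log2_value"])
    out: list[ProfileData] = []
    for pid, sub in df.groupby("protein_id", sort=True):
        temps, tcode = np.unique(sub["temperature"].to_numpy(dtype=float), return_inverse=True)
        runs, rcode = np.unique(sub["ms_run"].to_numpy(), return_inverse=True)
        out.append(ProfileData(
            protein_id=str(pid),
            y=sub["log2_value"].to_numpy(dtype=float),
            c=sub["log10_conc"].to_numpy(dtype=float),
            temp=sub["temperature"].to_numpy(dtype=float),
            temp_code=tcode.astype(np.intp),
            temps=temps,
            run_code=rcode.astype(np.intp),
            runs=runs,
        ))
    return out


def fit_null(profile: ProfileData, y: np.ndarray | None = None) -> NullFit:
    """Least-squares fit of the per-temperature baseline model."""
    y = profile.y if y is None else y
    m = profile.m_temps
    counts = np.bincount(profile.temp_code, minlength=m)
    sums = np.bincount(profile.temp_code, weights=y, minlength=m)
    beta0 = sums / counts
    fitted = beta0[profile.temp_code]
    rss0 = float(np.sum((y - fitted) ** 2))
    return NullFit(beta0=beta0, rss0=rss0, nu0=m, fitted=fitted)


def _pack(beta, alpha, delta, kappa, zeta0, a):
    return np.concatenate([beta, alpha, [delta, kappa, zeta0, a]])


def _obj_grad(x: np.ndarray, prof: ProfileData, y: np.ndarray):
    """RSS of the alternative model and its analytic gradient."""
    m = prof.m_temps
    beta = x[:m]
    alpha = x[m:2 * m]
    delta, kappa, zeta0, a = x[2 * m:]
    tc = prof.temp_code
    z = prof.c - (zeta0 + a * prof.temp)
    s = expit(kappa * z)
    amp = alpha[tc] * delta
    r = y - beta[tc] - amp * s
    rss = float(r @ r)

    ds_dx = s * (1.0 - s)          # derivative of expit wrt its argument
    common = r * amp * ds_dx
    g_beta = -2.0 * np.bincount(tc, weights=r, minlength=m)
    g_alpha = -2.0 * delta * np.bincount(tc, weights=r * s, minlength=m)
    g_delta = -2.0 * float(np.sum(r * alpha[tc] * s))
    g_kappa = -2.0 * float(np.sum(common * z))
    g_zeta0 = 2.0 * kappa * float(np.sum(common))
    g_a = 2.0 * kappa * float(np.sum(common * prof.temp))
    grad = _pack(g_beta, g_alpha, g_delta, g_kappa, g_zeta0, g_a)
    return rss, grad


def start_values(prof: ProfileData, y: np.ndarray) -> np.ndarray:
    """Prescribed start point: baselines at per-temperature means, alpha = 0,
    delta = the largest within-temperature spread, kappa from a pooled linear
    regression of y on log10 concentration, zeta0 = mean log10 concentration,
    a = 0."""
    m = prof.m_temps
    counts = np.bincount(prof.temp_code, minlength=m)
    beta = np.bincount(prof.temp_code, weights=y, minlength=m) / counts
    ymax = np.full(m, -np.inf)
    ymin = np.full(m, np.inf)
    np.maximum.at(ymax, prof.temp_code, y)
    np.minimum.at(ymin, prof.temp_code, y)
    delta = float(np.max(ymax - ymin))
    c = prof.c
    cc = c - c.mean()
    denom = float(cc @ cc)
    kappa = float(cc @ (y - y.mean()) / denom) if denom > 0 else 1.0
    if kappa == 0.0:
        kappa = 1.0
    zeta0 = float(c.mean())
    return _pack(beta, np.zeros(m), delta, kappa, zeta0, 0.0)


def _bounds(prof: ProfileData, kappa_sign: float, cfg: ModelConfig) -> list[tuple]:
    m = prof.m_temps
    lo_c, hi_c = float(prof.c.min()), float(prof.c.max())
    b: list[tuple] = [(None, None)] * m
    b += [(0.0, 1.0)] * m
    b.append((0.0, None))  # delta >= 0; direction carried by sign of kappa
    if kappa_sign >= 0:
        b.append((0.0, cfg.kappa_max))
    else:
        b.append((-cfg.kappa_max, 0.0))
    b.append((lo_c - cfg.zeta_margin, hi_c + cfg.zeta_margin))
    b.append((-cfg.a_max, cfg.a_max))
    return b


def fit_alternative(prof: ProfileData, cfg: ModelConfig | None = None,
                    y: np.ndarray | None = None) -> AltFit:
    """Bounded quasi-Newton (L-BFGS-B) fit of the sigmoid response model.

    The fit starts from the prescribed start point, whose objective value
    already equals RSS0 (alpha = 0 embeds the null model), so the returned
    RSS1 can exceed RSS0 only through optimizer failure; in that case up to
    ``n_restarts`` seeded restarts jitter kappa and zeta0, and as a last
    resort the null solution itself is returned with ``converged=False``.
    """
    cfg = cfg or ModelConfig()
    y = prof.y if y is None else y
    m = prof.m_temps
    x0 = start_values(prof, y)
    kappa_sign = np.sign(x0[2 * m + 1]) or 1.0
    bounds = _bounds(prof, kappa_sign, cfg)
    null = fit_null(prof, y)

    best = None
    n_used = 0
    rng = np.random.default_rng(cfg.seed)
    for attempt in range(1 + cfg.n_restarts):
        xs = x0.copy()
        if attempt > 0:
            n_used = attempt
            xs[2 * m + 1] *= rng.uniform(0.2, 5.0)       # jitter kappa
            xs[2 * m + 2] += rng.uniform(-1.0, 1.0)      # jitter zeta0
            xs[2 * m + 1] = np.clip(xs[2 * m + 1], *bounds[2 * m + 1])
            xs[2 * m + 2] = np.clip(xs[2 * m + 2], *bounds[2 * m + 2])
        res = minimize(_obj_grad, xs, args=(prof, y), jac=True, method="L-BFGS-B",
                       bounds=bounds,
                       options={"maxiter": cfg.max_iter, "ftol": cfg.tol, "gtol": 1e-5})
        if best is None or res.fun < best.fun:
            best = res
        if best.fun <= null.rss0 + 1e-9:
            break

    x = best.x
    rss1 = float(best.fun)
    converged = bool(best.success)
    if rss1 > null.rss0 + 1e-9:
        # embed the null solution in the alternative parameterization
        logger.debug("fit fell back to null embedding for %s", prof.protein_id)
        x = _pack(null.beta0, np.zeros(m), 0.0, kappa_sign, float(prof.c.mean()), 0.0)
        rss1 = null.rss0
        converged = False

    beta = x[:m]
    alpha = x[m:2 * m]
    delta, kappa, zeta0, a = x[2 * m:]
    z = prof.c - (zeta0 + a * prof.temp)
    fitted = beta[prof.temp_code] + alpha[prof.temp_code] * delta * expit(kappa * z)
    resid = y - fitted
    return AltFit(beta1=beta, alpha=alpha, delta=float(delta), kappa=float(kappa),
                  zeta0=float(zeta0), a_slope=float(a), rss1=rss1, nu1=2 * m + 4,
                  converged=converged, n_restarts=n_used, fitted=fitted, residuals=resid)


def f_statistic(rss0: float, rss1: float, d1: int, d2: int) -> float:
    """Nested-model F-statistic (RSS0 - RSS1)/RSS1 * d2/d1.

    A noise-free degenerate fit with RSS1 = 0 yields +inf (flagged by the
    caller); otherwise F >= 0 with equality iff the sigmoid explains nothing.
    """
    if d1 < 1 or d2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if rss1 <= 0.0:
        return np.inf
    return max(rss0 - rss1, 0.0) / rss1 * (d2 / d1)


def effect_size(kappa: float, rss0: float, rss1: float) -> float:
    """Signed effect size sign(kappa) * sqrt(RSS0 - RSS1).

    Positive for stabilized proteins, negative for destabilized ones.  A
    failed nesting (rss0 < rss1) yields magnitude 0.
    """
    diff = rss0 - rss1
    if diff < 0:
        return 0.0
    s = np.sign(kappa) or 1.0
    return float(s * np.sqrt(diff))


def fit_protein(prof: ProfileData, cfg: ModelConfig | None = None,
                y: np.ndarray | None = None) -> ProteinFitResult | None:
    """Fit both models for one protein; ``None`` if residual df < 1."""
    m, p = prof.m_temps, prof.p_obs
    d1 = m + 4
    d2 = p - (2 * m + 4)
    if d2 < 1:
        return None
    null = fit_null(prof, y)
    alt = fit_alternative(prof, cfg, y)
    f = f_statistic(null.rss0, alt.rss1, d1, d2)
    degenerate = not np.isfinite(f)
    es = effect_size(alt.kappa, null.rss0, alt.rss1)
    j_ref = int(np.argmax(alt.alpha))
    t_ref = float(prof.temps[j_ref])
    pec50 = -(alt.zeta0 + alt.a_slope * t_ref)
    return ProteinFitResult(protein_id=prof.protein_id, p_obs=p, m_temps=m,
                            null_fit=null, alt_fit=alt, d1=d1, d2=d2, f_stat=f,
                            effect_size=es, pec50=pec50, t_ref=t_ref,
                            degenerate=degenerate)


@dataclass
class FitResults:
    """Per-protein fits for a dataset plus the pieces the bootstrap reuses."""

    fits: list[ProteinFitResult]
    profiles: list[ProfileData]
    skipped: list[str] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        rows = []
        for r in self.fits:
            rows.append({
                "protein_id": r.protein_id, "p_obs": r.p_obs, "m_temps": r.m_temps,
                "d1": r.d1, "d2": r.d2, "rss0": r.null_fit.rss0, "rss1": r.alt_fit.rss1,
                "f_stat": r.f_stat, "effect_size": r.effect_size,
                "kappa": r.alt_fit.kappa, "delta": r.alt_fit.delta,
                "zeta0": r.alt_fit.zeta0, "a_slope": r.alt_fit.a_slope,
                "pec50": r.pec50, "t_ref": r.t_ref,
                "converged": r.alt_fit.converged,
            })
        return pd.DataFrame(rows)


def fit_dataset(ds: TwoDDataset, cfg: ModelConfig | None = None,
                profiles: list[ProfileData] | None = None) -> FitResults:
    """Fit the nested model pair for every protein in the dataset.

    Proteins with fewer residual degrees of freedom than one
    (p <= 2 m + 4) cannot be tested and are listed in ``skipped``.
    """
    cfg = cfg or ModelConfig()
    profiles = compile_profiles(ds) if profiles is None else profiles
    fits: list[ProteinFitResult] = []
    kept_profiles: list[ProfileData] = []
    skipped: list[str] = []
    for prof in profiles:
        if prof.p_obs == 0:
            skipped.append(prof.protein_id)
            continue
        res = fit_protein(prof, cfg)
        if res is None:
            skipped.append(prof.protein_id)
            continue
        fits.append(res)
        kept_profiles.append(prof)
    if skipped:
        logger.info("%d proteins skipped (insufficient residual df or no data)", len(skipped))
    return FitResults(fits=fits, profiles=kept_profiles, skipped=skipped)
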