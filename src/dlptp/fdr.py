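"""Bootstrap null calibration and stratified FDR estimation.

The nested-model F-statistic has no analytically known null
distribution for these fits, so it is calibrated empirically: for each
protein, residuals of the alternative fit are resampled with
replacement strictly within each MS run (noise levels differ between
runs) and added back to the null-model fitted values.  Refitting both
models on the resampled profile yields one null statistic per protein
per bootstrap round; the moderation hyperparameters are re-estimated on
every bootstrap dataset so the null statistics reflect the full
pipeline.

Proteins are stratified by their number of non-missing measurements D
via gamma(D) = floor(D/10 + 1/2), because missingness in 2D-TPP is
non-random (proteins denature out of the top temperatures).  Within a
stratum g, for a threshold theta,

    FDRhat_g(theta) = pi0hat_g(theta)
        * sum_b #{F0b >= theta in g} / (B * #{F >= theta in g})
    pi0hat_g(theta) = B * #{F < theta in g} / sum_b #{F0b < theta in g},

both clipped to [0, 1].  Candidate thresholds are the observed
statistics; a conservative sweep from the largest statistic downward
(cumulative maximum) makes the per-protein FDR monotone non-increasing
in the statistic before hits are called.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .models import FitResults, ModelConfig, fit_alternative, fit_null, f_statistic
from .moderation import merge_small_strata, moderate_stats

logger = logging.getLogger("dlptp")


def gamma_group(p_obs) -> np.ndarray:
    """Measurement-count stratum gamma(D) = floor(D/10 + 1/2)."""
    p = np.asarray(p_obs, dtype=float)
    if np.any(p < 1):
        raise ValueError("number of measurements must be >= 1")
    g = np.floor(p / 10.0 + 0.5).astype(int)
    return g if g.ndim else int(g)


def bootstrap_null_stats(fit_results: FitResults, B: int, seed: int = 0,
                         cfg: ModelConfig | None = None,
                         min_stratum_size: int = 10,
                         checkpoint: str | Path | None = None,
                         checkpoint_every: int = 10) -> dict[str, np.ndarray]:
    """Generate B bootstrap rounds of null F-statistics for every protein.

    Returns ``{"standard": (B, P) array, "moderated": (B, P) array}``
    in the protein order of ``fit_results.fits``.  With ``checkpoint``
    set, partial results are written every ``checkpoint_every`` rounds
    and reloaded on rerun with the same seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    cfg = cfg or ModelConfig()
    fits, profiles = fit_results.fits, fit_results.profiles
    P = len(fits)
    f_std = np.full((B, P), np.nan)
    f_mod = np.full((B, P), np.nan)
    start_b = 0

    ckpt = Path(checkpoint) if checkpoint else None
    if ckpt and ckpt.exists():
        saved = np.load(ckpt)
        if int(saved["seed"]) == seed and saved["f_std"].shape == (B, P):
            done = int(saved["done"])
            f_std[:done] = saved["f_std"][:done]
            f_mod[:done] = saved["f_mod"][:done]
            start_b = done
            logger.info("resuming bootstrap from round %d", start_b)

    # independent child streams per bootstrap round keep rounds reproducible
    # regardless of checkpoint/resume boundaries
    children = np.random.SeedSequence(seed).spawn(B)
    d1 = np.array([r.d1 for r in fits])
    d2 = np.array([r.d2 for r in fits])
    strata = gamma_group([r.p_obs for r in fits])

    for b in range(start_b, B):
        rng = np.random.default_rng(children[b])
        rss0_b = np.empty(P)
        rss1_b = np.empty(P)
        for i, (res, prof) in enumerate(zip(fits, profiles)):
            resid = res.alt_fit.residuals
            idx = np.empty(prof.p_obs, dtype=np.intp)
            for r_code in range(prof.runs.size):
                rows = np.flatnonzero(prof.run_code == r_code)
                idx[rows] = rows[rng.integers(0, rows.size, rows.size)]
            y_star = res.null_fit.fitted + resid[idx]
            nf = fit_null(prof, y_star)
            af = fit_alternative(prof, cfg, y_star)
            rss0_b[i] = nf.rss0
            rss1_b[i] = af.rss1
        with np.errstate(divide="ignore", invalid="ignore"):
            f_std[b] = np.where(rss1_b > 0,
                                np.maximum(rss0_b - rss1_b, 0.0) / rss1_b * (d2 / d1),
                                np.inf)
        tab = pd.DataFrame({"rss0": rss0_b, "rss1": rss1_b, "d1": d1, "d2": d2})
        tab_mod, _ = moderate_stats(tab, strata=strata, min_stratum_size=min_stratum_size)
        f_mod[b] = tab_mod["f_mod"].to_numpy()
        if ckpt and ((b + 1) % checkpoint_every == 0 or b + 1 == B):
            np.savez(ckpt, f_std=f_std, f_mod=f_mod, done=b + 1, seed=seed)
    return {"standard": f_std, "moderated": f_mod}


def pi0_hat(theta: float, observed_f: np.ndarray, null_f: np.ndarray, B: int) -> float:
    """Estimated true-null proportion at threshold theta (clipped to [0, 1]).

    ``null_f`` pools all bootstrap rounds of the group; a zero
    denominator returns the conservative value 1.
    """
    n_obs_lt = int(np.sum(observed_f < theta))
    n_null_lt = int(np.sum(null_f < theta))
    if n_null_lt == 0:
        return 1.0
    return float(np.clip(B * n_obs_lt / n_null_lt, 0.0, 1.0))


def fdr_hat(theta: float, observed_f: np.ndarray, null_f: np.ndarray, B: int,
            pi0: float | None = None) -> float:
    """Bootstrap FDR estimate at threshold theta (clipped to [0, 1]).

    Ties with theta count as exceedances.  With no observed exceedance
    the estimate is undefined and 1 is returned.
    """
    if pi0 is None:
        pi0 = pi0_hat(theta, observed_f, null_f, B)
    n_obs_ge = int(np.sum(observed_f >= theta))
    if n_obs_ge == 0:
        return 1.0
    n_null_ge = int(np.sum(null_f >= theta))
    return float(np.clip(pi0 * n_null_ge / (B * n_obs_ge), 0.0, 1.0))


def estimate_fdr(observed_f: np.ndarray, null_f: np.ndarray, p_obs: np.ndarray,
                 min_group_size: int = 20) -> pd.DataFrame:
    """Per-protein FDR estimates on the grid of observed statistics.

    ``null_f`` has shape (B, P).  Proteins are grouped by gamma(p_obs)
    (groups below ``min_group_size`` merged with the nearest group);
    within each group the FDR is evaluated at every observed statistic
    and monotonized by a cumulative minimum from the top statistic down.
    """
    observed_f = np.asarray(observed_f, dtype=float)
    B, P = null_f.shape
    if observed_f.size != P:
        raise ValueError("observed and null statistics disagree in length")
    groups = merge_small_strata(gamma_group(p_obs), min_group_size)
    fdr = np.full(P, np.nan)
    pi0 = np.full(P, np.nan)
    for g in np.unique(groups):
        sel = np.flatnonzero(groups == g)
        obs_g = observed_f[sel]
        null_g = np.sort(null_f[:, sel].ravel())
        n_g, n_null = obs_g.size, null_g.size
        obs_sorted = np.sort(obs_g)
        # counts via binary search on the pooled sorted null
        n_null_ge = n_null - np.searchsorted(null_g, obs_g, side="left")
        n_null_lt = n_null - n_null_ge
        n_obs_ge = n_g - np.searchsorted(obs_sorted, obs_g, side="left")
        n_obs_lt = n_g - n_obs_ge
        with np.errstate(divide="ignore", invalid="ignore"):
            pi0_g = np.where(n_null_lt > 0, B * n_obs_lt / np.maximum(n_null_lt, 1), 1.0)
            pi0_g = np.clip(pi0_g, 0.0, 1.0)
            fdr_g = np.clip(pi0_g * n_null_ge / (B * n_obs_ge), 0.0, 1.0)
        # monotone FDR: sweep thresholds from the top statistic downward and
        # carry the running maximum, so each protein reports the worst
        # estimate among thresholds at least as stringent as its own
        # statistic.  This keeps the per-protein FDR non-increasing in the
        # statistic and immunizes the estimate against the degenerate
        # pi0(theta) -> 0 behaviour at the lowest observed thresholds.
        order = np.argsort(-obs_g, kind="stable")
        fdr_g[order] = np.maximum.accumulate(fdr_g[order])
        fdr[sel] = fdr_g
        pi0[sel] = pi0_g
    return pd.DataFrame({"group": groups, "f_obs": observed_f, "pi0": pi0, "fdr": fdr})


def call_hits(results: pd.DataFrame, alpha: float = 0.10) -> pd.DataFrame:
    """Flag hits at nominal FDR ``alpha``; direction from the effect-size sign.

    ``results`` must carry ``fdr`` and ``effect_size`` columns.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    out = results.copy()
    out["hit"] = out["fdr"] <= alpha
    direction = np.where(out["effect_size"] >= 0, "stabilized", "destabilized")
    out["direction"] = np.where(out["hit"], direction, "")
    return out


def run_fdr_pipeline(fit_results: FitResults, B: int = 100, seed: int = 0,
                     alpha: float = 0.10, mode: str = "moderated",
                     cfg: ModelConfig | None = None,
                     min_group_size: int = 20,
                     null_stats: dict[str, np.ndarray] | None = None,
                     checkpoint: str | Path | None = None) -> pd.DataFrame:
    """Observed statistics + bootstrap null + FDR + hit calls in one sweep.

    ``mode`` selects the plain ("standard") or moderated F-statistic.
    Precomputed ``null_stats`` (from :func:`bootstrap_null_stats`) may
    be passed to evaluate both modes without redoing the bootstrap.
    """
    if mode not in ("standard", "moderated"):
        raise ValueError("mode must be 'standard' or 'moderated'")
    table = fit_results.table()
    strata = gamma_group(table["p_obs"].to_numpy())
    table, _ = moderate_stats(table, strata=strata)
    if null_stats is None:
        null_stats = bootstrap_null_stats(fit_results, B=B, seed=seed, cfg=cfg,
                                          checkpoint=checkpoint)
    stat_col = "f_stat" if mode == "standard" else "f_mod"
    observed = table[stat_col].to_numpy()
    res = estimate_fdr(observed, null_stats[mode], table["p_obs"].to_numpy(),
                       min_group_size=min_group_size)
    out = pd.concat([table.reset_index(drop=True), res.drop(columns=["f_obs"])], axis=1)
    return call_hits(out, alpha=alpha)
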