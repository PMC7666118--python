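"""Synthetic benchmark: null + spike-in profiles, comparator, FDR/TPR curves.

The benchmark emulates a 2D-TPP screen in which most proteins do not
respond to the ligand.  Null profiles have a melting-curve-shaped
per-temperature baseline, identical across concentrations, plus
independent Gaussian noise with a protein-specific standard deviation
drawn from a log-normal (median 0.08 log2 units, geometric SD 1.5, the
magnitude seen in real screens).  True-positive profiles add a sigmoid
concentration response from the alternative model with amplitudes that
grow towards high temperatures.  Ground-truth labels let observed FDR
and TPR be measured against nominal FDR for the statistical method and
for the legacy fixed-threshold rule.

What this generator does not emulate: TMT channel cross-talk,
carry-over between consecutive runs, correlated (non-Gaussian) noise,
and the fact that real spike-ins are real profiles with messier shapes.
Calibration results transfer to real data only to that extent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit

from .data import TwoDDataset, add_log10_conc, assign_runs, filter_min_observations
from .fdr import bootstrap_null_stats, call_hits, estimate_fdr, gamma_group
from .models import ModelConfig, fit_dataset
from .moderation import moderate_stats

logger = logging.getLogger("dlptp")

#: default 12-temperature gradient (deg C) of a 2D-TPP screen
DEFAULT_TEMPERATURES = (42.0, 44.1, 46.2, 48.1, 50.4, 51.9, 54.0, 56.1,
                        58.2, 60.1, 62.4, 63.9)
#: default concentration series in mol/L (vehicle + 4 doses)
DEFAULT_CONCS = (0.0, 4e-8, 2.9e-7, 2e-6, 1e-5)


@dataclass
class BenchmarkSpec:
    """Generator parameters for the null + spike-in benchmark dataset."""

    n_null: int = 5000
    n_tp: int = 80
    temperatures: tuple = DEFAULT_TEMPERATURES
    concs: tuple = DEFAULT_CONCS
    conc_offset: float = 2.0
    # noise: protein-level sigma ~ LogNormal(log median, log gsd)
    noise_median: float = 0.08
    noise_gsd: float = 1.5
    # baseline melting curve
    base_level: tuple = (8.0, 12.0)        # uniform range of low-T log2 level
    tm_range: tuple = (48.0, 58.0)         # melting midpoint, deg C
    melt_slope: tuple = (0.3, 0.8)         # 1/deg C
    plateau: tuple = (0.02, 0.2)           # residual soluble fraction
    # run-level missingness: probability of dropping the top 0/1/2 runs
    drop_run_probs: tuple = (0.6, 0.25, 0.15)
    cell_missing_rate: float = 0.02
    # spike-in effect ranges
    delta_range: tuple = (0.5, 3.0)        # log2 units, excludes 0
    kappa_range: tuple = (2.0, 20.0)       # magnitude per log10 conc unit
    pec50_range: tuple = (5.3, 7.0)        # within the tested dose range
    a_range: tuple = (-0.01, 0.01)         # inflection drift per deg C
    frac_stabilized: float = 0.8
    alpha_midpoint: tuple = (48.0, 56.0)   # temperature of half-maximal response
    alpha_width: tuple = (1.0, 4.0)
    B: int = 100
    seeds: tuple = (1, 2, 3)


#: full-scale conditions and a desk-scale variant for quick runs
PRESETS = {
    "paper": BenchmarkSpec(),
    "ci": BenchmarkSpec(n_null=1000, n_tp=40, B=20, seeds=(1,)),
}


def _baselines(spec: BenchmarkSpec, rng: np.random.Generator) -> np.ndarray:
    T = np.asarray(spec.temperatures)
    y0 = rng.uniform(*spec.base_level)
    tm = rng.uniform(*spec.tm_range)
    k = rng.uniform(*spec.melt_slope)
    pl = rng.uniform(*spec.plateau)
    frac = (1.0 - pl) * expit(k * (tm - T)) + pl
    return y0 + np.log2(frac)


def _emit_rows(rows: list, pid: str, spec: BenchmarkSpec, y_grid: np.ndarray,
               rng: np.random.Generator) -> None:
    """Append long-format rows for one protein, applying run dropout."""
    T = np.asarray(spec.temperatures)
    n_runs = (T.size + 1) // 2
    n_drop = rng.choice(len(spec.drop_run_probs), p=spec.drop_run_probs)
    keep_temps = T.size - 2 * n_drop
    miss = rng.random(y_grid.shape) < spec.cell_missing_rate
    for j in range(keep_temps):
        for k, conc in enumerate(spec.concs):
            val = np.nan if miss[j, k] else y_grid[j, k]
            rows.append((pid, T[j], conc, val))


def generate_null_profiles(spec: BenchmarkSpec, seed: int, start_index: int = 0,
                           n: int | None = None, prefix: str = "null") -> TwoDDataset:
    """Simulate profiles with no concentration effect (noise around baselines)."""
    rng = np.random.default_rng(seed)
    n = spec.n_null if n is None else n
    T = np.asarray(spec.temperatures)
    rows: list = []
    for i in range(n):
        beta = _baselines(spec, rng)
        sigma = rng.lognormal(np.log(spec.noise_median), np.log(spec.noise_gsd))
        y = beta[:, None] + rng.normal(0.0, sigma, (T.size, len(spec.concs)))
        _emit_rows(rows, f"{prefix}_{start_index + i:05d}", spec, y, rng)
    df = pd.DataFrame(rows, columns=["protein_id", "temperature", "conc", "log2_value"])
    df = add_log10_conc(df, spec.conc_offset)
    df = assign_runs(df)
    return TwoDDataset(df)


def generate_tp_profiles(spec: BenchmarkSpec, seed: int) -> tuple[TwoDDataset, pd.DataFrame]:
    """Simulate true-positive profiles from the sigmoid response model.

    Effect sizes are drawn from ``delta_range`` (which excludes zero, so
    every labelled positive genuinely differs from the null), slopes
    from ``kappa_range`` with sign set by ``frac_stabilized``, and the
    response amplitude alpha rises sigmoidally towards high
    temperatures.  Returns the dataset and the true parameters.
    """
    if spec.delta_range[0] <= 0:
        raise ValueError("delta_range must exclude 0 (profiles would be null)")
    rng = np.random.default_rng(seed)
    T = np.asarray(spec.temperatures)
    c_nonzero = np.log10(np.array([c for c in spec.concs if c > 0]))
    c = np.concatenate([[c_nonzero.min() - spec.conc_offset], c_nonzero])
    t_mid = float(T.mean())
    rows: list = []
    truth_rows: list = []
    for i in range(spec.n_tp):
        pid = f"tp_{i:05d}"
        beta = _baselines(spec, rng)
        sigma = rng.lognormal(np.log(spec.noise_median), np.log(spec.noise_gsd))
        delta = rng.uniform(*spec.delta_range)
        kappa = rng.uniform(*spec.kappa_range)
        stab = rng.random() < spec.frac_stabilized
        if not stab:
            kappa = -kappa
        pec50 = rng.uniform(*spec.pec50_range)
        a = rng.uniform(*spec.a_range)
        zeta0 = -pec50 - a * t_mid          # inflection hits -pEC50 mid-gradient
        alpha = expit((T - rng.uniform(*spec.alpha_midpoint)) / rng.uniform(*spec.alpha_width))
        zeta_t = zeta0 + a * T
        resp = alpha[:, None] * delta * expit(kappa * (c[None, :] - zeta_t[:, None]))
        y = beta[:, None] + resp + rng.normal(0.0, sigma, (T.size, c.size))
        _emit_rows(rows, pid, spec, y, rng)
        truth_rows.append({"protein_id": pid, "is_tp": True, "delta": delta,
                           "kappa": kappa, "pec50": pec50, "a_slope": a,
                           "sigma": sigma, "stabilized": stab})
    df = pd.DataFrame(rows, columns=["protein_id", "temperature", "conc", "log2_value"])
    df = add_log10_conc(df, spec.conc_offset)
    df = assign_runs(df)
    return TwoDDataset(df), pd.DataFrame(truth_rows)


def generate_benchmark(spec: BenchmarkSpec, seed: int) -> tuple[TwoDDataset, pd.DataFrame]:
    """Null profiles plus labelled spike-ins and the ground-truth table."""
    ss = np.random.SeedSequence(seed).spawn(2)
    null_ds = generate_null_profiles(spec, ss[0].generate_state(1)[0] % 2**31)
    tp_ds, truth_tp = generate_tp_profiles(spec, ss[1].generate_state(1)[0] % 2**31)
    df = pd.concat([null_ds.df, tp_ds.df], ignore_index=True)
    truth = pd.DataFrame({"protein_id": null_ds.proteins, "is_tp": False})
    truth = pd.concat([truth, truth_tp[["protein_id", "is_tp"]]], ignore_index=True)
    return TwoDDataset(df), truth


# -- legacy threshold comparator ---------------------------------------


def _loglogistic_r2(c: np.ndarray, fc: np.ndarray) -> float:
    """R^2 of a 3-parameter log-logistic fit of fold change vs log10 conc.

    The lower asymptote is anchored at the vehicle level 1; plateau,
    slope and inflection are free.  Returns -inf when unfittable.
    """
    if c.size < 4 or not np.all(np.isfinite(fc)):
        return -np.inf

    def resid(p):
        top, k, z = p
        return 1.0 + (top - 1.0) * expit(k * (c - z)) - fc

    p0 = np.array([fc[-1], 2.0, float(np.median(c))])
    try:
        sol = least_squares(resid, p0, method="lm", max_nfev=200)
    except Exception:
        return -np.inf
    rss = float(np.sum(sol.fun ** 2))
    tss = float(np.sum((fc - fc.mean()) ** 2))
    if tss <= 0:
        return -np.inf
    return 1.0 - rss / tss


def threshold_comparator(ds: TwoDDataset, r2_min: float = 0.8,
                         fc_min: float = 1.5) -> pd.DataFrame:
    """Legacy fixed-threshold hit rule on per-temperature dose-response fits.

    A protein is flagged when two consecutive observed temperatures both
    yield a log-logistic dose-response fit with R^2 > ``r2_min`` and a
    fold change of at least ``fc_min`` (or at most 1/``fc_min``) at the
    highest tested concentration relative to vehicle.
    """
    out_rows = []
    df = ds.df.dropna(subset=["log2_value"])
    vehicle_conc = df["conc"].min()
    max_conc = df["conc"].max()
    for pid, sub in df.groupby("protein_id", sort=True):
        temps = np.sort(sub["temperature"].unique())
        ok = np.zeros(temps.size, dtype=bool)
        for j, t in enumerate(temps):
            st = sub[sub["temperature"] == t].sort_values("log10_conc")
            veh = st.loc[st["conc"] == vehicle_conc, "log2_value"]
            top = st.loc[st["conc"] == max_conc, "log2_value"]
            if veh.empty or top.empty:
                continue
            fc_top = float(2.0 ** (top.iloc[0] - veh.iloc[0]))
            if max(fc_top, 1.0 / fc_top) < fc_min:
                continue
            fc = (2.0 ** (st["log2_value"] - veh.iloc[0])).to_numpy()
            r2 = _loglogistic_r2(st["log10_conc"].to_numpy(), fc)
            ok[j] = r2 > r2_min
        hit = bool(np.any(ok[:-1] & ok[1:]))
        out_rows.append({"protein_id": pid, "hit": hit})
    return pd.DataFrame(out_rows)


# -- evaluation ---------------------------------------------------------


def confusion(hits: pd.Series, truth: pd.Series) -> dict:
    """Observed FDR and TPR of a boolean hit call against ground truth."""
    hits = hits.astype(bool)
    truth = truth.astype(bool)
    tp = int((hits & truth).sum())
    fp = int((hits & ~truth).sum())
    n_tp_total = int(truth.sum())
    n_hits = tp + fp
    obs_fdr = fp / n_hits if n_hits > 0 else 0.0
    tpr = tp / n_tp_total if n_tp_total > 0 else 0.0
    return {"n_hits": n_hits, "tp": tp, "fp": fp, "observed_fdr": obs_fdr, "tpr": tpr}


def tpr_fdr_curve(score: np.ndarray, truth: np.ndarray) -> pd.DataFrame:
    """Observed TPR vs observed FDR by sweeping a score threshold downward."""
    order = np.argsort(-np.asarray(score, dtype=float), kind="stable")
    t = np.asarray(truth, dtype=bool)[order]
    tp = np.cumsum(t)
    fp = np.cumsum(~t)
    with np.errstate(invalid="ignore"):
        fdr = fp / np.maximum(tp + fp, 1)
    tpr = tp / max(int(t.sum()), 1)
    return pd.DataFrame({"observed_fdr": fdr, "tpr": tpr})


def evaluate(hit_tables: dict[str, pd.DataFrame], truth: pd.DataFrame,
             levels=(0.01, 0.05, 0.10)) -> pd.DataFrame:
    """Observed FDR / TPR per method and nominal level.

    ``hit_tables`` maps a method name to a per-protein table with
    ``protein_id``, ``fdr`` (may be absent for threshold methods) and
    ``hit`` columns.  Truth labels must cover every scored protein.
    """
    truth_map = truth.set_index("protein_id")["is_tp"]
    rows = []
    for method, tab in hit_tables.items():
        missing = set(tab["protein_id"]) - set(truth_map.index)
        if missing:
            raise ValueError(f"truth labels missing for {len(missing)} proteins")
        is_tp = tab["protein_id"].map(truth_map)
        if "fdr" in tab.columns:
            for lev in levels:
                conf = confusion(tab["fdr"] <= lev, is_tp)
                rows.append({"method": method, "nominal_fdr": lev, **conf})
        else:
            conf = confusion(tab["hit"], is_tp)
            rows.append({"method": method, "nominal_fdr": np.nan, **conf})
    return pd.DataFrame(rows)


def evaluate_dataset(ds: TwoDDataset, truth: pd.DataFrame, B: int, seed: int,
                     alpha: float = 0.10, levels=(0.01, 0.05, 0.10),
                     cfg: ModelConfig | None = None,
                     with_comparator: bool = True,
                     min_obs: int = 20) -> dict:
    """Evaluate all methods on a labelled dataset.

    Returns a dict with the per-method summary table (``summary``), the
    per-protein result tables, the truth labels, and TPR-FDR curves.
    """
    ds = filter_min_observations(ds, min_obs=min_obs)
    fits = fit_dataset(ds, cfg)
    table = fits.table()
    strata = gamma_group(table["p_obs"].to_numpy())
    table, _ = moderate_stats(table, strata=strata)
    null_stats = bootstrap_null_stats(fits, B=B, seed=seed, cfg=cfg)

    hit_tables: dict[str, pd.DataFrame] = {}
    curves: dict[str, pd.DataFrame] = {}
    truth_map = truth.set_index("protein_id")["is_tp"]
    for mode, col in (("standard", "f_stat"), ("moderated", "f_mod")):
        res = estimate_fdr(table[col].to_numpy(), null_stats[mode],
                           table["p_obs"].to_numpy())
        full = pd.concat([table.reset_index(drop=True),
                          res.drop(columns=["f_obs"])], axis=1)
        hit_tables[mode] = call_hits(full, alpha=alpha)
        curves[mode] = tpr_fdr_curve(full[col].to_numpy(),
                                     full["protein_id"].map(truth_map).to_numpy())
    if with_comparator:
        hit_tables["threshold"] = threshold_comparator(ds)
    summary = evaluate(hit_tables, truth, levels=levels)
    return {"summary": summary, "hit_tables": hit_tables, "truth": truth,
            "curves": curves, "dataset": ds, "fit_table": table}


def run_benchmark(spec: BenchmarkSpec, seed: int, alpha: float = 0.10,
                  levels=(0.01, 0.05, 0.10), cfg: ModelConfig | None = None,
                  with_comparator: bool = True, min_obs: int = 20) -> dict:
    """Generate one benchmark dataset per ``spec`` and evaluate all methods."""
    ds, truth = generate_benchmark(spec, seed)
    return evaluate_dataset(ds, truth, B=spec.B, seed=seed, alpha=alpha,
                            levels=levels, cfg=cfg,
                            with_comparator=with_comparator, min_obs=min_obs)
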