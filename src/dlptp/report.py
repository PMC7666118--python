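"""Result tables for volcano and q-q diagnostics.

The volcano representation puts the signed effect size
sign(kappa) * sqrt(RSS0 - RSS1) on the x-axis (how much extra variance
the dose-response model explains, signed by direction) and
log2(F + 1) on the y-axis; the +1 keeps the transform bounded as the
statistic approaches 0.  The q-q table compares the observed statistics
with the pooled bootstrap null: under a pure null the quantile pairs lie
on the diagonal, and true positives push the top quantiles above it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def volcano_table(results: pd.DataFrame, stat_col: str = "f_mod") -> pd.DataFrame:
    """Volcano-plot coordinates from a per-protein result table."""
    f = results[stat_col].to_numpy(dtype=float)
    out = pd.DataFrame({
        "protein_id": results["protein_id"],
        "effect_size": results["effect_size"],
        "log2_f_plus_1": np.log2(f + 1.0),
    })
    for extra in ("fdr", "hit", "direction", "pec50"):
        if extra in results.columns:
            out[extra] = results[extra].to_numpy()
    return out


def make_qq_table(observed_f: np.ndarray, null_f: np.ndarray,
                  n_quantiles: int | None = None) -> pd.DataFrame:
    """Matched quantiles of observed vs bootstrap-null statistics."""
    obs = np.asarray(observed_f, dtype=float).ravel()
    nul = np.asarray(null_f, dtype=float).ravel()
    obs = obs[np.isfinite(obs)]
    nul = nul[np.isfinite(nul)]
    if obs.size == 0 or nul.size == 0:
        raise ValueError("both statistic vectors must be non-empty")
    n = n_quantiles or min(obs.size, 1000)
    probs = (np.arange(n) + 0.5) / n
    return pd.DataFrame({
        "prob": probs,
        "null_quantile": np.quantile(nul, probs),
        "observed_quantile": np.quantile(obs, probs),
    })
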