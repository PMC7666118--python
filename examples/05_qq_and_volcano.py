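"""Diagnostic tables: q-q of observed vs bootstrap-null statistics, volcano.

On a small screen with spiked targets, the bulk of the observed
moderated F-statistics should match the bootstrap null distribution
(quantile pairs near the diagonal) while the top quantiles, carrying the
true positives, lift above it.  The volcano table pairs each protein's
signed effect size with log2(F + 1).
"""

import numpy as np

from dlptp.benchmark import BenchmarkSpec, generate_benchmark
from dlptp.data import filter_min_observations
from dlptp.fdr import bootstrap_null_stats, gamma_group
from dlptp.models import fit_dataset
from dlptp.moderation import moderate_stats
from dlptp.report import make_qq_table, volcano_table

spec = BenchmarkSpec(n_null=80, n_tp=8, B=5)
ds, truth = generate_benchmark(spec, seed=2)
fits = fit_dataset(filter_min_observations(ds))
table, _ = moderate_stats(fits.table(), strata=gamma_group(fits.table()["p_obs"]))
null_stats = bootstrap_null_stats(fits, B=5, seed=2)

qq = make_qq_table(table["f_mod"].to_numpy(), null_stats["moderated"])
bulk = qq[qq["prob"] < 0.9]
dev = (bulk["observed_quantile"] - bulk["null_quantile"]).abs().median()
print(f"median |observed - null| quantile deviation (bulk): {dev:.3f}")
top = qq.iloc[-1]
print(f"top quantile: observed {top['observed_quantile']:.1f} vs "
      f"null {top['null_quantile']:.1f} (spike-ins lift the tail)")

volcano = volcano_table(table)
print(volcano.nlargest(5, "log2_f_plus_1")[["protein_id", "effect_size",
                                            "log2_f_plus_1"]].to_string(index=False))
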