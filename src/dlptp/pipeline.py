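"""End-to-end detection pipeline and run artifacts.

``run_detect`` strings the stages together: import -> observation
filter -> nested model fits -> variance moderation -> run-aware
bootstrap -> stratified FDR -> hit calls, and writes the result tables
(fits, moderation report, per-protein results, volcano and q-q tables)
plus a manifest that fully determines a reproducible rerun.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .data import TwoDDataset, filter_min_observations, import_dataset
from .fdr import bootstrap_null_stats, call_hits, estimate_fdr, gamma_group
from .models import ModelConfig, fit_dataset
from .moderation import moderate_stats, moderation_report
from .report import make_qq_table, volcano_table

logger = logging.getLogger("dlptp")


@dataclass
class RunConfig:
    """Configuration of one detection run."""

    input_path: str
    output_dir: str = "dlptp_out"
    mode: str = "moderated"
    alpha: float = 0.10
    B: int = 100
    seed: int = 0
    min_obs: int = 20
    conc_offset: float = 2.0
    exclude_runs: list = field(default_factory=list)
    column_map: dict = field(default_factory=dict)
    runs: dict | None = None
    model: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.mode not in ("standard", "moderated"):
            raise ValueError("mode must be 'standard' or 'moderated'")

    @classmethod
    def from_yaml(cls, cfg: dict, **overrides) -> "RunConfig":
        model = ModelConfig(**cfg.pop("model", {}))
        known = {k: v for k, v in cfg.items() if k in cls.__dataclass_fields__}
        known.update({k: v for k, v in overrides.items() if v is not None})
        known["model"] = model
        return cls(**known)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_detect(config: RunConfig, dataset: TwoDDataset | None = None) -> dict:
    """Run the full detection pipeline and write result artifacts.

    Returns the result bundle (result table, fit table, moderation
    report, volcano and q-q tables, manifest).  Any stage failure
    surfaces as an exception naming the stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "mode": config.mode, "alpha": config.alpha, "B": config.B,
                      "config_hash": _config_hash(config), "stages": {}}

    def stage(name):
        logger.info("stage: %s", name)
        manifest["stages"][name] = {"t_start": time.time()}
        return time.time()

    try:
        t = stage("import")
        if dataset is None:
            dataset = import_dataset(config.input_path, {
                "column_map": config.column_map, "runs": config.runs,
                "exclude_runs": config.exclude_runs, "conc_offset": config.conc_offset,
            })
        manifest["stages"]["import"]["n_proteins"] = int(len(dataset.proteins))

        t = stage("filter")
        ds = filter_min_observations(dataset, min_obs=config.min_obs)
        manifest["stages"]["filter"]["n_proteins"] = int(len(ds.proteins))

        t = stage("fit")
        fits = fit_dataset(ds, config.model)
        manifest["stages"]["fit"]["n_fitted"] = len(fits.fits)
        manifest["stages"]["fit"]["n_skipped"] = len(fits.skipped)

        t = stage("moderate")
        table = fits.table()
        strata = gamma_group(table["p_obs"].to_numpy())
        table, params = moderate_stats(table, strata=strata)

        t = stage("bootstrap")
        null_stats = bootstrap_null_stats(
            fits, B=config.B, seed=config.seed, cfg=config.model,
            checkpoint=out / "bootstrap_checkpoint.npz")

        t = stage("fdr")
        stat_col = "f_stat" if config.mode == "standard" else "f_mod"
        res = estimate_fdr(table[stat_col].to_numpy(), null_stats[config.mode],
                           table["p_obs"].to_numpy())
        results = pd.concat([table.reset_index(drop=True),
                             res.drop(columns=["f_obs"])], axis=1)
        results = call_hits(results, alpha=config.alpha)
        manifest["stages"]["fdr"]["n_hits"] = int(results["hit"].sum())
    except Exception as exc:  # annotate with the failing stage
        failed = [k for k, v in manifest["stages"].items() if "t_end" not in v]
        raise RuntimeError(f"pipeline stage '{failed[-1] if failed else '?'}' failed: {exc}") from exc
    finally:
        for v in manifest["stages"].values():
            v.setdefault("t_end", time.time())
            v["seconds"] = round(v["t_end"] - v["t_start"], 3)

    volcano = volcano_table(results, stat_col=stat_col)
    qq = make_qq_table(table[stat_col].to_numpy(), null_stats[config.mode])

    results_cols = ["protein_id", "group", "f_stat", "f_mod", "effect_size",
                    "pec50", "fdr", "hit", "direction"]
    results[results_cols].to_csv(out / "results.tsv", sep="\t", index=False)
    fits.table().to_csv(out / "fits.tsv", sep="\t", index=False)
    moderation_report(params).to_csv(out / "moderation.tsv", sep="\t", index=False)
    volcano.to_csv(out / "volcano.tsv", sep="\t", index=False)
    qq.to_csv(out / "qq.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    return {"results": results, "fit_table": table, "moderation": params,
            "volcano": volcano, "qq": qq, "manifest": manifest,
            "null_stats": null_stats, "fits": fits}
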