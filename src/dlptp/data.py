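"""Canonical data model and I/O for 2D thermal proteome profiling tables.

A 2D-TPP experiment measures soluble protein abundance on a grid of
``m`` temperatures x ``n`` ligand concentrations (including a vehicle
control at concentration 0).  Each multiplexed MS run covers all
concentrations at two adjacent temperatures.  The canonical in-memory
representation is a tidy :class:`pandas.DataFrame` wrapped in
:class:`TwoDDataset`, one row per (protein, temperature, concentration)
with a log2 signal intensity that may be missing (NaN) but is never a
fabricated zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("dlptp")

#: canonical column order of a long-format 2D-TPP table
CANONICAL_COLUMNS = [
    "protein_id",
    "temperature",
    "conc",
    "log10_conc",
    "ms_run",
    "log2_value",
    "n_peptides",
]

RAW_COLUMNS = ["protein_id", "temperature", "conc", "sum_intensity", "rel_fc", "n_peptides"]


class ValidationError(ValueError):
    """Raised when an input table violates the 2D-TPP data contract."""


@dataclass
class TwoDDataset:
    """Tidy long-format table of per-protein log2 intensities.

    Parameters
    ----------
    df
        DataFrame with columns ``protein_id, temperature, conc,
        log10_conc, ms_run, log2_value`` and optionally ``n_peptides``.
        ``conc`` is molar on the original scale; ``log10_conc`` is the
        working coordinate (vehicle handled by an offset convention, see
        :func:`add_log10_conc`).  Missing intensities are NaN.
    """

    df: pd.DataFrame
    filter_report: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS[:-1] if c not in self.df.columns]
        if missing:
            raise ValidationError(f"missing required columns: {missing}")
        if "n_peptides" not in self.df.columns:
            self.df = self.df.assign(n_peptides=pd.array([pd.NA] * len(self.df), dtype="Int64"))
        self.df = self.df[CANONICAL_COLUMNS].reset_index(drop=True)

    # -- basic geometry -------------------------------------------------
    @property
    def proteins(self) -> np.ndarray:
        return self.df["protein_id"].unique()

    @property
    def temperatures(self) -> np.ndarray:
        return np.sort(self.df["temperature"].unique())

    @property
    def concentrations(self) -> np.ndarray:
        return np.sort(self.df["conc"].unique())

    @property
    def runs(self) -> np.ndarray:
        return np.sort(self.df["ms_run"].unique())

    def n_observations(self) -> pd.Series:
        """Number of non-missing values p_i per protein."""
        return self.df.dropna(subset=["log2_value"]).groupby("protein_id", sort=False).size()

    def validate(self) -> "TwoDDataset":
        """Check structural invariants; raise :class:`ValidationError` on failure."""
        dup = self.df.duplicated(subset=["protein_id", "temperature", "conc"])
        if dup.any():
            bad = self.df.loc[dup, ["protein_id", "temperature", "conc"]].head(5)
            raise ValidationError(f"duplicate (protein, temperature, conc) keys, e.g.\n{bad}")
        # a temperature belongs to exactly one MS run
        t2r = self.df.groupby("temperature")["ms_run"].nunique()
        if (t2r > 1).any():
            bad_t = t2r.index[t2r > 1].tolist()
            raise ValidationError(f"temperatures mapped to multiple MS runs: {bad_t}")
        # each run covers its temperatures crossed with all concentrations
        n_conc = len(self.concentrations)
        cover = self.df.groupby(["protein_id", "ms_run", "temperature"])["conc"].nunique()
        if (cover != n_conc).any():
            bad = cover.index[cover != n_conc][:5].tolist()
            raise ValidationError(
                f"runs not fully crossed with the concentration grid, e.g. {bad}"
            )
        if np.isinf(self.df["log2_value"].to_numpy(dtype=float, na_value=np.nan)).any():
            raise ValidationError("log2_value contains infinities; mark missing values as NaN")
        return self

    def exclude_runs(self, runs: list[str]) -> "TwoDDataset":
        """Drop all rows of the listed MS runs (generic per-run QC exclusion)."""
        keep = ~self.df["ms_run"].isin(runs)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("excluding %d rows from runs %s", n_dropped, runs)
        return TwoDDataset(self.df.loc[keep].reset_index(drop=True))


def assign_runs(df: pd.DataFrame, runs: dict[str, list[float]] | None = None) -> pd.DataFrame:
    """Attach an ``ms_run`` column mapping temperatures to MS runs.

    When ``runs`` is not given, consecutive temperature pairs in
    ascending order form one run each (the standard TMT labelling scheme
    in which one label set covers all concentrations at two adjacent
    temperatures).
    """
    temps = np.sort(df["temperature"].unique())
    if runs is None:
        runs = {f"run{i // 2 + 1}": temps[i : i + 2].tolist() for i in range(0, len(temps), 2)}
    t2r: dict[float, str] = {}
    for run, ts in runs.items():
        for t in ts:
            if t in t2r:
                raise ValidationError(f"temperature {t} assigned to runs {t2r[t]} and {run}")
            t2r[t] = run
    unmapped = sorted(set(temps) - set(t2r))
    if unmapped:
        raise ValidationError(f"temperatures without an MS run assignment: {unmapped}")
    return df.assign(ms_run=df["temperature"].map(t2r))


def add_log10_conc(df: pd.DataFrame, conc_offset: float = 2.0) -> pd.DataFrame:
    """Add the log10 working coordinate for concentration.

    The vehicle control (conc == 0) has no logarithm; it is placed
    ``conc_offset`` decades below the smallest nonzero concentration so
    it sits on the lower asymptote of any sigmoid in the tested range.
    """
    conc = df["conc"].to_numpy(dtype=float)
    if (conc < 0).any():
        raise ValidationError("negative concentrations")
    nonzero = conc[conc > 0]
    if nonzero.size == 0:
        raise ValidationError("no nonzero concentrations")
    floor = np.log10(nonzero.min()) - conc_offset
    with np.errstate(divide="ignore"):
        lc = np.where(conc > 0, np.log10(np.where(conc > 0, conc, 1.0)), floor)
    return df.assign(log10_conc=lc)


def compute_log2_intensity(raw: pd.DataFrame, conc_offset: float = 2.0,
                           runs: dict[str, list[float]] | None = None) -> TwoDDataset:
    """Derive per-condition log2 intensities from raw sums and fold changes.

    For protein *i* in condition *u* the log2 intensity is
    ``y_iu = log2((r_iu / sum_l r_il) * sum_l s_il)`` where ``r`` are the
    robust fold-change estimates relative to the control condition and
    ``s`` the per-condition sum intensities.  Conditions whose fold
    change was supported by at most one peptide are marked missing
    rather than kept as unreliable numbers.
    """
    missing = [c for c in RAW_COLUMNS[:-1] if c not in raw.columns]
    if missing:
        raise ValidationError(f"raw table missing columns: {missing}")
    r = raw["rel_fc"].to_numpy(dtype=float)
    s = raw["sum_intensity"].to_numpy(dtype=float)
    if np.nanmin(r) < 0 or np.nanmin(s) < 0:
        raise ValidationError("rel_fc and sum_intensity must be nonnegative")

    out = raw.copy()
    grp = out.groupby("protein_id", sort=False)
    r_tot = grp["rel_fc"].transform(lambda x: np.nansum(x))
    s_tot = grp["sum_intensity"].transform(lambda x: np.nansum(x))
    dead = r_tot <= 0
    if dead.any():
        dropped = out.loc[dead, "protein_id"].unique().tolist()
        logger.warning("dropping %d proteins with all-zero fold changes: %s",
                       len(dropped), dropped[:10])
        out = out.loc[~dead].reset_index(drop=True)
        r, r_tot, s_tot = (a[~dead.to_numpy()] for a in (r, r_tot.to_numpy(), s_tot.to_numpy()))
    else:
        r_tot, s_tot = r_tot.to_numpy(), s_tot.to_numpy()
    if (s_tot <= 0).any():
        raise ValidationError("sum of sum_intensity must be positive per protein")

    with np.errstate(divide="ignore"):
        y = np.log2(r / r_tot * s_tot)
    y[r <= 0] = np.nan
    npep = out.get("n_peptides")
    if npep is not None:
        y = np.where(npep.to_numpy(dtype=float, na_value=np.inf) <= 1, np.nan, y)
    out = out.assign(log2_value=y).drop(columns=["rel_fc", "sum_intensity"])
    out = add_log10_conc(out, conc_offset=conc_offset)
    out = assign_runs(out, runs)
    return TwoDDataset(out[CANONICAL_COLUMNS].copy())


def observation_report(ds: TwoDDataset) -> pd.DataFrame:
    """Per-protein counts of non-missing values, temperatures and concentrations."""
    obs = ds.df.dropna(subset=["log2_value"])
    g = obs.groupby("protein_id", sort=False)
    rep = pd.DataFrame({
        "p_obs": g.size(),
        "n_temps": g["temperature"].nunique(),
        "n_concs": g["conc"].nunique(),
    })
    return rep.reset_index()


def filter_min_observations(ds: TwoDDataset, min_obs: int = 20) -> TwoDDataset:
    """Retain proteins with at least ``min_obs`` non-missing measurements.

    The default of 20 corresponds, on a full 12 x 5 grid, to coverage of
    at least four temperatures and five concentrations; proteins that
    pass the count but violate that design intent (fewer than 4
    temperatures or 5 concentrations observed) are flagged in the
    attached ``filter_report``.
    """
    rep = observation_report(ds)
    rep["retained"] = rep["p_obs"] >= min_obs
    rep["design_flag"] = rep["retained"] & ((rep["n_temps"] < 4) | (rep["n_concs"] < 5))
    keep = set(rep.loc[rep["retained"], "protein_id"])
    if not keep:
        logger.warning("no protein passes the >=%d observation filter", min_obs)
    out = ds.df[ds.df["protein_id"].isin(keep)].reset_index(drop=True)
    return TwoDDataset(out, filter_report=rep)


# -- file I/O -----------------------------------------------------------


def load_config(path: str | Path) -> dict:
    """Load a YAML analysis configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return cfg


def import_dataset(path: str | Path, config: dict | None = None) -> TwoDDataset:
    """Read a TSV/CSV table into a validated :class:`TwoDDataset`.

    ``config`` keys (all optional): ``column_map`` (file column -> canonical
    name), ``runs`` (run name -> list of temperatures), ``exclude_runs``,
    ``conc_offset``.  Tables in raw mode (``sum_intensity``/``rel_fc``
    columns) are converted via :func:`compute_log2_intensity`.
    """
    config = config or {}
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    colmap = config.get("column_map") or {}
    df = df.rename(columns=colmap)
    runs = config.get("runs")
    conc_offset = float(config.get("conc_offset", 2.0))

    if "rel_fc" in df.columns and "log2_value" not in df.columns:
        ds = compute_log2_intensity(df, conc_offset=conc_offset, runs=runs)
    else:
        need = {"protein_id", "temperature", "conc", "log2_value"}
        missing = sorted(need - set(df.columns))
        if missing:
            raise ValidationError(f"{path.name}: missing columns {missing}")
        if "log10_conc" not in df.columns:
            df = add_log10_conc(df, conc_offset=conc_offset)
        if "ms_run" not in df.columns:
            df = assign_runs(df, runs)
        if "n_peptides" not in df.columns:
            df["n_peptides"] = pd.array([pd.NA] * len(df), dtype="Int64")
        ds = TwoDDataset(df[CANONICAL_COLUMNS].copy())
    ds = ds.validate()
    for key, col in (("temperature_grid", "temperature"), ("conc_grid", "conc")):
        grid = config.get(key)
        if grid is not None:
            extra = sorted(set(ds.df[col].unique()) - set(float(g) for g in grid))
            if extra:
                raise ValidationError(f"{col} values outside declared {key}: {extra}")
    excl = config.get("exclude_runs") or []
    if excl:
        ds = ds.exclude_runs(list(excl))
    return ds


def export_dataset(ds: TwoDDataset, path: str | Path) -> None:
    """Write the canonical table as UTF-8 TSV (round-trips through import)."""
    ds.df.to_csv(path, sep="\t", index=False, float_format="%.12g")
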