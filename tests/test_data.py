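"""Preprocessing: log2-intensity derivation, QC filtering, import/export."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dlptp.data import (
    ValidationError,
    add_log10_conc,
    compute_log2_intensity,
    export_dataset,
    filter_min_observations,
    import_dataset,
)
from conftest import CONCS_M, TEMPS, make_dataset, flat_profile


def raw_table(proteins: dict[str, tuple[np.ndarray, np.ndarray]],
              n_peptides: int = 5) -> pd.DataFrame:
    """Raw-mode table from {pid: (rel_fc grid, sum_intensity grid)}; grids
    are flat arrays over a temps x concs subset starting at the grid origin."""
    rows = []
    for pid, (r, s) in proteins.items():
        conds = [(t, c) for t in TEMPS for c in CONCS_M[::-1]][: len(r)]
        for (t, c), ri, si in zip(conds, r, s):
            rows.append((pid, t, c, si, ri, n_peptides))
    return pd.DataFrame(rows, columns=["protein_id", "temperature", "conc",
                                       "sum_intensity", "rel_fc", "n_peptides"])


class TestComputeLog2Intensity:
    @pytest.mark.parametrize("r, s, expected", [
        ([1.0], [8.0], [3.0]),                       # single condition: log2(s)
        ([1.0, 1.0], [4.0, 4.0], [2.0, 2.0]),        # symmetric split of the total
        ([1.0, 3.0], [10.0, 30.0], [np.log2(10.0), np.log2(30.0)]),
    ])
    def test_printed_formula(self, r, s, expected):
        ds = compute_log2_intensity(raw_table({"p1": (np.array(r), np.array(s))}))
        got = ds.df["log2_value"].to_numpy()  # input row order is preserved
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_single_peptide_entries_marked_missing(self):
        tab = raw_table({"p1": (np.array([1.0, 3.0]), np.array([10.0, 30.0]))})
        tab.loc[1, "n_peptides"] = 1
        ds = compute_log2_intensity(tab)
        vals = ds.df["log2_value"]
        assert np.isfinite(vals.iloc[0])
        assert np.isnan(vals.iloc[1])

    def test_all_zero_fold_changes_drop_protein(self, caplog):
        tab = raw_table({
            "dead": (np.zeros(2), np.array([5.0, 5.0])),
            "live": (np.array([1.0, 1.0]), np.array([4.0, 4.0])),
        })
        ds = compute_log2_intensity(tab)
        assert set(ds.proteins) == {"live"}

    def test_negative_inputs_rejected(self):
        tab = raw_table({"p1": (np.array([1.0, -0.5]), np.array([4.0, 4.0]))})
        with pytest.raises(ValidationError):
            compute_log2_intensity(tab)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3),
           r=st.lists(st.floats(min_value=0.05, max_value=20), min_size=2, max_size=5))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_invariant_under_fold_change_rescaling(self, scale, r):
        """The r-ratio normalizes any positive rescaling of a protein's fold changes."""
        r = np.asarray(r)
        s = np.linspace(5.0, 10.0, r.size)
        y1 = compute_log2_intensity(raw_table({"p": (r, s)})).df["log2_value"]
        y2 = compute_log2_intensity(raw_table({"p": (scale * r, s)})).df["log2_value"]
        np.testing.assert_allclose(y1, y2, rtol=1e-9)


class TestFilterMinObservations:
    def _dataset_with_counts(self, counts):
        grids = {}
        rng = np.random.default_rng(0)
        for pid, n_obs in counts.items():
            g = flat_profile(rng)
            flat = g.ravel()
            flat[n_obs:] = np.nan
            grids[pid] = flat.reshape(g.shape)
        return make_dataset(grids)

    def test_survivor_counts(self):
        ds = self._dataset_with_counts({"a": 60, "b": 20, "c": 12})
        out = filter_min_observations(ds, min_obs=20)
        assert set(out.proteins) == {"a", "b"}
        rep = out.filter_report.set_index("protein_id")
        assert not rep.loc["c", "retained"]
        assert rep.loc["a", "p_obs"] == 60

    def test_threshold_is_inclusive(self):
        ds = self._dataset_with_counts({"x": 19})
        assert len(filter_min_observations(ds, min_obs=20).proteins) == 0

    def test_idempotent(self):
        ds = self._dataset_with_counts({"a": 60, "b": 25, "c": 5})
        once = filter_min_observations(ds)
        twice = filter_min_observations(once)
        pd.testing.assert_frame_equal(once.df.reset_index(drop=True),
                                      twice.df.reset_index(drop=True))

    def test_design_intent_flag(self):
        # 20 observations over 4 temperatures x 5 concentrations meet the
        # design intent; 20 observations with a concentration missing
        # everywhere pass the count but are flagged
        ok = np.full((12, 5), np.nan)
        ok[:4, :] = 10.0
        flagged = np.full((12, 5), np.nan)
        flagged[:5, :4] = 10.0  # 20 obs, only 4 distinct concentrations
        ds = make_dataset({"ok": ok, "flagged": flagged})
        rep = filter_min_observations(ds).filter_report.set_index("protein_id")
        assert not rep.loc["ok", "design_flag"]
        assert rep.loc["flagged", "design_flag"]


class TestImportExport:
    def test_round_trip(self, tmp_path, rng):
        ds = make_dataset({"a": flat_profile(rng), "b": flat_profile(rng)})
        p = tmp_path / "ds.tsv"
        export_dataset(ds, p)
        back = import_dataset(p)
        pd.testing.assert_frame_equal(
            ds.df.reset_index(drop=True), back.df.reset_index(drop=True),
            check_exact=False, atol=1e-12, check_dtype=False)

    def test_geometry_of_well_formed_table(self, tmp_path, rng):
        ds = make_dataset({"a": flat_profile(rng)})
        p = tmp_path / "ds.tsv"
        export_dataset(ds, p)
        back = import_dataset(p)
        assert back.temperatures.size == 12
        assert back.concentrations.size == 5
        assert back.runs.size == 6  # one MS run per adjacent temperature pair

    def test_duplicate_key_named_in_error(self, tmp_path, rng):
        ds = make_dataset({"a": flat_profile(rng)})
        df = pd.concat([ds.df, ds.df.iloc[[0]]], ignore_index=True)
        p = tmp_path / "dup.tsv"
        df.to_csv(p, sep="\t", index=False)
        with pytest.raises(ValidationError, match="duplicate"):
            import_dataset(p)

    def test_exclude_run_drops_its_two_temperatures(self, tmp_path, rng):
        ds = make_dataset({"a": flat_profile(rng)})
        p = tmp_path / "ds.tsv"
        export_dataset(ds, p)
        run = ds.df["ms_run"].iloc[0]
        n_run_rows = int((ds.df["ms_run"] == run).sum())
        out = import_dataset(p, {"exclude_runs": [run]})
        assert len(out.df) == len(ds.df) - n_run_rows
        assert out.temperatures.size == 10

    def test_missing_columns_rejected(self, tmp_path):
        pd.DataFrame({"protein_id": ["a"], "temperature": [42.0]}).to_csv(
            tmp_path / "bad.tsv", sep="\t", index=False)
        with pytest.raises(ValidationError, match="missing columns"):
            import_dataset(tmp_path / "bad.tsv")


class TestVehicleConvention:
    def test_vehicle_placed_below_lowest_dose(self):
        df = pd.DataFrame({"conc": [0.0, 1e-6, 1e-5]})
        out = add_log10_conc(df, conc_offset=2.0)
        np.testing.assert_allclose(out["log10_conc"], [-8.0, -6.0, -5.0])

    def test_offset_configurable(self):
        df = pd.DataFrame({"conc": [0.0, 1e-6]})
        out = add_log10_conc(df, conc_offset=3.0)
        assert out["log10_conc"].iloc[0] == pytest.approx(-9.0)
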