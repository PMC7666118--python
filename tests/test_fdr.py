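"""Bootstrap null calibration and FDR estimation."""

import numpy as np
import pandas as pd
import pytest

from dlptp.fdr import (
    bootstrap_null_stats,
    call_hits,
    estimate_fdr,
    fdr_hat,
    gamma_group,
    pi0_hat,
    run_fdr_pipeline,
)
from dlptp.models import fit_dataset
from conftest import flat_profile, make_dataset, sigmoid_profile


@pytest.fixture(scope="module")
def small_fits():
    rng = np.random.default_rng(123)
    grids = {f"null_{i:02d}": flat_profile(rng) for i in range(10)}
    ds = make_dataset(grids)
    return fit_dataset(ds)


class TestGammaGroup:
    @pytest.mark.parametrize("d, g", [(20, 2), (25, 3), (34, 3), (60, 6), (14, 1)])
    def test_floor_formula(self, d, g):
        assert gamma_group(d) == g

    def test_vectorized(self):
        np.testing.assert_array_equal(gamma_group([20, 25, 34]), [2, 3, 3])

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            gamma_group(0)


class TestPi0Hat:
    def test_identical_distributions(self):
        f = np.arange(1, 11, dtype=float)
        assert pi0_hat(5.0, f, f, B=1) == 1.0

    def test_counting_example_unity(self):
        obs = np.concatenate([np.zeros(95), np.full(5, 10.0)])
        nul = np.concatenate([np.zeros(950), np.full(50, 10.0)])
        assert pi0_hat(1.0, obs, nul, B=10) == pytest.approx(1.0)

    def test_counting_example_fractional(self):
        obs = np.concatenate([np.zeros(40), np.full(60, 10.0)])
        nul = np.concatenate([np.zeros(500), np.full(500, 10.0)])
        assert pi0_hat(1.0, obs, nul, B=10) == pytest.approx(0.8)

    def test_zero_denominator_conservative(self):
        assert pi0_hat(-1.0, np.array([1.0]), np.array([1.0]), B=1) == 1.0


class TestFdrHat:
    def test_documented_counting_example(self):
        # pi0 = 0.8, 40 null exceedances over B = 10, 5 observed -> 0.64
        obs = np.concatenate([np.zeros(5), np.full(5, 10.0)])
        nul = np.concatenate([np.zeros(60), np.full(40, 10.0)])
        assert fdr_hat(1.0, obs, nul, B=10, pi0=0.8) == pytest.approx(0.64)

    def test_null_without_exceedances(self):
        assert fdr_hat(1.0, np.array([2.0, 3.0]), np.zeros(10), B=5) == 0.0

    def test_threshold_below_everything_returns_pi0(self):
        obs = np.array([1.0, 2.0, 3.0])
        nul = np.array([1.0, 2.0, 3.0])
        assert fdr_hat(0.0, obs, nul, B=1, pi0=0.77) == pytest.approx(0.77)

    def test_no_observed_exceedance_flagged_one(self):
        assert fdr_hat(99.0, np.array([1.0]), np.array([1.0]), B=1) == 1.0


class TestBootstrapNull:
    def test_shape_contract(self, small_fits):
        ns = bootstrap_null_stats(small_fits, B=2, seed=0)
        assert ns["standard"].shape == (2, 10)
        assert ns["moderated"].shape == (2, 10)
        assert np.all(np.isfinite(ns["standard"]))

    def test_zero_residuals_give_zero_statistics(self):
        grids = {f"p{i}": flat_profile(np.random.default_rng(i), sigma=0.0)
                 for i in range(5)}
        fits = fit_dataset(make_dataset(grids))
        ns = bootstrap_null_stats(fits, B=2, seed=0)
        # noise-free null data: resampled profiles are exactly the null fit
        np.testing.assert_allclose(ns["standard"], 0.0, atol=1e-6)

    def test_resampled_values_stay_within_run(self, small_fits, monkeypatch):
        """Every resampled observation equals null fit + a residual observed
        in the same MS run of the same protein (membership property)."""
        import dlptp.fdr as fdr_mod
        captured = []
        orig = fdr_mod.fit_null

        def spy(prof, y=None):
            if y is not None:
                captured.append((prof, y.copy()))
            return orig(prof, y)

        monkeypatch.setattr(fdr_mod, "fit_null", spy)
        bootstrap_null_stats(small_fits, B=2, seed=5)
        by_id = {p.protein_id: (r, p) for r, p in
                 zip(small_fits.fits, small_fits.profiles)}
        assert captured
        for prof, y_star in captured:
            res, _ = by_id[prof.protein_id]
            eps = y_star - res.null_fit.fitted
            for w in range(prof.runs.size):
                rows = prof.run_code == w
                allowed = np.round(res.alt_fit.residuals[rows], 10)
                got = np.round(eps[rows], 10)
                assert np.all(np.isin(got, allowed))

    def test_deterministic_given_seed(self, small_fits):
        a = bootstrap_null_stats(small_fits, B=2, seed=9)
        b = bootstrap_null_stats(small_fits, B=2, seed=9)
        np.testing.assert_array_equal(a["standard"], b["standard"])
        np.testing.assert_array_equal(a["moderated"], b["moderated"])

    def test_checkpoint_resume(self, small_fits, tmp_path):
        ck = tmp_path / "boot.npz"
        full = bootstrap_null_stats(small_fits, B=4, seed=3)
        partial = bootstrap_null_stats(small_fits, B=4, seed=3, checkpoint=ck,
                                       checkpoint_every=2)
        resumed = bootstrap_null_stats(small_fits, B=4, seed=3, checkpoint=ck,
                                       checkpoint_every=2)
        np.testing.assert_allclose(full["standard"], partial["standard"])
        np.testing.assert_allclose(full["standard"], resumed["standard"])

    def test_rejects_invalid_b(self, small_fits):
        with pytest.raises(ValueError):
            bootstrap_null_stats(small_fits, B=0)


class TestEstimateFdrAndHits:
    def _toy(self, rng, n_null=60, n_sig=5, B=10):
        obs = np.concatenate([rng.chisquare(2, n_null), np.full(n_sig, 60.0)])
        null = rng.chisquare(2, (B, n_null + n_sig))
        p_obs = np.full(n_null + n_sig, 60)
        return obs, null, p_obs

    def test_monotone_fdr_in_statistic(self, rng):
        obs, null, p_obs = self._toy(rng)
        res = estimate_fdr(obs, null, p_obs)
        order = np.argsort(obs)
        assert np.all(np.diff(res["fdr"].to_numpy()[order]) <= 1e-12)

    def test_clear_signal_detected_null_not(self, rng):
        obs, null, p_obs = self._toy(rng)
        res = call_hits(estimate_fdr(obs, null, p_obs).assign(
            effect_size=np.ones_like(obs)), alpha=0.10)
        assert res["hit"].to_numpy()[-5:].all()
        assert res.loc[res["f_obs"] < np.median(obs), "hit"].sum() == 0

    def test_hits_nested_across_alpha(self, rng):
        obs, null, p_obs = self._toy(rng)
        base = estimate_fdr(obs, null, p_obs).assign(effect_size=1.0)
        strict = call_hits(base, alpha=0.01)["hit"]
        loose = call_hits(base, alpha=0.10)["hit"]
        assert np.all(loose[strict])

    def test_direction_labels(self, rng):
        obs, null, p_obs = self._toy(rng)
        es = np.ones_like(obs)
        es[-1] = -2.0
        res = call_hits(estimate_fdr(obs, null, p_obs).assign(effect_size=es))
        assert res["direction"].iloc[-1] == "destabilized"
        assert res["direction"].iloc[-2] == "stabilized"

    def test_groups_respected(self, rng):
        # two measurement-count groups get independent calibrations
        obs = np.concatenate([rng.chisquare(2, 50), rng.chisquare(2, 50) * 10])
        null = np.concatenate([rng.chisquare(2, (5, 50)),
                               rng.chisquare(2, (5, 50)) * 10], axis=1)
        p_obs = np.array([30] * 50 + [60] * 50)
        res = estimate_fdr(obs, null, p_obs, min_group_size=20)
        assert set(res["group"]) == {3, 6}
        # scaling by 10 in group 6 should not inflate its FDR estimates
        assert res.loc[res["group"] == 6, "fdr"].median() == pytest.approx(
            res.loc[res["group"] == 3, "fdr"].median(), abs=0.35)


class TestAllNullPipeline:
    def test_few_or_no_hits_on_pure_null(self):
        """On null-only data at 10% FDR the hit count stays a trivial handful."""
        total_hits = 0
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            grids = {f"n{i:02d}": flat_profile(rng) for i in range(40)}
            fits = fit_dataset(make_dataset(grids))
            res = run_fdr_pipeline(fits, B=5, seed=seed, alpha=0.10, mode="standard")
            total_hits += int(res["hit"].sum())
        assert total_hits <= 6

    def test_identical_seed_identical_hit_table(self):
        rng = np.random.default_rng(5)
        grids = {f"n{i:02d}": flat_profile(rng) for i in range(12)}
        grids["tp"] = sigmoid_profile(np.random.default_rng(6), delta=2.0, sigma=0.03)
        ds = make_dataset(grids)
        r1 = run_fdr_pipeline(fit_dataset(ds), B=3, seed=11, mode="moderated")
        r2 = run_fdr_pipeline(fit_dataset(ds), B=3, seed=11, mode="moderated")
        pd.testing.assert_frame_equal(r1, r2)
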