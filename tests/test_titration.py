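import numpy as np
import pytest
from scipy.stats import norm

from phlinkage.ensemble import (ProtonationEnsemble, ProtonationTrajectory,
                                site_metadata_frame)
from phlinkage.exact import enumerate_equilibrium, exact_site_curves
from phlinkage.sampling import sample_ensemble
from phlinkage.testsystems import coupled_pair
from phlinkage.titration import (TitrationCurve, bootstrap_ci, fit_hill,
                                 global_curve, hill_curve, residue_curve)


def exact_curve_as_titration(pH, means, subject="exact"):
    """Wrap a noise-free curve in a TitrationCurve with zero-width CIs."""
    means = np.asarray(means, float)
    return TitrationCurve(subject=subject, pH=np.asarray(pH, float),
                          mean=means, ci_lo=means.copy(), ci_hi=means.copy(),
                          n_replicates=np.ones(means.size, int),
                          degenerate_ci=True)


def constant_ensemble(value, n_sites=2, n_frames=50, pH_grid=(4.0, 5.0)):
    sites = site_metadata_frame([f"s{i}" for i in range(n_sites)],
                                ["M"] * n_sites, ["lumenal"] * n_sites)
    ens = ProtonationEnsemble(system="monomer", sites=sites)
    for ph in pH_grid:
        for rep in range(3):
            ens.add(ProtonationTrajectory(
                system="monomer", pH=ph, replicate=rep,
                states=np.full((n_frames, n_sites), value, dtype=np.int8)))
    return ens


class TestResidueCurve:
    def test_constant_data_gives_mean_one_and_zero_width_ci(self):
        ens = constant_ensemble(1)
        curve = residue_curve(ens, "s0", chain_policy="single-chain")
        np.testing.assert_array_equal(curve.mean, 1.0)
        np.testing.assert_array_equal(curve.ci_hi - curve.ci_lo, 0.0)

    def test_single_site_curve_tracks_henderson_hasselbalch(self, single_site):
        grid = np.arange(3.0, 8.1, 0.5)
        ens = sample_ensemble(single_site, grid, n_replicates=5,
                              n_frames=20_000, seed=41)
        curve = residue_curve(ens, "Glu", chain_policy="single-chain",
                              n_boot=500, seed=1)
        truth = 1.0 / (1.0 + 10.0 ** (grid - 4.25))
        hw = np.maximum(curve.half_width, 2e-3)
        assert np.all(np.abs(curve.mean - truth) < 4 * hw)

    def test_average_chains_is_arithmetic_mean_of_chain_curves(self, toy_sampled):
        _, dim = toy_sampled
        avg = residue_curve(dim, "Glu173", chain_policy="average-chains")
        a = residue_curve(dim, "Glu173", chain_policy="single-chain", chain="A")
        b = residue_curve(dim, "Glu173", chain_policy="single-chain", chain="B")
        np.testing.assert_allclose(avg.mean, (a.mean + b.mean) / 2.0,
                                   atol=1e-12)

    def test_missing_site_raises(self, toy_sampled):
        mon, _ = toy_sampled
        with pytest.raises(KeyError):
            residue_curve(mon, "GluNope")


class TestGlobalCurve:
    def test_additivity_of_per_site_curves(self, sampled_pair_ensemble):
        """The global curve equals the stoichiometry-scaled sum of the
        per-site curves to machine precision on the same ensemble."""
        ens = sampled_pair_ensemble
        g = global_curve(ens, stoichiometry_factor=2.0)
        per_site = [residue_curve(ens, lab, chain_policy="single-chain").mean
                    for lab in ens.sites["label"]]
        np.testing.assert_allclose(g.mean, 2.0 * np.sum(per_site, axis=0),
                                   atol=1e-12)

    def test_saturated_data_gives_flat_curve_at_n_sites(self):
        ens = constant_ensemble(1, n_sites=3)
        g = global_curve(ens)
        np.testing.assert_array_equal(g.mean, 3.0)

    def test_global_curve_matches_enumeration_sum(self, mixed_six_site):
        ens = sample_ensemble(mixed_six_site, [5.0], n_replicates=6,
                              n_frames=50_000, seed=43)
        g = global_curve(ens)
        exact_total = enumerate_equilibrium(mixed_six_site, 5.0).mean.sum()
        reps = ens.replicate_site_means(5.0).sum(axis=1)
        se = max(reps.std(ddof=1) / np.sqrt(6), 1e-3)
        assert abs(g.mean[0] - exact_total) < 4 * se

    def test_empty_subset_rejected(self, sampled_pair_ensemble):
        with pytest.raises(ValueError, match="empty"):
            global_curve(sampled_pair_ensemble,
                         subset={"labels": ["nothing"]})


class TestHillFit:
    def test_exact_single_site_curve_recovers_reference_pka(self):
        """An exact aqueous-glutamate curve (pKa 4.25) on grid 3-8 step 0.25
        returns pKa = 4.25 and h = 1 to 1e-6."""
        grid = np.arange(3.0, 8.0 + 1e-9, 0.25)
        curve = exact_curve_as_titration(grid, hill_curve(grid, 4.25, 1.0))
        fit = fit_hill(curve)
        assert fit.converged and not fit.low_confidence
        assert fit.pka == pytest.approx(4.25, abs=1e-6)
        assert fit.hill_h == pytest.approx(1.0, abs=1e-6)

    def test_cooperative_curve_parameters_recovered(self):
        grid = np.arange(3.0, 8.0 + 1e-9, 0.25)
        curve = exact_curve_as_titration(grid, hill_curve(grid, 5.0, 2.0))
        fit = fit_hill(curve)
        assert fit.pka == pytest.approx(5.0, abs=1e-6)
        assert fit.hill_h == pytest.approx(2.0, abs=1e-6)

    def test_coupling_sign_sets_cooperativity_direction(self):
        """Positive coupling (double protonation penalized) flattens the
        per-site curve: h < 1; negative coupling sharpens it: h > 1."""
        grid = np.arange(3.0, 8.0 + 1e-9, 0.25)
        for energy, check in [(+2.5, lambda h: h < 0.95),
                              (-2.5, lambda h: h > 1.05)]:
            model = coupled_pair(5.0, 5.0, energy)
            means = exact_site_curves(model, grid)[:, 0]
            fit = fit_hill(exact_curve_as_titration(grid, means))
            assert fit.converged and check(fit.hill_h), (energy, fit.hill_h)

    def test_curve_not_crossing_half_flagged_low_confidence(self):
        grid = np.arange(3.0, 8.0 + 1e-9, 0.5)
        curve = exact_curve_as_titration(grid, hill_curve(grid, 10.5, 1.0))
        fit = fit_hill(curve)
        assert fit.low_confidence and "0.5" in fit.reason

    def test_too_few_points_rejected(self):
        curve = exact_curve_as_titration([4.0, 5.0], [0.6, 0.4])
        with pytest.raises(ValueError, match="3 pH points"):
            fit_hill(curve)


class TestBootstrapCI:
    def test_equal_replicate_means_give_zero_width(self):
        lo, hi, deg = bootstrap_ci(np.full(5, 0.37), n_boot=200, seed=0)
        assert lo == hi == pytest.approx(0.37)
        assert not deg

    def test_single_replicate_flagged_degenerate(self):
        lo, hi, deg = bootstrap_ci(np.array([0.4]), n_boot=200, seed=0)
        assert deg and lo == hi == 0.4

    def test_seed_determinism(self):
        stats = np.random.default_rng(3).normal(size=8)
        a = bootstrap_ci(stats, n_boot=1000, seed=5)
        b = bootstrap_ci(stats, n_boot=1000, seed=5)
        assert a[0] == b[0] and a[1] == b[1]

    def test_interval_width_matches_normal_theory(self):
        """For 10 i.i.d. normal replicate means the 68% percentile bootstrap
        interval width is within 20% of the analytic z * s / sqrt(n) width
        (with the bootstrap's 1/n variance convention)."""
        rng = np.random.default_rng(12)
        stats = rng.normal(loc=2.0, scale=1.0, size=10)
        lo, hi, _ = bootstrap_ci(stats, n_boot=10_000, seed=6)
        s_mle = stats.std(ddof=0)
        z = norm.ppf(0.84)
        analytic = 2.0 * z * s_mle / np.sqrt(10)
        assert (hi - lo) == pytest.approx(analytic, rel=0.2)

    def test_minimum_resample_count_enforced(self):
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_ci(np.ones(3), n_boot=50, seed=0)
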