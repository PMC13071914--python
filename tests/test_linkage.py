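import numpy as np
import pytest

from phlinkage.constants import LN10, kT
from phlinkage.exact import exact_relative_dimerization_energy
from phlinkage.linkage import (bootstrap_profile, delta_protonation,
                               integrate_linkage, linkage_input_from_models,
                               residue_decomposition, screen_key_residues)
from phlinkage.model import build_dimer_model
from phlinkage.sampling import sample_ensemble
from phlinkage.testsystems import (planted_key_residues, toy_dimer,
                                   toy_monomer, uncoupled_single_site)

GRID = np.round(np.arange(3.0, 8.0 + 1e-9, 0.25), 10)


@pytest.fixture(scope="module")
def toy_exact_input(toy_models):
    monomer, dimer = toy_models
    return linkage_input_from_models(monomer, dimer, GRID)


class TestDeltaProtonation:
    def test_independent_copy_dimer_gives_zero(self, independent_copy_dimer):
        monomer, dimer = independent_copy_dimer
        inp = linkage_input_from_models(monomer, dimer, GRID)
        dq = delta_protonation(inp)
        np.testing.assert_allclose(dq.total, 0.0, atol=1e-12)

    def test_single_site_shift_closed_form(self):
        """Monomer pKa 4.25 vs dimer chains at 3.25: dq has the explicit
        two-sigmoid closed form and is negative at all finite pH."""
        monomer = uncoupled_single_site(4.25)
        dimer = build_dimer_model(monomer, interface_pka_shift=[-1.0])
        inp = linkage_input_from_models(monomer, dimer, GRID)
        dq = delta_protonation(inp)
        expected = (2.0 / (1.0 + 10.0 ** (GRID - 3.25))
                    - 2.0 / (1.0 + 10.0 ** (GRID - 4.25)))
        np.testing.assert_allclose(dq.total, expected, atol=1e-12)
        assert np.all(dq.total < 0)

    def test_subset_partition_is_additive(self, toy_exact_input):
        full = delta_protonation(toy_exact_input).total
        lum = delta_protonation(toy_exact_input,
                                {"compartment": "lumenal"}).total
        strom = delta_protonation(toy_exact_input,
                                  {"compartment": "stromal"}).total
        np.testing.assert_allclose(lum + strom, full, atol=1e-12)

    def test_empty_subset_rejected(self, toy_exact_input):
        with pytest.raises(ValueError, match="no residues"):
            delta_protonation(toy_exact_input, {"labels": ["nope"]})


class TestIntegrateLinkage:
    def test_zero_delta_q_gives_flat_zero_profile(self):
        prof = integrate_linkage(np.zeros(GRID.size), GRID, 3.0, 298.15)
        np.testing.assert_array_equal(prof.values, 0.0)

    def test_constant_delta_q_analytic_integral(self):
        """dQ = -1 over pH 3..8 gives ddG(8) = -5 ln(10) kT, with kT computed
        from the temperature at run time."""
        prof = integrate_linkage(-np.ones(GRID.size), GRID, 3.0, 298.15)
        expected = -5.0 * LN10 * kT(298.15)
        assert prof.values[-1] == pytest.approx(expected, rel=1e-12)
        assert prof.values[0] == 0.0

    def test_quadrature_converges_to_partition_function_profile(self):
        """The trapezoid-integrated linkage profile approaches the exact
        free-energy difference, with roughly quadratic step shrinkage."""
        monomer = uncoupled_single_site(4.25)
        dimer = build_dimer_model(monomer, interface_pka_shift=[-1.0])
        errs = {}
        for step in (0.1, 0.05):
            grid = np.round(np.arange(3.0, 8.0 + 1e-9, step), 10)
            inp = linkage_input_from_models(monomer, dimer, grid)
            prof = integrate_linkage(delta_protonation(inp).total, grid, 3.0,
                                     monomer.temperature)
            exact = exact_relative_dimerization_energy(monomer, dimer, grid,
                                                       3.0)
            errs[step] = np.abs(prof.values - exact).max()
        assert errs[0.05] < 1e-3
        assert errs[0.1] / errs[0.05] == pytest.approx(4.0, rel=0.5)

    def test_reference_invariance_is_a_rigid_shift(self, toy_exact_input):
        dq = delta_protonation(toy_exact_input).total
        prof_a = integrate_linkage(dq, toy_exact_input.pH, 3.0, 298.15)
        prof_b = integrate_linkage(dq, toy_exact_input.pH, 5.0, 298.15)
        np.testing.assert_allclose(prof_a.values - prof_a.value_at(5.0),
                                   prof_b.values, atol=1e-12)
        np.testing.assert_allclose(prof_b.values,
                                   prof_a.re_anchor(5.0).values, atol=1e-12)

    def test_off_grid_reference_rejected(self):
        with pytest.raises(ValueError, match="reference pH"):
            integrate_linkage(np.zeros(GRID.size), GRID, 3.1, 298.15)


class TestResidueDecomposition:
    def test_residue_profiles_sum_to_total(self, toy_exact_input):
        total, residues = residue_decomposition(toy_exact_input, ref_pH=3.0)
        stacked = np.sum([p.values for p in residues.values()], axis=0)
        assert np.abs(stacked - total.values).max() < 1e-10

    def test_unshifted_uncoupled_residue_contributes_nothing(self, toy_exact_input):
        _, residues = residue_decomposition(toy_exact_input, ref_pH=3.0)
        np.testing.assert_allclose(residues["Glu78"].values, 0.0, atol=1e-10)

    def test_planted_interface_residues_dominate_lumenal_screen(self, toy_exact_input):
        """Only the three interface-shifted lumenal residues exceed
        1 kcal/mol in the lumenal decomposition of the exact profile."""
        _, residues = residue_decomposition(toy_exact_input, ref_pH=3.0,
                                            subset={"compartment": "lumenal"})
        hits = screen_key_residues(residues, threshold_kcal=1.0)
        assert sorted(l for l, _ in hits) == planted_key_residues()

    def test_direction_of_ph_dependence(self, toy_exact_input):
        """Interface stabilization of deprotonated acids makes the dimer
        progressively more stable at high pH: ddG decreases overall."""
        total, _ = residue_decomposition(toy_exact_input, ref_pH=3.0,
                                         subset={"compartment": "lumenal"})
        assert total.values[-1] < -2.0
        assert total.values[0] == 0.0


class TestScreenKeyResidues:
    def test_flat_decomposition_returns_empty(self, independent_copy_dimer):
        monomer, dimer = independent_copy_dimer
        inp = linkage_input_from_models(monomer, dimer, GRID)
        _, residues = residue_decomposition(inp, ref_pH=3.0)
        assert screen_key_residues(residues, 1.0) == []

    def test_zero_threshold_returns_all_ranked(self, toy_exact_input):
        _, residues = residue_decomposition(toy_exact_input, ref_pH=3.0)
        hits = screen_key_residues(residues, 0.0)
        assert len(hits) == len(residues)
        scores = [s for _, s in hits]
        assert scores == sorted(scores, reverse=True)


class TestBootstrapProfile:
    def test_identical_replicates_give_zero_width_bands(self, independent_copy_dimer):
        """Replicates that are exact copies carry no replicate variance, so
        the bootstrap band collapses onto the point estimate."""
        monomer, dimer = independent_copy_dimer
        grid = np.arange(3.0, 8.1, 1.0)
        mon = sample_ensemble(monomer, grid, 1, 2000, seed=71)
        dim = sample_ensemble(dimer, grid, 1, 2000, seed=72, system="dimer")
        # duplicate the single replicate to fake 3 identical ones
        for ens in (mon, dim):
            for ph in grid:
                t0 = ens.at(ph)[0]
                for rep in (1, 2):
                    t = type(t0)(system=t0.system, pH=t0.pH, replicate=rep,
                                 states=t0.states.copy())
                    ens.add(t)
        boot = bootstrap_profile(mon, dim, ref_pH=3.0, temperature=298.15,
                                 n_boot=200, seed=1)
        np.testing.assert_allclose(boot.total.ci_hi - boot.total.ci_lo, 0.0,
                                   atol=1e-12)

    def test_band_contains_point_estimate_and_is_deterministic(self, toy_sampled):
        mon, dim = toy_sampled
        a = bootstrap_profile(mon, dim, ref_pH=3.0, temperature=298.15,
                              n_boot=300, seed=9)
        b = bootstrap_profile(mon, dim, ref_pH=3.0, temperature=298.15,
                              n_boot=300, seed=9)
        assert np.all(a.total.ci_lo <= a.total.values + 1e-12)
        assert np.all(a.total.values <= a.total.ci_hi + 1e-12)
        np.testing.assert_array_equal(a.total.ci_lo, b.total.ci_lo)
        np.testing.assert_array_equal(a.total.ci_hi, b.total.ci_hi)

    def test_grid_mismatch_rejected(self, toy_models):
        monomer, dimer = toy_models
        mon = sample_ensemble(monomer, [3.0, 4.0], 2, 200, seed=73)
        dim = sample_ensemble(dimer, [3.0, 5.0], 2, 200, seed=74,
                              system="dimer")
        with pytest.raises(ValueError, match="share the pH grid"):
            bootstrap_profile(mon, dim, ref_pH=3.0, temperature=298.15,
                              n_boot=200, seed=0)

    def test_unmatched_sites_reported(self, toy_models):
        monomer, _ = toy_models
        mon = sample_ensemble(monomer, [3.0], 2, 100, seed=75)
        # a "dimer" that is actually a monomer: no A/B chains to match
        fake_dim = sample_ensemble(monomer, [3.0], 2, 100, seed=76,
                                   system="dimer")
        with pytest.raises(ValueError, match="without a unique match"):
            bootstrap_profile(mon, fake_dim, ref_pH=3.0, temperature=298.15,
                              n_boot=200, seed=0)
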