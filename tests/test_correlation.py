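import numpy as np
import pytest

from phlinkage.correlation import (build_network, correlation_time,
                                   ensemble_correlation_times,
                                   pairwise_correlation)
from phlinkage.ensemble import (ProtonationEnsemble, ProtonationTrajectory,
                                site_metadata_frame)
from phlinkage.exact import enumerate_equilibrium
from phlinkage.sampling import sample_ensemble
from phlinkage.testsystems import coupled_pair, uncoupled_single_site


def exact_phi(model, ph, i=0, j=1):
    res = enumerate_equilibrium(model, ph)
    denom = np.sqrt(res.covariance[i, i] * res.covariance[j, j])
    return res.covariance[i, j] / denom


class TestPairwiseCorrelation:
    def test_positive_coupling_gives_negative_phi_matching_oracle(self):
        """A +3 kcal/mol coupling penalizes double protonation, so the binary
        series anticorrelate; the sampled phi matches enumeration."""
        model = coupled_pair(4.5, 4.5, +3.0)
        ph = 4.0   # between the split effective midpoints
        ens = sample_ensemble(model, [ph], n_replicates=6, n_frames=30_000,
                              seed=51)
        cmap = pairwise_correlation(ens, ph)
        truth = exact_phi(model, ph)
        assert truth < -0.1
        # per-replicate phis give an empirical SE for the pooled estimate
        rep_phis = [pairwise_correlation(
            ProtonationEnsemble(system="monomer", sites=ens.sites,
                                trajectories={ph: [t]}), ph).matrix[0, 1]
            for t in ens.at(ph)]
        se = max(np.std(rep_phis, ddof=1) / np.sqrt(6), 1e-3)
        assert abs(cmap.matrix[0, 1] - truth) < 4 * se

    def test_independent_sites_uncorrelated(self, mixed_six_site):
        ens = sample_ensemble(mixed_six_site, [5.0], n_replicates=4,
                              n_frames=30_000, seed=53)
        cmap = pairwise_correlation(ens, 5.0)
        # site 5 is uncoupled from everything
        others = [0, 1, 2, 3, 4]
        assert np.all(np.abs(cmap.matrix[5, others]) < 0.05)

    def test_constant_site_masked_not_zeroed(self):
        sites = site_metadata_frame(["a", "b"], ["M", "M"],
                                    ["lumenal", "lumenal"])
        rng = np.random.default_rng(0)
        states = np.column_stack([np.ones(500, int),
                                  rng.integers(0, 2, 500)])
        ens = ProtonationEnsemble(
            system="monomer", sites=sites,
            trajectories={5.0: [ProtonationTrajectory("monomer", 5.0, 0,
                                                      states)]})
        cmap = pairwise_correlation(ens, 5.0)
        assert not cmap.defined[0, 1] and not cmap.defined[0, 0]
        assert np.isnan(cmap.matrix[0, 1])
        assert cmap.defined[1, 1]

    def test_sign_symmetry_under_coupling_flip(self):
        """Flipping the sign of the planted coupling flips the sign of the
        exact and the sampled correlation at matched pH."""
        ph = 5.4
        for energy in (+2.0, -2.0):
            model = coupled_pair(5.0, 5.0, energy)
            ens = sample_ensemble(model, [ph], n_replicates=3,
                                  n_frames=20_000, seed=57)
            sampled = pairwise_correlation(ens, ph).matrix[0, 1]
            assert np.sign(sampled) == np.sign(exact_phi(model, ph))
            assert np.sign(sampled) == -np.sign(energy)


class TestBuildNetwork:
    def test_subthreshold_map_gives_empty_network(self):
        sites = site_metadata_frame(["a", "b"], ["M", "M"],
                                    ["lumenal", "stromal"])
        from phlinkage.correlation import CorrelationMap
        m = np.array([[1.0, 0.2], [0.2, 1.0]])
        cmap = CorrelationMap(pH=5.0, matrix=m, defined=np.ones((2, 2), bool),
                              n_samples=100)
        net = build_network(cmap, sites, threshold=0.3)
        assert net.edges.empty

    def test_masked_pairs_never_become_edges(self):
        sites = site_metadata_frame(["a", "b"], ["M", "M"],
                                    ["lumenal", "stromal"])
        from phlinkage.correlation import CorrelationMap
        m = np.array([[1.0, 0.9], [0.9, 1.0]])
        defined = np.zeros((2, 2), bool)
        cmap = CorrelationMap(pH=5.0, matrix=np.where(defined, m, np.nan),
                              defined=defined, n_samples=100)
        assert build_network(cmap, sites, threshold=0.3).edges.empty

    def test_cross_compartment_edge_flagged(self):
        """A planted lumen-stroma coupling yields exactly one edge and it is
        flagged cross-compartment."""
        model = coupled_pair(5.0, 5.2, -2.5,
                             compartments=("lumenal", "stromal"))
        ph = 5.8
        ens = sample_ensemble(model, [ph], n_replicates=3, n_frames=20_000,
                              seed=59)
        cmap = pairwise_correlation(ens, ph)
        net = build_network(cmap, ens.sites, threshold=0.3)
        assert len(net.edges) == 1
        edge = net.edges.iloc[0]
        assert bool(edge.cross_compartment)
        assert edge.sign == 1

    def test_threshold_domain_enforced(self):
        sites = site_metadata_frame(["a"], ["M"], ["lumenal"])
        from phlinkage.correlation import CorrelationMap
        cmap = CorrelationMap(pH=5.0, matrix=np.eye(1),
                              defined=np.ones((1, 1), bool), n_samples=10)
        with pytest.raises(ValueError):
            build_network(cmap, sites, threshold=1.5)


class TestCorrelationTime:
    def test_iid_series_has_tau_half(self):
        rng = np.random.default_rng(61)
        traj = ProtonationTrajectory(
            "monomer", 5.0, 0, rng.integers(0, 2, (200_000, 1)))
        ct = correlation_time(traj, 0)
        assert ct.defined
        assert ct.tau_frames == pytest.approx(0.5, abs=0.05)

    def test_two_state_markov_chain_matches_closed_form(self):
        """Symmetric flip probability p per frame gives ACF lambda^t with
        lambda = 1 - 2p and tau = 1/2 + lambda/(1 - lambda)."""
        p = 0.02
        rng = np.random.default_rng(63)
        flips = rng.random(400_000) < p
        x = (np.cumsum(flips) % 2).astype(np.int8)[:, None]
        ct = correlation_time(ProtonationTrajectory("monomer", 5.0, 0, x), 0)
        lam = 1.0 - 2.0 * p
        expected = 0.5 + lam / (1.0 - lam)
        assert ct.tau_frames == pytest.approx(expected, rel=0.10)

    def test_zero_variance_site_undefined_with_reason(self):
        traj = ProtonationTrajectory("monomer", 5.0, 0,
                                     np.ones((1000, 1), dtype=np.int8))
        ct = correlation_time(traj, 0)
        assert not ct.defined and np.isnan(ct.tau_frames)
        assert "variance" in ct.reason

    def test_short_trajectory_rejected(self):
        traj = ProtonationTrajectory("monomer", 5.0, 0,
                                     np.zeros((5, 1), dtype=np.int8))
        with pytest.raises(ValueError, match="10 frames"):
            correlation_time(traj, 0)

    def test_tau_scales_inversely_with_flip_attempt_rate(self):
        """A decade in flip_attempt_prob changes tau by the rate ratio within
        a factor of 2 (sampler compared against itself across settings)."""
        model = uncoupled_single_site(5.0)
        taus = {}
        for p in (0.03, 0.3):
            ens = sample_ensemble(model, [5.0], n_replicates=4,
                                  n_frames=100_000, seed=67,
                                  flip_attempt_prob=np.array([p]))
            taus[p] = correlation_time(ens.at(5.0), 0).tau_frames
        ratio = taus[0.03] / taus[0.3]
        assert 5.0 < ratio < 20.0

    def test_strongly_coupled_sites_slower_than_isolated(self):
        """With uniform attempt rates, sites locked into strong correlations
        decorrelate more slowly than isolated sites at the same pH."""
        import numpy as np
        from phlinkage.model import SiteModel
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = -3.0
        model = SiteModel(pka_int=[5.0, 5.2, 5.1], coupling=w,
                          labels=("a", "b", "lone"), chain=("M",) * 3,
                          compartment=("lumenal",) * 3)
        ens = sample_ensemble(model, [5.8], n_replicates=4, n_frames=50_000,
                              seed=69)
        taus = [ct.tau_frames for ct in ensemble_correlation_times(ens, 5.8)]
        assert min(taus[0], taus[1]) > 1.5 * taus[2]
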