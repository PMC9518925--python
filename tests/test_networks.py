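"""Network generator: topologies, strengths, baselines, host ensembles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from glvnet.networks import (
    InteractionMatrix,
    StrengthDistribution,
    TopologySpec,
    edge_list,
    host_ensemble_table,
    sample_community,
    sample_host_ensemble,
    sample_species_baseline,
    sample_strengths,
    sample_topology,
)


class TestSpeciesBaseline:
    def test_bounds_and_positivity(self, rng):
        ens = sample_species_baseline(10, rng=rng)
        assert np.all((ens.r >= 0.05) & (ens.r <= 0.1))
        assert np.all((ens.K > 0.0) & (ens.K <= 1.0))

    def test_uniform_means(self, rng):
        ens = sample_species_baseline(100_000, rng=rng)
        assert ens.r.mean() == pytest.approx(0.075, abs=0.001)
        assert ens.K.mean() == pytest.approx(0.5, abs=0.005)

    def test_seed_determinism(self):
        a = sample_species_baseline(50, rng=np.random.default_rng(7))
        b = sample_species_baseline(50, rng=np.random.default_rng(7))
        np.testing.assert_array_equal(a.r, b.r)
        np.testing.assert_array_equal(a.K, b.K)

    def test_degenerate_range_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_species_baseline(5, growth_range=(0.1, 0.1), rng=rng)


class TestTopology:
    def test_zero_density_empty(self, rng):
        mask = sample_topology(TopologySpec(n_species=10, density=0.0), rng)
        assert not mask.any()

    def test_density_mean_matches_binomial(self, rng):
        # s=10, density 1/4: 90 ordered pairs, expected 22.5 present
        spec = TopologySpec(n_species=10, density=0.25)
        counts = [sample_topology(spec, rng).sum() for _ in range(4000)]
        mean = np.mean(counts)
        se = np.sqrt(90 * 0.25 * 0.75 / 4000)
        assert abs(mean - 22.5) < 4 * se

    def test_diagonal_always_empty(self, rng):
        for structure in ("random", "producer_consumer", "hub"):
            mask = sample_topology(
                TopologySpec(n_species=10, density=0.5, structure=structure), rng
            )
            assert not np.diag(mask).any()

    def test_hub_has_dominant_species(self, rng):
        # hubs concentrate interactions: max total degree >> median degree
        spec = TopologySpec(n_species=30, density=0.25, structure="hub")
        wins = 0
        for _ in range(200):
            mask = sample_topology(spec, rng)
            deg = mask.sum(0) + mask.sum(1)
            wins += deg.max() >= 2 * np.median(deg)
        assert wins >= 180

    def test_hub_density_adjusted_to_target(self, rng):
        spec = TopologySpec(n_species=10, density=0.25, structure="hub")
        for _ in range(20):
            assert sample_topology(spec, rng).sum() == round(0.25 * 90)

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            TopologySpec(n_species=9, density=0.25, structure="producer_consumer")
        with pytest.raises(ValueError):
            TopologySpec(n_species=10, density=1.5)
        with pytest.raises(ValueError):
            TopologySpec(n_species=2, density=0.5, structure="hub")


class TestStrengths:
    def test_empty_mask_gives_zero_matrix(self, rng):
        A = sample_strengths(np.zeros((5, 5), bool), rng=rng)
        assert not A.values.any()

    def test_mixture_truncation_and_mean(self, rng):
        # oracle: mean |alpha| of N(0.25, 0.1) truncated to (-0.5, 0.5);
        # the positive component rarely crosses zero so E|x| ~ E[x | trunc]
        mask = np.ones((350, 350), bool)
        np.fill_diagonal(mask, False)
        A = sample_strengths(mask, rng=rng)  # ~122k entries
        vals = A.values[mask]
        assert np.abs(vals).max() <= 0.5
        a, b = (-0.5 - 0.25) / 0.1, (0.5 - 0.25) / 0.1
        expected = stats.truncnorm(a, b, loc=0.25, scale=0.1).expect(np.abs)
        assert np.abs(vals).mean() == pytest.approx(expected, abs=0.005)

    def test_mixture_is_balanced(self, rng):
        mask = np.ones((200, 200), bool)
        np.fill_diagonal(mask, False)
        vals = sample_strengths(mask, rng=rng).values[mask]
        assert np.mean(vals > 0) == pytest.approx(0.5, abs=0.02)

    def test_producer_consumer_block_signs(self, rng):
        spec = TopologySpec(n_species=10, density=0.5, structure="producer_consumer")
        within_neg = between_pos = within_n = between_n = 0
        for _ in range(200):
            mask = sample_topology(spec, rng)
            A = sample_strengths(mask, structure="producer_consumer", rng=rng)
            block = np.zeros((10, 10), bool)
            block[:5, :5] = block[5:, 5:] = True
            w = A.values[mask & block]
            b = A.values[mask & ~block]
            within_neg += (w < 0).sum()
            within_n += w.size
            between_pos += (b > 0).sum()
            between_n += b.size
        # the negative component N(-0.25, 0.1) has P(x < 0) = Phi(2.5) ~ 0.994
        assert within_neg / within_n >= 0.99
        assert between_pos / between_n >= 0.99

    def test_uniform_family_bounds(self, rng):
        mask = np.ones((100, 100), bool)
        np.fill_diagonal(mask, False)
        dist = StrengthDistribution(family="uniform")
        vals = sample_strengths(mask, dist, rng=rng).values[mask]
        assert np.abs(vals).max() <= 0.5
        assert vals.mean() == pytest.approx(0.0, abs=0.01)

    def test_unimodal_family_moments(self, rng):
        mask = np.ones((200, 200), bool)
        np.fill_diagonal(mask, False)
        dist = StrengthDistribution(family="unimodal")
        vals = sample_strengths(mask, dist, rng=rng).values[mask]
        a = 0.5 / 0.15
        expected_sd = stats.truncnorm(-a, a, scale=0.15).std()
        assert vals.std() == pytest.approx(expected_sd, abs=0.005)


class TestHostEnsemble:
    def _community(self, rng, s=8):
        return sample_community(
            topology=TopologySpec(n_species=s, density=0.3), rng=rng
        )

    def test_zero_sigma_exact_copies(self, rng):
        c = self._community(rng)
        hosts = sample_host_ensemble(c, 20, 0.0, 0.0, 0.0, rng)
        for h in range(20):
            np.testing.assert_array_equal(hosts.r[h], c.r)
            np.testing.assert_array_equal(hosts.K[h], c.K)
            np.testing.assert_array_equal(hosts.A[h], c.A.values)

    def test_lognormal_median_and_mean(self, rng):
        # lognormal: median = exp(location), mean = exp(location + sigma^2/2)
        c = self._community(rng)
        hosts = sample_host_ensemble(c, 100_000, 0.25, 0.0, 0.0, rng)
        mask = c.A.mask
        base_abs = np.abs(c.A.values[mask])
        host_abs = np.abs(hosts.A[:, mask])
        med_ratio = np.median(host_abs / base_abs, axis=0)
        mean_ratio = host_abs.mean(0) / base_abs
        np.testing.assert_allclose(med_ratio, 1.0, atol=0.01)
        np.testing.assert_allclose(mean_ratio, np.exp(0.25**2 / 2), atol=0.01)

    @given(seed=st.integers(0, 2**31 - 1))
    def test_sign_and_zero_pattern_preserved(self, seed):
        rng = np.random.default_rng(seed)
        c = self._community(rng, s=6)
        hosts = sample_host_ensemble(c, 25, 0.4, 0.3, 0.2, rng)
        signs = np.sign(c.A.values)
        for h in range(25):
            np.testing.assert_array_equal(np.sign(hosts.A[h]), signs)
        assert np.all(hosts.r > 0) and np.all(hosts.K > 0)

    def test_contradictory_base_rejected(self, rng):
        from glvnet.networks import SpeciesEnsemble

        # a masked-in interaction with zero strength is a contradiction
        bad_mask = np.zeros((3, 3), bool)
        bad_mask[0, 1] = True
        A = InteractionMatrix(values=np.zeros((3, 3)), mask=bad_mask)
        base = SpeciesEnsemble(r=np.ones(3), K=np.ones(3), A=A)
        with pytest.raises(ValueError):
            sample_host_ensemble(base, 5, 0.1, 0, 0, rng)

    def test_negative_sigma_rejected(self, rng):
        c = self._community(rng)
        with pytest.raises(ValueError):
            sample_host_ensemble(c, 5, -0.1, 0, 0, rng)


class TestExports:
    def test_edge_list_matches_matrix(self, rng):
        c = sample_community(rng=rng)
        table = edge_list(c.A)
        assert len(table) == c.A.mask.sum()
        for row in table.itertuples():
            assert c.A.values[row.target, row.source] == row.weight
            assert np.sign(row.weight) == row.sign

    def test_host_table_shape(self, rng):
        c = sample_community(topology=TopologySpec(n_species=4, density=0.5), rng=rng)
        hosts = sample_host_ensemble(c, 3, 0.25, 0.0, 0.0, rng)
        table = host_ensemble_table(hosts)
        n_edges = c.A.mask.sum()
        assert len(table) == 3 * (4 + 4 + n_edges)
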