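import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from kernelfield.netspec import (
    ConnectionSpec,
    DepthProfile,
    connection_probability,
    delay_pmf_on_grid,
    expected_connections,
    expected_pairwise_connections,
    perturb_weights,
    reference_network,
    sample_realization,
    synapse_indegree_map,
)
from kernelfield.membrane import SynapseKernel
from kernelfield.morphology import build_ball_and_sticks, preset_sections


class TestExpectedConnections:
    def test_zero_probability(self):
        assert expected_connections(0.0, 100, 100) == 0

    def test_small_c_approximation(self):
        K = expected_connections(0.05, 8192, 8192)
        assert abs(K - 0.05 * 8192**2) / (0.05 * 8192**2) < 0.03

    def test_round_trip(self):
        for C in (0.01, 0.05, 0.3):
            K = expected_connections(C, 512, 256)
            assert connection_probability(K, 512, 256) == pytest.approx(C, abs=1e-5)

    def test_certain_connection_rejected(self):
        with pytest.raises(ValueError):
            expected_connections(1.0, 10, 10)

    def test_bernoulli_expectation_excludes_autapses(self):
        assert expected_pairwise_connections(0.1, 100, 100, True) == pytest.approx(990.0)
        assert expected_pairwise_connections(0.1, 100, 50, False) == pytest.approx(500.0)


class TestIndegreeMap:
    def test_uniform_profile_splits_equally(self):
        geom = build_ball_and_sticks(preset_sections("I"))
        net = reference_network(N_E=100, N_I=50)
        conn = net.connections[("I", "I")]
        # constant profile and equal areas on dendrites: equal shares
        from dataclasses import replace

        conn = replace(conn, profile=DepthProfile(), allowed_sections=("apic", "basal"))
        kmap = synapse_indegree_map(conn, geom, 50, net.populations["I"])
        dend = geom.section_mask(["apic", "basal"])
        assert np.all(kmap[~dend] == 0)
        np.testing.assert_allclose(kmap[dend], kmap[dend][0], rtol=1e-12)
        total = conn.multapse_mean() * expected_pairwise_connections(conn.C, 50, 50, True) / 50
        assert kmap.sum() == pytest.approx(total, rel=1e-9)

    def test_excitatory_input_avoids_soma(self):
        geom = build_ball_and_sticks(preset_sections("E"))
        net = reference_network()
        kmap = synapse_indegree_map(
            net.connections[("E", "E")], geom, 8192, net.populations["E"]
        )
        soma = geom.section_mask(["soma"])
        assert np.all(kmap[soma] == 0)
        assert kmap.sum() > 0

    def test_smearing_adds_soma_variance(self):
        # N(mu, s) * N(0, 75) = N(mu, sqrt(s^2+75^2)): checked numerically
        # through the profile the map is built from
        p = DepthProfile.gaussian(100.0, 50.0)
        sm = p.smeared(75.0)
        z = np.linspace(-600, 900, 4001)
        expected = norm.pdf(z, 100.0, np.hypot(50.0, 75.0))
        np.testing.assert_allclose(sm.pdf(z), expected, rtol=1e-10)
        var_raw = np.trapezoid(z**2 * p.pdf(z), z) - 100.0**2
        var_sm = np.trapezoid(z**2 * sm.pdf(z), z) - 100.0**2
        assert var_sm - var_raw == pytest.approx(75.0**2, rel=1e-3)

    def test_all_zero_profile_rejected(self):
        geom = build_ball_and_sticks(preset_sections("E"))
        net = reference_network()
        from dataclasses import replace

        conn = replace(
            net.connections[("E", "E")],
            profile=DepthProfile.gaussian(50000.0, 1.0),
            allowed_sections=("apic",),
        )
        with pytest.raises(ValueError, match="zero"):
            synapse_indegree_map(conn, geom, 8192, net.populations["E"],
                                 smear_with_soma_density=False)


class TestPerturbWeights:
    G = {("E", "E"): 0.15, ("E", "I"): 4.5, ("I", "E"): 0.125, ("I", "I"): 2.0}

    def test_identity_at_unit_factor(self):
        assert perturb_weights(self.G, 1.0) == self.G

    def test_supraunit_factor_shifts_balance_toward_excitation(self):
        out = perturb_weights(self.G, 1.05)
        ratio0 = self.G[("E", "E")] / self.G[("E", "I")]
        ratio1 = out[("E", "E")] / out[("E", "I")]
        assert ratio1 > ratio0

    def test_frozen_regression_values(self):
        # computed once from G' = G * J**(G_partner/G) with the tabulated
        # means at J = 1.025 and frozen as regression anchors
        out = perturb_weights(self.G, 1.025)
        assert out[("E", "E")] == pytest.approx(0.15 * 1.025 ** (4.5 / 0.15), rel=1e-12)
        assert out[("E", "I")] == pytest.approx(4.5 * 1.025 ** (0.15 / 4.5), rel=1e-12)
        assert out[("E", "E")] == pytest.approx(0.31463514, rel=1e-6)
        assert out[("E", "I")] == pytest.approx(4.50370542, rel=1e-6)
        assert out[("I", "E")] == pytest.approx(0.18556320, rel=1e-6)
        assert out[("I", "I")] == pytest.approx(2.00308896, rel=1e-6)

    def test_zero_weight_rejected(self):
        bad = dict(self.G)
        bad[("E", "E")] = 0.0
        with pytest.raises(ZeroDivisionError):
            perturb_weights(bad, 1.05)


class TestSampleRealization:
    def _setup(self):
        net = reference_network(N_E=64, N_I=16)
        geom = build_ball_and_sticks(preset_sections("E"))
        return net, geom

    def test_seed_determinism(self):
        net, geom = self._setup()
        conn = net.connections[("E", "E")]
        a = sample_realization(conn, net.populations["E"], net.populations["E"], geom, 7)
        b = sample_realization(conn, net.populations["E"], net.populations["E"], geom, 7)
        np.testing.assert_array_equal(a.pre, b.pre)
        np.testing.assert_array_equal(a.weight_nS, b.weight_nS)
        np.testing.assert_array_equal(a.soma_positions, b.soma_positions)

    def test_sample_invariants(self):
        net, geom = self._setup()
        conn = net.connections[("I", "E")]
        s = sample_realization(conn, net.populations["I"], net.populations["E"], geom, 3)
        assert np.all(s.delay_ms >= 0.3)
        assert np.all(s.weight_nS >= 0)
        assert np.all(s.pre != -1)
        # no autapses is vacuous across populations; placements on allowed comps
        soma = geom.section_mask(["soma"])
        # I -> E has no section restriction, soma allowed
        assert s.comp.min() >= 0 and s.comp.max() < geom.n

    def test_multapse_mean_within_3_se(self, rng):
        net, _ = self._setup()
        conn = net.connections[("E", "E")]
        k, p = conn.multapse_pmf()
        mean = k @ p
        var = (k**2) @ p - mean**2
        draws = rng.choice(k, size=100_000, p=p)
        se = np.sqrt(var / len(draws))
        assert abs(draws.mean() - mean) < 3 * se
        assert draws.min() >= 1 and draws.max() <= 20

    def test_connection_fraction_within_3_se(self):
        net, geom = self._setup()
        from dataclasses import replace

        conn = replace(net.connections[("E", "E")], C=0.05)
        hits = total = 0
        for seed in range(3):
            s = sample_realization(conn, net.populations["E"], net.populations["E"],
                                   geom, seed)
            pairs = set(zip(s.pre.tolist(), s.post.tolist()))
            hits += len(pairs)
            total += 64 * 63
        p_hat = hits / total
        se = np.sqrt(0.05 * 0.95 / total)
        assert abs(p_hat - 0.05) < 3 * se


@given(mu=st.floats(0.5, 10), sigma=st.floats(0.1, 5))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_discretized_and_gridded_distributions_are_normalized(mu, sigma):
    conn = ConnectionSpec(
        pre="E", post="E", C=0.05, multapse_mu=mu, multapse_sigma=sigma,
        weight_mu=1.0, weight_sigma=0.1, delay_mu=1.5, delay_sigma=0.3,
        profile=DepthProfile.gaussian(0, 100), synapse=SynapseKernel(0.2, 1.8),
    )
    k, p = conn.multapse_pmf()
    assert p.sum() == pytest.approx(1.0, abs=1e-12)
    d = delay_pmf_on_grid(conn, 0.0625, 1601)
    assert d.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.all(d[: int(0.3 / 0.0625)] == 0)


def test_reference_network_mirrors_tables():
    net = reference_network()
    assert net.populations["E"].N == 8192
    assert net.populations["I"].N == 1024
    c = net.connections[("I", "E")]  # inhibitory onto excitatory
    assert c.weight_mu == 4.5 and c.synapse.E_syn == -80.0
    assert c.synapse.tau1 == 0.1 and c.synapse.tau2 == 9.0
    assert net.external["E"].k_syn == 465 and net.external["I"].k_syn == 160
    assert net.rates == {"E": 2.6, "I": 5.1, "ext": 40.0}
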