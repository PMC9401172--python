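import numpy as np
import pytest
from dataclasses import replace

from kernelfield.forward import ProbeSpec, default_probe
from kernelfield.kernels import (
    KernelSet,
    build_kernel_set,
    hybrid_kernel_average,
    hybrid_kernel_oracle,
    predict_kernel,
)
from kernelfield.membrane import SynapseKernel
from kernelfield.netspec import (
    ConnectionSpec,
    DepthProfile,
    ExternalDriveSpec,
    NetworkSpec,
    PopulationSpec,
)

DT = 0.0625


def replace_connection(net, key, conn):
    out = NetworkSpec(
        populations=net.populations, connections=dict(net.connections),
        external=net.external, rates=net.rates,
    )
    out.connections[key] = conn
    return out


def _toy_net(weight=1.0, multapse_mu=1.0, delay=(1.0, 1e-6), N=4, C=1.0,
             depth_sigma=1e-3):
    """Two small populations of "I"-preset cells with synapses pinned to
    the distal apical compartment (degenerate depth profile), so sampled
    and expected placements coincide and responses admit exact checks."""
    pops = {
        "A": PopulationSpec("A", N, cell_preset="I", depth_sigma=depth_sigma,
                            radius=1.0, V_bar=-70.0),
        "B": PopulationSpec("B", N, cell_preset="I", depth_sigma=depth_sigma,
                            radius=1.0, V_bar=-70.0),
    }
    conn = ConnectionSpec(
        pre="A", post="B", C=C,
        multapse_mu=multapse_mu, multapse_sigma=1e-9,
        weight_mu=weight, weight_sigma=max(weight * 1e-12, 1e-15),
        delay_mu=delay[0], delay_sigma=delay[1],
        # apical tip of the "I" preset sits at z ~ 195; a sharp Gaussian
        # there puts every synapse on one compartment
        profile=DepthProfile.gaussian(195.0, 2.0),
        synapse=SynapseKernel(0.2, 1.8, 0.0, weight),
        allowed_sections=("apic",),
    )
    ext = {"B": ExternalDriveSpec(post="B", k_syn=10)}
    return NetworkSpec(populations=pops, connections={("A", "B"): conn},
                       external=ext, rates={"A": 2.0, "B": 2.0, "ext": 40.0})


class TestPredictKernel:
    def test_zero_weight_gives_zero_kernel(self):
        net = _toy_net(weight=0.0)
        net.connections[("A", "B")] = replace(
            net.connections[("A", "B")],
            synapse=SynapseKernel(0.2, 1.8, 0.0, 0.0), weight_mu=0.0,
        )
        H = predict_kernel(net, "A", "B", tau_max=20.0)
        # zero input: response is numerically indistinguishable from zero
        # (rest-state solve leaves ~1e-13 nA*um of rounding)
        assert np.abs(H["dipole"]).max() < 1e-9
        assert np.abs(H["potential"]).max() < 1e-12

    def test_kernel_linear_in_weight_and_multapse(self):
        H1 = predict_kernel(_toy_net(weight=0.5), "A", "B", tau_max=20.0,
                            g_eff=False)
        H2 = predict_kernel(_toy_net(weight=1.0), "A", "B", tau_max=20.0,
                            g_eff=False)
        H3 = predict_kernel(_toy_net(weight=0.5, multapse_mu=2.0), "A", "B",
                            tau_max=20.0, g_eff=False)
        scale = np.abs(H2["dipole"]).max()
        np.testing.assert_allclose(H2["dipole"], 2 * H1["dipole"],
                                   rtol=1e-9, atol=1e-9 * scale)
        np.testing.assert_allclose(H3["dipole"], 2 * H1["dipole"],
                                   rtol=1e-9, atol=1e-9 * scale)

    def test_causality_below_minimum_delay(self, small_net):
        H = predict_kernel(small_net, "E", "E", tau_max=50.0)
        k = int(0.3 / DT)  # minimum conduction delay
        peak = np.abs(H["potential"]).max()
        assert np.abs(H["potential"][:, :k]).max() <= 1e-12 * peak

    def test_inhibitory_kernel_opposite_polarity_for_matched_profiles(self, small_net):
        """At V̄m between the two reversal potentials the excitatory
        synaptic current is inward and the inhibitory one outward, so with
        identical placement profiles the kernels are channel-wise opposite
        in sign (and proportional up to the temporal kinetics)."""
        ee = small_net.connections[("E", "E")]
        matched = replace(
            small_net.connections[("I", "E")],
            profile=ee.profile, allowed_sections=ee.allowed_sections,
            delay_mu=ee.delay_mu, delay_sigma=ee.delay_sigma,
        )
        net = replace_connection(small_net, ("I", "E"), matched)
        Hee = predict_kernel(net, "E", "E", tau_max=50.0)["potential"]
        Hie = predict_kernel(net, "I", "E", tau_max=50.0)["potential"]
        for ch in range(Hee.shape[0]):
            if np.abs(Hee[ch]).max() < 0.05 * np.abs(Hee).max():
                continue
            s_ee = Hee[ch].flat[np.argmax(np.abs(Hee[ch]))]
            s_ie = Hie[ch].flat[np.argmax(np.abs(Hie[ch]))]
            assert np.sign(s_ee) == -np.sign(s_ie)

    def test_geff_reduces_amplitude_and_speeds_decay(self, small_net):
        Hon = predict_kernel(small_net, "I", "E", tau_max=100.0, g_eff=True)
        Hoff = predict_kernel(small_net, "I", "E", tau_max=100.0, g_eff=False)
        z_on = Hon["dipole"][2]
        z_off = Hoff["dipole"][2]
        assert np.abs(z_off).max() > np.abs(z_on).max()
        # effective decay: lag by which 95% of the cumulative |H| is reached
        def t95(h):
            c = np.cumsum(np.abs(h))
            return np.searchsorted(c, 0.95 * c[-1]) * DT
        assert t95(z_off) > t95(z_on)

    def test_frozen_vs_quasi_active_within_ten_percent(self, small_net):
        """Freezing the gating dynamics changes the kernel set by < 10% in
        relative L2 per signal type (pathways stacked: what enters a
        predicted signal is the pathway sum, so a negligible, strongly
        cancelling component such as the E->E dipole is weighted by its
        actual contribution)."""
        ksf = build_kernel_set(small_net, tau_max=100.0, mode="frozen",
                               with_ih=True)
        ksl = build_kernel_set(small_net, tau_max=100.0, mode="lin",
                               with_ih=True)
        for sig in ("potential", "dipole"):
            f = np.vstack([ksf.get(p, sig) for p in ksf.pathways()])
            l = np.vstack([ksl.get(p, sig) for p in ksl.pathways()])
            assert np.linalg.norm(f - l) / np.linalg.norm(l) < 0.10

    def test_kernel_grid_and_decay(self, small_net):
        H = predict_kernel(small_net, "E", "E", tau_max=100.0, dt=DT)
        assert H["potential"].shape == (13, 1601)
        peak = np.abs(H["potential"]).max()
        assert np.abs(H["potential"][:, -1]).max() < 0.01 * peak
        assert np.isfinite(H["potential"]).all()


class TestHybridOracle:
    def test_single_synapse_population_equals_shifted_response(self):
        # one presynaptic neuron, one postsynaptic neuron, one synapse,
        # fixed delay: the kernel is the single-synapse response shifted by
        # the delay and divided by N_A = 1
        net = _toy_net(weight=1.0, N=1, C=1.0, delay=(1.0, 1e-9))
        H = hybrid_kernel_oracle(net, "A", "B", seed=0, tau_max=20.0,
                                 g_eff=False, delay_override=1.0)
        Hp = predict_kernel(net, "A", "B", tau_max=20.0, g_eff=False)
        # deterministic predictor with (near) delta delay at the same lag
        np.testing.assert_allclose(H["dipole"], Hp["dipole"],
                                   atol=1e-6 * np.abs(Hp["dipole"]).max())

    def test_delta_delay_equivalence(self):
        net = _toy_net(weight=2.0, N=4, C=1.0, delay=(2.0, 1e-9))
        Ho = hybrid_kernel_oracle(net, "A", "B", seed=1, tau_max=30.0,
                                  g_eff=False, delay_override=2.0)
        Hp = predict_kernel(net, "A", "B", tau_max=30.0, g_eff=False)
        scale = np.abs(Hp["dipole"]).max()
        np.testing.assert_allclose(Ho["dipole"], Hp["dipole"], atol=1e-6 * scale)

    def test_seed_average_converges_to_prediction(self, small_net):
        Hp = predict_kernel(small_net, "E", "E", tau_max=50.0)["dipole"][2]
        errs = []
        for n_seeds in (2, 8, 32):
            Ha = hybrid_kernel_average(
                small_net, "E", "E", seeds=range(n_seeds), tau_max=50.0,
                signals=("dipole",),
            )["dipole"][2]
            errs.append(np.linalg.norm(Hp - Ha) / np.linalg.norm(Ha))
        assert errs[2] < errs[0]
        assert errs[2] < 0.05


class TestKernelSet:
    def test_build_covers_all_pathways_and_roundtrips(self, small_net, tmp_path):
        ks = build_kernel_set(small_net, tau_max=20.0)
        assert sorted(ks.pathways()) == ["E->E", "E->I", "I->E", "I->I"]
        assert ks.n_lags == int(20.0 / DT) + 1
        p = tmp_path / "kernels.h5"
        ks.to_hdf5(p)
        ks2 = KernelSet.from_hdf5(p)
        for pw in ks.pathways():
            for sig in ("potential", "dipole"):
                np.testing.assert_array_equal(ks.get(pw, sig), ks2.get(pw, sig))
        # determinism: byte-identical files on rebuild
        ks3 = build_kernel_set(small_net, tau_max=20.0)
        p3 = tmp_path / "kernels2.h5"
        ks3.to_hdf5(p3)
        assert p.read_bytes() == p3.read_bytes()

    def test_text_export(self, small_net, tmp_path):
        ks = build_kernel_set(small_net, tau_max=5.0, signals=("dipole",))
        f = tmp_path / "k.tsv"
        ks.to_text(f, "E->E", "dipole")
        arr = np.loadtxt(f)
        assert arr.shape == (ks.n_lags, 4)
        np.testing.assert_allclose(arr[:, 1:].T, ks.get("E->E", "dipole"))
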