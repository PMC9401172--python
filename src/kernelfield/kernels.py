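"""Causal spike-to-signal kernels per connection pathway.

Two routes to the same quantity — the population-averaged impulse response
H_YX(R, tau) mapping a presynaptic spike in population X at tau = 0 to the
extracellular signal contributed by postsynaptic population Y:

* :func:`predict_kernel` — the direct deterministic predictor.  One linear
  multicompartment simulation per pathway: the expected per-compartment
  synaptic input evoked by a single presynaptic spike, summed over the
  whole postsynaptic population, is injected into a single collapsed
  "population neuron"; the resulting transmembrane currents are mapped
  through population-level forward matrices and convolved with the
  discretized conduction-delay density.
* :func:`hybrid_kernel_oracle` — the Monte-Carlo reference.  A discrete
  population realization is sampled (soma positions, connectome, weights,
  delays); every presynaptic neuron fires once synchronously; each sampled
  postsynaptic neuron is simulated receiving its sampled synapses; summed
  signals are divided by the presynaptic population size.

Kernels are stored in signal units *per presynaptic spike* (mV for
potentials, nA*um for dipole rows) on the lag grid tau = 0, dt, ...,
tau_max; they vanish for lags below the minimum conduction delay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as dc_replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import norm

from .cable import CompartmentalCell, LinearCableSystem
from .forward import (
    ForwardMatrix,
    ProbeSpec,
    default_probe,
    dipole_matrix,
    line_source_matrix,
    population_disk_matrix,
    population_dipole_matrix,
)
from .membrane import current_synapse, effective_conductance
from .morphology import CompartmentGeometry
from .netspec import (
    ConnectionSpec,
    NetworkSpec,
    build_preset_cell,
    delay_pmf_on_grid,
    expected_connections,
    indegree_maps_onto,
    sample_realization,
    synapse_indegree_map,
)

__all__ = [
    "KernelSet",
    "predict_kernel",
    "build_kernel_set",
    "hybrid_kernel_oracle",
    "hybrid_kernel_average",
    "prepare_post_cell",
]

SIGNALS = ("potential", "dipole")


@dataclass
class KernelSet:
    """Spatiotemporal kernels per pathway and signal type.

    ``kernels[pathway][signal]`` is an array (n_channels, n_lags):
    13 probe channels for ``"potential"`` (mV per spike), 3 axes for
    ``"dipole"`` (nA*um per spike).  ``tau`` is the lag grid (ms).
    """

    tau: np.ndarray
    dt: float
    kernels: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def n_lags(self) -> int:
        return len(self.tau)

    def add(self, pathway: str, signal: str, values: np.ndarray) -> None:
        self.kernels.setdefault(pathway, {})[signal] = np.asarray(values, float)

    def get(self, pathway: str, signal: str) -> np.ndarray:
        return self.kernels[pathway][signal]

    def pathways(self) -> list:
        return sorted(self.kernels)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("tau", data=self.tau, track_times=False)
            f.attrs["dt"] = self.dt
            for k, v in self.meta.items():
                f.attrs[f"meta_{k}"] = v
            for pathway, sigs in self.kernels.items():
                g = f.require_group(pathway.replace("->", "_to_"))
                for signal, values in sigs.items():
                    g.create_dataset(signal, data=values, track_times=False)

    @classmethod
    def from_hdf5(cls, path) -> "KernelSet":
        import h5py

        with h5py.File(path, "r") as f:
            tau = f["tau"][:]
            dt = float(f.attrs["dt"])
            meta = {
                k[5:]: f.attrs[k] for k in f.attrs if k.startswith("meta_")
            }
            ks = cls(tau=tau, dt=dt, meta=meta)
            for name, grp in f.items():
                if name == "tau":
                    continue
                pathway = name.replace("_to_", "->")
                for signal, dset in grp.items():
                    ks.add(pathway, signal, dset[:])
        return ks

    def to_text(self, path, pathway: str, signal: str) -> None:
        """Export one kernel as delimited text (lag column + one column per
        channel), e.g. as FIR coefficients for an online filter node."""
        vals = self.get(pathway, signal)
        out = np.column_stack([self.tau, vals.T])
        np.savetxt(path, out, delimiter="\t",
                   header="tau_ms\t" + "\t".join(str(i) for i in range(len(vals))))


def prepare_post_cell(
    net: NetworkSpec,
    post: str,
    mode: str = "frozen",
    g_eff: bool = True,
    with_ih: bool = False,
    cell: Optional[CompartmentalCell] = None,
) -> CompartmentalCell:
    """Linearized postsynaptic cell, optionally with effective leak.

    Builds the population's preset cell (unless ``cell`` is given),
    linearizes synapse and channel dynamics about the population's V̄m
    (``mode``: ``"lin"``/``"quasi_active"`` or ``"frozen"``), and, with
    ``g_eff``, replaces the passive leak by the effective conductance from
    persistent synaptic activation of every pathway (recurrent + external)
    at the rates stored in the network description.
    """
    post_pop = net.populations[post]
    if cell is None:
        cell = build_preset_cell(post_pop, with_ih=with_ih)
    if mode in ("lin", "quasi_active"):
        mode = "quasi_active"
    lin = cell.linearized(post_pop.V_bar, mode=mode)
    if g_eff:
        kmaps, syns = indegree_maps_onto(net, post, cell.geometry)
        rates = {key: net.rates["ext" if key == "ext" else key] for key in kmaps}
        g = effective_conductance(lin.g_L, cell.geometry.areas, kmaps, rates, syns)
        lin = lin.with_leak(g)
    return lin


def _forward_matrices(
    probe: ProbeSpec,
    geometry: CompartmentGeometry,
    post_pop,
    signals: Sequence[str],
) -> dict:
    out = {}
    if "potential" in signals:
        sig = post_pop.depth_sigma
        out["potential"] = population_disk_matrix(
            probe, geometry, disk_radius=post_pop.radius,
            depth_density=lambda z: norm.pdf(z, 0.0, sig),
            density_support=(-8 * sig, 8 * sig),
        )
    if "dipole" in signals:
        out["dipole"] = population_dipole_matrix(geometry)
    return out


#: Gauss-Hermite order for the soma-depth quadrature
_GH_ORDER = 25


def _depth_nodes(sigma: float, order: int = _GH_ORDER):
    """Gauss-Hermite nodes/weights for averaging over N(0, sigma) depth."""
    x, w = np.polynomial.hermite.hermgauss(order)
    return np.sqrt(2.0) * sigma * x, w / np.sqrt(np.pi)


def predict_kernel(
    net: NetworkSpec,
    pre: str,
    post: str,
    probe: Optional[ProbeSpec] = None,
    mode: str = "frozen",
    g_eff: bool = True,
    tau_max: float = 100.0,
    dt: float = 0.0625,
    signals: Sequence[str] = SIGNALS,
    with_ih: bool = False,
    cell: Optional[CompartmentalCell] = None,
    forward: Optional[Mapping[str, ForwardMatrix]] = None,
    depth_average: str = "quadrature",
) -> dict:
    """Deterministic kernel for pathway ``pre -> post``.

    Pipeline: (1) expected synaptic in-degree per compartment; (2)
    optional effective leak conductance from all persistent pathways; (3)
    linear simulation(s) with injected current
    ``(N_Y/N_X) * <k_syn,m> * I_syn * f(tau)`` — the population-summed
    expected synaptic current per presynaptic spike; (4) transmembrane
    currents mapped through the population forward models (radially
    homogeneous disk for potentials, vertical axis for the dipole); (5)
    temporal convolution with the discretized conduction-delay density;
    (6) truncation to [0, tau_max].

    ``depth_average`` controls how the soma-depth scatter of the
    postsynaptic population enters:

    * ``"quadrature"`` (default): the expectation over soma depth is taken
      *jointly* — per Gauss-Hermite depth node, the in-degree map is the
      depth-shifted profile (normalized per cell) and the disk forward is
      evaluated at the shifted compartment depths; one batched linear
      simulation covers all nodes.  This preserves the covariance between
      cell depth and synapse placement and converges to the Monte-Carlo
      oracle.
    * ``"factorized"``: in-degree and forward model are each smeared with
      the depth density independently (profile convolution + disk-density
      convolution) and a single simulation is run.  Cheaper, but a
      product-of-expectations approximation that smooths the potential
      kernels near amplitude extrema and sign flips.

    Returns ``{signal: array (n_channels, n_lags)}``.
    """
    if probe is None:
        probe = default_probe()
    if depth_average not in ("quadrature", "factorized"):
        raise ValueError("depth_average must be 'quadrature' or 'factorized'")
    conn = net.connections[(pre, post)]
    pre_pop = net.populations[pre]
    post_pop = net.populations[post]
    lin = prepare_post_cell(net, post, mode=mode, g_eff=g_eff, with_ih=with_ih, cell=cell)
    geom = lin.geometry

    I_bar, waveform = current_synapse(conn.synapse, post_pop.V_bar)
    n_lags = int(round(tau_max / dt)) + 1
    tau = np.arange(n_lags) * dt
    A_scale = post_pop.N / pre_pop.N
    f_tau = waveform(tau)
    sys = LinearCableSystem(lin, dt)
    delay = delay_pmf_on_grid(conn, dt, n_lags)
    out = {}

    if depth_average == "factorized":
        kmap = synapse_indegree_map(conn, geom, pre_pop.N, post_pop,
                                    smear_with_soma_density=True)
        inputs = A_scale * kmap[None, :] * I_bar * f_tau[:, None]
        _, I_m = sys.run(inputs, n_lags)
        if forward is None:
            forward = _forward_matrices(probe, geom, post_pop, signals)
        for signal in signals:
            out[signal] = forward[signal].apply(I_m)
    else:
        z_nodes, z_w = _depth_nodes(post_pop.depth_sigma)
        allowed = (
            geom.section_mask(conn.allowed_sections)
            if conn.allowed_sections is not None
            else np.ones(geom.n, bool)
        )
        total = _per_neuron_indegree(conn, pre_pop, post_pop)
        inputs = np.empty((n_lags, geom.n, len(z_nodes)))
        for j, zv in enumerate(z_nodes):
            dens = conn.profile.pdf(geom.z + zv) * geom.areas
            dens = np.where(allowed, dens, 0.0)
            s = dens.sum()
            if s == 0:
                raise ValueError("synapse density vanishes at a depth node; "
                                 "check profile and allowed sections")
            k_m = total * dens / s
            inputs[:, :, j] = A_scale * k_m[None, :] * I_bar * f_tau[:, None]
        _, I_m = sys.run(inputs, n_lags)  # (n, n_lags, n_nodes)
        if "dipole" in signals:
            F = population_dipole_matrix(geom)
            out["dipole"] = F.apply(I_m @ z_w)
        if "potential" in signals:
            from .forward import disk_potential

            psi = np.zeros((probe.n_contacts, n_lags))
            for j, (zv, w) in enumerate(zip(z_nodes, z_w)):
                Fj = disk_potential(
                    probe.z[:, None] - (geom.z[None, :] + zv),
                    post_pop.radius, probe.sigma,
                )
                psi += w * (Fj @ I_m[:, :, j])
            out["potential"] = psi

    for signal in list(out):
        H = np.apply_along_axis(lambda row: np.convolve(row, delay)[:n_lags], 1,
                                out[signal])
        peak = np.abs(H).max()
        if peak > 0 and np.abs(H[:, -1]).max() > 0.01 * peak:
            warnings.warn(
                f"kernel {pre}->{post}/{signal} not decayed at tau_max: "
                f"residual {np.abs(H[:, -1]).max() / peak:.2%} of peak",
                stacklevel=2,
            )
        out[signal] = H
    return out


def _per_neuron_indegree(conn: ConnectionSpec, pre_pop, post_pop) -> float:
    """Expected synapses per postsynaptic neuron for a pathway."""
    from .netspec import expected_pairwise_connections

    K = expected_pairwise_connections(
        conn.C, pre_pop.N, post_pop.N, same_population=(conn.pre == conn.post)
    )
    return conn.multapse_mean() * K / post_pop.N


def build_kernel_set(
    net: NetworkSpec,
    probe: Optional[ProbeSpec] = None,
    mode: str = "frozen",
    g_eff: bool = True,
    tau_max: float = 100.0,
    dt: float = 0.0625,
    signals: Sequence[str] = SIGNALS,
    with_ih: bool = False,
    depth_average: str = "quadrature",
) -> KernelSet:
    """Deterministic kernels for every recurrent pathway in the network.

    The external drive enters only through the effective leak conductance
    (its rate is stationary, so it contributes no kernel of its own).
    """
    if probe is None:
        probe = default_probe()
    n_lags = int(round(tau_max / dt)) + 1
    ks = KernelSet(tau=np.arange(n_lags) * dt, dt=dt,
                   meta={"mode": mode, "g_eff": int(g_eff), "tau_max": tau_max,
                         "depth_average": depth_average})
    cells: dict[str, CompartmentalCell] = {}
    forwards: dict[str, Optional[dict]] = {}
    for (pre, post) in sorted(net.connections):
        if post not in cells:
            cells[post] = build_preset_cell(net.populations[post], with_ih=with_ih)
            forwards[post] = (
                _forward_matrices(probe, cells[post].geometry,
                                  net.populations[post], signals)
                if depth_average == "factorized" else None
            )
        entry = predict_kernel(
            net, pre, post, probe=probe, mode=mode, g_eff=g_eff,
            tau_max=tau_max, dt=dt, signals=signals, with_ih=with_ih,
            cell=cells[post], forward=forwards[post], depth_average=depth_average,
        )
        for signal, H in entry.items():
            ks.add(f"{pre}->{post}", signal, H)
    return ks


def hybrid_kernel_oracle(
    net: NetworkSpec,
    pre: str,
    post: str,
    seed,
    probe: Optional[ProbeSpec] = None,
    mode: str = "frozen",
    g_eff: bool = True,
    tau_max: float = 100.0,
    dt: float = 0.0625,
    signals: Sequence[str] = SIGNALS,
    with_ih: bool = False,
    delay_override: Optional[float] = None,
) -> dict:
    """Monte-Carlo kernel for ``pre -> post`` from one sampled realization.

    All presynaptic neurons fire once, synchronously, at tau = 0; each
    sampled postsynaptic neuron receives its sampled synapses (placement,
    weight, conduction delay) as current-based inputs; signals are summed
    over the population and divided by the presynaptic count N_X.  The
    external drive contributes only through the effective leak conductance
    (steady-state approximation), so the simulation stays linear and fully
    seeded.  ``delay_override`` forces every conduction delay to a fixed
    value (used by equivalence checks).
    """
    if probe is None:
        probe = default_probe()
    conn = net.connections[(pre, post)]
    pre_pop = net.populations[pre]
    post_pop = net.populations[post]
    lin = prepare_post_cell(net, post, mode=mode, g_eff=g_eff, with_ih=with_ih)
    geom = lin.geometry

    sample = sample_realization(conn, pre_pop, post_pop, geom, seed)
    delays = (np.full_like(sample.delay_ms, delay_override)
              if delay_override is not None else sample.delay_ms)

    n_lags = int(round(tau_max / dt)) + 1
    tau = np.arange(n_lags) * dt
    n = geom.n
    inputs = np.zeros((n_lags, n, post_pop.N))
    syn = conn.synapse
    for w, d, m, v in zip(sample.weight_nS, delays, sample.comp, sample.post):
        I_bar = w * (post_pop.V_bar - syn.E_syn) * 1e-3  # nA
        inputs[:, m, v] += I_bar * syn.waveform(tau - d)

    sys = LinearCableSystem(lin, dt)
    _, I_m = sys.run(inputs, n_lags)  # (n, n_lags, N_Y)

    out = {}
    if "dipole" in signals:
        # soma offsets drop out of the dipole because currents sum to zero
        F = dipole_matrix(geom)
        out["dipole"] = F.apply(I_m.sum(axis=2)) / pre_pop.N
    if "potential" in signals:
        psi = np.zeros((probe.n_contacts, n_lags))
        for v in range(post_pop.N):
            pos = sample.soma_positions[v]
            g_v = dc_replace(
                geom,
                starts=geom.starts + pos,
                ends=geom.ends + pos,
                midpoints=geom.midpoints + pos,
            )
            F_v = line_source_matrix(probe, g_v)
            psi += F_v.values @ I_m[:, :, v]
        out["potential"] = psi / pre_pop.N
    return out


def hybrid_kernel_average(
    net: NetworkSpec,
    pre: str,
    post: str,
    seeds: Iterable,
    **kwargs,
) -> dict:
    """Seed-averaged Monte-Carlo kernel (mean over realizations)."""
    acc: dict[str, np.ndarray] = {}
    count = 0
    for seed in seeds:
        entry = hybrid_kernel_oracle(net, pre, post, seed, **kwargs)
        for signal, H in entry.items():
            acc[signal] = acc.get(signal, 0.0) + H
        count += 1
    return {signal: H / count for signal, H in acc.items()}
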