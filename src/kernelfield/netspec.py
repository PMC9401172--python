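"""Statistical network description: populations, pathways, distributions.

A network is described only by statistics — population sizes and soma-depth
densities, pairwise connection probabilities, multapse / weight / delay
distributions, depth-dependent synapse-density profiles — never by an
explicit connectome.  Two consumers use it:

* the deterministic kernel predictor, which needs *expectation* quantities
  (:func:`expected_connections`, :func:`synapse_indegree_map`,
  discretized delay densities);
* the Monte-Carlo hybrid oracle, which needs *sampled realizations*
  (:func:`sample_realization`).

Distribution conventions: discretized Gaussians are evaluated on their
integer support and renormalized to unit sum; truncated Gaussians are
sampled by rejection; all densities are normalized so the integral or sum
over the support equals 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.stats import norm

from .cable import CompartmentalCell, make_cell
from .membrane import LeakSpec, SynapseKernel, generic_ih
from .morphology import CompartmentGeometry, build_ball_and_sticks, preset_sections

__all__ = [
    "DepthProfile",
    "PopulationSpec",
    "ConnectionSpec",
    "ExternalDriveSpec",
    "NetworkSpec",
    "expected_connections",
    "connection_probability",
    "discretized_gaussian_pmf",
    "truncated_gaussian_samples",
    "synapse_indegree_map",
    "indegree_maps_onto",
    "perturb_weights",
    "sample_realization",
    "SampledConnectome",
    "delay_pmf_on_grid",
    "build_preset_cell",
    "reference_network",
]


@dataclass(frozen=True)
class DepthProfile:
    """Depth-dependent synapse density L(z): Gaussian mixture or constant.

    ``components`` is a sequence of ``(weight, mu, sigma)`` triples with
    weights summing to 1; an empty sequence means the constant profile
    L(z) = 1 (depth-independent placement, e.g. the external drive).
    """

    components: tuple = ()

    @classmethod
    def gaussian(cls, mu: float, sigma: float) -> "DepthProfile":
        return cls(components=((1.0, mu, sigma),))

    @classmethod
    def mixture(cls, *comps: tuple) -> "DepthProfile":
        w = sum(c[0] for c in comps)
        if not np.isclose(w, 1.0):
            raise ValueError("mixture weights must sum to 1")
        return cls(components=tuple(comps))

    @property
    def is_uniform(self) -> bool:
        return len(self.components) == 0

    def pdf(self, z) -> np.ndarray:
        z = np.asarray(z, float)
        if self.is_uniform:
            return np.ones_like(z)
        out = np.zeros_like(z)
        for w, mu, sigma in self.components:
            out += w * norm.pdf(z, loc=mu, scale=sigma)
        return out

    def smeared(self, sigma_s: float) -> "DepthProfile":
        """Convolve with a zero-mean Gaussian of width ``sigma_s``.

        Gaussian convolution identity: each component N(mu, s) becomes
        N(mu, sqrt(s^2 + sigma_s^2)); the constant profile is unchanged.
        """
        if self.is_uniform:
            return self
        return DepthProfile(
            components=tuple(
                (w, mu, float(np.hypot(s, sigma_s))) for w, mu, s in self.components
            )
        )


@dataclass(frozen=True)
class PopulationSpec:
    """One neuron population.

    ``depth_sigma`` is the std of the Gaussian soma-depth density (mean 0),
    ``radius`` the lateral population radius (uniform areal density within
    it), ``cell_preset`` the morphology/channel preset name, ``V_bar`` the
    linearization voltage (mV).
    """

    name: str
    N: int
    cell_preset: str
    depth_sigma: float = 75.0
    radius: float = 150.0
    V_bar: float = -70.0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("population size must be >= 1")

    def depth_density(self, z) -> np.ndarray:
        return norm.pdf(np.asarray(z, float), loc=0.0, scale=self.depth_sigma)


@dataclass(frozen=True)
class ConnectionSpec:
    """Statistical description of one pathway X -> Y.

    ``multapse_mu/sigma`` parametrize the discretized Gaussian multapse
    count on 1..20; ``weight_mu/sigma`` the zero-truncated Gaussian peak
    conductance (nS); ``delay_mu/sigma`` the Gaussian conduction delay
    truncated below ``delay_min`` (ms).  ``profile`` is the synapse depth
    density L_YX(z) and ``allowed_sections`` the section names synapses may
    target.  ``synapse`` holds the temporal kernel and reversal.
    """

    pre: str
    post: str
    C: float
    multapse_mu: float
    multapse_sigma: float
    weight_mu: float
    weight_sigma: float
    delay_mu: float
    delay_sigma: float
    profile: DepthProfile
    synapse: SynapseKernel
    allowed_sections: Optional[tuple[str, ...]] = None
    delay_min: float = 0.3
    multapse_support: tuple[int, int] = (1, 20)

    def multapse_pmf(self) -> tuple[np.ndarray, np.ndarray]:
        """(support, probabilities) of the discretized multapse Gaussian."""
        lo, hi = self.multapse_support
        k = np.arange(lo, hi + 1)
        p = norm.pdf(k, loc=self.multapse_mu, scale=self.multapse_sigma)
        return k, p / p.sum()

    def multapse_mean(self) -> float:
        k, p = self.multapse_pmf()
        return float(k @ p)


@dataclass(frozen=True)
class ExternalDriveSpec:
    """Fixed-rate Poisson external drive onto one population.

    ``k_syn`` synapses per neuron, each activated at ``rate`` s^-1; depth
    profile constant, conduction delay zero.
    """

    post: str
    k_syn: int
    rate: float = 40.0
    synapse: SynapseKernel = field(
        default_factory=lambda: SynapseKernel(tau1=0.2, tau2=1.8, E_syn=0.0, G_mean=0.2)
    )
    profile: DepthProfile = field(default_factory=DepthProfile)
    allowed_sections: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.k_syn < 0:
            raise ValueError("k_syn must be >= 0")


@dataclass
class NetworkSpec:
    """Full statistical network: populations, recurrent pathways, external
    drives, and the mean presynaptic rates (s^-1) used by the deterministic
    predictor (keys: population names plus ``'ext'``)."""

    populations: dict
    connections: dict
    external: dict
    rates: dict

    def pathways_onto(self, post: str) -> list[ConnectionSpec]:
        return [c for c in self.connections.values() if c.post == post]


# ---------------------------------------------------------------------------
# expectation quantities

def connection_probability(K: float, N_X: int, N_Y: int) -> float:
    """Pairwise connection probability C for K total connections
    (binomial in/out-degrees): ``C = 1 - (1 - 1/(N_Y N_X))^K``."""
    return 1.0 - (1.0 - 1.0 / (N_Y * N_X)) ** K


def expected_connections(C: float, N_X: int, N_Y: int) -> int:
    """Total pairwise connection count K_YX from connection probability C.

    Inverts ``C = 1 - (1 - 1/(N_Y N_X))^K``:
    ``K = ln(1 - C) / ln(1 - 1/(N_Y N_X))`` rounded to nearest integer;
    ``K ≈ C N_Y N_X`` for small C.
    """
    if not 0 <= C < 1:
        raise ValueError("require 0 <= C < 1 (C = 1 is unattainable)")
    if C == 0:
        return 0
    return int(round(np.log1p(-C) / np.log1p(-1.0 / (N_Y * N_X))))


def expected_pairwise_connections(C: float, N_X: int, N_Y: int,
                                  same_population: bool = False) -> float:
    """Expected connection count under pairwise-Bernoulli sampling.

    ``K = C * N_Y * (N_X - 1)`` within a population (no autapses), else
    ``C * N_Y * N_X``.  This is the expectation the kernel predictor uses:
    it matches the sampled (Bernoulli) connectome exactly for any C,
    whereas the fixed-edge-count inversion of
    :func:`expected_connections` exceeds it by a factor ~(1 + C/2) and
    only agrees in the small-C limit.
    """
    if not 0 <= C <= 1:
        raise ValueError("require 0 <= C <= 1")
    return C * N_Y * (N_X - 1 if same_population else N_X)


def discretized_gaussian_pmf(mu: float, sigma: float, support: np.ndarray) -> np.ndarray:
    """Gaussian density evaluated on a discrete support, renormalized to 1."""
    p = norm.pdf(support, loc=mu, scale=sigma)
    s = p.sum()
    if s == 0:
        raise ValueError("distribution has no mass on the support")
    return p / s


def truncated_gaussian_samples(
    rng: np.random.Generator, mu: float, sigma: float, low: float, size: int,
) -> np.ndarray:
    """Rejection-sample N(mu, sigma) conditioned on x >= low."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mu, sigma, size=max(size - filled, 16))
        ok = draw[draw >= low]
        take = min(len(ok), size - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out


def delay_pmf_on_grid(conn: ConnectionSpec, dt: float, n_lags: int) -> np.ndarray:
    """Conduction-delay density discretized on the lag grid.

    The truncated Gaussian is evaluated at lags 0, dt, ..., zeroed below
    the truncation point, and renormalized to unit sum — the FIR kernel the
    deterministic predictor convolves with (Θ(t - delay_min) density).
    """
    tau = np.arange(n_lags) * dt
    p = norm.pdf(tau, loc=conn.delay_mu, scale=conn.delay_sigma)
    p[tau < conn.delay_min] = 0.0
    s = p.sum()
    if s == 0:
        raise ValueError("delay density has no mass on the lag grid")
    return p / s


def synapse_indegree_map(
    conn,
    post_geometry: CompartmentGeometry,
    pre_N: int,
    post_pop: PopulationSpec,
    smear_with_soma_density: bool = True,
    K: Optional[int] = None,
) -> np.ndarray:
    """Expected synaptic in-degree per compartment ⟨k_syn,m⟩.

    The per-postsynaptic-neuron expected in-degree ⟨k̃⟩·K_YX/N_Y is
    distributed over allowed compartments proportionally to
    ``L_YX(z_m) · A_m``, where the depth profile is optionally convolved
    with the z-component of the population's soma-placement density
    (``smear_with_soma_density``) to account for cell scatter in depth.

    Accepts a :class:`ConnectionSpec` or an :class:`ExternalDriveSpec`
    (for which the per-neuron in-degree is simply ``k_syn``).

    Returns an array summing to the per-neuron expected in-degree.
    """
    if isinstance(conn, ExternalDriveSpec):
        total = float(conn.k_syn)
        profile = conn.profile
        allowed = conn.allowed_sections
    else:
        if K is None:
            K = expected_pairwise_connections(
                conn.C, pre_N, post_pop.N, same_population=(conn.pre == conn.post)
            )
        total = conn.multapse_mean() * K / post_pop.N
        profile = conn.profile
        allowed = conn.allowed_sections
    if smear_with_soma_density:
        profile = profile.smeared(post_pop.depth_sigma)
    w = profile.pdf(post_geometry.z) * post_geometry.areas
    if allowed is not None:
        w = np.where(post_geometry.section_mask(allowed), w, 0.0)
    s = w.sum()
    if s == 0:
        raise ValueError("synapse density is zero on all allowed compartments")
    return total * w / s


def indegree_maps_onto(
    net: NetworkSpec,
    post: str,
    post_geometry: CompartmentGeometry,
    smear: bool = True,
) -> tuple[dict, dict]:
    """(indegree maps, synapse kernels) for every pathway onto ``post``,
    including the external drive under key ``'ext'`` — the inputs
    :func:`kernelfield.membrane.effective_conductance` needs."""
    post_pop = net.populations[post]
    kmaps, syns = {}, {}
    for conn in net.pathways_onto(post):
        pre_N = net.populations[conn.pre].N
        kmaps[conn.pre] = synapse_indegree_map(
            conn, post_geometry, pre_N, post_pop, smear_with_soma_density=smear
        )
        syns[conn.pre] = conn.synapse
    if post in net.external:
        drive = net.external[post]
        kmaps["ext"] = synapse_indegree_map(
            drive, post_geometry, 0, post_pop, smear_with_soma_density=smear
        )
        syns["ext"] = drive.synapse
    return kmaps, syns


def perturb_weights(G_bar: Mapping[tuple, float], J: float) -> dict:
    """Rescale mean synaptic conductances by the balance factor J.

    Each pathway's mean weight is raised as
    ``G'_{YX} = G_{YX} * J ** (G_{YX'} / G_{YX})`` where X' is the opposite
    presynaptic type (E<->I), so J > 1 shifts the excitation/inhibition
    balance toward excitation and J = 1 is the identity.

    ``G_bar`` maps (post, pre) pairs, e.g. ``("E", "E")`` for E->E.
    """
    if J <= 0:
        raise ValueError("J must be > 0")
    other = {"E": "I", "I": "E"}
    out = {}
    for (post, pre), g in G_bar.items():
        partner = G_bar[(post, other[pre])]
        if g == 0:
            raise ZeroDivisionError(f"zero mean conductance for pathway {post}<-{pre}")
        out[(post, pre)] = g * J ** (partner / g)
    return out


# ---------------------------------------------------------------------------
# sampled realizations (Monte-Carlo oracle)

@dataclass
class SampledConnectome:
    """One discrete realization of a pathway onto a sampled population.

    Per-synapse arrays: presynaptic neuron index, postsynaptic neuron
    index, postsynaptic compartment, weight (nS), delay (ms); plus the
    sampled soma positions (N_Y, 3) in um.
    """

    pre: np.ndarray
    post: np.ndarray
    comp: np.ndarray
    weight_nS: np.ndarray
    delay_ms: np.ndarray
    soma_positions: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "pre": self.pre,
                "post": self.post,
                "compartment": self.comp,
                "weight_nS": self.weight_nS,
                "delay_ms": self.delay_ms,
            }
        )


def sample_soma_positions(pop: PopulationSpec, rng: np.random.Generator) -> np.ndarray:
    """Sample soma positions: uniform areal density within the population
    radius (pdf proportional to r), Gaussian depth N(0, depth_sigma)."""
    r = pop.radius * np.sqrt(rng.uniform(size=pop.N))
    th = rng.uniform(0, 2 * np.pi, size=pop.N)
    z = rng.normal(0.0, pop.depth_sigma, size=pop.N)
    return np.column_stack([r * np.cos(th), r * np.sin(th), z])


def sample_realization(
    conn: ConnectionSpec,
    pre_pop: PopulationSpec,
    post_pop: PopulationSpec,
    post_geometry: CompartmentGeometry,
    seed,
) -> SampledConnectome:
    """Sample a discrete connectome for one pathway.

    Per (pre, post) pair a connection exists with probability C (no
    autapses within a population); per connection the multapse count is
    drawn from the discretized Gaussian, synapse placements from
    ``L(z_m + z_soma) * A_m`` over allowed compartments (evaluated at each
    cell's own depth — the discrete counterpart of the smeared expectation
    profile), weights from the zero-truncated and delays from the
    0.3 ms-truncated Gaussians.  Fully reproducible per seed.
    """
    rng = np.random.default_rng(seed)
    soma = sample_soma_positions(post_pop, rng)
    k_support, k_pmf = conn.multapse_pmf()
    allowed_mask = (
        post_geometry.section_mask(conn.allowed_sections)
        if conn.allowed_sections is not None
        else np.ones(post_geometry.n, bool)
    )
    same_pop = conn.pre == conn.post
    pre_l, post_l, comp_l = [], [], []
    for v in range(post_pop.N):
        connected = rng.uniform(size=pre_pop.N) < conn.C
        if same_pop and v < pre_pop.N:
            connected[v] = False  # no autapses
        partners = np.flatnonzero(connected)
        if len(partners) == 0:
            continue
        counts = rng.choice(k_support, size=len(partners), p=k_pmf)
        n_syn = int(counts.sum())
        w = conn.profile.pdf(post_geometry.z + soma[v, 2]) * post_geometry.areas
        w = np.where(allowed_mask, w, 0.0)
        s = w.sum()
        if s == 0:
            raise ValueError("synapse density is zero on all allowed compartments")
        comps = rng.choice(post_geometry.n, size=n_syn, p=w / s)
        pre_l.append(np.repeat(partners, counts))
        post_l.append(np.full(n_syn, v))
        comp_l.append(comps)
    if pre_l:
        pre = np.concatenate(pre_l)
        post = np.concatenate(post_l)
        comp = np.concatenate(comp_l)
    else:
        pre = post = comp = np.empty(0, dtype=int)
    n_total = len(pre)
    weights = truncated_gaussian_samples(rng, conn.weight_mu, conn.weight_sigma, 0.0, n_total)
    delays = truncated_gaussian_samples(
        rng, conn.delay_mu, conn.delay_sigma, conn.delay_min, n_total
    )
    return SampledConnectome(
        pre=pre, post=post, comp=comp, weight_nS=weights, delay_ms=delays,
        soma_positions=soma,
    )


# ---------------------------------------------------------------------------
# built-in reference parameterization

#: per-section passive leak (S/cm²) for the ball-and-sticks presets;
#: leak reversal -90 mV, capacitance 1 uF/cm², axial resistivity 100 Ohm*cm
_LEAK = {
    "soma": LeakSpec(g_L=0.0000338, E_L=-90.0, c_m=1.0),
    "apic": LeakSpec(g_L=0.0000589, E_L=-90.0, c_m=1.0),
    "basal": LeakSpec(g_L=0.0000589, E_L=-90.0, c_m=1.0),
}

#: I_h-style conductance densities (S/cm²) per section for the presets;
#: kinetics are the package's generic/synthetic single-gate model
_IH_DENSITY = {"soma": 0.0002, "apic": 0.002, "basal": 0.002}


def build_preset_cell(pop: PopulationSpec, with_ih: bool = False) -> CompartmentalCell:
    """Build the (nonlinearized) cell for a population preset.

    ``with_ih=True`` adds the generic single-gate I_h-style channel at the
    tabulated section densities; the default is the passive cell (leak
    only), on which "frozen" linearization is a no-op beyond the
    current-based synapse approximation.
    """
    geom = build_ball_and_sticks(preset_sections(pop.cell_preset))
    densities = None
    if with_ih:
        densities = {
            sec: (generic_ih(g_w=g),) for sec, g in _IH_DENSITY.items()
        }
    return make_cell(geom, _LEAK, R_a=100.0, channel_densities=densities)


def _syn(pre: str, G_mean: float) -> SynapseKernel:
    if pre == "E":
        return SynapseKernel(tau1=0.2, tau2=1.8, E_syn=0.0, G_mean=G_mean)
    return SynapseKernel(tau1=0.1, tau2=9.0, E_syn=-80.0, G_mean=G_mean)


def reference_network(
    N_E: int = 8192,
    N_I: int = 1024,
    rates: Optional[Mapping[str, float]] = None,
    V_bar: float = -70.0,
    J: float = 1.0,
) -> NetworkSpec:
    """The built-in two-population reference network.

    Excitatory ("E", ball-and-sticks with a 1 mm apical dendrite) and
    inhibitory ("I", symmetric about the soma) populations, pairwise
    connection probability 0.05, tabulated multapse / weight / delay
    distributions and depth profiles, plus a fixed-rate Poisson external
    drive.  ``rates`` defaults to the reference stationary rates
    ``{"E": 2.6, "I": 5.1, "ext": 40.0}``; ``J`` applies the
    excitation/inhibition balance perturbation to the mean weights.
    """
    pops = {
        "E": PopulationSpec(name="E", N=N_E, cell_preset="E", V_bar=V_bar),
        "I": PopulationSpec(name="I", N=N_I, cell_preset="I", V_bar=V_bar),
    }
    G = {("E", "E"): 0.15, ("I", "E"): 0.125, ("E", "I"): 4.5, ("I", "I"): 2.0}
    if J != 1.0:
        G = perturb_weights(G, J)
    # weight std scales with the mean (10% for E->E and I->I/I->E per table)
    G_sigma = {
        ("E", "E"): G[("E", "E")] * (0.02 / 0.15),
        ("I", "E"): G[("I", "E")] * (0.0125 / 0.125),
        ("E", "I"): G[("E", "I")] * (0.45 / 4.5),
        ("I", "I"): G[("I", "I")] * (0.2 / 2.0),
    }
    multapse = {"E": (2.0, 0.5), "I": (5.0, 1.0)}
    delays = {
        ("E", "E"): (1.5, 0.3),
        ("I", "E"): (1.4, 0.4),
        ("E", "I"): (1.3, 0.5),
        ("I", "I"): (1.2, 0.6),
    }
    profiles = {
        ("E", "E"): DepthProfile.mixture((1 / 3, 0.0, 100.0), (2 / 3, 500.0, 100.0)),
        ("I", "E"): DepthProfile.gaussian(50.0, 100.0),
        ("E", "I"): DepthProfile.gaussian(-50.0, 100.0),
        ("I", "I"): DepthProfile.gaussian(-100.0, 100.0),
    }
    # excitatory axons avoid the soma; no restriction for inhibitory inputs
    allowed = {
        ("E", "E"): ("apic", "basal"),
        ("I", "E"): ("apic", "basal"),
        ("E", "I"): None,
        ("I", "I"): None,
    }
    conns = {}
    for (post, pre), g in G.items():
        mm, ms = multapse[pre]
        dm, dsd = delays[(post, pre)]
        conns[(pre, post)] = ConnectionSpec(
            pre=pre, post=post, C=0.05,
            multapse_mu=mm, multapse_sigma=ms,
            weight_mu=g, weight_sigma=G_sigma[(post, pre)],
            delay_mu=dm, delay_sigma=dsd,
            profile=profiles[(post, pre)],
            synapse=_syn(pre, g),
            allowed_sections=allowed[(post, pre)],
        )
    external = {
        "E": ExternalDriveSpec(post="E", k_syn=465),
        "I": ExternalDriveSpec(post="I", k_syn=160),
    }
    if rates is None:
        rates = {"E": 2.6, "I": 5.1, "ext": 40.0}
    return NetworkSpec(
        populations=pops, connections=conns, external=external, rates=dict(rates)
    )
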