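"""Configuration round-trip and seeded test fixtures.

The statistical network description (populations, pathways, external
drives, rates) serializes to a plain YAML/JSON-able dict mirroring the
reference parameter tables, so a run is fully specified by one
human-readable file plus a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .membrane import SynapseKernel, generic_ih
from .netspec import (
    ConnectionSpec,
    DepthProfile,
    ExternalDriveSpec,
    NetworkSpec,
    PopulationSpec,
    reference_network,
)

__all__ = [
    "network_to_dict",
    "network_from_dict",
    "load_network",
    "save_network",
    "RunConfig",
    "make_fixtures",
]

SCHEMA_VERSION = 1


def _profile_to_dict(p: DepthProfile) -> dict:
    return {"components": [list(c) for c in p.components]}


def _profile_from_dict(d: dict) -> DepthProfile:
    return DepthProfile(components=tuple(tuple(c) for c in d["components"]))


def _syn_to_dict(s: SynapseKernel) -> dict:
    return {"tau1": s.tau1, "tau2": s.tau2, "E_syn": s.E_syn,
            "G_mean": s.G_mean, "t_s": s.t_s}


def network_to_dict(net: NetworkSpec) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "populations": {
            name: {
                "N": p.N, "cell_preset": p.cell_preset,
                "depth_sigma": p.depth_sigma, "radius": p.radius,
                "V_bar": p.V_bar,
            }
            for name, p in net.populations.items()
        },
        "connections": [
            {
                "pre": c.pre, "post": c.post, "C": c.C,
                "multapse": [c.multapse_mu, c.multapse_sigma],
                "weight": [c.weight_mu, c.weight_sigma],
                "delay": [c.delay_mu, c.delay_sigma],
                "delay_min": c.delay_min,
                "profile": _profile_to_dict(c.profile),
                "synapse": _syn_to_dict(c.synapse),
                "allowed_sections": (
                    list(c.allowed_sections) if c.allowed_sections else None
                ),
            }
            for c in net.connections.values()
        ],
        "external": {
            name: {"k_syn": d.k_syn, "rate": d.rate, "synapse": _syn_to_dict(d.synapse)}
            for name, d in net.external.items()
        },
        "rates": dict(net.rates),
    }


def network_from_dict(d: dict) -> NetworkSpec:
    if d.get("schema_version", 1) != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {d.get('schema_version')!r}")
    pops = {
        name: PopulationSpec(name=name, **p) for name, p in d["populations"].items()
    }
    conns = {}
    for c in d["connections"]:
        conns[(c["pre"], c["post"])] = ConnectionSpec(
            pre=c["pre"], post=c["post"], C=c["C"],
            multapse_mu=c["multapse"][0], multapse_sigma=c["multapse"][1],
            weight_mu=c["weight"][0], weight_sigma=c["weight"][1],
            delay_mu=c["delay"][0], delay_sigma=c["delay"][1],
            delay_min=c.get("delay_min", 0.3),
            profile=_profile_from_dict(c["profile"]),
            synapse=SynapseKernel(**c["synapse"]),
            allowed_sections=(
                tuple(c["allowed_sections"]) if c.get("allowed_sections") else None
            ),
        )
    external = {
        name: ExternalDriveSpec(post=name, k_syn=e["k_syn"], rate=e["rate"],
                                synapse=SynapseKernel(**e["synapse"]))
        for name, e in d["external"].items()
    }
    return NetworkSpec(populations=pops, connections=conns, external=external,
                       rates=dict(d["rates"]))


def save_network(net: NetworkSpec, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(network_to_dict(net), fh, sort_keys=True)


def load_network(path) -> NetworkSpec:
    import yaml

    with open(path) as fh:
        return network_from_dict(yaml.safe_load(fh))


@dataclass
class RunConfig:
    """End-to-end run options binding the pipeline stages together."""

    network: Optional[str] = None  # path to a network YAML (None = built-in)
    mode: str = "frozen"
    g_eff: bool = True
    tau_max: float = 100.0
    dt: float = 0.0625
    duration: float = 12000.0
    seed: int = 1
    lif_current_scale: float = 9.275e-4
    outdir: str = "."

    def __post_init__(self) -> None:
        n = self.tau_max / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("tau_max must be a multiple of dt")

    def load_network(self) -> NetworkSpec:
        if self.network is None:
            return reference_network()
        return load_network(self.network)


def make_fixtures(kind: str, seed: int = 1):
    """Seeded, documented fixtures used across the test suite.

    kinds: ``toy-cell`` (single-compartment passive cell),
    ``synthetic-channel`` (sigmoid-gate channel with registered analytic
    derivative), ``tiny-population`` (scaled-down two-population network,
    N_E=32/N_I=8), ``delta-spikes`` (one spike per population),
    ``sine-rates`` (55 Hz modulated rate series).
    """
    rng = np.random.default_rng(seed)
    if kind == "toy-cell":
        from .cable import make_cell
        from .membrane import LeakSpec
        from .morphology import SectionSpec, build_ball_and_sticks

        geom = build_ball_and_sticks([SectionSpec("soma", 30.0, 30.0, 1)])
        return make_cell(geom, LeakSpec(g_L=5e-5, E_L=-70.0))
    if kind == "synthetic-channel":
        return generic_ih(g_w=1e-4)
    if kind == "tiny-population":
        return reference_network(N_E=32, N_I=8)
    if kind == "delta-spikes":
        from .lifnet import SpikeData

        return SpikeData(
            ids=np.array([0, 32]), times=np.array([10.0, 10.0]),
            populations={"E": (0, 32), "I": (32, 40)}, duration=100.0,
        )
    if kind == "sine-rates":
        from .lifnet import RateSeries

        dt = 0.0625
        t = (np.arange(int(round(2000.0 / dt))) + 0.5) * dt
        base = 5.0 + 4.0 * np.sin(2 * np.pi * 55.0 * t / 1000.0)
        jitter = 0.1 * rng.standard_normal(len(t))
        return RateSeries(t=t, dt=dt, rates={"E": base + jitter, "I": base[::-1].copy()})
    raise ValueError(f"unknown fixture kind {kind!r}")
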