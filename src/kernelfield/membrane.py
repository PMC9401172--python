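"""Membrane current models and their linearizations.

Implements the building blocks of the quasi-active cable description:

* passive leak (:class:`LeakSpec`),
* generic voltage-gated channels with a single gating variable
  (:class:`GatedChannel`),
* their first-order ("quasi-active") linearization about a holding voltage
  V̄m, including the "passive-frozen" special case
  (:func:`linearize_channel`),
* the current-based approximation to conductance synapses
  (:func:`current_synapse`) with the two-exponential (beta) waveform
  (:class:`SynapseKernel`),
* the effective membrane conductance g_eff that absorbs the time-averaged
  conductance of persistently active synapses
  (:func:`effective_conductance`).

Linearizing a channel ``i_w = -ḡ_w ω (V - E_w)`` about V̄m yields a
conductance ratio ``γ_R = 1 + ḡ_w ω_∞(V̄m)/ḡ_L`` and a feedback strength
``η = (ḡ_w (V̄m - E_w)/ḡ_L) ∂ω_∞/∂V``; η > 0 acts as negative feedback
(sag/rebound for I_h-type currents), η = 0 freezes the gate, leaving a
purely passive extra conductance.

Units: specific conductances S/cm², capacitance uF/cm², voltages mV,
times ms, synaptic conductance nS, synaptic current nA.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional

import numpy as np

__all__ = [
    "LeakSpec",
    "GatedChannel",
    "QuasiActiveChannel",
    "SynapseKernel",
    "generic_ih",
    "linearize_channel",
    "shift_leak_reversal",
    "current_synapse",
    "synapse_waveform_integral",
    "effective_conductance",
]

#: central-difference step (mV) for numerical d(omega_inf)/dV
_DV = 1e-3


@dataclass(frozen=True)
class LeakSpec:
    """Passive membrane: leak conductance ḡ_L (S/cm²), reversal E_L (mV),
    capacitance c_m (uF/cm²)."""

    g_L: float
    E_L: float
    c_m: float = 1.0

    def __post_init__(self) -> None:
        if self.g_L <= 0:
            raise ValueError("g_L must be > 0")
        if self.c_m <= 0:
            raise ValueError("c_m must be > 0")


@dataclass(frozen=True)
class GatedChannel:
    """Voltage-gated channel with one gating variable omega.

    ``i_w(t) = -g_w * omega(t) * (V - E_w)`` with
    ``tau_w(V) d(omega)/dt = omega_inf(V) - omega``.

    Parameters
    ----------
    g_w : peak conductance density, S/cm².
    E_w : reversal potential, mV.
    omega_inf : activation function V -> [0, 1].
    tau_w : activation time function V -> ms (> 0).
    d_omega_inf : optional analytic derivative of ``omega_inf``; when absent
        a central difference with step 1e-3 mV is used.
    name : label used in diagnostics.
    """

    g_w: float
    E_w: float
    omega_inf: Callable[[float], float]
    tau_w: Callable[[float], float]
    d_omega_inf: Optional[Callable[[float], float]] = None
    name: str = "channel"

    def slope(self, V: float) -> float:
        """d(omega_inf)/dV at V."""
        if self.d_omega_inf is not None:
            return float(self.d_omega_inf(V))
        return (self.omega_inf(V + _DV) - self.omega_inf(V - _DV)) / (2 * _DV)


@dataclass(frozen=True)
class QuasiActiveChannel:
    """Linearized channel: parameters of the quasi-active approximation.

    ``gamma_R`` is the ratio of total to leak conductance at V̄m, ``eta``
    the feedback strength, ``tau_w_bar`` the gating time constant at V̄m.
    ``frozen`` channels have their gating dynamics removed (eta treated as
    zero).  ``g_open = g_w * omega_inf(V̄m)`` (S/cm²) and
    ``b = g_L * eta = g_w (V̄m - E_w) * d(omega_inf)/dV`` (S/cm² per mV of
    the auxiliary state) are the absolute quantities entering the cable
    equations, so the dynamics do not depend on which leak value gamma_R
    and eta were normalized by.
    """

    gamma_R: float
    eta: float
    tau_w_bar: float
    V_bar: float
    g_open: float
    b: float
    E_w: float
    g_w: float
    frozen: bool = False
    name: str = "channel"

    @property
    def eta_effective(self) -> float:
        return 0.0 if self.frozen else self.eta


def linearize_channel(
    ch: GatedChannel,
    leak: LeakSpec,
    V_bar: float,
    mode: str = "quasi_active",
) -> QuasiActiveChannel:
    """Linearize a gated channel about V̄m.

    ``mode="quasi_active"`` keeps the first-order gating dynamics as an
    auxiliary state; ``mode="frozen"`` sets eta = 0 while keeping the same
    steady-state conductance (gamma_R).

    Raises
    ------
    ZeroDivisionError if the leak conductance is zero.
    """
    if mode not in ("quasi_active", "frozen"):
        raise ValueError("mode must be 'quasi_active' or 'frozen'")
    if leak.g_L == 0:
        raise ZeroDivisionError("leak conductance is zero")
    if not -120.0 <= V_bar <= 60.0:
        warnings.warn(
            f"V_bar = {V_bar} mV outside the channel validity window [-120, 60] mV",
            stacklevel=2,
        )
    w_inf = float(ch.omega_inf(V_bar))
    tau = float(ch.tau_w(V_bar))
    if tau <= 0:
        raise ValueError("tau_w(V_bar) must be > 0")
    slope = ch.slope(V_bar)
    gamma_R = 1.0 + ch.g_w * w_inf / leak.g_L
    eta = ch.g_w * (V_bar - ch.E_w) / leak.g_L * slope
    return QuasiActiveChannel(
        gamma_R=gamma_R,
        eta=eta,
        tau_w_bar=tau,
        V_bar=V_bar,
        g_open=ch.g_w * w_inf,
        b=ch.g_w * (V_bar - ch.E_w) * slope,
        E_w=ch.E_w,
        g_w=ch.g_w,
        frozen=(mode == "frozen"),
        name=ch.name,
    )


def shift_leak_reversal(
    leak: LeakSpec,
    channels: Iterable[QuasiActiveChannel],
    V_bar: float,
) -> float:
    """Leak reversal E_L' that makes V̄m the resting potential.

    With linearized channels kept as explicit conductances
    ``g_open = ḡ_w ω_∞(V̄m)``, a resting membrane requires

    ``E_L' = V̄m + Σ_w ḡ_w ω_∞(V̄m) (V̄m − E_w) / ḡ_L``

    so that leak and channel currents cancel at V̄m.  With no channels the
    shift is the identity, E_L' = V̄m.
    """
    s = sum(c.g_open * (V_bar - c.E_w) for c in channels)
    return V_bar + s / leak.g_L


@dataclass(frozen=True)
class SynapseKernel:
    """Two-exponential (beta) synaptic conductance time course.

    ``f(t) = (exp(-(t-t_s)/tau1) - exp(-(t-t_s)/tau2)) / norm`` for
    ``t >= t_s``, normalized to peak exactly 1 at ``t_s + tau_peak`` with
    ``tau_peak = tau2*tau1/(tau2-tau1) * log(tau2/tau1)``.

    ``tau1`` is the rise and ``tau2`` the decay time constant (ms,
    ``tau2 > tau1 > 0``); ``E_syn`` the reversal potential (mV); ``G_mean``
    the mean peak conductance (nS); ``t_s`` the activation time (ms).
    """

    tau1: float
    tau2: float
    E_syn: float = 0.0
    G_mean: float = 1.0
    t_s: float = 0.0

    def __post_init__(self) -> None:
        if not (self.tau2 > self.tau1 > 0):
            raise ValueError(
                "require tau2 > tau1 > 0 (the alpha-function limit tau1 == tau2 "
                "is not supported)"
            )

    @property
    def tau_peak(self) -> float:
        t1, t2 = self.tau1, self.tau2
        return t2 * t1 / (t2 - t1) * math.log(t2 / t1)

    @property
    def _norm(self) -> float:
        tp = self.tau_peak
        return math.exp(-tp / self.tau1) - math.exp(-tp / self.tau2)

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Evaluate f(t) (unitless, in [0, 1]) on time array t (ms)."""
        t = np.asarray(t, dtype=float)
        rel = t - self.t_s
        out = np.zeros_like(rel)
        m = rel >= 0
        out[m] = (np.exp(-rel[m] / self.tau1) - np.exp(-rel[m] / self.tau2)) / self._norm
        return out


def current_synapse(syn: SynapseKernel, V_bar: float) -> tuple[float, Callable]:
    """Current-based approximation: Ī_syn = Ḡ_syn (V̄m − E_syn).

    Returns the constant current amplitude Ī_syn in nA (negative = inward,
    e.g. excitatory at subthreshold V̄m) together with the unitless
    waveform ``f(t)``.  The synaptic current is ``Ī_syn · f(t)``.
    """
    # nS * mV = pA -> nA
    I_bar = syn.G_mean * (V_bar - syn.E_syn) * 1e-3
    return I_bar, syn.waveform


def synapse_waveform_integral(syn: SynapseKernel) -> float:
    """∫₀^∞ f(t) dt in ms (closed form).

    ``∫ f = (tau1 - tau2) / (exp(-tau_peak/tau1) - exp(-tau_peak/tau2))``,
    positive for tau2 > tau1.
    """
    return (syn.tau1 - syn.tau2) / syn._norm


def effective_conductance(
    leak: Union["LeakSpec", np.ndarray],
    areas_um2: np.ndarray,
    indegree_maps: Mapping[str, np.ndarray],
    rates: Mapping[str, float],
    synapses: Mapping[str, SynapseKernel],
) -> np.ndarray:
    """Per-compartment effective leak conductance g_eff,m (S/cm²).

    Persistent synaptic bombardment at presynaptic rate ⟨ν_X'⟩ adds a
    time-averaged conductance per compartment

    ``g_eff,m = ḡ_L + (1/A_m) Σ_X' ⟨ν_X'⟩ ⟨k_syn,m⟩ Ḡ_syn ∫₀^∞ f(t) dt``

    where the sum runs over every pathway key in ``indegree_maps``
    (recurrent pathways *and* the external drive ``'ext'``).

    Parameters
    ----------
    areas_um2 : compartment membrane areas (um²).
    leak : base leak as a :class:`LeakSpec` or a per-compartment
        conductance array (S/cm², e.g. already-modified values).
    indegree_maps : pathway -> per-compartment expected synapse count.
    rates : pathway -> mean presynaptic rate (s⁻¹, >= 0).
    synapses : pathway -> synapse kernel (supplies Ḡ in nS and ∫f in ms).

    Notes
    -----
    Units: s⁻¹ · nS · ms = 1e-12 S; areas are converted um² -> cm²
    (1 um² = 1e-8 cm²).
    """
    areas_cm2 = np.asarray(areas_um2, float) * 1e-8
    g_base = leak.g_L if isinstance(leak, LeakSpec) else np.asarray(leak, float)
    g = np.broadcast_to(g_base, (len(areas_cm2),)).astype(float).copy()
    for key, kmap in indegree_maps.items():
        nu = float(rates[key])
        if nu < 0:
            raise ValueError(f"negative rate for pathway {key!r}")
        syn = synapses[key]
        intf = synapse_waveform_integral(syn)  # ms
        incr_S = nu * np.asarray(kmap, float) * syn.G_mean * 1e-9 * intf * 1e-3
        g += incr_S / areas_cm2
    return g


def generic_ih(g_w: float, E_w: float = -45.0, v_half: float = -107.0,
               k: float = 12.0, name: str = "Ih_generic") -> GatedChannel:
    """A generic (synthetic) hyperpolarization-activated cation channel.

    Stand-in kinetics in the style of HCN/I_h currents: sigmoidal
    activation opening with hyperpolarization (half-activation ``v_half``,
    slope ``k`` — defaults in the range published for neocortical HCN,
    around -107 mV and 12 mV) and a bell-shaped activation time constant
    of a few tens of ms peaking near ``v_half``.  These are *not* the
    kinetics of any particular published cell model; only the conductance
    density and reversal are caller-supplied.
    """

    def omega_inf(V):
        return 1.0 / (1.0 + math.exp((V - v_half) / k))

    def d_omega_inf(V):
        s = 1.0 / (1.0 + math.exp((V - v_half) / k))
        return -s * (1.0 - s) / k

    def tau_w(V):
        return 8.0 + 40.0 / math.cosh((V - v_half) / 20.0)

    return GatedChannel(
        g_w=g_w, E_w=E_w, omega_inf=omega_inf, tau_w=tau_w,
        d_omega_inf=d_omega_inf, name=name,
    )
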