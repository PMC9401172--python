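"""Compartmental cable solver.

Assembles the coupled compartment equations for a morphology with passive
leak, gated or linearized (quasi-active / frozen) channels, and injected
current waveforms, and integrates them:

* **linear mode** (all channels linearized, the normal operating mode for
  kernel prediction): unconditionally stable implicit stepping
  (Crank-Nicolson) on the full state (voltages plus auxiliary gating
  states), with the coefficient matrix factorized once;
* **nonlinear mode** (gated channels retained, used for small validation
  experiments only): stiff ODE integration via ``scipy.integrate.solve_ivp``.

The per-compartment transmembrane current ``I_m`` returned with each
simulation is the net axial current flowing into each compartment, which by
charge conservation equals the total membrane current (capacitive + ionic +
point currents booked to their host compartment, with electrode/synaptic
point currents counted as membrane currents).  Summed over the cell it is
zero to machine precision at every step — the property volume-conductor
forward models require.

Internal absolute units: capacitance nF, conductance uS, current nA,
voltage mV, time ms.  (1 uS * 1 mV = 1 nA; 1 nF * 1 mV/ms = 1 nA.)
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
import scipy.linalg

from .membrane import (
    GatedChannel,
    LeakSpec,
    QuasiActiveChannel,
    linearize_channel,
    shift_leak_reversal,
)
from .morphology import CompartmentGeometry

__all__ = [
    "CompartmentalCell",
    "SimulationResult",
    "IntegrationError",
    "make_cell",
    "axial_conductance_matrix",
    "simulate",
    "step_current_experiment",
]


class IntegrationError(RuntimeError):
    """Raised when the nonlinear integrator diverges (NaN/Inf)."""


def axial_conductance_matrix(geometry: CompartmentGeometry, R_a: float) -> np.ndarray:
    """Symmetric axial conductance matrix (uS).

    The conductance between two adjacent compartments is the series
    combination of their half-compartment cytoplasmic resistances
    ``R_half = R_a * (L/2) / (pi (d/2)^2)`` (R_a in Ohm*cm, L and d
    converted um -> cm); at branch points half-resistances pair up the same
    way.  Off-diagonal entries are ``+g_ij``; the diagonal holds
    ``-sum_j g_ij`` so that ``(G @ V)_i`` is the net axial current (nA)
    flowing *into* compartment i.
    """
    n = geometry.n
    L_cm = geometry.lengths * 1e-4
    r_cm = geometry.diameters / 2 * 1e-4
    half_R = R_a * (L_cm / 2) / (np.pi * r_cm**2)  # Ohm
    G = np.zeros((n, n))
    for i in range(n):
        p = geometry.parent_index[i]
        if p < 0:
            continue
        g_uS = 1e6 / (half_R[i] + half_R[p])
        G[i, p] += g_uS
        G[p, i] += g_uS
        G[i, i] -= g_uS
        G[p, p] -= g_uS
    return G


@dataclass
class CompartmentalCell:
    """Discretized cell: geometry plus per-compartment membrane description.

    ``g_L``, ``E_L``, ``c_m`` are per-compartment arrays (S/cm², mV,
    uF/cm²); ``channels`` is a list of ``(compartment_index, channel)``
    pairs where each channel is either a :class:`GatedChannel` (nonlinear
    mode) or a :class:`QuasiActiveChannel` (linear mode).  ``V_bar`` is the
    per-compartment linearization voltage (NaN until :meth:`linearized` is
    applied).
    """

    geometry: CompartmentGeometry
    g_L: np.ndarray
    E_L: np.ndarray
    c_m: np.ndarray
    R_a: float
    channels: list = field(default_factory=list)
    V_bar: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n = self.geometry.n
        for name in ("g_L", "E_L", "c_m"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim == 0:
                arr = np.full(n, float(arr))
            if len(arr) != n:
                raise ValueError(f"{name} must have one value per compartment")
            setattr(self, name, arr)

    # -- derived absolute quantities ------------------------------------
    @property
    def areas_cm2(self) -> np.ndarray:
        return self.geometry.areas * 1e-8

    @property
    def C_nF(self) -> np.ndarray:
        return self.c_m * self.areas_cm2 * 1e3

    @property
    def G_L_uS(self) -> np.ndarray:
        return self.g_L * self.areas_cm2 * 1e6

    @property
    def is_linear(self) -> bool:
        return all(isinstance(ch, QuasiActiveChannel) for _, ch in self.channels)

    # -- transformations -------------------------------------------------
    def linearized(self, V_bar: Union[float, np.ndarray], mode: str = "quasi_active"
                   ) -> "CompartmentalCell":
        """Return a copy with all gated channels linearized about V̄m.

        The leak reversal is shifted per compartment so the linearized cell
        rests at V̄m (``shift_leak_reversal``); already-linearized channels
        are re-linearized from their stored gate parameters only if gated.
        """
        n = self.geometry.n
        Vb = np.broadcast_to(np.asarray(V_bar, float), (n,)).copy()
        new_channels = []
        per_comp: dict[int, list[QuasiActiveChannel]] = {}
        for idx, ch in self.channels:
            if isinstance(ch, QuasiActiveChannel):
                qa = replace(ch, frozen=(mode == "frozen") or ch.frozen)
            else:
                leak = LeakSpec(g_L=self.g_L[idx], E_L=self.E_L[idx], c_m=self.c_m[idx])
                qa = linearize_channel(ch, leak, Vb[idx], mode=mode)
            new_channels.append((idx, qa))
            per_comp.setdefault(idx, []).append(qa)
        E_L_new = np.empty(n)
        for i in range(n):
            leak = LeakSpec(g_L=self.g_L[i], E_L=self.E_L[i], c_m=self.c_m[i])
            E_L_new[i] = shift_leak_reversal(leak, per_comp.get(i, []), Vb[i])
        return CompartmentalCell(
            geometry=self.geometry, g_L=self.g_L.copy(), E_L=E_L_new,
            c_m=self.c_m.copy(), R_a=self.R_a, channels=new_channels, V_bar=Vb,
        )

    def with_leak(self, g_L: np.ndarray) -> "CompartmentalCell":
        """Copy with per-compartment leak replaced (e.g. by g_eff).

        For a linearized cell the leak reversal is re-derived so the rest
        stays at V̄m.
        """
        out = CompartmentalCell(
            geometry=self.geometry, g_L=np.asarray(g_L, float).copy(),
            E_L=self.E_L.copy(), c_m=self.c_m.copy(), R_a=self.R_a,
            channels=list(self.channels), V_bar=None if self.V_bar is None else self.V_bar.copy(),
        )
        if out.V_bar is not None and out.is_linear:
            per_comp: dict[int, list[QuasiActiveChannel]] = {}
            for idx, ch in out.channels:
                per_comp.setdefault(idx, []).append(ch)
            for i in range(out.geometry.n):
                leak = LeakSpec(g_L=out.g_L[i], E_L=out.E_L[i], c_m=out.c_m[i])
                out.E_L[i] = shift_leak_reversal(leak, per_comp.get(i, []), out.V_bar[i])
        return out


def make_cell(
    geometry: CompartmentGeometry,
    leak: Union[LeakSpec, Mapping[str, LeakSpec]],
    R_a: float = 100.0,
    channels: Sequence[tuple] = (),
    channel_densities: Optional[Mapping[str, Sequence]] = None,
) -> CompartmentalCell:
    """Build a :class:`CompartmentalCell`.

    ``leak`` is either one :class:`LeakSpec` for the whole cell or one per
    section name.  ``channels`` lists explicit ``(compartment_index,
    channel)`` pairs; ``channel_densities`` maps section name -> iterable of
    channels applied to every compartment of that section.
    """
    n = geometry.n
    if isinstance(leak, LeakSpec):
        g_L = np.full(n, leak.g_L)
        E_L = np.full(n, leak.E_L)
        c_m = np.full(n, leak.c_m)
    else:
        g_L = np.empty(n)
        E_L = np.empty(n)
        c_m = np.empty(n)
        for i, sec in enumerate(geometry.section):
            spec = leak[sec]
            g_L[i], E_L[i], c_m[i] = spec.g_L, spec.E_L, spec.c_m
    chan_list = list(channels)
    if channel_densities:
        for sec, chs in channel_densities.items():
            for i in np.flatnonzero(geometry.section == sec):
                for ch in chs:
                    chan_list.append((int(i), ch))
    return CompartmentalCell(geometry, g_L, E_L, c_m, R_a, chan_list)


@dataclass
class SimulationResult:
    """Time grid plus per-compartment voltages and transmembrane currents.

    ``V`` and ``I_m`` have shape ``(n_compartments, n_steps)``; ``I_m`` is
    in nA, outward positive, and sums to ~0 over compartments at every step.
    """

    t: np.ndarray
    V: np.ndarray
    I_m: np.ndarray
    dt: float

    def to_hdf5(self, path, geometry: Optional[CompartmentGeometry] = None) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("time", data=self.t, track_times=False)
            f.create_dataset("V_m", data=self.V, track_times=False)
            f.create_dataset("I_m", data=self.I_m, track_times=False)
            f.attrs["dt"] = self.dt
            if geometry is not None:
                g = f.create_group("compartments")
                g.create_dataset("midpoints", data=geometry.midpoints, track_times=False)
                g.create_dataset("lengths", data=geometry.lengths, track_times=False)
                g.create_dataset("diameters", data=geometry.diameters, track_times=False)
                g.create_dataset(
                    "section",
                    data=np.array([s.encode() for s in geometry.section]),
                    track_times=False,
                )


class LinearCableSystem:
    """Assembled linear (quasi-active/frozen) compartment equations.

    State ``x = [V_0..V_{n-1}, eps_0..]`` obeys ``dx/dt = A x + c + u(t)``
    with ``u`` nonzero only in the voltage block (injected current / C).
    Provides a Crank-Nicolson stepper whose matrix factors are computed
    once, and supports batched inputs (many cells sharing one membrane
    description, as used by the Monte-Carlo kernel oracle).
    """

    def __init__(self, cell: CompartmentalCell, dt: float):
        if not cell.is_linear:
            raise ValueError("cell has non-linearized channels")
        self.cell = cell
        self.dt = dt
        n = cell.geometry.n
        self.n = n
        C = cell.C_nF
        G_ax = axial_conductance_matrix(cell.geometry, cell.R_a)
        self.G_ax = G_ax
        qa = [(i, ch) for i, ch in cell.channels]
        eps_channels = [(i, ch) for i, ch in qa if not ch.frozen]
        n_eps = len(eps_channels)
        nst = n + n_eps
        A = np.zeros((nst, nst))
        c = np.zeros(nst)
        A[:n, :n] = G_ax / C[:, None]
        diag_G = cell.G_L_uS.copy()
        c[:n] = cell.G_L_uS * cell.E_L
        areas = cell.areas_cm2
        for i, ch in qa:
            G_open = ch.g_open * areas[i] * 1e6  # uS
            diag_G[i] += G_open
            c[i] += G_open * ch.E_w
        for k, (i, ch) in enumerate(eps_channels):
            B = ch.b * areas[i] * 1e6  # uS per mV of eps
            A[i, n + k] += -B / C[i]
            A[n + k, i] = 1.0 / ch.tau_w_bar
            A[n + k, n + k] = -1.0 / ch.tau_w_bar
            c[n + k] = -ch.V_bar / ch.tau_w_bar
        A[:n, :n] -= np.diag(diag_G / C)
        c[:n] /= C
        self.A = A
        self.c = c
        self.C = C
        self.eps_channels = eps_channels
        h = dt
        I = np.eye(nst)
        self._lu = scipy.linalg.lu_factor(I - (h / 2) * A)
        self._M2 = I + (h / 2) * A

    def rest_state(self) -> np.ndarray:
        """Steady state of the input-free system (A x = -c)."""
        return np.linalg.solve(self.A, -self.c)

    def initial_state(self, V_init: Optional[float]) -> np.ndarray:
        if V_init is None:
            return self.rest_state()
        n = self.n
        x = np.empty(n + len(self.eps_channels))
        x[:n] = V_init
        for k, (i, ch) in enumerate(self.eps_channels):
            x[n + k] = V_init - ch.V_bar
        return x

    def run(self, inputs: Optional[np.ndarray], n_steps: int,
            x0: Optional[np.ndarray] = None) -> tuple[np.ndarray, np.ndarray]:
        """Integrate for ``n_steps`` grid points (including t=0).

        ``inputs``: injected current, nA, shape ``(n_steps, n)`` or
        ``(n_steps, n, n_batch)``; ``None`` means input-free.  Returns
        ``(V, I_m)`` with leading shape ``(n, n_steps[, n_batch])``.
        """
        n, nst = self.n, len(self.c)
        batched = inputs is not None and inputs.ndim == 3
        nb = inputs.shape[2] if batched else 1
        if x0 is None:
            x0 = self.rest_state()
        x = np.repeat(x0[:, None], nb, axis=1) if batched else x0.copy()
        shape = (n, n_steps, nb) if batched else (n, n_steps)
        V = np.empty(shape)
        if batched:
            V[:, 0, :] = x[:n]
        else:
            V[:, 0] = x[:n]
        h = self.dt
        u = np.zeros((nst, nb) if batched else nst)
        for k in range(1, n_steps):
            if inputs is not None:
                u[:n] = (inputs[k - 1] + inputs[k]) / (2 * self.C[:, None] if batched
                                                       else 2 * self.C)
            rhs = self._M2 @ x + h * (self.c[:, None] if batched else self.c) + h * u
            x = scipy.linalg.lu_solve(self._lu, rhs)
            if batched:
                V[:, k, :] = x[:n]
            else:
                V[:, k] = x[:n]
        I_m = np.einsum("ij,j...->i...", self.G_ax, V)
        return V, I_m


def _simulate_nonlinear(cell: CompartmentalCell, duration: float, dt: float,
                        V_init: float, inputs) -> SimulationResult:
    from scipy.integrate import solve_ivp

    n = cell.geometry.n
    t_grid = np.arange(0.0, duration + dt / 2, dt)
    gated = [(i, ch) for i, ch in cell.channels]
    C = cell.C_nF
    G_L = cell.G_L_uS
    G_ax = axial_conductance_matrix(cell.geometry, cell.R_a)
    areas = cell.areas_cm2
    G_w_abs = np.array([ch.g_w * areas[i] * 1e6 for i, ch in gated])

    if inputs is None:
        inj = lambda t: 0.0
    elif callable(inputs):
        inj = inputs
    else:
        arr = np.asarray(inputs)

        def inj(t):
            k = min(int(t / dt), len(arr) - 1)
            return arr[k]

    def rhs(t, x):
        V = x[:n]
        w = x[n:]
        I_ion = G_L * (V - cell.E_L)
        dV = -I_ion + G_ax @ V + inj(t)
        dw = np.empty(len(gated))
        for k, (i, ch) in enumerate(gated):
            dV[i] -= G_w_abs[k] * w[k] * (V[i] - ch.E_w)
            dw[k] = (ch.omega_inf(V[i]) - w[k]) / ch.tau_w(V[i])
        return np.concatenate((dV / C, dw))

    x0 = np.concatenate(
        (np.full(n, V_init), [ch.omega_inf(V_init) for _, ch in gated])
    )
    sol = solve_ivp(rhs, (0.0, t_grid[-1]), x0, method="LSODA", t_eval=t_grid,
                    rtol=1e-8, atol=1e-8, max_step=5.0)
    if not sol.success or not np.all(np.isfinite(sol.y)):
        bad = np.flatnonzero(~np.all(np.isfinite(sol.y), axis=0))
        step = int(bad[0]) if len(bad) else len(sol.t)
        raise IntegrationError(f"nonlinear integration diverged at step {step}")
    V = sol.y[:n]
    I_m = G_ax @ V
    return SimulationResult(t=t_grid, V=V, I_m=I_m, dt=dt)


def simulate(
    cell: CompartmentalCell,
    duration: float,
    dt: float = 0.0625,
    V_init: Optional[float] = None,
    inputs: Optional[np.ndarray] = None,
) -> SimulationResult:
    """Simulate a cell on the grid t = 0, dt, ..., duration.

    Linear mode (all channels linearized) uses unconditionally stable
    Crank-Nicolson stepping; nonlinear mode (any gated channel) uses a
    stiff ODE solver.  ``inputs`` is an injected-current array (nA) of
    shape ``(n_steps, n_compartments)`` or, in nonlinear mode, optionally a
    callable ``t -> (n,) array``.  ``V_init=None`` starts at rest (linear
    mode) or requires an explicit value (nonlinear mode defaults to the
    common -65 mV).
    """
    if duration < dt:
        raise ValueError("duration must be >= dt")
    n_steps = int(round(duration / dt)) + 1
    if cell.is_linear:
        if callable(inputs):
            raise TypeError("linear mode requires inputs as an array, not a callable")
        if inputs is not None:
            inputs = np.asarray(inputs, float)
            if inputs.shape[0] < n_steps:
                pad = np.zeros((n_steps - inputs.shape[0],) + inputs.shape[1:])
                inputs = np.concatenate((inputs, pad), axis=0)
        sys = LinearCableSystem(cell, dt)
        x0 = sys.initial_state(V_init)
        V, I_m = sys.run(inputs, n_steps, x0=x0)
        t = np.arange(n_steps) * dt
        return SimulationResult(t=t, V=V, I_m=I_m, dt=dt)
    return _simulate_nonlinear(cell, duration, dt,
                               -65.0 if V_init is None else V_init, inputs)


def step_current_experiment(
    cell: CompartmentalCell,
    amplitude: float,
    onset: float,
    offset: float,
    site: int = 0,
    duration: Optional[float] = None,
    dt: float = 0.0625,
    V_init: Optional[float] = None,
) -> SimulationResult:
    """Somatic (or arbitrary-site) step-current protocol.

    Injects ``amplitude`` nA into compartment ``site`` between ``onset``
    and ``offset`` ms.  In linear mode the response is affine in the
    amplitude.
    """
    n = cell.geometry.n
    if not 0 <= site < n:
        raise ValueError(f"site {site} outside 0..{n - 1}")
    if duration is None:
        duration = offset + (offset - onset)
    n_steps = int(round(duration / dt)) + 1
    t = np.arange(n_steps) * dt
    inputs = np.zeros((n_steps, n))
    inputs[(t >= onset) & (t < offset), site] = amplitude
    return simulate(cell, duration, dt, V_init=V_init, inputs=inputs)
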