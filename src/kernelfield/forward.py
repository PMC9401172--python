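"""Volume-conductor forward models.

Linear maps F from per-compartment transmembrane currents to measurable
signals, for an infinite homogeneous isotropic conductor of conductivity
sigma:

* :func:`line_source_matrix` — extracellular potential at disk electrodes
  from line-source compartments (single cells at explicit positions);
* :func:`dipole_matrix` — current dipole moment P = sum_m r_m I_m;
* :func:`population_disk_matrix` — potential from a radially homogeneous
  disk of current at each compartment depth, convolved with the
  population's soma-depth density (the collapsed-population model used by
  the deterministic kernel predictor);
* :func:`population_dipole_matrix` — dipole for the collapsed population
  (lateral components cancel by radial symmetry; only z survives).

Unit convention (package-wide): current nA, length um, conductivity S/m,
potential mV, dipole nA*um.  With these units the point-source potential is
exactly ``phi[mV] = I[nA] / (4 pi sigma[S/m] r[um])`` — no extra conversion
constant is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.integrate import quad

from .morphology import CompartmentGeometry

__all__ = [
    "ProbeSpec",
    "ForwardMatrix",
    "default_probe",
    "line_source_matrix",
    "dipole_matrix",
    "population_disk_matrix",
    "population_dipole_matrix",
]

#: seed for the disk-electrode surface sampling, fixed so forward matrices
#: are bit-reproducible
_DISK_SEED = 20220812
_N_DISK_POINTS = 100


@dataclass(frozen=True)
class ProbeSpec:
    """Laminar probe: contact positions (um), contact radius, conductivity.

    ``contacts`` has shape (n_contacts, 3); ``normal`` is the contact
    surface normal (contacts are disks in the plane orthogonal to it).
    """

    contacts: np.ndarray
    r_contact: float = 5.0
    sigma: float = 0.3
    normal: tuple[float, float, float] = (0.0, 1.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "contacts", np.atleast_2d(np.asarray(self.contacts, float)))
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        c = self.contacts
        if len(np.unique(c, axis=0)) != len(c):
            raise ValueError("contacts must be distinct")

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)

    @property
    def z(self) -> np.ndarray:
        return self.contacts[:, 2]


def default_probe() -> ProbeSpec:
    """The built-in 13-contact laminar probe: x=y=0, z = 1000, 900, ..., -200 um."""
    z = np.arange(1000.0, -300.0, -100.0)
    contacts = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
    return ProbeSpec(contacts=contacts)


@dataclass
class ForwardMatrix:
    """Linear source-to-signal map.

    ``values[n, m]`` maps compartment m's current (nA) to row n of the
    signal: mV per nA for potential rows, um for dipole rows.  ``rows``
    labels each output channel (contact z position or axis name).
    """

    values: np.ndarray
    rows: list
    kind: str  # "potential" | "dipole"

    def apply(self, I_m: np.ndarray) -> np.ndarray:
        """Map currents (n_comp, ...) to signals (n_rows, ...)."""
        return np.einsum("nm,m...->n...", self.values, I_m)


def _disk_offsets(probe: ProbeSpec) -> np.ndarray:
    """Fixed-seed sample of points on the contact disk (offsets from centre)."""
    rng = np.random.default_rng(_DISK_SEED)
    r = probe.r_contact * np.sqrt(rng.uniform(size=_N_DISK_POINTS))
    th = rng.uniform(0, 2 * np.pi, size=_N_DISK_POINTS)
    # orthonormal basis of the plane orthogonal to the surface normal
    n = np.asarray(probe.normal, float)
    n = n / np.linalg.norm(n)
    a = np.array([1.0, 0.0, 0.0])
    if abs(n @ a) > 0.9:
        a = np.array([0.0, 0.0, 1.0])
    e1 = np.cross(n, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return r[:, None] * (np.cos(th)[:, None] * e1 + np.sin(th)[:, None] * e2)


def _line_source_points(points: np.ndarray, geometry: CompartmentGeometry,
                        sigma: float) -> np.ndarray:
    """Potential per unit current at `points` from each line-source compartment.

    Integrates the point-source solution along each compartment axis:
    ``f = 1/(4 pi sigma ds) [asinh(t/rho) - asinh((t - ds)/rho)]`` with t
    the axial and rho the perpendicular contact coordinate relative to the
    compartment start.  rho is floored at the compartment radius so a
    contact on (or inside) the line never yields an infinite value.
    """
    a = geometry.starts  # (M, 3)
    b = geometry.ends
    ds = geometry.lengths
    u = (b - a) / ds[:, None]
    rel = points[:, None, :] - a[None, :, :]  # (P, M, 3)
    t = np.einsum("pmk,mk->pm", rel, u)
    perp = rel - t[..., None] * u[None, :, :]
    rho = np.linalg.norm(perp, axis=-1)
    rho = np.maximum(rho, geometry.diameters[None, :] / 2)
    integral = np.arcsinh(t / rho) - np.arcsinh((t - ds[None, :]) / rho)
    return integral / (4 * np.pi * sigma * ds[None, :])


def line_source_matrix(probe: ProbeSpec, geometry: CompartmentGeometry) -> ForwardMatrix:
    """Line-source + disk-electrode potential matrix (mV per nA).

    Each entry is the mean over 100 fixed-seed uniformly sampled points on
    the contact disk of the line-source solution, mimicking the finite
    contact extent.
    """
    offsets = _disk_offsets(probe)
    vals = np.zeros((probe.n_contacts, geometry.n))
    for off in offsets:
        vals += _line_source_points(probe.contacts + off, geometry, probe.sigma)
    vals /= len(offsets)
    return ForwardMatrix(values=vals, rows=list(probe.z), kind="potential")


def dipole_matrix(geometry: CompartmentGeometry) -> ForwardMatrix:
    """Current dipole moment map: rows x, y, z; ``P = sum_m r_m I_m`` (nA*um).

    With current-conserving sources (sum I_m = 0) the result is invariant
    under a global origin shift.
    """
    return ForwardMatrix(values=geometry.midpoints.T.copy(),
                         rows=["x", "y", "z"], kind="dipole")


def population_dipole_matrix(geometry: CompartmentGeometry) -> ForwardMatrix:
    """Dipole map for a radially symmetric population: x and y rows are
    identically zero (lateral components cancel), z row is z_m."""
    vals = np.zeros((3, geometry.n))
    vals[2] = geometry.z
    return ForwardMatrix(values=vals, rows=["x", "y", "z"], kind="dipole")


def disk_potential(dz: np.ndarray, R: float, sigma: float) -> np.ndarray:
    """Potential (mV per nA) at axial distance dz from a homogeneous
    current disk of radius R: ``(sqrt(dz^2 + R^2) - |dz|) / (2 sigma pi R^2)``."""
    dz = np.asarray(dz, float)
    return (np.sqrt(dz**2 + R**2) - np.abs(dz)) / (2 * sigma * np.pi * R**2)


def population_disk_matrix(
    probe: ProbeSpec,
    geometry: CompartmentGeometry,
    disk_radius: float,
    depth_density: Callable[[float], float],
    density_support: tuple[float, float] = (-np.inf, np.inf),
) -> ForwardMatrix:
    """Collapsed-population potential matrix (mV per nA).

    The current of canonical compartment m, carried by cells spread
    homogeneously over a disk of radius R and along depth with density
    g(z), produces at contact depth z_n the potential

    ``f_nm = ∫ a(z_n - z_m - z) g(z) dz``,

    the disk solution convolved with the soma-depth density, evaluated by
    adaptive quadrature.

    Parameters
    ----------
    disk_radius : population radius R (um, > 0).
    depth_density : normalized soma-depth pdf g(z) (1/um).
    density_support : integration limits for g.
    """
    if disk_radius <= 0:
        raise ValueError("disk_radius must be > 0")
    sigma = probe.sigma
    R = disk_radius
    scale = 1.0 / (2 * sigma * np.pi * R)  # integrand magnitude at dz = 0
    # f depends only on dz = z_n - z_m; cache per unique dz
    vals = np.empty((probe.n_contacts, geometry.n))
    cache: dict[float, float] = {}
    for n_i, zn in enumerate(probe.z):
        for m_i, zm in enumerate(geometry.z):
            dz = round(zn - zm, 9)
            if dz not in cache:
                f, _ = quad(
                    lambda z: disk_potential(dz - z, R, sigma) * depth_density(z),
                    density_support[0], density_support[1],
                    epsabs=1e-12 * scale, limit=200,
                )
                cache[dz] = f
            vals[n_i, m_i] = cache[dz]
    return ForwardMatrix(values=vals, rows=list(probe.z), kind="potential")
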