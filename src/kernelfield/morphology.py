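"""Stylized "ball-and-sticks" morphologies and generic section trees.

A morphology is described as a tree of cylindrical *sections* (soma, apical
dendrite, basal dendrite, ...), each subdivided into ``nseg`` equal-length
compartments.  The resulting :class:`CompartmentGeometry` carries everything
downstream consumers need: compartment midpoints, start/end points, lengths,
diameters, membrane areas and the section each compartment belongs to.

Conventions
-----------
* Coordinates are 3-D with ``z`` the vertical (cortical-depth) axis.
* The soma is a single cylindrical compartment placed with its *midpoint* at
  the cell's nominal z-position; the apical section attaches at the soma's
  top end and points along +z, the basal section attaches at the bottom end
  and points along -z.
* All lengths are in micrometres (um), areas in um^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SectionSpec",
    "CompartmentGeometry",
    "build_ball_and_sticks",
    "preset_sections",
    "read_swc",
]


@dataclass(frozen=True)
class SectionSpec:
    """One cylindrical section of a neuron morphology.

    Parameters
    ----------
    name
        Section identifier (``soma``, ``apic``, ``basal`` for built-ins).
    length
        Section length in um (> 0).
    diameter
        Section diameter in um (> 0).
    nseg
        Number of equal-length compartments the section is split into.
    parent
        Name of the parent section, or ``None`` for the root (soma).
    orientation
        Unit vector giving the direction the section extends in.
    attach_at
        Fractional position along the parent axis where this section
        attaches: 0 = parent start, 1 = parent end.
    """

    name: str
    length: float
    diameter: float
    nseg: int = 1
    parent: Optional[str] = None
    orientation: tuple[float, float, float] = (0.0, 0.0, 1.0)
    attach_at: float = 1.0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"section {self.name!r}: length must be > 0")
        if self.diameter <= 0:
            raise ValueError(f"section {self.name!r}: diameter must be > 0")
        if int(self.nseg) < 1 or self.nseg != int(self.nseg):
            raise ValueError(f"section {self.name!r}: nseg must be a positive integer")
        n = np.linalg.norm(self.orientation)
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValueError(f"section {self.name!r}: orientation must be a unit vector")


@dataclass
class CompartmentGeometry:
    """Discretized morphology: per-compartment geometry arrays.

    Attributes are all arrays of length ``n_compartments`` (or ``(n, 3)``):
    ``midpoints``, ``starts``, ``ends`` (um), ``lengths`` (um), ``diameters``
    (um), ``areas`` (um^2, lateral cylinder area pi*d*L), ``section`` (str
    per compartment) and ``parent_index`` (index of the parent compartment,
    -1 for the root).
    """

    midpoints: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    lengths: np.ndarray
    diameters: np.ndarray
    areas: np.ndarray
    section: np.ndarray
    parent_index: np.ndarray

    @property
    def n(self) -> int:
        return len(self.lengths)

    @property
    def z(self) -> np.ndarray:
        """Midpoint z-projection z_m (um)."""
        return self.midpoints[:, 2]

    def section_mask(self, names: Sequence[str]) -> np.ndarray:
        """Boolean mask of compartments belonging to any of `names`."""
        return np.isin(self.section, list(names))

    def validate(self) -> None:
        a = np.pi * self.diameters * self.lengths
        if not np.allclose(a, self.areas, rtol=1e-9):
            raise ValueError("areas inconsistent with pi*d*L")
        # tree: exactly one root, parents precede children
        roots = np.flatnonzero(self.parent_index < 0)
        if len(roots) != 1:
            raise ValueError("geometry must have exactly one root compartment")
        if np.any(self.parent_index >= np.arange(self.n)):
            raise ValueError("parent indices must precede children (no cycles)")


# Table of built-in ball-and-sticks presets: section (length um, diameter um,
# nseg) for the excitatory ("E") and inhibitory ("I") phenomenological cells.
_PRESETS = {
    "E": {"soma": (30.0, 30.0, 1), "apic": (1000.0, 3.0, 21), "basal": (200.0, 2.0, 5)},
    "I": {"soma": (30.0, 15.0, 1), "apic": (200.0, 2.0, 5), "basal": (200.0, 2.0, 5)},
}


def preset_sections(name: str) -> list[SectionSpec]:
    """Return the built-in section list for preset ``"E"`` or ``"I"``.

    Both presets have a single-compartment soma with the apical dendrite
    pointing up (+z, attached at the soma top) and the basal dendrite
    pointing down (-z, attached at the soma bottom).  The "I" cell is
    mirror-symmetric about the soma.
    """
    try:
        p = _PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(_PRESETS)}") from None
    sections = [SectionSpec("soma", *p["soma"])]
    sections.append(
        SectionSpec("apic", *p["apic"], parent="soma", orientation=(0, 0, 1.0), attach_at=1.0)
    )
    sections.append(
        SectionSpec("basal", *p["basal"], parent="soma", orientation=(0, 0, -1.0), attach_at=0.0)
    )
    return sections


def _rotation_matrix(angles: Optional[Sequence[float]]) -> np.ndarray:
    if angles is None:
        return np.eye(3)
    ax, ay, az = angles
    from scipy.spatial.transform import Rotation

    return Rotation.from_euler("xyz", [ax, ay, az]).as_matrix()


def build_ball_and_sticks(
    spec: Sequence[SectionSpec],
    soma_center_z: float = 0.0,
    rotation: Optional[Sequence[float]] = None,
) -> CompartmentGeometry:
    """Discretize a section tree into compartments.

    Parameters
    ----------
    spec
        Sections forming a tree rooted at the unique parent-less section
        (the soma).  Each section is split into ``nseg`` equal compartments;
        the built-in presets model the soma as a single compartment.
    soma_center_z
        z-coordinate (um) of the root section's midpoint.
    rotation
        Optional Euler angles (radians, x-y-z) applied about the soma
        midpoint after construction.

    Returns
    -------
    CompartmentGeometry

    Raises
    ------
    ValueError
        If the sections do not form a tree rooted at a single section.
    """
    by_name = {s.name: s for s in spec}
    if len(by_name) != len(spec):
        raise ValueError("duplicate section names")
    roots = [s for s in spec if s.parent is None]
    if len(roots) != 1:
        raise ValueError("sections must form a tree with exactly one root")
    root = roots[0]
    for s in spec:
        if s.parent is not None and s.parent not in by_name:
            raise ValueError(f"section {s.name!r} has unknown parent {s.parent!r}")

    # detect cycles / ensure every section reaches the root
    order: list[SectionSpec] = []
    placed = {root.name}
    pending = [s for s in spec if s is not root]
    while pending:
        progress = [s for s in pending if s.parent in placed]
        if not progress:
            raise ValueError("section graph is not a tree rooted at the soma")
        for s in progress:
            order.append(s)
            placed.add(s.name)
        pending = [s for s in pending if s.name not in placed]

    # lay out the root along its orientation, midpoint at soma_center_z
    sec_endpoints: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    u = np.asarray(root.orientation, float)
    mid = np.array([0.0, 0.0, soma_center_z])
    sec_endpoints[root.name] = (mid - u * root.length / 2, mid + u * root.length / 2)

    for s in order:
        p0, p1 = sec_endpoints[s.parent]
        attach = p0 + (p1 - p0) * s.attach_at
        u = np.asarray(s.orientation, float)
        sec_endpoints[s.name] = (attach, attach + u * s.length)

    starts, ends, lengths, diams, secs, parent_idx = [], [], [], [], [], []
    first_comp: dict[str, int] = {}
    last_comp: dict[str, int] = {}

    def add_section(s: SectionSpec, parent_comp: int) -> None:
        a, b = sec_endpoints[s.name]
        # partition the section length exactly into nseg compartments
        fr = np.linspace(0.0, 1.0, s.nseg + 1)
        pts = a[None, :] + (b - a)[None, :] * fr[:, None]
        first_comp[s.name] = len(lengths)
        for i in range(s.nseg):
            starts.append(pts[i])
            ends.append(pts[i + 1])
            lengths.append(s.length / s.nseg)
            diams.append(s.diameter)
            secs.append(s.name)
            parent_idx.append(parent_comp if i == 0 else len(lengths) - 2)
        last_comp[s.name] = len(lengths) - 1

    add_section(root, -1)
    for s in order:
        # attach to the nearer end's compartment of the parent section
        pc = first_comp[s.parent] if s.attach_at < 0.5 else last_comp[s.parent]
        add_section(s, pc)

    starts_arr = np.array(starts)
    ends_arr = np.array(ends)
    if rotation is not None:
        R = _rotation_matrix(rotation)
        center = np.array([0.0, 0.0, soma_center_z])
        starts_arr = (starts_arr - center) @ R.T + center
        ends_arr = (ends_arr - center) @ R.T + center

    lengths_arr = np.asarray(lengths)
    diams_arr = np.asarray(diams)
    geom = CompartmentGeometry(
        midpoints=(starts_arr + ends_arr) / 2,
        starts=starts_arr,
        ends=ends_arr,
        lengths=lengths_arr,
        diameters=diams_arr,
        areas=np.pi * diams_arr * lengths_arr,
        section=np.asarray(secs, dtype=object),
        parent_index=np.asarray(parent_idx, dtype=int),
    )
    geom.validate()
    return geom


def read_swc(path) -> CompartmentGeometry:
    """Read an SWC morphology file into a :class:`CompartmentGeometry`.

    Each SWC sample (beyond the root) becomes one compartment spanning from
    its parent sample to itself; SWC structure-type codes map onto section
    names (1=soma, 2=axon, 3=basal, 4=apic, other=dend).  Intended for
    mapping externally reconstructed cells onto the section-tree
    representation; the built-in presets do not use it.
    """
    type_names = {1: "soma", 2: "axon", 3: "basal", 4: "apic"}
    samples = {}
    order = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sid, stype, x, y, z, r, parent = line.split()[:7]
            samples[int(sid)] = (int(stype), float(x), float(y), float(z), float(r), int(parent))
            order.append(int(sid))

    roots = [sid for sid in order if samples[sid][5] == -1]
    if len(roots) != 1:
        raise ValueError("SWC file must contain exactly one root sample")
    index_of: dict[int, int] = {}
    starts, ends, lengths, diams, secs, parent_idx = [], [], [], [], [], []
    root = roots[0]
    st, x, y, z, r, _ = samples[root]
    # root sample: soma sphere approximated as L=d cylinder centred on it
    d = 2 * r
    starts.append(np.array([x, y, z - r]))
    ends.append(np.array([x, y, z + r]))
    lengths.append(d)
    diams.append(d)
    secs.append(type_names.get(st, "dend"))
    parent_idx.append(-1)
    index_of[root] = 0

    for sid in order:
        st, x, y, z, r, par = samples[sid]
        if par == -1:
            continue
        if par not in index_of:
            raise ValueError("SWC samples out of order (parent after child)")
        p = samples[par]
        a = np.array([p[1], p[2], p[3]])
        b = np.array([x, y, z])
        L = float(np.linalg.norm(b - a))
        if L == 0:
            continue
        starts.append(a)
        ends.append(b)
        lengths.append(L)
        diams.append(2 * r)
        secs.append(type_names.get(st, "dend"))
        parent_idx.append(index_of[par])
        index_of[sid] = len(lengths) - 1

    lengths_arr = np.asarray(lengths)
    diams_arr = np.asarray(diams)
    starts_arr = np.array(starts)
    ends_arr = np.array(ends)
    geom = CompartmentGeometry(
        midpoints=(starts_arr + ends_arr) / 2,
        starts=starts_arr,
        ends=ends_arr,
        lengths=lengths_arr,
        diameters=diams_arr,
        areas=np.pi * diams_arr * lengths_arr,
        section=np.asarray(secs, dtype=object),
        parent_index=np.asarray(parent_idx, dtype=int),
    )
    geom.validate()
    return geom
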