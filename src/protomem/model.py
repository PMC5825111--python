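"""Core data model: periodic boxes, role-tagged topologies, frames, trajectories.

Unit conventions used throughout the package:

* coordinates and distances in angstrom (Å)
* times in femtoseconds (fs)
* partial charges in elementary charges (e)
* angles in degrees at the API surface, cosines internally

Boxes are orthorhombic; triclinic cells are rejected explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

# Atom roles recognised by the analysis stages.
WATER_OXYGEN = "water_oxygen"
WATER_HYDROGEN = "water_hydrogen"
PHOSPHATE_OXYGEN = "phosphate_oxygen"
LIPID_OTHER = "lipid_other"
EXCESS_HYDROGEN = "excess_hydrogen"

ROLES = (WATER_OXYGEN, WATER_HYDROGEN, PHOSPHATE_OXYGEN, LIPID_OTHER, EXCESS_HYDROGEN)

#: molecule id assigned to the excess proton, which belongs to no molecule at build time
NO_MOLECULE = -1

# atomic masses (u) for the elements the fixtures use
ATOMIC_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974}


class TopologyError(ValueError):
    """Raised when a topology violates its structural invariants."""


class BoxError(ValueError):
    """Raised for invalid or unsupported periodic cells."""


@dataclass(frozen=True)
class Box:
    """Orthorhombic periodic cell.

    Parameters
    ----------
    lengths : tuple of float
        Edge lengths (Lx, Ly, Lz) in Å.
    periodic : tuple of bool
        Per-axis periodicity flags. The membrane systems this package
        targets are periodic in all three axes.
    """

    lengths: tuple[float, float, float]
    periodic: tuple[bool, bool, bool] = (True, True, True)

    def __post_init__(self):
        L = np.asarray(self.lengths, dtype=float)
        if L.shape != (3,) or not np.all(np.isfinite(L)) or not np.all(L > 0):
            raise BoxError(f"box lengths must be three positive finite numbers, got {self.lengths}")
        object.__setattr__(self, "lengths", tuple(float(x) for x in L))
        object.__setattr__(self, "periodic", tuple(bool(p) for p in self.periodic))

    @property
    def L(self) -> np.ndarray:
        return np.asarray(self.lengths, dtype=float)

    @property
    def volume(self) -> float:
        return float(np.prod(self.L))


@dataclass
class Topology:
    """Role-tagged topology stored column-wise.

    Atom ids are implicit: dense integers ``0..n_atoms-1`` in array order.
    """

    elements: np.ndarray          # (N,) unicode element symbols
    roles: np.ndarray             # (N,) unicode role strings
    molecule_ids: np.ndarray      # (N,) int, NO_MOLECULE for the excess proton
    charges: np.ndarray           # (N,) float, elementary charges
    net_charge: float = 0.0       # declared net charge of the system

    def __post_init__(self):
        self.elements = np.asarray(self.elements, dtype="U4")
        self.roles = np.asarray(self.roles, dtype="U20")
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=int)
        self.charges = np.asarray(self.charges, dtype=float)
        n = len(self.elements)
        for arr, name in ((self.roles, "roles"), (self.molecule_ids, "molecule_ids"),
                          (self.charges, "charges")):
            if len(arr) != n:
                raise TopologyError(f"{name} has length {len(arr)}, expected {n}")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def atom_ids(self) -> np.ndarray:
        return np.arange(self.n_atoms)

    def indices(self, *roles: str) -> np.ndarray:
        """Atom ids with any of the given roles."""
        mask = np.isin(self.roles, list(roles))
        return np.nonzero(mask)[0]

    def water_molecules(self) -> list[tuple[int, int, int]]:
        """(O, H1, H2) atom-id triples for every water molecule."""
        out = []
        o_ids = self.indices(WATER_OXYGEN)
        h_by_mol: dict[int, list[int]] = {}
        for h in self.indices(WATER_HYDROGEN):
            h_by_mol.setdefault(int(self.molecule_ids[h]), []).append(int(h))
        for o in o_ids:
            hs = h_by_mol.get(int(self.molecule_ids[o]), [])
            if len(hs) != 2:
                raise TopologyError(
                    f"water oxygen {o} (molecule {self.molecule_ids[o]}) has "
                    f"{len(hs)} hydrogens, expected 2")
            out.append((int(o), hs[0], hs[1]))
        return out

    def validate(self) -> None:
        """Enforce the structural invariants; raise TopologyError on violation."""
        bad = ~np.isin(self.roles, ROLES)
        if bad.any():
            raise TopologyError(f"unknown roles: {sorted(set(self.roles[bad]))}")
        self.water_molecules()  # raises on broken waters
        excess = self.indices(EXCESS_HYDROGEN)
        if not np.all(self.molecule_ids[excess] == NO_MOLECULE):
            raise TopologyError("the excess hydrogen belongs to no molecule at build time")
        total = float(self.charges.sum())
        if abs(total - self.net_charge) > 1e-6:
            raise TopologyError(
                f"charges sum to {total:+.8f} e, declared net charge {self.net_charge:+.1f} e")


@dataclass
class Frame:
    """One snapshot: per-atom Cartesian positions (Å) plus the periodic box."""

    time: float                   # fs
    positions: np.ndarray         # (N, 3) Å
    box: Box

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError(f"positions must be (N, 3), got {self.positions.shape}")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("frame positions contain non-finite values")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]


@dataclass
class Trajectory:
    """An ordered sequence of frames sharing one topology."""

    topology: Topology
    frames: list[Frame] = field(default_factory=list)

    def __post_init__(self):
        for i, f in enumerate(self.frames):
            if f.n_atoms != self.topology.n_atoms:
                raise ValueError(
                    f"frame {i} has {f.n_atoms} atoms, topology has {self.topology.n_atoms}")
        times = np.array([f.time for f in self.frames])
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def timestep(self) -> float:
        """Time between the first two frames (fs); 0 for <2 frames."""
        if self.n_frames < 2:
            return 0.0
        return self.frames[1].time - self.frames[0].time


def minimum_image_displacement(a, b, box: Box) -> np.ndarray:
    """Minimum-image displacement of ``a`` relative to ``b`` (i.e. a - b, wrapped).

    Each periodic component of the result lies in ``[-L/2, L/2)``; the norm of
    the returned vector is the minimum-image distance. Broadcasts over leading
    axes.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("minimum_image_displacement: non-finite coordinates")
    d = a - b
    L = box.L
    per = np.asarray(box.periodic)
    wrapped = d - L * np.floor(d / L + 0.5)
    return np.where(per, wrapped, d)


def minimum_image_distance(a, b, box: Box) -> np.ndarray:
    """Minimum-image distance between positions ``a`` and ``b`` (Å)."""
    d = minimum_image_displacement(a, b, box)
    return np.linalg.norm(d, axis=-1)


def wrap_positions(positions: np.ndarray, box: Box) -> np.ndarray:
    """Wrap coordinates of periodic axes into ``[0, L)`` (for spatial indexing)."""
    pos = np.array(positions, dtype=float)
    L = box.L
    for ax in range(3):
        if box.periodic[ax]:
            pos[:, ax] = np.mod(pos[:, ax], L[ax])
            # guard against pos == L from floating-point round-off
            pos[:, ax][pos[:, ax] >= L[ax]] = 0.0
    return pos


def neighbor_pairs(frame: Frame, topology: Topology, roles_a, roles_b,
                   cutoff: float) -> list[tuple[int, int, float]]:
    """All role-filtered atom pairs within a minimum-image distance cutoff.

    Returns unordered pairs ``(i, j, distance)`` with ``i < j`` whenever both
    orders would qualify, no self pairs. ``cutoff`` must be smaller than half
    the shortest periodic box edge so the minimum image is unambiguous.
    """
    if isinstance(roles_a, str):
        roles_a = (roles_a,)
    if isinstance(roles_b, str):
        roles_b = (roles_b,)
    L = frame.box.L
    per = np.asarray(frame.box.periodic)
    half_min = 0.5 * min(L[per]) if per.any() else np.inf
    if cutoff >= half_min:
        raise ValueError(
            f"cutoff {cutoff} Å is not below half the smallest periodic box "
            f"edge ({half_min:.3f} Å); minimum-image pair search is ambiguous")
    idx_a = topology.indices(*roles_a)
    idx_b = topology.indices(*roles_b)
    if len(idx_a) == 0 or len(idx_b) == 0:
        return []
    pos = wrap_positions(frame.positions, frame.box)
    if per.all():
        tree_a = cKDTree(pos[idx_a], boxsize=L)
        tree_b = cKDTree(pos[idx_b], boxsize=L)
        sparse = tree_a.sparse_distance_matrix(tree_b, cutoff, output_type="coo_matrix")
        candidates = zip(idx_a[sparse.row], idx_b[sparse.col], sparse.data)
    else:
        d = minimum_image_distance(frame.positions[idx_a][:, None, :],
                                   frame.positions[idx_b][None, :, :], frame.box)
        ii, jj = np.nonzero(d <= cutoff)
        candidates = zip(idx_a[ii], idx_b[jj], d[ii, jj])
    seen = set()
    out = []
    both = set(idx_a.tolist()) & set(idx_b.tolist())
    for i, j, dist in candidates:
        i, j = int(i), int(j)
        if i == j:
            continue
        if i in both and j in both:
            key = (min(i, j), max(i, j))
        else:
            key = (i, j)
        if key in seen:
            continue
        seen.add(key)
        out.append((key[0], key[1], float(dist)))
    out.sort()
    return out
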