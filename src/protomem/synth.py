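"""Seeded generator of membrane-slab fixtures with scripted proton relays.

The generator emulates the geometry of a small phosphatidylcholine bilayer
slab in water: lipids are coarse pseudo-atom stacks filling ``|z| < z_head``
with their four phosphate oxygens on the two headgroup planes ``z = ±z_head``,
and rigid three-site waters fill the remainder of the periodic box. Interfacial
waters (within a cutoff of a headgroup plane) receive dipole tilt angles drawn
from a wrapped-normal distribution around a mode angle; bulk waters are uniform
on cos(theta).

Proton relays are scripted, not simulated: an excess hydrogen is walked along a
hydrogen-bonded chain of water oxygens, each hop linearly interpolating the
shared proton along the donor->acceptor O-O axis so the transfer coordinate
sweeps monotonically through zero at the window midpoint. A concerted event
moves the shared protons of several consecutive bonds in the same window.

Everything is deterministic under the spec's seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .model import (
    EXCESS_HYDROGEN, LIPID_OTHER, NO_MOLECULE, PHOSPHATE_OXYGEN, WATER_HYDROGEN,
    WATER_OXYGEN, Box, Frame, Topology, Trajectory, minimum_image_distance,
)

# fixed molecular formulas (heavy-atom + hydrogen counts) of the two species
LIPID_FORMULAS = {
    "DPhPC": {"C": 48, "H": 96, "N": 1, "O": 8, "P": 1},   # 154 atoms
    "DOPC": {"C": 44, "H": 84, "N": 1, "O": 8, "P": 1},    # 138 atoms
}
PAPER_BOXES = {"DPhPC": (19.7, 19.7, 70.6), "DOPC": (19.1, 19.1, 69.8)}
PAPER_N_WATERS = {"DPhPC": 418, "DOPC": 358}

# rigid water geometry (TIP3P-like) and default partial charges (e)
R_OH = 0.9572
HOH_ANGLE_DEG = 104.52
Q_WATER_O, Q_WATER_H = -0.834, 0.417
Q_PHOSPHATE_O, Q_PHOSPHORUS, Q_NITROGEN = -0.5, 1.0, 1.0
Q_EXCESS_H = 1.0

#: O-H distance used for hydrogens resting on a relay axis; hops interpolate
#: this distance across the O-O gap.
R_OH_RELAY = 1.0
#: O-O spacing along scripted relay chains (hydrogen-bonded by construction)
CHAIN_SPACING = 2.5
MIN_WATER_OO = 2.0


class FixtureError(ValueError):
    """Raised when a fixture specification cannot be realised."""


@dataclass
class OrientationRule:
    """Imposed interfacial dipole orientation.

    ``mode_angle_deg`` is the preferred angle between the water dipole and the
    outward headgroup-plane normal; ``kappa`` the wrapped-normal concentration
    (sigma = kappa**-0.5 rad); ``cutoff`` the distance from a headgroup plane
    (angstrom) within which the rule applies.
    """

    mode_angle_deg: float = 150.0
    kappa: float = 16.0
    cutoff: float = 6.0


@dataclass
class HopEvent:
    """One scripted proton-transfer event.

    ``frame_index`` is the window centre (the midpoint-crossing frame);
    ``concerted_group`` is the ordered oxygen-id chain, length 2 for a single
    hop and 4 for a triple concerted hop.
    """

    frame_index: int
    donor_oxygen_id: int
    acceptor_oxygen_id: int
    concerted_group: tuple[int, ...] = ()

    def __post_init__(self):
        if not self.concerted_group:
            self.concerted_group = (self.donor_oxygen_id, self.acceptor_oxygen_id)
        self.concerted_group = tuple(int(x) for x in self.concerted_group)
        if (self.concerted_group[0] != self.donor_oxygen_id
                or self.concerted_group[-1] != self.acceptor_oxygen_id):
            raise FixtureError("concerted_group must run donor ... acceptor")

    @property
    def bonds(self) -> list[tuple[int, int]]:
        g = self.concerted_group
        return [(g[i], g[i + 1]) for i in range(len(g) - 1)]


@dataclass
class FixtureSpec:
    """Full description of a synthetic membrane-slab trajectory."""

    species: str | None = "DPhPC"
    n_lipids: int = 10
    n_waters: int = 418
    has_excess_proton: bool = True
    box: Box = field(default_factory=lambda: Box(PAPER_BOXES["DPhPC"]))
    z_head: float = 17.5
    orientation: OrientationRule = field(default_factory=OrientationRule)
    relay_script: list[HopEvent] = field(default_factory=list)
    jitter_sigma: float = 0.05
    #: per-frame rigid z-displacement of each lipid (Å), emulating protrusion
    #: motions; smears the headgroup charge layers as in a thermal membrane
    lipid_z_sigma: float = 0.5
    n_frames: int = 1
    hop_window: int = 11
    timestep_fs: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.z_head >= self.box.lengths[2] / 2:
            raise FixtureError("z_head must be below Lz/2")
        if self.jitter_sigma < 0:
            raise FixtureError("jitter_sigma must be >= 0")
        if not 0.0 <= self.orientation.mode_angle_deg <= 180.0:
            raise FixtureError("mode angle must lie in [0, 180] degrees")
        if self.hop_window < 3 or self.hop_window % 2 == 0:
            raise FixtureError("hop_window must be an odd integer >= 3")

    @classmethod
    def paper_system(cls, species: str, **overrides) -> "FixtureSpec":
        """The study compositions: 10 lipids, 418/358 waters, one proton."""
        if species not in LIPID_FORMULAS:
            raise FixtureError(f"unknown lipid species {species!r}")
        kwargs = dict(species=species, n_lipids=10, n_waters=PAPER_N_WATERS[species],
                      has_excess_proton=True, box=Box(PAPER_BOXES[species]))
        kwargs.update(overrides)
        return cls(**kwargs)


def spec_to_dict(spec: FixtureSpec) -> dict:
    d = asdict(spec)
    d["box"] = {"lengths": list(spec.box.lengths), "periodic": list(spec.box.periodic)}
    d["relay_script"] = [
        {"frame_index": h.frame_index, "donor_oxygen_id": h.donor_oxygen_id,
         "acceptor_oxygen_id": h.acceptor_oxygen_id,
         "concerted_group": list(h.concerted_group)}
        for h in spec.relay_script]
    return d


def spec_from_dict(d: dict) -> FixtureSpec:
    d = dict(d)
    d["box"] = Box(tuple(d["box"]["lengths"]), tuple(d["box"]["periodic"]))
    d["orientation"] = OrientationRule(**d["orientation"])
    d["relay_script"] = [HopEvent(frame_index=h["frame_index"],
                                  donor_oxygen_id=h["donor_oxygen_id"],
                                  acceptor_oxygen_id=h["acceptor_oxygen_id"],
                                  concerted_group=tuple(h["concerted_group"]))
                         for h in d["relay_script"]]
    return FixtureSpec(**d)


def spec_hash(spec: FixtureSpec) -> str:
    text = yaml.safe_dump(spec_to_dict(spec), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()


# ---------------------------------------------------------------------------
# topology

def compose_system(spec: FixtureSpec) -> Topology:
    """Build the role-tagged topology for a fixture spec.

    Atom order: lipids (leaflet by leaflet), then waters (O, H1, H2 each),
    then the excess hydrogen last.
    """
    elements, roles, molids, charges = [], [], [], []
    mol = 0
    if spec.n_lipids > 0:
        species = spec.species or "DPhPC"
        if species not in LIPID_FORMULAS:
            raise FixtureError(f"unknown lipid species {species!r}")
        formula = LIPID_FORMULAS[species]
        for _ in range(spec.n_lipids):
            # headgroup: choline N, phosphorus, 4 phosphate O; then ester O, tails
            elements += ["N", "P"] + ["O"] * formula["O"]
            roles += [LIPID_OTHER, LIPID_OTHER] + [PHOSPHATE_OXYGEN] * 4 \
                + [LIPID_OTHER] * (formula["O"] - 4)
            charges += [Q_NITROGEN, Q_PHOSPHORUS] + [Q_PHOSPHATE_O] * 4 \
                + [0.0] * (formula["O"] - 4)
            elements += ["C"] * formula["C"] + ["H"] * formula["H"]
            roles += [LIPID_OTHER] * (formula["C"] + formula["H"])
            charges += [0.0] * (formula["C"] + formula["H"])
            molids += [mol] * (2 + formula["O"] + formula["C"] + formula["H"])
            mol += 1
    for _ in range(spec.n_waters):
        elements += ["O", "H", "H"]
        roles += [WATER_OXYGEN, WATER_HYDROGEN, WATER_HYDROGEN]
        charges += [Q_WATER_O, Q_WATER_H, Q_WATER_H]
        molids += [mol] * 3
        mol += 1
    if spec.has_excess_proton:
        elements.append("H")
        roles.append(EXCESS_HYDROGEN)
        charges.append(Q_EXCESS_H)
        molids.append(NO_MOLECULE)
    top = Topology(elements=np.array(elements), roles=np.array(roles),
                   molecule_ids=np.array(molids), charges=np.array(charges),
                   net_charge=1.0 if spec.has_excess_proton else 0.0)
    top.validate()
    return top


def compose_paper_system(species: str) -> Topology:
    """Topology with the printed compositions (2,795 / 2,455 atoms)."""
    return compose_system(FixtureSpec.paper_system(species))


def lipid_atoms_per_molecule(species: str) -> int:
    return sum(LIPID_FORMULAS[species].values())


def water_oxygen_ids(topology: Topology) -> np.ndarray:
    return topology.indices(WATER_OXYGEN)


def chain_oxygen_ids(topology: Topology, n: int) -> tuple[int, ...]:
    """Atom ids of the first ``n`` water oxygens (the default relay chain)."""
    o = water_oxygen_ids(topology)
    if len(o) < n:
        raise FixtureError(f"need {n} waters for the relay chain, have {len(o)}")
    return tuple(int(x) for x in o[:n])


# ---------------------------------------------------------------------------
# geometry helpers

def _perpendicular(u: np.ndarray) -> np.ndarray:
    a = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e = np.cross(u, a)
    return e / np.linalg.norm(e)


def _rigid_water(o_pos: np.ndarray, dipole: np.ndarray, psi: float) -> tuple[np.ndarray, np.ndarray]:
    """H positions of a rigid water with its dipole (O->H bisector) along ``dipole``."""
    u = dipole / np.linalg.norm(dipole)
    e = _perpendicular(u)
    w = np.cos(psi) * e + np.sin(psi) * np.cross(u, e)
    alpha = np.deg2rad(HOH_ANGLE_DEG / 2)
    h1 = o_pos + R_OH * (np.cos(alpha) * u + np.sin(alpha) * w)
    h2 = o_pos + R_OH * (np.cos(alpha) * u - np.sin(alpha) * w)
    return h1, h2


def _sample_dipole(rng: np.random.Generator, rule: OrientationRule,
                   outward: np.ndarray, interfacial: bool) -> np.ndarray:
    """Unit dipole; interfacial waters tilt by a wrapped-normal angle to ``outward``."""
    if not interfacial:
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)
    sigma = rule.kappa ** -0.5
    theta = np.deg2rad(rule.mode_angle_deg) + sigma * rng.normal()
    # fold the wrapped angle into [0, pi] (angle to a fixed axis)
    theta = np.abs((theta + np.pi) % (2 * np.pi) - np.pi)
    phi = rng.uniform(0, 2 * np.pi)
    e = _perpendicular(outward)
    w = np.cos(phi) * e + np.sin(phi) * np.cross(outward, e)
    return np.cos(theta) * outward + np.sin(theta) * w


def _lipid_sites(spec: FixtureSpec) -> list[tuple[float, float, int]]:
    """Lateral (x, y) grid positions and leaflet sign per lipid."""
    sites = []
    Lx, Ly = spec.box.lengths[0], spec.box.lengths[1]
    n_upper = (spec.n_lipids + 1) // 2
    for leaflet, count in ((1, n_upper), (-1, spec.n_lipids - n_upper)):
        if count == 0:
            continue
        nx = int(np.ceil(np.sqrt(count)))
        ny = int(np.ceil(count / nx))
        k = 0
        for i in range(nx):
            for j in range(ny):
                if k >= count:
                    break
                sites.append(((i + 0.5) * Lx / nx, (j + 0.5) * Ly / ny, leaflet))
                k += 1
    return sites


def _place_lipid(x0: float, y0: float, s: int, spec: FixtureSpec,
                 rng: np.random.Generator, formula: dict) -> np.ndarray:
    """Pseudo-atom stack for one lipid: headgroup at s*z_head, tails toward z=0.

    The zwitterionic headgroup is layered like a PC lipid: choline nitrogen
    outermost (just beyond the phosphate plane, inside the water clearance
    gap), phosphate oxygens on the plane, phosphorus just beneath. The
    alternating +/-/+ charge layers give each leaflet the dipole that shapes
    the membrane potential profile.
    """
    zh = spec.z_head
    pos = [np.array([x0, y0, s * (zh + 1.0)]),          # choline N (outermost)
           np.array([x0 + 0.3, y0, s * (zh - 0.5)])]    # phosphorus
    for dx, dy in ((0.8, 0.0), (-0.8, 0.0), (0.0, 0.8), (0.0, -0.8)):
        pos.append(np.array([x0 + dx, y0 + dy, s * zh]))  # phosphate O on the plane
    for dx, dy in ((0.5, 0.5), (-0.5, 0.5), (0.5, -0.5), (-0.5, -0.5)):
        pos.append(np.array([x0 + dx, y0 + dy, s * (zh - 3.0)]))  # ester O
    n_tail = formula["C"] + formula["H"]
    z_tail = np.linspace(s * (zh - 3.5), s * 1.0, n_tail)
    lateral = rng.uniform(-1.2, 1.2, size=(n_tail, 2))
    for k in range(n_tail):
        pos.append(np.array([x0 + lateral[k, 0], y0 + lateral[k, 1], z_tail[k]]))
    return np.array(pos)


# ---------------------------------------------------------------------------
# frame construction

_WATER_GAP = 1.5  # Å clearance between headgroup plane and first water


def _insert_waters(n: int, spec: FixtureSpec, rng: np.random.Generator,
                   fixed: np.ndarray, z_lo: float, z_hi: float) -> np.ndarray:
    """Place ``n`` water oxygens in the slab region without O-O overlap.

    Batch rejection: draw everything at once, then iteratively redraw the
    higher-index member of every clashing pair (including clashes with the
    ``fixed`` points) until clash-free. Deterministic under ``rng``.
    """
    from scipy.spatial import cKDTree

    if n == 0:
        return np.zeros((0, 3))
    L = spec.box.L

    def draw(k):
        side = np.where(rng.uniform(size=k) < 0.5, 1.0, -1.0)
        return np.column_stack([rng.uniform(0, L[0], k), rng.uniform(0, L[1], k),
                                side * rng.uniform(z_lo, z_hi, k)])

    pos = draw(n)
    for _ in range(300):
        wrapped = np.mod(pos, L)
        wrapped[wrapped >= L] = 0.0
        tree = cKDTree(wrapped, boxsize=L)
        bad = set()
        for i, j in tree.query_pairs(MIN_WATER_OO):
            bad.add(max(i, j))
        if len(fixed):
            ftree = cKDTree(np.mod(fixed, L), boxsize=L)
            for lst_i, nbrs in enumerate(ftree.query_ball_tree(tree, MIN_WATER_OO)):
                bad.update(nbrs)
        if not bad:
            return pos
        idx = sorted(bad)
        pos[idx] = draw(len(idx))
    raise FixtureError(
        f"overpacked box: could not insert {n} waters without O-O overlap "
        "after 300 redraw rounds")


@dataclass
class _ChainGeometry:
    oxygen_ids: tuple[int, ...]
    sites: np.ndarray            # (k, 3) chain oxygen positions
    start_index: int = 0         # chain index initially owning the excess proton
    step: int = 1                # +1/-1: direction of the first traversal


def build_slab_frame(spec: FixtureSpec, topology: Topology | None = None,
                     rng: np.random.Generator | None = None,
                     chain: _ChainGeometry | None = None) -> Frame:
    """Build the base slab frame: lipid stacks, oriented waters, excess proton.

    Deterministic under a fixed seed (``rng`` defaults to the spec's seed).
    Raises FixtureError if waters cannot be inserted without O-O overlap
    (< 2.0 Å) after a bounded number of attempts.
    """
    top = topology or compose_system(spec)
    rng = rng or np.random.default_rng(spec.seed)
    L = spec.box.L
    positions = np.zeros((top.n_atoms, 3))

    species = spec.species or "DPhPC"
    formula = LIPID_FORMULAS.get(species)
    n_lip_atoms = lipid_atoms_per_molecule(species) if spec.n_lipids else 0
    for li, (x0, y0, s) in enumerate(_lipid_sites(spec)):
        block = _place_lipid(x0, y0, s, spec, rng, formula)
        positions[li * n_lip_atoms:(li + 1) * n_lip_atoms] = block

    o_ids = water_oxygen_ids(top)
    accepted: list[np.ndarray] = []
    chain_ids = set(chain.oxygen_ids) if chain else set()
    phos = positions[top.indices(PHOSPHATE_OXYGEN)] if spec.n_lipids else np.zeros((0, 3))

    if chain:
        for oid, site in zip(chain.oxygen_ids, chain.sites):
            accepted.append(np.asarray(site, dtype=float))

    zh, cutoff = spec.z_head, spec.orientation.cutoff
    z_lo, z_hi = zh + _WATER_GAP, L[2] / 2
    if z_lo >= z_hi:
        raise FixtureError("no water region: z_head + clearance exceeds Lz/2")

    free_oxygens = [oid for oid in o_ids if oid not in chain_ids]
    fixed = np.vstack([np.asarray(accepted).reshape(-1, 3), phos.reshape(-1, 3)])
    sampled_pts = _insert_waters(len(free_oxygens), spec, rng, fixed, z_lo, z_hi)

    # assign water positions: chain oxygens first (by id), then the sampled ones
    sampled = iter(sampled_pts)
    chain_site_by_id = dict(zip(chain.oxygen_ids, chain.sites)) if chain else {}
    for oid in o_ids:
        o_pos = np.asarray(chain_site_by_id[oid]) if oid in chain_ids else next(sampled)
        positions[oid] = o_pos
        if oid in chain_ids:
            h1, h2 = _chain_water_hydrogens(oid, chain, spec)
        else:
            # distance of the (wrapped) |z| above the headgroup plane
            zwrap = ((o_pos[2] + L[2] / 2) % L[2]) - L[2] / 2
            d_plane = abs(zwrap) - zh
            interfacial = 0 <= d_plane <= cutoff
            outward = np.array([0.0, 0.0, 1.0 if zwrap >= 0 else -1.0])
            dipole = _sample_dipole(rng, spec.orientation, outward, interfacial)
            h1, h2 = _rigid_water(o_pos, dipole, rng.uniform(0, 2 * np.pi))
        positions[oid + 1] = h1
        positions[oid + 2] = h2

    if spec.has_excess_proton:
        h_id = top.indices(EXCESS_HYDROGEN)[0]
        if chain:
            owner = chain.oxygen_ids[chain.start_index]
            nxt = chain.oxygen_ids[chain.start_index + chain.step]
            axis = chain_site_by_id[nxt] - chain_site_by_id[owner]
            axis = axis / np.linalg.norm(axis)
            positions[h_id] = chain_site_by_id[owner] + R_OH_RELAY * axis
        else:
            o0 = o_ids[0]
            bisector = (positions[o0 + 1] + positions[o0 + 2]) / 2 - positions[o0]
            u = -bisector / np.linalg.norm(bisector)
            positions[h_id] = positions[o0] + R_OH_RELAY * u
    return Frame(time=0.0, positions=positions, box=spec.box)


def _chain_water_hydrogens(oid: int, chain: _ChainGeometry,
                           spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Own hydrogens of a relay-chain water.

    The donor hydrogen of water i points at its forward neighbour (relative to
    the relay's first traversal); terminal waters and the initial proton owner
    keep both hydrogens off-axis so the mobile proton is unambiguous.
    """
    ids = list(chain.oxygen_ids)
    i = ids.index(oid)
    sites = chain.sites
    step = chain.step
    j = i + step
    is_owner = (i == chain.start_index)
    lateral = _perpendicular(np.array([0.0, 0.0, 1.0]))  # x-hat
    if 0 <= j < len(ids) and not is_owner:
        u = sites[j] - sites[i]
        u = u / np.linalg.norm(u)
        h1 = sites[i] + R_OH_RELAY * u
        v = _perpendicular(u)
        h2 = sites[i] + R_OH * v
    else:
        # both hydrogens off-axis, tilted slightly toward the membrane
        d1 = lateral - 0.25 * np.array([0.0, 0.0, 1.0])
        d2 = -lateral - 0.25 * np.array([0.0, 0.0, 1.0])
        h1 = sites[i] + R_OH * d1 / np.linalg.norm(d1)
        h2 = sites[i] + R_OH * d2 / np.linalg.norm(d2)
    return h1, h2


# ---------------------------------------------------------------------------
# trajectories

def _resample_water_hydrogens(o_pos: np.ndarray, spec: FixtureSpec,
                              rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised re-draw of all water dipoles for one frame.

    Interfacial waters (within the orientation cutoff of a headgroup plane)
    get wrapped-normal tilt angles to the outward normal; bulk waters are
    uniform on the sphere. Returns (H1, H2) position arrays.
    """
    n = len(o_pos)
    L = spec.box.L
    rule = spec.orientation
    zwrap = ((o_pos[:, 2] + L[2] / 2) % L[2]) - L[2] / 2
    d_plane = np.abs(zwrap) - spec.z_head
    interfacial = (d_plane >= 0) & (d_plane <= rule.cutoff)
    out_sign = np.where(zwrap >= 0, 1.0, -1.0)

    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    if interfacial.any():
        m = int(interfacial.sum())
        sigma = rule.kappa ** -0.5
        theta = np.deg2rad(rule.mode_angle_deg) + sigma * rng.normal(size=m)
        theta = np.abs((theta + np.pi) % (2 * np.pi) - np.pi)
        phi = rng.uniform(0, 2 * np.pi, size=m)
        # outward = (0, 0, s): a perpendicular basis is (x-hat, s*y-hat)
        s = out_sign[interfacial]
        w = np.column_stack([np.cos(phi), s * np.sin(phi), np.zeros(m)])
        ui = (np.cos(theta)[:, None] * np.column_stack([np.zeros(m), np.zeros(m), s])
              + np.sin(theta)[:, None] * w)
        u[interfacial] = ui
    # rigid water around each dipole direction
    a = np.where(np.abs(u[:, [0]]) < 0.9, [[1.0, 0, 0]], [[0, 1.0, 0]])
    e = np.cross(u, a)
    e /= np.linalg.norm(e, axis=1, keepdims=True)
    psi = rng.uniform(0, 2 * np.pi, size=n)
    w2 = np.cos(psi)[:, None] * e + np.sin(psi)[:, None] * np.cross(u, e)
    alpha = np.deg2rad(HOH_ANGLE_DEG / 2)
    h1 = o_pos + R_OH * (np.cos(alpha) * u + np.sin(alpha) * w2)
    h2 = o_pos + R_OH * (np.cos(alpha) * u - np.sin(alpha) * w2)
    return h1, h2


def generate_trajectory(spec: FixtureSpec, resample_positions: bool = True) -> Trajectory:
    """Multi-frame slab trajectory of statistically independent snapshots.

    Each frame re-draws the water oxygen positions and dipole orientations
    (emulating the diffusive and rotational decorrelation between
    well-separated snapshots of a liquid) and adds thermal jitter on every
    atom. With ``resample_positions=False`` only orientations and jitter vary
    and the oxygen lattice is frozen.
    """
    if spec.relay_script:
        return script_relay(spec)
    top = compose_system(spec)
    rng = np.random.default_rng(spec.seed)
    base = build_slab_frame(spec, top, rng)
    frames = []
    o_ids = water_oxygen_ids(top)
    L = spec.box.L
    zh, cutoff = spec.z_head, spec.orientation.cutoff
    z_lo, z_hi = zh + _WATER_GAP, L[2] / 2
    phos = base.positions[top.indices(PHOSPHATE_OXYGEN)] if spec.n_lipids \
        else np.zeros((0, 3))
    lipid_atoms = []
    if spec.n_lipids:
        per = lipid_atoms_per_molecule(spec.species or "DPhPC")
        lipid_atoms = [np.arange(li * per, (li + 1) * per) for li in range(spec.n_lipids)]
    for f in range(spec.n_frames):
        pos = base.positions.copy()
        if f > 0 and spec.lipid_z_sigma > 0:
            for idx in lipid_atoms:
                pos[idx, 2] += rng.normal(scale=spec.lipid_z_sigma)
        if f > 0 and len(o_ids):
            if resample_positions:
                pos[o_ids] = _insert_waters(len(o_ids), spec, rng, phos, z_lo, z_hi)
            h1, h2 = _resample_water_hydrogens(pos[o_ids], spec, rng)
            pos[o_ids + 1] = h1
            pos[o_ids + 2] = h2
            if spec.has_excess_proton and resample_positions:
                # keep the excess proton attached to its host water oxygen
                h_id = top.indices(EXCESS_HYDROGEN)[0]
                o0 = o_ids[0]
                bis = (pos[o0 + 1] + pos[o0 + 2]) / 2 - pos[o0]
                pos[h_id] = pos[o0] - R_OH_RELAY * bis / np.linalg.norm(bis)
        if spec.jitter_sigma > 0:
            pos = pos + rng.normal(scale=spec.jitter_sigma, size=pos.shape)
        frames.append(Frame(time=f * spec.timestep_fs, positions=pos, box=spec.box))
    return Trajectory(topology=top, frames=frames)


def default_relay_chain(spec: FixtureSpec, topology: Topology, n: int = 4,
                        toward_plane: bool = False) -> _ChainGeometry:
    """Chain geometry anchored above the first phosphate oxygen of lipid 0.

    Chain oxygen 0 sits 2.5 Å above the phosphate (near branch, < 3 Å);
    successive oxygens step outward by 2.5 Å, putting chain oxygen 3 about
    10 Å from it (far branch, > 6 Å).
    """
    ids = chain_oxygen_ids(topology, n)
    if spec.n_lipids > 0:
        # phosphate positions are deterministic: reuse the lipid lattice layout
        site = _lipid_sites(spec)[0]
        anchor = np.array([site[0] + 0.8, site[1], site[2] * spec.z_head])
        s = site[2]
    else:
        anchor = np.array([spec.box.lengths[0] / 2, spec.box.lengths[1] / 2, spec.z_head])
        s = 1
    sites = np.array([anchor + np.array([0.0, 0.0, s * (CHAIN_SPACING + CHAIN_SPACING * i)])
                      for i in range(n)])
    return _ChainGeometry(oxygen_ids=ids, sites=sites,
                          start_index=n - 1 if toward_plane else 0,
                          step=-1 if toward_plane else 1)


def script_relay(spec: FixtureSpec, chain: _ChainGeometry | None = None) -> Trajectory:
    """Trajectory realising the spec's scripted hop events along a water chain.

    The excess hydrogen (and, for concerted events, the donor hydrogens of the
    interior bonds) interpolates along each donor->acceptor O-O axis across the
    hop window, crossing the bond midpoint at the window's centre frame.
    """
    if not spec.relay_script:
        raise FixtureError("spec has no relay_script")
    top = compose_system(spec)
    if not spec.has_excess_proton:
        raise FixtureError("a relay fixture needs the excess proton")
    rng = np.random.default_rng(spec.seed)
    if chain is None:
        n_chain = max(len(h.concerted_group) for h in spec.relay_script)
        n_chain = max(n_chain, max(
            max(spec_chain_index(h, top) for h in spec.relay_script) + 1, 2))
        first = spec.relay_script[0]
        toward_plane = spec_chain_index_of(first.acceptor_oxygen_id, top) \
            < spec_chain_index_of(first.donor_oxygen_id, top)
        chain = default_relay_chain(spec, top, n=n_chain, toward_plane=toward_plane)
    # validate chain hydrogen-bond spacing
    for i in range(len(chain.sites) - 1):
        d = np.linalg.norm(chain.sites[i + 1] - chain.sites[i])
        if d > 2.6:
            raise FixtureError(f"chain oxygens {i},{i + 1} are {d:.2f} Å apart (> 2.6)")
    # the initial owner is the first hop's donor
    first = spec.relay_script[0]
    chain.start_index = chain.oxygen_ids.index(first.donor_oxygen_id)
    chain.step = (chain.oxygen_ids.index(first.acceptor_oxygen_id)
                  - chain.start_index)
    if abs(chain.step) != 1:
        raise FixtureError("the first hop must connect adjacent chain oxygens")

    base = build_slab_frame(spec, top, rng, chain=chain)
    w2 = spec.hop_window // 2
    n_frames = max(spec.n_frames, max(h.frame_index for h in spec.relay_script) + w2 + 2)

    events = sorted(spec.relay_script, key=lambda h: h.frame_index)
    # reject overlapping windows touching a common oxygen
    for a, b in zip(events, events[1:]):
        if b.frame_index - a.frame_index < spec.hop_window \
                and set(a.concerted_group) & set(b.concerted_group):
            raise FixtureError(
                f"hop windows at frames {a.frame_index} and {b.frame_index} "
                "overlap on a shared oxygen")

    site_by_id = dict(zip(chain.oxygen_ids, chain.sites))
    rest = {}   # hydrogen id -> rest position (mobile hydrogens only)
    h_excess = int(top.indices(EXCESS_HYDROGEN)[0])
    rest[h_excess] = base.positions[h_excess].copy()
    for oid in chain.oxygen_ids:
        rest[oid + 1] = base.positions[oid + 1].copy()
        rest[oid + 2] = base.positions[oid + 2].copy()

    max_cos = np.cos(np.deg2rad(30.0))

    def find_mobile_hydrogen(donor: int, acceptor: int) -> int:
        axis = site_by_id[acceptor] - site_by_id[donor]
        axis = axis / np.linalg.norm(axis)
        best, best_cos = None, max_cos
        for hid, hpos in rest.items():
            v = hpos - site_by_id[donor]
            r = np.linalg.norm(v)
            if r > 1.3:
                continue
            c = float(v @ axis) / r
            if c > best_cos or (c == best_cos and (best is None or hid < best)):
                best, best_cos = hid, c
        if best is None:
            raise FixtureError(
                f"no donatable hydrogen on oxygen {donor} aligned toward {acceptor}: "
                "chain is not hydrogen-bonded for this hop")
        return best

    # plan each event's mobile hydrogens in script order, updating rest positions
    plan = []
    for ev in events:
        moves = []
        for d, a in ev.bonds:
            if d not in site_by_id or a not in site_by_id:
                raise FixtureError(f"hop references oxygen {d} or {a} outside the chain")
            hid = find_mobile_hydrogen(d, a)
            axis = site_by_id[a] - site_by_id[d]
            d_oo = np.linalg.norm(axis)
            axis = axis / d_oo
            moves.append((hid, site_by_id[d].copy(), axis, d_oo))
        for hid, origin, axis, d_oo in moves:
            rest[hid] = origin + (d_oo - R_OH_RELAY) * axis   # now bound to acceptor
        plan.append((ev, moves))

    frames = []
    for f in range(n_frames):
        pos = base.positions.copy()
        # rest positions that have become final by frame f
        for ev, moves in plan:
            start = ev.frame_index - w2
            end = ev.frame_index + w2
            for hid, origin, axis, d_oo in moves:
                if f < start:
                    pass  # still at pre-event rest = base or earlier event end
                elif f > end:
                    pos[hid] = origin + (d_oo - R_OH_RELAY) * axis
                else:
                    t = (f - start) / (2 * w2)
                    r = R_OH_RELAY + (d_oo - 2 * R_OH_RELAY) * t
                    pos[hid] = origin + r * axis
        # earlier events must leave their hydrogens at the acceptor even while a
        # later event window is pending: handled above because plan is in order.
        if spec.jitter_sigma > 0:
            mobile = {hid for _, moves in plan for hid, *_ in moves}
            protect = set(chain.oxygen_ids) | {o + k for o in chain.oxygen_ids for k in (1, 2)} \
                | mobile | {h_excess}
            noise = rng.normal(scale=spec.jitter_sigma, size=pos.shape)
            noise[sorted(protect)] = 0.0
            pos = pos + noise
        frames.append(Frame(time=f * spec.timestep_fs, positions=pos, box=spec.box))
    return Trajectory(topology=top, frames=frames)


def spec_chain_index_of(oxygen_id: int, topology: Topology) -> int:
    o = water_oxygen_ids(topology)
    return int(np.nonzero(o == oxygen_id)[0][0])


def spec_chain_index(hop: HopEvent, topology: Topology) -> int:
    return max(spec_chain_index_of(x, topology) for x in hop.concerted_group)


def fixture_manifest(spec: FixtureSpec) -> dict:
    """Seed, spec hash, and the scripted hop table (for the run manifest)."""
    return {
        "seed": spec.seed,
        "spec_sha256": spec_hash(spec),
        "hop_events": [
            {"frame_index": h.frame_index, "donor": h.donor_oxygen_id,
             "acceptor": h.acceptor_oxygen_id, "group": list(h.concerted_group)}
            for h in spec.relay_script],
    }
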