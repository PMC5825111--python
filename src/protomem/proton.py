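"""Hydronium tracking, water wires, transfer coordinates and joint histograms.

The excess proton has no fixed identity under Grotthuss transfer, so the
frame-wise proton locus is defined operationally: every hydrogen is assigned
to its nearest oxygen (minimum image), and the hydronium is the water oxygen
carrying three hydrogens. At hop midpoints, where no oxygen holds three, the
oxygen minimising the sum of its three shortest O-H distances is used.

A water wire is a simple directed path in the hydrogen-bond graph rooted at
the hydronium oxygen, up to four oxygens long. For each consecutive pair the
shared proton is the donor's hydrogen participating in the bond, and the
transfer coordinate is

    v_i = r(O(i)-H) - r(O(i+1)-H)

so v < 0 while the proton is bound to the donor and v = 0 at the bond
midpoint. Joint histograms P(v1, v2) and P(v1, (v2+v3)/2) accumulate one
count per wire over all frames, binned with half-width 0.03 A and normalised
by the number of contributing wires, so probabilities sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .model import (
    EXCESS_HYDROGEN, PHOSPHATE_OXYGEN, WATER_HYDROGEN, WATER_OXYGEN,
    Frame, Topology, Trajectory, minimum_image_displacement,
    minimum_image_distance, wrap_positions,
)

DEFAULT_ASSIGN_CUTOFF = 1.3      # Å, covalent O-H assignment
DEFAULT_HBOND_OO = 3.5           # Å, donor-acceptor O-O cutoff
DEFAULT_HBOND_ANGLE = 30.0       # degrees, H-O(d)...O(a) cone
DEFAULT_BIN_HALFWIDTH = 0.03     # Å, transfer-coordinate bin half-width
DEFAULT_V_RANGE = (-1.5, 1.5)    # Å, histogram axis range


class ProtonTrackingError(ValueError):
    pass


@dataclass
class HydrogenAssignment:
    """Per-hydrogen owning oxygen, and per-oxygen hydrogen counts."""

    hydrogen_ids: np.ndarray     # (nH,) atom ids (water + excess hydrogens)
    owner: np.ndarray            # (nH,) owning oxygen atom id
    distance: np.ndarray         # (nH,) O-H distance, Å
    oxygen_ids: np.ndarray       # (nO,) oxygen atom ids considered
    counts: dict = field(default_factory=dict)  # oxygen id -> hydrogen count
    unassigned: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def hydrogens_of(self, oxygen_id: int) -> np.ndarray:
        return self.hydrogen_ids[self.owner == oxygen_id]


@dataclass
class WaterWire:
    """Ordered hydrogen-bonded oxygen chain rooted at the hydronium."""

    oxygens: tuple[int, ...]
    shared_protons: tuple[int, ...]   # hydrogen id per consecutive O pair

    @property
    def length(self) -> int:
        return len(self.oxygens)


@dataclass
class TransferCoordinates:
    v1: float
    v2: float | None = None
    v3: float | None = None


@dataclass
class JointProbabilityHistogram:
    """Binned joint probability of two transfer-coordinate axes.

    Bin membership is v in [c - delta, c + delta) for centre c, with centres
    spaced 2*delta; ``n_wires`` is the number of contributing (in-range)
    wires, ``n_dropped`` the out-of-range count.
    """

    mode: str                    # "pair" or "triple"
    x_centers: np.ndarray
    y_centers: np.ndarray
    counts: np.ndarray           # (nx, ny) integer counts
    delta: float
    v_range: tuple[float, float]
    n_wires: int
    n_dropped: int

    @property
    def probabilities(self) -> np.ndarray:
        if self.n_wires == 0:
            raise ProtonTrackingError("empty histogram: no contributing wires")
        return self.counts / self.n_wires


def assign_hydrogens(frame: Frame, topology: Topology,
                     cutoff: float = DEFAULT_ASSIGN_CUTOFF) -> HydrogenAssignment:
    """Map every water/excess hydrogen to its nearest oxygen (minimum image).

    Oxygens considered are water and phosphate oxygens. Exact distance ties
    break to the lower oxygen atom id. Hydrogens with no oxygen within
    ``cutoff`` are flagged in ``unassigned`` (a broken fixture or wrong
    cutoff), not silently dropped.
    """
    h_ids = topology.indices(WATER_HYDROGEN, EXCESS_HYDROGEN)
    o_ids = topology.indices(WATER_OXYGEN, PHOSPHATE_OXYGEN)
    if len(o_ids) == 0:
        raise ProtonTrackingError("frame has no oxygens to assign hydrogens to")
    pos = wrap_positions(frame.positions, frame.box)
    if all(frame.box.periodic):
        tree = cKDTree(pos[o_ids], boxsize=frame.box.L)
        k = min(4, len(o_ids))
        dist, idx = tree.query(pos[h_ids], k=k)
        dist = dist.reshape(len(h_ids), k)
        idx = idx.reshape(len(h_ids), k)
    else:
        d = minimum_image_distance(frame.positions[h_ids][:, None, :],
                                   frame.positions[o_ids][None, :, :], frame.box)
        idx = np.argsort(d, axis=1)[:, :4]
        dist = np.take_along_axis(d, idx, axis=1)
    owner = np.empty(len(h_ids), dtype=int)
    odist = np.empty(len(h_ids))
    for i in range(len(h_ids)):
        d0 = dist[i, 0]
        tied = idx[i][dist[i] == d0]
        owner[i] = int(o_ids[tied].min())   # deterministic tie-break: lowest id
        odist[i] = d0
    unassigned = h_ids[odist > cutoff]
    counts: dict[int, int] = {int(o): 0 for o in o_ids}
    for o, d0 in zip(owner, odist):
        if d0 <= cutoff:
            counts[int(o)] += 1
    return HydrogenAssignment(hydrogen_ids=h_ids, owner=owner, distance=odist,
                              oxygen_ids=o_ids, counts=counts, unassigned=unassigned)


def find_hydronium(assignment: HydrogenAssignment, frame: Frame,
                   topology: Topology) -> int:
    """The water oxygen carrying the excess proton in this frame.

    Returns the unique water oxygen with three assigned hydrogens; at hop
    midpoints (no triply-coordinated oxygen) falls back to the oxygen
    minimising the sum of its three shortest O-H distances. Deterministic.
    """
    if len(topology.indices(EXCESS_HYDROGEN)) != 1:
        raise ProtonTrackingError("system must contain exactly one excess hydrogen")
    water_o = set(int(o) for o in topology.indices(WATER_OXYGEN))
    triply = sorted(o for o, c in assignment.counts.items()
                    if c >= 3 and o in water_o)
    if len(triply) == 1:
        return triply[0]
    if len(triply) > 1:
        raise ProtonTrackingError(
            f"fixture inconsistency: oxygens {triply} all carry 3+ hydrogens")
    # mid-hop frame: sum of the three shortest O-H distances, minimum wins
    h_ids = assignment.hydrogen_ids
    best, best_sum = None, np.inf
    for o in sorted(water_o):
        d = minimum_image_distance(frame.positions[h_ids], frame.positions[o], frame.box)
        s = float(np.sort(d)[:3].sum())
        if s < best_sum:
            best, best_sum = o, s
    return best


def hydrogen_bond_pairs(frame: Frame, topology: Topology,
                        assignment: HydrogenAssignment,
                        oo_cutoff: float = DEFAULT_HBOND_OO,
                        angle_cutoff: float = DEFAULT_HBOND_ANGLE) -> dict:
    """Directed donor->acceptor hydrogen bonds between oxygens.

    A bond (O_d, O_a) exists when the minimum-image O-O distance is at most
    ``oo_cutoff`` and some hydrogen of the donor lies within ``angle_cutoff``
    degrees of the O_d->O_a axis. Returns ``{(donor, acceptor): hydrogen_id}``;
    if several hydrogens qualify, the one closest to the acceptor is kept.
    """
    o_ids = assignment.oxygen_ids
    pos = wrap_positions(frame.positions, frame.box)
    cos_cut = np.cos(np.deg2rad(angle_cutoff))
    bonds: dict[tuple[int, int], int] = {}
    if all(frame.box.periodic):
        tree = cKDTree(pos[o_ids], boxsize=frame.box.L)
        pairs = tree.query_pairs(oo_cutoff, output_type="ndarray")
        neighbor_lists = [(int(o_ids[i]), int(o_ids[j])) for i, j in pairs]
        neighbor_lists += [(b, a) for a, b in neighbor_lists]
    else:
        d = minimum_image_distance(frame.positions[o_ids][:, None, :],
                                   frame.positions[o_ids][None, :, :], frame.box)
        ii, jj = np.nonzero((d <= oo_cutoff) & (d > 0))
        neighbor_lists = [(int(o_ids[i]), int(o_ids[j])) for i, j in zip(ii, jj)]
    for od, oa in neighbor_lists:
        hs = assignment.hydrogens_of(od)
        if len(hs) == 0:
            continue
        axis = minimum_image_displacement(frame.positions[oa], frame.positions[od],
                                          frame.box)
        axis = axis / np.linalg.norm(axis)
        hv = minimum_image_displacement(frame.positions[hs], frame.positions[od],
                                        frame.box)
        hr = np.linalg.norm(hv, axis=1)
        cosang = (hv @ axis) / hr
        ok = cosang >= cos_cut
        if not ok.any():
            continue
        cand = hs[ok]
        d_ha = minimum_image_distance(frame.positions[cand], frame.positions[oa],
                                      frame.box)
        bonds[(od, oa)] = int(cand[np.argmin(d_ha)])
    return bonds


def enumerate_wires(bonds: dict, hydronium: int, max_length: int = 4) -> list[WaterWire]:
    """All simple directed paths in the H-bond graph rooted at the hydronium.

    Path lengths 2..max_length oxygens; revisiting an oxygen is not allowed.
    """
    adjacency: dict[int, list[int]] = {}
    for (d, a) in bonds:
        adjacency.setdefault(d, []).append(a)
    for nbrs in adjacency.values():
        nbrs.sort()
    wires: list[WaterWire] = []

    def dfs(path: list[int], protons: list[int]):
        if len(path) >= 2:
            wires.append(WaterWire(oxygens=tuple(path), shared_protons=tuple(protons)))
        if len(path) == max_length:
            return
        for nxt in adjacency.get(path[-1], []):
            if nxt in path:
                continue
            dfs(path + [nxt], protons + [bonds[(path[-1], nxt)]])

    dfs([hydronium], [])
    wires.sort(key=lambda w: w.oxygens)
    return wires


def transfer_coordinates(wire: WaterWire, frame: Frame) -> TransferCoordinates:
    """v_i = r(O(i)-H_shared) - r(O(i+1)-H_shared), minimum-image distances.

    Antisymmetric under swapping the pair's oxygens.
    """
    if wire.length < 2:
        raise ProtonTrackingError("wire must contain at least two oxygens")
    vs = []
    for i in range(wire.length - 1):
        h = wire.shared_protons[i]
        if h is None:
            raise ProtonTrackingError(
                f"missing shared proton for pair {wire.oxygens[i]}-{wire.oxygens[i + 1]}")
        r_d = minimum_image_distance(frame.positions[wire.oxygens[i]],
                                     frame.positions[h], frame.box)
        r_a = minimum_image_distance(frame.positions[wire.oxygens[i + 1]],
                                     frame.positions[h], frame.box)
        vs.append(float(r_d - r_a))
    return TransferCoordinates(*vs)


def wire_coordinates(trajectory: Trajectory,
                     assign_cutoff: float = DEFAULT_ASSIGN_CUTOFF,
                     oo_cutoff: float = DEFAULT_HBOND_OO,
                     angle_cutoff: float = DEFAULT_HBOND_ANGLE,
                     max_length: int = 4) -> list[TransferCoordinates]:
    """Transfer coordinates of every wire in every frame (Eq-level stream)."""
    out = []
    for frame in trajectory.frames:
        asg = assign_hydrogens(frame, trajectory.topology, cutoff=assign_cutoff)
        hyd = find_hydronium(asg, frame, trajectory.topology)
        bonds = hydrogen_bond_pairs(frame, trajectory.topology, asg,
                                    oo_cutoff=oo_cutoff, angle_cutoff=angle_cutoff)
        for wire in enumerate_wires(bonds, hyd, max_length=max_length):
            out.append(transfer_coordinates(wire, frame))
    return out


def joint_probability(coords, mode: str = "pair",
                      delta: float = DEFAULT_BIN_HALFWIDTH,
                      v_range: tuple[float, float] = DEFAULT_V_RANGE) -> JointProbabilityHistogram:
    """Joint probability histogram of transfer coordinates.

    ``pair`` bins (v1, v2) over wires of >= 3 oxygens; ``triple`` bins
    (v1, (v2+v3)/2) over 4-oxygen wires. Values outside ``v_range`` are
    dropped and counted in ``n_dropped``.
    """
    if mode not in ("pair", "triple"):
        raise ValueError(f"mode must be 'pair' or 'triple', got {mode!r}")
    lo, hi = v_range
    width = 2 * delta
    # centres at integer multiples of 2*delta so v = 0 sits at a bin centre;
    # bin membership is [c - delta, c + delta)
    k = int(round(max(hi, -lo) / width))
    centers = width * np.arange(-k, k + 1)
    n_bins = len(centers)
    lo = centers[0] - delta
    counts = np.zeros((n_bins, n_bins), dtype=int)
    n_in = n_drop = 0
    got_any = False
    for c in coords:
        if mode == "pair":
            if c.v2 is None:
                continue
            x, y = c.v1, c.v2
        else:
            if c.v3 is None:
                continue
            x, y = c.v1, (c.v2 + c.v3) / 2
        got_any = True
        ix = int(np.floor((x - lo) / width))
        iy = int(np.floor((y - lo) / width))
        if 0 <= ix < n_bins and 0 <= iy < n_bins:
            counts[ix, iy] += 1
            n_in += 1
        else:
            n_drop += 1
    if not got_any:
        raise ProtonTrackingError(
            f"no wires long enough for {mode!r} mode: normalisation undefined")
    return JointProbabilityHistogram(mode=mode, x_centers=centers, y_centers=centers,
                                     counts=counts, delta=delta, v_range=v_range,
                                     n_wires=n_in, n_dropped=n_drop)


def nearest_phosphate_distance(trajectory: Trajectory,
                               assign_cutoff: float = DEFAULT_ASSIGN_CUTOFF
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame distance from the excess proton to the nearest phosphate oxygen.

    The hydronium oxygen position stands for "the excess proton": hydrogen
    identity is exchanged under Grotthuss transfer, so the individual excess
    hydrogen is not a meaningful locus. Returns (times_fs, distances_A).
    """
    phos = trajectory.topology.indices(PHOSPHATE_OXYGEN)
    if len(phos) == 0:
        raise ProtonTrackingError("topology contains no phosphate oxygens")
    times, dists = [], []
    for frame in trajectory.frames:
        asg = assign_hydrogens(frame, trajectory.topology, cutoff=assign_cutoff)
        hyd = find_hydronium(asg, frame, trajectory.topology)
        d = minimum_image_distance(frame.positions[phos], frame.positions[hyd],
                                   frame.box)
        times.append(frame.time)
        dists.append(float(d.min()))
    return np.array(times), np.array(dists)
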