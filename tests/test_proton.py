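"""Hydronium assignment, hydrogen bonds, wire enumeration, transfer
coordinates and joint histograms, each checked against an independent oracle."""

import numpy as np
import pytest

import protomem as pm
from protomem.model import Box, Frame, Topology, WATER_OXYGEN, WATER_HYDROGEN, EXCESS_HYDROGEN
from protomem.proton import (ProtonTrackingError, WaterWire, enumerate_wires,
                             hydrogen_bond_pairs, joint_probability,
                             transfer_coordinates)

BOX = Box((25.0, 25.0, 25.0))


def water_box_topology(n_waters, excess=True):
    el, rl, mol, q = [], [], [], []
    for i in range(n_waters):
        el += ["O", "H", "H"]
        rl += [WATER_OXYGEN, WATER_HYDROGEN, WATER_HYDROGEN]
        mol += [i] * 3
        q += [-0.834, 0.417, 0.417]
    if excess:
        el.append("H"); rl.append(EXCESS_HYDROGEN); mol.append(-1); q.append(1.0)
    return Topology(elements=np.array(el), roles=np.array(rl),
                    molecule_ids=np.array(mol), charges=np.array(q),
                    net_charge=1.0 if excess else 0.0)


def random_water_frame(rng, n_waters, excess=True, box=BOX):
    """Loose random waters (no overlap constraints needed for assignment tests)."""
    top = water_box_topology(n_waters, excess)
    pos = np.zeros((top.n_atoms, 3))
    centers = rng.uniform(0, box.lengths[0], size=(n_waters, 3))
    for i, c in enumerate(centers):
        pos[3 * i] = c
        for k in (1, 2):
            v = rng.normal(size=3)
            pos[3 * i + k] = c + 0.96 * v / np.linalg.norm(v)
    if excess:
        host = centers[0]
        v = rng.normal(size=3)
        pos[-1] = host + 1.0 * v / np.linalg.norm(v)
    return Frame(time=0.0, positions=pos, box=box), top


class TestAssignment:
    def test_excess_makes_hydronium(self, rng):
        frame, top = random_water_frame(rng, 10)
        asg = pm.assign_hydrogens(frame, top)
        hyd = pm.find_hydronium(asg, frame, top)
        assert hyd == 0                       # excess H was planted on water 0
        assert asg.counts[0] == 3

    def test_equidistant_tie_breaks_to_lower_id(self):
        top = water_box_topology(2, excess=True)
        pos = np.zeros((7, 3))
        pos[0] = [5.0, 5.0, 5.0]
        pos[1] = [5.8, 5.6, 5.0]; pos[2] = [5.8, 4.4, 5.0]
        pos[3] = [7.4, 5.0, 5.0]
        pos[4] = [8.2, 5.6, 5.0]; pos[5] = [8.2, 4.4, 5.0]
        pos[6] = [6.2, 5.0, 5.0]              # exactly 1.2 from both oxygens
        frame = Frame(time=0.0, positions=pos, box=BOX)
        asg = pm.assign_hydrogens(frame, top)
        i = list(asg.hydrogen_ids).index(6)
        assert asg.owner[i] == 0

    def test_matches_exhaustive_nearest_oxygen(self, rng):
        frame, top = random_water_frame(rng, 500)
        asg = pm.assign_hydrogens(frame, top)
        o_ids = asg.oxygen_ids
        for hi, h in enumerate(asg.hydrogen_ids):
            d = pm.minimum_image_distance(frame.positions[h],
                                          frame.positions[o_ids], frame.box)
            assert asg.owner[hi] == o_ids[np.argmin(d)]
            assert asg.distance[hi] == pytest.approx(d.min(), abs=1e-12)

    def test_unassigned_hydrogen_flagged(self):
        top = water_box_topology(1, excess=True)
        pos = np.array([[5, 5, 5], [5.9, 5, 5], [5, 5.9, 5], [12.0, 12.0, 12.0]],
                       dtype=float)
        frame = Frame(time=0.0, positions=pos, box=BOX)
        asg = pm.assign_hydrogens(frame, top)
        assert list(asg.unassigned) == [3]

    def test_neutral_box_has_no_hydronium(self, rng):
        frame, top = random_water_frame(rng, 5, excess=False)
        asg = pm.assign_hydrogens(frame, top)
        with pytest.raises(ProtonTrackingError, match="excess"):
            pm.find_hydronium(asg, frame, top)


class TestHydrogenBonds:
    def _dimer(self, oo, angle_deg):
        top = water_box_topology(2, excess=False)
        pos = np.zeros((6, 3))
        pos[0] = [5, 5, 5]
        pos[3] = [5 + oo, 5, 5]
        a = np.radians(angle_deg)
        pos[1] = pos[0] + 0.96 * np.array([np.cos(a), np.sin(a), 0])  # donor H
        pos[2] = pos[0] + 0.96 * np.array([-0.3, -0.9, 0]) / np.linalg.norm([-0.3, -0.9, 0])
        pos[4] = pos[3] + 0.96 * np.array([0.5, 0.8, 0]) / np.linalg.norm([0.5, 0.8, 0])
        pos[5] = pos[3] + 0.96 * np.array([0.5, -0.8, 0]) / np.linalg.norm([0.5, -0.8, 0])
        frame = Frame(time=0.0, positions=pos, box=BOX)
        asg = pm.assign_hydrogens(frame, top)
        return hydrogen_bond_pairs(frame, top, asg), top

    def test_aligned_dimer_bonds(self):
        bonds, _ = self._dimer(2.8, 0.0)
        assert (0, 3) in bonds
        assert bonds[(0, 3)] == 1

    def test_distance_cutoff(self):
        bonds, _ = self._dimer(3.6, 0.0)
        assert (0, 3) not in bonds

    def test_angle_cutoff(self):
        bonds, _ = self._dimer(2.8, 45.0)
        assert (0, 3) not in bonds

    def test_matches_brute_force_scan(self, rng):
        frame, top = random_water_frame(rng, 100, excess=False)
        asg = pm.assign_hydrogens(frame, top)
        got = hydrogen_bond_pairs(frame, top, asg)
        # independent O(N^2) scan over oxygen pairs and donor hydrogens
        want = set()
        o_ids = asg.oxygen_ids
        for od in o_ids:
            for oa in o_ids:
                if od == oa:
                    continue
                d_oo = pm.minimum_image_distance(frame.positions[od],
                                                 frame.positions[oa], frame.box)
                if d_oo > 3.5:
                    continue
                for hi, h in enumerate(asg.hydrogen_ids):
                    if asg.owner[hi] != od:
                        continue
                    vh = pm.minimum_image_displacement(frame.positions[h],
                                                       frame.positions[od], frame.box)
                    va = pm.minimum_image_displacement(frame.positions[oa],
                                                       frame.positions[od], frame.box)
                    cos = vh @ va / (np.linalg.norm(vh) * np.linalg.norm(va))
                    if np.degrees(np.arccos(np.clip(cos, -1, 1))) <= 30.0:
                        want.add((int(od), int(oa)))
                        break
        assert set(got) == want


class TestWireEnumeration:
    def test_isolated_hydronium(self):
        assert enumerate_wires({}, hydronium=0) == []

    def test_linear_chain_paths(self):
        bonds = {(0, 1): 10, (1, 2): 11, (2, 3): 12}
        wires = enumerate_wires(bonds, hydronium=0)
        assert [w.oxygens for w in wires] == [(0, 1), (0, 1, 2), (0, 1, 2, 3)]
        assert wires[2].shared_protons == (10, 11, 12)

    def test_matches_networkx_simple_paths(self, rng):
        nx = pytest.importorskip("networkx")
        for trial in range(20):
            n = 12
            g = nx.gnp_random_graph(n, 0.25, seed=int(rng.integers(1 << 30)),
                                    directed=True)
            bonds = {(u, v): 100 + 10 * u + v for u, v in g.edges}
            wires = enumerate_wires(bonds, hydronium=0, max_length=4)
            got = sorted(w.oxygens for w in wires)
            want = sorted(tuple(p) for t in g.nodes if t != 0
                          for p in nx.all_simple_paths(g, 0, t, cutoff=3)
                          if 2 <= len(p) <= 4)
            assert got == want


class TestTransferCoordinates:
    def test_midpoint_is_zero(self):
        top = water_box_topology(2)
        pos = np.zeros((7, 3))
        pos[0] = [5, 5, 5]; pos[3] = [7.4, 5, 5]; pos[6] = [6.2, 5, 5]
        frame = Frame(time=0.0, positions=pos, box=BOX)
        wire = WaterWire(oxygens=(0, 3), shared_protons=(6,))
        assert transfer_coordinates(wire, frame).v1 == pytest.approx(0.0)

    def test_forced_arithmetic(self):
        top = water_box_topology(2)
        pos = np.zeros((7, 3))
        pos[0] = [0, 0, 0]; pos[3] = [2.5, 0, 0]; pos[6] = [1.0, 0, 0]
        frame = Frame(time=0.0, positions=pos, box=BOX)
        wire = WaterWire(oxygens=(0, 3), shared_protons=(6,))
        assert transfer_coordinates(wire, frame).v1 == pytest.approx(-0.5)

    def test_antisymmetric_on_random_geometries(self, rng):
        for _ in range(200):
            pos = np.zeros((7, 3))
            pos[0] = rng.uniform(0, 25, 3)
            pos[3] = pos[0] + rng.normal(size=3) * 1.2
            pos[6] = pos[0] + rng.normal(size=3) * 0.8
            frame = Frame(time=0.0, positions=pos, box=BOX)
            fwd = transfer_coordinates(WaterWire((0, 3), (6,)), frame).v1
            rev = transfer_coordinates(WaterWire((3, 0), (6,)), frame).v1
            assert fwd == -rev


class TestJointProbability:
    def test_single_wire_origin_bin(self):
        coords = [pm.TransferCoordinates(v1=0.0, v2=0.0)]
        h = joint_probability(coords, mode="pair")
        i = np.argmin(np.abs(h.x_centers))
        assert h.x_centers[i] == 0.0
        assert h.probabilities[i, i] == 1.0
        assert h.probabilities.sum() == 1.0

    def test_empty_stream_rejected(self):
        with pytest.raises(ProtonTrackingError, match="normalisation"):
            joint_probability([], mode="pair")

    def test_matches_direct_binning(self, rng):
        coords = [pm.TransferCoordinates(*rng.uniform(-1.6, 1.6, 3)) for _ in range(2000)]
        h = joint_probability(coords, mode="pair", delta=0.03)
        # independent direct count: membership v in [c - 0.03, c + 0.03)
        for _ in range(50):
            i, j = rng.integers(0, len(h.x_centers), 2)
            cx, cy = h.x_centers[i], h.y_centers[j]
            n = sum(1 for c in coords
                    if cx - 0.03 <= c.v1 < cx + 0.03 and cy - 0.03 <= c.v2 < cy + 0.03)
            assert h.counts[i, j] == n
        assert h.n_wires + h.n_dropped == len(coords)

    def test_pair_marginal_equals_direct_v1_histogram(self, rng):
        coords = [pm.TransferCoordinates(*rng.uniform(-1.0, 1.0, 2), None)
                  for _ in range(1000)]
        h = joint_probability(coords, mode="pair")
        marg = h.counts.sum(axis=1)
        edges = np.concatenate([h.x_centers - h.delta, [h.x_centers[-1] + h.delta]])
        direct, _ = np.histogram([c.v1 for c in coords], bins=edges)
        assert np.array_equal(marg, direct)


class TestNearestPhosphate:
    def test_no_phosphates_rejected(self, rng):
        frame, top = random_water_frame(rng, 3)
        traj = pm.Trajectory(topology=top, frames=[frame])
        with pytest.raises(ProtonTrackingError, match="phosphate"):
            pm.nearest_phosphate_distance(traj)

    def test_matches_brute_force_minimum(self, relay_trajectory):
        traj, _ = relay_trajectory
        times, d = pm.nearest_phosphate_distance(traj)
        phos = traj.topology.indices(pm.PHOSPHATE_OXYGEN)
        for i in (0, 15, 40, 76):
            f = traj.frames[i]
            asg = pm.assign_hydrogens(f, traj.topology)
            hyd = pm.find_hydronium(asg, f, traj.topology)
            want = min(pm.minimum_image_distance(f.positions[p], f.positions[hyd], f.box)
                       for p in phos)
            assert d[i] == pytest.approx(want, abs=1e-12)

    def test_shuttle_visits_near_and_far_branches(self, relay_trajectory):
        traj, _ = relay_trajectory
        _, d = pm.nearest_phosphate_distance(traj)
        assert d[0] < 3.0
        assert d.max() > 6.0
        assert d[-1] < 3.0
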