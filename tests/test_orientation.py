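"""Water dipole orientation: geometry, Eq-level normalisation, symmetry and
end-to-end recovery of the generator's injected orientation field."""

import numpy as np
import pytest
from scipy.stats import kstest

import protomem as pm
from protomem.interface import InterfaceSurface, coarse_grain_density, extract_surface
from protomem.model import Box, Frame
from protomem.orientation import (OrientationError, layer_mode_angle,
                                  orientation_histogram, water_dipole)
from protomem.synth import FixtureSpec, OrientationRule
from test_proton import water_box_topology


BOX = Box((20.0, 20.0, 20.0))


def one_water_frame(o, h1, h2, box=BOX):
    top = water_box_topology(1, excess=False)
    pos = np.array([o, h1, h2], dtype=float)
    return Frame(time=0.0, positions=pos, box=box), top


class TestWaterDipole:
    def test_standard_pose_bisector(self):
        frame, _ = one_water_frame([5, 5, 5], [5.76, 5.59, 5], [5.76, 4.41, 5])
        d = water_dipole(frame, 0, 1, 2)
        assert np.allclose(d, [1, 0, 0], atol=1e-12)

    def test_straddling_periodic_boundary(self):
        frame, _ = one_water_frame([19.8, 5, 5], [0.56, 5.59, 5], [0.56, 4.41, 5])
        d = water_dipole(frame, 0, 1, 2)
        assert np.allclose(d, [1, 0, 0], atol=1e-9)

    def test_rotation_equivariance(self, rng):
        for _ in range(50):
            # random rotation matrix via QR
            q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            if np.linalg.det(q) < 0:
                q[:, 0] *= -1
            o = np.array([10.0, 10.0, 10.0])
            h1 = o + np.array([0.76, 0.59, 0.0])
            h2 = o + np.array([0.76, -0.59, 0.0])
            f1, _ = one_water_frame(o, h1, h2)
            f2, _ = one_water_frame(o, o + q @ (h1 - o), o + q @ (h2 - o))
            d1 = water_dipole(f1, 0, 1, 2)
            d2 = water_dipole(f2, 0, 1, 2)
            assert np.allclose(q @ d1, d2, atol=1e-12)


def flat_surface(z0, box, nv=9):
    """Hand-built flat surface at z = z0 with +z normals (one leaflet)."""
    xs = np.linspace(0, box.lengths[0], nv, endpoint=False)
    ys = np.linspace(0, box.lengths[1], nv, endpoint=False)
    verts = np.array([[x, y, z0] for x in xs for y in ys])
    faces = []
    for i in range(nv - 1):
        for j in range(nv - 1):
            a = i * nv + j
            faces.append([a, a + 1, a + nv])
            faces.append([a + 1, a + nv + 1, a + nv])
    normals = np.tile([0.0, 0.0, 1.0], (len(verts), 1))
    return InterfaceSurface(vertices=verts, faces=np.array(faces), normals=normals,
                            leaflet=np.ones(len(verts), dtype=int), box=box,
                            level=0.5, rho_bulk=0.0333)


class TestHistogram:
    def test_aligned_dipoles_fill_top_cos_column(self):
        box = Box((20.0, 20.0, 40.0))
        n = 20
        top = water_box_topology(n, excess=False)
        pos = np.zeros((3 * n, 3))
        rng = np.random.default_rng(0)
        centers = np.column_stack([rng.uniform(0, 20, (n, 2)), rng.uniform(3, 12, n)])
        pos[0::3] = centers
        pos[1::3] = centers + [0.59, 0, 0.76]       # dipole along +z = the normal
        pos[2::3] = centers + [-0.59, 0, 0.76]
        frame = Frame(time=0.0, positions=pos, box=box)
        traj = pm.Trajectory(topology=top, frames=[frame])
        hist = orientation_histogram(traj, [flat_surface(0.0, box)], rho_bulk=0.0333)
        nz = np.nonzero(hist.weights.sum(axis=1))[0]
        assert list(nz) == [len(hist.cos_centers) - 1]

    def test_mismatched_surface_count_rejected(self, small_slab):
        with pytest.raises(OrientationError, match="surfaces"):
            orientation_histogram(small_slab, [])

    def test_rotation_by_quarter_turn_invariant(self, small_slab):
        traj = small_slab
        frame = traj.frames[0]
        field = coarse_grain_density(frame, traj.topology)
        surf = extract_surface(field)
        h1 = orientation_histogram(traj, [surf])
        # exact 90-degree rotation about z: (x, y) -> (-y, x) on everything
        def rot(p):
            q = p.copy()
            q[..., 0], q[..., 1] = -p[..., 1], p[..., 0]
            return q
        frame2 = Frame(time=0.0, positions=rot(frame.positions), box=frame.box)
        traj2 = pm.Trajectory(topology=traj.topology, frames=[frame2])
        surf2 = InterfaceSurface(vertices=rot(surf.vertices), faces=surf.faces,
                                 normals=rot(surf.normals), leaflet=surf.leaflet,
                                 box=surf.box, level=surf.level, rho_bulk=surf.rho_bulk)
        h2 = orientation_histogram(traj2, [surf2])
        assert np.array_equal(h1.weights, h2.weights)

    def test_bulk_plateau_flat_and_normalised(self):
        # bulk-only fixture: uniform waters filling the box far above a flat
        # surface; P flat in cos theta and its cos-integral near 1 at plateau Z
        box = Box((20.0, 20.0, 40.0))
        rho = 0.0333
        n = int(rho * 20 * 20 * 40)
        top = water_box_topology(n, excess=False)
        rng = np.random.default_rng(3)
        frames = []
        for k in range(20):
            centers = np.column_stack([rng.uniform(0, 20, (n, 2)),
                                       rng.uniform(-20, 20, n)])
            pos = np.zeros((3 * n, 3))
            pos[0::3] = centers
            u = rng.normal(size=(n, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            w = np.cross(u, rng.normal(size=(n, 3)))
            w /= np.linalg.norm(w, axis=1, keepdims=True)
            pos[1::3] = centers + 0.9572 * (np.cos(0.912) * u + np.sin(0.912) * w)
            pos[2::3] = centers + 0.9572 * (np.cos(0.912) * u - np.sin(0.912) * w)
            frames.append(Frame(time=float(k), positions=pos, box=box))
        traj = pm.Trajectory(topology=top, frames=frames)
        surf = flat_surface(-19.0, box)
        # single flat surface: area proxy must count one leaflet
        hist = orientation_histogram(traj, [surf] * 20, z_range=(0.0, 30.0),
                                     rho_bulk=rho)
        hist.area = 20.0 * 20.0
        P = hist.probability
        dcos = np.diff(hist.cos_edges)[0]
        # min-image distances reach at most half the box beyond the surface
        plateau = (hist.z_centers > 5) & (hist.z_centers < 18)
        integ = P[:, plateau].sum(axis=0) * dcos
        assert integ.mean() == pytest.approx(1.0, abs=0.05)
        assert np.allclose(integ, 1.0, atol=0.35)    # per-bin Monte-Carlo error
        # flat in cos theta within Monte-Carlo error
        marg = hist.weights[:, plateau].sum(axis=1)
        assert marg.max() < 1.3 * marg.mean()


class TestLayerMode:
    def _delta_hist(self, angle_deg):
        hist_box = Box((20.0, 20.0, 40.0))
        n = 50
        top = water_box_topology(n, excess=False)
        rng = np.random.default_rng(5)
        centers = np.column_stack([rng.uniform(0, 20, (n, 2)), rng.uniform(1.5, 5.0, n)])
        pos = np.zeros((3 * n, 3))
        pos[0::3] = centers
        t = np.radians(angle_deg)
        u = np.array([np.sin(t), 0.0, np.cos(t)])     # fixed tilt from +z normal
        w = np.array([0.0, 1.0, 0.0])
        pos[1::3] = centers + 0.9572 * (np.cos(0.912) * u + np.sin(0.912) * w)
        pos[2::3] = centers + 0.9572 * (np.cos(0.912) * u - np.sin(0.912) * w)
        frame = Frame(time=0.0, positions=pos, box=hist_box)
        traj = pm.Trajectory(topology=top, frames=[frame])
        return orientation_histogram(traj, [flat_surface(0.0, hist_box)],
                                     rho_bulk=0.0333)

    def test_delta_orientation_recovered(self):
        hist = self._delta_hist(150.0)
        mode = layer_mode_angle(hist, z_max=6.0)
        assert not mode.flat
        assert abs(mode.angle_deg - 150.0) <= mode.resolution_deg + 1e-9

    def test_uniform_layer_flagged_flat(self, rng):
        hist_box = Box((20.0, 20.0, 40.0))
        n = 400
        top = water_box_topology(n, excess=False)
        centers = np.column_stack([rng.uniform(0, 20, (n, 2)), rng.uniform(1.5, 5.5, n)])
        pos = np.zeros((3 * n, 3))
        pos[0::3] = centers
        u = rng.normal(size=(n, 3)); u /= np.linalg.norm(u, axis=1, keepdims=True)
        w = np.cross(u, rng.normal(size=(n, 3))); w /= np.linalg.norm(w, axis=1, keepdims=True)
        pos[1::3] = centers + 0.9572 * (np.cos(0.912) * u + np.sin(0.912) * w)
        pos[2::3] = centers + 0.9572 * (np.cos(0.912) * u - np.sin(0.912) * w)
        frame = Frame(time=0.0, positions=pos, box=hist_box)
        traj = pm.Trajectory(topology=top, frames=[frame])
        hist = orientation_histogram(traj, [flat_surface(0.0, hist_box)], rho_bulk=0.0333)
        mode = layer_mode_angle(hist, z_max=6.0)
        assert mode.flat
        assert np.isnan(mode.angle_deg)


class TestEndToEndRecovery:
    def test_injected_mode_recovered_through_interface(self):
        """generator -> density -> surface -> histogram recovers the injected
        interfacial mode within 5 degrees and leaves bulk waters flat."""
        spec = FixtureSpec(species="DPhPC", n_lipids=10, n_waters=418,
                           has_excess_proton=False, n_frames=20, seed=11,
                           jitter_sigma=0.05,
                           orientation=OrientationRule(150.0, 16.0, 6.0))
        traj = pm.generate_trajectory(spec)
        surfs = [extract_surface(coarse_grain_density(f, traj.topology))
                 for f in traj.frames]
        hist = orientation_histogram(traj, surfs)
        mode = layer_mode_angle(hist, z_max=6.0)
        assert not mode.flat
        assert abs(mode.angle_deg - 150.0) < 5.0
        cosv = []
        for f, s in zip(traj.frames, surfs):
            for o, h1, h2 in traj.topology.water_molecules():
                _, z, nrm = pm.surface_query(s, f.positions[o])
                if z > 8.0:
                    dip = water_dipole(f, o, h1, h2)
                    cosv.append(float(np.clip(dip @ nrm, -1, 1)))
        res = kstest(cosv, lambda x: (np.asarray(x) + 1) / 2)
        assert res.pvalue > 0.01
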