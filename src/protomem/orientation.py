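"""Water dipole orientation relative to the instantaneous interface.

For every water the dipole direction is the geometric O->H bisector (identical
to the charge-weighted dipole for a symmetric three-site water), theta is its
angle to the interface normal at the nearest surface point, and Z the signed
distance to the surface. The two are accumulated into P(cos theta, Z),
normalised so that in bulk water the cos(theta)-integral of P approaches one:

    P(cos theta, Z) = <sum_i m delta delta> / (rho_bulk m A dcos dZ)

with A the total interfacial area proxy n_surfaces * Lx * Ly (two leaflets per
frame). The water mass m cancels in shape but is carried for fidelity to the
mass-weighted definition.

With the into-water normal convention, hydrogens pointing toward the membrane
give theta > 90 degrees; the interfacial layer of a phosphatidylcholine slab
shows a mode near 150 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chisquare

from .model import Frame, Topology, Trajectory, minimum_image_displacement
from .interface import InterfaceSurface, surface_query

WATER_MASS = 18.01528            # u
DEFAULT_DCOS = 0.05
DEFAULT_DZ = 0.5                 # Å
DEFAULT_Z_RANGE = (-2.0, 15.0)   # Å
DEFAULT_LAYER_Z = 6.0            # Å, "first two layers" selector
#: chi-square p-value above which a layer's cos(theta) marginal is called flat
FLATNESS_PVALUE = 0.01


class OrientationError(ValueError):
    pass


@dataclass
class OrientationHistogram:
    cos_edges: np.ndarray        # (n_cos + 1,)
    z_edges: np.ndarray          # (n_z + 1,) Å
    weights: np.ndarray          # (n_cos, n_z) mass-weighted counts
    rho_bulk: float              # number density, Å^-3
    area: float                  # n_surfaces * Lx * Ly, Å^2
    n_frames: int
    water_mass: float = WATER_MASS

    @property
    def probability(self) -> np.ndarray:
        """P(cos theta, Z): bulk plateau integrates to ~1 over cos theta."""
        dcos = np.diff(self.cos_edges)[0]
        dz = np.diff(self.z_edges)[0]
        norm = self.rho_bulk * self.water_mass * self.area * self.n_frames * dcos * dz
        return self.weights / norm

    @property
    def cos_centers(self) -> np.ndarray:
        return 0.5 * (self.cos_edges[:-1] + self.cos_edges[1:])

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])


@dataclass
class LayerMode:
    """Mode of the interfacial-layer orientation marginal."""

    angle_deg: float             # NaN when the marginal is flat
    resolution_deg: float        # half-width of the mode bin, in angle
    flat: bool
    n_samples: int


def water_dipole(frame: Frame, o_id: int, h1_id: int, h2_id: int) -> np.ndarray:
    """Unit dipole (O->H bisector) of one water, minimum-image safe."""
    v1 = minimum_image_displacement(frame.positions[h1_id], frame.positions[o_id],
                                    frame.box)
    v2 = minimum_image_displacement(frame.positions[h2_id], frame.positions[o_id],
                                    frame.box)
    u = (v1 + v2) / 2
    n = np.linalg.norm(u)
    if n < 1e-8:
        raise OrientationError(f"degenerate water geometry at oxygen {o_id}")
    return u / n


def orientation_histogram(trajectory: Trajectory, surfaces: list[InterfaceSurface],
                          dcos: float = DEFAULT_DCOS, dz: float = DEFAULT_DZ,
                          z_range: tuple[float, float] = DEFAULT_Z_RANGE,
                          rho_bulk: float | None = None) -> OrientationHistogram:
    """Accumulate P(cos theta, Z) over a trajectory with per-frame surfaces.

    ``surfaces[i]`` must be the instantaneous interface of frame ``i``; the
    nearest leaflet is found automatically by the surface query. Waters whose
    Z falls outside ``z_range`` are ignored.
    """
    if len(surfaces) != trajectory.n_frames:
        raise OrientationError(
            f"{trajectory.n_frames} frames but {len(surfaces)} surfaces")
    if trajectory.n_frames == 0:
        raise OrientationError("empty trajectory")
    n_cos = int(round(2.0 / dcos))
    cos_edges = np.linspace(-1.0, 1.0, n_cos + 1)
    n_z = int(round((z_range[1] - z_range[0]) / dz))
    z_edges = z_range[0] + dz * np.arange(n_z + 1)
    weights = np.zeros((n_cos, n_z))
    molecules = trajectory.topology.water_molecules()
    box = trajectory.frames[0].box
    area = 2 * box.lengths[0] * box.lengths[1]     # two leaflet surfaces
    if rho_bulk is None:
        rho_bulk = float(np.mean([s.rho_bulk for s in surfaces]))
    for frame, surface in zip(trajectory.frames, surfaces):
        for o, h1, h2 in molecules:
            dip = water_dipole(frame, o, h1, h2)
            _, z_i, normal = surface_query(surface, frame.positions[o])
            cos_t = float(np.clip(dip @ normal, -1.0, 1.0))
            ic = min(int((cos_t + 1.0) / dcos), n_cos - 1)
            iz = int(np.floor((z_i - z_range[0]) / dz))
            if 0 <= iz < n_z:
                weights[ic, iz] += WATER_MASS
    return OrientationHistogram(cos_edges=cos_edges, z_edges=z_edges,
                                weights=weights, rho_bulk=rho_bulk, area=area,
                                n_frames=trajectory.n_frames)


def layer_mode_angle(hist: OrientationHistogram,
                     z_max: float = DEFAULT_LAYER_Z) -> LayerMode:
    """Mode of the dipole angle in the interfacial layer Z < z_max (degrees).

    The marginal over Z < z_max is tested for flatness in cos(theta): an
    isotropic layer has equal expected counts per cos bin, so a chi-square
    uniformity test with p > ``FLATNESS_PVALUE`` flags the layer as flat (no
    defined mode, reported NaN).
    Otherwise the bin counts are converted to an angular density by dividing
    each by its bin's angular width (cos bins near 0/180 degrees span far
    more angle than bins near 90), and the mode is the maximum-density bin's
    angular midpoint, with the bin angular half-width as resolution.
    """
    if z_max <= hist.z_edges[0]:
        raise OrientationError(f"z_max {z_max} below histogram range")
    sel = hist.z_centers < z_max
    marginal = hist.weights[:, sel].sum(axis=1)
    n = int(round(marginal.sum() / hist.water_mass))
    if n == 0:
        raise OrientationError(f"no waters with Z < {z_max} Å")
    counts = marginal / hist.water_mass
    pvalue = chisquare(counts).pvalue if counts.sum() > 0 else 1.0
    if pvalue > FLATNESS_PVALUE:
        return LayerMode(angle_deg=float("nan"), resolution_deg=float("nan"),
                         flat=True, n_samples=n)
    ang_edges = np.degrees(np.arccos(np.clip(hist.cos_edges, -1, 1)))
    widths = ang_edges[:-1] - ang_edges[1:]          # angular width per cos bin
    density = marginal / widths
    i = int(np.argmax(density))
    center = 0.5 * (ang_edges[i] + ang_edges[i + 1])
    return LayerMode(angle_deg=float(center),
                     resolution_deg=float(widths[i] / 2),
                     flat=False, n_samples=n)


def export_histogram(hist: OrientationHistogram, path) -> None:
    """2D TSV matrix (rows: cos theta bins, columns: Z bins), edges in header."""
    with open(path, "w") as fh:
        fh.write("# P(cos_theta, Z); rows cos theta, columns Z (A)\n")
        fh.write("# cos_edges\t" + "\t".join(f"{e:.4f}" for e in hist.cos_edges) + "\n")
        fh.write("# z_edges_A\t" + "\t".join(f"{e:.4f}" for e in hist.z_edges) + "\n")
        fh.write(f"# rho_bulk_A^-3\t{hist.rho_bulk:.6f}\tarea_A^2\t{hist.area:.4f}"
                 f"\tn_frames\t{hist.n_frames}\twater_mass_u\t{hist.water_mass}\n")
        np.savetxt(fh, hist.probability, fmt="%.8g", delimiter="\t")
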