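"""Willard-Chandler instantaneous water/membrane interface.

The water-oxygen number density is coarse-grained with a periodic Gaussian
kernel of width xi onto a regular grid,

    rho(r) = sum_i (2 pi xi^2)^(-3/2) exp(-|r - r_i|^2_min-image / 2 xi^2),

the bulk density rho_bulk is estimated from the plateau at the centre of the
water slab, and the instantaneous interface is the rho_bulk/2 isosurface,
triangulated by marching cubes and recomputed every frame. Normals point from
the membrane into the water phase (up the density gradient). The two leaflet
surfaces of a bilayer are labelled and never merged.

Default parameters follow the common water convention for this construction:
xi = 2.4 A, grid spacing 1.0 A, isolevel rho_bulk/2; all are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.measure import marching_cubes

from .model import WATER_OXYGEN, Box, Frame, Topology, minimum_image_displacement

DEFAULT_XI = 2.4                 # Å, coarse-graining width
DEFAULT_SPACING = 1.0            # Å, target grid spacing
DEFAULT_PLATEAU_HALFWIDTH = 4.0  # Å, half-width of the bulk-plateau region
FALLBACK_RHO_BULK = 0.0333       # Å^-3, ambient liquid water number density
_KERNEL_CUTOFF_SIGMAS = 4.5      # per-axis truncation of the Gaussian kernel


class InterfaceError(ValueError):
    pass


@dataclass
class DensityField:
    """Coarse-grained water number density on a periodic grid.

    Grid point (i, j, k) sits at ``origin + (i*hx, j*hy, k*hz)`` with
    ``origin = -L/2``; the grid wraps periodically in all axes.
    """

    values: np.ndarray           # (nx, ny, nz), Å^-3
    spacing: tuple[float, float, float]
    box: Box
    xi: float
    rho_bulk: float
    water_center_z: float        # circular-mean z of the water slab (Å)

    @property
    def origin(self) -> np.ndarray:
        return -self.box.L / 2

    def integral(self) -> float:
        """Integral of the field over the box (should equal the water count)."""
        return float(self.values.sum() * np.prod(self.spacing))


@dataclass
class InterfaceSurface:
    """Triangulated instantaneous interface with outward (into-water) normals."""

    vertices: np.ndarray         # (M, 3) Å, box-centred coordinates
    faces: np.ndarray            # (K, 3) vertex indices
    normals: np.ndarray          # (M, 3) unit, pointing into the water phase
    leaflet: np.ndarray          # (M,) +1 upper / -1 lower
    box: Box
    level: float
    rho_bulk: float
    _max_edge: float = field(default=0.0, repr=False)

    def __post_init__(self):
        if self._max_edge == 0.0 and len(self.faces):
            tri = self.vertices[self.faces]
            e = np.linalg.norm(np.stack([tri[:, 0] - tri[:, 1],
                                         tri[:, 1] - tri[:, 2],
                                         tri[:, 2] - tri[:, 0]]), axis=-1)
            self._max_edge = float(e.max())

    def triangle_areas(self) -> np.ndarray:
        tri = self.vertices[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def area(self, leaflet: int | None = None) -> float:
        areas = self.triangle_areas()
        if leaflet is None:
            return float(areas.sum())
        # assign each triangle by majority vertex label
        lab = self.leaflet[self.faces].sum(axis=1)
        return float(areas[np.sign(lab) == np.sign(leaflet)].sum())


def _circular_mean(x: np.ndarray, L: float) -> float:
    ang = x / L * 2 * np.pi
    m = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
    return float(m / (2 * np.pi) * L)


def coarse_grain_density(frame: Frame, topology: Topology,
                         xi: float = DEFAULT_XI,
                         spacing: float = DEFAULT_SPACING,
                         plateau_halfwidth: float = DEFAULT_PLATEAU_HALFWIDTH,
                         rho_bulk: float | None = None) -> DensityField:
    """Gaussian coarse-grained water-oxygen density on a periodic grid.

    Only water oxygens contribute. ``rho_bulk`` is estimated as the mean field
    over the slab of grid planes within ``plateau_halfwidth`` of the water
    slab's (circular-mean) centre, unless given explicitly.
    """
    if xi <= spacing / 2:
        raise InterfaceError(f"xi ({xi}) must exceed half the grid spacing ({spacing})")
    o_ids = topology.indices(WATER_OXYGEN)
    if len(o_ids) == 0:
        raise InterfaceError("no water oxygens: density field undefined")
    L = frame.box.L
    n = np.maximum(4, np.round(L / spacing).astype(int))
    h = L / n
    waters = frame.positions[o_ids]
    norm = (2 * np.pi * xi ** 2) ** -1.5
    gs = []
    for ax in range(3):
        grid = -L[ax] / 2 + h[ax] * np.arange(n[ax])
        dx = grid[None, :] - waters[:, ax:ax + 1]
        dx = dx - L[ax] * np.round(dx / L[ax])          # minimum image per axis
        g = np.exp(-0.5 * (dx / xi) ** 2)
        g[np.abs(dx) > _KERNEL_CUTOFF_SIGMAS * xi] = 0.0
        gs.append(g)
    values = norm * np.einsum("wi,wj,wk->ijk", gs[0], gs[1], gs[2])

    zc = _circular_mean(waters[:, 2], L[2])
    if rho_bulk is None:
        gz = -L[2] / 2 + h[2] * np.arange(n[2])
        dz = gz - zc
        dz = dz - L[2] * np.round(dz / L[2])
        mask = np.abs(dz) <= plateau_halfwidth
        if not mask.any():
            rho_bulk = FALLBACK_RHO_BULK
        else:
            rho_bulk = float(values[:, :, mask].mean())
            if not np.isfinite(rho_bulk) or rho_bulk <= 0:
                rho_bulk = FALLBACK_RHO_BULK
    return DensityField(values=values, spacing=tuple(h), box=frame.box, xi=xi,
                        rho_bulk=float(rho_bulk), water_center_z=zc)


def _periodic_gradient(values: np.ndarray, h) -> list[np.ndarray]:
    return [(np.roll(values, -1, axis=ax) - np.roll(values, 1, axis=ax)) / (2 * h[ax])
            for ax in range(3)]


def extract_surface(field: DensityField, isolevel_fraction: float = 0.5,
                    level: float | None = None) -> InterfaceSurface:
    """Triangulated isosurface at ``level`` (default rho_bulk/2).

    Marching cubes with linear edge interpolation on the periodically padded
    grid; vertex normals are the interpolated density gradient, normalised to
    point toward increasing water density (into the water phase). Vertices are
    split into upper/lower leaflets by z relative to the membrane midplane.
    """
    if level is None:
        level = isolevel_fraction * field.rho_bulk
    v = field.values
    if not (v.min() < level < v.max()):
        raise InterfaceError(
            f"no interface: the level {level:.4g} does not separate the field "
            f"(range {v.min():.4g}..{v.max():.4g})")
    h = np.asarray(field.spacing)
    padded = np.pad(v, ((0, 1), (0, 1), (0, 1)), mode="wrap")
    verts, faces, _, _ = marching_cubes(padded, level=level, spacing=tuple(h))
    verts = verts + field.origin     # into box-centred coordinates

    grads = _periodic_gradient(v, h)
    idx = ((verts - field.origin) / h).T     # fractional grid indices
    g = np.stack([map_coordinates(gax, idx, order=1, mode="grid-wrap")
                  for gax in grads], axis=1)
    norms = np.linalg.norm(g, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    normals = g / norms

    L = field.box.L
    z_mem = field.water_center_z + L[2] / 2
    z_mem = (z_mem + L[2] / 2) % L[2] - L[2] / 2      # membrane midplane, wrapped
    dz = verts[:, 2] - z_mem
    dz = dz - L[2] * np.round(dz / L[2])
    leaflet = np.where(dz >= 0, 1, -1)
    return InterfaceSurface(vertices=verts, faces=faces, normals=normals,
                            leaflet=leaflet, box=field.box, level=float(level),
                            rho_bulk=field.rho_bulk)


# ---------------------------------------------------------------------------
# nearest-point queries

def _barycentric(s, a, b, c):
    ab, ac, asv = b - a, c - a, s - a
    d00 = ab @ ab
    d01 = ab @ ac
    d11 = ac @ ac
    det = d00 * d11 - d01 * d01
    if abs(det) < 1e-12:
        return np.array([1.0, 0.0, 0.0])
    v = (d11 * (asv @ ab) - d01 * (asv @ ac)) / det
    w = (d00 * (asv @ ac) - d01 * (asv @ ab)) / det
    v, w = float(np.clip(v, 0, 1)), float(np.clip(w, 0, 1))
    u = max(0.0, 1.0 - v - w)
    return np.array([u, v, w])


def surface_query(surface: InterfaceSurface, point) -> tuple[np.ndarray, float, np.ndarray]:
    """(nearest surface point s*, signed distance, normal at s*) for ``point``.

    The signed distance is >= 0 on the water side of the surface and < 0 on
    the membrane side. The search is exact over the whole mesh (a vertex
    prefilter bounds which triangles can contain the closest point); exact
    distance ties resolve to the lowest vertex/triangle index.
    """
    if len(surface.vertices) == 0:
        raise InterfaceError("empty surface")
    p = np.asarray(point, dtype=float)
    verts = surface.vertices
    dv = minimum_image_displacement(p, verts, surface.box)
    d = np.linalg.norm(dv, axis=1)
    i0 = int(np.argmin(d))               # first occurrence: lowest index on ties
    d0 = float(d[i0])
    if len(surface.faces) == 0:
        return verts[i0], d0, surface.normals[i0]
    faces = surface.faces
    tri_min = d[faces].min(axis=1)
    short = np.nonzero(tri_min <= d0 + surface._max_edge + 1e-9)[0]
    a = verts[faces[short, 0]]
    # place the point in the local (unwrapped) frame of each triangle
    p_loc = a + minimum_image_displacement(p, a, surface.box)
    b = verts[faces[short, 1]]
    c = verts[faces[short, 2]]
    pts, dist = _closest_on_triangles_multi(p_loc, a, b, c)
    j = int(np.argmin(dist))
    if dist[j] < d0 - 1e-12:
        tri = faces[short[j]]
        s_star = pts[j]
        bary = _barycentric(s_star, verts[tri[0]], verts[tri[1]], verts[tri[2]])
        normal = bary @ surface.normals[tri]
        nn = np.linalg.norm(normal)
        normal = surface.normals[tri[0]] if nn == 0 else normal / nn
        dd = float(dist[j])
        p_ref = p_loc[j]
    else:
        s_star = verts[i0]
        normal = surface.normals[i0]
        dd = d0
        p_ref = verts[i0] + dv[i0]
    sign = 1.0 if float((p_ref - s_star) @ normal) >= 0 else -1.0
    return s_star, sign * dd, normal


def _closest_on_triangles_multi(p_loc, a, b, c):
    """As _closest_on_triangles but with a per-triangle point (local frames)."""
    ab, ac = b - a, c - a
    ap = p_loc - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p_loc - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p_loc - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = np.clip(d1 / (d1 - d3), 0, 1)
        t_ac = np.clip(d2 / (d2 - d6), 0, 1)
        t_bc = np.clip((d4 - d3) / ((d4 - d3) + (d5 - d6)), 0, 1)
        denom = va + vb + vc
        v_in = vb / denom
        w_in = vc / denom
    for arr in (t_ab, t_ac, t_bc, v_in, w_in):
        np.nan_to_num(arr, copy=False)
    out = a + v_in[:, None] * ab + w_in[:, None] * ac
    m = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    out[m] = b[m] + t_bc[m, None] * (c[m] - b[m])
    m = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    out[m] = a[m] + t_ac[m, None] * ac[m]
    m = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    out[m] = a[m] + t_ab[m, None] * ab[m]
    m = (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    m = (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    dist = np.linalg.norm(out - p_loc, axis=1)
    return out, dist


def export_obj(surface: InterfaceSurface, path) -> None:
    """OBJ-style vertex/face text export."""
    with open(path, "w") as fh:
        for v, n in zip(surface.vertices, surface.normals):
            fh.write(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
            fh.write(f"vn {n[0]:.6f} {n[1]:.6f} {n[2]:.6f}\n")
        for f in surface.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


def export_vertex_table(surface: InterfaceSurface, path) -> None:
    """TSV vertex table: position, normal, leaflet label."""
    with open(path, "w") as fh:
        fh.write("# x_A\ty_A\tz_A\tnx\tny\tnz\tleaflet\n")
        for v, nrm, lf in zip(surface.vertices, surface.normals, surface.leaflet):
            fh.write(f"{v[0]:.6f}\t{v[1]:.6f}\t{v[2]:.6f}\t"
                     f"{nrm[0]:.6f}\t{nrm[1]:.6f}\t{nrm[2]:.6f}\t{int(lf)}\n")
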