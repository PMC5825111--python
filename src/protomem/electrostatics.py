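"""Electrostatic potential profile across the bilayer.

The laterally averaged charge density rho_q(z) is binned per frame after
recentring z on the lipid centre of mass, then the potential follows from
Poisson's equation in planar symmetry by double integration:

    E(z)  = (1/eps0) * integral_{-Lz/2}^z rho_q(z') dz'
    phi(z) = - integral_0^z E(z') dz'                     (phi(0) = 0)

with z = 0 at the bilayer centre. The field is anchored to zero at the lower
box edge, which lies in the middle of the bulk-water slab; for a symmetric
neutral bilayer this also makes E(0) = 0 at the centre. Charges
are point charges binned to the nearest z bin; the excess proton is excluded,
matching the charge-neutral classical boxes this profile emulates. Output in
volts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.constants import elementary_charge, epsilon_0

from .model import ATOMIC_MASS, EXCESS_HYDROGEN, Topology, Trajectory

DEFAULT_DZ = 0.5   # Å

#: (e / Å^2) / eps0 expressed in V / Å
_E_FACTOR = elementary_charge / epsilon_0 * 1e20 * 1e-10


class ElectrostaticsError(ValueError):
    pass


@dataclass
class PotentialProfile:
    z: np.ndarray          # bin centres, Å, z = 0 at the bilayer centre
    rho_q: np.ndarray      # e Å^-3
    efield: np.ndarray     # V Å^-1
    phi: np.ndarray        # V


def charge_density_profile(trajectory: Trajectory, dz: float = DEFAULT_DZ,
                           exclude_excess: bool = True,
                           recenter: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Frame-averaged planar charge density rho_q(z) in e/Å^3.

    z is recentred each frame so the lipid centre of mass sits at 0 (skipped
    when the system has no lipids or ``recenter`` is false). Molecules are
    made whole before binning (atoms unwrapped next to the first atom of
    their molecule): a molecule straddling the periodic boundary must not
    split into monopoles at opposite box edges, which would tilt the doubly
    integrated potential across the whole box. Returns (bin centres, rho_q).
    """
    top = trajectory.topology
    if trajectory.n_frames == 0:
        raise ElectrostaticsError("empty trajectory")
    charges = top.charges.copy()
    if not np.any(charges != 0):
        raise ElectrostaticsError("topology carries no partial charges")
    keep = np.ones(top.n_atoms, dtype=bool)
    if exclude_excess:
        keep[top.indices(EXCESS_HYDROGEN)] = False
    lipid_idx = top.indices("phosphate_oxygen", "lipid_other")
    box = trajectory.frames[0].box
    Lz = box.lengths[2]
    n_bins = int(round(Lz / dz))
    edges = np.linspace(-Lz / 2, Lz / 2, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    acc = np.zeros(n_bins)
    masses = np.array([ATOMIC_MASS.get(el, 12.0) for el in top.elements])
    # first atom of each molecule serves as the unwrap reference
    mols = top.molecule_ids.copy()
    mols[mols < 0] = mols.max(initial=0) + 1 + np.arange(np.sum(mols < 0))
    _, first_idx, inverse = np.unique(mols, return_index=True, return_inverse=True)
    for frame in trajectory.frames:
        z = frame.positions[:, 2].copy()
        if recenter and len(lipid_idx):
            m = masses[lipid_idx]
            zc = float(np.average(z[lipid_idx], weights=m))
            z = z - zc
        zref = ((z[first_idx] + Lz / 2) % Lz - Lz / 2)[inverse]
        dzu = z - z[first_idx][inverse]
        dzu = dzu - Lz * np.round(dzu / Lz)
        z = zref + dzu
        idx = np.clip(np.floor((z + Lz / 2) / (Lz / n_bins)).astype(int), 0, n_bins - 1)
        np.add.at(acc, idx[keep], charges[keep])
    vol = box.lengths[0] * box.lengths[1] * (Lz / n_bins)
    return centers, acc / (trajectory.n_frames * vol)


def potential_profile(z: np.ndarray, rho_q: np.ndarray) -> PotentialProfile:
    """Double-integrate rho_q(z) to E(z) and phi(z).

    ``rho_q`` is a binned (histogram) density with bin centres ``z``; the
    integration is exact for the piecewise-constant density: the field is
    cumulated to the bin edges (so a charge-neutral profile closes to E = 0
    exactly, with no quadrature leakage of a spurious uniform field), and the
    resulting piecewise-linear field is integrated exactly to phi. E vanishes
    at the lower grid edge (bulk water for a membrane slab); phi is anchored
    to zero at the bilayer centre z = 0.
    """
    z = np.asarray(z, dtype=float)
    rho_q = np.asarray(rho_q, dtype=float)
    dzs = np.diff(z)
    if len(z) < 3 or np.any(np.abs(dzs - dzs[0]) > 1e-9 * max(1.0, abs(dzs[0]))):
        raise ElectrostaticsError("potential_profile requires a uniform z grid")
    h = float(dzs[0])
    # field at bin edges: exact cumulative of the piecewise-constant density
    e_edges = np.concatenate([[0.0], np.cumsum(rho_q) * h]) * _E_FACTOR   # V/Å
    efield = 0.5 * (e_edges[:-1] + e_edges[1:])          # exact value at centres
    # potential at bin edges: exact integral of the piecewise-linear field
    phi_edges = np.concatenate([[0.0], -np.cumsum(0.5 * (e_edges[:-1] + e_edges[1:]) * h)])
    # value at a centre: edge value plus the half-bin integral of linear E
    phi = phi_edges[:-1] - 0.5 * (e_edges[:-1] + efield) * (h / 2)
    edges = np.concatenate([z - h / 2, [z[-1] + h / 2]])
    phi0 = np.interp(0.0, edges, phi_edges)
    phi = phi - phi0
    return PotentialProfile(z=z, rho_q=rho_q, efield=efield, phi=phi)


def trajectory_potential(trajectory: Trajectory, dz: float = DEFAULT_DZ,
                         exclude_excess: bool = True) -> PotentialProfile:
    """Charge density + double integration in one call."""
    z, rho = charge_density_profile(trajectory, dz=dz, exclude_excess=exclude_excess)
    return potential_profile(z, rho)


def export_profile(profile: PotentialProfile, path) -> None:
    """TSV columns z (Å), rho_q (e/Å^3), E (V/Å), phi (V)."""
    with open(path, "w") as fh:
        fh.write("# z_A\trho_q_e_per_A3\tE_V_per_A\tphi_V\n")
        for row in zip(profile.z, profile.rho_q, profile.efield, profile.phi):
            fh.write("\t".join(f"{x:.10g}" for x in row) + "\n")
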