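"""Trajectory readers and writers: extended XYZ and PDB.

XYZ uses the extended dialect with an orthorhombic box in the comment line::

    2795
    Lattice="19.7 0.0 0.0 0.0 19.7 0.0 0.0 0.0 70.6" Properties=species:S:1:pos:R:3 Time=0.000
    O 1.234567 ...

Box metadata is mandatory: every analysis in this package is periodic, so a
file without a ``Lattice=`` entry (or a PDB without CRYST1) is rejected rather
than silently treated as non-periodic.

Roles, molecule ids and charges are not representable in plain XYZ, and PDB
cannot carry charges; both writers therefore emit a JSON sidecar
(``<file>.roles.json``). On read, the sidecar takes precedence; for PDB
without a sidecar, roles are recovered from residue/atom names:

* residue HOH/TIP3/SOL: atom ``O*`` -> water_oxygen, ``H*`` -> water_hydrogen
* residue PRT (single hydrogen): excess_hydrogen
* residues in the lipid set (default LIP/DPC/DOP): atom names O1P..O4P /
  OP1..OP4 -> phosphate_oxygen, everything else -> lipid_other
"""

from __future__ import annotations

import json
import re
import warnings
from pathlib import Path

import numpy as np

from .model import (
    EXCESS_HYDROGEN, LIPID_OTHER, NO_MOLECULE, PHOSPHATE_OXYGEN, WATER_HYDROGEN,
    WATER_OXYGEN, Box, Frame, Topology, Trajectory,
)

WATER_RESNAMES = {"HOH", "TIP3", "SOL", "WAT"}
EXCESS_RESNAME = "PRT"
DEFAULT_LIPID_RESNAMES = {"LIP", "DPC", "DOP"}
PHOSPHATE_ATOM_NAMES = {"O1P", "O2P", "O3P", "O4P", "OP1", "OP2", "OP3", "OP4"}

# default partial charges reconstructed when no sidecar is available (e)
ROLE_DEFAULT_CHARGE = {
    WATER_OXYGEN: -0.834, WATER_HYDROGEN: 0.417, EXCESS_HYDROGEN: 1.0,
    PHOSPHATE_OXYGEN: 0.0, LIPID_OTHER: 0.0,
}


class FormatError(ValueError):
    """Malformed trajectory file; the message names the offending line."""


class MissingBoxError(FormatError):
    """The file carries no periodic-box metadata, which periodic analyses require."""


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".roles.json")


def _write_sidecar(topology: Topology, path) -> None:
    data = {
        "roles": topology.roles.tolist(),
        "molecule_ids": topology.molecule_ids.tolist(),
        "charges": topology.charges.tolist(),
        "net_charge": topology.net_charge,
    }
    _sidecar_path(path).write_text(json.dumps(data))


def _topology_from_sidecar(elements: np.ndarray, path) -> Topology | None:
    sc = _sidecar_path(path)
    if not sc.exists():
        return None
    data = json.loads(sc.read_text())
    return Topology(elements=elements, roles=np.array(data["roles"]),
                    molecule_ids=np.array(data["molecule_ids"]),
                    charges=np.array(data["charges"]),
                    net_charge=float(data["net_charge"]))


# ---------------------------------------------------------------------------
# extended XYZ

_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')
_TIME_RE = re.compile(r"Time=([-\d.eE+]+)")


def write_xyz(traj: Trajectory, path, precision: int = 6) -> None:
    """Write an extended-XYZ trajectory plus the role-map sidecar."""
    fmt = f"%s %.{precision}f %.{precision}f %.{precision}f\n"
    with open(path, "w") as fh:
        for frame in traj.frames:
            L = frame.box.lengths
            lattice = f'Lattice="{L[0]:.6f} 0.0 0.0 0.0 {L[1]:.6f} 0.0 0.0 0.0 {L[2]:.6f}"'
            fh.write(f"{frame.n_atoms}\n")
            fh.write(f"{lattice} Properties=species:S:1:pos:R:3 Time={frame.time:.6f}\n")
            for el, p in zip(traj.topology.elements, frame.positions):
                fh.write(fmt % (el, p[0], p[1], p[2]))
    _write_sidecar(traj.topology, path)


def read_xyz(path, topology: Topology | None = None) -> Trajectory:
    """Read an extended-XYZ trajectory; roles come from ``topology`` or the sidecar."""
    lines = Path(path).read_text().splitlines()
    frames: list[Frame] = []
    elements_ref: np.ndarray | None = None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise FormatError(f"{path}: line {i + 1}: expected atom count, got {lines[i]!r}")
        if i + 1 + n >= len(lines) + 1 and n > 0 and i + 1 + n > len(lines):
            raise FormatError(f"{path}: line {i + 1}: truncated frame ({n} atoms declared)")
        comment = lines[i + 1]
        m = _LATTICE_RE.search(comment)
        if m is None:
            raise MissingBoxError(
                f"{path}: line {i + 2}: no Lattice=\"...\" box metadata; "
                "periodic analyses require a box")
        cell = np.array(m.group(1).split(), dtype=float)
        if cell.size != 9:
            raise FormatError(f"{path}: line {i + 2}: Lattice must have 9 numbers")
        cell = cell.reshape(3, 3)
        if np.any(np.abs(cell - np.diag(np.diag(cell))) > 1e-9):
            raise FormatError(f"{path}: line {i + 2}: only orthorhombic boxes are supported")
        box = Box(tuple(np.diag(cell)))
        tm = _TIME_RE.search(comment)
        time = float(tm.group(1)) if tm else float(len(frames))
        els, pos = [], []
        for j in range(n):
            parts = lines[i + 2 + j].split()
            if len(parts) < 4:
                raise FormatError(f"{path}: line {i + 3 + j}: malformed atom record {lines[i + 2 + j]!r}")
            els.append(parts[0])
            try:
                pos.append([float(x) for x in parts[1:4]])
            except ValueError:
                raise FormatError(f"{path}: line {i + 3 + j}: non-numeric coordinate in {lines[i + 2 + j]!r}")
        els = np.array(els, dtype="U4")
        if elements_ref is None:
            elements_ref = els
        elif not np.array_equal(elements_ref, els):
            raise FormatError(f"{path}: line {i + 1}: frames disagree on atom ordering")
        frames.append(Frame(time=time, positions=np.array(pos), box=box))
        i += 2 + n
    if elements_ref is None:
        raise FormatError(f"{path}: no frames found")
    if topology is None:
        topology = _topology_from_sidecar(elements_ref, path)
    if topology is None:
        raise FormatError(
            f"{path}: no role map: pass a Topology or provide the "
            f"'{_sidecar_path(path).name}' sidecar")
    if topology.n_atoms != len(elements_ref):
        raise FormatError(f"{path}: topology has {topology.n_atoms} atoms, file has {len(elements_ref)}")
    return Trajectory(topology=topology, frames=frames)


# ---------------------------------------------------------------------------
# PDB (via MDAnalysis)

def _atom_names(topology: Topology) -> list[str]:
    """Deterministic per-residue atom names encoding the role convention."""
    names = []
    counters: dict[tuple[int, str], int] = {}
    phos_counter: dict[int, int] = {}
    water_h: dict[int, int] = {}
    for i in range(topology.n_atoms):
        mol = int(topology.molecule_ids[i])
        role = topology.roles[i]
        el = topology.elements[i]
        if role == WATER_OXYGEN:
            names.append("O")
        elif role == WATER_HYDROGEN:
            water_h[mol] = water_h.get(mol, 0) + 1
            names.append(f"H{water_h[mol]}")
        elif role == EXCESS_HYDROGEN:
            names.append("H")
        elif role == PHOSPHATE_OXYGEN:
            phos_counter[mol] = phos_counter.get(mol, 0) + 1
            names.append(f"O{phos_counter[mol]}P")
        else:
            counters[(mol, el)] = counters.get((mol, el), 0) + 1
            names.append(f"{el}{counters[(mol, el)]}"[:4])
    return names


def write_pdb(traj: Trajectory, path) -> None:
    """Write a (multi-frame) PDB with CRYST1, plus the role-map sidecar."""
    import MDAnalysis as mda

    top = traj.topology
    mols = top.molecule_ids.copy()
    # the excess proton gets its own one-atom residue at the end
    mols[mols == NO_MOLECULE] = mols.max(initial=0) + 1
    uniq, resindex = np.unique(mols, return_inverse=True)
    resnames = []
    for m in uniq:
        roles = set(top.roles[mols == m])
        if EXCESS_HYDROGEN in roles:
            resnames.append(EXCESS_RESNAME)
        elif roles <= {WATER_OXYGEN, WATER_HYDROGEN}:
            resnames.append("HOH")
        else:
            resnames.append("LIP")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(top.n_atoms, n_residues=len(uniq),
                               atom_resindex=resindex, trajectory=True)
        u.add_TopologyAttr("names", _atom_names(top))
        u.add_TopologyAttr("elements", top.elements.tolist())
        u.add_TopologyAttr("resnames", resnames)
        u.add_TopologyAttr("resids", (np.arange(len(uniq)) % 9999) + 1)
        with mda.Writer(str(path), multiframe=True, n_atoms=top.n_atoms) as w:
            for frame in traj.frames:
                u.atoms.positions = frame.positions
                u.dimensions = [*frame.box.lengths, 90.0, 90.0, 90.0]
                w.write(u.atoms)
    _write_sidecar(top, path)


def read_pdb(path, timestep: float = 1.0,
             lipid_resnames=frozenset(DEFAULT_LIPID_RESNAMES)) -> Trajectory:
    """Read a PDB trajectory; roles from the sidecar or the naming convention.

    ``timestep`` (fs) spaces the frames, since PDB carries no time axis.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        dims = u.dimensions
        if dims is None:
            # multi-MODEL files keep CRYST1 in the header, which the reader skips
            for line in Path(path).read_text().splitlines():
                if line.startswith("CRYST1"):
                    dims = np.array([float(line[6:15]), float(line[15:24]),
                                     float(line[24:33]), float(line[33:40]),
                                     float(line[40:47]), float(line[47:54])])
                    break
        if dims is None or not np.all(dims[:3] > 0):
            raise MissingBoxError(f"{path}: no CRYST1 box record; periodic analyses require a box")
        if np.any(np.abs(dims[3:] - 90.0) > 1e-3):
            raise FormatError(f"{path}: only orthorhombic (90/90/90) cells are supported")
        elements = np.array([el.capitalize() if el else name[0]
                             for el, name in zip(
                                 getattr(u.atoms, "elements", [""] * len(u.atoms)),
                                 u.atoms.names)], dtype="U4")
        topology = _topology_from_sidecar(elements, path)
        if topology is None:
            roles, molids, charges = [], [], []
            for atom in u.atoms:
                res, name = atom.resname.upper(), atom.name.upper()
                if res == EXCESS_RESNAME:
                    role, mol = EXCESS_HYDROGEN, NO_MOLECULE
                elif res in WATER_RESNAMES:
                    role = WATER_OXYGEN if name.startswith("O") else WATER_HYDROGEN
                    mol = atom.resindex
                elif res in lipid_resnames:
                    role = PHOSPHATE_OXYGEN if name in PHOSPHATE_ATOM_NAMES else LIPID_OTHER
                    mol = atom.resindex
                else:
                    role, mol = LIPID_OTHER, atom.resindex
                roles.append(role)
                molids.append(mol)
                charges.append(ROLE_DEFAULT_CHARGE[role])
            charges = np.array(charges)
            net = round(float(charges.sum()))
            topology = Topology(elements=elements, roles=np.array(roles),
                                molecule_ids=np.array(molids), charges=charges,
                                net_charge=float(net))
        frames = []
        for i, ts in enumerate(u.trajectory):
            fd = ts.dimensions if ts.dimensions is not None else dims
            box = Box(tuple(float(x) for x in fd[:3]))
            frames.append(Frame(time=i * timestep, positions=ts.positions.astype(float).copy(),
                                box=box))
    return Trajectory(topology=topology, frames=frames)


# ---------------------------------------------------------------------------
# dispatch

def write_trajectory(traj: Trajectory, path, format: str | None = None) -> None:
    fmt = (format or Path(path).suffix.lstrip(".")).lower()
    if fmt == "xyz":
        write_xyz(traj, path)
    elif fmt == "pdb":
        write_pdb(traj, path)
    else:
        raise ValueError(f"unsupported trajectory format {fmt!r} (xyz, pdb)")


def read_trajectory(path, format: str | None = None, topology: Topology | None = None,
                    **kwargs) -> Trajectory:
    fmt = (format or Path(path).suffix.lstrip(".")).lower()
    if fmt == "xyz":
        return read_xyz(path, topology=topology, **kwargs)
    if fmt == "pdb":
        return read_pdb(path, **kwargs)
    raise ValueError(f"unsupported trajectory format {fmt!r} (xyz, pdb)")
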