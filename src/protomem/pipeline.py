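"""End-to-end orchestration: generate -> track-proton -> interface -> orient -> epot.

A RunConfig bundles the fixture specification and every stage parameter (all
defaults documented on the dataclass); it round-trips losslessly through YAML.
`run_pipeline` executes the selected stages in order, streaming over frames
within each stage, and writes plain-text outputs (TSV/JSON) plus a manifest
recording the seed, a hash of the configuration, and a checksum per output
file. Re-running with an identical config and seed reproduces every output
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import io as pio
from . import synth
from .interface import (coarse_grain_density, export_obj, export_vertex_table,
                        extract_surface)
from .electrostatics import export_profile, trajectory_potential
from .orientation import export_histogram, layer_mode_angle, orientation_histogram
from .proton import joint_probability, nearest_phosphate_distance, wire_coordinates

log = logging.getLogger("protomem")

ALL_STAGES = ("generate", "track-proton", "interface", "orient", "epot")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All pipeline parameters with their documented defaults.

    Distances in Å, angles in degrees. ``input_path`` replaces the generate
    stage with a trajectory read from disk (XYZ/PDB).
    """

    fixture: synth.FixtureSpec = field(default_factory=synth.FixtureSpec)
    stages: tuple[str, ...] = ALL_STAGES
    input_path: str | None = None
    outdir: str = "protomem_run"
    seed: int | None = None          # overrides fixture.seed when set
    # proton tracking
    assign_cutoff: float = 1.3
    hbond_oo_cutoff: float = 3.5
    hbond_angle_cutoff: float = 30.0
    bin_halfwidth: float = 0.03
    v_range: tuple[float, float] = (-1.5, 1.5)
    max_wire_length: int = 4
    # instantaneous interface
    xi: float = 2.4
    grid_spacing: float = 1.0
    isolevel_fraction: float = 0.5
    # orientation
    dcos: float = 0.05
    dz_orientation: float = 0.5
    z_range: tuple[float, float] = (-2.0, 15.0)
    layer_z_max: float = 6.0
    # electrostatics
    dz_potential: float = 0.5

    def resolved_fixture(self) -> synth.FixtureSpec:
        if self.seed is None:
            return self.fixture
        d = synth.spec_to_dict(self.fixture)
        d["seed"] = int(self.seed)
        return synth.spec_from_dict(d)


def config_to_dict(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    d["fixture"] = synth.spec_to_dict(cfg.fixture)
    d["stages"] = list(cfg.stages)
    d["v_range"] = list(cfg.v_range)
    d["z_range"] = list(cfg.z_range)
    return d


def config_from_dict(d: dict) -> RunConfig:
    d = dict(d)
    if "fixture" in d:
        d["fixture"] = synth.spec_from_dict(d["fixture"])
    for key in ("stages", "v_range", "z_range"):
        if key in d:
            d[key] = tuple(d[key])
    return RunConfig(**d)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=True))


def load_config(path) -> RunConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


def config_hash(cfg: RunConfig) -> str:
    """Hash of every parameter that influences the numbers (not the outdir)."""
    d = config_to_dict(cfg)
    d.pop("outdir", None)
    text = yaml.safe_dump(d, sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the selected stages; return the run directory.

    A failing stage raises StageError naming the stage; outputs written so far
    are retained and listed in ``manifest.json`` under ``"partial"``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = config.resolved_fixture()
    outputs: list[Path] = []
    manifest = {
        "seed": spec.seed,
        "config_sha256": config_hash(config),
        "fixture": synth.fixture_manifest(spec),
        "stages_run": [],
        "defaults_used": sorted(
            k for k, v in asdict(RunConfig()).items()
            if k not in ("fixture", "outdir") and asdict(config).get(k) == v),
    }
    stage = "generate"
    traj = None
    surfaces = None
    try:
        if config.input_path is not None:
            traj = pio.read_trajectory(config.input_path)
            log.info("loaded trajectory %s (%d frames)", config.input_path, traj.n_frames)
        elif "generate" in config.stages or traj is None:
            traj = synth.generate_trajectory(spec)
            p = outdir / "fixture.xyz"
            pio.write_xyz(traj, p)
            outputs += [p, Path(str(p) + ".roles.json")]
            manifest["stages_run"].append("generate")
            log.info("generated fixture: %d atoms, %d frames",
                     traj.topology.n_atoms, traj.n_frames)

        if "track-proton" in config.stages:
            stage = "track-proton"
            times, dists = nearest_phosphate_distance(traj, assign_cutoff=config.assign_cutoff)
            p = outdir / "nearest_phosphate_distance.tsv"
            with open(p, "w") as fh:
                fh.write("# time_fs\tdistance_A\n")
                np.savetxt(fh, np.column_stack([times, dists]), fmt="%.10g", delimiter="\t")
            outputs.append(p)
            coords = wire_coordinates(traj, assign_cutoff=config.assign_cutoff,
                                      oo_cutoff=config.hbond_oo_cutoff,
                                      angle_cutoff=config.hbond_angle_cutoff,
                                      max_length=config.max_wire_length)
            for mode in ("pair", "triple"):
                hist = joint_probability(coords, mode=mode, delta=config.bin_halfwidth,
                                         v_range=config.v_range)
                p = outdir / f"transfer_hist_{mode}.tsv"
                with open(p, "w") as fh:
                    fh.write(f"# P(v1, {'v2' if mode == 'pair' else '(v2+v3)/2'}); "
                             "rows v1 bins, columns second-axis bins\n")
                    fh.write("# centers_A\t" + "\t".join(f"{c:.4f}" for c in hist.x_centers) + "\n")
                    np.savetxt(fh, hist.probabilities, fmt="%.8g", delimiter="\t")
                meta = {"mode": mode, "n_wires": hist.n_wires, "n_dropped": hist.n_dropped,
                        "delta_A": hist.delta, "v_range_A": list(hist.v_range)}
                pj = outdir / f"transfer_hist_{mode}.json"
                pj.write_text(json.dumps(meta, indent=1, sort_keys=True))
                outputs += [p, pj]
            manifest["stages_run"].append(stage)

        if "interface" in config.stages or "orient" in config.stages:
            stage = "interface"
            surfaces = []
            for frame in traj.frames:
                fld = coarse_grain_density(frame, traj.topology, xi=config.xi,
                                           spacing=config.grid_spacing)
                surfaces.append(extract_surface(fld, isolevel_fraction=config.isolevel_fraction))
            if "interface" in config.stages:
                s0 = surfaces[0]
                export_obj(s0, outdir / "interface_frame0.obj")
                export_vertex_table(s0, outdir / "interface_frame0.tsv")
                summary = {"n_frames": len(surfaces),
                           "rho_bulk_A^-3": float(np.mean([s.rho_bulk for s in surfaces])),
                           "area_upper_A^2": s0.area(+1), "area_lower_A^2": s0.area(-1),
                           "xi_A": config.xi, "isolevel_fraction": config.isolevel_fraction}
                p = outdir / "interface_summary.json"
                p.write_text(json.dumps(summary, indent=1, sort_keys=True))
                outputs += [outdir / "interface_frame0.obj", outdir / "interface_frame0.tsv", p]
                manifest["stages_run"].append("interface")

        if "orient" in config.stages:
            stage = "orient"
            hist = orientation_histogram(traj, surfaces, dcos=config.dcos,
                                         dz=config.dz_orientation, z_range=config.z_range)
            export_histogram(hist, outdir / "orientation_histogram.tsv")
            mode = layer_mode_angle(hist, z_max=config.layer_z_max)
            summary = {"mode_angle_deg": None if mode.flat else mode.angle_deg,
                       "resolution_deg": None if mode.flat else mode.resolution_deg,
                       "flat": mode.flat, "n_layer_samples": mode.n_samples,
                       "layer_z_max_A": config.layer_z_max,
                       "rho_bulk_A^-3": hist.rho_bulk, "area_A^2": hist.area,
                       "n_frames": hist.n_frames}
            p = outdir / "orientation_summary.json"
            p.write_text(json.dumps(summary, indent=1, sort_keys=True))
            outputs += [outdir / "orientation_histogram.tsv", p]
            manifest["stages_run"].append(stage)

        if "epot" in config.stages:
            stage = "epot"
            profile = trajectory_potential(traj, dz=config.dz_potential)
            export_profile(profile, outdir / "potential_profile.tsv")
            outputs.append(outdir / "potential_profile.tsv")
            manifest["stages_run"].append(stage)
    except Exception as exc:
        manifest["partial"] = True
        manifest["checksums"] = {p.name: _sha256(p) for p in outputs if p.exists()}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise StageError(stage, exc) from exc

    manifest["checksums"] = {p.name: _sha256(p) for p in outputs}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return outdir


def write_report(outdir) -> Path:
    """Aggregate the stage summaries of a finished run into report.json."""
    outdir = Path(outdir)
    report = {}
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists():
        report["manifest"] = json.loads(manifest_path.read_text())
    for name in ("orientation_summary.json", "interface_summary.json",
                 "transfer_hist_pair.json", "transfer_hist_triple.json"):
        p = outdir / name
        if p.exists():
            report[name.removesuffix(".json")] = json.loads(p.read_text())
    p = outdir / "report.json"
    p.write_text(json.dumps(report, indent=1, sort_keys=True))
    return p
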