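# Methods

This note documents the models, conventions, numerical choices and
limitations behind each analysis stage, and what the synthetic fixtures do
and do not establish about real trajectories.

## Units and conventions

Coordinates and distances in Å, times in fs, partial charges in elementary
charges, potentials in volts; angles are degrees at the API surface and
cosines internally. Boxes are orthorhombic with per-axis periodic flags;
triclinic cells are rejected. `minimum_image_displacement(a, b)` returns
a − b with every periodic component wrapped to [−L/2, L/2) (half-open, so
the result is single-valued at exactly ±L/2). Trajectory files must carry
box metadata (extended-XYZ `Lattice="…"` comment or PDB CRYST1); a missing
box is an error rather than a silent non-periodic fallback, because every
analysis here is periodic.

Roles and charges are not representable in bare XYZ/PDB, so both writers
emit a `<file>.roles.json` sidecar. Reading a PDB without the sidecar
recovers roles from names: water residues HOH/TIP3/SOL/WAT, the excess
hydrogen as a one-atom residue `PRT`, lipid residues from a configurable set
with `O1P…O4P`/`OP1…OP4` marking phosphate oxygens.

## Hydronium and water wires

The excess proton has no persistent atomic identity under Grotthuss
transfer, so the proton locus is defined operationally per frame:

* every water/excess hydrogen is assigned to its nearest oxygen (water or
  phosphate) under minimum image, cutoff 1.3 Å, exact ties to the lower
  atom id; hydrogens with no oxygen within the cutoff are flagged, not
  dropped;
* the hydronium is the unique water oxygen with three assigned hydrogens;
  at hop midpoints (none triply coordinated) it is the water oxygen
  minimising the sum of its three shortest O–H distances, iterated in id
  order so the result is deterministic;
* for distance series, the hydronium **oxygen** position represents "the
  excess proton". Tracking the individual excess hydrogen would pin the
  series to an atom whose chemical identity is exchanged at every hop.

Hydrogen bonds use the standard water criterion — donor–acceptor O–O
≤ 3.5 Å and the donor hydrogen within 30° of the O_d→O_a axis — both
configurable, since the source analyses never state one. When several donor
hydrogens qualify, the one closest to the acceptor is the shared proton.
Wires are simple directed paths (no revisited oxygen) rooted at the
hydronium, two to four oxygens, enumerated by depth-first search with
sorted adjacency for reproducibility.

Transfer coordinates v_i = r(O_i–H) − r(O_{i+1}–H) use minimum-image
distances and are exactly antisymmetric under reversing a pair. Joint
histograms bin (v₁, v₂) over wires of ≥ 3 oxygens and (v₁, (v₂+v₃)/2) over
4-oxygen wires. Bin membership is the printed interval
v ∈ [c − Δν, c + Δν) with Δν = 0.03 Å, so bins are 0.06 Å wide with centres
at integer multiples of 0.06 Å — the origin is a bin centre, which is what
makes the concerted-transfer signature (mass exactly at (0,0)) well defined.
Default axis range ±1.5 Å; out-of-range values are dropped and counted, and
the normalisation N_f is the number of contributing wires so probabilities
sum to one. Frames at hop midpoints contribute like any other frame. Whether
N_f should count wires per frame or unique wires per trajectory is
ambiguous in the source description; the per-frame interpretation is
implemented.

## Instantaneous interface

The water-oxygen number density is coarse-grained with a periodic Gaussian
of width ξ onto a regular grid (target spacing 1 Å; the actual spacing is
L/round(L/spacing) per axis). The kernel is truncated at 4.5ξ per axis,
keeping a single molecule's integrated mass within 10⁻³ of one. ρ_bulk is
the mean field over the grid planes within 4 Å of the water slab's circular
mean z (the slab wraps the periodic boundary), with a fallback of
0.0333 Å⁻³; the interface is the ρ_bulk/2 isosurface. Defaults ξ = 2.4 Å,
spacing 1.0 Å and the half-density level follow the construction's common
water parameterisation and are configurable.

Marching cubes runs on the periodically padded grid, so the surface tiles
the box exactly once and is invariant under lattice translations of the
input. Vertex normals are the trilinearly interpolated density gradient,
normalised to point toward increasing density — into the water phase.
Vertices split into upper/lower leaflets by z relative to the membrane
midplane (the antipode of the water-slab centre); the two leaflet surfaces
are never merged, and each query finds its nearest leaflet automatically.

Nearest-point queries are exact over the whole mesh: minimum-image vertex
distances give a bound d₀, every triangle whose nearest vertex lies within
d₀ + (longest mesh edge) is tested with the exact point–triangle closest
point (Ericson's region method, vectorised), and exact distance ties
resolve to the lowest vertex/triangle index. The signed distance is
positive on the water side (sign of the displacement against the local
normal). Surfaces are per-frame; no time averaging.

## Orientation distribution

The water dipole is the geometric O→H bisector — identical in direction to
the charge-weighted dipole for a symmetric 3-site water, which is why the
bisector is used. cos θᵢ is its dot product with the interpolated normal at
the nearest surface point; Z is the signed surface distance. The histogram
weights each water by the molecular mass m = 18.01528 u and divides by
ρ_bulk(mass) · L_x L_y · n_surfaces · Δcos θ · ΔZ · n_frames, with
n_surfaces = 2 because each frame has two leaflet surfaces; m cancels in
the shape but keeps the absolute normalisation meaningful: in bulk the
cos θ-integral of P tends to one. Defaults Δcos θ = 0.05, ΔZ = 0.5 Å,
Z ∈ [−2, 15] Å.

`layer_mode_angle` summarises the layer Z < 6 Å (the "first two layers").
Two details matter. Flatness is decided by a chi-square uniformity test on
the cos θ marginal (p > 0.01 → no defined mode, NaN): an isotropic layer has
equal expected counts per cos bin, and a peak-to-mean ratio is too fragile
at realistic counts. For a non-flat layer the mode is computed on the
**angular density**: equal-width cos θ bins span very different amounts of
angle (the bin touching 180° covers ~18°, a bin at 90° under 3°), so the
raw maximum-count bin is biased toward 0°/180°; dividing each count by its
bin's angular width removes that Jacobian bias, and the mode is the
maximum-density bin's angular midpoint with the bin half-width as the
quoted resolution.

End-to-end, the pipeline recovers a 150° injected interfacial mode to
within ~4–5°: the residual pull toward 90° is physical measurement blur —
the instantaneous surface is rough, its local normals tilt ~10–15° from the
slab normal, and projecting a fixed tilt onto a wobbling normal
systematically shrinks the measured angle.

## Electrostatic potential profile

ρ_q(z) bins point charges by nearest z-bin (no Gaussian spreading) after
recentring each frame on the lipid centre of mass, averaging over frames
and dividing by the bin volume. Two numerical choices proved essential:

* **Molecules are made whole before binning.** A water straddling the
  periodic z-boundary would otherwise split into opposite-sign monopoles at
  the two box edges; the double integral turns that into a spurious uniform
  field across the whole box.
* **The double integration is exact for the binned density.** The field is
  cumulated to bin *edges* (piecewise-constant ρ), and the resulting
  piecewise-linear E is integrated exactly to φ. Trapezoidal integration on
  bin centres leaks an O(h) net field even for an exactly charge-neutral
  histogram, which tilts φ by several volts over a 70 Å box and destroys
  the profile's symmetry.

E is anchored to zero at the lower box edge — bulk water, mid-slab for
these systems — and φ(0) = 0 at the bilayer centre; for a neutral,
z-symmetric bilayer this also yields E(0) = 0. This convention reproduces
the parallel-plate closed form (φ linear between the sheets at slope σ/ε₀,
constant outside). The excess proton is excluded, matching the
charge-neutral classical boxes the profile emulates. Default Δz = 0.5 Å.

## Synthetic fixtures: what they emulate

The generator produces the study geometries, not their physics. Lipids are
coarse pseudo-atom stacks with the correct per-species atom counts
(DPhPC C₄₈H₉₆NO₈P = 154 atoms, DOPC C₄₄H₈₄NO₈P = 138) and a zwitterionic
headgroup layering: choline N (+1 e) just outside the phosphate plane at
±(z_head + 1 Å), four phosphate oxygens (−0.5 e each) on ±z_head, the
phosphorus (+1 e) just beneath, neutral tails stacked toward the midplane.
That +/−/+ layering gives each leaflet the dipole that shapes φ(z),
including the local extremum at the headgroups; its magnitude is set by
these coarse charges and is not calibrated to an experimental dipole
potential. Defaults: z_head = 17.5 Å, water charges O −0.834/H +0.417 e
(TIP3P-like, rigid geometry O–H 0.9572 Å, 104.52°), excess hydrogen +1 e,
so the net charge is +1 e with a proton and 0 without.

Waters fill the slab outside the membrane (1.5 Å clearance from the
headgroup planes) by batch rejection sampling with a hard 2.0 Å O–O core.
Interfacial waters — within 6 Å of a headgroup plane — draw their dipole
tilt to the outward plane normal from a wrapped normal centred on 150° with
concentration κ = 16 (σ ≈ 14°, a realistic interfacial breadth); bulk
waters are uniform on the sphere. Each frame re-draws water positions and
orientations and adds i.i.d. Gaussian jitter (σ = 0.05 Å) plus a rigid
per-lipid z-displacement (σ = 0.5 Å, protrusion-like). Frames therefore
model statistically independent snapshots of a diffusive liquid rather
than continuous dynamics: position resampling is what lets frame averaging
actually reduce the quenched Poisson noise of the water structure in
φ(z), and the lipid z-motion smears the headgroup charge sheets across
bins as thermal membranes do. The cost is that nothing time-dependent
(diffusion constants, residence times, surface relaxation) can be studied
on these fixtures, and passing tests say nothing about such observables.

Scripted relays bypass dynamics entirely: chain oxygens sit 2.5 Å apart
anchored 2.5 Å above a phosphate oxygen, each interior water donates one
hydrogen along the chain, and each hop linearly interpolates the shared
proton from 1.0 Å off the donor to 1.0 Å off the acceptor across an 11-frame
window, crossing the midpoint at the centre frame — so v sweeps −0.5 → +0.5
Å through zero by construction. Concerted events move the shared protons of
up to three consecutive bonds in one window. Hop windows that overlap on a
shared oxygen are rejected. Chain atoms and mobile protons are exempt from
jitter so the scripted invariants (exactly one triply-coordinated oxygen
off-midpoint, monotone v) hold exactly.

What passing tests on these fixtures show: the *analysis* is correct —
assignment, graph enumeration, coordinates, histogram normalisation,
surface geometry, orientation recovery and electrostatics integration all
reproduce ground truths that are known by construction or by independent
oracle. What they do not show: anything about real interfacial proton
kinetics, hydrogen-bond populations, or surface fluctuation spectra, which
require actual trajectories.

## Pipeline and determinism

`RunConfig` carries every stage parameter with its documented default and
round-trips losslessly through YAML. `run_pipeline` executes
generate → track-proton → interface → orient → epot (as selected),
streaming over frames within each stage, and writes TSV/JSON outputs plus a
manifest with the seed, a hash of all numerical parameters (the output
directory is excluded from the hash), the scripted hop table, and a SHA-256
checksum per output file. All randomness flows from one `numpy` Generator
seeded by the fixture seed, and all output formatting uses fixed precision,
so identical config and seed give bit-identical outputs. A failing stage
raises an error naming the stage; partial outputs are kept and marked in
the manifest.

Problem sizes used by the validation suite and the reproduction script —
e.g. 500 waters × 50 frames for orientation recovery, 64 frames for
potential profiles, 1000 random geometries for the transfer-coordinate
oracle — were chosen as the smallest sets at which the recovered quantities
are stable against the seed, and run in well under an hour on one CPU.

## Known limitations

* Orthorhombic boxes only; no velocities/forces; XYZ/PDB only (no binary
  trajectory formats).
* The hydronium definition is geometric; Eigen/Zundel classification and
  nuclear quantum effects are out of scope.
* The orientation normalisation assumes two leaflet surfaces of lateral
  area L_x L_y each; strongly overhanging (multivalued) interfaces would
  need a true surface-area measure.
* φ(z) is a slab double integral, not an Ewald-consistent 3D potential;
  dielectric profiles and tin-foil corrections are out of scope.
* The generator's lipids have no realistic conformations; only phosphate
  positions, charges and excluded volume are meaningful.
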