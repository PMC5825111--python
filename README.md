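# protomem

Analysis toolkit for an excess proton at phosphatidylcholine membrane/water
interfaces: hydronium tracking and water-wire proton-transfer statistics,
water orientation relative to the Willard–Chandler instantaneous interface,
proton–phosphate distance series, and the z-resolved electrostatic potential
profile — together with a seeded synthetic-trajectory generator that makes
every stage testable end to end.

It is written for people studying interfacial proton transport in molecular
simulations (ab initio or classical) who need the *analysis layer*: given
frames of Cartesian coordinates with a periodic box and a topology labelling
atoms by role (water O/H, phosphate O, other lipid atoms, the excess
hydrogen), it computes the quantities below. It is not an MD engine.

## The quantities it computes

**Proton-transfer coordinates and joint probabilities.** Every hydrogen is
assigned to its nearest oxygen; the hydronium is the water oxygen carrying
three hydrogens (with a sum-of-distances fallback at hop midpoints). Water
wires are simple directed paths in the hydrogen-bond graph rooted at the
hydronium oxygen, O(1)…O(k), k ≤ 4. For each consecutive pair the transfer
coordinate of the shared proton H is

    v_i = r_O(i)–H − r_O(i+1)–H ,

zero when the proton sits midway. The joint probabilities P(v₁, v₂) and
P(v₁, (v₂+v₃)/2) are accumulated over all wires in all frames with bin
half-width Δν = 0.03 Å and normalised by the wire count N_f, so simultaneous
midpoint crossings of consecutive bonds — concerted transfer — show up as
probability at the origin.

**Instantaneous interface.** The water-oxygen density is Gaussian
coarse-grained (ξ = 2.4 Å) on a periodic grid; the interface is the
ρ_bulk/2 isosurface, triangulated by marching cubes each frame, with normals
pointing from the membrane into the water.

**Water orientation.** For water i, θᵢ is the angle between its dipole
(O→H bisector) and the interface normal at the nearest surface point, and
zᵢ its signed distance to the surface:

    P(cos θ, Z) = ⟨Σᵢ m δ(cos θᵢ − cos θ) δ(zᵢ − Z)⟩ / (ρ_bulk L²) ,

normalised so the bulk plateau integrates to one over cos θ. With the
into-water normal convention, an interfacial mode near 150° means the
hydrogens point toward the membrane.

**Electrostatic potential profile.** The laterally averaged charge density
ρ_q(z) (molecules kept whole, lipid centre of mass at z = 0, the excess
proton excluded) is integrated twice, exactly for the binned density, to
E(z) and φ(z) in volts, with E anchored to zero in bulk water and φ(0) = 0
at the bilayer centre.

**Synthetic fixtures.** `protomem.synth` builds bilayer-slab systems with the
study compositions (10 DPhPC + 418 waters + 1 H⁺, 2,795 atoms, in
19.7 × 19.7 × 70.6 Å; 10 DOPC + 358 waters + 1 H⁺, 2,455 atoms, in
19.1 × 19.1 × 69.8 Å), imposed interfacial dipole tilts, and scripted
Grotthuss-like relays including concerted multi-bond hops — all
deterministic under a seed.

## Worked example

```bash
python examples/02_proton_relay.py
```

prints

```
77 frames; proton-to-phosphate distance: start 2.5 A -> far branch 10.0 A -> end 2.5 A
wires analysed: pair mode N_f = 154, triple mode N_f = 57
P(v1=0, (v2+v3)/2=0) = 0.0175
```

The scripted proton starts 2.5 Å from a phosphate oxygen (the bound branch,
< 3 Å), shuttles out along a 4-water wire to 10 Å (the interfacial branch,
> 6 Å), and returns in one concerted jump over three hydrogen bonds. That
concerted event is what puts the 0.0175 probability at the origin of the
P(v₁, (v₂+v₃)/2) histogram — with only sequential hops that bin stays empty.
The other examples cover composition/IO round trips
(`01_compose_and_io.py`), interface construction and orientation recovery
(`03_interface_orientation.py`, mode 145.7° for an injected 150° field), and
the potential profile of both lipid species (`04_potential_profile.py`).

A thin CLI wraps the same pipeline:

```bash
protomem run --seed 1 --outdir run1       # generate → track-proton → interface → orient → epot
protomem write-config defaults.yaml       # every parameter with its default
```

Outputs are plain TSV/JSON plus a manifest with per-file checksums;
identical config and seed reproduce every output bit-identically.

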