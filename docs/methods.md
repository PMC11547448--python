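# Methods

## The physical picture

A cation⊗3π complex is one alkali cation (Li⁺, Na⁺, K⁺) held inside a
triangular arrangement (◬) of three aromatic rings — the idealised
"aromatic box" motif found around cationic moieties in proteins.  Its
stability is quantified by the **one-benzene-binding (OBB) energy**: the
energy required to pull one benzene, together with the *n* water molecules
hydrating it, out of the full complex,

```
E_binding[(M⁺-mW)⊗3Bz-3nW] = E(full) − E(reduced) − E(Bz) − n·E(W)
```

where *full* is the (M⁺-mW)⊗3Bz-3nW complex, *reduced* the
(M⁺-mW)⊗2Bz-2nW complex, and E(Bz), E(W) are monomer energies.  Hydration
is modelled at three canonical sites: **coordinated** (m = 2 waters on the
cation), **hollow** (one water above each ring centroid, outer face) and
**bridge** (waters above ring C–C bond midpoints); the combined pattern
(m = 2 and n = 3 per ring) stacks all three.

## Five-component decomposition

The OBB energy is decomposed into supermolecular components, each a
3-ring-minus-2-ring difference of subsystem totals at frozen geometry:

| component | meaning | definition |
|---|---|---|
| E_M⁺-π | cation–π | [E(M⁺⊗3Bz)−E(M⁺)−E(3Bz)] − [E(M⁺⊗2Bz)−E(M⁺)−E(2Bz)] |
| E_π-π | π–π | [E(3Bz)−3E(Bz)] − [E(2Bz)−2E(Bz)] |
| E_W-π | water–π | [E(mW⊗3Bz-3nW)−E(3Bz)−E(mW-3nW)] − (2-ring analogue) |
| E_W-W | water–water | [E(mW-3nW)−(m+3n)E(W)] − (2-ring analogue) |
| E_W-M⁺ | water–cation | [E(M⁺-mW-3nW)−E(mW-3nW)−E(M⁺)] − (2-ring analogue) |

E_Sum is assembled exactly as the sum of the five floats.  The engine
enumerates the minimal subsystem set automatically: 15 distinct labeled
subsystems in the general m, n > 0 case, merging degenerate compositions
(6 labels at m = n = 0).  Labels are an ASCII rendering of the complex
notation; the grammar is

```
[<cat>+[<m>W]@]<N>Bz[-<w>W]     subsystems containing benzenes
<cat>+[-<m>W][-<w>W]            cation + waters
<m>W-<w>W | <k>W | W            waters only
Bz, W, <cat>+                   monomers
```

with `<cat>` ∈ {Li, Na, K}, `<m>` coordinated waters, `<w>` total
benzene-side waters (e.g. `Na+2W@3Bz-9W`, `2W-9W`, `Na+-2W-9W`).  A
`~opt` suffix (below) marks the separately optimised reference geometry.

### Telescoping and why E_Sum can miss E_binding

For an energy function that is a strict sum of fragment-pair terms, with
all monomer energies zero and every subsystem cut from one frozen
geometry, the five components add up to the OBB energy **exactly** —
every pair term appears once on each side of the identity.  The
decomposition becomes a "rough estimate" through exactly two mechanisms,
both represented here as explicit switches:

1. **Many-body energy.**  Polarization, three-body dispersion and, in ab
   initio totals, electron correlation are not pairwise.  The surrogate's
   `polarization_strength` dials this in continuously (see below).
2. **A relaxed reference.**  The study convention optimises the
   two-benzene complex separately, while the component subsystems stay on
   the frozen scaffold.  With a `relaxed_reduced` complex attached, *only*
   the E(reduced) term of the OBB formula switches to that geometry
   (subsystem label suffixed `~opt`); the components do not.  A
   lower-energy reference then makes E_binding less negative while E_Sum
   is unchanged — the component sum overestimates the binding strength.
   Using the relaxed geometry for *all* 2-ring subsystems would restore
   the telescoping identically for any pairwise backend (the algebra does
   not care which geometry it telescopes over), which is why the mixed
   convention is the default meaning of "relaxed" here.

## Energy backends

**Tabulated.**  A pure label → energy lookup (CSV
`label,energy_kcal_mol` or a JSON object) for externally computed
subsystem totals, e.g. correlated ab initio energies.  No numeric
transformation is applied; unknown labels fail with near-match hints.

**Surrogate potential.**  A classical stand-in that makes every identity
testable at desk scale:

* Coulomb term over inter-fragment atom pairs, constant pinned at
  k = 332.0637 kcal·Å/(mol·e²); default charges: benzene C −0.115 e /
  H +0.115 e (a quadrupole-bearing 12-site ring), water O −0.834 e /
  H +0.417 e, cation +1 e.
* 12-6 repulsion–dispersion with Lorentz–Berthelot combination.
  Defaults (ε kcal/mol, σ Å): C (0.070, 3.55), benzene H (0.030, 2.42),
  O (0.152, 3.151), water H (0, 0), Li (0.018, 1.80), Na (0.0874, 2.43),
  K (0.100, 3.14).  These are calibration choices for a plausible energy
  scale, not fitted values.
* Intra-fragment energy is defined as zero (rigid fragments), so every
  monomer energy is exactly 0.  Ab initio totals behave differently —
  tabulated workflows must supply true monomer energies.
* **Polarization (many-body switch).**  Each non-cation fragment carries
  an isotropic responder at its |q|-weighted charge centroid; a subsystem
  gains −½·α·k·|F|² per fragment, where F is the summed field of all
  other selected fragments at that point and α = `polarization_strength`
  (Å³-like units, default 0).  Because the gain is quadratic in a sum of
  per-source fields, its cross terms couple fragment triples: the energy
  is genuinely non-pairwise, the additivity identity breaks by an amount
  linear in α, and for a {cation, one fragment} subsystem the term
  reduces to the plain cation-field expression.

## Geometry conventions

Å everywhere; right-handed frame, cation at the origin, C3 axis = +z,
ring centroids in the xy-plane with normals through the cation (tilt 0)
so each ring's outer face points radially outward.  Benzene is a rigid
regular hexagon, r(C–C) = 1.397 Å, r(C–H) = 1.087 Å; water is rigid with
r(O–H) = 0.9572 Å and ∠HOH = 104.52°.  Default cation–centroid distances:
Li 2.5, Na 2.6, K 2.9 Å (three-ring values; the two-ring distances
1.9/2.4/3.0 Å ship in `centroid_distances.csv`).

Hydration defaults: coordinated O–M⁺ at 1.9 (Li), 2.3 (Na), 2.7 (K) Å,
hollow O 3.2 Å above the centroid with one O–H aimed at the ring, bridge
O 3.3 Å above a C–C midpoint.  Two placement choices are this package's
own: (i) the two coordinated waters go **axially through the two open
ends of the box** (±z) — on the Li scale any same-side placement puts a
water either <2 Å from another water or <2 Å from ring atoms, and
M⁺(H₂O)₂ is near-linear for these cations anyway; (ii) in the combined
n = 3 pattern the hollow water is lifted to 5.4 Å (a second-shell
position above the bridge pair), because its single-site default would
sit 1.2 Å from the bridge oxygens.  All heights and distances are free
parameters of `add_hydration`.

Adding hydration never moves existing atoms (frozen scaffold).  The
removed benzene of a pair defaults to the ring with the largest centroid
z, ties broken toward the lowest fragment index — in the equatorial
convention all three tie, so ring 1 is removed.

## Synthetic data: what it emulates and what it does not

`gen_complex_suite` reproduces the study inventory — 3 cations × 4
hydration patterns, each with its frozen two-benzene reduction.
`gen_energy_table` fills all decomposition labels with surrogate
energies; `many_body_scale` sets α, so scale 0 yields tables that are
exactly pairwise-consistent.  `gen_trajectory` moves a cation around the
three fixed rings of the box: the first round(bound_fraction·n_frames)
frames are sampled (rejection, cap 5000 tries) so all three shortest
cation–ring distances fall in the closed band [2.5, 3.5] Å; the rest are
displaced 8 Å out through the box opening and must put at least one ring
beyond 4.5 Å (a deliberately arbitrary margin past the band edge).
Default conditions: 200 frames, 0.05 ps apart, cation jitter 0.15 Å per
coordinate.

The generator is deterministic: geometry depends only on the spec,
trajectories on the seed (one top-level seed; per-artifact streams via
fixed offsets), and repeated runs write byte-identical files.  It does
**not** emulate correlated ab initio energetics, water–water hydrogen-bond
networks, ring flexibility, or solvent molecules in the trajectory.
Passing the closed-loop tests therefore shows the *bookkeeping* —
enumeration, decomposition algebra, distance/occupancy analysis — is
correct, not that the surrogate reproduces real solvation energetics;
quantitative statements about real systems enter through the tabulated
backend and the shipped study tables.

## Numerical choices

* Printed-table tolerance 0.02 kcal/mol (two-decimal rounding); several
  shipped rows re-sum 0.01 off their printed totals and are treated as
  rounding, not logic.
* Telescoping asserted to 1e-8 kcal/mol (observed ≈ 1e-13 at the suite's
  O(10) kcal/mol energy scale).
* Consistency flag threshold |E_Sum − E_binding| > 2.0 kcal/mol marks the
  decomposition as a rough estimate.
* Occupancy uses a closed band on both ends and requires all three rings
  by default (the ◬ criterion); both are parameters because the band's
  interval closure and the all-rings rule are conventions, not data.
* Rigid scans break energy ties toward the smaller distance.
* Sign classification of SAPT shifts is strict: Δ = 0 counts as "mixed",
  never as unanimous.
* Fixture CSVs are verified by SHA-256 at load time.

## Known limitations

* The surrogate's fixed charges cannot reproduce cation-size trends in
  cation–π energies quantitatively (no charge penetration, no real
  polarizability tensor); it exists to make identities testable.
* One SAPT-table sentence in the source material defines E_elst with the
  wording that belongs to E_disp (electron correlation between monomers);
  this is reproduced nowhere — the standard component meanings are used —
  but flagged here rather than silently "corrected" in the data.
* The combined (n = 3) hydration arrangement is under-determined by the
  study tables; geometry-level checks skip it and only its energies are
  used.
* No basis-set-superposition / counterpoise handling anywhere, matching
  the study setup; no geometry optimisation against quantum-chemistry
  engines.
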