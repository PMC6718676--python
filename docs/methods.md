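# Methods

This note records the models, conventions, and numerical choices behind
`lipswitch`, and what the synthetic-data generators do and do not emulate.

## Coordinate and data conventions

Coordinates are in Å, trajectory time in ps (reported in ns), assay time in
s. Frames are 0-indexed; residues are 1-based (PDB convention). The
trajectory interchange format is multi-model PDB with two chains, `P`
(protein) and `M` (membrane); leaflet membership is stored explicitly in the
B-factor column (0 none, 1 upper, 2 lower) or a sidecar TSV, never inferred
at read time, so I/O is deterministic. Binary trajectory formats and
topology formats are out of scope. The in-memory container is a biotite
`AtomArrayStack`; synthetic trajectories keep float64 coordinates internally
because the noiseless-recovery guarantees are tighter than float32
resolution, while files round-trip at the PDB's 3-decimal precision.

## Membrane reference plane and docking metrics

The reference plane is the arithmetic mean z of upper-leaflet headgroup
nitrogens (atoms named `N`). All vertical metrics are *signed* distances to
this plane:

- **h** — z of the protein centre of mass minus the plane. Residue and
  protein COMs use unit masses by default, because the pseudo-atom fixtures
  carry no meaningful elements; a mass table inferred from atom names
  (first alphabetic character → standard atomic mass) can be supplied for
  real structures.
- **h_entry** — z of the mass centre of all atoms of the three pocket-entry
  residues (default 129, 185, 190) minus the plane.
- **θ** — the angle between the orientation segment (default residues
  346–356) and the membrane plane, folded into [0°, 90°]. The segment axis
  is the first principal component of the segment's Cα positions, which is
  robust to jitter; an endpoint-vector axis is provided as a cross-check.
  The sign is fixed toward increasing residue number (irrelevant after
  folding). An `angle_ref` flag switches the report to the membrane-normal
  convention (complementary to 90°); the plane convention is the default
  because that is how docking orientation plots are usually read.

**Contact fractions.** A residue contacts the membrane in a frame iff the
signed z-distance of its COM to the plane is strictly below the threshold
(default 5 Å). Using the signed distance means residues inserted below the
headgroup plane always count as contacts, which is the intended reading for
inserted loops; whether an absolute-distance rule was meant is genuinely
ambiguous, and the signed choice is the package's. The strict `<` makes a
residue sitting exactly at the threshold a non-contact.

**RMSD/RMSF.** Superposed RMSD uses the optimal least-squares rigid fit
(Kabsch, via `scipy.spatial.transform.Rotation.align_vectors`). RMSF
superposes every frame onto the time-average (computed after an initial
superposition onto frame 0, then refined once) and reports the per-residue
root of the atom-averaged mean-square deviation.

## Interaction energies

Both the Coulomb and Lennard-Jones terms are multiplied by the same
potential switch S(x) = 1 − 3x² + 2x³, x = (r − r_on)/(r_off − r_on), full
below r_on = 10 Å and zero beyond r_off = 12 Å. S is C¹-continuous at both
edges; the cubic potential switch was chosen over a force switch for
simplicity, and the window is configurable for sensitivity checks. Coulomb
uses the CHARMM constant 332.0636 kcal·Å·mol⁻¹·e⁻²; LJ uses
4ε[(σ/r)¹² − (σ/r)⁶] with arithmetic-σ / geometric-ε combining. The
per-frame sum enumerates all cross pairs inside the cutoff and is bit-equal
to the brute-force double loop (tested against one).

This is a desk-scale surrogate for a force-field energy rerun: it is
non-periodic and has no mesh-Ewald reciprocal-space term, so absolute
magnitudes are not comparable to energies computed on a periodic, solvated
system; the module is meant for relative comparisons between poses and for
testing the switching machinery itself.

## Accessible surface area

Shrake–Rupley with golden-spiral (deterministic, seed-free) sphere sampling,
default 960 points per atom, probe radius 1.5 Å. A sample point on the
expanded sphere of atom *i* is accessible when outside every other expanded
sphere; per-atom ASA is the accessible fraction of 4π(rᵢ + probe)². Radii
default to a standard element-keyed VdW set (C 1.70, N 1.55, O 1.52, S/P
1.80, H 1.20); they are configurable and no attempt is made to reproduce any
specific program's radius table bit-wise. ΔASA between a full and a
truncated structure (atoms only removed) is ASA(truncated) − ASA(full) per
shared residue, hence ≥ 0; convergence with point density and the
two-sphere spherical-cap closed form are both tested.

## Assay quantification

Calibration anchors: F₀ (pre-protein baseline), F_max (full-transfer or
fully-bound reference), F_min (buffer-only). The accessible ligand
concentration is total lipid × ligand mole fraction × accessible fraction;
the accessible fraction defaults to 0.5 (outer leaflet of a large
unilamellar vesicle), which reproduces both standard compositions
(200 µM × 5% → 5 µM; 80 µM × 2% → 0.8 µM). Extraction percentage and
100·F_Norm are exact complements, a tested identity.

The initial transport rate is the OLS slope (intercept free, to absorb
injection artifacts) of delivered(t) over the first 8 samples strictly after
protein injection; with the default 0.5 s sampling these span 4 s, and the
fit window is validated against `fit_span`. The per-protein rate divides by
the *total* protein concentration — no soluble-fraction correction — and
multiplies by 60 to give lipids·min⁻¹·protein⁻¹. Because the exponential
bends within the finite window, the OLS slope underestimates
accessible × k (by ~11% at k = 0.05 s⁻¹ with the default window); the tests
compute that correction in closed form rather than treating it as error.
The rate-constant fit holds F₀/F_max fixed at their calibrated values and
fits k alone by nonlinear least squares, with a half-rise initial guess.
Dissociation traces are min–max normalized over their own range, since only
the relative decay is defined for them.

## Synthetic generators

All generators are pure functions of (inputs, seed).

- **Bilayer**: headgroup-only pseudo-lipids — one `N` atom each — because
  every in-scope metric uses only headgroup nitrogens; tails would add cost
  without information. Two jittered square lattices at ±separation/2
  (default 38 Å, a typical fluid PC headgroup-to-headgroup distance; no
  metric depends on it beyond sign conventions). Anionic lipids (default
  30%, charge −1) are placed by half-up rounding of the bilayer total (tie
  toward the anionic species), the odd lipid going to the upper leaflet,
  and sites chosen uniformly per leaflet. The counterion count is the
  magnitude of the total anionic charge — a count, not particles. A
  minimum-spacing check (default 6 Å) rejects overcrowded patches.
- **Docking trajectories**: the protein is rigid; each frame it is rotated
  so the segment axis makes the scheduled angle with the plane (Rodrigues
  rotation from the reference axis) and translated so the COM sits the
  scheduled height above the *realized* plane, then i.i.d. Gaussian noise is
  added to every coordinate. Ground truth records the noiseless heights,
  angles, and per-residue contact indicators. Because the noise is
  isotropic and per-atom, contact-fraction recovery tolerances follow from
  binomial statistics with an exactly normal distance error — this is what
  makes the noisy-recovery test sharp. The default approach preset starts
  54 Å above the plane (a protein placed "in solution") and docks over the
  first 60% of the run; real approach kinetics are not modelled, and
  recovery tests use their own schedules.
- **Transport traces**: flat at F₀ until the injection time, then a
  single-exponential rise to F_max plus additive Gaussian noise.
- **Sequences**: uniform random 20-letter sequences, rejection-checked to be
  motif-free; the planted fraction receives the motif at a recorded
  position, re-drawn until it is the unique occurrence.

The pseudo-protein is a compact random Cα cloud (residues 36–434 by
default, an ORD-sized construct without its low-complexity N-terminus) whose
orientation-segment residues lie on an exact straight line with a 1.5 Å
helix-like rise, so the segment axis — and hence the scheduled angle — is
exact. With `atoms_per_residue > 1` each residue is a rigid cluster with its
first atom at the residue centre.

**What passing tests do and do not show.** The generators provide exact,
controllable ground truth, which validates the estimators' algebra, sign
conventions, and statistical behaviour. They do not emulate internal protein
dynamics, membrane undulations, correlated noise, lipid diffusion, or
photobleaching/drift in traces; agreement on synthetic data therefore
validates the analysis machinery, not any claim about a particular real
system.

## Problem sizes

Defaults were chosen so every analysis is interactive on one CPU: test
bilayers of 100 lipids (the full 1000-lipid patch is built where the
counterion count is the point), recovery trajectories of 20–400 frames, one
full 5000-frame (500 ns at 100 ps) run to exercise the sampling contract,
600-point kinetic traces with 100-seed Monte-Carlo recovery, and 50×50-atom
systems for the energy oracle. These sizes are the package's own test
conditions, not statements about real production analyses.

## Known limitations

- The energy module's absolute values are not comparable to periodic
  mesh-Ewald reruns (see above).
- Only literal motifs with a single-character wildcard are supported; full
  Prosite grammar, multiple alignment, and evolution-rate scoring are out
  of scope, and historical database-dependent sequence counts are not
  reproducible by construction.
- The contact rule's signed-distance reading and the unit-mass residue COM
  default are package choices where the field's usage varies; both are
  overridable.
- ASA ignores nothing about hydrogens per se — they are occluders like any
  atom if present — but default radii are generic, not a specific program's
  set.
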