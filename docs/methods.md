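# Methods

This note records the models, conventions and numerical choices behind
`npflip`, what the synthetic-configuration generator does and does not
emulate, and the design decisions taken where more than one reasonable
choice existed.

## System model and conventions

Units are nm for lengths, ns for times and kcal/mol for energies
throughout; the one exception is the harmonic bias spring constant, which
is stored in kJ/mol/nm² — the unit in which MD pull codes print it — and
converted on output (1 kcal = 4.184 kJ).

The bilayer normal is z. The "upper" leaflet is at positive z and holds
all 29 charged end groups in the initial 29+/0− state, matching the
n+/m− nomenclature. Boxes are orthorhombic; x and y are periodic
(minimum-image for all raw pair distances, wrap on output), z is treated
as non-periodic for quantities tied to the bilayer normal (d_z,
cylindrical density maps).

Atoms carry a *role* from a closed vocabulary (gold, thiol S, MUS/OT
backbone C, sulfonate S/O, choline N, phosphate P, lipid tail, water O,
Na⁺, Cl⁻). Every analysis consumes positions + roles only, so coordinate
files need no chemistry beyond a role sidecar.

### Nanoparticle builder

The 2 nm core is a rigid sphere represented by 92 surface beads; the
published mass redistribution of the hollow core affects dynamics only
and is not represented. Graft points for the 58 ligands come from a
deterministic Fibonacci (golden-angle) sphere lattice — the true
grafting pattern of thiol monolayers is not known in this detail, and
the lattice is reproducible and quasi-uniform (nearest-neighbor spacing
varies by well under 30 %).
MUS/OT identities are a seeded shuffle at the configured 1:1 ratio.
Backbones are extended chains along the graft direction at 0.127 nm C–C
spacing; MUS terminates in a sulfonate (S plus an O tripod at 0.149 nm).
58 ligands on a 2 nm core give the published grafting density
58/(4π·1²) = 4.62 ligands/nm². Net charge is −1 e per MUS; Na⁺/Cl⁻
counts follow the mole-fraction formula round(c·N_water/55.5 M) for Cl⁻
plus counter-ions for Na⁺. The published composition (21,418 waters,
150 mM) prints 60 Cl⁻ where the formula gives 58 — whether a
box-volume-based formula was used is not recoverable — so the Cl⁻ count
is overridable and defaults to the printed 60, giving 89 Na⁺.

### Bilayer model

Lipids are reduced to four beads (choline N, phosphate P, two tail
beads) on a square lattice at the configured area per lipid
(0.65 nm²/lipid), with phosphate planes at ±1.9 nm. The midplane is the
midpoint of the two leaflets' mean phosphate z; users who prefer a
tail-bead-based estimator can compute one from the same Frame. When an
NP is embedded, a cylindrical gap is left in any leaflet whose head
plane overlaps the NP volume, so leaflet counts may differ.

## Synthetic-configuration generator

The generator stands in for equilibrated MD configurations. It
reproduces the *statistical* structure the analyses assume, not the
chemistry:

* **Distribution** — n_plus/n_minus charged end groups above/below the
  midplane, recoverable exactly by the classifier whenever the jitter is
  small against the placement offsets.
* **Depth law** — the NP core sits at depth_max·(14 − n_minus)/14 above
  the midplane, linear by construction (the observed core-height trend
  is approximately linear). depth_max defaults to 1.0 nm; the plotted
  axis values are not tabulated, so the default is an order-of-magnitude
  emulation, chosen once.
* **Hydration gradient** — each sulfonate carries a water shell of
  round(hydration_floor + hydration_slope·|d_z|) molecules (defaults 2
  and 4/nm), so coordination numbers grow with distance from the
  midplane as in the real system. Regressing measured coordination
  against |d_z| recovers the slope within 15 % at 50 frames.

Placement choices serve measurability. End groups occupy a 1.1-nm-spaced
lateral grid around the NP axis, each at a per-ligand target |d_z| drawn
once (deterministically per seed) from (0.1, 1.0) × the head-plane
offset — a spread of depths is required for the hydration gradient to be
measurable at all. Hydration waters sit at 0.45 × the coordination
cutoff from their sulfur: at this spacing and radius, neighbouring
shells stay outside each other's cutoff, so each end group's
coordination counts exactly its own shell. Lipids are excluded from a
cylinder one margin beyond the end-group grid, and ions are placed in
the bulk slabs beyond the head planes, for the same reason. Shell sizes
are computed from the placement target rather than the jittered
position, so a trajectory at fixed distribution has a constant atom
count.

All randomness is truncated-Gaussian jitter (clipped at 3σ, default
σ = 0.05 nm) applied on top of deterministic placements; static
placements derive from the seed alone and jitter from (seed,
frame_index), so σ = 0 yields bit-identical frames and any (seed, index)
pair is exactly reproducible.

**What the generator does not emulate:** lipid conformations, bilayer
curvature and thinning, water structure beyond the end-group shells,
sulfonate–choline contact statistics (end groups are deliberately kept
laterally clear of lipids), SASA trends along the pathway (backbones do
not reorganize), and any dynamics. Passing tests therefore demonstrate
the correctness of the *operations* — classification, selection,
counting, quadrature, binning, error estimation — on inputs with known
ground truth, not the reproduction of MD-derived observables, which
require the original trajectories.

## Flip state machine

d_z uses the mass-weighted center of the sulfonate S + 3 O.
Classification uses the strict sign of the per-ligand mean over the
supplied frames; an exact zero raises rather than silently assigning a
side. Selection takes the smallest positive mean d_z; ties break to the
smallest ligand id — an arbitrary but deterministic, logged rule. The sampling window behind the mean is a frame-count parameter
of the generator — the 20 ns equilibration and 50/120 ns production
windows of the original workflow are recorded as schedule metadata, not
simulated. Bias schedules default to k = 3000 kJ/mol/nm², 1.5 ns pull,
20 ns equilibration, target −d_z, and serialize to key=value restraint
descriptors.

## SASA

Shrake–Rupley sphere quadrature rather than the exact analytic
(Eisenhaber) method: the observable is identical and the quadrature
error is controlled and testable (isolated-sphere and two-sphere
closed forms agree to < 1 % at the default 960 points; totals move by
< 0.5 % on quadrupling the point count). Quadrature points come from a
deterministic golden-section spiral — no RNG anywhere in the SASA path.
Neighbor search uses a k-d tree with a conservative cutoff and is
verified identical to the all-pairs scan. Occluders are all atoms except
waters and ions (the solvent defines the probe, it does not occlude);
this set is configurable. Boxes are treated as non-periodic here since
the built systems keep the NP far from the walls. The van der Waals
radii are a single documented default set (C 0.17, S 0.18, O 0.152,
N 0.155, P 0.18, Au 0.166 nm, plus ionic radii so every role is
covered), overridable in configuration, since different SASA tools ship
slightly different radii tables. The default probe is 0.14 nm and
γ = 4.7 kcal/mol/nm².

## Structural statistics

RDFs use minimum-image histograms normalized by the ideal-gas
expectation at the partner species' number density; the first minimum is
read from a centered moving average (default window 3 bins) as the first
local minimum after the first maximum. Contact counting (sulfonate
S–choline N < 0.7 nm) and coordination numbers reuse the same
minimum-image machinery; the per-species coordination cutoffs should
come from each species' RDF first minimum, but as tabulated per-species
values are not available, every polar role defaults to
0.7 nm and is overridable in configuration — users are explicitly warned
this is a placeholder. Whether Cl⁻ or carbonyl oxygens belong in the
polar inventory is likewise not recoverable; the default set is water O,
choline N, phosphate P, other sulfonate S and Na⁺.

Cylindrical density maps bin by (radial distance from the NP core axis,
z − midplane) and divide by 2π·r̄·Δr·Δz per frame; the mirrored negative
radii sometimes shown in such plots are presentation-only and not
produced. Core-depth trends are ordinary least squares.

Block averaging follows the Flyvbjerg–Petersen transform: successive
pairwise averaging, with the estimate taken at the first level that
changes by < 5 % over two successive levels, falling back to the largest
estimate (a conservative bound) when no plateau appears. Series shorter
than 4 samples fall back to the naive standard error where an error bar
is still needed (e.g. d_z records over few frames).

## Landscape assembly

Prior-work constants — protrusion +6.0, per-flip barrier 11.2 ± 0.2,
two-state −232.1 ± 5.6 for the 130-ligand NP, per-leaflet
−115.05 ± 2.8 — are configuration inputs tagged PRIOR_WORK_CONSTANT and
never recomputed; the package implements only the scaling arithmetic
printed alongside them. Note the printed per-leaflet value is not
exactly half the two-state value (−232.1/2 = −116.05); the printed
−115.05 is honored as the scaling input and the report flags the
discrepancy. The 4-nm hydrophobic-sphere reference uses the bare
geometric area −γ·π·d² (which reproduces the printed ≈ −236 kcal/mol),
not a probe-inflated one. The landscape is reported as a table of
labeled states and transitions rather than a drawn curve; barriers
(protrusion, per-flip) attach to transitions, not minima, and state 5 is
drawn one flip's share of the flipping leg below state 3. Uncertainties
of summed components propagate in quadrature — a simplification, as the
original arithmetic sums point estimates.

## Problem sizes

Default test and demo runs use the full published composition (58
ligands, 334 lipids, 89 Na⁺/60 Cl⁻) with hydration shells as the only
explicit waters (~2,400 atoms per frame), trajectories of 5–50 frames,
and 14-step flip sequences with 8 resampled frames per selection window;
statistical recovery tests (hydration slope, block errors) use 50 frames
and 4,096-sample series respectively. These sizes make every quantity's
ground truth recoverable with comfortable margins while keeping any
single analysis under a few seconds.

## Known limitations

No dynamics, free-energy barriers or PMFs are computed (the flip barrier
is a cited constant); atomistic force-field detail, lipid flip-flop, and
the ribbon-to-box conversion used for system preparation are out of
scope. The synthetic generator's geometric idealizations mean
contact-count and SASA *trends* along the pathway are not emergent; the
corresponding operations are validated on constructed inputs instead.
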