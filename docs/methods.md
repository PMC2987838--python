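# Methods

This note documents the models implemented in `ionsite`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the package's numerical choices and known limitations.

## Structures and ensembles

Structures are ordered atom lists parsed from PDB files (gemmi does the
parsing; this package applies its own conventions on top). Alternate
locations are resolved to the highest-occupancy conformer, ties broken
alphabetically. A HETATM residue named NA, CA or MG consisting of a single
atom is a cation; this disambiguates an ion "CA" from an alpha-carbon "CA"
(an ATOM-record atom name). Multi-model files become ensembles, one frame
per MODEL block, with topology identity enforced across frames. Residue
numbering is taken as-is (1-based, no renumbering).

Van der Waals radii are a Bondi-type element table (C 1.70, N 1.55, O 1.52,
S 1.80, H 1.20 Å) with cation radii Na⁺ 1.87, Ca²⁺ 1.71, Mg²⁺ 1.18 Å,
packaged as TOML and overridable. This is a deliberate dialect choice: it
shifts absolute SASA and PB values slightly relative to any particular
force-field radius set, but not the pipeline's comparative logic
(occupancies, CN splits, ΔSASA memberships, Ep orderings). The `formal`
charge scheme places integer side-chain charges (Asp/Glu −1 split over the
two carboxylate oxygens, Lys/Arg +1, histidines neutral, termini neutral);
ions carry their species charge. A coarse tabulated per-atom set (backbone
dipole + charged groups) is packaged for callers who want smoother charge
distributions. All shell/SASA/PB operations are defined on heavy atoms;
crystal structures rarely carry hydrogens.

## First solvation shells

The first-shell outer limits are fixed distances per species — 3.2 Å for
Na⁺ and Ca²⁺, 2.9 Å for Mg²⁺ — corresponding to the first minimum of the
ion–oxygen radial distribution function; they are config-overridable.
Donor elements default to {O, N}: shells are oxygen-dominated, but
histidine can coordinate through its imidazole nitrogen, and excluding N
would silently drop such contacts. Coordination numbers count *atoms*
(a bidentate carboxylate contributes 2 to CN_aa); residue participation
(%t_occ) counts a residue once per frame however many of its atoms
coordinate. CN means are taken over bound frames (the shell of a bound
cation), %t_occ over all frames of the analysis window, so a site occupied
75% of the time shows donor %t_occ near 75 even when coordination is
perfect on bound frames. Water-mediated contacts (ion–water–residue, water
oxygen within 3.5 Å of a protein O/N) are detected separately and are not
merged into %t_occ by default.

RDFs are normalized with the sampled spherical shell volume around each
ion (no periodic images — the ensembles handled here are not periodic
boxes), so a uniform ideal-gas fixture gives g(r) = 1 and the cumulative
integral n(r) at the cutoff equals the mean total CN, a consistency that
is tested across the two code paths.

Water residence is per water *identity* (residue key) over the frames the
ion is bound; identities at or above a 0.95 residence fraction are flagged
non-exchangeable — the behaviour of a water locked between the cation and
a protein group, as opposed to bulk-exchanging shell waters.

## Site detection

All frames are least-squares superposed (Kabsch, reflections excluded) on
Cα onto the first frame; ion observations having at least one protein
donor in the shell are clustered by single linkage with ε = 2.5 Å.
Single linkage was preferred over density-based methods because it is
deterministic and parameter-light; ε is set by the scale of one-to-two
metal–oxygen bond lengths (~2.1 Å), so positions within one coordination
rearrangement merge. Clusters below 20% frame occupancy are discarded by
default — low enough to keep weak but real pockets, high enough to drop
transient encounters; the threshold is exposed in config since it gates
the headline site count. Sites are labeled by descending occupancy. Two
sites sharing at least two fingerprint residues at ≥50 %t_occ are reported
as sub-sites of one double site (labels `siteNa`, `siteNb`, ...); the
sharing relation is closed transitively, and frames where several
sub-sites hold ions simultaneously are counted and reported without
drawing an exclusivity conclusion.

## Coordination geometry

The coordination polyhedron of a bound ion is classified by template
fitting: the ideal octahedron (CN 6) or tricapped trigonal prism (CN 9,
D3h; unit-sphere vertices from a prism with height/edge ratio 1 plus caps
on the rectangular-face normals) is scaled to the observed mean bond
length and fitted over rotations and vertex assignments. The production
search alternates Hungarian assignment with Kabsch rotation from a
deterministic bank of 64 starting rotations (the 24-element octahedral
group plus a fixed quasi-random fill); the residual RMSD is the distortion
score. The class is assigned below a 0.45 Å distortion threshold,
calibrated on the synthetic noise study so that vertex noise up to
σ ≈ 0.15 Å is accepted; CN 7 and 8 shells are reported as "other" rather
than force-fitted. The test suite verifies that the optimized search
equals exhaustive 720-permutation enumeration for CN 6 and a
partition-exhaustive oracle for CN 9, and that classification is invariant
under rotation, translation, uniform scaling and ligand reordering.

## Solvent accessibility and interfaces

SASA is Shrake–Rupley with a deterministic golden-spiral point set
(default 960 points, no RNG anywhere in the SASA path) and a 1.4 Å probe;
an isolated atom reproduces 4π(r+probe)² essentially exactly and the
two-sphere closed form to well under 1%. Waters and ions are stripped
before protein SASA. Interface regions are residues of a chain losing at
least 1.0 Å² upon complexation (free minus complexed, residues matched by
resid and name); with several complexes the union is taken by default,
with an intersection mode available. The 1.0 Å² threshold is the knob that
gates interface residue counts and is exposed in config. Cation
accessibility is the ion's SASA against the solute with bulk waters always
removed; excluding vs retaining the coordinating first-shell waters is a
flag, since a buried catalytic ion and a surface-exposed one differ
precisely in that number. Formal region net charge counts Asp/Glu as −1,
Arg/Lys +1, His 0.

## Linearized Poisson–Boltzmann electrostatics

The solver discretizes ∇·(ε∇φ) − ε_s κ²(x) φ = −4π l_B ρ on a uniform
cubic grid (φ in kT/e, lengths in Å, charges in e; l_B is the vacuum
Bjerrum length at the configured temperature). Defaults: 150 mM 1:1 salt
(Debye length ≈ 7.85 Å at 298.15 K), ε_solv 78.4, ε_solute 2, 1.4 Å
probe, 2.0 Å Stern layer, 0.6 Å spacing, 12 Å padding. Design choices:

- **Surface:** the solvent-excluded region is obtained by probe-inflating
  the atom spheres on the grid and eroding back by the probe depth with a
  Euclidean distance transform — a grid approximation of the molecular
  surface whose accuracy is set by the spacing (documented knob), not an
  analytic SES.
- **Screening:** κ² is zeroed inside the solute and within the Stern layer
  of any atom; the ion-exclusion boundary is anti-aliased with a one-cell
  linear ramp to suppress staircase error.
- **Charges** are spread with an interpolating cubic-spline (Catmull–Rom)
  kernel over a 4×4×4 stencil. The kernel reproduces constants and linear
  functions, so total charge and dipole are conserved exactly, and it
  collapses onto a single node when a charge sits on one.
- **Iteration:** red–black SOR with the spectral-radius-optimal relaxation
  factor, Dirichlet boundary from the per-charge screened-Coulomb
  (Debye–Hückel) sum, convergence at relative residual 10⁻⁶, with the
  residual history attached to any convergence failure. A single grid
  replaces multigrid/focusing schemes: at desk scale the Born-ion test
  (q = +2, R = 1.71 Å) agrees with the analytic screened-Coulomb solution
  to ~2% at 0.5 Å spacing for r ≥ R+2 Å, and halving the spacing moves the
  surface-range potential by ~1%. Near the source (r ≲ R+1) the lattice
  Green's function error grows as (h/r)², which is why validated use
  starts at R+2 Å.

The interface potential Ep is the mean (± sd) of the potential
trilinearly interpolated at the unoccluded probe-inflated golden-spiral
surface points of the region atoms; a nearest-node aggregation is
available by flag, and the choice is recorded in the scan output. Ep is
reported per frame and can be averaged over snapshots. Complement scans
run one solve per ion complement on one shared grid geometry (so values
are comparable), placing each species at the site centroid with a radial
nudge (with warning) out of sub-1 Å clashes, and report the
charge-reversal point: the smallest total bound-cation charge with
Ep > 0. On the bundled acidic-patch fixture (net −4 with four +2 pockets)
the nested scan reproduces the brute-force scan over all 2⁴ complements.

## Ensemble metrics

Superposition is Kabsch least squares over a selection (reflections
excluded). RMSD series report per-frame values plus mean ± sd over an
analysis window defaulting to the final 80% of frames (the equilibrated
tail of a trajectory). RMSF is measured about the ensemble mean structure,
refined over two fit-then-average passes, because a mean-structure
reference is the standard convention and is testable against closed
forms. Note a statistical subtlety the tests account for: rigid-body
fitting absorbs 6 degrees of freedom, shrinking apparent fluctuations by
a factor ≈ √(1 − 6/3N) for N fit atoms (and more for high-leverage atoms),
so the σ√3 closed form is recovered within 5% only when fitting over many
atoms.

## The synthetic generator

`make_pockets_ensemble` builds what the analysis assumes and nothing more:
rigid donor scaffolds (Gly–donor–Gly stubs whose supporting atoms point
away from the ion, so exactly the intended donor atom enters the shell),
first-shell waters at template vertices, per-frame Bernoulli(occupancy)
bound/unbound states, isotropic Gaussian jitter (default σ = 0.05 Å, small
enough that geometry recovery stays deterministic at 3σ) applied to donors
and waters but never to the ideal topology or the ion, an 8 Å unbound
parking spot chosen to clear every atom by a wide margin, and an optional
water-exchange schedule that rotates fresh identities from a parked bulk
pool into the shell every period. All randomness flows through a single
seeded generator; equal seeds give bit-identical ensembles.

What it does **not** emulate — and therefore what passing tests do and do
not show: there is no force field, no correlated protein motion, no
realistic water dynamics, no partial/competing occupancy of one pocket by
several species at once, and no conformational response of the pocket to
ion binding. Passing the recovery suite demonstrates that the estimators
are unbiased and correctly calibrated on data satisfying their own
assumptions; it does not validate force-field accuracy or sampling of any
real trajectory. Quantities that depend on real molecular detail
(absolute RMSF profiles, real interface compositions, reversal charges of
real enzymes) require real ensembles as input.

## Problem sizes and determinism

The test and acceptance workloads are sized for a desk machine: Born grids
of ~50³–80³ nodes, ensembles of 400 frames × ~90 atoms for occupancy
recovery, 2000 frames for the RMSF closed form, 100 noise draws per
polyhedron class, and 16-complement PB scans on ~40³ grids. Every
stochastic stage takes an explicit seed; the pipeline bundle serializes
its config and reproduces bit-for-bit under an identical config.

## Known limitations

- PDB only (no mmCIF); altloc ensembles and insertion-code arithmetic are
  out of scope.
- The PB solver is linear; no nonlinear PB, no conformational
  reorganization upon ion binding, no claim of numerical parity with
  production multigrid solvers.
- Percent-relative ("Gly-X-Gly normalized") accessibilities are not
  computed, only absolute Å².
- Alignments are consumed, not computed; homolog retrieval is the caller's
  job.
- Site detection assumes the protein scaffold superposes well on Cα;
  large-scale conformational heterogeneity would smear ion clusters.
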