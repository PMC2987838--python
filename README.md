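# ionsite

Cation-binding-site analysis for protein structure ensembles.

Enzymes such as DNase I depend on bound Ca²⁺ and Mg²⁺ both for structural
integrity and for catalysis, yet the number and location of their
ion-binding sites is hard to pin down from any single crystal structure:
ions exchange, sites are partially occupied, and monovalent ions are nearly
invisible to X-ray crystallography. Given an ensemble of structures
(trajectory snapshots or multiple crystal forms as multi-model PDB),
`ionsite` answers, quantitatively:

- **Where do cations bind?** Ion observations with protein donors in their
  first solvation shell are clustered (single-linkage, ε = 2.5 Å after Cα
  superposition) into discrete sites with residue fingerprints and
  occupancies.
- **How are they coordinated?** Per-frame coordination spheres use
  species-specific first-shell cutoffs (3.2 Å for Na⁺/Ca²⁺, 2.9 Å for
  Mg²⁺, the first minimum of the ion–oxygen RDF). The coordination number
  CN is decomposed into amino-acid and water contributions, residue
  participation is reported as %t_occ (percent of analyzed frames), and
  first-shell waters are classified exchangeable vs non-exchangeable by
  residence fraction.
- **What shape is the shell?** The coordination polyhedron is classified as
  octahedral (CN 6, typical Mg²⁺) or tricapped trigonal prism (CN 9,
  high-coordination Ca²⁺) by least-squares template fitting over rotations
  and vertex assignments, with an RMSD distortion score.
- **Do the ions matter electrostatically?** An in-house finite-difference
  solver for the linearized Poisson–Boltzmann equation
  ∇·(ε∇φ) − ε_s κ²(x) φ = −ρ/ε₀ (150 mM salt, 298.15 K, ε_solv 78.4,
  ε_solute 2, 1.4 Å probe) evaluates the mean surface potential Ep (kT/e)
  of an interface region as a function of the bound-ion complement, and
  locates the **charge-reversal point** — the smallest total bound-cation
  charge at which the interface turns electropositive.
- **Is the site conserved?** Binding-site residues are mapped into multiple
  sequence alignments and scored for identity and dominant substitution
  (by residue or physicochemical class).

Interfaces between macromolecules are defined the classical way: residues
losing solvent-accessible surface area (Shrake–Rupley, 1.4 Å probe,
deterministic golden-spiral point set) between the free and complexed
structures.

A first-class synthetic-ensemble generator (`ionsite.synthetic_data`)
builds pockets with *known* coordination complement, geometry, occupancy,
jitter and water-exchange schedule, plus Born-ion and two-body oracle
systems — so every stage of the pipeline is validated by
generator-parameter recovery and closed-form physics, without any external
downloads.

## Worked example

Simulate an octahedral Mg²⁺ pocket (2 Asp carboxylate oxygens + 4 first-shell
waters, 80% occupancy over 200 frames), then detect and characterize the site:

```sh
$ ionsite simulate --spec pocket.toml --out traj.pdb
wrote 200 frames to traj.pdb

$ ionsite detect --pdb traj.pdb
[
  {
    "label": "site1",
    "occupancy_pct": 78.0,
    "species": ["MG"],
    "centroid": [-0.05, -0.0, -0.0],
    "fingerprint": {"A:ASP101": 78.0, "A:ASP111": 78.0}
  }
]

$ ionsite coord --pdb traj.pdb --ion-serial 31
{
  "cn_aa": 2.0,
  "cn_water": 4.0,
  "cn_total": 6.0,
  "occupancy_pct": 78.0,
  "pct_t_occ": {"A:ASP101": 78.0, "A:ASP111": 78.0}
}
```

Reading the numbers: the single detected site is occupied by Mg²⁺ in 78% of
frames (the realized draw of the 80% Bernoulli occupancy), both engineered
aspartates coordinate the ion in every bound frame (%t_occ equals the site
occupancy), and the coordination number splits exactly into the generated
2 protein + 4 water donors. `ionsite run --config run.toml` chains all
stages (sites → coordination/geometry → interface SASA → PB complement
scan → conservation) into a deterministic JSON/TSV report bundle.

The same analyses are available as a library (`from ionsite import
detect_sites, coordination_summary, shrake_rupley, solve_lpbe, ...`); a
pocket specification in TOML is shown in `tests/test_cli.py`.

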