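# Packaged defaults: van der Waals radii, formal/partial charge tables,
# ion species definitions, coordination-polyhedron templates and
# substitution classes. Editable copies may be passed to the loaders.

[radii]
# Element -> van der Waals radius (A). Protein-element set plus the three
# cations handled by the pipeline. Ion radii are the cation radii used for
# surface and PB calculations, not the neutral-element vdW radii.
C = 1.70
N = 1.55
O = 1.52
S = 1.80
H = 1.20
P = 1.80
NA = 1.87
CA = 1.71
MG = 1.18

[ions.NA]
charge = 1
shell_cutoff = 3.2
cn_max = 6

[ions.CA]
charge = 2
shell_cutoff = 3.2
cn_max = 9

[ions.MG]
charge = 2
shell_cutoff = 2.9
cn_max = 6

[water]
resnames = ["HOH", "WAT", "TIP3", "SOL", "H2O"]

# Formal charge scheme: integer side-chain charges at neutral pH, split
# over the terminal polar atoms of the charged group. Histidines neutral.
[formal_charges.ASP]
OD1 = -0.5
OD2 = -0.5

[formal_charges.GLU]
OE1 = -0.5
OE2 = -0.5

[formal_charges.LYS]
NZ = 1.0

[formal_charges.ARG]
NH1 = 0.5
NH2 = 0.5

# Tabulated scheme: a coarse per-atom polar-charge set (backbone dipole +
# charged side chains). Atoms absent from the table get 0.
[tabulated_charges.backbone]
N = -0.40
C = 0.50
O = -0.50
CA = 0.40

[tabulated_charges.ASP]
CG = 0.6
OD1 = -0.8
OD2 = -0.8

[tabulated_charges.GLU]
CD = 0.6
OE1 = -0.8
OE2 = -0.8

[tabulated_charges.LYS]
NZ = 0.6
CE = 0.4

[tabulated_charges.ARG]
CZ = 0.4
NH1 = 0.3
NH2 = 0.3

[geometry]
distortion_threshold = 0.45
# Tricapped trigonal prism template: square-face height/edge ratio, caps on
# rectangular-face normals at the prism mid-height; all vertices normalized
# to the unit sphere before scaling to the observed mean bond length.
ttp_height_edge_ratio = 1.0

[substitution_classes]
polar = ["SER", "THR", "ASN", "GLN", "TYR", "CYS", "TRP"]
charged = ["ASP", "GLU", "LYS", "ARG", "HIS"]
"polar/charged" = ["SER", "THR", "ASN", "GLN", "TYR", "CYS", "TRP", "ASP", "GLU", "LYS", "ARG", "HIS"]
hydrophobic = ["ALA", "VAL", "LEU", "ILE", "MET", "PHE", "PRO", "GLY"]
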