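"""Synthetic ensemble and fixture generators.

Builds multi-model ensembles with the statistical structure the downstream
analyses assume, with every generating parameter known: engineered ion
pockets (k carboxylate/imidazole donors plus first-shell waters in an
octahedral or tricapped-trigonal-prismatic arrangement), Bernoulli site
occupancy over frames, isotropic thermal jitter, exchangeable vs
non-exchangeable first-shell waters, and the Born-ion / two-body systems
used as closed-form oracles for the electrostatics and surface-area stages.

All randomness flows through one ``numpy.random.Generator`` seeded from the
trajectory spec; the same seed yields a bit-identical ensemble.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from types import SimpleNamespace

import numpy as np

from .geometry import octahedron_vertices, ttp_vertices
from .structure_io import Atom, Ensemble, IonSpecies, Structure

__all__ = [
    "PocketSpec",
    "TrajectorySpec",
    "PocketLayout",
    "make_pocket_ensemble",
    "make_pockets_ensemble",
    "make_born_system",
    "make_two_body_complex",
    "make_acidic_patch",
]

_GEOMETRY_SIZES = {"octahedral": 6, "tricapped_trigonal_prism": 9}
_DONOR_ATOMS = {"ASP": "OD1", "GLU": "OE1", "HIS": "NE2", "ASN": "OD1"}
_SECOND_O = {"ASP": "OD2", "GLU": "OE2"}
_BRIDGE_ATOM = {"ASP": "CG", "GLU": "CD", "HIS": "CG", "ASN": "CG"}


@dataclass(frozen=True)
class PocketSpec:
    """An engineered cation pocket with known coordination complement."""

    n_protein_donors: int
    donor_resnames: tuple[str, ...]
    n_first_shell_waters: int
    geometry: str  # "octahedral" | "tricapped_trigonal_prism"
    bond_length: float  # A, ion-donor distance
    ion: IonSpecies

    def __post_init__(self) -> None:
        if self.geometry not in _GEOMETRY_SIZES:
            raise ValueError(f"unknown geometry {self.geometry!r}")
        size = _GEOMETRY_SIZES[self.geometry]
        if self.n_protein_donors + self.n_first_shell_waters != size:
            raise ValueError(
                f"{self.geometry} needs {size} vertices, got "
                f"{self.n_protein_donors} donors + {self.n_first_shell_waters} waters"
            )


@dataclass(frozen=True)
class TrajectorySpec:
    """Frame-generation parameters: occupancy, jitter, water exchange."""

    n_frames: int
    occupancy_target: float = 1.0
    jitter_sigma: float = 0.05  # A, isotropic per-coordinate Gaussian
    unbound_displacement: float = 8.0  # A, ion offset on unbound frames
    water_exchange_period: int | None = None  # frames; None = never exchange
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy_target <= 1.0:
            raise ValueError("occupancy_target must be in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


@dataclass
class PocketLayout:
    """Ground truth of a generated pocket, for parameter-recovery tests."""

    center: np.ndarray
    vertices: np.ndarray  # (cn, 3) ideal ligand positions
    donor_residue_keys: list[tuple[str, int, str]]
    donor_atom_indices: list[int]
    water_residue_keys: list[tuple[str, int, str]]  # shell identities, frame 0
    ion_index: int
    bound: np.ndarray = field(default=None)  # per-frame bound flags


def _perp_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    v = np.cross(u, ref)
    v /= np.linalg.norm(v)
    return v, np.cross(u, v)


def _golden_directions(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + math.sqrt(5.0)) * k
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def _build_pocket_atoms(
    pocket: PocketSpec,
    center: np.ndarray,
    resid_base: int,
    water_resid_base: int,
    ion_resid: int,
    n_water_identities: int,
    serial_start: int,
) -> tuple[list[Atom], PocketLayout]:
    """Static (frame-0, zero-jitter) atoms for one pocket plus ground truth.

    Protein donors are carried by minimal 3-residue stubs (Gly-donor-Gly)
    whose supporting atoms point radially away from the ion so that only the
    intended donor atom enters the first shell.
    """
    verts = (
        octahedron_vertices() if pocket.geometry == "octahedral" else ttp_vertices()
    )
    vertices = center + pocket.bond_length * verts
    atoms: list[Atom] = []
    serial = serial_start
    b = pocket.bond_length
    donor_keys: list[tuple[str, int, str]] = []
    donor_idx: list[int] = []

    def add(name, element, resname, resid, chain, pos, *, water=False, ion=False, rec="ATOM"):
        nonlocal serial
        atoms.append(
            Atom(serial, name, element, resname, resid, chain, np.asarray(pos, float),
                 is_water=water, is_ion=ion, record=rec)
        )
        serial += 1
        return len(atoms) - 1

    for d in range(pocket.n_protein_donors):
        u = verts[d]
        v, w = _perp_basis(u)
        resname = pocket.donor_resnames[d % len(pocket.donor_resnames)].upper()
        rbase = resid_base + 10 * d
        # leading Gly stub
        for name, off in (("N", 5.2), ("CA", 4.8), ("C", 4.4), ("O", 4.2)):
            add(name, name[0], "GLY", rbase, "A", center + (b + off) * u + 1.5 * v)
        # donor residue: side-chain donor atom exactly at the vertex
        add("N", "N", resname, rbase + 1, "A", center + (b + 3.4) * u + 0.8 * v)
        add("CA", "C", resname, rbase + 1, "A", center + (b + 2.6) * u)
        add(_BRIDGE_ATOM[resname], "C", resname, rbase + 1, "A", center + (b + 1.3) * u)
        di = add(_DONOR_ATOMS[resname], _DONOR_ATOMS[resname][0], resname, rbase + 1,
                 "A", center + b * u)
        if resname in _SECOND_O:
            add(_SECOND_O[resname], "O", resname, rbase + 1, "A",
                center + (b + 1.0) * u + 1.15 * w)
        # trailing Gly stub
        for name, off in (("N", 4.2), ("CA", 4.6), ("C", 5.0), ("O", 5.3)):
            add(name, name[0], "GLY", rbase + 2, "A", center + (b + off) * u - 1.5 * v)
        donor_keys.append(("A", rbase + 1, resname))
        donor_idx.append(di)

    # water pool: shell identities first, spares parked on a far shell
    park_dirs = _golden_directions(max(n_water_identities, 1))
    water_keys: list[tuple[str, int, str]] = []
    for wi in range(n_water_identities):
        if wi < pocket.n_first_shell_waters:
            pos = vertices[pocket.n_protein_donors + wi]
        else:
            pos = center + 14.0 * park_dirs[wi]
        add("O", "O", "HOH", water_resid_base + wi, "W", pos, water=True, rec="HETATM")
        if wi < pocket.n_first_shell_waters:
            water_keys.append(("W", water_resid_base + wi, "HOH"))

    sym = pocket.ion.symbol.upper()
    ion_i = add(sym, pocket.ion.symbol, sym, ion_resid, "I", center, ion=True, rec="HETATM")
    layout = PocketLayout(
        center=center.copy(),
        vertices=vertices,
        donor_residue_keys=donor_keys,
        donor_atom_indices=donor_idx,
        water_residue_keys=water_keys,
        ion_index=ion_i,
    )
    return atoms, layout


def make_pocket_ensemble(
    pocket: PocketSpec,
    traj: TrajectorySpec,
    center: np.ndarray | tuple[float, float, float] = (0.0, 0.0, 0.0),
    return_layout: bool = False,
) -> Ensemble | tuple[Ensemble, PocketLayout]:
    """Generate a single-pocket ensemble (see :func:`make_pockets_ensemble`)."""
    result = make_pockets_ensemble([pocket], traj, [center], return_layouts=True)
    ens, layouts = result
    return (ens, layouts[0]) if return_layout else ens


def make_pockets_ensemble(
    pockets: list[PocketSpec],
    traj: TrajectorySpec,
    centers: list[np.ndarray | tuple[float, float, float]] | None = None,
    return_layouts: bool = False,
) -> Ensemble | tuple[Ensemble, list[PocketLayout]]:
    """Generate an ensemble containing one or more engineered ion pockets.

    On bound frames the pocket's ion sits at the pocket centroid with its
    donors at ``bond_length`` (plus jitter on donors and waters, never on
    the ideal topology); on unbound frames the ion is parked at
    ``unbound_displacement`` from the centroid, along +x when that spot
    clears every atom, otherwise along the clearest direction, so a parked
    ion is always far outside any shell cutoff.
    Bound/unbound states are independent Bernoulli(occupancy_target) draws
    per frame and per pocket.  With ``water_exchange_period`` set, the
    identities occupying the first-shell water positions are replaced by
    fresh identities from a parked bulk pool every period.
    """
    if centers is None:
        centers = [(25.0 * k, 0.0, 0.0) for k in range(len(pockets))]
    if len(centers) != len(pockets):
        raise ValueError("need one center per pocket")
    period = traj.water_exchange_period
    n_gens = 1 if period is None else max(1, math.ceil(traj.n_frames / period))

    base_atoms: list[Atom] = []
    layouts: list[PocketLayout] = []
    serial = 1
    for p, (pocket, c) in enumerate(zip(pockets, centers)):
        c = np.asarray(c, dtype=float)
        n_ids = pocket.n_first_shell_waters * n_gens
        atoms, layout = _build_pocket_atoms(
            pocket,
            c,
            resid_base=100 * (p + 1),
            water_resid_base=1000 * (p + 1),
            ion_resid=900 + p,
            n_water_identities=n_ids,
            serial_start=serial,
        )
        offset = len(base_atoms)
        layout.ion_index += offset
        layout.donor_atom_indices = [i + offset for i in layout.donor_atom_indices]
        base_atoms.extend(atoms)
        layouts.append(layout)
        serial += len(atoms)

    base = Structure(base_atoms, title="synthetic pocket ensemble", source="generator")
    rng = np.random.default_rng(traj.seed)
    bound = [
        rng.random(traj.n_frames) < traj.occupancy_target for _ in pockets
    ]
    for lay, b in zip(layouts, bound):
        lay.bound = b

    mobile = np.array(
        [not (a.is_ion) for a in base_atoms]
    )  # jitter applies to protein and waters only
    xyz0 = base.coords
    # unbound parking direction per pocket: prefer +x, otherwise the golden
    # direction whose parking spot clears every static atom by the largest
    # margin (a parked ion must sit cleanly outside any shell cutoff)
    park_dir: list[np.ndarray] = []
    for lay in layouts:
        candidates = np.vstack([[1.0, 0.0, 0.0], _golden_directions(64)])
        spots = lay.center + traj.unbound_displacement * candidates
        dmin = np.min(
            np.linalg.norm(xyz0[mobile][None, :, :] - spots[:, None, :], axis=2),
            axis=1,
        )
        park_dir.append(
            candidates[0] if dmin[0] > 4.5 else candidates[int(np.argmax(dmin))]
        )
    frames: list[Structure] = []
    for f in range(traj.n_frames):
        xyz = xyz0.copy()
        if traj.jitter_sigma > 0:
            xyz[mobile] += rng.normal(0.0, traj.jitter_sigma, size=(mobile.sum(), 3))
        for p, (pocket, lay) in enumerate(zip(pockets, layouts)):
            # water exchange: generation g parks the previous shell identities
            # and moves the next n fresh identities onto the shell vertices
            if period is not None:
                g = min(f // period, n_gens - 1)
                nsw = pocket.n_first_shell_waters
                pool_start = lay.ion_index - nsw * n_gens  # waters precede the ion
                shell_positions = lay.vertices[pocket.n_protein_donors:]
                park = _golden_directions(nsw * n_gens)
                for wi in range(nsw * n_gens):
                    ai = pool_start + wi
                    in_shell = g * nsw <= wi < (g + 1) * nsw
                    if in_shell:
                        pos = shell_positions[wi - g * nsw]
                    else:
                        pos = lay.center + 14.0 * park[wi]
                    jit = xyz[ai] - xyz0[ai]
                    xyz[ai] = pos + jit
            if not lay.bound[f]:
                xyz[lay.ion_index] = lay.center + traj.unbound_displacement * park_dir[p]
        frames.append(base.with_coords(xyz))
    ens = Ensemble(frames)
    return (ens, layouts) if return_layouts else ens


def make_born_system(q: float, radius: float, box: float = 30.0) -> Structure:
    """A single charged sphere centered in a cubic box: the Born-ion oracle
    system for the linearized PB solver (closed-form Debye-Hueckel solution).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    c = box / 2.0
    atom = Atom(
        serial=1,
        name="ION",
        element="X",
        resname="ION",
        resid=1,
        chain="I",
        coords=np.array([c, c, c]),
        radius=float(radius),
        partial_charge=float(q),
        is_ion=True,
        record="HETATM",
    )
    return Structure([atom], title=f"born q={q:+.2f} r={radius:.2f}", source="generator")


def make_acidic_patch(
    n_side: int = 4,
    spacing: float = 4.5,
    n_asp: int = 4,
) -> tuple[Structure, list[SimpleNamespace], list[tuple[int, str]]]:
    """A charged-surface fixture for the electrostatic complement scan.

    A rigid ``n_side x n_side`` slab of one-atom Gly residues carries
    ``n_asp`` Asp residues (carboxylates pointing +z, net charge -n_asp);
    above each Asp sits a cation pocket position.  Returns the structure,
    a list of site descriptors (objects with ``label`` and ``centroid``,
    duck-typed for the scan), and the region residue keys (the whole slab
    face).
    """
    atoms: list[Atom] = []
    serial = 1
    region: list[tuple[int, str]] = []
    asp_cells = np.linspace(0, n_side * n_side - 1, n_asp, dtype=int)
    sites: list[dict] = []
    rid = 1
    for i in range(n_side):
        for j in range(n_side):
            cell = i * n_side + j
            x, y = i * spacing, j * spacing
            if cell in asp_cells:
                atoms.append(Atom(serial, "CA", "C", "ASP", rid, "A", np.array([x, y, 0.0])))
                serial += 1
                atoms.append(Atom(serial, "CG", "C", "ASP", rid, "A", np.array([x, y, 1.4])))
                serial += 1
                atoms.append(
                    Atom(serial, "OD1", "O", "ASP", rid, "A", np.array([x - 1.0, y, 2.2]))
                )
                serial += 1
                atoms.append(
                    Atom(serial, "OD2", "O", "ASP", rid, "A", np.array([x + 1.0, y, 2.2]))
                )
                serial += 1
                sites.append(
                    SimpleNamespace(
                        label=f"s{len(sites) + 1}", centroid=np.array([x, y, 4.2])
                    )
                )
                region.append((rid, "ASP"))
            else:
                atoms.append(Atom(serial, "CA", "C", "GLY", rid, "A", np.array([x, y, 0.0])))
                serial += 1
                region.append((rid, "GLY"))
            rid += 1
    return Structure(atoms, title="acidic patch", source="generator"), sites, region


def make_two_body_complex(
    sep: float,
    n_side: int = 3,
    spacing: float = 5.0,
) -> tuple[Structure, Structure]:
    """Two rigid single-atom-residue slabs for interface detection.

    Each slab (chains A and B) is two square layers of one-atom Gly
    residues; the facing layers of both chains lose solvent accessibility
    when the slabs are brought to small separation ``sep`` along z, while
    the back layers do not.  Returns (free chain A, A-B complex).
    """
    atoms_a: list[Atom] = []
    serial = 1
    resid = 1

    def layer(chain: str, z: float, rid0: int, out: list[Atom], s0: int) -> int:
        s = s0
        rid = rid0
        for i in range(n_side):
            for j in range(n_side):
                out.append(
                    Atom(s, "CA", "C", "GLY", rid, chain,
                         np.array([i * spacing, j * spacing, z]))
                )
                s += 1
                rid += 1
        return s

    serial = layer("A", 0.0, 1, atoms_a, serial)  # facing layer of A
    serial = layer("A", -4.0, 1 + n_side**2, atoms_a, serial)  # back layer
    free = Structure(list(atoms_a), title="slab A", source="generator")
    atoms_ab = list(atoms_a)
    serial = layer("B", sep, 1, atoms_ab, serial)  # facing layer of B
    serial = layer("B", sep + 4.0, 1 + n_side**2, atoms_ab, serial)
    complexed = Structure(atoms_ab, title=f"slab A-B sep={sep}", source="generator")
    return free, complexed
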