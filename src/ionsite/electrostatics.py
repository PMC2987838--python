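"""Linearized Poisson-Boltzmann electrostatics on a finite-difference grid.

Solves div(eps grad phi) - eps_s kappa^2(x) phi = -4 pi l_B rho for the
dimensionless potential phi in kT/e on a uniform cubic grid (lengths in A,
charges in e), with a position-dependent dielectric (solute inside the
probe-defined solvent-excluded surface, solvent outside), Debye screening
switched off inside the solute and its Stern layer, and Debye-Hueckel
Dirichlet boundary conditions.  The iteration is red-black successive
over-relaxation.

Solute charges are spread onto the grid with an interpolating cubic-spline
kernel (64-node stencil) that conserves total charge and dipole exactly and
collapses onto a single node when a charge sits on one.

On top of the solver: surface-point averaging of the potential over an
interface region (the Ep statistic, kT/e) and bound-ion complement scans
locating the charge-reversal point — the smallest total bound-cation charge
at which the interface potential turns positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .sasa import golden_spiral_points
from .structure_io import Atom, Structure, ion_species, load_default_tables

__all__ = [
    "PBParameters",
    "PBGrid",
    "PotentialMap",
    "IonComplement",
    "EpResult",
    "ScanResult",
    "build_grid",
    "solve_lpbe",
    "interface_potential",
    "charge_reversal_scan",
    "write_opendx",
]

# physical constants (SI)
_E = 1.602176634e-19
_EPS0 = 8.8541878128e-12
_KB = 1.380649e-23
_NA = 6.02214076e23


@dataclass(frozen=True)
class PBParameters:
    """Continuum-electrostatics parameters.

    Defaults follow physiological conditions: 150 mM 1:1 salt, 298.15 K,
    solvent dielectric 78.4, solute dielectric 2, 1.4 A probe.
    """

    solvent_dielectric: float = 78.4
    solute_dielectric: float = 2.0
    ionic_strength_mM: float = 150.0
    temperature: float = 298.15
    probe: float = 1.4
    stern_layer: float = 2.0
    grid_spacing: float = 0.6
    padding: float = 12.0
    tolerance: float = 1e-6
    max_iterations: int = 30000

    def __post_init__(self) -> None:
        if self.solvent_dielectric <= 1 or self.solute_dielectric < 1:
            raise ValueError("dielectrics must exceed 1 (solvent) / be >= 1 (solute)")
        if not 0.2 < self.grid_spacing < 1.5:
            raise ValueError("grid spacing out of the supported (0.2, 1.5) A range")

    @property
    def bjerrum_vacuum(self) -> float:
        """Vacuum Bjerrum length e^2/(4 pi eps0 kT), in A."""
        return _E**2 / (4.0 * np.pi * _EPS0 * _KB * self.temperature) * 1e10

    @property
    def kappa2(self) -> float:
        """Debye parameter kappa^2 in the solvent, A^-2 (Debye formula)."""
        i_si = self.ionic_strength_mM  # mM == mol/m^3
        k2 = (
            2.0
            * _NA
            * _E**2
            * i_si
            / (_EPS0 * self.solvent_dielectric * _KB * self.temperature)
        )
        return k2 * 1e-20  # m^-2 -> A^-2

    @property
    def kappa(self) -> float:
        return float(np.sqrt(self.kappa2))


@dataclass
class PBGrid:
    origin: np.ndarray  # A
    spacing: float  # A
    dims: tuple[int, int, int]
    eps: np.ndarray  # node dielectric map
    kappa2_bar: np.ndarray  # modified screening eps_s * kappa^2 (A^-2) per node
    charge: np.ndarray  # spread charge per node, e
    source_charges: np.ndarray = field(repr=False, default=None)  # (n, 5): xyz, q, radius

    @property
    def extent(self) -> np.ndarray:
        return self.origin + self.spacing * (np.asarray(self.dims) - 1)


def _spline_weights(u: np.ndarray) -> np.ndarray:
    """Interpolating cubic (Catmull-Rom) weights for nodes i-1..i+2.

    Partition of unity and exact linear reproduction: conserves total
    charge and dipole; a charge exactly on a node maps entirely to it.
    """
    u2, u3 = u * u, u * u * u
    return np.stack(
        [
            -0.5 * u3 + u2 - 0.5 * u,
            1.5 * u3 - 2.5 * u2 + 1.0,
            -1.5 * u3 + 2.0 * u2 + 0.5 * u,
            0.5 * u3 - 0.5 * u2,
        ]
    )


def _stamp_sphere(mask: np.ndarray, origin: np.ndarray, h: float, center: np.ndarray,
                  radius: float) -> None:
    """Set mask nodes within ``radius`` of ``center`` to True (local stamp)."""
    lo = np.maximum(np.floor((center - radius - origin) / h).astype(int), 0)
    hi = np.minimum(
        np.ceil((center + radius - origin) / h).astype(int) + 1, np.asarray(mask.shape)
    )
    if np.any(lo >= hi):
        return
    ax = [origin[d] + h * np.arange(lo[d], hi[d]) - center[d] for d in range(3)]
    d2 = (
        ax[0][:, None, None] ** 2
        + ax[1][None, :, None] ** 2
        + ax[2][None, None, :] ** 2
    )
    view = mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    view |= d2 <= radius * radius


def _stamp_ramp(weight: np.ndarray, origin: np.ndarray, h: float, center: np.ndarray,
                radius: float) -> None:
    """Lower ``weight`` to a 0->1 linear ramp across the sphere boundary.

    Anti-aliases the ion-exclusion boundary over one cell, removing most of
    the staircase error of a boolean stamp.
    """
    reach = radius + h
    lo = np.maximum(np.floor((center - reach - origin) / h).astype(int), 0)
    hi = np.minimum(
        np.ceil((center + reach - origin) / h).astype(int) + 1, np.asarray(weight.shape)
    )
    if np.any(lo >= hi):
        return
    ax = [origin[d] + h * np.arange(lo[d], hi[d]) - center[d] for d in range(3)]
    d = np.sqrt(
        ax[0][:, None, None] ** 2
        + ax[1][None, :, None] ** 2
        + ax[2][None, None, :] ** 2
    )
    ramp = np.clip((d - radius) / h + 0.5, 0.0, 1.0)
    view = weight[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    np.minimum(view, ramp, out=view)


def build_grid(
    s: Structure,
    p: PBParameters,
    bounds: tuple[np.ndarray, tuple[int, int, int]] | None = None,
) -> PBGrid:
    """Discretize a structure onto a PB grid.

    The dielectric is the solute value inside the solvent-excluded region
    (probe-inflated atom spheres eroded back by the probe depth, computed
    with a Euclidean distance transform) and the solvent value outside.
    Debye screening is zeroed inside the solute and within the Stern layer
    of any atom. Charges are spread with the 64-node cubic-spline stencil.
    ``bounds`` (origin, dims) fixes the grid geometry, e.g. for complement
    scans where all solves must share one grid.
    """
    xyz = s.coords
    radii = np.array([a.radius if a.radius is not None else np.nan for a in s.atoms])
    if np.any(np.isnan(radii)):
        raise ValueError("all atoms need radii; run assign_properties first")
    charges = np.array([a.partial_charge for a in s.atoms])
    h = p.grid_spacing
    if bounds is None:
        lo = xyz.min(axis=0) - p.padding
        hi = xyz.max(axis=0) + p.padding
        dims = tuple(int(np.ceil((hi[d] - lo[d]) / h)) + 1 for d in range(3))
        origin = lo
    else:
        origin, dims = np.asarray(bounds[0], dtype=float), tuple(bounds[1])
    top = origin + h * (np.asarray(dims) - 1)
    margin = 2.0 * h
    if np.any(xyz - radii[:, None] < origin + margin) or np.any(
        xyz + radii[:, None] > top - margin
    ):
        raise ValueError("structure does not fit in the box minus padding")

    inflated = np.zeros(dims, dtype=bool)
    accessible = np.ones(dims)  # 1 in bulk, ramping to 0 inside the Stern shell
    for i in range(len(s)):
        _stamp_sphere(inflated, origin, h, xyz[i], radii[i] + p.probe)
        _stamp_ramp(accessible, origin, h, xyz[i], radii[i] + p.stern_layer)
    # erode the probe-inflated region by the probe depth -> solvent-excluded
    if inflated.any():
        depth = ndimage.distance_transform_edt(inflated, sampling=h)
        solute = depth >= p.probe - 1e-9
    else:
        solute = inflated
    eps = np.where(solute, p.solute_dielectric, p.solvent_dielectric)
    kappa2_bar = np.where(solute, 0.0, p.solvent_dielectric * p.kappa2 * accessible)

    q = np.zeros(dims)
    for i in np.flatnonzero(charges != 0.0):
        g = (xyz[i] - origin) / h
        i0 = np.floor(g).astype(int)
        u = g - i0
        wx, wy, wz = (_spline_weights(np.array([u[d]]))[:, 0] for d in range(3))
        block = wx[:, None, None] * wy[None, :, None] * wz[None, None, :]
        sl = tuple(slice(i0[d] - 1, i0[d] + 3) for d in range(3))
        q[sl] += charges[i] * block
    src = np.column_stack([xyz, charges, radii])
    return PBGrid(
        origin=np.asarray(origin, dtype=float),
        spacing=h,
        dims=dims,
        eps=eps,
        kappa2_bar=kappa2_bar,
        charge=q,
        source_charges=src,
    )


@dataclass
class PotentialMap:
    origin: np.ndarray
    spacing: float
    dims: tuple[int, int, int]
    phi: np.ndarray  # kT/e
    iterations: int
    residual: float
    converged: bool
    residual_history: list[float] = field(default_factory=list, repr=False)

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of the potential at Cartesian points (A)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        g = (pts - self.origin) / self.spacing
        if np.any(g < 0) or np.any(g > np.asarray(self.dims) - 1):
            raise ValueError("point outside the potential grid")
        return ndimage.map_coordinates(self.phi, g.T, order=1, mode="nearest")


class PBConvergenceError(RuntimeError):
    def __init__(self, message: str, history: list[float]):
        super().__init__(message)
        self.history = history


def _dh_boundary(grid: PBGrid, p: PBParameters) -> np.ndarray:
    """Debye-Hueckel Dirichlet boundary: screened Coulomb sum per charge."""
    phi = np.zeros(grid.dims)
    nx, ny, nz = grid.dims
    h = grid.spacing
    ax = [grid.origin[d] + h * np.arange(grid.dims[d]) for d in range(3)]
    faces = []
    for d in range(3):
        for side in (0, grid.dims[d] - 1):
            idx = [slice(None)] * 3
            idx[d] = side
            faces.append(tuple(idx))
    xg, yg, zg = np.meshgrid(ax[0], ax[1], ax[2], indexing="ij")
    kap = p.kappa
    lb = p.bjerrum_vacuum
    for face in faces:
        fx, fy, fz = xg[face], yg[face], zg[face]
        acc = np.zeros_like(fx)
        for x, y, z, q, r in grid.source_charges:
            if q == 0.0:
                continue
            d = np.sqrt((fx - x) ** 2 + (fy - y) ** 2 + (fz - z) ** 2)
            d = np.maximum(d, 1e-6)
            acc += (
                q
                * lb
                / (p.solvent_dielectric * d)
                * np.exp(-kap * np.maximum(d - r, 0.0))
                / (1.0 + kap * r)
            )
        phi[face] = acc
    return phi


def solve_lpbe(grid: PBGrid, p: PBParameters) -> PotentialMap:
    """Solve the linearized PB equation by red-black SOR.

    Iterates to a relative residual (||b - A phi|| / ||b||) at or below
    ``p.tolerance`` or raises :class:`PBConvergenceError` with the residual
    history. A chargeless system returns the zero potential immediately.
    """
    h = grid.spacing
    b = 4.0 * np.pi * p.bjerrum_vacuum * grid.charge / h
    if not np.any(grid.charge):
        return PotentialMap(
            grid.origin, h, grid.dims, np.zeros(grid.dims), 0, 0.0, True
        )
    phi = _dh_boundary(grid, p)
    # face dielectrics (harmonic means between adjacent nodes)
    e = grid.eps
    ex = 2.0 * e[1:, :, :] * e[:-1, :, :] / (e[1:, :, :] + e[:-1, :, :])
    ey = 2.0 * e[:, 1:, :] * e[:, :-1, :] / (e[:, 1:, :] + e[:, :-1, :])
    ez = 2.0 * e[:, :, 1:] * e[:, :, :-1] / (e[:, :, 1:] + e[:, :, :-1])
    core = (slice(1, -1), slice(1, -1), slice(1, -1))
    diag = (
        ex[1:, 1:-1, 1:-1]
        + ex[:-1, 1:-1, 1:-1]
        + ey[1:-1, 1:, 1:-1]
        + ey[1:-1, :-1, 1:-1]
        + ez[1:-1, 1:-1, 1:]
        + ez[1:-1, 1:-1, :-1]
        + h * h * grid.kappa2_bar[core]
    )
    bc = b[core]
    bnorm = float(np.linalg.norm(bc))
    ii, jj, kk = np.indices(diag.shape)
    red = (ii + jj + kk) % 2 == 0
    black = ~red
    nmax = max(grid.dims)
    omega = 2.0 / (1.0 + np.sin(np.pi / nmax))

    def neighbor_sum() -> np.ndarray:
        return (
            ex[1:, 1:-1, 1:-1] * phi[2:, 1:-1, 1:-1]
            + ex[:-1, 1:-1, 1:-1] * phi[:-2, 1:-1, 1:-1]
            + ey[1:-1, 1:, 1:-1] * phi[1:-1, 2:, 1:-1]
            + ey[1:-1, :-1, 1:-1] * phi[1:-1, :-2, 1:-1]
            + ez[1:-1, 1:-1, 1:] * phi[1:-1, 1:-1, 2:]
            + ez[1:-1, 1:-1, :-1] * phi[1:-1, 1:-1, :-2]
        )

    history: list[float] = []
    rel = np.inf
    it = 0
    while it < p.max_iterations:
        for mask in (red, black):
            num = neighbor_sum()
            upd = (num + bc) / diag
            cur = phi[core]
            cur[mask] = (1.0 - omega) * cur[mask] + omega * upd[mask]
            phi[core] = cur
        it += 1
        if it % 10 == 0 or it == p.max_iterations:
            r = bc + neighbor_sum() - diag * phi[core]
            rel = float(np.linalg.norm(r) / bnorm)
            history.append(rel)
            if rel <= p.tolerance:
                return PotentialMap(grid.origin, h, grid.dims, phi, it, rel, True, history)
    raise PBConvergenceError(
        f"LPBE solver did not reach tolerance {p.tolerance} in {it} iterations "
        f"(final relative residual {rel:.3e})",
        history,
    )


@dataclass(frozen=True)
class EpResult:
    """Interface potential Ep: surface-point mean +/- sd, kT/e."""

    mean: float
    sd: float
    n_points: int
    method: str


def _region_atom_indices(s: Structure, region, chain: str | None) -> list[int]:
    """Resolve region residue keys to heavy solute atom indices."""
    keys = getattr(region, "residue_keys", region)
    chain = chain if chain is not None else getattr(region, "chain", None)
    wanted2 = {(rid, rn) for rid, rn in keys} if keys and len(keys[0]) == 2 else None
    wanted3 = {tuple(k) for k in keys} if keys and len(keys[0]) == 3 else None
    out = []
    for i, a in enumerate(s.atoms):
        if a.is_water or a.is_ion or a.element.upper() == "H":
            continue
        if wanted2 is not None:
            if chain is not None and a.chain != chain:
                continue
            if (a.resid, a.resname) in wanted2:
                out.append(i)
        elif wanted3 is not None and a.residue_key in wanted3:
            out.append(i)
    return out


def interface_potential(
    pmap: PotentialMap,
    s: Structure,
    region,
    p: PBParameters,
    n_surface_points: int = 240,
    method: str = "sas_points",
    chain: str | None = None,
) -> EpResult:
    """Average potential over the solvent-accessible surface of a region.

    ``method="sas_points"`` (default) interpolates the potential trilinearly
    at probe-inflated golden-spiral points of the region atoms that are not
    occluded by other solute atoms; ``method="nodes"`` averages the nearest
    grid node of each region atom instead.
    """
    idx = _region_atom_indices(s, region, chain)
    if not idx:
        raise ValueError("region resolves to no atoms on the structure")
    solute = [i for i, a in enumerate(s.atoms) if not a.is_water]
    xyz = s.coords
    radii = np.array(
        [s.atoms[i].radius if s.atoms[i].radius is not None else 1.7 for i in solute]
    )
    sxyz = xyz[solute]
    if method == "nodes":
        pts = xyz[idx]
        vals = pmap.interpolate(pts)
        return EpResult(float(vals.mean()), float(vals.std()), len(vals), method)
    if method != "sas_points":
        raise ValueError(f"unknown aggregation method {method!r}")
    sphere = golden_spiral_points(n_surface_points)
    pos_of = {g: k for k, g in enumerate(solute)}
    kept: list[np.ndarray] = []
    infl = radii + p.probe
    for i in idx:
        r_i = s.atoms[i].radius + p.probe
        pts = xyz[i] + r_i * sphere
        d2 = np.sum((pts[:, None, :] - sxyz[None, :, :]) ** 2, axis=2)
        d2[:, pos_of[i]] = np.inf
        free = np.all(d2 >= (infl[None, :] - 1e-9) ** 2, axis=1)
        if free.any():
            kept.append(pts[free])
    if not kept:
        raise ValueError("region surface is fully occluded")
    pts = np.vstack(kept)
    vals = pmap.interpolate(pts)
    return EpResult(float(vals.mean()), float(vals.std()), len(vals), method)


@dataclass(frozen=True)
class IonComplement:
    """Which species (if any) occupies each site in one PB scenario."""

    placements: dict[str, str | None]  # site label -> species symbol or None

    @property
    def total_charge(self) -> int:
        return sum(
            ion_species(sym).charge for sym in self.placements.values() if sym
        )

    def describe(self) -> str:
        occ = [f"{k}:{v}" for k, v in sorted(self.placements.items()) if v]
        return "+".join(occ) if occ else "none"


@dataclass
class ScanResult:
    table: pd.DataFrame  # complement, total_charge, ep, ep_sd
    reversal_charge: int | None  # minimal total charge with Ep > 0


def _place_ions(s: Structure, sites, complement: IonComplement) -> Structure:
    """Add complement ions at site centroids, nudging out of 1 A clashes."""
    tables = load_default_tables()
    by_label = {site.label: site for site in sites}
    atoms = list(s.atoms)
    xyz = s.coords
    serial = max((a.serial for a in s.atoms), default=0) + 1
    for label, sym in sorted(complement.placements.items()):
        if not sym:
            continue
        site = by_label[label]
        sp = ion_species(sym)
        pos = np.asarray(site.centroid, dtype=float).copy()
        for _ in range(40):
            d = np.linalg.norm(xyz - pos, axis=1)
            jmin = int(np.argmin(d))
            if d[jmin] >= 1.0:
                break
            away = pos - xyz[jmin]
            away = away / max(np.linalg.norm(away), 1e-9)
            pos = pos + 0.25 * away
        else:
            warnings.warn(f"could not fully resolve clash at {label}")
        if np.linalg.norm(pos - np.asarray(site.centroid)) > 1e-9:
            warnings.warn(f"ion at {label} nudged off the centroid to avoid a clash")
        atoms.append(
            Atom(
                serial,
                sp.symbol.upper(),
                sp.symbol,
                sp.symbol.upper(),
                800 + serial % 100,
                "Z",
                pos,
                radius=float(tables["radii"][sp.symbol.upper()]),
                partial_charge=float(sp.charge),
                is_ion=True,
                record="HETATM",
            )
        )
        serial += 1
    return Structure(atoms, s.title, s.source)


def charge_reversal_scan(
    s: Structure,
    sites,
    complements: list[IonComplement],
    region,
    p: PBParameters,
    chain: str | None = None,
    method: str = "sas_points",
) -> ScanResult:
    """Ep as a function of the bound-ion complement, on one shared grid.

    Runs one LPBE solve per complement (all on identical grid geometry so
    the Ep values are comparable), tabulates Ep against the total charge
    added by the bound cations, and reports the charge-reversal point: the
    smallest total charge whose Ep is positive, or None within the scan.
    """
    complements = sorted(complements, key=lambda c: c.total_charge)
    # fixed geometry covering the protein and every possible placed ion
    all_pts = [s.coords]
    for site in sites:
        all_pts.append(np.asarray(site.centroid, dtype=float).reshape(1, 3))
    pts = np.vstack(all_pts)
    h = p.grid_spacing
    lo = pts.min(axis=0) - p.padding
    hi = pts.max(axis=0) + p.padding
    dims = tuple(int(np.ceil((hi[d] - lo[d]) / h)) + 1 for d in range(3))
    rows = []
    for comp in complements:
        loaded = _place_ions(s, sites, comp)
        grid = build_grid(loaded, p, bounds=(lo, dims))
        pmap = solve_lpbe(grid, p)
        ep = interface_potential(pmap, loaded, region, p, method=method, chain=chain)
        rows.append(
            {
                "complement": comp.describe(),
                "total_charge": comp.total_charge,
                "ep": ep.mean,
                "ep_sd": ep.sd,
            }
        )
    table = pd.DataFrame(rows)
    positive = table[table["ep"] > 0.0]
    reversal = int(positive["total_charge"].min()) if len(positive) else None
    return ScanResult(table=table, reversal_charge=reversal)


def write_opendx(pmap: PotentialMap, path) -> None:
    """Write the potential map as an OpenDX scalar grid (kT/e)."""
    nx, ny, nz = pmap.dims
    ox, oy, oz = pmap.origin
    h = pmap.spacing
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {ox:.6e} {oy:.6e} {oz:.6e}\n")
        fh.write(f"delta {h:.6e} 0.0 0.0\n")
        fh.write(f"delta 0.0 {h:.6e} 0.0\n")
        fh.write(f"delta 0.0 0.0 {h:.6e}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {nx * ny * nz} data follows\n"
        )
        flat = pmap.phi.ravel(order="C")
        for i in range(0, len(flat), 3):
            fh.write(" ".join(f"{v:.6e}" for v in flat[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "potential" class field\n')
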