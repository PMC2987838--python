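"""Solvent-accessible surface areas and interface determination.

Shrake-Rupley SASA with a deterministic golden-spiral point set (no RNG),
interface regions defined by per-residue accessibility loss between free
and complexed structures, cation accessibility with or without the
coordinating first-shell waters, and formal net charge of a residue region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .solvation_shell import coordination_sphere, default_cutoff
from .structure_io import Structure

__all__ = [
    "SASAResult",
    "InterfaceRegion",
    "golden_spiral_points",
    "shrake_rupley",
    "interface_residues",
    "ion_accessibility",
    "region_net_charge",
    "FORMAL_RESIDUE_CHARGE",
]

DEFAULT_PROBE = 1.4  # A, water-sized probe
DEFAULT_N_POINTS = 960

FORMAL_RESIDUE_CHARGE = {"ASP": -1, "GLU": -1, "LYS": 1, "ARG": 1}

_POINT_CACHE: dict[int, np.ndarray] = {}


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden-angle spiral)."""
    if n not in _POINT_CACHE:
        k = np.arange(n) + 0.5
        phi = np.arccos(1.0 - 2.0 * k / n)
        theta = np.pi * (1.0 + np.sqrt(5.0)) * k
        _POINT_CACHE[n] = np.stack(
            [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
            axis=1,
        )
    return _POINT_CACHE[n]


@dataclass(frozen=True)
class SASAResult:
    per_atom: np.ndarray  # A^2, aligned with the input structure's atoms
    per_residue: dict[tuple[str, int, str], float]
    probe: float
    n_points: int

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


def _radii(s: Structure) -> np.ndarray:
    r = np.empty(len(s))
    for i, a in enumerate(s.atoms):
        if a.radius is None:
            raise ValueError(
                f"atom {a.serial} {a.name} ({a.resname}{a.resid}) has no radius; "
                "run assign_properties first"
            )
        r[i] = a.radius
    return r


def shrake_rupley(
    s: Structure,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> SASAResult:
    """Shrake-Rupley SASA of every atom in the structure.

    Each atom's accessible sphere (radius r_i + probe) is sampled with a
    deterministic golden-spiral point set; a point is exposed when outside
    every neighbor's accessible sphere.  Per-atom area =
    (exposed / n_points) x 4 pi (r_i + probe)^2; per-residue areas are sums
    over member atoms.
    """
    xyz = s.coords
    radii = _radii(s) + probe
    n = len(s)
    sphere = golden_spiral_points(n_points)
    areas = np.zeros(n)
    if n == 0:
        return SASAResult(areas, {}, probe, n_points)
    tree = cKDTree(xyz)
    rmax = radii.max()
    for i in range(n):
        pts = xyz[i] + radii[i] * sphere
        neighbors = [j for j in tree.query_ball_point(xyz[i], radii[i] + rmax) if j != i]
        exposed = np.ones(n_points, dtype=bool)
        if neighbors:
            nb = np.asarray(neighbors)
            # keep only true overlaps
            close = np.linalg.norm(xyz[nb] - xyz[i], axis=1) < radii[i] + radii[nb]
            nb = nb[close]
            for j in nb:
                if not exposed.any():
                    break
                d2 = np.sum((pts[exposed] - xyz[j]) ** 2, axis=1)
                still = d2 >= radii[j] ** 2
                idx = np.flatnonzero(exposed)
                exposed[idx[~still]] = False
        areas[i] = exposed.sum() / n_points * 4.0 * np.pi * radii[i] ** 2
    per_res: dict[tuple[str, int, str], float] = {}
    for key, members in s.residues():
        per_res[key] = float(areas[members].sum())
    return SASAResult(areas, per_res, probe, n_points)


@dataclass(frozen=True)
class InterfaceRegion:
    """Residues losing solvent accessibility upon complexation."""

    residue_keys: list[tuple[int, str]]  # (resid, resname) on the studied chain
    delta_sasa: dict[tuple[int, str], float]  # free - complexed, A^2
    net_charge: int
    chain: str
    threshold: float


def _strip_solvent(s: Structure) -> Structure:
    keep = [i for i, a in enumerate(s.atoms) if not a.is_water and not a.is_ion]
    return s.subset(keep)


def _chain_residue_sasa(
    s: Structure, chain: str, probe: float, n_points: int
) -> dict[tuple[int, str], float]:
    res = shrake_rupley(s, probe, n_points)
    out: dict[tuple[int, str], float] = {}
    for (ch, rid, rname), area in res.per_residue.items():
        if ch == chain:
            out[(rid, rname)] = out.get((rid, rname), 0.0) + area
    return out


def interface_residues(
    free: Structure,
    complexed: Structure | list[Structure],
    chain: str,
    threshold: float = 1.0,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    mode: str = "union",
) -> InterfaceRegion:
    """Chain residues whose SASA drops by >= ``threshold`` upon complexation.

    Waters and ions are stripped before the SASA calculations. Residues are
    matched between the free and complexed structures by (resid, resname);
    a mismatch is an error listing the offending residues. With several
    complexes, the union of per-complex interfaces is taken by default
    (``mode="intersection"`` for the common core).
    """
    complexes = complexed if isinstance(complexed, list) else [complexed]
    if mode not in ("union", "intersection"):
        raise ValueError("mode must be 'union' or 'intersection'")
    free_s = _strip_solvent(free)
    sasa_free = _chain_residue_sasa(free_s, chain, probe, n_points)
    if not sasa_free:
        raise ValueError(f"chain {chain!r} not present in the free structure")
    member_sets: list[set[tuple[int, str]]] = []
    deltas: dict[tuple[int, str], float] = {}
    for cs in complexes:
        sasa_cplx = _chain_residue_sasa(_strip_solvent(cs), chain, probe, n_points)
        unmatched = sorted(set(sasa_free) - set(sasa_cplx))
        if unmatched:
            raise ValueError(
                f"residues of chain {chain} absent from the complex: {unmatched}"
            )
        members: set[tuple[int, str]] = set()
        for key, a_free in sasa_free.items():
            d = a_free - sasa_cplx[key]
            if d >= threshold:
                members.add(key)
                deltas[key] = max(deltas.get(key, -np.inf), d) if mode == "union" else d
        member_sets.append(members)
    final = set.union(*member_sets) if mode == "union" else set.intersection(*member_sets)
    keys = sorted(final)
    net = sum(FORMAL_RESIDUE_CHARGE.get(rname.upper(), 0) for _, rname in keys)
    return InterfaceRegion(
        residue_keys=keys,
        delta_sasa={k: deltas[k] for k in keys},
        net_charge=net,
        chain=chain,
        threshold=threshold,
    )


def ion_accessibility(
    frame: Structure,
    ion: int,
    exclude_coordinating_waters: bool = True,
    cutoff: float | None = None,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> float:
    """SASA (A^2) of one bound cation with respect to the solute.

    Bulk waters are always removed (accessibility is defined against the
    solute surface); the first-shell waters are removed too when
    ``exclude_coordinating_waters`` is set, giving the accessibility of the
    ion devoid of its coordinating water molecules. ``cutoff`` defaults to
    the species first-shell cutoff.
    """
    if not (0 <= ion < len(frame)) or not frame.atoms[ion].is_ion:
        raise ValueError(f"atom index {ion} is not an ion")
    if cutoff is None:
        cutoff = default_cutoff(frame.atoms[ion].resname)
    shell_waters: set[tuple[str, int, str]] = set()
    if not exclude_coordinating_waters:
        rec = coordination_sphere(frame, ion, cutoff)
        shell_waters = rec.water_residues
    keep: list[int] = []
    ion_pos = None
    for i, a in enumerate(frame.atoms):
        if a.is_water and a.residue_key not in shell_waters:
            continue
        if i == ion:
            ion_pos = len(keep)
        keep.append(i)
    sub = frame.subset(keep)
    res = shrake_rupley(sub, probe, n_points)
    return float(res.per_atom[ion_pos])


def region_net_charge(
    s: Structure,
    region: list[tuple[int, str]] | list[tuple[str, int, str]],
    scheme: str = "formal",
) -> int:
    """Formal net charge (e) of a residue region.

    Asp/Glu count -1, Arg/Lys +1, His 0 (neutral histidines); everything
    else 0. Region entries are (resid, resname) or (chain, resid, resname);
    a region residue absent from the structure is an error.
    """
    if scheme != "formal":
        raise ValueError("only the formal scheme is defined for net charge")
    present2 = {(a.resid, a.resname) for a in s.atoms}
    present3 = {a.residue_key for a in s.atoms}
    total = 0
    for key in region:
        if len(key) == 2:
            rid, rname = key
            if (rid, rname) not in present2:
                raise KeyError(f"region residue {key} absent from structure")
        else:
            ch, rid, rname = key
            if (ch, rid, rname) not in present3:
                raise KeyError(f"region residue {key} absent from structure")
        total += FORMAL_RESIDUE_CHARGE.get(str(rname).upper(), 0)
    return total
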