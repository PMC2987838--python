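"""Coordination-polyhedron classification.

Bound-cation coordination spheres in proteins fall, for the species handled
here, into two idealized shapes: the octahedron (CN 6, typical of Mg2+ and
Na+) and the tricapped trigonal prism (CN 9, high-coordination Ca2+).  A
ligand shell is classified by fitting the corresponding ideal template --
scaled to the observed mean bond length -- over all rotations and
vertex-to-ligand assignments; the residual RMSD is the distortion score.

The assignment search is a Hungarian-assisted iterative-closest-point from a
deterministic bank of starting rotations; for CN 6 it is exact (verified
against exhaustive 720-permutation enumeration in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.transform import Rotation

from .ensemble_metrics import kabsch_rotation
from .structure_io import load_default_tables

__all__ = [
    "GeometryAssignment",
    "octahedron_vertices",
    "ttp_vertices",
    "classify_polyhedron",
    "DEFAULT_DISTORTION_THRESHOLD",
]

DEFAULT_DISTORTION_THRESHOLD = float(
    load_default_tables()["geometry"]["distortion_threshold"]
)
_TTP_RATIO = float(load_default_tables()["geometry"]["ttp_height_edge_ratio"])


@dataclass(frozen=True)
class GeometryAssignment:
    geometry_class: str  # "octahedral" | "tricapped_trigonal_prism" | "other"
    distortion: float  # A, RMSD to the best-fit scaled ideal template
    cn: int


def octahedron_vertices() -> np.ndarray:
    """Unit vertices of the ideal octahedron (the six +/- axis directions)."""
    return np.array(
        [
            [1, 0, 0],
            [-1, 0, 0],
            [0, 1, 0],
            [0, -1, 0],
            [0, 0, 1],
            [0, 0, -1],
        ],
        dtype=float,
    )


def ttp_vertices(height_edge_ratio: float | None = None) -> np.ndarray:
    """Unit vertices of the ideal tricapped trigonal prism (D3h).

    Six prism vertices form two parallel equilateral triangles (edge a,
    separation ``height_edge_ratio * a``); the three caps sit on the
    normals of the rectangular faces at the prism mid-height. All nine
    vertices are normalized to the unit sphere, matching a coordination
    shell with a single bond length.
    """
    ratio = _TTP_RATIO if height_edge_ratio is None else height_edge_ratio
    a = 1.0
    rho = a / np.sqrt(3.0)  # triangle circumradius
    h = ratio * a
    verts = []
    for z in (h / 2.0, -h / 2.0):
        for ang in (0.0, 2 * np.pi / 3, 4 * np.pi / 3):
            verts.append([rho * np.cos(ang), rho * np.sin(ang), z])
    for ang in (np.pi / 3, np.pi, 5 * np.pi / 3):  # cap directions, offset 60 deg
        verts.append([np.cos(ang), np.sin(ang), 0.0])
    v = np.asarray(verts)
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _rotation_bank(n_random: int = 40, seed: int = 7) -> list[np.ndarray]:
    """Deterministic starting rotations: octahedral group + quasi-random fill."""
    bank = [r.as_matrix() for r in Rotation.create_group("O")]
    rng = np.random.default_rng(seed)
    bank.extend(Rotation.random(n_random, random_state=rng).as_matrix())
    return bank


_BANK = _rotation_bank()


def _fit_template(points: np.ndarray, template: np.ndarray) -> float:
    """Best RMSD between ion-centered ligand points and a scaled template.

    Minimizes over rotations and vertex assignments by alternating Hungarian
    assignment and Kabsch rotation from each rotation in the deterministic
    bank; returns the lowest RMSD found.
    """
    n = len(points)
    scale = float(np.mean(np.linalg.norm(points, axis=1)))
    tmpl = template * scale
    best = np.inf
    for r0 in _BANK:
        r = r0
        prev_perm = None
        for _ in range(60):
            rotated = tmpl @ r.T
            cost = np.sum((points[:, None, :] - rotated[None, :, :]) ** 2, axis=2)
            rows, cols = linear_sum_assignment(cost)
            perm = cols[np.argsort(rows)]
            if prev_perm is not None and np.array_equal(perm, prev_perm):
                break
            prev_perm = perm
            r = kabsch_rotation(tmpl[perm], points)
        rotated = tmpl[prev_perm] @ r.T
        rmsd = float(np.sqrt(np.mean(np.sum((rotated - points) ** 2, axis=1))))
        best = min(best, rmsd)
    return best


def classify_polyhedron(
    ion: np.ndarray,
    ligands: np.ndarray,
    threshold: float | None = None,
) -> GeometryAssignment:
    """Classify a coordination shell as octahedral, tricapped trigonal prism
    or other.

    ``ligands`` are absolute positions; the shell is centered on the ion,
    the matching ideal template (CN 6 -> octahedron, CN 9 -> prism) is
    scaled to the mean bond length and fitted over rotations and vertex
    permutations. The class is assigned when the residual RMSD (distortion)
    is at most ``threshold``; any other CN, or a distortion above threshold,
    yields "other". Classification is invariant under rotation, translation,
    uniform scaling and ligand reordering.
    """
    thr = DEFAULT_DISTORTION_THRESHOLD if threshold is None else threshold
    ion = np.asarray(ion, dtype=float)
    pts = np.asarray(ligands, dtype=float) - ion
    if len(pts) < 2:
        raise ValueError("classification needs at least 2 ligands")
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=2)
    np.fill_diagonal(d2, np.inf)
    if np.min(d2) < 1e-12:
        raise ValueError("coincident ligand points")
    cn = len(pts)
    if cn == 6:
        distortion = _fit_template(pts, octahedron_vertices())
        cls = "octahedral" if distortion <= thr else "other"
    elif cn == 9:
        distortion = _fit_template(pts, ttp_vertices())
        cls = "tricapped_trigonal_prism" if distortion <= thr else "other"
    else:
        return GeometryAssignment("other", float("inf"), cn)
    return GeometryAssignment(cls, distortion, cn)
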