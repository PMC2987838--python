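"""LPBE solver: charge spreading, Born-ion closed form, linearity, Ep scans."""

import itertools

import numpy as np
import pytest

from ionsite import (
    PBParameters,
    assign_properties,
    build_grid,
    interface_potential,
    make_born_system,
    solve_lpbe,
)
from ionsite.electrostatics import (
    IonComplement,
    PBConvergenceError,
    charge_reversal_scan,
    write_opendx,
)
from ionsite.structure_io import Atom, Structure
from ionsite.synthetic_data import make_acidic_patch

UNIFORM = dict(solute_dielectric=78.4, stern_layer=0.0)


def _born(q=2.0, radius=1.71, spacing=0.5, box=30.0, **kw):
    s = make_born_system(q, radius, box)
    p = PBParameters(grid_spacing=spacing, padding=12.0, **{**UNIFORM, **kw})
    return s, p


def test_debye_parameters_physiological():
    p = PBParameters()
    assert 1.0 / p.kappa == pytest.approx(7.85, abs=0.15)  # Debye length, A
    assert p.bjerrum_vacuum / p.solvent_dielectric == pytest.approx(7.15, abs=0.1)


def test_charge_spreading_conserves_charge_and_dipole():
    atoms = [
        Atom(1, "O", "O", "GLU", 1, "A", np.array([14.83, 15.21, 15.4]),
             radius=1.52, partial_charge=-0.5),
        Atom(2, "N", "N", "LYS", 2, "A", np.array([16.4, 14.9, 14.63]),
             radius=1.55, partial_charge=1.0),
    ]
    s = Structure(atoms)
    p = PBParameters(grid_spacing=0.6, padding=10.0)
    grid = build_grid(s, p)
    assert grid.charge.sum() == pytest.approx(0.5, abs=1e-9)
    # dipole of the spread density equals the point-charge dipole
    ax = [grid.origin[d] + grid.spacing * np.arange(grid.dims[d]) for d in range(3)]
    xg, yg, zg = np.meshgrid(*ax, indexing="ij")
    spread = np.array(
        [(grid.charge * g).sum() for g in (xg, yg, zg)]
    )
    point = sum(a.partial_charge * a.coords for a in atoms)
    assert np.allclose(spread, point, atol=1e-9)


def test_charge_on_a_grid_node_collapses_to_that_node():
    s = make_born_system(2.0, 1.71, box=30.0)  # center 15.0 lies on a 0.5 A node
    p = PBParameters(grid_spacing=0.5, padding=12.0, **UNIFORM)
    grid = build_grid(s, p)
    node = np.round((np.array([15.0] * 3) - grid.origin) / 0.5).astype(int)
    assert grid.charge[tuple(node)] == pytest.approx(2.0, abs=1e-12)
    assert np.count_nonzero(np.abs(grid.charge) > 1e-12) == 1


def test_born_sphere_dielectric_map():
    s = make_born_system(2.0, 2.0, box=24.0)
    p = PBParameters(grid_spacing=0.5, padding=9.0)
    grid = build_grid(s, p)
    ax = [grid.origin[d] + 0.5 * np.arange(grid.dims[d]) - 12.0 for d in range(3)]
    d = np.sqrt(
        ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2 + ax[2][None, None, :] ** 2
    )
    assert np.all(grid.eps[d <= 2.0 - 0.51] == p.solute_dielectric)
    assert np.all(grid.eps[d >= 2.0 + p.probe + 0.51] == p.solvent_dielectric)
    assert np.all(grid.kappa2_bar[d <= 2.0 + p.stern_layer - 0.51] == 0.0)


def test_structure_must_fit_in_the_box():
    s = make_born_system(1.0, 1.71, box=30.0)
    p = PBParameters(grid_spacing=0.5, padding=12.0)
    with pytest.raises(ValueError, match="fit"):
        build_grid(s, p, bounds=(np.array([14.0, 14.0, 14.0]), (8, 8, 8)))


def test_zero_charge_system_has_zero_potential():
    s, p = _born(q=0.0)
    pmap = solve_lpbe(build_grid(s, p), p)
    assert pmap.converged
    assert np.all(pmap.phi == 0.0)


def test_born_ion_matches_debye_hueckel_closed_form():
    """q=+2, R=1.71 A, 150 mM, 298.15 K: numeric potential within 5% of the
    screened-Coulomb analytic solution over r in [R+2, box/2-5] at 0.5 A."""
    q, R = 2.0, 1.71
    s, p = _born(q, R, spacing=0.5)
    pmap = solve_lpbe(build_grid(s, p), p)
    kap, lb = p.kappa, p.bjerrum_vacuum
    center = np.array([15.0, 15.0, 15.0])
    dirs = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1] / np.sqrt(3)], dtype=float)
    dirs[3] /= np.linalg.norm(dirs[3])
    for r in np.arange(R + 2.0, 10.0 + 1e-9, 0.5):
        ana = q * lb / (p.solvent_dielectric * r) * np.exp(-kap * (r - R)) / (1 + kap * R)
        for d in dirs:
            num = pmap.interpolate(center + r * d)[0]
            assert num == pytest.approx(ana, rel=0.05)


def test_lpbe_linearity_superposition():
    """phi(q1 + q2) equals phi(q1) + phi(q2) on a shared grid."""
    p = PBParameters(grid_spacing=0.6, padding=10.0)
    a1 = Atom(1, "O", "O", "GLU", 1, "A", np.array([13.0, 15.0, 15.0]),
              radius=1.52, partial_charge=-1.0)
    a2 = Atom(2, "N", "N", "LYS", 2, "A", np.array([17.0, 15.0, 15.0]),
              radius=1.55, partial_charge=1.0)
    both = Structure([a1, a2])
    bounds_grid = build_grid(both, p)
    bounds = (bounds_grid.origin, bounds_grid.dims)
    phi_both = solve_lpbe(build_grid(both, p, bounds=bounds), p).phi
    only1 = Structure([a1, Atom(2, "N", "N", "LYS", 2, "A", a2.coords,
                                radius=1.55, partial_charge=0.0)])
    only2 = Structure([Atom(1, "O", "O", "GLU", 1, "A", a1.coords,
                            radius=1.52, partial_charge=0.0), a2])
    phi1 = solve_lpbe(build_grid(only1, p, bounds=bounds), p).phi
    phi2 = solve_lpbe(build_grid(only2, p, bounds=bounds), p).phi
    scale = np.abs(phi1).max()
    assert np.abs(phi_both - (phi1 + phi2)).max() <= 5e-3 * scale


def test_potential_scales_linearly_with_charge():
    s1, p = _born(q=1.0, spacing=0.6)
    s2, _ = _born(q=2.0, spacing=0.6)
    g1 = build_grid(s1, p)
    m1 = solve_lpbe(g1, p)
    m2 = solve_lpbe(build_grid(s2, p, bounds=(g1.origin, g1.dims)), p)
    mask = np.abs(m1.phi) > 1e-3
    assert np.allclose(m2.phi[mask] / m1.phi[mask], 2.0, atol=2e-3)


def test_grid_refinement_consistency():
    """Halving the spacing moves the Born surface potential by < 3%."""
    q, R = 2.0, 1.71
    center = np.array([12.0, 12.0, 12.0])
    vals = []
    for spacing in (0.6, 0.3):
        s = make_born_system(q, R, box=24.0)
        p = PBParameters(grid_spacing=spacing, padding=9.0, **UNIFORM)
        pmap = solve_lpbe(build_grid(s, p), p)
        pts = center + (R + 2.0) * np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        vals.append(pmap.interpolate(pts).mean())
    assert abs(vals[1] - vals[0]) / abs(vals[1]) < 0.03


def test_non_convergence_raises_with_history():
    s, p = _born(q=2.0, spacing=0.6)
    strict = PBParameters(grid_spacing=0.6, padding=12.0, max_iterations=10,
                          tolerance=1e-14, **UNIFORM)
    with pytest.raises(PBConvergenceError) as err:
        solve_lpbe(build_grid(s, strict), strict)
    assert len(err.value.history) >= 1


@pytest.fixture(scope="module")
def patch_scan():
    s, sites, region = make_acidic_patch()
    s = assign_properties(s)
    p = PBParameters(grid_spacing=0.8, padding=9.0)
    labels = [x.label for x in sites]
    return s, sites, region, p, labels


def test_uncharged_region_has_zero_ep(patch_scan):
    s, sites, region, p, labels = patch_scan
    neutral = Structure(
        [Atom(a.serial, a.name, a.element, "GLY", a.resid, a.chain, a.coords,
              radius=a.radius, partial_charge=0.0) for a in s.atoms]
    )
    grid = build_grid(neutral, p)
    pmap = solve_lpbe(grid, p)
    ep = interface_potential(pmap, neutral, [(rid, "GLY") for rid, _ in region], p)
    assert ep.mean == 0.0


def test_buried_positive_charge_gives_positive_ep(patch_scan):
    s, sites, region, p, labels = patch_scan
    lone = Structure(
        [Atom(1, "NZ", "N", "LYS", 1, "A", np.array([6.0, 6.0, 0.0]),
              radius=1.55, partial_charge=1.0)]
    )
    pmap = solve_lpbe(build_grid(lone, p), p)
    ep = interface_potential(pmap, lone, [(1, "LYS")], p)
    assert ep.mean > 0


def test_ep_strictly_increases_with_added_cations(patch_scan):
    s, sites, region, p, labels = patch_scan
    comps = [
        IonComplement({l: ("MG" if i < k else None) for i, l in enumerate(labels)})
        for k in range(len(labels) + 1)
    ]
    scan = charge_reversal_scan(s, sites, comps, region, p)
    eps = scan.table["ep"].to_numpy()
    assert np.all(np.diff(eps) > 0)
    assert scan.table["total_charge"].tolist() == [0, 2, 4, 6, 8]


def test_reversal_point_matches_exhaustive_complement_scan(patch_scan):
    s, sites, region, p, labels = patch_scan
    nested = [
        IonComplement({l: ("MG" if i < k else None) for i, l in enumerate(labels)})
        for k in range(len(labels) + 1)
    ]
    nested_scan = charge_reversal_scan(s, sites, nested, region, p)
    exhaustive = [
        IonComplement({l: ("MG" if b else None) for l, b in zip(labels, bits)})
        for bits in itertools.product([False, True], repeat=len(labels))
    ]
    full_scan = charge_reversal_scan(s, sites, exhaustive, region, p)
    assert nested_scan.reversal_charge == full_scan.reversal_charge
    assert nested_scan.reversal_charge is not None


def test_no_sites_means_no_reversal(patch_scan):
    s, sites, region, p, labels = patch_scan
    scan = charge_reversal_scan(s, [], [IonComplement({})], region, p)
    assert scan.reversal_charge is None
    assert scan.table["ep"].iloc[0] < 0  # the naked patch is negative


def test_opendx_output_roundtrips_header(tmp_path):
    s, p = _born(q=1.0, spacing=0.8, box=20.0)
    p = PBParameters(grid_spacing=0.8, padding=8.0, **UNIFORM)
    pmap = solve_lpbe(build_grid(s, p), p)
    out = tmp_path / "pot.dx"
    write_opendx(pmap, out)
    text = out.read_text().splitlines()
    assert text[0].startswith("object 1 class gridpositions counts")
    counts = tuple(int(x) for x in text[0].split()[-3:])
    assert counts == pmap.dims
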