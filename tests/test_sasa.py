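"""SASA closed forms, interface detection oracle, ion accessibility, charges."""

import numpy as np
import pytest

from ionsite import (
    TrajectorySpec,
    assign_properties,
    interface_residues,
    ion_accessibility,
    make_two_body_complex,
    region_net_charge,
    shrake_rupley,
)
from ionsite.sasa import golden_spiral_points
from ionsite.structure_io import Atom, Structure
from ionsite.synthetic_data import make_pocket_ensemble


def _sphere_atoms(specs):
    """specs: list of (pos, radius) -> structure of bare carbon spheres."""
    return Structure(
        [
            Atom(i + 1, "C", "C", "GLY", i + 1, "A", np.asarray(p, float), radius=r)
            for i, (p, r) in enumerate(specs)
        ]
    )


def test_isolated_sphere_matches_closed_form():
    r = 1.52
    res = shrake_rupley(_sphere_atoms([((0, 0, 0), r)]), probe=1.4, n_points=960)
    exact = 4 * np.pi * (r + 1.4) ** 2
    assert res.total == pytest.approx(exact, rel=0.02)


def test_two_sphere_overlap_matches_closed_form():
    r, d = 1.7, 2.0
    res = shrake_rupley(_sphere_atoms([((0, 0, 0), r), ((d, 0, 0), r)]), 1.4, 960)
    big_r = r + 1.4
    h = big_r - d / 2
    exact = 2 * 4 * np.pi * big_r**2 - 2 * 2 * np.pi * big_r * h
    assert res.total == pytest.approx(exact, rel=0.02)


def test_enclosed_atom_has_zero_area():
    cage = [(3.0 * v, 1.9) for v in golden_spiral_points(60)]
    s = _sphere_atoms([((0.0, 0.0, 0.0), 1.5)] + cage)
    res = shrake_rupley(s)
    assert res.per_atom[0] == 0.0


def test_sasa_additive_over_distant_molecules():
    near = _sphere_atoms([((0, 0, 0), 1.7), ((2.5, 0, 0), 1.5)])
    far_copy = _sphere_atoms(
        [((100.0, 0, 0), 1.7), ((102.5, 0, 0), 1.5)]
    )
    both = Structure(near.atoms + [a for a in far_copy.atoms])
    total = shrake_rupley(both).total
    assert total == pytest.approx(shrake_rupley(near).total + shrake_rupley(far_copy).total, abs=1e-9)


def test_adding_an_atom_never_increases_existing_areas():
    base = _sphere_atoms([((0, 0, 0), 1.7), ((3.0, 0, 0), 1.5)])
    grown = _sphere_atoms([((0, 0, 0), 1.7), ((3.0, 0, 0), 1.5), ((1.5, 1.5, 0), 1.6)])
    a0 = shrake_rupley(base).per_atom
    a1 = shrake_rupley(grown).per_atom[:2]
    assert np.all(a1 <= a0 + 1e-9)


def test_point_count_convergence_on_two_sphere_fixture():
    s = _sphere_atoms([((0, 0, 0), 1.7), ((2.0, 0, 0), 1.7)])
    t1 = shrake_rupley(s, n_points=960).total
    t2 = shrake_rupley(s, n_points=1920).total
    assert abs(t2 - t1) / t1 < 0.01


def test_missing_radius_is_an_error():
    s = Structure([Atom(1, "C", "C", "GLY", 1, "A", np.zeros(3))])
    with pytest.raises(ValueError, match="radius"):
        shrake_rupley(s)


def _brute_force_interface(free, cplx, chain, threshold, probe=1.4, n_points=960):
    """Independent per-atom point-counting oracle (single-atom residues)."""
    losses = {}
    f_xyz, f_r = free.coords, np.array([a.radius for a in free.atoms])
    c_xyz, c_r = cplx.coords, np.array([a.radius for a in cplx.atoms])
    sphere = golden_spiral_points(n_points)
    for i, a in enumerate(free.atoms):
        if a.chain != chain:
            continue

        def area(xyz, radii, k):
            pts = xyz[k] + (radii[k] + probe) * sphere
            ok = np.ones(n_points, bool)
            for j in range(len(xyz)):
                if j == k:
                    continue
                ok &= np.sum((pts - xyz[j]) ** 2, axis=1) >= (radii[j] + probe) ** 2
            return ok.sum() / n_points * 4 * np.pi * (radii[k] + probe) ** 2

        ci = next(
            j
            for j, b in enumerate(cplx.atoms)
            if b.chain == a.chain and b.resid == a.resid and b.name == a.name
        )
        delta = area(f_xyz, f_r, i) - area(c_xyz, c_r, ci)
        if delta >= threshold:
            losses[(a.resid, a.resname)] = delta
    return losses


def test_interface_equals_brute_force_oracle_at_close_separation():
    free, cplx = make_two_body_complex(sep=4.0)
    free, cplx = assign_properties(free), assign_properties(cplx)
    region = interface_residues(free, cplx, chain="A", threshold=1.0)
    oracle = _brute_force_interface(free, cplx, "A", 1.0)
    assert set(region.residue_keys) == set(oracle)
    for key in oracle:
        assert region.delta_sasa[key] == pytest.approx(oracle[key], abs=1e-9)
    # the facing layer faces chain B; the back layer does not
    facing = {rid for rid, _ in region.residue_keys}
    assert facing == set(range(1, 10))


def test_interface_residue_mismatch_is_reported():
    free, cplx = make_two_body_complex(sep=4.0)
    free, cplx = assign_properties(free), assign_properties(cplx)
    broken = cplx.subset([i for i, a in enumerate(cplx.atoms) if not (a.chain == "A" and a.resid == 1)])
    with pytest.raises(ValueError, match="absent"):
        interface_residues(free, broken, chain="A")


def test_union_and_intersection_over_multiple_complexes():
    free, close = make_two_body_complex(sep=4.0)
    _, farther = make_two_body_complex(sep=6.5)
    free, close, farther = (assign_properties(x) for x in (free, close, farther))
    union = interface_residues(free, [close, farther], "A", mode="union")
    inter = interface_residues(free, [close, farther], "A", mode="intersection")
    assert set(inter.residue_keys) <= set(union.residue_keys)


def test_bare_ion_accessibility_closed_form():
    mg = Atom(1, "MG", "Mg", "MG", 1, "I", np.zeros(3), radius=1.18,
              is_ion=True, record="HETATM")
    s = Structure([mg])
    area = ion_accessibility(s, 0, cutoff=2.9)
    assert area == pytest.approx(4 * np.pi * (1.18 + 1.4) ** 2, rel=0.02)


def test_caged_ion_has_zero_accessibility():
    mg = Atom(1, "MG", "Mg", "MG", 1, "I", np.zeros(3), radius=1.18,
              is_ion=True, record="HETATM")
    cage = [
        Atom(i + 2, "C", "C", "GLY", i + 2, "A", 3.0 * v, radius=1.9)
        for i, v in enumerate(golden_spiral_points(60))
    ]
    s = Structure([mg] + cage)
    assert ion_accessibility(s, 0, cutoff=2.9) == 0.0


def test_excluding_coordinating_waters_opens_the_ion_surface(mg_octa_spec):
    ens, lay = make_pocket_ensemble(
        mg_octa_spec, TrajectorySpec(1, 1.0, 0.0, seed=2), return_layout=True
    )
    fr = assign_properties(ens.frames[0])
    with_waters = ion_accessibility(fr, lay.ion_index, exclude_coordinating_waters=False)
    without = ion_accessibility(fr, lay.ion_index, exclude_coordinating_waters=True)
    assert with_waters < without


def test_region_net_charge_rules(perfect_octa):
    ens, lay = perfect_octa
    fr = ens.frames[0]
    asp = lay.donor_residue_keys[0]
    assert region_net_charge(fr, [asp]) == -1
    assert region_net_charge(fr, [(asp[1], "ASP")]) == -1
    gly_keys = sorted({a.residue_key for a in fr.atoms if a.resname == "GLY"})
    assert region_net_charge(fr, gly_keys) == 0
    with pytest.raises(KeyError, match="absent"):
        region_net_charge(fr, [(999, "ARG")])


def test_sasa_agrees_with_independent_biotite_implementation(mg_octa_spec):
    """Cross-check against biotite's Shrake-Rupley (same Bondi radii set)."""
    biotite_struc = pytest.importorskip("biotite.structure")
    ens, _ = make_pocket_ensemble(
        mg_octa_spec, TrajectorySpec(1, 1.0, 0.0, seed=2), return_layout=True
    )
    fr = assign_properties(ens.frames[0])
    sub = fr.subset([i for i, a in enumerate(fr.atoms) if not a.is_water and not a.is_ion])
    mine = shrake_rupley(sub, 1.4, 960)
    arr = biotite_struc.AtomArray(len(sub))
    arr.coord = sub.coords.astype(np.float32)
    arr.element = np.array([a.element.upper() for a in sub.atoms])
    arr.res_id = np.array([a.resid for a in sub.atoms])
    arr.res_name = np.array([a.resname for a in sub.atoms])
    arr.atom_name = np.array([a.name for a in sub.atoms])
    arr.chain_id = np.array([a.chain for a in sub.atoms])
    ref = biotite_struc.sasa(arr, probe_radius=1.4, point_number=960, vdw_radii="Single")
    assert mine.total == pytest.approx(float(ref.sum()), rel=0.01)


def test_asp_plus_arg_region_is_neutral():
    atoms = [
        Atom(1, "CA", "C", "ASP", 1, "A", np.zeros(3)),
        Atom(2, "CA", "C", "ARG", 2, "A", np.array([5.0, 0, 0])),
    ]
    s = Structure(atoms)
    assert region_net_charge(s, [(1, "ASP"), (2, "ARG")]) == 0
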