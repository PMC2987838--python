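"""RDFs, coordination spheres, occupancy statistics and water residence."""

import numpy as np
import pytest

from ionsite import (
    TrajectorySpec,
    coordination_sphere,
    coordination_summary,
    default_cutoff,
    ion_species,
    radial_distribution,
    water_residence,
)
from ionsite.solvation_shell import CoordinationRecord, detect_water_bridges
from ionsite.structure_io import Atom, Ensemble, Structure
from ionsite.synthetic_data import PocketSpec, make_pocket_ensemble


def test_species_shell_cutoffs():
    assert default_cutoff(ion_species("Mg")) == pytest.approx(2.9)
    assert default_cutoff(ion_species("Ca")) == pytest.approx(3.2)
    assert default_cutoff("NA") == pytest.approx(3.2)
    assert default_cutoff("Zn", overrides={"ZN": 2.5}) == pytest.approx(2.5)
    with pytest.raises(KeyError):
        default_cutoff("Zn")


def _ion_with_points(points: np.ndarray) -> Structure:
    atoms = [
        Atom(1, "MG", "Mg", "MG", 1, "I", np.zeros(3), is_ion=True, record="HETATM")
    ]
    for k, p in enumerate(points, start=2):
        atoms.append(Atom(k, "O", "O", "HOH", k, "W", p, is_water=True, record="HETATM"))
    return Structure(atoms)


def test_rdf_of_uniform_ideal_gas_is_flat():
    rng = np.random.default_rng(17)
    rmax = 8.0
    n = 10_000
    # uniform points in the sphere of radius rmax around the ion
    u = rng.random(n)
    r = rmax * u ** (1.0 / 3.0)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    s = _ion_with_points(r[:, None] * v)
    ens = Ensemble([s])
    prof = radial_distribution(ens, "ion", "water", dr=0.4, rmax=rmax)
    density = n / (4.0 / 3.0 * np.pi * rmax**3)
    shell_vol = 4.0 / 3.0 * np.pi * (
        (prof.bin_centers + 0.2) ** 3 - (prof.bin_centers - 0.2) ** 3
    )
    expected_counts = density * shell_vol
    sigma = np.sqrt(expected_counts)
    assert np.all(np.abs(prof.counts - expected_counts) <= 3.0 * sigma)
    assert prof.g_of_r.mean() == pytest.approx(1.0, abs=0.2)


def test_rdf_single_pair_lands_in_one_bin():
    s = _ion_with_points(np.array([[2.1, 0.0, 0.0]]))
    prof = radial_distribution(Ensemble([s]), "ion", "water", dr=0.1, rmax=5.0)
    nonzero = np.flatnonzero(prof.counts)
    assert len(nonzero) == 1
    lo = prof.bin_centers[nonzero[0]] - 0.05
    assert lo == pytest.approx(2.1, abs=0.051)


def test_rdf_cumulative_integral_counts_octahedral_shell(perfect_octa):
    ens, _ = perfect_octa
    prof = radial_distribution(ens, "ion", "element O,N and not ion", dr=0.05, rmax=6.0)
    assert prof.n_at(2.9) == pytest.approx(6.0)


def test_rdf_rejects_empty_selection_and_bad_bins(perfect_octa):
    ens, _ = perfect_octa
    with pytest.raises(ValueError, match="empty"):
        radial_distribution(ens, "resname ZZZ", "water")
    with pytest.raises(ValueError, match="dr"):
        radial_distribution(ens, "ion", "water", dr=0.0)


def test_coordination_sphere_distance_cutoff_is_sharp():
    pts = np.vstack([2.1 * v for v in np.eye(3)] + [[-3.0, 0.0, 0.0]])
    s = _ion_with_points(pts)
    rec = coordination_sphere(s, 0, cutoff=2.9)
    assert rec.cn_total == 3 and rec.cn_water == 3
    assert all(l.distance <= 2.9 for l in rec.ligands)
    distances = [l.distance for l in rec.ligands]
    assert distances == sorted(distances)


def test_donor_element_set_controls_his_nitrogen():
    his_pocket = PocketSpec(1, ("HIS",), 5, "octahedral", 2.2, ion_species("MG"))
    ens, lay = make_pocket_ensemble(
        his_pocket, TrajectorySpec(1, 1.0, 0.0, seed=2), return_layout=True
    )
    fr = ens.frames[0]
    with_n = coordination_sphere(fr, lay.ion_index, 2.9, donors={"O", "N"})
    assert lay.donor_residue_keys[0] in with_n.protein_residues
    only_o = coordination_sphere(fr, lay.ion_index, 2.9, donors={"O"})
    assert lay.donor_residue_keys[0] not in only_o.protein_residues
    assert only_o.cn_water == 5 and only_o.cn_aa == 0


def test_coordination_sphere_requires_ion_atom(perfect_octa):
    ens, _ = perfect_octa
    with pytest.raises(ValueError, match="not an ion"):
        coordination_sphere(ens.frames[0], 0, 2.9)


def test_summary_occupancy_percentages():
    key = ("A", 7, "ASP")
    full = [
        CoordinationRecord(k, 9, 2.9, (make_ligand(key),)) for k in range(10)
    ]
    assert coordination_summary(full).pct_t_occ[key] == pytest.approx(100.0)
    half = [
        CoordinationRecord(k, 9, 2.9, (make_ligand(key),) if k % 2 == 0 else ())
        for k in range(10)
    ]
    assert coordination_summary(half).pct_t_occ[key] == pytest.approx(50.0)
    with pytest.raises(ValueError, match="window"):
        coordination_summary(full, window=(4, 4))


def make_ligand(residue_key, cls="protein", dist=2.1, idx=1):
    from ionsite.solvation_shell import Ligand

    return Ligand(idx, dist, cls, residue_key, "O")


def test_generator_cn_split_recovered_exactly(two_pocket_400):
    ens, lays = two_pocket_400
    lay = lays[0]  # Mg pocket: 2 protein donors + 4 waters
    recs = [
        coordination_sphere(fr, lay.ion_index, 2.9, frame_index=k)
        for k, fr in enumerate(ens.frames)
    ]
    summ = coordination_summary(recs)
    assert summ.cn_aa == pytest.approx(2.0)
    assert summ.cn_water == pytest.approx(4.0)
    assert summ.cn_total == summ.cn_aa + summ.cn_water
    se = 100 * np.sqrt(0.75 * 0.25 / 400)
    assert abs(summ.occupancy_pct - 75.0) <= 3 * se
    for rk in lay.donor_residue_keys:
        assert abs(summ.pct_t_occ[rk] - 75.0) <= 3 * se


def test_cn_identity_holds_on_random_records(two_pocket_400):
    ens, lays = two_pocket_400
    lay = lays[1]
    recs = [
        coordination_sphere(fr, lay.ion_index, 3.2, frame_index=k)
        for k, fr in enumerate(ens.frames[:100])
    ]
    summ = coordination_summary(recs)
    assert summ.cn_total == pytest.approx(summ.cn_aa + summ.cn_water, abs=1e-9)


def test_rdf_integral_consistent_with_summary_cn(perfect_octa):
    """The two code paths (RDF integral, per-frame shells) must agree."""
    ens, lay = perfect_octa
    prof = radial_distribution(ens, "ion", "element O,N and not ion", dr=0.05, rmax=6.0)
    recs = [
        coordination_sphere(fr, lay.ion_index, 2.9, frame_index=k)
        for k, fr in enumerate(ens.frames)
    ]
    summ = coordination_summary(recs)
    assert prof.n_at(2.9) == pytest.approx(summ.cn_total, abs=1e-9)


def test_fixed_waters_are_non_exchangeable(mg_octa_spec):
    ens, lay = make_pocket_ensemble(
        mg_octa_spec, TrajectorySpec(50, 1.0, 0.0, seed=6), return_layout=True
    )
    recs = [
        coordination_sphere(fr, lay.ion_index, 2.9, frame_index=k)
        for k, fr in enumerate(ens.frames)
    ]
    res = water_residence(recs)
    assert len(res.fractions) == 4
    assert all(f == pytest.approx(1.0) for f in res.fractions.values())
    assert all(res.non_exchangeable.values())


def test_per_frame_exchange_leaves_no_flags(mg_octa_spec):
    ens, lay = make_pocket_ensemble(
        mg_octa_spec,
        TrajectorySpec(20, 1.0, 0.0, seed=6, water_exchange_period=1),
        return_layout=True,
    )
    recs = [
        coordination_sphere(fr, lay.ion_index, 2.9, frame_index=k)
        for k, fr in enumerate(ens.frames)
    ]
    res = water_residence(recs)
    assert not any(res.non_exchangeable.values())
    assert all(f == pytest.approx(1 / 20) for f in res.fractions.values())


def test_exchange_period_counting_oracle(mg_octa_spec):
    """period=10 over 100 frames: each identity resides exactly 10/100."""
    ens, lay = make_pocket_ensemble(
        mg_octa_spec,
        TrajectorySpec(100, 1.0, 0.0, seed=4, water_exchange_period=10),
        return_layout=True,
    )
    recs = [
        coordination_sphere(fr, lay.ion_index, 2.9, frame_index=k)
        for k, fr in enumerate(ens.frames)
    ]
    res = water_residence(recs)
    assert len(res.fractions) == 40
    assert all(f == pytest.approx(0.1) for f in res.fractions.values())
    assert not any(res.non_exchangeable.values())


def test_residence_requires_bound_frames():
    with pytest.raises(ValueError, match="never bound"):
        water_residence([CoordinationRecord(0, 1, 2.9, ())])


def test_water_bridge_detection(mg_octa_spec):
    """A shell water within H-bond range of a protein polar atom bridges it."""
    ens, lay = make_pocket_ensemble(
        mg_octa_spec, TrajectorySpec(1, 1.0, 0.0, seed=2), return_layout=True
    )
    fr = ens.frames[0]
    rec = coordination_sphere(fr, lay.ion_index, 2.9)
    # plant a polar backbone O next to a shell water
    water_lig = next(l for l in rec.ligands if l.ligand_class == "water")
    pos = fr.coords[water_lig.atom_index] + np.array([0.0, 0.0, 2.8])
    planted = Atom(999, "O", "O", "SER", 55, "A", pos)
    frame2 = Structure(fr.atoms + [planted])
    rec2 = coordination_sphere(frame2, lay.ion_index, 2.9)
    bridged = detect_water_bridges(frame2, rec2)
    assert ("A", 55, "SER") in bridged
    assert ("A", 55, "SER") not in rec2.protein_residues
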