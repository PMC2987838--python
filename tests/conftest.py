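"""Shared fixtures: engineered pockets and small handcrafted PDB content."""

from __future__ import annotations

import numpy as np
import pytest

from ionsite import PocketSpec, TrajectorySpec, ion_species
from ionsite.synthetic_data import make_pocket_ensemble, make_pockets_ensemble


@pytest.fixture(scope="session")
def mg_octa_spec() -> PocketSpec:
    """Octahedral Mg2+ pocket: 2 Asp carboxylate oxygens + 4 waters."""
    return PocketSpec(2, ("ASP",), 4, "octahedral", 2.08, ion_species("MG"))


@pytest.fixture(scope="session")
def ca_ttp_spec() -> PocketSpec:
    """Tricapped-trigonal-prismatic Ca2+ pocket: 5 donors + 4 waters."""
    return PocketSpec(
        5, ("ASP", "GLU"), 4, "tricapped_trigonal_prism", 2.45, ion_species("CA")
    )


@pytest.fixture(scope="session")
def perfect_octa(mg_octa_spec):
    """Always-bound, jitter-free octahedral pocket with its layout."""
    traj = TrajectorySpec(n_frames=5, occupancy_target=1.0, jitter_sigma=0.0, seed=1)
    return make_pocket_ensemble(mg_octa_spec, traj, return_layout=True)


@pytest.fixture(scope="session")
def two_pocket_400(mg_octa_spec, ca_ttp_spec):
    """The 400-frame two-pocket recovery ensemble (Mg 75%, Ca always bound)."""
    traj = TrajectorySpec(n_frames=400, occupancy_target=0.75, jitter_sigma=0.05, seed=1)
    return make_pockets_ensemble(
        [mg_octa_spec, ca_ttp_spec], traj, [(0.0, 0.0, 0.0), (25.0, 0.0, 0.0)],
        return_layouts=True,
    )


@pytest.fixture()
def two_atom_pdb(tmp_path):
    """A minimal handcrafted PDB: one alpha-carbon and one backbone oxygen."""
    text = (
        "ATOM      1  CA  ALA A   1      11.000  12.000  13.000  1.00  0.00           C\n"
        "ATOM      2  O   ALA A   1      12.500  12.000  13.000  1.00  0.00           O\n"
        "END\n"
    )
    path = tmp_path / "two_atom.pdb"
    path.write_text(text)
    return path
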