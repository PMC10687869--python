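"""Shared fixtures: synthetic structures and (expensive) bead parameter sets."""

import numpy as np
import pytest

from sasbead.bead_mapping import map_nucleic_3B, map_protein_1B
from sasbead.sba_parametrization import build_parameter_set, default_q_grid
from sasbead.synthetic_fixtures import make_ensemble, make_peptide, make_rna

ALL20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def helix_peptide():
    return make_peptide(ALL20, "helix", seed=1)


@pytest.fixture(scope="session")
def helix_peptide_h():
    return make_peptide(ALL20, "helix", seed=1, hydrogens=True)


@pytest.fixture(scope="session")
def rna12():
    return make_rna("AGUAGAUUAGCA", seed=2)


@pytest.fixture(scope="session")
def q_grid():
    return default_q_grid()


@pytest.fixture(scope="session")
def protein_decomposition(helix_peptide):
    return map_protein_1B(helix_peptide)


@pytest.fixture(scope="session")
def rna_decomposition(rna12):
    return map_nucleic_3B(rna12)


@pytest.fixture(scope="session")
def protein_params(helix_peptide, q_grid):
    ens = make_ensemble(helix_peptide, 20, jitter_sigma=0.3, seed=7)
    return build_parameter_set(ens, q_grid, min_instances=1)


@pytest.fixture(scope="session")
def rna_params(rna12, q_grid):
    ens = make_ensemble(rna12, 10, jitter_sigma=0.3, seed=8)
    return build_parameter_set(ens, q_grid, min_instances=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
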