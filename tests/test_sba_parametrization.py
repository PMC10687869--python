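"""Single-bead-approximation term decomposition, averaging, fitting, I/O."""

import numpy as np
import pytest

from sasbead.io_structures import Ensemble
from sasbead.sba_parametrization import (
    MODES,
    FitError,
    ParameterFileError,
    atomic_amplitudes,
    average_terms,
    build_parameter_set,
    default_q_grid,
    fit_polynomial,
    read_params,
    sba_terms_single_frame,
    write_params,
)
from sasbead.synthetic_fixtures import make_ensemble, make_peptide


def _direct_sba(structure, bead, q, mode, rho):
    """Independent oracle: Debye sum over f' = phi - rho*g at density rho."""
    phi, g = atomic_amplitudes(structure, bead.atom_indices, q, mode)
    f = phi - rho * g
    xyz = np.array([structure.atoms[i].position for i in bead.atom_indices])
    d = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=-1)
    w = np.sinc(d[:, :, None] * q[None, None, :] / np.pi)
    return np.einsum("iq,kq,ikq->q", f, f, w)


@pytest.mark.parametrize("mode", MODES)
def test_decomposition_identity_random_q_rho(helix_peptide, protein_decomposition, mode, rng):
    """F^2 = A - rho*Mx + rho^2*S is algebraically exact at any density."""
    q_grid = default_q_grid()
    for bead in protein_decomposition.beads[::4]:
        A, Mx, S = sba_terms_single_frame(bead, helix_peptide, q_grid, mode)
        for _ in range(5):
            rho = rng.uniform(0.0, 0.6)
            iq = rng.integers(0, q_grid.size)
            direct = _direct_sba(helix_peptide, bead, q_grid[iq:iq + 1], mode, rho)[0]
            decomposed = A[iq] - rho * Mx[iq] + rho**2 * S[iq]
            assert decomposed == pytest.approx(direct, rel=1e-12, abs=1e-9)


def test_single_atom_bead_terms_at_q0(helix_peptide):
    from sasbead.bead_mapping import Bead
    from sasbead.scattering_factors import load_tables

    t = load_tables()
    # nitrogen backbone atom as a one-atom bead
    atom = helix_peptide.atoms[0]
    bead = Bead("X", atom.position, (0,))
    q = np.array([1e-10])
    A, Mx, S = sba_terms_single_frame(bead, helix_peptide, q, "SAXS")
    # united-atom group for this N carries its implicit hydrogens
    from sasbead.sba_parametrization import implicit_hydrogen_counts

    n_h = implicit_hydrogen_counts(helix_peptide)[0]
    f0 = t.group_cm(atom.element, n_h).f0()
    nu = t.group_volume(atom.element, n_h)
    assert A[0] == pytest.approx(f0**2, rel=1e-6)
    assert Mx[0] == pytest.approx(2 * f0 * nu, rel=1e-6)
    assert S[0] == pytest.approx(nu**2, rel=1e-6)


def test_two_atom_bead_sinc_node(helix_peptide):
    """At q*r = pi the cross term vanishes: only diagonal contributions."""
    import dataclasses

    from sasbead.bead_mapping import Bead
    from sasbead.io_structures import Structure

    r = 3.0
    a0 = dataclasses.replace(helix_peptide.atoms[1], index=0, position=np.zeros(3))
    a1 = dataclasses.replace(helix_peptide.atoms[1], index=1, position=np.array([r, 0, 0]))
    st = Structure([a0, a1])
    bead = Bead("X", np.zeros(3), (0, 1))
    q = np.array([np.pi / r])
    A, Mx, S = sba_terms_single_frame(bead, st, q, "SAXS")
    phi, g = atomic_amplitudes(st, (0, 1), q, "SAXS")
    assert A[0] == pytest.approx(float((phi[:, 0] ** 2).sum()), rel=1e-10)
    assert S[0] == pytest.approx(float((g[:, 0] ** 2).sum()), rel=1e-10)


def test_averaging_idempotent_for_duplicated_frames(helix_peptide):
    q = default_q_grid(0.3, 0.01)
    e1 = Ensemble([helix_peptide])
    e2 = Ensemble([helix_peptide, helix_peptide])
    t1 = average_terms(e1, q, "SAXS")
    t2 = average_terms(e2, q, "SAXS")
    for label in t1:
        assert np.allclose(t1[label].A, t2[label].A)
        assert np.allclose(t1[label].Mx, t2[label].Mx)
        assert np.allclose(t1[label].S, t2[label].S)
        assert t2[label].n_frames_averaged == 2


def test_fit_polynomial_exact_recovery_and_constant():
    q = np.linspace(0, 0.5, 201)
    coeffs_true = np.array([2.0, -1.0, 3.0, 0.5, -0.2, 0.1, -0.05])
    y = np.polynomial.polynomial.polyval(q, coeffs_true)
    c, resid = fit_polynomial(y, q, order=6)
    assert np.allclose(c, coeffs_true, atol=1e-10)
    assert resid < 1e-9
    c2, _ = fit_polynomial(np.full_like(q, 7.0), q, order=6)
    assert c2[0] == pytest.approx(7.0, abs=1e-9)
    assert np.allclose(c2[1:], 0, atol=1e-7)


def test_fit_polynomial_gaussian_within_half_percent():
    q = np.linspace(0, 0.5, 201)
    y = np.exp(-(q**2) * 8.0) * 100.0
    c, _ = fit_polynomial(y, q, order=6)
    fitted = np.polynomial.polynomial.polyval(q, c)
    assert np.max(np.abs(fitted - y) / y) < 0.005


def test_fit_polynomial_too_few_points():
    q = np.linspace(0, 0.5, 5)
    with pytest.raises(FitError):
        fit_polynomial(np.ones(5), q, order=6)


def test_post_fit_error_below_one_percent(protein_params, helix_peptide, protein_decomposition):
    """Fitted F(q) tracks the tabulated F(q) to <=1% over the fitted range."""
    q = default_q_grid()
    rho = 0.334
    ens = Ensemble([helix_peptide])
    tabs = average_terms(ens, q, "SAXS")
    pset = build_parameter_set(ens, q, modes=("SAXS",), min_instances=1)
    for label, tab in tabs.items():
        f_tab = np.sqrt(np.clip(tab.f_squared(rho), 0, None))
        f_fit = pset.form_factor(label, "SAXS", q, rho)
        mask = f_tab > 1e-6
        assert np.max(np.abs(f_fit[mask] - f_tab[mask]) / f_tab[mask]) < 0.01


def test_rho_independence_of_term_tables(helix_peptide, protein_decomposition):
    """One set of term tables reproduces the direct SBA at any density."""
    q = default_q_grid(0.3, 0.01)
    bead = protein_decomposition.beads[7]
    A, Mx, S = sba_terms_single_frame(bead, helix_peptide, q, "SAXS")
    for rho in (0.0, 0.2, 0.334, 0.55):
        direct = _direct_sba(helix_peptide, bead, q, "SAXS", rho)
        assert np.allclose(A - rho * Mx + rho**2 * S, direct, rtol=1e-10)


def test_sans_h_equals_sans_d_for_hydrogen_free_bead(rna12, rna_decomposition):
    """The phosphate bead has no hydrogens: H and D term sets coincide."""
    q = default_q_grid(0.3, 0.01)
    bead = next(b for b in rna_decomposition.beads if b.type_label == "PHOSPHATE")
    ah, mh, sh = sba_terms_single_frame(bead, rna12, q, "SANS-H")
    ad, md, sd = sba_terms_single_frame(bead, rna12, q, "SANS-D")
    assert np.allclose(ah, ad) and np.allclose(mh, md) and np.allclose(sh, sd)


def test_build_parameter_set_covers_all_20_aa(protein_params):
    types = set(protein_params.bead_types())
    # all 20 amino acids present (histidine as its epsilon tautomer type)
    expected = {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HISE", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }
    assert expected <= types
    for label in expected:
        for mode in MODES:
            for term in ("A", "Mx", "S"):
                assert len(protein_params.coefficients[label][mode][term]) == 7


def test_rna_parameter_set_bead_type_inventory(rna_params):
    types = set(rna_params.bead_types())
    assert {"A", "C", "G", "U", "PHOSPHATE", "SUGAR_R", "SUGAR5_R", "SUGAR3_R"} <= types


def test_params_roundtrip_byte_identical(tmp_path, rna_params):
    p1 = tmp_path / "a.json"
    p2 = tmp_path / "b.json"
    write_params(rna_params, p1)
    back = read_params(p1)
    write_params(back, p2)
    assert p1.read_bytes() == p2.read_bytes()
    for label in rna_params.bead_types():
        for mode in rna_params.modes:
            for term in ("A", "Mx", "S"):
                assert np.allclose(
                    back.coefficients[label][mode][term],
                    rna_params.coefficients[label][mode][term],
                )


def test_truncated_params_file_raises(tmp_path, rna_params):
    p = tmp_path / "t.json"
    write_params(rna_params, p)
    p.write_text(p.read_text()[: 100])
    with pytest.raises(ParameterFileError):
        read_params(p)


def test_wrong_version_raises(tmp_path, rna_params):
    p = tmp_path / "v.json"
    write_params(rna_params, p)
    doc = p.read_text().replace('"version": 1', '"version": 99')
    p.write_text(doc)
    with pytest.raises(ParameterFileError):
        read_params(p)


def test_rebuild_is_deterministic(helix_peptide):
    q = default_q_grid(0.2, 0.01)
    ens = make_ensemble(helix_peptide, 3, jitter_sigma=0.3, seed=11)
    a = build_parameter_set(ens, q, modes=("SAXS",), min_instances=1)
    b = build_parameter_set(ens, q, modes=("SAXS",), min_instances=1)
    for label in a.bead_types():
        assert np.array_equal(a.coefficients[label]["SAXS"]["A"],
                              b.coefficients[label]["SAXS"]["A"])


def test_evaluation_refuses_extrapolation(protein_params):
    with pytest.raises(ValueError, match="extrapolate"):
        protein_params.f_squared("ALA", "SAXS", np.array([0.7]), 0.334)
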