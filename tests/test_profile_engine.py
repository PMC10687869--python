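"""Debye intensities, corrections, gradients and comparison metrics."""

import dataclasses

import numpy as np
import pytest

from sasbead.io_structures import Structure
from sasbead.profile_engine import (
    Profile,
    SolvationCorrection,
    chi_squared,
    debye_intensity_atomistic,
    debye_intensity_cg,
    ensemble_average_profile,
    guinier_rg,
    intensity_gradients,
    log10_rmse,
    read_profile,
    residuals_percent,
    write_profile,
)
from sasbead.scattering_factors import SolventModel, cromer_mann_f, load_tables
from sasbead.synthetic_fixtures import make_sphere_cluster

Q = np.linspace(1e-10, 0.3, 31)


def test_single_atom_vacuum_saxs_is_f_squared():
    st = make_sphere_cluster(1, 1.0, seed=0)
    prof = debye_intensity_atomistic(st, Q, SolventModel(rho0=0.0))
    f = cromer_mann_f(load_tables().cm("C"), Q)
    assert np.allclose(prof.intensity, f**2, rtol=1e-12)


def test_two_atom_closed_form():
    st = make_sphere_cluster(2, 1.0, seed=0)
    r = 5.0
    a0 = dataclasses.replace(st.atoms[0], position=np.zeros(3))
    a1 = dataclasses.replace(st.atoms[1], position=np.array([r, 0.0, 0.0]))
    st2 = Structure([a0, a1])
    prof = debye_intensity_atomistic(st2, Q, SolventModel(rho0=0.0))
    f = cromer_mann_f(load_tables().cm("C"), Q)
    expected = 2 * f**2 * (1 + np.sinc(Q * r / np.pi))
    assert np.allclose(prof.intensity, expected, rtol=1e-12)


def test_vectorized_debye_equals_naive_loop():
    """O(N^2) brute-force double loop as independent oracle (50 atoms)."""
    st = make_sphere_cluster(50, 12.0, seed=3)
    sol = SolventModel(rho0=0.334)
    prof = debye_intensity_atomistic(st, Q, sol)
    t = load_tables()
    from sasbead.scattering_factors import excluded_volume_g

    f = cromer_mann_f(t.cm("C"), Q) - sol.rho0 * excluded_volume_g(t.group_volume("C"), Q)
    xyz = st.positions
    naive = np.zeros_like(Q)
    for iq, qv in enumerate(Q):
        s = 0.0
        for i in range(50):
            for j in range(50):
                r = np.linalg.norm(xyz[i] - xyz[j])
                s += f[iq] * f[iq] * (np.sin(qv * r) / (qv * r) if qv * r > 0 else 1.0)
        naive[iq] = s
    assert np.allclose(prof.intensity, naive, rtol=1e-10)


def test_rigid_transform_invariance():
    st = make_sphere_cluster(40, 10.0, seed=4)
    sol = SolventModel(rho0=0.334)
    base = debye_intensity_atomistic(st, Q, sol).intensity
    rng = np.random.default_rng(5)
    a = rng.normal(size=(3, 3))
    qmat, _ = np.linalg.qr(a)
    moved = st.with_positions(st.positions @ qmat.T + np.array([10.0, -3.0, 7.0]))
    after = debye_intensity_atomistic(moved, Q, sol).intensity
    assert np.max(np.abs(after - base) / base) < 1e-10


def test_i0_equals_square_of_total_amplitude(helix_peptide):
    sol = SolventModel(rho0=0.334)
    q = np.array([1e-10])
    prof = debye_intensity_atomistic(helix_peptide, q, sol)
    from sasbead.profile_engine import _atomistic_amplitudes

    amps = _atomistic_amplitudes(helix_peptide, q, sol, None)
    assert prof.intensity[0] == pytest.approx(float(amps[:, 0].sum()) ** 2, rel=1e-10)


def test_guinier_rg_matches_coordinate_rg():
    st = make_sphere_cluster(400, 20.0, seed=6)
    q = np.linspace(1e-10, 0.08, 50)
    prof = debye_intensity_atomistic(st, q, SolventModel(rho0=0.0))
    rg = guinier_rg(prof)
    assert rg == pytest.approx(st.radius_of_gyration(), rel=0.03)


# ---------------------------------------------------------------------------
# coarse-grained path
# ---------------------------------------------------------------------------


def test_correction_disabled_equals_slc_zero(protein_decomposition, protein_params):
    sol = SolventModel(rho0=0.334)
    off = debye_intensity_cg(protein_decomposition, protein_params, Q, sol,
                             SolvationCorrection(enabled=False))
    zero = debye_intensity_cg(protein_decomposition, protein_params, Q, sol,
                              SolvationCorrection(slc=0.0, enabled=True))
    assert np.allclose(off.intensity, zero.intensity, rtol=1e-12)


def test_huge_sasa_cutoff_equals_uncorrected(protein_decomposition, protein_params):
    sol = SolventModel(rho0=0.334)
    off = debye_intensity_cg(protein_decomposition, protein_params, Q, sol)
    huge = debye_intensity_cg(protein_decomposition, protein_params, Q, sol,
                              SolvationCorrection(slc=0.08, sasa_cutoff=1e9, enabled=True))
    assert np.allclose(off.intensity, huge.intensity, rtol=1e-12)


def test_slc_reduces_forward_intensity(protein_decomposition, protein_params):
    """Density decrement on exposed beads raises contrast: I(0) must move."""
    sol = SolventModel(rho0=0.334)
    off = debye_intensity_cg(protein_decomposition, protein_params, Q, sol)
    on = debye_intensity_cg(protein_decomposition, protein_params, Q, sol,
                            SolvationCorrection(slc=0.08, sasa_cutoff=0.4, enabled=True))
    assert on.intensity[0] != pytest.approx(off.intensity[0], rel=1e-6)
    # lowering the solvent density raises every exposed bead's contrast,
    # so the forward intensity increases
    assert on.intensity[0] > off.intensity[0]


def test_sans_d0_profile_independent_of_seed(protein_decomposition, protein_params):
    sol = SolventModel(rho0=0.334, deuterium_fraction=0.0, mode="SANS")
    a = debye_intensity_cg(protein_decomposition, protein_params, Q, sol, seed=1)
    b = debye_intensity_cg(protein_decomposition, protein_params, Q, sol, seed=999)
    assert np.array_equal(a.intensity, b.intensity)


def test_sans_deterministic_hd_reproducible(protein_decomposition, protein_params):
    sol = SolventModel(rho0=0.334, deuterium_fraction=0.5, mode="SANS")
    i5a = debye_intensity_cg(protein_decomposition, protein_params, Q, sol, seed=1,
                             deterministic_hd=True).intensity
    i5b = debye_intensity_cg(protein_decomposition, protein_params, Q, sol, seed=2,
                             deterministic_hd=True).intensity
    assert np.array_equal(i5a, i5b)  # expectation mode ignores the seed
    assert np.all(i5a >= 0)


def test_sans_contrast_variation_i0_is_quadratic_in_d(
        protein_decomposition, protein_params):
    """I(0) along a D2O titration follows the classic contrast-variation
    parabola (quadratic in d to good approximation)."""
    d_vals = np.linspace(0, 1, 11)
    i0 = []
    for d in d_vals:
        sol = SolventModel(rho0=0.334, deuterium_fraction=d, mode="SANS")
        i0.append(debye_intensity_cg(
            protein_decomposition, protein_params, np.array([1e-10]), sol,
            deterministic_hd=True).intensity[0])
    i0 = np.array(i0)
    coeffs = np.polyfit(d_vals, i0, 2)
    fit = np.polyval(coeffs, d_vals)
    ss_res = np.sum((i0 - fit) ** 2)
    ss_tot = np.sum((i0 - i0.mean()) ** 2)
    assert 1 - ss_res / ss_tot > 0.99


def test_sans_seed_variance_vanishes_at_extreme_d(protein_decomposition, protein_params):
    for d in (0.0, 1.0):
        sol = SolventModel(rho0=0.334, deuterium_fraction=d, mode="SANS")
        vals = [
            debye_intensity_cg(protein_decomposition, protein_params, Q, sol, seed=s).intensity[0]
            for s in range(4)
        ]
        assert np.ptp(vals) == 0.0


def test_cg_missing_bead_type_raises(protein_decomposition, rna_params):
    with pytest.raises(KeyError):
        debye_intensity_cg(protein_decomposition, rna_params, Q, SolventModel())


def test_cg_q_outside_validity_raises(protein_decomposition, protein_params):
    q_bad = np.linspace(1e-10, 0.8, 10)
    with pytest.raises(ValueError, match="extrapolate"):
        debye_intensity_cg(protein_decomposition, protein_params, q_bad, SolventModel())


# ---------------------------------------------------------------------------
# gradients
# ---------------------------------------------------------------------------


def test_gradients_match_central_differences(protein_decomposition, protein_params):
    q = np.linspace(1e-10, 0.3, 7)
    sol = SolventModel(rho0=0.334)
    grads = intensity_gradients(protein_decomposition, protein_params, q, sol,
                                center="mapped").gradients
    h = 1e-4
    dec = protein_decomposition
    rel_devs = []
    for bead_i in (0, 7, 19):
        for axis in range(3):
            orig = dec.beads[bead_i].center.copy()
            dec.beads[bead_i].center = orig + np.eye(3)[axis] * h
            ip = debye_intensity_cg(dec, protein_params, q, sol, center="mapped").intensity
            dec.beads[bead_i].center = orig - np.eye(3)[axis] * h
            im = debye_intensity_cg(dec, protein_params, q, sol, center="mapped").intensity
            dec.beads[bead_i].center = orig
            fd = (ip - im) / (2 * h)
            an = grads[:, bead_i, axis]
            scale = np.maximum(np.abs(fd), 1e-3 * np.abs(ip))
            rel_devs.append(np.max(np.abs(an - fd) / scale))
    assert max(rel_devs) < 1e-5


def test_gradients_sum_to_zero_translation_invariance(protein_decomposition, protein_params):
    q = np.linspace(1e-10, 0.3, 7)
    g = intensity_gradients(protein_decomposition, protein_params, q,
                            SolventModel(rho0=0.334)).gradients
    total = g.sum(axis=1)
    scale = np.abs(g).sum(axis=(1, 2)) + 1e-30
    assert np.max(np.abs(total) / scale[:, None]) < 1e-12


# ---------------------------------------------------------------------------
# comparison metrics
# ---------------------------------------------------------------------------


def _profile(i, q=Q):
    return Profile(q, np.asarray(i, dtype=float))


def test_residuals_identity_and_doubling():
    p = _profile(np.linspace(10, 1, Q.size))
    assert np.allclose(residuals_percent(p, p), 0.0)
    p2 = _profile(2 * p.intensity)
    assert np.allclose(residuals_percent(p2, p), 100.0)


def test_residuals_grid_mismatch_raises():
    a = _profile(np.ones(Q.size))
    b = Profile(Q + 0.001, np.ones(Q.size))
    with pytest.raises(ValueError):
        residuals_percent(a, b)


def test_log10_rmse_scale_invariance_and_hand_value():
    i = np.linspace(100, 1, Q.size)
    a = _profile(i)
    assert log10_rmse(a, a) == 0.0
    assert log10_rmse(_profile(10 * i), a) == pytest.approx(0.0, abs=1e-14)
    assert log10_rmse(_profile(10 * i), a, fit_scale=False) == pytest.approx(1.0)
    # constructed offset: half the points multiplied by 10^0.2 -> rmse 0.1 after fit
    i2 = i.copy()
    i2[::2] *= 10 ** 0.2
    n_even = np.arange(Q.size)[::2].size
    mean_off = 0.2 * n_even / Q.size
    expected = np.sqrt(((0.2 - mean_off) ** 2 * n_even
                        + mean_off**2 * (Q.size - n_even)) / Q.size)
    assert log10_rmse(_profile(i2), a) == pytest.approx(expected, rel=1e-10)


def test_log10_rmse_rejects_nonpositive():
    a = _profile(np.ones(Q.size))
    b = _profile(np.ones(Q.size))
    b.intensity[3] = -1.0
    with pytest.raises(ValueError):
        log10_rmse(a, b)


def test_chi_squared_exact_match_is_zero():
    icalc = np.linspace(50, 5, Q.size)
    exp = Profile(Q, 3.3 * icalc, sigma=np.full(Q.size, 0.5))
    calc = _profile(icalc)
    assert chi_squared(calc, exp) == pytest.approx(0.0, abs=1e-18)


def test_chi_squared_calibrated_on_gaussian_noise():
    """Simulated data c*I + N(0, sigma) must give reduced chi^2 near 1."""
    rng = np.random.default_rng(42)
    n = 200
    q = np.linspace(1e-10, 0.3, n)
    icalc = 1000 * np.exp(-(q**2) * 40)
    sigma = 5.0
    chis = []
    for _ in range(30):
        iexp = 2.0 * icalc + rng.normal(0, sigma, n)
        chis.append(chi_squared(Profile(q, icalc), Profile(q, iexp, sigma=np.full(n, sigma))))
    assert np.mean(chis) == pytest.approx(1.0, abs=3 / np.sqrt(n))


def test_chi_squared_huge_sigma_goes_to_zero():
    icalc = np.linspace(50, 5, Q.size)
    exp = Profile(Q, icalc + 1.0, sigma=np.full(Q.size, 1e9))
    assert chi_squared(_profile(icalc), exp) < 1e-10


def test_chi_squared_too_few_points():
    q = np.array([0.01, 0.02])
    with pytest.raises(ValueError):
        chi_squared(Profile(q, np.ones(2)), Profile(q, np.ones(2), sigma=np.ones(2)))


def test_ensemble_average_profile():
    a = _profile(np.full(Q.size, 2.0))
    b = _profile(np.full(Q.size, 4.0))
    assert np.allclose(ensemble_average_profile([a]).intensity, 2.0)
    assert np.allclose(ensemble_average_profile([a, a]).intensity, 2.0)
    assert np.allclose(ensemble_average_profile([a, b]).intensity, 3.0)


def test_profile_io_roundtrip(tmp_path):
    p = Profile(Q, np.linspace(9, 1, Q.size), sigma=np.linspace(0.1, 0.2, Q.size))
    path = tmp_path / "prof.dat"
    write_profile(p, path, header="test")
    back = read_profile(path)
    assert np.allclose(back.q, p.q)
    assert np.allclose(back.intensity, p.intensity, rtol=1e-7)
    assert np.allclose(back.sigma, p.sigma, rtol=1e-6)
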