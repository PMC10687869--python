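"""SAXS/SANS intensity evaluation and profile comparison.

Two resolutions share the Debye equation
``I(q) = sum_ij F_i(q) F_j(q) sinc(q r_ij)``:

* atomistic — F are solvent-corrected atomic amplitudes (the reference);
* coarse-grained — F are bead form factors evaluated from precomputed
  three-term tables, where each solvent-exposed bead (per-bead SASA above a
  cutoff) can receive a solvation-layer density decrement
  ``rho = rho0 - SLC`` and, for SANS, swaps to deuterated terms with
  probability equal to the buffer's D2O fraction.

Comparison operations (percent residuals, log10 RMSE, reduced chi-squared
against experimental data) and analytic coordinate gradients for restrained
simulations live here as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bead_mapping import BeadDecomposition
from .io_structures import Structure
from .sasa_lcpo import PROBE_RADIUS_DEFAULT, bead_sasa, lcpo_sasa, solvated_flags
from .sba_parametrization import (
    BeadParameterSet,
    atomic_amplitudes,
    implicit_hydrogen_counts,
)
from .scattering_factors import (
    ScatteringTables,
    SolventModel,
    excluded_volume_g,
    load_tables,
    sans_solvent_density,
)

__all__ = [
    "SolvationCorrection",
    "Profile",
    "GradientSet",
    "debye_intensity_atomistic",
    "debye_intensity_cg",
    "intensity_gradients",
    "residuals_percent",
    "log10_rmse",
    "chi_squared",
    "ensemble_average_profile",
    "guinier_rg",
    "read_profile",
    "write_profile",
]


@dataclass(frozen=True)
class SolvationCorrection:
    """Solvation-layer correction: density decrement for solvent-exposed beads.

    ``slc`` in e/A^3 for SAXS (the same decrement is applied to the neutron
    scattering density, in that mode's units, for SANS); ``sasa_cutoff`` in
    nm^2. Presets from practice: protein slc=0.08, SC=0.7 nm^2; nucleic
    slc=0.12, SC=0.8 nm^2. The correction is always opt-in.
    """

    slc: float = 0.0
    sasa_cutoff: float = 0.7
    enabled: bool = False

    def __post_init__(self):
        if self.slc < 0:
            raise ValueError("SLC decrement must be non-negative")
        if self.sasa_cutoff < 0:
            raise ValueError("SASA cutoff must be non-negative")


PROTEIN_SLC_PRESET = SolvationCorrection(slc=0.08, sasa_cutoff=0.7, enabled=True)
NUCLEIC_SLC_PRESET = SolvationCorrection(slc=0.12, sasa_cutoff=0.8, enabled=True)


@dataclass
class Profile:
    """A scattering profile: q grid (1/A), intensities, mode and provenance."""

    q: np.ndarray
    intensity: np.ndarray
    mode: str = "SAXS"
    sigma: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity must have identical shapes")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q grid must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")


@dataclass
class GradientSet:
    """dI(q)/dR per (q, bead): array of shape (n_q, n_beads, 3)."""

    q: np.ndarray
    gradients: np.ndarray


def _sinc(x):
    return np.sinc(np.asarray(x) / np.pi)


def _dsinc(x):
    """d/dx [sin(x)/x], series-guarded near 0."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-4
    xs = x[small]
    out[small] = -xs / 3.0 + xs**3 / 30.0
    xl = x[~small]
    out[~small] = np.cos(xl) / xl - np.sin(xl) / xl**2
    return out


def _debye_sum(amplitudes: np.ndarray, xyz: np.ndarray, q: np.ndarray) -> np.ndarray:
    """I(q) = sum_ij f_i(q) f_j(q) sinc(q r_ij), vectorized over q."""
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    out = np.empty(q.size)
    for iq, qv in enumerate(q):
        w = _sinc(qv * d)
        f = amplitudes[:, iq]
        out[iq] = f @ w @ f
    return out


def _atomistic_amplitudes(structure, q, solvent, tables):
    t = tables or load_tables()
    implicit = implicit_hydrogen_counts(structure, t)
    idx = range(len(structure.atoms))
    if solvent.mode == "SAXS":
        phi, g = atomic_amplitudes(structure, idx, q, "SAXS", t, implicit)
        return phi - solvent.rho0 * g
    # SANS: per-atom isotope tags decide b_i; implicit H stay protium unless
    # the caller tagged atoms explicitly (bead-level H/D swapping happens in
    # the coarse-grained path)
    rho_sans = sans_solvent_density(solvent.rho0, solvent.deuterium_fraction, t)
    amps = np.empty((len(structure.atoms), q.size))
    for row, a in enumerate(structure.atoms):
        n_h = int(implicit[a.index])
        if a.element == "H":
            b = t.neutron_b(a.isotope_tag or "H")
        else:
            b = t.group_neutron_b(a.element, n_h, hydrogen_isotope="H")
        amps[row] = b - rho_sans * excluded_volume_g(t.group_volume(a.element, n_h), q)
    return amps


def debye_intensity_atomistic(
    structure: Structure,
    q_grid: np.ndarray,
    solvent: SolventModel | None = None,
    tables: ScatteringTables | None = None,
) -> Profile:
    """Reference atomistic Debye intensity (exact orientational average)."""
    solvent = solvent or SolventModel()
    q = np.asarray(q_grid, dtype=float)
    amps = _atomistic_amplitudes(structure, q, solvent, tables)
    intensity = _debye_sum(amps, structure.positions, q)
    return Profile(
        q, intensity, mode=solvent.mode,
        metadata={"resolution": "atomistic", "rho0": solvent.rho0,
                  "deuterium_fraction": solvent.deuterium_fraction},
    )


def _bead_form_factors(
    decomposition: BeadDecomposition,
    params: BeadParameterSet,
    q: np.ndarray,
    solvent: SolventModel,
    correction: SolvationCorrection,
    seed: int | None,
    deterministic_hd: bool,
    per_bead_sasa: np.ndarray | None,
    probe_radius: float,
) -> np.ndarray:
    beads = decomposition.beads
    if correction.enabled or solvent.mode == "SANS":
        if per_bead_sasa is None:
            per_atom = lcpo_sasa(decomposition.source, probe_radius=probe_radius)
            per_bead_sasa = bead_sasa(per_atom, decomposition)
        flags = solvated_flags(per_bead_sasa, correction.sasa_cutoff)
        for b, fl, ar in zip(beads, flags, per_bead_sasa):
            b.sasa, b.solvated = float(ar), bool(fl)
    else:
        flags = np.zeros(len(beads), dtype=bool)

    if solvent.mode == "SAXS":
        rho_base = solvent.rho0
    else:
        rho_base = sans_solvent_density(solvent.rho0, solvent.deuterium_fraction)
    rho = np.where(flags & correction.enabled, rho_base - correction.slc, rho_base)

    F = np.empty((len(beads), q.size))
    if solvent.mode == "SAXS":
        for i, b in enumerate(beads):
            F[i] = params.form_factor(b.type_label, "SAXS", q, rho[i])
        return F, rho, np.zeros(len(beads), dtype=bool)

    d = solvent.deuterium_fraction
    rng = np.random.default_rng(seed)
    for i, b in enumerate(beads):
        if flags[i] and d > 0:
            if deterministic_hd:
                f2 = (1.0 - d) * params.f_squared(b.type_label, "SANS-H", q, rho[i]) \
                    + d * params.f_squared(b.type_label, "SANS-D", q, rho[i])
                F[i] = np.sqrt(np.clip(f2, 0.0, None))
                continue
            use_d = rng.random() < d
            b.deuterated = bool(use_d)
            F[i] = params.form_factor(b.type_label, "SANS-D" if use_d else "SANS-H", q, rho[i])
        else:
            b.deuterated = False
            F[i] = params.form_factor(b.type_label, "SANS-H", q, rho[i])
    return F, rho, np.array([b.deuterated for b in beads], dtype=bool)


def scattering_centers(
    decomposition: BeadDecomposition,
    mode: str,
    rho_per_bead: np.ndarray,
    tables: ScatteringTables | None = None,
    deuterated: np.ndarray | None = None,
) -> np.ndarray:
    """Per-bead centers weighted by each atom's zero-angle contrast amplitude.

    At the contrast-weighted center the first-order (dipole) term of the
    bead's multipole expansion vanishes, which makes the coarse-grained Debye
    sum markedly more accurate than mass centers once solvent contrast is on
    (carbon is nearly contrast-matched in water, so the mass and scattering
    centers differ substantially). Falls back to the mass center for beads
    with vanishing net contrast.
    """
    t = tables or load_tables()
    st = decomposition.source
    implicit = implicit_hydrogen_counts(st, t)
    q0 = np.array([0.0])
    centers = np.empty((len(decomposition.beads), 3))
    for i, b in enumerate(decomposition.beads):
        atoms = [st.atoms[k] for k in b.atom_indices]
        xyz = np.array([a.position for a in atoms])
        if mode == "SAXS":
            w = np.array(
                [t.group_cm(a.element, int(implicit[a.index])).f0() for a in atoms]
            ) - rho_per_bead[i] * np.array(
                [t.group_volume(a.element, int(implicit[a.index])) for a in atoms]
            )
        else:
            iso = "D" if (deuterated is not None and deuterated[i]) else "H"
            w = np.array(
                [
                    t.neutron_b(iso if a.element == "H" else a.element)
                    + (0 if a.element == "H" else int(implicit[a.index]) * t.neutron_b(iso))
                    for a in atoms
                ]
            ) - rho_per_bead[i] * np.array(
                [t.group_volume(a.element, int(implicit[a.index])) for a in atoms]
            )
        total = w.sum()
        if abs(total) < 1e-3 * np.abs(w).sum():
            centers[i] = bead_center_mass(atoms)
        else:
            centers[i] = (w[:, None] * xyz).sum(axis=0) / total
    return centers


def bead_center_mass(atoms) -> np.ndarray:
    w = np.array([a.mass for a in atoms])
    return np.average(np.array([a.position for a in atoms]), axis=0, weights=w)


def debye_intensity_cg(
    decomposition: BeadDecomposition,
    params: BeadParameterSet,
    q_grid: np.ndarray,
    solvent: SolventModel | None = None,
    correction: SolvationCorrection | None = None,
    seed: int | None = None,
    deterministic_hd: bool = False,
    per_bead_sasa: np.ndarray | None = None,
    probe_radius: float = PROBE_RADIUS_DEFAULT,
    center: str = "scattering",
) -> Profile:
    """Coarse-grained Debye intensity from fitted bead form factors.

    With the correction enabled, solvent-exposed beads (per-bead LCPO SASA
    above ``correction.sasa_cutoff``) scatter against the decremented density
    ``rho0 - slc``. For SANS, exposed beads independently swap to the
    deuterated term set with probability ``solvent.deuterium_fraction``
    (seeded; or mixed in expectation with ``deterministic_hd``).

    ``center`` selects the inter-bead distance reference: ``scattering``
    (contrast-weighted, default — most accurate), or the mapped bead centers
    (``mapped``: mass or geometric as chosen at mapping time).
    """
    solvent = solvent or SolventModel()
    correction = correction or SolvationCorrection()
    q = np.asarray(q_grid, dtype=float)
    F, rho, deut = _bead_form_factors(
        decomposition, params, q, solvent, correction, seed,
        deterministic_hd, per_bead_sasa, probe_radius,
    )
    if center == "scattering":
        centers = scattering_centers(decomposition, solvent.mode, rho, deuterated=deut)
    elif center == "mapped":
        centers = decomposition.centers
    else:
        raise ValueError(f"unknown center choice {center!r}")
    intensity = _debye_sum(F, centers, q)
    return Profile(
        q, intensity, mode=solvent.mode,
        metadata={
            "resolution": "cg", "rho0": solvent.rho0,
            "deuterium_fraction": solvent.deuterium_fraction,
            "slc": correction.slc if correction.enabled else 0.0,
            "sasa_cutoff": correction.sasa_cutoff, "seed": seed,
        },
    )


def intensity_gradients(
    decomposition: BeadDecomposition,
    params: BeadParameterSet,
    q_grid: np.ndarray,
    solvent: SolventModel | None = None,
    correction: SolvationCorrection | None = None,
    seed: int | None = None,
    deterministic_hd: bool = False,
    per_bead_sasa: np.ndarray | None = None,
    center: str = "scattering",
) -> GradientSet:
    """Analytic dI(q)/dR_bead with SASA flags frozen during differentiation."""
    solvent = solvent or SolventModel()
    correction = correction or SolvationCorrection()
    q = np.asarray(q_grid, dtype=float)
    F, rho, deut = _bead_form_factors(
        decomposition, params, q, solvent, correction, seed,
        deterministic_hd, per_bead_sasa, PROBE_RADIUS_DEFAULT,
    )
    if center == "scattering":
        xyz = scattering_centers(decomposition, solvent.mode, rho, deuterated=deut)
    else:
        xyz = decomposition.centers
    m = xyz.shape[0]
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    np.fill_diagonal(dist, 1.0)  # avoid 0/0; diagonal contributes nothing
    unit = diff / dist[:, :, None]
    grads = np.zeros((q.size, m, 3))
    for iq, qv in enumerate(q):
        ds = _dsinc(qv * dist) * qv
        np.fill_diagonal(ds, 0.0)
        f = F[:, iq]
        # dI/dR_i = sum_j 2 F_i F_j sinc'(q r_ij) q * (R_i - R_j)/r_ij
        coef = 2.0 * f[:, None] * f[None, :] * ds
        grads[iq] = np.einsum("ij,ijd->id", coef, unit)
    return GradientSet(q, grads)


# ---------------------------------------------------------------------------
# profile comparison
# ---------------------------------------------------------------------------


def _check_grids(a: Profile, b: Profile) -> None:
    if a.q.shape != b.q.shape or not np.allclose(a.q, b.q, rtol=0, atol=1e-9):
        raise ValueError("profiles are on different q grids")


def residuals_percent(test: Profile, reference: Profile) -> np.ndarray:
    """Per-q percent difference 100*(I_test - I_ref)/I_ref."""
    _check_grids(test, reference)
    return 100.0 * (test.intensity - reference.intensity) / reference.intensity


def log10_rmse(a: Profile, b: Profile, fit_scale: bool = True) -> float:
    """RMSE between log10 intensities, after an optional least-squares scale.

    The scale is a single multiplicative factor on ``a`` (an offset in log
    space, fitted in closed form); with ``fit_scale=False`` the raw RMSE is
    returned.
    """
    _check_grids(a, b)
    if np.any(a.intensity <= 0) or np.any(b.intensity <= 0):
        raise ValueError("log10 RMSE requires strictly positive intensities")
    la = np.log10(a.intensity)
    lb = np.log10(b.intensity)
    offset = float(np.mean(lb - la)) if fit_scale else 0.0
    return float(np.sqrt(np.mean((la + offset - lb) ** 2)))


def chi_squared(calc: Profile, experimental: Profile) -> float:
    """Reduced chi-squared of a calculated profile against experimental data.

    The calculated curve is interpolated onto the experimental grid; a
    multiplicative scale and a constant background are fitted by weighted
    least squares; the sum is reduced by N-1.
    """
    if experimental.sigma is None or np.any(experimental.sigma <= 0):
        raise ValueError("experimental profile must carry positive uncertainties")
    n = experimental.q.size
    if n < 3:
        raise ValueError("need at least 3 experimental points")
    icalc = np.interp(experimental.q, calc.q, calc.intensity)
    iexp = experimental.intensity
    w = 1.0 / experimental.sigma**2
    # weighted LSQ for scale c and background b: minimize sum w (c*icalc+b-iexp)^2
    amat = np.column_stack((icalc, np.ones(n)))
    aw = amat * np.sqrt(w)[:, None]
    yw = iexp * np.sqrt(w)
    (c, b), *_ = np.linalg.lstsq(aw, yw, rcond=None)
    return float(np.sum(w * (c * icalc + b - iexp) ** 2) / (n - 1))


def ensemble_average_profile(profiles: list[Profile]) -> Profile:
    """Arithmetic mean of intensities over matching q grids."""
    if not profiles:
        raise ValueError("no profiles to average")
    for p in profiles[1:]:
        _check_grids(p, profiles[0])
    mean = np.mean([p.intensity for p in profiles], axis=0)
    return Profile(profiles[0].q, mean, mode=profiles[0].mode,
                   metadata={"averaged_over": len(profiles)})


def guinier_rg(profile: Profile, qrg_max: float = 1.3) -> float:
    """Radius of gyration from the Guinier regime (ln I vs q^2, q*Rg < qrg_max).

    Iterates the window until the fitted Rg is self-consistent.
    """
    q = profile.q
    i = profile.intensity
    if np.any(i <= 0):
        raise ValueError("Guinier fit requires positive intensities")
    rg = 10.0
    for _ in range(50):
        mask = q * rg < qrg_max
        if mask.sum() < 3:
            raise ValueError("too few points in the Guinier window")
        slope, _ = np.polyfit(q[mask] ** 2, np.log(i[mask]), 1)
        if slope >= 0:
            raise ValueError("non-negative Guinier slope; no decay at low q")
        new_rg = float(np.sqrt(-3.0 * slope))
        if abs(new_rg - rg) < 1e-6:
            return new_rg
        rg = new_rg
    return rg


# ---------------------------------------------------------------------------
# profile I/O: SASBDB-style whitespace text, 2 or 3 columns, '#' comments
# ---------------------------------------------------------------------------


def read_profile(path, mode: str = "SAXS") -> Profile:
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] not in (2, 3):
        raise ValueError(f"expected 2 or 3 columns in {path}, got {data.shape[1]}")
    sigma = data[:, 2] if data.shape[1] == 3 else None
    return Profile(data[:, 0], data[:, 1], mode=mode, sigma=sigma)


def write_profile(profile: Profile, path, header: str = "") -> None:
    with open(path, "w") as fh:
        for line in header.splitlines():
            fh.write(f"# {line}\n")
        fh.write(f"# mode: {profile.mode}\n")
        for k, v in profile.metadata.items():
            fh.write(f"# {k}: {v}\n")
        fh.write("# q(1/A)  I(q)" + ("  sigma\n" if profile.sigma is not None else "\n"))
        for k in range(profile.q.size):
            row = f"{profile.q[k]:.6e} {profile.intensity[k]:.8e}"
            if profile.sigma is not None:
                row += f" {profile.sigma[k]:.8e}"
            fh.write(row + "\n")
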