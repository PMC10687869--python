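"""Bead form-factor parametrization via the single-bead approximation (SBA).

A bead's orientationally averaged squared form factor is the intra-bead Debye
sum over solvent-corrected atomic amplitudes ``f'_i(q) = phi_i(q) - rho g_i(q)``:

    F^2(q; rho) = sum_{i,k} f'_i f'_k sinc(q r_ik)

Expanding in the solvent density rho splits this into three rho-independent
terms that can be precomputed once per bead type,

    F^2(q; rho) = A(q) - rho * Mx(q) + rho^2 * S(q)

with ``A = sum phi_i phi_k sinc``, ``Mx = sum (phi_i g_k + g_i phi_k) sinc``
and ``S = sum g_i g_k sinc``. Any solvent density — including a per-bead
solvation-layer decrement and, for neutrons, any D2O fraction — can then be
applied at evaluation time at no extra cost. Term curves are averaged over
every bead instance across an ensemble and fitted to sixth-order polynomials
in q (21 coefficients per bead type and mode).

Modes: ``SAXS`` (Cromer-Mann amplitudes), ``SANS-H`` / ``SANS-D`` (coherent
neutron lengths with every bead hydrogen as H or as D respectively).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .bead_mapping import Bead, BeadDecomposition, map_structure
from .io_structures import Ensemble, Structure
from .scattering_factors import ScatteringTables, cromer_mann_f, excluded_volume_g, load_tables

__all__ = [
    "MODES",
    "BeadTermTable",
    "BeadParameterSet",
    "FitError",
    "ParameterFileError",
    "default_q_grid",
    "implicit_hydrogen_counts",
    "atomic_amplitudes",
    "sba_terms_single_frame",
    "average_terms",
    "fit_polynomial",
    "build_parameter_set",
    "write_params",
    "read_params",
]

MODES = ("SAXS", "SANS-H", "SANS-D")

#: Parametrization grid: 201 points from 1e-10 to 0.5 1/A in steps of 0.0025.
Q_MIN_DEFAULT = 1e-10
Q_MAX_DEFAULT = 0.5


class FitError(RuntimeError):
    """Raised when a polynomial fit is rank-deficient or under-determined."""


class ParameterFileError(ValueError):
    """Raised on malformed or version-incompatible parameter files."""


def default_q_grid(q_max: float = Q_MAX_DEFAULT, dq: float = 0.0025) -> np.ndarray:
    """Evaluation grid starting at 1e-10 (a numerically safe stand-in for 0)."""
    n = int(round(q_max / dq)) + 1
    grid = np.arange(n) * dq
    grid[0] = Q_MIN_DEFAULT
    return grid


def _sinc(x: np.ndarray) -> np.ndarray:
    # np.sinc is sin(pi x)/(pi x); rescale to sin(x)/x with sinc(0)=1
    return np.sinc(x / np.pi)


def implicit_hydrogen_counts(structure: Structure, tables: ScatteringTables | None = None) -> np.ndarray:
    """Hydrogens folded into each heavy atom in united-atom mode.

    Zero for structures that carry explicit hydrogens (they scatter
    individually). Terminal hydroxyls (free 5'-OH / 3'-OH, protonated
    N-terminus) are accounted for by position in the chain.
    """
    t = tables or load_tables()
    n = len(structure.atoms)
    counts = np.zeros(n, dtype=int)
    if any(a.element == "H" for a in structure.atoms):
        return counts
    for chain_id, chain_atoms in structure.chains().items():
        kind = structure.polymer_kind(chain_id)
        residues = [(k, v) for k, v in structure.residues() if k[0] == chain_id]
        polymer = "protein" if kind == "protein" else ("RNA" if kind == "RNA" else "DNA")
        if kind == "other":
            continue
        for pos, (key, atoms) in enumerate(residues):
            rname = atoms[0].residue_name
            has_p = any(a.name == "P" for a in atoms)
            for a in atoms:
                c = t.hydrogen_count(rname, a.name, polymer)
                if kind == "protein" and pos == 0 and a.name == "N" and rname != "PRO":
                    c += 2  # protonated N-terminal ammonium (3 H total)
                if kind != "protein":
                    if a.name == "O5'" and not has_p and pos == 0:
                        c += 1  # free 5'-hydroxyl
                    if a.name == "O3'" and pos == len(residues) - 1:
                        c += 1  # free 3'-hydroxyl
                counts[a.index] = c
    return counts


def atomic_amplitudes(
    structure: Structure,
    indices,
    q: np.ndarray,
    mode: str,
    tables: ScatteringTables | None = None,
    implicit_h: np.ndarray | None = None,
):
    """Per-atom amplitude curves (phi, g) for a subset of atoms.

    Returns arrays of shape (n_atoms, n_q): ``phi`` the atomic amplitude
    (Cromer-Mann for SAXS; flat neutron length for SANS) and ``g`` the
    excluded-volume Gaussian. In SANS-H / SANS-D every hydrogen — explicit or
    implicit — takes b_H / b_D.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be non-negative")
    t = tables or load_tables()
    if implicit_h is None:
        implicit_h = implicit_hydrogen_counts(structure, t)
    atoms = [structure.atoms[i] for i in indices]
    phi = np.empty((len(atoms), q.size))
    g = np.empty((len(atoms), q.size))
    for row, a in enumerate(atoms):
        n_h = int(implicit_h[a.index])
        g[row] = excluded_volume_g(t.group_volume(a.element, n_h), q)
        if mode == "SAXS":
            phi[row] = cromer_mann_f(t.group_cm(a.element, n_h), q)
        else:
            iso = "H" if mode == "SANS-H" else "D"
            if a.element == "H":
                phi[row] = t.neutron_b(iso)
            else:
                phi[row] = t.group_neutron_b(a.element, n_h, hydrogen_isotope=iso)
    return phi, g


def sba_terms_single_frame(
    bead: Bead,
    structure: Structure,
    q_grid: np.ndarray,
    mode: str,
    tables: ScatteringTables | None = None,
    implicit_h: np.ndarray | None = None,
):
    """The three SBA term curves (A, Mx, S) of one bead instance.

    ``F^2(q; rho) = A - rho*Mx + rho^2*S`` is an algebraic identity with the
    direct Debye sum over ``phi_i - rho g_i``.
    """
    q = np.asarray(q_grid, dtype=float)
    phi, g = atomic_amplitudes(structure, bead.atom_indices, q, mode, tables, implicit_h)
    xyz = np.array([structure.atoms[i].position for i in bead.atom_indices])
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    w = _sinc(d[:, :, None] * q[None, None, :])  # (m, m, nq)
    a_term = np.einsum("iq,kq,ikq->q", phi, phi, w)
    mx_term = 2.0 * np.einsum("iq,kq,ikq->q", phi, g, w)
    s_term = np.einsum("iq,kq,ikq->q", g, g, w)
    return a_term, mx_term, s_term


@dataclass
class BeadTermTable:
    """Ensemble-averaged A / Mx / S curves for one bead type and mode."""

    bead_type: str
    mode: str
    q_grid: np.ndarray
    A: np.ndarray
    Mx: np.ndarray
    S: np.ndarray
    n_instances: int = 1
    n_frames_averaged: int = 1

    def __post_init__(self):
        for name, cur in (("A", self.A), ("S", self.S), ("Mx", self.Mx)):
            if not np.all(np.isfinite(cur)):
                raise ValueError(f"{name} curve of {self.bead_type} not finite")
        if np.any(self.A < 0) or np.any(self.S < 0):
            raise ValueError(
                f"negative atomic/solvent term for bead type {self.bead_type}: "
                "single-bead Debye sums must stay positive at SAS-relevant q"
            )

    def f_squared(self, rho: float) -> np.ndarray:
        return self.A - rho * self.Mx + rho**2 * self.S


def average_terms(
    ensemble: Ensemble,
    q_grid: np.ndarray,
    mode: str,
    decomposition_rule=map_structure,
    tables: ScatteringTables | None = None,
) -> dict[str, BeadTermTable]:
    """Average SBA terms over every bead instance of each type across frames.

    Pooled instance-weighted averaging: all instances of a type in all frames
    contribute equally.
    """
    t = tables or load_tables()
    q = np.asarray(q_grid, dtype=float)
    acc: dict[str, list] = {}
    counts: dict[str, int] = {}
    first = ensemble.frames[0]
    dec0 = decomposition_rule(first)
    implicit0 = implicit_hydrogen_counts(first, t)
    for frame in ensemble.frames:
        for bead in dec0.beads:
            atoms = [frame.atoms[i] for i in bead.atom_indices]
            fb = Bead(bead.type_label, np.mean([a.position for a in atoms], axis=0), bead.atom_indices)
            a_c, mx_c, s_c = sba_terms_single_frame(fb, frame, q, mode, t, implicit0)
            if bead.type_label not in acc:
                acc[bead.type_label] = [np.zeros_like(q) for _ in range(3)]
                counts[bead.type_label] = 0
            acc[bead.type_label][0] += a_c
            acc[bead.type_label][1] += mx_c
            acc[bead.type_label][2] += s_c
            counts[bead.type_label] += 1
    out = {}
    for label, (a_s, mx_s, s_s) in acc.items():
        n = counts[label]
        out[label] = BeadTermTable(
            label, mode, q, a_s / n, mx_s / n, s_s / n,
            n_instances=n, n_frames_averaged=len(ensemble.frames),
        )
    return out


def fit_polynomial(curve: np.ndarray, q_grid: np.ndarray, order: int = 6):
    """Least-squares polynomial fit in q; returns (coefficients, residual norm).

    Coefficients are in the power basis, low order first (7 values for the
    default sixth-order fit).
    """
    q = np.asarray(q_grid, dtype=float)
    y = np.asarray(curve, dtype=float)
    if q.size < order + 2:
        raise FitError(f"need at least {order + 2} grid points for an order-{order} fit")
    # scale q to [0,1] for conditioning, then transform back to plain powers
    scale = q.max()
    with warnings.catch_warnings():
        warnings.simplefilter("error", np.exceptions.RankWarning)
        try:
            c_scaled = np.polynomial.polynomial.polyfit(q / scale, y, order)
        except np.exceptions.RankWarning as exc:  # pragma: no cover - defensive
            raise FitError(f"rank-deficient polynomial fit: {exc}") from exc
    coeffs = c_scaled / scale ** np.arange(order + 1)
    resid = float(np.linalg.norm(np.polynomial.polynomial.polyval(q, coeffs) - y))
    return coeffs, resid


@dataclass
class BeadParameterSet:
    """Fitted polynomial coefficients per (bead type, mode) over [q_min, q_max].

    ``coefficients[bead_type][mode]`` holds the three 7-vectors A, Mx, S.
    Evaluation outside the fitted q range raises, never extrapolates.
    """

    q_min: float
    q_max: float
    order: int
    modes: tuple[str, ...]
    coefficients: dict[str, dict[str, dict[str, np.ndarray]]]
    provenance: dict = field(default_factory=dict)
    version: int = 1

    def bead_types(self) -> list[str]:
        return sorted(self.coefficients)

    def _check_range(self, q: np.ndarray) -> None:
        if np.any(q > self.q_max + 1e-12) or np.any(q < 0):
            raise ValueError(
                f"q outside fitted validity range [0, {self.q_max}]: refusing to extrapolate"
            )

    def term_curves(self, bead_type: str, mode: str, q: np.ndarray):
        q = np.asarray(q, dtype=float)
        self._check_range(q)
        try:
            c = self.coefficients[bead_type][mode]
        except KeyError:
            raise KeyError(f"no parameters for bead type {bead_type!r} in mode {mode!r}") from None
        pv = np.polynomial.polynomial.polyval
        return pv(q, c["A"]), pv(q, c["Mx"]), pv(q, c["S"])

    def f_squared(self, bead_type: str, mode: str, q: np.ndarray, rho: float) -> np.ndarray:
        a_c, mx_c, s_c = self.term_curves(bead_type, mode, q)
        return a_c - rho * mx_c + rho**2 * s_c

    def form_factor(self, bead_type: str, mode: str, q: np.ndarray, rho: float) -> np.ndarray:
        """F(q; rho) = sqrt(max(F^2, 0)); logs if clipping ever activates."""
        f2 = self.f_squared(bead_type, mode, q, rho)
        if np.any(f2 < 0):
            warnings.warn(
                f"clipped negative F^2 for bead type {bead_type} (min {f2.min():.3g})",
                stacklevel=2,
            )
        return np.sqrt(np.clip(f2, 0.0, None))


MIN_INSTANCES_DEFAULT = 10


def build_parameter_set(
    ensemble: Ensemble,
    q_grid: np.ndarray | None = None,
    modes=MODES,
    order: int = 6,
    decomposition_rule=map_structure,
    tables: ScatteringTables | None = None,
    min_instances: int = MIN_INSTANCES_DEFAULT,
) -> BeadParameterSet:
    """Full parametrization: average terms over the ensemble, fit polynomials."""
    q = default_q_grid() if q_grid is None else np.asarray(q_grid, dtype=float)
    unknown = set(modes) - set(MODES)
    if unknown:
        raise ValueError(f"unknown modes {sorted(unknown)}")
    coefficients: dict[str, dict[str, dict[str, np.ndarray]]] = {}
    provenance: dict = {"n_frames": len(ensemble.frames), "residual_norms": {}, "warnings": []}
    for mode in modes:
        tabs = average_terms(ensemble, q, mode, decomposition_rule, tables)
        for label, tab in tabs.items():
            if tab.n_instances < min_instances and mode == modes[0]:
                provenance["warnings"].append(
                    f"bead type {label}: only {tab.n_instances} instances averaged"
                )
            dest = coefficients.setdefault(label, {})
            entry = {}
            res = {}
            for term_name, curve in (("A", tab.A), ("Mx", tab.Mx), ("S", tab.S)):
                c, r = fit_polynomial(curve, q, order)
                entry[term_name] = c
                res[term_name] = r
            dest[mode] = entry
            provenance["residual_norms"][f"{label}/{mode}"] = res
    return BeadParameterSet(
        q_min=float(q.min()),
        q_max=float(q.max()),
        order=order,
        modes=tuple(modes),
        coefficients=coefficients,
        provenance=provenance,
    )


FILE_VERSION = 1


def write_params(pset: BeadParameterSet, path) -> None:
    """Write a parameter set as self-describing JSON (lossless round trip)."""
    doc = {
        "format": "sasbead-params",
        "version": FILE_VERSION,
        "q_min": pset.q_min,
        "q_max": pset.q_max,
        "order": pset.order,
        "modes": list(pset.modes),
        "bead_types": {
            label: {
                mode: {k: [float(x) for x in v] for k, v in terms.items()}
                for mode, terms in per_mode.items()
            }
            for label, per_mode in pset.coefficients.items()
        },
        "provenance": pset.provenance,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_params(path) -> BeadParameterSet:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParameterFileError(f"cannot parse parameter file {path}: {exc}") from exc
    if doc.get("format") != "sasbead-params":
        raise ParameterFileError(f"{path} is not a bead parameter file")
    if doc.get("version") != FILE_VERSION:
        raise ParameterFileError(
            f"parameter file version {doc.get('version')} unsupported (expected {FILE_VERSION})"
        )
    coefficients = {
        label: {
            mode: {k: np.asarray(v, dtype=float) for k, v in terms.items()}
            for mode, terms in per_mode.items()
        }
        for label, per_mode in doc["bead_types"].items()
    }
    return BeadParameterSet(
        q_min=float(doc["q_min"]),
        q_max=float(doc["q_max"]),
        order=int(doc["order"]),
        modes=tuple(doc["modes"]),
        coefficients=coefficients,
        provenance=doc.get("provenance", {}),
        version=int(doc["version"]),
    )
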