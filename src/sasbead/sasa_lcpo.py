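"""Solvent-accessible surface area via LCPO, with a numerical cross-check.

LCPO (linear combination of pairwise overlaps) approximates each atom's SASA
from the isolated-sphere area and sums of pairwise sphere-overlap areas:

    A_i = P1*S_i + P2*sum_j A_ij + P3*sum_{j,k} A_jk + P4*sum_j A_ij sum_k A_jk

where j, k run over overlapping neighbors of i (k also a neighbor of j),
S_i = 4 pi (R_i + probe)^2 and A_ij is the area of sphere i buried inside
sphere j. Parameters are per atom class (element + bonded heavy-neighbor
count, with sp2/carboxylate variants resolved from standard residue atom
names). LCPO is a heavy-atom method: hydrogens get zero area.

``shrake_rupley_sasa`` is an independent numerical oracle (deterministic
Fibonacci sphere point set) used for validation.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .bead_mapping import BeadDecomposition
from .io_structures import Structure
from .scattering_factors import _read_tsv

__all__ = [
    "LCPOParameterError",
    "load_lcpo_params",
    "classify_atoms",
    "lcpo_sasa",
    "shrake_rupley_sasa",
    "bead_sasa",
    "solvated_flags",
    "SasaResult",
]

PROBE_RADIUS_DEFAULT = 1.4  # water probe, Angstrom

#: van der Waals radii used for both LCPO and the numerical oracle (A).
VDW_RADII = {"C": 1.70, "N": 1.65, "O": 1.60, "S": 1.90, "P": 1.90}

# Bond-detection cutoffs for heavy-neighbor counting (A).
BOND_CUTOFF = 1.9
BOND_CUTOFF_SP = 2.2  # bonds involving S or P

# sp2 carbons by residue (aromatic rings, carbonyl/carboxyl/guanidinium C).
_SP2_CARBONS = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "CD2", "CE1"},
    "ARG": {"CZ"},
    "ASP": {"CG"},
    "GLU": {"CD"},
    "ASN": {"CG"},
    "GLN": {"CD"},
}
_SP2_BASE_CARBONS = {"C2", "C4", "C5", "C6", "C8"}
_NUCLEOTIDES = {"A", "C", "G", "U", "DA", "DC", "DG", "DT", "T"}
_CARBOXYLATE_O = {
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
}


class LCPOParameterError(KeyError):
    """Raised when an atom cannot be assigned an LCPO parameter class."""


def load_lcpo_params() -> dict[str, tuple[float, float, float, float, float]]:
    """Bundled LCPO table: class -> (radius, P1, P2, P3, P4)."""
    out = {}
    for row in _read_tsv("lcpo_params.tsv"):
        label, *vals = row
        v = [float(x) for x in vals]
        out[label] = (v[0], v[1], v[2], v[3], v[4])
    return out


def _heavy_neighbor_counts(structure: Structure, heavy_idx: np.ndarray) -> np.ndarray:
    xyz = structure.positions[heavy_idx]
    elements = [structure.atoms[i].element for i in heavy_idx]
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(r=BOND_CUTOFF_SP, output_type="ndarray")
    counts = np.zeros(len(heavy_idx), dtype=int)
    for i, j in pairs:
        d = np.linalg.norm(xyz[i] - xyz[j])
        cutoff = BOND_CUTOFF_SP if ("S" in (elements[i], elements[j]) or "P" in (elements[i], elements[j])) else BOND_CUTOFF
        if d <= cutoff:
            counts[i] += 1
            counts[j] += 1
    return counts


def classify_atoms(structure: Structure, params: dict | None = None):
    """LCPO class per heavy atom; returns (heavy indices, radii, P matrix).

    Atoms with zero bonded neighbors fall back to the exact isolated sphere
    (P1=1, P2..P4=0).
    """
    params = params or load_lcpo_params()
    heavy_idx = np.array([a.index for a in structure.atoms if a.element != "H"], dtype=int)
    if heavy_idx.size == 0:
        raise LCPOParameterError("structure has no heavy atoms")
    counts = _heavy_neighbor_counts(structure, heavy_idx)
    radii = np.empty(heavy_idx.size)
    pmat = np.empty((heavy_idx.size, 4))
    for row, idx in enumerate(heavy_idx):
        a = structure.atoms[idx]
        el = a.element
        if el not in VDW_RADII:
            raise LCPOParameterError(f"no LCPO radius for element {el!r} (atom {a.name})")
        n = int(counts[row])
        key = _class_key(a.residue_name, a.name, el, n)
        if key is None:
            # no bonded neighbors: exact sphere minus first-order pairwise
            # overlap (inclusion-exclusion; exact for an isolated atom and
            # for any non-bonded pair)
            radii[row] = VDW_RADII[el]
            pmat[row] = (1.0, -1.0, 0.0, 0.0)
            continue
        if key not in params:
            raise LCPOParameterError(
                f"no LCPO parameters for atom {a.name} ({a.residue_name}): class {key}"
            )
        r, p1, p2, p3, p4 = params[key]
        radii[row] = r
        pmat[row] = (p1, p2, p3, p4)
    return heavy_idx, radii, pmat


def _class_key(resname: str, atname: str, el: str, n_neighbors: int) -> str | None:
    if n_neighbors == 0:
        return None
    resname = resname.strip()
    if el == "C":
        n = min(n_neighbors, 4)
        sp2 = (
            atname == "C"  # backbone carbonyl
            or atname in _SP2_CARBONS.get("HIS" if resname.startswith("HI") or resname.startswith("HS") else resname, set())
            or (resname in _NUCLEOTIDES and atname in _SP2_BASE_CARBONS)
        )
        if sp2 and n in (2, 3):
            return f"C_sp2_{n}"
        return f"C_sp3_{n}"
    if el == "O":
        n = min(n_neighbors, 2)
        if atname in ("OXT", "OP1", "OP2", "OP3", "O1P", "O2P") or (resname, atname) in _CARBOXYLATE_O:
            return "O_carboxylate_1"
        if atname == "O" or (resname in _NUCLEOTIDES and atname in ("O2", "O4", "O6")) or (
            resname in ("ASN", "GLN") and atname in ("OD1", "OE1")
        ):
            return "O_sp2_1"
        return f"O_sp3_{n}"
    if el == "N":
        return f"N_sp3_{min(n_neighbors, 3)}"
    if el == "S":
        return f"S_sp3_{min(n_neighbors, 2)}"
    if el == "P":
        return f"P_sp3_{min(max(n_neighbors, 3), 4)}"
    raise LCPOParameterError(f"unsupported element {el!r}")


def _overlap_area(r1: float, r2: float, d: float) -> float:
    """Area of the cap of sphere 1 buried inside sphere 2 (both inflated)."""
    if d >= r1 + r2:
        return 0.0
    a = 2.0 * np.pi * r1 * (r1 - d / 2.0 - (r1 * r1 - r2 * r2) / (2.0 * d))
    return float(np.clip(a, 0.0, 4.0 * np.pi * r1 * r1))


def lcpo_sasa(
    structure: Structure,
    params: dict | None = None,
    probe_radius: float = PROBE_RADIUS_DEFAULT,
) -> np.ndarray:
    """Per-atom SASA (A^2), aligned to structure atoms; hydrogens get 0."""
    heavy_idx, radii, pmat = classify_atoms(structure, params)
    xyz = structure.positions[heavy_idx]
    r = radii + probe_radius
    n = heavy_idx.size
    tree = cKDTree(xyz)
    # neighbor sets: overlap when d < r_i + r_j
    rmax = float(r.max())
    neighbor: list[np.ndarray] = []
    for i in range(n):
        cand = np.array(tree.query_ball_point(xyz[i], r[i] + rmax), dtype=int)
        cand = cand[cand != i]
        if cand.size:
            d = np.linalg.norm(xyz[cand] - xyz[i], axis=1)
            cand = cand[d < r[i] + r[cand]]
        neighbor.append(cand)
    dist = {}

    def d_of(i, j):
        key = (i, j) if i < j else (j, i)
        if key not in dist:
            dist[key] = float(np.linalg.norm(xyz[i] - xyz[j]))
        return dist[key]

    areas = np.zeros(len(structure.atoms))
    for row in range(n):
        p1, p2, p3, p4 = pmat[row]
        s1 = 4.0 * np.pi * r[row] ** 2
        nb = neighbor[row]
        sum_aij = 0.0
        sum_ajk = 0.0
        sum_aij_ajk = 0.0
        nbset = set(nb.tolist())
        for j in nb:
            aij = _overlap_area(r[row], r[j], d_of(row, j))
            sum_aij += aij
            inner = 0.0
            for k in neighbor[j]:
                if k == row or k not in nbset:
                    continue
                ajk = _overlap_area(r[j], r[k], d_of(j, k))
                sum_ajk += ajk
                inner += ajk
            sum_aij_ajk += aij * inner
        a_i = p1 * s1 + p2 * sum_aij + p3 * sum_ajk + p4 * sum_aij_ajk
        areas[heavy_idx[row]] = max(a_i, 0.0)
    return areas


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5**0.5) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def shrake_rupley_sasa(
    structure: Structure,
    radii: dict[str, float] | None = None,
    probe_radius: float = PROBE_RADIUS_DEFAULT,
    n_points: int = 960,
) -> np.ndarray:
    """Numerical per-atom SASA oracle (A^2); heavy atoms only, deterministic."""
    if n_points < 92:
        raise ValueError("n_points must be at least 92")
    radii = radii or VDW_RADII
    heavy = [a for a in structure.atoms if a.element != "H"]
    xyz = np.array([a.position for a in heavy])
    r = np.array([radii[a.element] for a in heavy]) + probe_radius
    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(xyz)
    areas = np.zeros(len(structure.atoms))
    rmax = float(r.max())
    for i, atom in enumerate(heavy):
        pts = xyz[i] + r[i] * sphere
        cand = np.array(tree.query_ball_point(xyz[i], r[i] + rmax), dtype=int)
        cand = cand[cand != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in cand:
            exposed &= np.linalg.norm(pts - xyz[j], axis=1) >= r[j]
            if not exposed.any():
                break
        areas[atom.index] = 4.0 * np.pi * r[i] ** 2 * exposed.mean()
    return areas


class SasaResult:
    """Per-atom and per-bead SASA (A^2) for one structure/decomposition."""

    def __init__(self, per_atom: np.ndarray, decomposition: BeadDecomposition, probe_radius: float):
        self.per_atom = per_atom
        self.per_bead = bead_sasa(per_atom, decomposition)
        self.probe_radius = probe_radius


def bead_sasa(per_atom: np.ndarray, decomposition: BeadDecomposition) -> np.ndarray:
    """Per-bead SASA: sum of member-atom areas (hydrogens contribute 0)."""
    return np.array(
        [float(sum(per_atom[i] for i in b.atom_indices)) for b in decomposition.beads]
    )


def solvated_flags(per_bead_A2: np.ndarray, sasa_cutoff_nm2: float) -> np.ndarray:
    """Solvent-exposure flags: bead area (converted to nm^2) > cutoff.

    The cutoff is in nm^2 as quoted in the field; areas are internal A^2
    (1 nm^2 = 100 A^2).
    """
    if sasa_cutoff_nm2 < 0:
        raise ValueError("SASA cutoff must be non-negative")
    return np.asarray(per_bead_A2, dtype=float) / 100.0 > sasa_cutoff_nm2
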