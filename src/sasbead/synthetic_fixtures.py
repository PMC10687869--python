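"""Deterministic synthetic structures for testing and parametrization.

Builds idealized peptides (helix / extended, standard backbone geometry with
ideal bond lengths, angles and phi/psi dihedrals), single-stranded RNA with
free 5'-OH and 3'-OH termini, jittered conformational ensembles, and uniform
sphere clusters for Debye/Guinier oracles. Side chains and nucleotides are
grown as internal-coordinate trees (NeRF placement) from embedded residue
topologies — chemically plausible geometry, not force-field minimized;
aromatic ring closures are left open, which no consumer of these fixtures
depends on.

Everything is seeded and reproducible: identical spec + seed gives identical
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_structures import Atom, Ensemble, Structure

__all__ = [
    "FixtureSpec",
    "make_peptide",
    "make_rna",
    "make_ensemble",
    "make_sphere_cluster",
    "make_dimer",
    "build_fixture",
    "AA1TO3",
]

AA1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# (phi, psi) per conformation, degrees
CONFORMATIONS = {"helix": (-57.0, -47.0), "extended": (-120.0, 120.0)}

# side-chain trees: (atom, parent); children listed main-branch first
SIDE_CHAINS: dict[str, list[tuple[str, str]]] = {
    "ALA": [("CB", "CA")],
    "ARG": [("CB", "CA"), ("CG", "CB"), ("CD", "CG"), ("NE", "CD"),
            ("CZ", "NE"), ("NH1", "CZ"), ("NH2", "CZ")],
    "ASN": [("CB", "CA"), ("CG", "CB"), ("OD1", "CG"), ("ND2", "CG")],
    "ASP": [("CB", "CA"), ("CG", "CB"), ("OD1", "CG"), ("OD2", "CG")],
    "CYS": [("CB", "CA"), ("SG", "CB")],
    "GLN": [("CB", "CA"), ("CG", "CB"), ("CD", "CG"), ("OE1", "CD"), ("NE2", "CD")],
    "GLU": [("CB", "CA"), ("CG", "CB"), ("CD", "CG"), ("OE1", "CD"), ("OE2", "CD")],
    "GLY": [],
    "HIS": [("CB", "CA"), ("CG", "CB"), ("ND1", "CG"), ("CE1", "ND1"),
            ("CD2", "CG"), ("NE2", "CD2")],
    "ILE": [("CB", "CA"), ("CG1", "CB"), ("CD1", "CG1"), ("CG2", "CB")],
    "LEU": [("CB", "CA"), ("CG", "CB"), ("CD1", "CG"), ("CD2", "CG")],
    "LYS": [("CB", "CA"), ("CG", "CB"), ("CD", "CG"), ("CE", "CD"), ("NZ", "CE")],
    "MET": [("CB", "CA"), ("CG", "CB"), ("SD", "CG"), ("CE", "SD")],
    "PHE": [("CB", "CA"), ("CG", "CB"), ("CD1", "CG"), ("CE1", "CD1"),
            ("CZ", "CE1"), ("CD2", "CG"), ("CE2", "CD2")],
    "PRO": [("CB", "CA"), ("CG", "CB"), ("CD", "CG")],
    "SER": [("CB", "CA"), ("OG", "CB")],
    "THR": [("CB", "CA"), ("OG1", "CB"), ("CG2", "CB")],
    "TRP": [("CB", "CA"), ("CG", "CB"), ("CD1", "CG"), ("NE1", "CD1"),
            ("CD2", "CG"), ("CE2", "CD2"), ("CZ2", "CE2"),
            ("CE3", "CD2"), ("CZ3", "CE3"), ("CH2", "CZ3")],
    "TYR": [("CB", "CA"), ("CG", "CB"), ("CD1", "CG"), ("CE1", "CD1"),
            ("CZ", "CE1"), ("OH", "CZ"), ("CD2", "CG"), ("CE2", "CD2")],
    "VAL": [("CB", "CA"), ("CG1", "CB"), ("CG2", "CB")],
}

# nucleobase trees rooted at the glycosidic nitrogen (child of C1')
BASES: dict[str, list[tuple[str, str]]] = {
    "A": [("N9", "C1'"), ("C8", "N9"), ("N7", "C8"), ("C4", "N9"),
          ("C5", "C4"), ("C6", "C5"), ("N6", "C6"), ("N1", "C6"),
          ("C2", "N1"), ("N3", "C2")],
    "G": [("N9", "C1'"), ("C8", "N9"), ("N7", "C8"), ("C4", "N9"),
          ("C5", "C4"), ("C6", "C5"), ("O6", "C6"), ("N1", "C6"),
          ("C2", "N1"), ("N2", "C2"), ("N3", "C2")],
    "C": [("N1", "C1'"), ("C2", "N1"), ("O2", "C2"), ("N3", "C2"),
          ("C4", "N3"), ("N4", "C4"), ("C5", "C4"), ("C6", "C5")],
    "U": [("N1", "C1'"), ("C2", "N1"), ("O2", "C2"), ("N3", "C2"),
          ("C4", "N3"), ("O4", "C4"), ("C5", "C4"), ("C6", "C5")],
}

_DOUBLE_BOND_O = {"O", "OXT", "OD1", "OD2", "OE1", "OE2", "O2", "O4", "O6", "OP1", "OP2"}


def _bond_length(el_parent: str, name_child: str, el_child: str) -> float:
    if el_child == "H":
        return {"C": 1.09, "N": 1.01, "O": 0.96, "S": 1.34}.get(el_parent, 1.0)
    pair = frozenset((el_parent, el_child))
    if el_child == "O" and name_child in _DOUBLE_BOND_O:
        return 1.23
    if pair == frozenset(("C", "C")):
        return 1.52
    if pair == frozenset(("C", "N")):
        return 1.43
    if pair == frozenset(("C", "O")):
        return 1.42
    if pair == frozenset(("C", "S")):
        return 1.81
    if pair == frozenset(("P", "O")):
        return 1.60
    return 1.50


def _place(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NeRF: position d from the a-b-c frame with given internal coordinates."""
    ang = np.deg2rad(angle_deg)
    dih = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-8:  # colinear frame: pick any perpendicular
        alt = np.array([1.0, 0.0, 0.0]) if abs(bc[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        n = np.cross(alt, bc)
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * np.cos(ang), bond * np.sin(ang) * np.cos(dih), bond * np.sin(ang) * np.sin(dih)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


class _ChainBuilder:
    """Grows an internal-coordinate tree of named atoms."""

    def __init__(self):
        self.pos: dict[str, np.ndarray] = {}
        self.parent: dict[str, str] = {}
        self.n_children: dict[str, int] = {}
        self._branch_slots = (-60.0, 60.0, 120.0, -120.0, 0.0)

    def seed(self, keys: list[str], coords: list[np.ndarray]):
        for i, (k, c) in enumerate(zip(keys, coords)):
            self.pos[k] = np.asarray(c, dtype=float)
            if i > 0:
                self.parent[k] = keys[i - 1]
                self.n_children[keys[i - 1]] = self.n_children.get(keys[i - 1], 0) + 1

    def frame(self, key: str):
        c = self.parent[key]
        b = self.parent.get(c)
        if b is None:
            b = next(k for k in self.pos if k != key and k != c)
        a = self.parent.get(b)
        if a is None:
            a = next(k for k in self.pos if k not in (key, c, b))
        return self.pos[a], self.pos[b], self.pos[c]

    def add(self, key: str, parent: str, bond: float, angle: float = 111.0,
            dihedral: float | None = None):
        self.parent[key] = parent
        slot_i = self.n_children.get(parent, 0)
        self.n_children[parent] = slot_i + 1
        a, b, c = self.frame(key)
        if dihedral is not None:
            self.pos[key] = _place(a, b, c, bond, angle, dihedral)
            return self.pos[key]
        # deterministic steric choice: the dihedral slot with the best
        # clearance from everything already placed (parent excluded)
        others = np.array([v for k, v in self.pos.items() if k != parent])
        best, best_clearance = None, -1.0
        for cand in (180.0,) + self._branch_slots:
            p = _place(a, b, c, bond, angle, cand)
            clearance = float(np.min(np.linalg.norm(others - p, axis=1))) if len(others) else 10.0
            if clearance > best_clearance + 1e-9:
                best, best_clearance = p, clearance
        self.pos[key] = best
        return best


def _normalize_sequence(sequence) -> list[str]:
    if isinstance(sequence, str):
        out = []
        for ch in sequence:
            if ch.upper() not in AA1TO3:
                raise ValueError(f"unknown amino-acid letter {ch!r}")
            out.append(AA1TO3[ch.upper()])
        return out
    out = []
    for code in sequence:
        c = code.upper()
        if c not in SIDE_CHAINS and not c.startswith("HIS"):
            raise ValueError(f"unknown residue code {code!r}")
        out.append(c)
    return out


def _h_names(heavy_name: str, count: int) -> list[str]:
    suffix = heavy_name[1:] if len(heavy_name) > 1 else ""
    if count == 1:
        return [f"H{suffix}" if suffix else "H"]
    return [f"H{suffix}{i}" for i in range(1, count + 1)]


def make_peptide(
    sequence,
    conformation: str = "helix",
    seed: int = 0,
    hydrogens: bool = False,
    jitter_sigma: float = 0.0,
    chain_id: str = "A",
) -> Structure:
    """Idealized peptide on an ideal backbone (helix / extended / perturbed).

    ``sequence`` is a 1-letter string or a list of 3-letter codes; histidine
    tautomer variants HISD / HISE / HISP are accepted as 3-letter codes and
    expressed through the hydrogens attached (residue name stays HIS), so they
    are only distinguishable with ``hydrogens=True``.
    """
    residues = _normalize_sequence(sequence)
    if conformation == "perturbed":
        phi, psi = CONFORMATIONS["helix"]
        if jitter_sigma <= 0:
            jitter_sigma = 0.3
    else:
        try:
            phi, psi = CONFORMATIONS[conformation]
        except KeyError:
            raise ValueError(f"unknown conformation {conformation!r}") from None
    from .scattering_factors import load_tables

    tables = load_tables()
    bld = _ChainBuilder()
    atoms: list[Atom] = []
    idx = 0

    def emit(name: str, element: str, resname: str, resseq: int, pos: np.ndarray):
        nonlocal idx
        atoms.append(Atom(idx, name, element, resname, resseq, chain_id, pos))
        idx += 1

    # phase 1: the whole backbone, so side-chain placement can steer clear
    for i, res in enumerate(residues, start=1):
        tag = f"{i}:"
        prev = f"{i - 1}:"
        if i == 1:
            bld.seed(
                [f"{tag}N", f"{tag}CA"],
                [np.zeros(3), np.array([1.458, 0.0, 0.0])],
            )
            bld.pos[f"{tag}C"] = _place(
                np.array([0.0, 1.0, 0.0]), bld.pos[f"{tag}N"], bld.pos[f"{tag}CA"],
                1.525, 111.0, 155.0,
            )
            bld.parent[f"{tag}C"] = f"{tag}CA"
            bld.n_children[f"{tag}CA"] = 1
        else:
            bld.add(f"{tag}N", f"{prev}C", 1.329, 116.2, psi)
            bld.add(f"{tag}CA", f"{tag}N", 1.458, 121.7, 180.0)  # omega trans
            bld.add(f"{tag}C", f"{tag}CA", 1.525, 111.0, phi)
        # carbonyl O anti to the next N
        bld.add(f"{tag}O", f"{tag}C", 1.231, 120.8, psi + 180.0)
        if i == len(residues):
            bld.add(f"{tag}OXT", f"{tag}C", 1.25, 117.0, psi)

    # phase 2: side chains and hydrogens, residue by residue
    for i, res in enumerate(residues, start=1):
        tag = f"{i}:"
        resname = "HIS" if res.startswith("HIS") else res
        tree = SIDE_CHAINS["HIS"] if res.startswith("HIS") else SIDE_CHAINS[res]
        if tree:
            # CB sits ~122 degrees from C around the N-CA axis (L-amino acid)
            bld.add(f"{tag}CB", f"{tag}CA", 1.53, 110.5, phi - 122.0)
            for name, parent in tree[1:]:
                el = name[0] if name[0] in "CNOS" else "C"
                angle = 120.0 if res in ("PHE", "TYR", "TRP", "HIS", "ARG") and parent != "CB" else 111.0
                bld.add(f"{tag}{name}", f"{tag}{parent}",
                        _bond_length(parent[0], name, el), angle)
        heavy_order = ["N", "CA", "C", "O"] + [n for n, _ in tree] + (
            ["OXT"] if i == len(residues) else []
        )
        for name in heavy_order:
            emit(name, name[0], resname, i, bld.pos[f"{tag}{name}"])
        if hydrogens:
            for name in heavy_order:
                n_h = tables.hydrogen_count(res, name, "protein")
                if i == 1 and name == "N" and res != "PRO":
                    n_h += 2
                for hname in _h_names(name, n_h):
                    pos = bld.add(f"{tag}{hname}", f"{tag}{name}",
                                  _bond_length(name[0], hname, "H"), 109.5)
                    emit(hname, "H", resname, i, pos)

    st = Structure(atoms)
    if conformation == "perturbed" or jitter_sigma > 0:
        rng = np.random.default_rng(seed)
        st = st.with_positions(st.positions + rng.normal(0.0, jitter_sigma, (len(atoms), 3)))
    return st


SUGAR_TREE = [
    ("C5'", "O5'"), ("C4'", "C5'"), ("O4'", "C4'"), ("C3'", "C4'"),
    ("O3'", "C3'"), ("C2'", "C3'"), ("O2'", "C2'"), ("C1'", "C2'"),
]

RNA_MAIN_CHAIN = {"P", "O5'", "C5'", "C4'", "C3'", "O3'"}


def make_rna(sequence: str, seed: int = 0, hydrogens: bool = False,
             jitter_sigma: float = 0.0, chain_id: str = "A") -> Structure:
    """Idealized single-stranded RNA with free 5'-OH and 3'-OH termini."""
    seq = [s.upper() for s in sequence]
    bad = [s for s in seq if s not in BASES]
    if bad:
        raise ValueError(f"unknown RNA base(s) {bad}")
    from .scattering_factors import load_tables

    tables = load_tables()
    bld = _ChainBuilder()
    atoms: list[Atom] = []
    idx = 0

    def emit(name, element, resname, resseq, pos):
        nonlocal idx
        atoms.append(Atom(idx, name, element, resname, resseq, chain_id, pos))
        idx += 1

    # per-residue dihedral hints for a gently twisted extended strand
    hints = {"C5'": 180.0, "C4'": -150.0, "C3'": 170.0, "O3'": -160.0,
             "O4'": 60.0, "C2'": -65.0, "O2'": 175.0, "C1'": 60.0}
    orders: list[list[str]] = []
    for i, base in enumerate(seq, start=1):
        tag = f"{i}:"
        prev = f"{i - 1}:"
        names: list[str] = []
        if i == 1:
            bld.seed(
                [f"{tag}O5'", f"{tag}C5'"],
                [np.zeros(3), np.array([1.42, 0.0, 0.0])],
            )
            bld.pos[f"{tag}C4'"] = _place(
                np.array([0.0, 1.0, 0.0]), bld.pos[f"{tag}O5'"], bld.pos[f"{tag}C5'"],
                1.52, 111.0, 150.0,
            )
            bld.parent[f"{tag}C4'"] = f"{tag}C5'"
            bld.n_children[f"{tag}C5'"] = 1
            sugar_rest = SUGAR_TREE[2:]
            names += ["O5'", "C5'", "C4'"]
        else:
            bld.add(f"{tag}P", f"{prev}O3'", 1.60, 120.0, -170.0)
            bld.add(f"{tag}O5'", f"{tag}P", 1.60, 104.0, -70.0)
            bld.add(f"{tag}OP1", f"{tag}P", 1.49, 110.0, 55.0)
            bld.add(f"{tag}OP2", f"{tag}P", 1.49, 110.0, 170.0)
            bld.add(f"{tag}C5'", f"{tag}O5'", 1.44, 120.0, hints["C5'"])
            bld.add(f"{tag}C4'", f"{tag}C5'", 1.52, 111.0, hints["C4'"])
            sugar_rest = SUGAR_TREE[2:]
            names += ["P", "OP1", "OP2", "O5'", "C5'", "C4'"]
        for name, parent in sugar_rest:
            bld.add(f"{tag}{name}", f"{tag}{parent}",
                    _bond_length(parent[0], name, name[0]), 111.0, hints.get(name))
            names.append(name)
        for name, parent in BASES[base]:
            el = name[0]
            bld.add(f"{tag}{name}", f"{tag}{parent}",
                    _bond_length(parent[0], name, el), 120.0)
            names.append(name)
        # conventional PDB atom order within the residue
        order = [n for n in ("P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'",
                             "C3'", "O3'", "C2'", "O2'", "C1'") if n in names]
        order += [n for n, _ in BASES[base]]
        orders.append(order)

    # emission (and hydrogen placement) after all heavy atoms exist
    for i, base in enumerate(seq, start=1):
        tag = f"{i}:"
        order = orders[i - 1]
        for name in order:
            emit(name, name[0], base, i, bld.pos[f"{tag}{name}"])
        if hydrogens:
            for name in order:
                n_h = tables.hydrogen_count(base, name, "RNA")
                if name == "O5'" and i == 1:
                    n_h += 1
                if name == "O3'" and i == len(seq):
                    n_h += 1
                for hname in _h_names(name, n_h):
                    pos = bld.add(f"{tag}{hname}", f"{tag}{name}",
                                  _bond_length(name[0], hname, "H"), 109.5)
                    emit(hname, "H", base, i, pos)
    st = Structure(atoms)
    if jitter_sigma > 0:
        rng = np.random.default_rng(seed)
        st = st.with_positions(st.positions + rng.normal(0.0, jitter_sigma, (len(atoms), 3)))
    return st


def make_sphere_cluster(n_atoms: int, radius: float, element: str = "C",
                        seed: int = 0) -> Structure:
    """Atoms uniform in a ball of the given radius (A); Debye/Guinier oracle."""
    rng = np.random.default_rng(seed)
    pts = []
    while len(pts) < n_atoms:
        cand = rng.uniform(-radius, radius, (n_atoms * 2, 3))
        pts.extend(cand[np.linalg.norm(cand, axis=1) <= radius].tolist())
    xyz = np.array(pts[:n_atoms])
    atoms = [
        Atom(i, element, element, "SPH", i + 1, "X", xyz[i]) for i in range(n_atoms)
    ]
    return Structure(atoms)


def make_dimer(monomer: Structure, separation: float = 20.0) -> Structure:
    """Two copies of a structure translated apart along x (distinct chains)."""
    import dataclasses

    atoms = list(monomer.atoms)
    n = len(atoms)
    shift = np.array([separation, 0.0, 0.0])
    for a in monomer.atoms:
        atoms.append(dataclasses.replace(
            a, index=a.index + n, chain_id="B", position=a.position + shift))
    return Structure(atoms)


def make_ensemble(base: Structure, n_frames: int, jitter_sigma: float = 0.3,
                  seed: int = 0) -> Ensemble:
    """Jittered conformational ensemble around a base structure (frame 1 =
    the unperturbed base)."""
    rng = np.random.default_rng(seed)
    frames = [base]
    for _ in range(n_frames - 1):
        frames.append(base.with_positions(
            base.positions + rng.normal(0.0, jitter_sigma, (len(base), 3))))
    return Ensemble(frames)


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative fixture description: same spec + seed => identical output."""

    kind: str  # peptide-helix | peptide-coil | rna-strand | sphere-cluster | dimer
    seed: int = 0
    params: dict = field(default_factory=dict)


def build_fixture(spec: FixtureSpec) -> Structure:
    p = dict(spec.params)
    if spec.kind == "peptide-helix":
        return make_peptide(p.pop("sequence", "ACDEFGHIKLMNPQRSTVWY"),
                            "helix", spec.seed, **p)
    if spec.kind == "peptide-coil":
        return make_peptide(p.pop("sequence", "ACDEFGHIKLMNPQRSTVWY"),
                            "extended", spec.seed, **p)
    if spec.kind == "rna-strand":
        return make_rna(p.pop("sequence", "AGUAGAUUAGCA"), spec.seed, **p)
    if spec.kind == "sphere-cluster":
        return make_sphere_cluster(p.pop("n_atoms", 100), p.pop("radius", 15.0),
                                   p.pop("element", "C"), spec.seed)
    if spec.kind == "dimer":
        mono = make_peptide(p.pop("sequence", "ACDEFGHIKL"), "helix", spec.seed)
        return make_dimer(mono, p.pop("separation", 20.0))
    raise ValueError(f"unknown fixture kind {spec.kind!r}")
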