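"""Structure and ensemble I/O.

The atomistic data model consumed by every other module: ordered atoms with
element, residue and chain identity and Cartesian coordinates in Angstrom.
PDB parsing is delegated to :mod:`gemmi`; writing uses fixed-column ATOM
records directly so that a read/write round trip preserves names, elements
and coordinates to the 3-decimal precision of the format.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Ensemble",
    "FormatError",
    "EmptyStructureError",
    "TopologyError",
    "ElementInferenceError",
    "read_structure",
    "read_ensemble",
    "write_structure",
    "write_ensemble",
    "infer_element",
]

PROTEIN_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP "
    "TYR VAL HID HIE HIP HISD HISE HISP HSD HSE HSP".split()
)
RNA_RESIDUES = frozenset({"A", "C", "G", "U", "RA", "RC", "RG", "RU"})
DNA_RESIDUES = frozenset({"DA", "DC", "DG", "DT"})
WATER_RESIDUES = frozenset({"HOH", "WAT", "SOL", "TIP3", "TIP4", "SPC", "DOD"})

#: Standard atomic masses (u) for bead center-of-mass computation.
ATOMIC_MASSES = {
    "H": 1.008,
    "D": 2.014,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
}


class FormatError(ValueError):
    """Raised when a file cannot be parsed as PDB."""


class EmptyStructureError(ValueError):
    """Raised when a selection yields no atoms."""


class TopologyError(ValueError):
    """Raised when ensemble frames do not share a topology."""


class ElementInferenceError(ValueError):
    """Raised when an atom name cannot be resolved to an element."""


@dataclass(frozen=True)
class Atom:
    """A single atom: identity plus position (Angstrom).

    ``element`` is the chemical element; ``isotope_tag`` distinguishes
    deuterium ("D") from protium ("H") for neutron scattering while the
    element stays "H".
    """

    index: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    position: np.ndarray
    isotope_tag: str = ""
    icode: str = ""

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not self.isotope_tag:
            object.__setattr__(
                self, "isotope_tag", "D" if self.name.startswith("D") and self.element == "H" else self.element
            )

    @property
    def mass(self) -> float:
        return ATOMIC_MASSES.get(self.isotope_tag, ATOMIC_MASSES.get(self.element, 12.0))

    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.icode)


def classify_polymer(residue_names) -> str:
    """Classify a chain as protein / RNA / DNA / other from its residue names."""
    names = set(residue_names)
    n = len(names) or 1
    if len(names & PROTEIN_RESIDUES) / n > 0.5:
        return "protein"
    if len(names & RNA_RESIDUES) / n > 0.5:
        return "RNA"
    if len(names & DNA_RESIDUES) / n > 0.5:
        return "DNA"
    return "other"


@dataclass
class Structure:
    """An ordered collection of atoms grouped into residues and chains."""

    atoms: list[Atom] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    def with_positions(self, xyz: np.ndarray) -> "Structure":
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        return Structure([replace(a, position=xyz[i]) for i, a in enumerate(self.atoms)])

    def residues(self) -> list[tuple[tuple[str, int, str], list[Atom]]]:
        """Group atoms by (chain, residue_seq, icode), preserving file order."""
        order: dict[tuple, list[Atom]] = {}
        for a in self.atoms:
            order.setdefault(a.residue_key(), []).append(a)
        return list(order.items())

    def chains(self) -> dict[str, list[Atom]]:
        out: dict[str, list[Atom]] = {}
        for a in self.atoms:
            out.setdefault(a.chain_id, []).append(a)
        return out

    def polymer_kind(self, chain_id: str) -> str:
        atoms = [a for a in self.atoms if a.chain_id == chain_id]
        return classify_polymer(a.residue_name for a in atoms)

    def radius_of_gyration(self) -> float:
        """Mass-weighted radius of gyration, Angstrom."""
        xyz = self.positions
        m = np.array([a.mass for a in self.atoms])
        com = np.average(xyz, axis=0, weights=m)
        return float(np.sqrt(np.average(np.sum((xyz - com) ** 2, axis=1), weights=m)))


@dataclass
class Ensemble:
    """Ordered frames sharing one topology (atom count, names, order)."""

    frames: list[Structure]

    def __post_init__(self):
        if not self.frames:
            raise TopologyError("ensemble must contain at least one frame")
        ref = self.frames[0]
        for k, fr in enumerate(self.frames[1:], start=2):
            if len(fr) != len(ref):
                raise TopologyError(
                    f"frame {k} has {len(fr)} atoms, frame 1 has {len(ref)}"
                )
            for a, b in zip(fr.atoms, ref.atoms):
                if (a.name, a.residue_name, a.chain_id) != (b.name, b.residue_name, b.chain_id):
                    raise TopologyError(f"frame {k}: atom ordering differs at {a.name}")

    def __len__(self) -> int:
        return len(self.frames)


_TWO_LETTER = {"CL", "BR", "FE", "ZN", "MG", "MN", "NA", "CA", "SE", "CU", "NI", "CO"}


def infer_element(atom_name: str, residue_name: str = "") -> str:
    """Infer the element from a PDB atom name.

    Follows PDB naming conventions for biopolymers: the element is the first
    alphabetic character after leading digits, with greek-position letters
    (``CA``, ``CB`` ...) read as carbon in amino acids, not calcium.
    Deuterium names (``D``, ``DA`` ... in deuterated files) map to element H.
    """
    name = atom_name.strip()
    if not name:
        raise ElementInferenceError("empty atom name")
    stripped = name.lstrip(string.digits)
    if not stripped:
        raise ElementInferenceError(f"cannot infer element from atom name {atom_name!r}")
    first = stripped[0].upper()
    if first in ("H", "D"):
        return "H"
    # Two-letter elements only plausible for non-polymer atoms; inside standard
    # residues single-letter chemistry (C, N, O, S, P) always applies.
    if residue_name.strip().upper() not in PROTEIN_RESIDUES | RNA_RESIDUES | DNA_RESIDUES:
        two = stripped[:2].upper()
        if two in _TWO_LETTER and len(name) <= 2:
            return two.capitalize()
    if first in ("C", "N", "O", "S", "P"):
        return first
    raise ElementInferenceError(f"cannot infer element from atom name {atom_name!r}")


def _atom_from_gemmi(idx, chain, res, at) -> Atom:
    el = at.element.name if at.element and at.element.name not in ("X", "") else ""
    isotope = ""
    if el.upper() == "D":
        el, isotope = "H", "D"
    if not el:
        el = infer_element(at.name, res.name)
    if el == "H" and at.name.startswith("D"):
        isotope = "D"
    return Atom(
        index=idx,
        name=at.name,
        element=el.capitalize() if len(el) > 1 else el.upper(),
        residue_name=res.name.strip(),
        residue_seq=res.seqid.num,
        chain_id=chain.name,
        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
        isotope_tag=isotope,
        icode=(res.seqid.icode or "").strip(),
    )


def _structure_from_model(model, keep_waters: bool, keep_hetero: bool) -> Structure:
    atoms: list[Atom] = []
    idx = 0
    for chain in model:
        for res in chain:
            rname = res.name.strip()
            is_water = rname in WATER_RESIDUES
            if is_water and not keep_waters:
                continue
            if res.het_flag == "H" and not is_water and not keep_hetero:
                # heteroatoms (ligands, ions) excluded by default
                continue
            # alternate locations: keep highest occupancy per atom name
            best: dict[str, gemmi.Atom] = {}
            for at in res:
                prev = best.get(at.name)
                if prev is None or at.occ > prev.occ:
                    best[at.name] = at
            for at in res:
                if best[at.name] is not at:
                    continue
                atoms.append(_atom_from_gemmi(idx, chain, res, at))
                idx += 1
    return Structure(atoms)


def read_structure(
    path,
    model_index: int | None = None,
    keep_waters: bool = False,
    keep_hetero: bool = False,
) -> Structure:
    """Read one model from a PDB file.

    Parameters
    ----------
    model_index
        1-based model number for multi-model files; the first model by default.
    keep_waters, keep_hetero
        Waters and HETATM ligands are dropped unless requested.
    """
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"no models found in {path}")
    k = 0 if model_index is None else model_index - 1
    if not 0 <= k < len(st):
        raise FormatError(f"model {model_index} not in file with {len(st)} models")
    out = _structure_from_model(st[k], keep_waters, keep_hetero)
    if len(out) == 0:
        raise EmptyStructureError(f"no atoms selected from {path}")
    return out


def read_ensemble(path, keep_waters: bool = False, keep_hetero: bool = False) -> Ensemble:
    """Read every model of a multi-model PDB as an ensemble (topology-checked)."""
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc
    frames = [_structure_from_model(m, keep_waters, keep_hetero) for m in st]
    frames = [f for f in frames if len(f)]
    if not frames:
        raise EmptyStructureError(f"no atoms selected from {path}")
    return Ensemble(frames)


def _format_atom_record(serial: int, a: Atom) -> str:
    name = a.name
    # PDB column alignment: 1-3 char names start in column 14
    if len(name) < 4 and (len(a.element) == 1):
        name = " " + name
    x, y, z = a.position
    el = a.element.rjust(2)
    return (
        f"ATOM  {serial:>5d} {name:<4s} {a.residue_name:<4s}"[:21]
        + f"{a.chain_id[:1] or 'A'}{a.residue_seq:>4d}{a.icode[:1] or ' '}   "
        + f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {el}\n"
    )


def write_structure(structure: Structure, path) -> None:
    """Write a single-model PDB file."""
    with open(path, "w") as fh:
        _write_model(fh, structure)
        fh.write("END\n")


def write_ensemble(ensemble: Ensemble, path) -> None:
    """Write a multi-model PDB file (MODEL/ENDMDL records)."""
    with open(path, "w") as fh:
        for i, fr in enumerate(ensemble.frames, start=1):
            fh.write(f"MODEL     {i:>4d}\n")
            _write_model(fh, fr)
            fh.write("ENDMDL\n")
        fh.write("END\n")


def _write_model(fh, structure: Structure) -> None:
    serial = 0
    prev_chain = None
    for a in structure.atoms:
        if prev_chain is not None and a.chain_id != prev_chain:
            fh.write("TER\n")
        prev_chain = a.chain_id
        serial += 1
        fh.write(_format_atom_record(serial, a))
    fh.write("TER\n")
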