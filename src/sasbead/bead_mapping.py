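"""Coarse-grained bead mapping.

Proteins map to one bead per amino acid (1B); nucleic acids map to three
beads per nucleotide (3B): phosphate group, pentose sugar and nitrogenous
base. Terminal nucleotides with free hydroxyls use dedicated 5'-end / 3'-end
sugar bead types; histidine resolves to a tautomer-specific bead type from
the protonation pattern of the hydrogens present in the structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_structures import Atom, Structure

__all__ = [
    "Bead",
    "BeadDecomposition",
    "MappingError",
    "map_protein_1B",
    "map_nucleic_3B",
    "map_structure",
    "bead_center",
]

STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)
HIS_ALIASES = {"HIS", "HID", "HIE", "HIP", "HSD", "HSE", "HSP", "HISD", "HISE", "HISP"}

PHOSPHATE_ATOMS = frozenset({"P", "OP1", "OP2", "OP3", "O1P", "O2P", "O3P", "O5'"})
SUGAR_ATOMS = frozenset({"C1'", "C2'", "C3'", "C4'", "C5'", "O4'", "O2'", "O3'"})


class MappingError(ValueError):
    """Raised when a residue has no coarse-grained parameter entry."""


@dataclass
class Bead:
    """A coarse-grained bead: type label, center (A) and member atoms."""

    type_label: str
    center: np.ndarray
    atom_indices: tuple[int, ...]
    residue_key: tuple = ()
    sasa: float = 0.0
    solvated: bool = False
    deuterated: bool = False

    def __post_init__(self):
        if len(self.atom_indices) == 0:
            raise ValueError("bead must contain at least one atom")
        self.center = np.asarray(self.center, dtype=float)
        if not np.all(np.isfinite(self.center)):
            raise ValueError("bead center must be finite")


@dataclass
class BeadDecomposition:
    """Ordered beads partitioning the polymer atoms of a source structure."""

    beads: list[Bead]
    source: Structure
    polymer_of_bead: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.beads)

    @property
    def centers(self) -> np.ndarray:
        return np.array([b.center for b in self.beads]).reshape(-1, 3)

    def check_partition(self) -> None:
        seen: set[int] = set()
        for b in self.beads:
            overlap = seen & set(b.atom_indices)
            if overlap:
                raise ValueError(f"atoms {sorted(overlap)} assigned to multiple beads")
            seen |= set(b.atom_indices)

    def recenter(self, center: str = "mass") -> None:
        """Recompute bead centers from current source coordinates."""
        for b in self.beads:
            b.center = bead_center([self.source.atoms[i] for i in b.atom_indices], center)


def bead_center(atoms: list[Atom], center: str = "mass") -> np.ndarray:
    """Center of a group of atoms: mass-weighted mean (default) or geometric."""
    xyz = np.array([a.position for a in atoms])
    if center == "geometric":
        return xyz.mean(axis=0)
    w = np.array([a.mass for a in atoms])
    return np.average(xyz, axis=0, weights=w)


def _histidine_type(atoms: list[Atom], residue_name: str) -> str:
    """Resolve the histidine tautomer bead type from present H atoms."""
    explicit = {"HID": "HISD", "HSD": "HISD", "HISD": "HISD",
                "HIE": "HISE", "HSE": "HISE", "HISE": "HISE",
                "HIP": "HISP", "HSP": "HISP", "HISP": "HISP"}
    if residue_name in explicit:
        return explicit[residue_name]
    names = {a.name for a in atoms}
    has_h = any(a.element == "H" for a in atoms)
    hd1 = "HD1" in names
    he2 = "HE2" in names
    if not has_h:
        warnings.warn(
            "histidine without hydrogens: defaulting to the epsilon tautomer (HISE)",
            stacklevel=3,
        )
        return "HISE"
    if hd1 and he2:
        return "HISP"
    if hd1:
        return "HISD"
    return "HISE"


def map_protein_1B(structure: Structure, center: str = "mass", chains: set[str] | None = None) -> BeadDecomposition:
    """One bead per amino-acid residue; bead type = residue code.

    Histidine resolves to HISD / HISE / HISP (delta-, epsilon- and doubly
    protonated imidazole).
    """
    beads: list[Bead] = []
    found_protein = False
    for key, atoms in structure.residues():
        chain = key[0]
        if chains is not None and chain not in chains:
            continue
        if structure.polymer_kind(chain) != "protein":
            continue
        found_protein = True
        rname = atoms[0].residue_name
        if rname in HIS_ALIASES:
            label = _histidine_type(atoms, rname)
        elif rname in STANDARD_AA:
            label = rname
        else:
            raise MappingError(f"no bead parameters for residue {rname!r} ({key})")
        beads.append(
            Bead(label, bead_center(atoms, center), tuple(a.index for a in atoms), residue_key=key)
        )
    if not found_protein:
        raise MappingError("structure contains no protein chain")
    dec = BeadDecomposition(beads, structure, ["protein"] * len(beads))
    dec.check_partition()
    return dec


def _nucleotide_base_label(rname: str, polymer: str) -> str:
    base = rname.lstrip("DR")
    if base in {"A", "C", "G", "U", "T"}:
        return base
    raise MappingError(f"unknown nucleotide residue {rname!r}")


def _split_nucleotide(atoms: list[Atom]):
    has_p = any(a.name == "P" for a in atoms)
    phosphate, sugar, base = [], [], []
    for a in atoms:
        n = a.name
        if n in PHOSPHATE_ATOMS:
            phosphate.append(a)
        elif n in SUGAR_ATOMS:
            sugar.append(a)
        elif a.element == "H":
            # hydrogens follow their parent heavy atom by name convention:
            # primed H atoms sit on the sugar; HO5' follows O5'
            if n in ("HO5'", "H5T"):
                (phosphate if has_p else sugar).append(a)
            elif n.endswith("'") or n in ("H3T",):
                sugar.append(a)
            else:
                base.append(a)
        else:
            base.append(a)
    return phosphate, sugar, base


def map_nucleic_3B(structure: Structure, center: str = "mass", chains: set[str] | None = None) -> BeadDecomposition:
    """Three beads per nucleotide: phosphate (absent at free 5'-OH termini),
    pentose sugar (with 5'-end / 3'-end variants at hydroxyl termini) and base.
    """
    beads: list[Bead] = []
    found = False
    for chain_id, chain_atoms in structure.chains().items():
        if chains is not None and chain_id not in chains:
            continue
        kind = structure.polymer_kind(chain_id)
        if kind not in ("RNA", "DNA"):
            continue
        found = True
        residues = [(k, v) for k, v in structure.residues() if k[0] == chain_id]
        for pos, (key, atoms) in enumerate(residues):
            rname = atoms[0].residue_name
            base_label = _nucleotide_base_label(rname, kind)
            phosphate, sugar, base = _split_nucleotide(atoms)
            is_5p = pos == 0
            is_3p = pos == len(residues) - 1
            has_p = any(a.name == "P" for a in phosphate)
            if not has_p:
                # free 5'-OH: O5' (and its hydroxyl H) belongs to the sugar
                sugar = sugar + phosphate
                phosphate = []
                if not is_5p:
                    warnings.warn(
                        f"nucleotide {key} lacks a phosphate mid-chain; treated as internal",
                        stacklevel=2,
                    )
            sugar_label = "SUGAR"
            if is_5p and not has_p:
                sugar_label = "SUGAR5"
            elif is_3p:
                sugar_label = "SUGAR3"
            sugar_label += "_R" if kind == "RNA" else "_D"
            if phosphate:
                beads.append(
                    Bead("PHOSPHATE", bead_center(phosphate, center),
                         tuple(a.index for a in phosphate), residue_key=key)
                )
            if not sugar:
                raise MappingError(f"nucleotide {key} has no sugar atoms")
            beads.append(
                Bead(sugar_label, bead_center(sugar, center),
                     tuple(a.index for a in sugar), residue_key=key)
            )
            if not base:
                raise MappingError(f"nucleotide {key} has no base atoms")
            beads.append(
                Bead(base_label, bead_center(base, center),
                     tuple(a.index for a in base), residue_key=key)
            )
    if not found:
        raise MappingError("structure contains no nucleic chain")
    dec = BeadDecomposition(beads, structure, ["nucleic"] * len(beads))
    dec.check_partition()
    return dec


def map_structure(structure: Structure, center: str = "mass") -> BeadDecomposition:
    """Map every polymer chain: 1B for protein chains, 3B for nucleic chains."""
    beads: list[Bead] = []
    kinds: list[str] = []
    chain_ids = list(structure.chains())
    prot = {c for c in chain_ids if structure.polymer_kind(c) == "protein"}
    nuc = {c for c in chain_ids if structure.polymer_kind(c) in ("RNA", "DNA")}
    if prot:
        d = map_protein_1B(structure, center, chains=prot)
        beads += d.beads
        kinds += d.polymer_of_bead
    if nuc:
        d = map_nucleic_3B(structure, center, chains=nuc)
        beads += d.beads
        kinds += d.polymer_of_bead
    if not beads:
        raise MappingError("structure contains no mappable polymer chains")
    dec = BeadDecomposition(beads, structure, kinds)
    dec.check_partition()
    return dec
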