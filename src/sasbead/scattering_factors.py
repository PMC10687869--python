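"""Atomic scattering amplitudes for X-rays and neutrons.

X-ray amplitudes use the Cromer-Mann 4-Gaussian parametrization
``f(q) = sum_k a_k exp(-b_k (q/4pi)^2) + c``; the solvent-displaced volume is
modelled as a spherical Gaussian ``g(q) = v exp(-v^(2/3) q^2 / 4pi)``
(Fraser-MacRae-Suzuki convention, as in CRYSOL/FoXS), giving the effective
contrast amplitude ``f'(q) = f(q) - rho * g(q)``.

Neutron amplitudes are q-independent coherent scattering lengths ``b_i`` per
isotope; the solvent neutron density for an H2O/D2O mixture with deuterium
fraction ``d`` is ``rho_sans = 0.1 rho0 (b_O + 2(1-d) b_H + 2 d b_D)``, the
0.1 converting the 10-electron water electron density to molecule density.

United-atom groups (``CH2``, ``NH3`` ...) are built additively from element
entries: Gaussian terms concatenate and volumes/lengths add, which is exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

__all__ = [
    "CromerMannCoefficients",
    "SolventModel",
    "ScatteringTables",
    "TableError",
    "load_tables",
    "cromer_mann_f",
    "excluded_volume_g",
    "xray_effective_f",
    "sans_solvent_density",
    "sans_effective_f",
]

#: Electron density of bulk water, e / A^3.
RHO0_WATER = 0.334


class TableError(KeyError):
    """Raised when an element/isotope/group has no parameter-table entry."""


@dataclass(frozen=True)
class CromerMannCoefficients:
    """Gaussian amplitudes ``a`` (e), widths ``b`` (A^2) and constant ``c`` (e).

    Element entries have 4 Gaussians; united-atom groups may carry more
    (parent terms plus one H term per attached hydrogen).
    """

    label: str
    a: tuple[float, ...]
    b: tuple[float, ...]
    c: float

    def f0(self) -> float:
        return float(sum(self.a) + self.c)


@dataclass(frozen=True)
class SolventModel:
    """Bulk-solvent description shared by both scattering modes.

    ``rho0`` in e/A^3 (0.334 for water); ``deuterium_fraction`` is the D2O
    volume fraction of the buffer, used only for SANS.
    """

    rho0: float = RHO0_WATER
    deuterium_fraction: float = 0.0
    mode: str = "SAXS"

    def __post_init__(self):
        if self.rho0 < 0:
            raise ValueError("rho0 must be non-negative")
        if not 0.0 <= self.deuterium_fraction <= 1.0:
            raise ValueError("deuterium fraction must lie in [0, 1]")
        if self.mode not in ("SAXS", "SANS"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _read_tsv(name: str) -> list[list[str]]:
    text = resources.files("sasbead.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


class ScatteringTables:
    """Bundled Cromer-Mann coefficients, displaced volumes, neutron lengths.

    ``group(element, n_hydrogens)`` returns united-atom entries; with
    ``n_hydrogens=0`` these reduce to the bare element.
    """

    def __init__(self):
        self.cromer_mann: dict[str, CromerMannCoefficients] = {}
        for row in _read_tsv("cromer_mann.tsv"):
            el, *vals = row
            v = [float(x) for x in vals]
            self.cromer_mann[el] = CromerMannCoefficients(el, tuple(v[:4]), tuple(v[4:8]), v[8])
        self.volumes: dict[str, float] = {r[0]: float(r[1]) for r in _read_tsv("displaced_volumes.tsv")}
        self.neutron: dict[str, float] = {r[0]: float(r[1]) for r in _read_tsv("neutron_lengths.tsv")}
        self.residue_hydrogens: dict = json.loads(
            resources.files("sasbead.data").joinpath("residue_hydrogens.json").read_text()
        )

    # -- element / group lookups ------------------------------------------
    def cm(self, element: str) -> CromerMannCoefficients:
        try:
            return self.cromer_mann[element]
        except KeyError:
            raise TableError(f"no Cromer-Mann entry for element {element!r}") from None

    def group_cm(self, element: str, n_h: int = 0) -> CromerMannCoefficients:
        base = self.cm(element)
        if n_h == 0:
            return base
        h = self.cm("H")
        return CromerMannCoefficients(
            f"{element}H{n_h}", base.a + tuple(n_h * x for x in h.a), base.b + h.b, base.c + n_h * h.c
        )

    def group_volume(self, element: str, n_h: int = 0) -> float:
        try:
            return self.volumes[element] + n_h * self.volumes["H"]
        except KeyError:
            raise TableError(f"no displaced-volume entry for element {element!r}") from None

    def neutron_b(self, isotope: str) -> float:
        try:
            return self.neutron[isotope]
        except KeyError:
            raise TableError(f"no neutron scattering length for isotope {isotope!r}") from None

    def group_neutron_b(self, element: str, n_h: int = 0, hydrogen_isotope: str = "H") -> float:
        return self.neutron_b(element if element != "H" else hydrogen_isotope) + n_h * self.neutron_b(
            hydrogen_isotope
        )

    # -- united-atom hydrogen counts --------------------------------------
    def hydrogen_count(self, residue_name: str, atom_name: str, polymer: str = "protein") -> int:
        """Hydrogens implicitly attached to a heavy atom of a standard residue."""
        tab = self.residue_hydrogens
        res = residue_name.strip()
        aliases = {"HID": "HISD", "HIE": "HISE", "HIP": "HISP", "HSD": "HISD", "HSE": "HISE", "HSP": "HISP"}
        res = aliases.get(res, res)
        if polymer == "protein":
            backbone = tab["_backbone_protein"]
            side = tab.get(res if res in tab else "HIS" if res.startswith("HIS") else res, {})
            if res == "PRO" and atom_name == "N":
                return 0
            if atom_name in backbone:
                return backbone[atom_name]
            if isinstance(side, dict) and atom_name in side:
                return side[atom_name]
            return 0
        # nucleic acids
        backbone = dict(tab["_backbone_nucleic"])
        base_key = {"A": "A", "G": "G", "C": "C_base", "U": "U", "T": "T"}.get(res.lstrip("DR")[:1])
        if polymer == "RNA":
            backbone.update(tab["_sugar_rna"])
        else:
            backbone.update(tab["_sugar_dna"])
        if atom_name in backbone:
            return backbone[atom_name]
        if base_key and atom_name in tab[base_key]:
            return tab[base_key][atom_name]
        return 0


@lru_cache(maxsize=1)
def load_tables() -> ScatteringTables:
    return ScatteringTables()


def cromer_mann_f(group: CromerMannCoefficients, q) -> np.ndarray:
    """Cromer-Mann amplitude f(q) in electrons; ``q`` in 1/A, q >= 0."""
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be non-negative")
    s2 = (q / (4.0 * np.pi)) ** 2
    a = np.asarray(group.a)
    b = np.asarray(group.b)
    return a @ np.exp(-np.multiply.outer(b, s2)) + group.c


def excluded_volume_g(volume: float, q) -> np.ndarray:
    """Displaced-solvent Gaussian amplitude per unit density, A^3.

    ``g(q) = v exp(-v^(2/3) q^2 / 4pi)``; g(0) = v.
    """
    if volume <= 0:
        raise ValueError("displaced volume must be positive")
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be non-negative")
    return volume * np.exp(-(volume ** (2.0 / 3.0)) * q**2 / (4.0 * np.pi))


def xray_effective_f(group: CromerMannCoefficients, volume: float, q, rho: float) -> np.ndarray:
    """Contrast amplitude f'(q) = f_CM(q) - rho * g(q), electrons."""
    return cromer_mann_f(group, q) - rho * excluded_volume_g(volume, q)


def sans_solvent_density(rho0: float, d: float, tables: ScatteringTables | None = None) -> float:
    """Neutron scattering density of an H2O/D2O mixture, fm / A^3."""
    if not 0.0 <= d <= 1.0:
        raise ValueError("deuterium fraction must lie in [0, 1]")
    t = tables or load_tables()
    b_o, b_h, b_d = t.neutron_b("O"), t.neutron_b("H"), t.neutron_b("D")
    return 0.1 * rho0 * (b_o + 2.0 * (1.0 - d) * b_h + 2.0 * d * b_d)


def sans_effective_f(b_i: float, volume: float, q, rho_sans: float) -> np.ndarray:
    """Neutron contrast amplitude b_i - rho_sans * g(q); flat atomic part."""
    q = np.asarray(q, dtype=float)
    return b_i - rho_sans * excluded_volume_g(volume, q)
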