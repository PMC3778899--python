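"""Lipid species, head-group scan definitions, and ion mass arithmetic.

Head-group (class-selective) MS/MS scans on a unit-resolution triple
quadrupole report one phospholipid class at a time: a precursor-ion scan
of the phosphocholine fragment (m/z 184, positive mode) detects every PC
species, the inositol phosphate fragment (m/z 241, negative mode) every
PI species, and a neutral loss of 87 Da (the serine head group, negative
mode) every PS species.  Deuterated head-group substrates
(methyl-D9-choline, myo-D6-inositol, serine-D3) shift the diagnostic by
the label mass, so the newly synthesised pool of each class is read out
by a parallel scan (P193+, P247-, NL90-).

Two mass scales are supported:

``paper_nominal`` (default)
    Unit-resolution centroid positions on a one-decimal m/z ladder
    anchored at the dominant species of each class, stepping +14 per CH2
    and -2 per double bond, with integer label shifts (+9 D9-choline,
    +6 D6-inositol, +3 D3-serine).  This reproduces the positions a
    quadrupole instrument centroids and reports, which sit ~0.2-0.3 Da
    above the monoisotopic mass.

``monoisotopic``
    Exact ion mass from elemental composition for the class's standard
    adduct ([M+H]+ for PC/SM/ceramides, [M-H]- for PS/PI/PE/PG/PA/CL,
    [M+NH4]+ for TAG), with deuterium label shifts of n x 1.006277 Da.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache

from pyteomics import mass as _pmass

from .errors import ConfigurationError

__all__ = [
    "LipidClass",
    "Label",
    "LipidSpecies",
    "ScanMode",
    "ScanDefinition",
    "MassAnchor",
    "HEAD_GROUP_SCANS",
    "GLYCEROPHOSPHOLIPID_CLASSES",
    "chain_delta",
    "species_mz",
    "class_anchor",
    "total_carbons",
    "monoisotopic_mz",
    "enumerate_species",
    "parse_species",
    "format_species",
]

# Monoisotopic constants (NIST values as shipped with pyteomics).
PROTON_MASS = _pmass.nist_mass["H+"][0][0]
D_MINUS_H = _pmass.nist_mass["H"][2][0] - _pmass.nist_mass["H"][1][0]
_NH3_MASS = _pmass.calculate_mass(formula="NH3")
_H2O_MASS = _pmass.calculate_mass(formula="H2O")


class LipidClass(str, Enum):
    """Lipid classes covered by the head-group, MRM and shotgun arms."""

    PC = "PC"
    PS = "PS"
    PI = "PI"
    PE = "PE"
    PG = "PG"
    PA = "PA"
    CL = "CL"
    SM = "SM"
    CER = "Cer"
    DHCER = "DHCer"
    SPH = "Sph"
    TAG = "TAG"
    CHOL = "Chol"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


GLYCEROPHOSPHOLIPID_CLASSES = frozenset(
    {
        LipidClass.PC,
        LipidClass.PS,
        LipidClass.PI,
        LipidClass.PE,
        LipidClass.PG,
        LipidClass.PA,
        LipidClass.CL,
    }
)

_SPHINGOLIPID_CLASSES = frozenset({LipidClass.SM, LipidClass.CER, LipidClass.DHCER})


class Label(Enum):
    """Stable-isotope head-group label channels.

    Each deuterated substrate attaches to exactly one phospholipid class
    during synthesis, so a label is only chemically valid on that class.
    """

    NONE = ("none", 0, None)
    D9_CHOLINE = ("D9-choline", 9, "PC")
    D6_INOSITOL = ("D6-inositol", 6, "PI")
    D3_SERINE = ("D3-serine", 3, "PS")

    def __init__(self, key: str, n_deuterium: int, target: str | None):
        self.key = key
        self.n_deuterium = n_deuterium
        self._target = target

    @property
    def target_class(self) -> LipidClass | None:
        return LipidClass(self._target) if self._target else None


_SN_RE = re.compile(r"^(\d+):(\d+)(?:/(\d+):(\d+)){1,3}$")


def _sn_totals(sn_name: str) -> tuple[int, int]:
    """Sum carbons and double bonds over the acyl chains of an sn name."""
    chains = sn_name.split("/")
    carbons = 0
    double_bonds = 0
    for chain in chains:
        m = re.fullmatch(r"(\d+):(\d+)", chain)
        if m is None:
            raise ConfigurationError(f"malformed acyl chain {chain!r} in {sn_name!r}")
        carbons += int(m.group(1))
        double_bonds += int(m.group(2))
    return carbons, double_bonds


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid species at total acyl-composition resolution.

    ``carbons``/``double_bonds`` are totals over the acyl chains (for
    sphingolipids, over the N-acyl chain; the d18:1 backbone is implied).
    An optional sn-resolved name ("16:0/18:1") is a display alias only:
    head-group scans cannot resolve positional isomers, so equality and
    hashing ignore it.
    """

    lipid_class: LipidClass
    carbons: int
    double_bonds: int
    label: Label = Label.NONE
    sn_name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        cls = self.lipid_class
        c, d = self.carbons, self.double_bonds
        if cls is LipidClass.CL:
            if c % 2 or not (48 <= c <= 80) or not (0 <= d <= 12):
                raise ConfigurationError(f"invalid cardiolipin composition {c}:{d}")
        elif cls in GLYCEROPHOSPHOLIPID_CLASSES:
            if c % 2 or not (24 <= c <= 48):
                raise ConfigurationError(
                    f"glycerophospholipid acyl carbons must be even and in [24, 48], got {c}"
                )
            if not (0 <= d <= 8):
                raise ConfigurationError(f"double bonds must be in [0, 8], got {d}")
        elif cls in _SPHINGOLIPID_CLASSES:
            if not (12 <= c <= 30) or not (0 <= d <= 2):
                raise ConfigurationError(f"invalid sphingolipid N-acyl composition {c}:{d}")
        elif cls is LipidClass.SPH:
            if c != 18 or d not in (0, 1):
                raise ConfigurationError("sphingoid bases are limited to 18:0 and 18:1")
        elif cls is LipidClass.TAG:
            if not (40 <= c <= 60) or not (0 <= d <= 8):
                raise ConfigurationError(f"invalid TAG composition {c}:{d}")
        elif cls is LipidClass.CHOL:
            if (c, d) != (27, 1):
                raise ConfigurationError("cholesterol has a fixed composition")
        if self.label is not Label.NONE and self.label.target_class is not cls:
            raise ConfigurationError(
                f"label {self.label.key} is not chemically valid on class {cls.value}"
            )
        if self.sn_name is not None:
            totals = _sn_totals(self.sn_name)
            if totals != (c, d):
                raise ConfigurationError(
                    f"sn name {self.sn_name!r} sums to {totals[0]}:{totals[1]}, "
                    f"species declares {c}:{d}"
                )

    def with_label(self, label: Label) -> "LipidSpecies":
        return LipidSpecies(self.lipid_class, self.carbons, self.double_bonds, label, self.sn_name)

    def unlabelled(self) -> "LipidSpecies":
        return self.with_label(Label.NONE)

    def __str__(self) -> str:
        return format_species(self)


class ScanMode(Enum):
    PRECURSOR = "precursor"
    NEUTRAL_LOSS = "neutral_loss"


@dataclass(frozen=True)
class ScanDefinition:
    """A class-selective MS/MS scan and the label channel it reads."""

    name: str
    mode: ScanMode
    polarity: str  # '+' or '-'
    diagnostic: float  # fragment m/z (precursor scan) or neutral mass in Da
    lipid_class: LipidClass
    label: Label


HEAD_GROUP_SCANS: dict[str, ScanDefinition] = {
    s.name: s
    for s in (
        ScanDefinition("P184+", ScanMode.PRECURSOR, "+", 184.0, LipidClass.PC, Label.NONE),
        ScanDefinition("P193+", ScanMode.PRECURSOR, "+", 193.0, LipidClass.PC, Label.D9_CHOLINE),
        ScanDefinition("P241-", ScanMode.PRECURSOR, "-", 241.0, LipidClass.PI, Label.NONE),
        ScanDefinition("P247-", ScanMode.PRECURSOR, "-", 247.0, LipidClass.PI, Label.D6_INOSITOL),
        ScanDefinition("NL87-", ScanMode.NEUTRAL_LOSS, "-", 87.0, LipidClass.PS, Label.NONE),
        ScanDefinition("NL90-", ScanMode.NEUTRAL_LOSS, "-", 90.0, LipidClass.PS, Label.D3_SERINE),
    )
}


# --------------------------------------------------------------------------
# Elemental composition and monoisotopic masses
# --------------------------------------------------------------------------

# Diacyl glycerophospholipids: formula C(n+c_off) H(2n-2d+h_off) + heteroatoms,
# where n and d are total acyl carbons and double bonds.
_GPL_COMPOSITION: dict[LipidClass, tuple[int, int, dict[str, int]]] = {
    LipidClass.PC: (8, 16, {"N": 1, "O": 8, "P": 1}),
    LipidClass.PE: (5, 10, {"N": 1, "O": 8, "P": 1}),
    LipidClass.PS: (6, 10, {"N": 1, "O": 10, "P": 1}),
    LipidClass.PI: (9, 15, {"O": 13, "P": 1}),
    LipidClass.PG: (6, 11, {"O": 10, "P": 1}),
    LipidClass.PA: (3, 5, {"O": 8, "P": 1}),
    LipidClass.CL: (9, 14, {"O": 17, "P": 2}),
}

# Backbone double bonds implied by the class (sphingosine 4,5-trans bond).
_BACKBONE_DB = {LipidClass.SM: 1, LipidClass.CER: 1, LipidClass.DHCER: 0}


def elemental_composition(species: LipidSpecies) -> dict[str, int]:
    """Neutral elemental composition {element: count} of an unlabelled species."""
    cls = species.lipid_class
    n, d = species.carbons, species.double_bonds
    if cls in _GPL_COMPOSITION:
        c_off, h_off, hetero = _GPL_COMPOSITION[cls]
        comp = {"C": n + c_off, "H": 2 * n - 2 * d + h_off}
        comp.update(hetero)
        return comp
    if cls in (LipidClass.CER, LipidClass.DHCER):
        total_c = 18 + n
        total_db = _BACKBONE_DB[cls] + d + 1  # +1: amide carbonyl
        return {"C": total_c, "H": 2 * total_c - 2 * total_db + 3, "N": 1, "O": 3}
    if cls is LipidClass.SM:
        # ceramide core + phosphocholine head (C5H12NO3P)
        total_c = 18 + n
        total_db = 1 + d + 1
        return {
            "C": total_c + 5,
            "H": 2 * total_c - 2 * total_db + 3 + 12,
            "N": 2,
            "O": 6,
            "P": 1,
        }
    if cls is LipidClass.SPH:
        return {"C": 18, "H": 2 * 18 - 2 * d + 3, "N": 1, "O": 2}
    if cls is LipidClass.TAG:
        return {"C": n + 3, "H": 2 * n - 2 * d + 2, "O": 6}
    if cls is LipidClass.CHOL:
        return {"C": 27, "H": 46, "O": 1}
    raise ConfigurationError(f"no elemental composition model for class {cls.value}")


def total_carbons(species: LipidSpecies) -> int:
    """Total molecular carbon count (acyls + backbone + head group).

    This is the carbon count that governs the natural-abundance 13C
    isotope envelope, e.g. 42 for PC 34:1 and 44 for PC 36:2.
    """
    return elemental_composition(species)["C"]


# Adduct applied per class in monoisotopic mode: (description, mass shift, sign on mz)
_ADDUCTS: dict[LipidClass, tuple[str, float]] = {
    LipidClass.PC: ("[M+H]+", PROTON_MASS),
    LipidClass.SM: ("[M+H]+", PROTON_MASS),
    LipidClass.CER: ("[M+H]+", PROTON_MASS),
    LipidClass.DHCER: ("[M+H]+", PROTON_MASS),
    LipidClass.SPH: ("[M+H]+", PROTON_MASS),
    LipidClass.TAG: ("[M+NH4]+", _NH3_MASS + PROTON_MASS),
    LipidClass.CHOL: ("[M+H-H2O]+", PROTON_MASS - _H2O_MASS),
    LipidClass.PS: ("[M-H]-", -PROTON_MASS),
    LipidClass.PI: ("[M-H]-", -PROTON_MASS),
    LipidClass.PE: ("[M-H]-", -PROTON_MASS),
    LipidClass.PG: ("[M-H]-", -PROTON_MASS),
    LipidClass.PA: ("[M-H]-", -PROTON_MASS),
    LipidClass.CL: ("[M-H]-", -PROTON_MASS),
}


def monoisotopic_mz(species: LipidSpecies) -> float:
    """Exact ion m/z for the class's standard adduct, including any label."""
    comp = elemental_composition(species)
    neutral = _pmass.calculate_mass(composition=_pmass.Composition(comp))
    adduct_name, shift = _ADDUCTS[species.lipid_class]
    return neutral + shift + species.label.n_deuterium * D_MINUS_H


# --------------------------------------------------------------------------
# Anchored nominal-mass ladders
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MassAnchor:
    """Reference species fixing the one-decimal ladder of a class."""

    lipid_class: LipidClass
    anchor_species: LipidSpecies
    anchor_mz: float


# Anchors printed in the source spectra: the dominant PC and PS species.
_PRINTED_ANCHORS: dict[LipidClass, tuple[tuple[int, int, str], float]] = {
    LipidClass.PC: ((34, 1, "16:0/18:1"), 760.8),
    LipidClass.PS: ((36, 1, "18:0/18:1"), 788.9),
}

# Classes whose ladder anchor is derived from the monoisotopic mass of a
# representative species (rounded to the instrument's one-decimal report).
_DERIVED_ANCHOR_SPECIES: dict[LipidClass, tuple[int, int, str | None]] = {
    LipidClass.PI: (38, 4, "18:0/20:4"),
    LipidClass.PE: (34, 1, "16:0/18:1"),
    LipidClass.PG: (34, 1, "16:0/18:1"),
    LipidClass.PA: (34, 1, "16:0/18:1"),
    LipidClass.CL: (72, 8, None),
    LipidClass.SM: (16, 0, None),
    LipidClass.CER: (16, 0, None),
    LipidClass.DHCER: (16, 0, None),
    LipidClass.SPH: (18, 1, None),
    LipidClass.TAG: (52, 2, None),
    LipidClass.CHOL: (27, 1, None),
}


@lru_cache(maxsize=None)
def class_anchor(lipid_class: LipidClass) -> MassAnchor:
    """The single paper-nominal anchor of a class."""
    if lipid_class in _PRINTED_ANCHORS:
        (c, d, sn), mz = _PRINTED_ANCHORS[lipid_class]
        return MassAnchor(lipid_class, LipidSpecies(lipid_class, c, d, sn_name=sn), mz)
    if lipid_class in _DERIVED_ANCHOR_SPECIES:
        c, d, sn = _DERIVED_ANCHOR_SPECIES[lipid_class]
        sp = LipidSpecies(lipid_class, c, d, sn_name=sn)
        return MassAnchor(lipid_class, sp, round(monoisotopic_mz(sp), 1))
    raise ConfigurationError(f"no mass anchor defined for class {lipid_class.value}")


def chain_delta(carbons_a: int, db_a: int, carbons_b: int, db_b: int) -> int:
    """Nominal mass difference (Da) between two acyl compositions.

    One CH2 adds 14 Da and one double bond removes 2 Da on the
    unit-resolution ladder, so the step from (Ca, Da) to (Cb, Db) is
    14*(Cb-Ca) - 2*(Db-Da).
    """
    return 14 * (carbons_b - carbons_a) - 2 * (db_b - db_a)


def species_mz(species: LipidSpecies, mass_mode: str = "paper_nominal") -> float:
    """Expected ion m/z of a species in the requested mass mode."""
    if mass_mode == "paper_nominal":
        anchor = class_anchor(species.lipid_class)
        a = anchor.anchor_species
        mz = anchor.anchor_mz + chain_delta(
            a.carbons, a.double_bonds, species.carbons, species.double_bonds
        )
        return round(mz + species.label.n_deuterium, 1)
    if mass_mode == "monoisotopic":
        return monoisotopic_mz(species)
    raise ConfigurationError(f"unknown mass mode {mass_mode!r}")


def enumerate_species(
    lipid_class: LipidClass,
    carbon_range: tuple[int, int],
    db_range: tuple[int, int],
    label: Label = Label.NONE,
    mass_mode: str = "paper_nominal",
) -> list[LipidSpecies]:
    """All (carbons, double bonds) combinations of a class, sorted by m/z.

    Glycerophospholipid lattices step by two carbons (biological species
    are even-carbon; odd-carbon internal standards are added explicitly
    by the caller, never enumerated).
    """
    cmin, cmax = carbon_range
    dmin, dmax = db_range
    if cmin > cmax or dmin > dmax:
        return []
    step = 2 if lipid_class in GLYCEROPHOSPHOLIPID_CLASSES else 1
    if step == 2 and (cmin % 2 or cmax % 2):
        raise ConfigurationError("carbon range bounds must be even for glycerophospholipids")
    species = [
        LipidSpecies(lipid_class, c, d, label)
        for c in range(cmin, cmax + 1, step)
        for d in range(dmin, dmax + 1)
    ]
    return sorted(species, key=lambda s: species_mz(s, mass_mode))


# --------------------------------------------------------------------------
# Text notation
# --------------------------------------------------------------------------

_CLASS_BY_TOKEN = {c.value: c for c in LipidClass}
_SPECIES_TEXT_RE = re.compile(r"^(?P<cls>[A-Za-z]+)(?:\s+(?P<comp>[\d:/]+))?$")


def parse_species(text: str, label: Label = Label.NONE) -> LipidSpecies:
    """Parse "<CLASS> <C>:<DB>" or "<CLASS> <sn1>/<sn2>" notation.

    "Chol" parses without a composition.  Round-trips bit-stably with
    :func:`format_species`.
    """
    m = _SPECIES_TEXT_RE.match(text.strip())
    if m is None:
        raise ConfigurationError(f"unparseable species notation {text!r}")
    token = m.group("cls")
    if token not in _CLASS_BY_TOKEN:
        raise ConfigurationError(f"unknown lipid class {token!r} in {text!r}")
    cls = _CLASS_BY_TOKEN[token]
    comp = m.group("comp")
    if comp is None:
        if cls is LipidClass.CHOL:
            return LipidSpecies(cls, 27, 1, label)
        raise ConfigurationError(f"species {text!r} lacks an acyl composition")
    if "/" in comp:
        carbons, db = _sn_totals(comp)
        return LipidSpecies(cls, carbons, db, label, sn_name=comp)
    cm = re.fullmatch(r"(\d+):(\d+)", comp)
    if cm is None:
        raise ConfigurationError(f"malformed composition {comp!r} in {text!r}")
    return LipidSpecies(cls, int(cm.group(1)), int(cm.group(2)), label)


def format_species(species: LipidSpecies) -> str:
    """Canonical text form; uses the sn alias when one is attached."""
    if species.lipid_class is LipidClass.CHOL:
        return "Chol"
    comp = species.sn_name or f"{species.carbons}:{species.double_bonds}"
    return f"{species.lipid_class.value} {comp}"
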