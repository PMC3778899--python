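"""Synthetic-spectrum generator for the two-group lipidomics study.

The generator produces, from a ground-truth lipidome, everything the
analysis pipeline consumes: centroided peak lists for the six
class-selective head-group scans (endogenous and deuterium-labelled
channels), MRM transition tables for the sphingolipid panel, and
per-class shotgun spectra of ileal biopsies with internal-standard
spikes.

The default ground truth and study design encode the study conditions
being emulated: macrophage phospholipid profiles dominated by
PC 16:0/18:1 / PC 18:0/18:2, PS 18:0/18:1 (>40 % of PS) and
PI 18:0/20:4 (42.9 % of PI); a diverse newly-synthesised PI pool in
which PI 18:0/20:4 is only 12.3 %; D6-inositol incorporation of 16.1 %
over the 3 h labelling window; Crohn's-disease macrophages with the
newly-synthesised PI 16:0/18:1 fraction reduced; and bacterial
(heat-killed E. coli) stimulation that lowers C16:0/C24:0/C24:1
ceramides, raises dihydrosphingosine, raises D9-choline incorporation
into PC and lowers endogenous PC 16:0/20:4.

Peaks carry a natural-abundance 13C envelope (binomial in the total
molecular carbon count, truncated at M+2), log-normal intensity noise,
and m/z jitter.  All randomness descends from one seed through
``numpy.random.SeedSequence`` spawning, so equal seeds give bit-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import PeakList, shotgun_scan_type
from .registry import (
    HEAD_GROUP_SCANS,
    Label,
    LipidClass,
    LipidSpecies,
    ScanDefinition,
    format_species,
    parse_species,
    species_mz,
    total_carbons,
)

ENDOGENOUS = "endogenous"
NEWLY_SYNTHESISED = "newly_synthesised"

#: Isotopologue spacing on the unit-resolution ladder vs the exact 13C-12C gap.
ISOTOPE_SPACING = {"paper_nominal": 1.0, "monoisotopic": 1.0033548}

#: Natural 13C abundance.
P_13C = 0.0107


# --------------------------------------------------------------------------
# Ground truth
# --------------------------------------------------------------------------


@dataclass
class ClassProfile:
    """Endogenous and newly-synthesised species pools of one labelled class.

    ``incorporation`` is the fractional incorporation phi of the
    deuterated head-group substrate over the labelling window: the
    labelled channel carries weight phi, the endogenous channel 1 - phi.
    """

    endogenous: dict[LipidSpecies, float]
    newly_synthesised: dict[LipidSpecies, float]
    incorporation: float

    def channel(self, name: str) -> dict[LipidSpecies, float]:
        if name == ENDOGENOUS:
            return self.endogenous
        if name == NEWLY_SYNTHESISED:
            return self.newly_synthesised
        raise ConfigurationError(f"unknown channel {name!r}")


@dataclass
class ShotgunClass:
    """Per-class biopsy ground truth: class total and species fractions."""

    total: float  # nmol/mg protein (Cer: pmol/mg protein)
    fractions: dict[LipidSpecies, float]


@dataclass
class GroundTruthLipidome:
    """Complete per-sample (or template) lipidome."""

    profiles: dict[LipidClass, ClassProfile]
    sphingolipid_pmol: dict[LipidSpecies, float]  # MRM panel, pmol/mg protein
    shotgun: dict[LipidClass, ShotgunClass]
    protein_mg: float = 0.5

    def validate(self) -> None:
        for cls, prof in self.profiles.items():
            for name in (ENDOGENOUS, NEWLY_SYNTHESISED):
                total = sum(prof.channel(name).values())
                if abs(total - 1.0) > 1e-9:
                    raise ConfigurationError(
                        f"{cls.value} {name} mole fractions sum to {total}, expected 1"
                    )
            if not 0.0 <= prof.incorporation <= 1.0:
                raise ConfigurationError(f"{cls.value} incorporation outside [0, 1]")
        if any(v < 0 for v in self.sphingolipid_pmol.values()):
            raise ConfigurationError("sphingolipid amounts must be >= 0")
        for cls, sc in self.shotgun.items():
            if sc.total < 0:
                raise ConfigurationError(f"shotgun total for {cls.value} must be >= 0")
            total = sum(sc.fractions.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"shotgun {cls.value} fractions sum to {total}, expected 1"
                )
        if self.protein_mg <= 0:
            raise ConfigurationError("protein_mg must be > 0")


def _profile(cls: str, entries: dict[str, float], label: Label = Label.NONE):
    return {parse_species(f"{cls} {comp}", label): frac for comp, frac in entries.items()}


def default_lipidome() -> GroundTruthLipidome:
    """Template lipidome with the study-condition defaults described above."""
    pc_endo = _profile("PC", {
        "16:0/16:0": 0.18, "16:0/18:1": 0.24, "18:0/18:2": 0.16, "16:0/18:2": 0.10,
        "16:0/20:4": 0.08, "16:0/16:1": 0.06, "18:0/18:1": 0.06, "18:0/20:4": 0.05,
        "16:0/22:6": 0.04, "34:0": 0.03,
    })
    pc_new = _profile("PC", {
        "16:0/18:1": 0.22, "16:0/18:2": 0.18, "18:0/18:2": 0.14, "16:0/16:0": 0.12,
        "16:0/16:1": 0.10, "18:0/18:1": 0.06, "16:0/20:4": 0.06, "34:0": 0.05,
        "18:0/20:4": 0.04, "16:0/22:6": 0.03,
    }, Label.D9_CHOLINE)
    ps_endo = _profile("PS", {
        "18:0/18:1": 0.42, "18:0/18:2": 0.14, "16:0/18:1": 0.12, "18:0/20:4": 0.10,
        "18:0/22:6": 0.06, "18:0/20:3": 0.05, "18:0/18:0": 0.04, "18:0/22:5": 0.04,
        "16:0/18:2": 0.03,
    })
    ps_new = _profile("PS", {
        "18:0/18:1": 0.18, "16:0/18:1": 0.17, "18:0/18:2": 0.16, "18:0/20:4": 0.14,
        "16:0/18:2": 0.08, "18:0/20:3": 0.06, "18:0/22:6": 0.06, "18:0/18:0": 0.05,
        "18:0/22:5": 0.05, "16:0/16:1": 0.05,
    }, Label.D3_SERINE)
    pi_endo = _profile("PI", {
        "18:0/20:4": 0.429, "18:0/18:2": 0.100, "16:0/18:1": 0.075, "18:0/18:1": 0.070,
        "18:0/20:3": 0.060, "18:0/20:5": 0.055, "18:0/22:6": 0.050, "18:1/18:2": 0.045,
        "16:0/18:2": 0.040, "18:0/22:4": 0.035, "16:0/20:4": 0.026, "16:0/16:1": 0.015,
    })
    pi_new = _profile("PI", {
        "18:0/20:4": 0.123, "16:0/18:1": 0.120, "18:0/18:2": 0.110, "16:0/16:0": 0.107,
        "16:0/18:2": 0.090, "18:0/18:1": 0.085, "16:0/16:1": 0.070, "18:0/20:3": 0.070,
        "18:1/18:2": 0.065, "18:0/20:5": 0.060, "16:0/20:4": 0.050, "18:0/22:6": 0.050,
    }, Label.D6_INOSITOL)
    sphingo = {parse_species(t): v for t, v in {
        # pmol/mg protein; C16:0, C24:0 and C24:1 ceramides dominate
        "Cer 16:0": 220.0, "Cer 18:0": 40.0, "Cer 20:0": 35.0, "Cer 22:0": 90.0,
        "Cer 24:0": 260.0, "Cer 24:1": 240.0, "Cer 26:0": 20.0,
        "DHCer 16:0": 25.0, "DHCer 24:0": 30.0,
        "Sph 18:1": 60.0, "Sph 18:0": 35.0,
    }.items()}
    shotgun = {
        LipidClass.PC: ShotgunClass(60.0, pc_endo),
        LipidClass.PE: ShotgunClass(40.0, _profile("PE", {
            "18:0/20:4": 0.30, "18:0/18:2": 0.20, "16:0/18:1": 0.12, "18:0/22:6": 0.12,
            "18:0/18:1": 0.10, "18:0/20:5": 0.08, "16:0/18:2": 0.08,
        })),
        LipidClass.PS: ShotgunClass(12.0, ps_endo),
        LipidClass.PI: ShotgunClass(10.0, pi_endo),
        LipidClass.PG: ShotgunClass(3.0, _profile("PG", {
            "16:0/18:1": 0.50, "18:0/18:2": 0.30, "16:0/18:2": 0.20,
        })),
        LipidClass.PA: ShotgunClass(2.5, _profile("PA", {
            "16:0/18:1": 0.40, "18:0/18:2": 0.35, "18:0/20:4": 0.25,
        })),
        LipidClass.CL: ShotgunClass(8.0, _profile("CL", {"72:8": 1.0})),
        LipidClass.SM: ShotgunClass(15.0, _profile("SM", {
            "16:0": 0.45, "24:1": 0.25, "24:0": 0.20, "18:0": 0.10,
        })),
        # ceramide class total in pmol/mg protein, matching its standard
        LipidClass.CER: ShotgunClass(500.0, _profile("Cer", {
            "16:0": 0.35, "24:0": 0.30, "24:1": 0.25, "22:0": 0.10,
        })),
        LipidClass.TAG: ShotgunClass(20.0, _profile("TAG", {
            "52:2": 0.40, "52:3": 0.35, "54:4": 0.25,
        })),
        LipidClass.CHOL: ShotgunClass(80.0, {parse_species("Chol"): 1.0}),
    }
    lip = GroundTruthLipidome(
        profiles={
            LipidClass.PC: ClassProfile(pc_endo, pc_new, incorporation=0.08),
            LipidClass.PS: ClassProfile(ps_endo, ps_new, incorporation=0.05),
            LipidClass.PI: ClassProfile(pi_endo, pi_new, incorporation=0.161),
        },
        sphingolipid_pmol=sphingo,
        shotgun=shotgun,
    )
    lip.validate()
    return lip


# --------------------------------------------------------------------------
# Noise model and isotope envelope
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseModel:
    """Within-spectrum measurement noise.

    intensity_cv: log-normal multiplicative CV per centroid.
    baseline: additive intensity offset on every centroid.
    mz_jitter_sd: gaussian jitter on centroid positions (m/z units).
    p_13c: per-carbon 13C abundance for the isotope envelope.
    """

    intensity_cv: float = 0.05
    baseline: float = 0.0
    mz_jitter_sd: float = 0.02
    p_13c: float = P_13C

    def __post_init__(self) -> None:
        if self.intensity_cv < 0:
            raise ConfigurationError("intensity_cv must be >= 0")
        if not 0.0 <= self.p_13c < 1.0:
            raise ConfigurationError("p_13c must be in [0, 1)")

    @classmethod
    def off(cls, p_13c: float = 0.0) -> "NoiseModel":
        return cls(intensity_cv=0.0, baseline=0.0, mz_jitter_sd=0.0, p_13c=p_13c)


def isotope_envelope(carbon_count: int, p: float) -> np.ndarray:
    """Relative M0/M+1/M+2 intensities of the natural 13C envelope.

    The number of 13C atoms in an n-carbon molecule is binomial(n, p);
    the envelope is truncated at M+2 and reported relative to M0, so the
    result is ``(1, n*q, n*(n-1)/2 * q**2)`` with ``q = p/(1-p)``.
    """
    if carbon_count <= 0:
        raise ConfigurationError("carbon_count must be > 0")
    q = p / (1.0 - p)
    n = carbon_count
    return np.array([1.0, n * q, 0.5 * n * (n - 1) * q * q])


# --------------------------------------------------------------------------
# Scan simulation
# --------------------------------------------------------------------------


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_scan(
    lipidome: GroundTruthLipidome,
    scan_def: ScanDefinition,
    noise: NoiseModel,
    seed,
    sample_id: str = "sample",
    gain: float = 1e6,
    mass_mode: str = "paper_nominal",
) -> PeakList:
    """Simulate one head-group scan as a centroided peak list.

    One centroid per isotopologue position (M0, M+1, M+2) of every
    species in the scan's class and label channel; coincident positions
    (the M+2 of a species overlapping the monoisotopic peak of the
    species with one fewer double bond) are merged before noise is
    applied.  Base intensity is gain x mole fraction x channel weight,
    the weight being phi for the labelled channel and 1 - phi for the
    endogenous one.
    """
    rng = np.random.default_rng(seed)
    profile = lipidome.profiles.get(scan_def.lipid_class)
    if profile is None:
        return PeakList(sample_id, scan_def.name, scan_def.polarity,
                        np.empty(0), np.empty(0))
    if scan_def.label is Label.NONE:
        fractions = profile.endogenous
        weight = 1.0 - profile.incorporation
    else:
        fractions = profile.newly_synthesised
        weight = profile.incorporation
    spacing = ISOTOPE_SPACING[mass_mode]
    positions: dict[float, float] = {}
    for sp, frac in fractions.items():
        base = gain * frac * weight
        if base <= 0:
            continue
        env = isotope_envelope(total_carbons(sp), noise.p_13c)
        mz0 = species_mz(sp.with_label(scan_def.label), mass_mode)
        for k in range(3):
            if env[k] <= 0:
                continue
            pos = round(mz0 + k * spacing, 4)
            positions[pos] = positions.get(pos, 0.0) + base * env[k]
    if not positions:
        return PeakList(sample_id, scan_def.name, scan_def.polarity,
                        np.empty(0), np.empty(0))
    mz = np.array(sorted(positions))
    intensity = np.array([positions[m] for m in mz])
    intensity = intensity * _lognormal_factors(rng, noise.intensity_cv, intensity.size)
    intensity = intensity + noise.baseline
    if noise.mz_jitter_sd > 0:
        mz = mz + rng.normal(0.0, noise.mz_jitter_sd, mz.size)
    order = np.argsort(mz)
    return PeakList(sample_id, scan_def.name, scan_def.polarity, mz[order], intensity[order])


# MRM product ions: sphingoid-backbone fragments (d18:1 -> 264.3, d18:0 -> 266.3).
_MRM_PRODUCT = {LipidClass.CER: 264.3, LipidClass.SPH: 264.3, LipidClass.DHCER: 266.3}

#: Internal standard of the sphingolipid MRM arm (spiked per mg protein).
MRM_INTERNAL_STANDARD = parse_species("Cer 17:0")
MRM_IS_PMOL_PER_MG = 40.0


def _mrm_product(sp: LipidSpecies) -> float:
    if sp.lipid_class is LipidClass.SPH:
        return 264.3 if sp.double_bonds == 1 else 266.3
    return _MRM_PRODUCT[sp.lipid_class]


def simulate_mrm(
    lipidome: GroundTruthLipidome,
    noise: NoiseModel,
    seed,
    sample_id: str = "sample",
    gain: float = 1e4,
    is_species: LipidSpecies = MRM_INTERNAL_STANDARD,
    is_pmol_per_mg: float = MRM_IS_PMOL_PER_MG,
) -> pd.DataFrame:
    """Simulate the sphingolipid MRM transition table of one sample.

    Peak areas are proportional to the absolute analyte amount in the
    extract (amount per mg protein x protein mass); the internal
    standard is spiked at a fixed amount per mg protein.
    """
    rng = np.random.default_rng(seed)
    rows = []
    species = list(lipidome.sphingolipid_pmol) + [is_species]
    factors = _lognormal_factors(rng, noise.intensity_cv, len(species))
    for sp, f in zip(species, factors):
        is_flag = sp == is_species
        pmol_per_mg = is_pmol_per_mg if is_flag else lipidome.sphingolipid_pmol[sp]
        area = gain * pmol_per_mg * lipidome.protein_mg * f
        rows.append({
            "sample_id": sample_id,
            "analyte": format_species(sp),
            "precursor_mz": species_mz(sp),
            "product_mz": _mrm_product(sp),
            "area": area,
            "is_flag": is_flag,
        })
    return pd.DataFrame(rows)


def simulate_shotgun_scan(
    lipidome: GroundTruthLipidome,
    lipid_class: LipidClass,
    noise: NoiseModel,
    seed,
    sample_id: str = "sample",
    gain: float = 1e4,
    is_species: LipidSpecies | None = None,
    is_amount_per_mg: float = 0.0,
    mass_mode: str = "paper_nominal",
) -> PeakList:
    """Simulate one per-class shotgun spectrum of a biopsy extract.

    Species intensity is proportional to the absolute amount in the
    extract; the class internal standard (when one exists) is spiked at
    a known amount per mg protein and appears in the same scan.
    """
    rng = np.random.default_rng(seed)
    sc = lipidome.shotgun.get(lipid_class)
    polarity = "+" if lipid_class in (
        LipidClass.PC, LipidClass.SM, LipidClass.CER, LipidClass.DHCER,
        LipidClass.SPH, LipidClass.TAG, LipidClass.CHOL,
    ) else "-"
    scan_type = shotgun_scan_type(lipid_class)
    if sc is None:
        return PeakList(sample_id, scan_type, polarity, np.empty(0), np.empty(0))
    amounts = {sp: sc.total * frac for sp, frac in sc.fractions.items()}
    if is_species is not None:
        amounts[is_species] = is_amount_per_mg
    spacing = ISOTOPE_SPACING[mass_mode]
    positions: dict[float, float] = {}
    for sp, per_mg in amounts.items():
        base = gain * per_mg * lipidome.protein_mg
        if base <= 0:
            continue
        env = isotope_envelope(total_carbons(sp), noise.p_13c)
        mz0 = species_mz(sp, mass_mode)
        for k in range(3):
            if env[k] <= 0:
                continue
            pos = round(mz0 + k * spacing, 4)
            positions[pos] = positions.get(pos, 0.0) + base * env[k]
    mz = np.array(sorted(positions))
    intensity = np.array([positions[m] for m in mz])
    intensity = intensity * _lognormal_factors(rng, noise.intensity_cv, intensity.size)
    intensity = intensity + noise.baseline
    if noise.mz_jitter_sd > 0:
        mz = mz + rng.normal(0.0, noise.mz_jitter_sd, mz.size)
    order = np.argsort(mz)
    return PeakList(sample_id, scan_type, polarity, mz[order], intensity[order])


# --------------------------------------------------------------------------
# Study design and effects
# --------------------------------------------------------------------------

GROUPS = ("HC", "CD")
CONDITIONS = ("unstim", "HkEc")

PHOSPHOLIPID_ARM = "phospholipid"
SPHINGOLIPID_ARM = "sphingolipid"
SHOTGUN_ARM = "shotgun"

#: Classes whose shotgun scans are simulated per biopsy sample.
SHOTGUN_CLASSES = (
    LipidClass.PC, LipidClass.PE, LipidClass.PS, LipidClass.PI, LipidClass.PG,
    LipidClass.PA, LipidClass.CL, LipidClass.SM, LipidClass.CER,
    LipidClass.TAG, LipidClass.CHOL,
)


@dataclass(frozen=True)
class Effect:
    """A multiplicative group/condition effect on one generator parameter.

    ``parameter`` is one of ``fraction`` (a head-group channel species
    mole fraction, renormalized afterwards), ``phi`` (fractional
    incorporation of a labelled class), ``sphingolipid`` (an MRM panel
    amount), ``shotgun_fraction`` or ``shotgun_total``.  ``group`` or
    ``condition`` of None applies to all.
    """

    parameter: str
    multiplier: float
    group: str | None = None
    condition: str | None = None
    lipid_class: LipidClass | None = None
    channel: str | None = None
    species: str | None = None

    def applies(self, group: str, condition: str) -> bool:
        return (self.group in (None, group)) and (self.condition in (None, condition))


def default_effects() -> list[Effect]:
    """Effects encoding the group and stimulation differences emulated."""
    return [
        # Crohn's macrophages: reduced newly-synthesised PI 16:0/18:1
        Effect("fraction", 0.65, group="CD", lipid_class=LipidClass.PI,
               channel=NEWLY_SYNTHESISED, species="PI 16:0/18:1"),
        # bacterial stimulation: faster PC synthesis, arachidonate mobilisation
        Effect("phi", 1.6, condition="HkEc", lipid_class=LipidClass.PC),
        Effect("fraction", 0.65, condition="HkEc", lipid_class=LipidClass.PC,
               channel=ENDOGENOUS, species="PC 16:0/20:4"),
        # bacterial stimulation: ceramide drop, dihydrosphingosine rise
        Effect("sphingolipid", 0.65, condition="HkEc", species="Cer 16:0"),
        Effect("sphingolipid", 0.65, condition="HkEc", species="Cer 24:0"),
        Effect("sphingolipid", 0.60, condition="HkEc", species="Cer 24:1"),
        Effect("sphingolipid", 1.80, condition="HkEc", species="Sph 18:0"),
        # Crohn's biopsies: reduced PI 16:0/18:1 as a share of PI
        Effect("shotgun_fraction", 0.60, group="CD", lipid_class=LipidClass.PI,
               species="PI 16:0/18:1"),
    ]


@dataclass
class StudyDesign:
    """Arms, per-cell sample sizes, effects and variability of a study.

    ``arms`` maps arm name -> {(group, condition): n}.  The three arms
    mirror the study structure: a macrophage phospholipid arm (six
    head-group scans per sample), a macrophage sphingolipid MRM arm, and
    a biopsy shotgun arm (unstimulated only).
    """

    arms: dict[str, dict[tuple[str, str], int]]
    effects: list[Effect] = field(default_factory=default_effects)
    between_subject_cv: float = 0.20
    paired: bool = False
    seed: int = 0


def default_design(
    effects: list[Effect] | None = None, paired: bool = False, seed: int = 0
) -> StudyDesign:
    """Sample sizes of the emulated study, per arm, group and condition."""
    arms = {
        SPHINGOLIPID_ARM: {
            ("HC", "unstim"): 7, ("CD", "unstim"): 8,
            ("HC", "HkEc"): 7, ("CD", "HkEc"): 12,
        },
        PHOSPHOLIPID_ARM: {
            ("HC", "unstim"): 7, ("CD", "unstim"): 9,
            ("HC", "HkEc"): 6, ("CD", "HkEc"): 5,
        },
        SHOTGUN_ARM: {("HC", "unstim"): 5, ("CD", "unstim"): 5},
    }
    return StudyDesign(
        arms=arms,
        effects=default_effects() if effects is None else effects,
        paired=paired,
        seed=seed,
    )


def null_design(seed: int = 0, **kwargs) -> StudyDesign:
    """The same design with every effect removed (type-I error control)."""
    return default_design(effects=[], seed=seed, **kwargs)


def _apply_multiplier(mapping: dict, key_text: str, multiplier: float, what: str) -> None:
    keyed = {format_species(sp): sp for sp in mapping}
    if key_text not in keyed:
        raise ConfigurationError(f"effect on unknown {what} {key_text!r}")
    mapping[keyed[key_text]] *= multiplier


def _renormalize(mapping: dict) -> None:
    total = sum(mapping.values())
    if total > 0:
        for k in mapping:
            mapping[k] /= total


def apply_effects(
    lipidome: GroundTruthLipidome, effects: list[Effect], group: str, condition: str
) -> GroundTruthLipidome:
    """Return a copy of the lipidome with all applicable effects applied.

    Species-fraction effects are renormalized within their channel so
    profiles remain mole-fraction distributions.
    """
    lip = _copy_lipidome(lipidome)
    for eff in effects:
        if not eff.applies(group, condition):
            continue
        if eff.parameter == "fraction":
            if eff.lipid_class not in lip.profiles:
                raise ConfigurationError(f"effect on unknown class {eff.lipid_class}")
            channel = lip.profiles[eff.lipid_class].channel(eff.channel)
            _apply_multiplier(channel, eff.species, eff.multiplier, "species")
            _renormalize(channel)
        elif eff.parameter == "phi":
            if eff.lipid_class not in lip.profiles:
                raise ConfigurationError(f"effect on unknown class {eff.lipid_class}")
            prof = lip.profiles[eff.lipid_class]
            prof.incorporation = min(1.0, prof.incorporation * eff.multiplier)
        elif eff.parameter == "sphingolipid":
            _apply_multiplier(lip.sphingolipid_pmol, eff.species, eff.multiplier, "sphingolipid")
        elif eff.parameter == "shotgun_fraction":
            if eff.lipid_class not in lip.shotgun:
                raise ConfigurationError(f"effect on unknown shotgun class {eff.lipid_class}")
            fractions = lip.shotgun[eff.lipid_class].fractions
            _apply_multiplier(fractions, eff.species, eff.multiplier, "species")
            _renormalize(fractions)
        elif eff.parameter == "shotgun_total":
            if eff.lipid_class not in lip.shotgun:
                raise ConfigurationError(f"effect on unknown shotgun class {eff.lipid_class}")
            lip.shotgun[eff.lipid_class].total *= eff.multiplier
        else:
            raise ConfigurationError(f"effect on unknown parameter {eff.parameter!r}")
    return lip


def _copy_lipidome(lip: GroundTruthLipidome) -> GroundTruthLipidome:
    return GroundTruthLipidome(
        profiles={
            cls: ClassProfile(dict(p.endogenous), dict(p.newly_synthesised), p.incorporation)
            for cls, p in lip.profiles.items()
        },
        sphingolipid_pmol=dict(lip.sphingolipid_pmol),
        shotgun={cls: ShotgunClass(sc.total, dict(sc.fractions)) for cls, sc in lip.shotgun.items()},
        protein_mg=lip.protein_mg,
    )


def perturb_lipidome(
    lip: GroundTruthLipidome, cv: float, rng: np.random.Generator
) -> GroundTruthLipidome:
    """Draw one subject's lipidome log-normally around the group template.

    Each species fraction, incorporation, amount and the protein mass
    receives an independent unit-mean log-normal factor; fraction
    profiles are renormalized afterwards.
    """
    out = _copy_lipidome(lip)
    for prof in out.profiles.values():
        for channel in (prof.endogenous, prof.newly_synthesised):
            factors = _lognormal_factors(rng, cv, len(channel))
            for sp, f in zip(list(channel), factors):
                channel[sp] *= f
            _renormalize(channel)
        prof.incorporation = float(
            np.clip(prof.incorporation * _lognormal_factors(rng, cv, 1)[0], 0.0, 1.0)
        )
    factors = _lognormal_factors(rng, cv, len(out.sphingolipid_pmol))
    for sp, f in zip(list(out.sphingolipid_pmol), factors):
        out.sphingolipid_pmol[sp] *= f
    for sc in out.shotgun.values():
        sc.total *= _lognormal_factors(rng, cv, 1)[0]
        factors = _lognormal_factors(rng, cv, len(sc.fractions))
        for sp, f in zip(list(sc.fractions), factors):
            sc.fractions[sp] *= f
        _renormalize(sc.fractions)
    out.protein_mg *= _lognormal_factors(rng, 0.10, 1)[0]
    return out


# --------------------------------------------------------------------------
# Whole-study simulation
# --------------------------------------------------------------------------


@dataclass
class SimulatedSample:
    """One subject's simulated acquisition plus its ground truth."""

    sample_id: str
    arm: str
    group: str
    condition: str
    subject_id: str
    protein_mg: float
    peak_lists: dict[str, PeakList] = field(default_factory=dict)
    mrm: pd.DataFrame | None = None
    truth: GroundTruthLipidome | None = None


@dataclass
class StudySimulation:
    design: StudyDesign
    samples: list[SimulatedSample]

    def by_arm(self, arm: str) -> list[SimulatedSample]:
        return [s for s in self.samples if s.arm == arm]


def simulate_study(
    design: StudyDesign,
    lipidome_template: GroundTruthLipidome | None = None,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    mass_mode: str = "paper_nominal",
) -> StudySimulation:
    """Simulate every sample of a study design.

    Effects are applied to the template to form the (group, condition)
    mean, and each subject is drawn log-normally around that mean.  With
    ``design.paired`` the same subject draw is reused across conditions
    of an arm (stimulated/unstimulated aliquots of one subject), in
    which case each arm uses the maximum per-condition n.
    """
    template = lipidome_template if lipidome_template is not None else default_lipidome()
    template.validate()
    noise = noise if noise is not None else NoiseModel()
    root = np.random.SeedSequence(design.seed if seed is None else seed)
    samples: list[SimulatedSample] = []
    for arm in sorted(design.arms):
        cells = design.arms[arm]
        for n in cells.values():
            if n < 2:
                raise ConfigurationError("study cells need n >= 2 for downstream statistics")
        arm_seq = root.spawn(1)[0]
        if design.paired:
            samples.extend(_simulate_arm_paired(arm, cells, design, template, noise, arm_seq, mass_mode))
        else:
            for (group, condition), n in sorted(cells.items()):
                for i in range(n):
                    subject_seq = arm_seq.spawn(1)[0]
                    subject_id = f"{arm}-{group}-{condition}-{i + 1}"
                    samples.append(_simulate_sample(
                        arm, group, condition, subject_id, subject_id, design,
                        template, noise, subject_seq, mass_mode,
                    ))
    return StudySimulation(design, samples)


def _simulate_arm_paired(arm, cells, design, template, noise, arm_seq, mass_mode):
    groups = sorted({g for g, _ in cells})
    out = []
    for group in groups:
        conds = sorted({c for g, c in cells if g == group})
        n = max(cells[(group, c)] for c in conds)
        for i in range(n):
            subject_seq = arm_seq.spawn(1)[0]
            # One perturbation seed per subject: the same between-subject
            # draw is reused for every condition of that subject.
            perturb_seq = subject_seq.spawn(1)[0]
            subject_id = f"{arm}-{group}-{i + 1}"
            for condition in conds:
                sample_id = f"{subject_id}-{condition}"
                out.append(_simulate_sample(
                    arm, group, condition, sample_id, subject_id, design,
                    template, noise, subject_seq.spawn(1)[0], mass_mode,
                    perturb_seq=perturb_seq,
                ))
    return out


def _simulate_sample(
    arm, group, condition, sample_id, subject_id, design, template, noise,
    subject_seq, mass_mode, perturb_seq=None,
) -> SimulatedSample:
    shifted = apply_effects(template, design.effects, group, condition)
    rng = np.random.default_rng(perturb_seq if perturb_seq is not None else subject_seq.spawn(1)[0])
    truth = perturb_lipidome(shifted, design.between_subject_cv, rng)
    sample = SimulatedSample(
        sample_id=sample_id, arm=arm, group=group, condition=condition,
        subject_id=subject_id, protein_mg=truth.protein_mg, truth=truth,
    )
    if arm == PHOSPHOLIPID_ARM:
        for name, scan_def in HEAD_GROUP_SCANS.items():
            sample.peak_lists[name] = simulate_scan(
                truth, scan_def, noise, subject_seq.spawn(1)[0], sample_id,
                mass_mode=mass_mode,
            )
    elif arm == SPHINGOLIPID_ARM:
        sample.mrm = simulate_mrm(truth, noise, subject_seq.spawn(1)[0], sample_id)
    elif arm == SHOTGUN_ARM:
        from .quantify import default_internal_standards

        is_table = default_internal_standards()
        for cls in SHOTGUN_CLASSES:
            entry = is_table.get(cls)
            sample.peak_lists[shotgun_scan_type(cls)] = simulate_shotgun_scan(
                truth, cls, noise, subject_seq.spawn(1)[0], sample_id,
                is_species=entry.species if entry else None,
                is_amount_per_mg=entry.amount_per_mg if entry else 0.0,
                mass_mode=mass_mode,
            )
    else:
        raise ConfigurationError(f"unknown study arm {arm!r}")
    return sample
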