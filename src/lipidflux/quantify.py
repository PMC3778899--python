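"""Absolute quantification against internal standards.

Two arms:

* MRM sphingolipid panel - each analyte's peak area is ratioed to a
  single spiked ceramide standard and scaled by the spiked amount
  (per mg protein) and an optional per-species response factor;
  amounts are reported in pmol/mg protein.

* Single-step shotgun quantification - each class scan carries its own
  spiked standard (e.g. dimyristoyl-PC at 15 nmol/mg protein); after
  13C correction, species amount = intensity ratio to the standard x
  spiked amount.  PI, which carries no standard, is re-expressed as
  mole-% of the PI total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .composition import CompositionTable, composition
from .errors import ConfigurationError, DataError
from .io import PeakList
from .processing import (
    CorrectedIntensities,
    DEFAULT_TOLERANCE,
    assign_peaks,
    correct_13C,
)
from .registry import (
    LipidClass,
    LipidSpecies,
    enumerate_species,
    format_species,
    parse_species,
)


@dataclass(frozen=True)
class MrmMeasurement:
    """One MRM transition of one sample."""

    analyte: LipidSpecies
    precursor_mz: float
    product_mz: float
    area: float
    is_flag: bool = False
    response_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.area < 0:
            raise DataError("MRM peak areas must be >= 0")
        if self.response_factor <= 0:
            raise ConfigurationError("response factors must be > 0")


@dataclass(frozen=True)
class InternalStandard:
    """A class's spiked standard and its amount per mg protein."""

    lipid_class: LipidClass
    species: LipidSpecies
    amount_per_mg: float
    units: str  # units of the reported amounts, per mg protein

    def __post_init__(self) -> None:
        if self.amount_per_mg <= 0:
            raise ConfigurationError("internal standard amounts must be > 0")


InternalStandardTable = dict[LipidClass, InternalStandard]


def default_internal_standards() -> InternalStandardTable:
    """The shotgun spike mix: one exogenous species per quantified class."""
    entries = [
        InternalStandard(LipidClass.PC, parse_species("PC 14:0/14:0"), 15.0, "nmol/mg"),
        InternalStandard(LipidClass.PS, parse_species("PS 14:0/14:0"), 1.0, "nmol/mg"),
        InternalStandard(LipidClass.PG, parse_species("PG 15:0/15:0"), 4.2, "nmol/mg"),
        InternalStandard(LipidClass.PE, parse_species("PE 15:0/15:0"), 18.75, "nmol/mg"),
        InternalStandard(LipidClass.CER, parse_species("Cer 17:0"), 40.0, "pmol/mg"),
        InternalStandard(LipidClass.TAG, parse_species("TAG 51:3"), 10.0, "nmol/mg"),
    ]
    return {e.lipid_class: e for e in entries}


@dataclass
class AbsoluteQuantResult:
    """Per-species amounts (per mg protein), class totals, PI mole-%."""

    species_amounts: pd.DataFrame  # columns: lipid_class, species, amount, units
    class_totals: pd.DataFrame  # columns: lipid_class, total, units
    pi_composition: CompositionTable | None = None
    warnings: list[str] = field(default_factory=list)
    all_zero: bool = False


def mrm_measurements_from_table(
    table: pd.DataFrame, response_factors: dict[str, float] | None = None
) -> list[MrmMeasurement]:
    """Build measurements from a delimited MRM transition table."""
    out = []
    for row in table.itertuples():
        rf = (response_factors or {}).get(row.analyte, 1.0)
        out.append(MrmMeasurement(
            analyte=parse_species(row.analyte),
            precursor_mz=float(row.precursor_mz),
            product_mz=float(row.product_mz),
            area=float(row.area),
            is_flag=bool(row.is_flag),
            response_factor=rf,
        ))
    return out


def quantify_mrm(
    measurements: list[MrmMeasurement],
    protein_mg: float,
    is_amount_per_mg: float,
    include_dihydro_in_total: bool = False,
) -> AbsoluteQuantResult:
    """Quantify the sphingolipid MRM panel of one sample.

    amount_s = (area_s / area_IS) * spiked amount * response factor,
    reported in pmol/mg protein.  The spiked amount is defined per mg
    protein, so the absolute spike is scaled by the sample's protein
    mass and the result normalised back.  Total ceramide sums the
    ceramide species (dihydroceramides excluded by default).
    """
    if protein_mg <= 0:
        raise ConfigurationError("protein_mg must be > 0")
    standards = [m for m in measurements if m.is_flag]
    if not standards:
        raise DataError("sample rejected: no internal standard in MRM batch")
    if len(standards) > 1:
        raise DataError("sample rejected: multiple internal standards flagged")
    is_area = standards[0].area
    if is_area <= 0:
        raise DataError("sample rejected: internal standard area is zero")
    spiked_pmol = is_amount_per_mg * protein_mg
    rows = []
    for m in measurements:
        if m.is_flag:
            continue
        pmol = (m.area / is_area) * spiked_pmol * m.response_factor
        rows.append({
            "lipid_class": m.analyte.lipid_class.value,
            "species": format_species(m.analyte),
            "amount": pmol / protein_mg,
            "units": "pmol/mg",
        })
    species_amounts = pd.DataFrame(rows)
    total_classes = [LipidClass.CER.value]
    if include_dihydro_in_total:
        total_classes.append(LipidClass.DHCER.value)
    totals = (
        species_amounts.groupby("lipid_class", as_index=False)["amount"].sum()
        .rename(columns={"amount": "total"})
    )
    totals["units"] = "pmol/mg"
    total_cer = species_amounts.loc[
        species_amounts["lipid_class"].isin(total_classes), "amount"
    ].sum()
    totals = pd.concat(
        [totals, pd.DataFrame([{"lipid_class": "total_ceramide", "total": total_cer,
                                "units": "pmol/mg"}])],
        ignore_index=True,
    )
    return AbsoluteQuantResult(species_amounts, totals)


def _default_candidates(lipid_class: LipidClass) -> list[LipidSpecies]:
    """Candidate lattice for a shotgun class scan (biological species)."""
    if lipid_class in (LipidClass.PC, LipidClass.PS, LipidClass.PI, LipidClass.PE,
                       LipidClass.PG, LipidClass.PA):
        return enumerate_species(lipid_class, (28, 44), (0, 6))
    if lipid_class is LipidClass.CL:
        return enumerate_species(lipid_class, (64, 76), (4, 10))
    if lipid_class in (LipidClass.SM, LipidClass.CER, LipidClass.DHCER):
        return [LipidSpecies(lipid_class, c, d) for c in range(14, 27, 2) for d in (0, 1)]
    if lipid_class is LipidClass.TAG:
        return enumerate_species(lipid_class, (48, 56), (0, 6))
    if lipid_class is LipidClass.CHOL:
        return [parse_species("Chol")]
    raise ConfigurationError(f"no candidate lattice for class {lipid_class.value}")


def quantify_shotgun(
    class_peaks: dict[LipidClass, PeakList],
    is_table: InternalStandardTable | None = None,
    protein_mg: float = 1.0,
    tolerance: float = DEFAULT_TOLERANCE,
    p: float = 0.0107,
    mass_mode: str = "paper_nominal",
    candidates: dict[LipidClass, list[LipidSpecies]] | None = None,
) -> AbsoluteQuantResult:
    """Single-step internal-standard quantification of biopsy class scans.

    For every class with a standard: assign peaks (the odd-carbon
    standard species is whitelisted into the candidate list), correct
    13C contamination, then amount = corrected ratio to the standard x
    spiked amount per mg protein.  Classes whose scan is missing are
    omitted with a warning; a class scan missing its standard peak is a
    data error for that sample.  PI mole-% composition is always
    computed from the PI scan when present.
    """
    if protein_mg <= 0:
        raise ConfigurationError("protein_mg must be > 0")
    is_table = default_internal_standards() if is_table is None else is_table
    warnings: list[str] = []
    amount_rows = []
    total_rows = []
    pi_composition = None
    any_signal = False
    for cls, entry in sorted(is_table.items(), key=lambda kv: kv[0].value):
        peaks = class_peaks.get(cls)
        if peaks is None:
            warnings.append(f"class scan missing for {cls.value}; class omitted")
            continue
        cand = list((candidates or {}).get(cls) or _default_candidates(cls))
        if entry.species not in cand:
            cand.append(entry.species)  # whitelisted standard (may be odd-carbon)
        corrected = correct_13C(
            assign_peaks(peaks, cand, tolerance, mass_mode), p, mass_mode=mass_mode
        )
        if len(peaks) == 0 or corrected.total() <= 0:
            warnings.append(f"empty {cls.value} scan: all-zero result")
            total_rows.append({"lipid_class": cls.value, "total": 0.0, "units": entry.units})
            continue
        any_signal = True
        is_intensity = corrected.intensities.get(entry.species, 0.0)
        if is_intensity <= 0:
            raise DataError(
                f"internal standard {format_species(entry.species)} not detected "
                f"in {cls.value} scan of sample {peaks.sample_id}"
            )
        class_total = 0.0
        for sp, inten in sorted(corrected.intensities.items(),
                                key=lambda kv: format_species(kv[0])):
            if sp == entry.species or inten <= 0:
                continue
            amount = (inten / is_intensity) * entry.amount_per_mg
            class_total += amount
            amount_rows.append({
                "lipid_class": cls.value, "species": format_species(sp),
                "amount": amount, "units": entry.units,
            })
        total_rows.append({"lipid_class": cls.value, "total": class_total,
                           "units": entry.units})
    pi_peaks = class_peaks.get(LipidClass.PI)
    if pi_peaks is not None:
        cand = list((candidates or {}).get(LipidClass.PI)
                    or _default_candidates(LipidClass.PI))
        corrected = correct_13C(
            assign_peaks(pi_peaks, cand, tolerance, mass_mode), p, mass_mode=mass_mode
        )
        pi_composition = composition(corrected, LipidClass.PI, "endogenous")
        any_signal = any_signal or not pi_composition.empty_channel
    species_amounts = pd.DataFrame(
        amount_rows, columns=["lipid_class", "species", "amount", "units"]
    )
    class_totals = pd.DataFrame(total_rows, columns=["lipid_class", "total", "units"])
    return AbsoluteQuantResult(
        species_amounts, class_totals, pi_composition, warnings, all_zero=not any_signal
    )
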