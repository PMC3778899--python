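"""Peak assignment and natural-abundance 13C correction (deisotoping).

Within a head-group scan, species of the same acyl carbon number differ
by two double bonds' worth of mass: the M+2 isotopologue of a species
therefore lands exactly on the monoisotopic peak of the species with
one fewer double bond.  Because contamination only propagates upward in
mass, a single ascending sweep that subtracts the modelled M+2
contribution of each already-corrected donor removes it.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .io import PeakList
from .registry import LipidSpecies, species_mz, total_carbons
from .simulate import ISOTOPE_SPACING, isotope_envelope

logger = logging.getLogger(__name__)

DEFAULT_TOLERANCE = 0.5  # m/z; unit-resolution quadrupole centroids


@dataclass
class PeakAssignment:
    """One centroid matched (or not) to a candidate isotopologue position."""

    mz: float
    intensity: float
    species: LipidSpecies | None = None
    isotopologue_index: int | None = None  # 0 = M0, 1 = M+1, 2 = M+2
    delta_mz: float = float("nan")
    tie_broken: bool = False

    @property
    def assigned(self) -> bool:
        return self.species is not None


@dataclass
class CorrectionRecord:
    species: LipidSpecies
    donor: LipidSpecies
    subtracted: float
    floored: bool


@dataclass
class CorrectedIntensities:
    """Corrected monoisotopic intensities with a full subtraction audit."""

    intensities: dict[LipidSpecies, float]
    audit: list[CorrectionRecord] = field(default_factory=list)
    flooring_events: int = 0

    def total(self) -> float:
        return float(sum(self.intensities.values()))


def assign_peaks(
    peaks: PeakList,
    candidates: list[LipidSpecies],
    tolerance: float = DEFAULT_TOLERANCE,
    mass_mode: str = "paper_nominal",
) -> list[PeakAssignment]:
    """Match each centroid to the nearest candidate isotopologue position.

    Candidate positions are the M0, M+1 and M+2 locations of every
    species.  Ties at equal |delta| prefer the lower isotopologue index
    (so a peak sitting exactly on both a monoisotopic position and the
    M+2 position of the species two double bonds away is treated as a
    monoisotopic peak, which is what the 13C correction assumes), then
    the lower expected m/z; tie-breaks are recorded on the assignment.
    Each (species, isotopologue) pair keeps at most one peak - the
    closest; displaced peaks become unassigned.
    """
    if tolerance <= 0:
        raise ConfigurationError("tolerance must be > 0")
    spacing = ISOTOPE_SPACING[mass_mode] if mass_mode in ISOTOPE_SPACING else 1.0
    positions: list[tuple[float, int, LipidSpecies]] = []
    for sp in candidates:
        mz0 = species_mz(sp, mass_mode)
        for k in range(3):
            positions.append((mz0 + k * spacing, k, sp))
    positions.sort(key=lambda t: (t[0], t[1]))
    pos_mz = [t[0] for t in positions]

    mz = np.asarray(peaks.mz, dtype=float)
    intensity = np.asarray(peaks.intensity, dtype=float)
    if mz.size and np.any(np.diff(mz) < 0):
        logger.warning("non-monotone peak list %s/%s: sorting internally",
                       peaks.sample_id, peaks.scan_type)
        order = np.argsort(mz)
        mz, intensity = mz[order], intensity[order]

    assignments: list[PeakAssignment] = []
    best_by_slot: dict[tuple[LipidSpecies, int], PeakAssignment] = {}
    for m, inten in zip(mz, intensity):
        a = PeakAssignment(mz=float(m), intensity=float(inten))
        if positions:
            i = bisect.bisect_left(pos_mz, m)
            window = [positions[j] for j in range(max(0, i - 4), min(len(positions), i + 4))]
            scored = sorted(
                ((abs(m - p), k, p, sp) for p, k, sp in window if abs(m - p) <= tolerance),
                key=lambda t: (round(t[0], 9), t[1], t[2]),
            )
            if scored:
                d, k, p, sp = scored[0]
                if len(scored) > 1 and abs(scored[1][0] - d) < 1e-9:
                    a.tie_broken = True
                slot = (sp, k)
                incumbent = best_by_slot.get(slot)
                if incumbent is None or abs(incumbent.delta_mz) > d:
                    if incumbent is not None:
                        incumbent.species = None
                        incumbent.isotopologue_index = None
                        incumbent.delta_mz = float("nan")
                    a.species, a.isotopologue_index, a.delta_mz = sp, k, float(m - p)
                    best_by_slot[slot] = a
        assignments.append(a)
    return assignments


def monoisotopic_intensities(assignments: list[PeakAssignment]) -> dict[LipidSpecies, float]:
    """Measured M0 intensity per assigned species (M+1/M+2 peaks are
    assigned for completeness but not used quantitatively)."""
    out: dict[LipidSpecies, float] = {}
    for a in assignments:
        if a.assigned and a.isotopologue_index == 0:
            out[a.species] = a.intensity
    return out


def correct_13C(
    assignments: list[PeakAssignment] | dict[LipidSpecies, float],
    p: float = 0.0107,
    carbon_counts: dict[LipidSpecies, int] | None = None,
    mass_mode: str = "paper_nominal",
) -> CorrectedIntensities:
    """Remove 13C M+2 cross-contamination between species 2 Da apart.

    Sweeps species in ascending m/z; for each species the donor is the
    assigned species one double bond up (2 Da below).  The subtracted
    amount is the donor's *corrected* intensity times its modelled
    M+2/M0 envelope ratio, so the sweep is exactly forward substitution
    of the band-diagonal envelope system.  Results are floored at zero
    and every subtraction is recorded.
    """
    if not 0.0 <= p < 0.05:
        raise ConfigurationError("13C abundance p must be in [0, 0.05)")
    if isinstance(assignments, dict):
        measured = dict(assignments)
    else:
        measured = monoisotopic_intensities(assignments)
    order = sorted(measured, key=lambda sp: species_mz(sp, mass_mode))
    by_key = {(sp.lipid_class, sp.label, sp.carbons, sp.double_bonds): sp for sp in measured}
    corrected: dict[LipidSpecies, float] = {}
    audit: list[CorrectionRecord] = []
    flooring = 0
    for sp in order:
        value = measured[sp]
        donor = by_key.get((sp.lipid_class, sp.label, sp.carbons, sp.double_bonds + 1))
        if donor is not None:
            n_c = carbon_counts[donor] if carbon_counts else total_carbons(donor)
            f2 = float(isotope_envelope(n_c, p)[2])
            subtracted = f2 * corrected[donor]
            value -= subtracted
            floored = value < 0
            if floored:
                flooring += 1
                logger.info("flooring corrected intensity of %s at 0", sp)
                value = 0.0
            audit.append(CorrectionRecord(sp, donor, subtracted, floored))
        corrected[sp] = value
    return CorrectedIntensities(corrected, audit, flooring)


def process_scan(
    peaks: PeakList,
    candidates: list[LipidSpecies],
    tolerance: float = DEFAULT_TOLERANCE,
    p: float = 0.0107,
    mass_mode: str = "paper_nominal",
) -> CorrectedIntensities:
    """Convenience: assign then correct one scan."""
    return correct_13C(
        assign_peaks(peaks, candidates, tolerance, mass_mode), p, mass_mode=mass_mode
    )
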