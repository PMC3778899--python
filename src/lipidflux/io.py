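"""File formats, in-memory peak lists, and run configuration.

The interchange format is delimited UTF-8 text (comma separator, '.'
decimal).  A peak-list file holds one centroided scan per
(sample_id, scan_type) block with columns::

    sample_id, scan_type, polarity, mz, intensity

``scan_type`` is a closed vocabulary: the six head-group scans (P184+,
P193+, P241-, P247-, NL87-, NL90-), ``MRM``, and ``SHOTGUN:<class>``.
A study manifest lists every emitted file with its sample metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .errors import ConfigurationError, DataError
from .registry import LipidClass

HEAD_GROUP_SCAN_TYPES = ("P184+", "P193+", "P241-", "P247-", "NL87-", "NL90-")


def shotgun_scan_type(lipid_class: LipidClass) -> str:
    return f"SHOTGUN:{lipid_class.value}"


def _valid_scan_type(scan_type: str) -> bool:
    if scan_type in HEAD_GROUP_SCAN_TYPES or scan_type == "MRM":
        return True
    if scan_type.startswith("SHOTGUN:"):
        token = scan_type.split(":", 1)[1]
        return token in {c.value for c in LipidClass}
    return False


@dataclass
class PeakList:
    """One scan's centroided (m/z, intensity) pairs with metadata."""

    sample_id: str
    scan_type: str
    polarity: str
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise DataError("mz and intensity arrays differ in length")
        if not _valid_scan_type(self.scan_type):
            raise DataError(f"unknown scan_type {self.scan_type!r}")
        if self.mz.size and (np.any(self.mz <= 0) or np.any(self.intensity < 0)):
            raise DataError("peak lists require mz > 0 and intensity >= 0")

    def __len__(self) -> int:
        return self.mz.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_id": self.sample_id,
            "scan_type": self.scan_type,
            "polarity": self.polarity,
            "mz": self.mz,
            "intensity": self.intensity,
        })


PEAK_LIST_COLUMNS = ["sample_id", "scan_type", "polarity", "mz", "intensity"]


def write_peak_list(peaks: PeakList, path: str | Path) -> None:
    peaks.to_frame().to_csv(path, index=False, float_format="%.6f")


def read_peak_list(path: str | Path) -> PeakList:
    """Read a single-scan peak-list file, validating schema and values."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"peak-list file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in PEAK_LIST_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    if df.empty:
        raise DataError(f"{path}: empty peak-list file")
    for col in ("sample_id", "scan_type", "polarity"):
        if df[col].nunique() != 1:
            raise DataError(f"{path}: column {col} must be constant within a scan file")
    for i, row in enumerate(df.itertuples(), start=2):
        if not np.isfinite(row.mz) or row.mz <= 0 or row.intensity < 0:
            raise DataError(f"{path}: malformed peak on row {i}")
    scan_type = str(df["scan_type"].iloc[0])
    if not _valid_scan_type(scan_type):
        raise DataError(f"{path}: unknown scan_type {scan_type!r}")
    return PeakList(
        sample_id=str(df["sample_id"].iloc[0]),
        scan_type=scan_type,
        polarity=str(df["polarity"].iloc[0]),
        mz=df["mz"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
    )


MRM_COLUMNS = ["sample_id", "analyte", "precursor_mz", "product_mz", "area", "is_flag"]


def write_mrm_table(table: pd.DataFrame, path: str | Path) -> None:
    table[MRM_COLUMNS].to_csv(path, index=False, float_format="%.6f")


def read_mrm_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"MRM table not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in MRM_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    if (df["area"] < 0).any():
        raise DataError(f"{path}: negative MRM peak area")
    df["is_flag"] = df["is_flag"].astype(bool)
    return df


MANIFEST_COLUMNS = [
    "sample_id", "arm", "group", "condition", "subject_id",
    "protein_mg", "scan_type", "file", "seed",
]


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest[MANIFEST_COLUMNS].to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"manifest not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing manifest columns {missing}")
    return df


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------


class NoiseConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    intensity_cv: float = Field(0.05, ge=0)
    baseline: float = Field(0.0, ge=0)
    mz_jitter_sd: float = Field(0.02, ge=0)
    p_13c: float = Field(0.0107, ge=0, lt=1)


class EffectConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    parameter: str
    multiplier: float = Field(gt=0)
    group: str | None = None
    condition: str | None = None
    lipid_class: str | None = None
    channel: str | None = None
    species: str | None = None


class DesignConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    # arm -> "GROUP/CONDITION" -> n
    arms: dict[str, dict[str, int]] | None = None
    between_subject_cv: float = Field(0.20, ge=0)
    paired: bool = False
    null: bool = False  # drop all effects (type-I error studies)
    effects: list[EffectConfig] | None = None


class RunConfig(BaseModel):
    """Validated configuration for the simulate and analyse commands."""

    model_config = ConfigDict(extra="forbid")

    mass_mode: str = "paper_nominal"
    tolerance: float = Field(0.5, gt=0)
    alpha_macrophage: float = Field(0.05, gt=0, lt=1)
    alpha_shotgun: float = Field(0.01, gt=0, lt=1)
    quantifiable_only: bool = True  # restrict tests to species > 2 % of class
    # spiked amount of the MRM sphingolipid standard; no published default
    # exists for the MRM arm, so this mirrors the shotgun ceramide spike
    mrm_is_pmol_per_mg: float = Field(40.0, gt=0)
    seed: int = 0
    noise: NoiseConfig = NoiseConfig()
    design: DesignConfig = DesignConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls.model_validate(raw)
        except Exception as exc:  # pydantic ValidationError
            raise ConfigurationError(f"invalid config {path}: {exc}") from exc

    def build_noise(self):
        from .simulate import NoiseModel

        return NoiseModel(
            intensity_cv=self.noise.intensity_cv,
            baseline=self.noise.baseline,
            mz_jitter_sd=self.noise.mz_jitter_sd,
            p_13c=self.noise.p_13c,
        )

    def build_design(self):
        from .simulate import Effect, StudyDesign, default_design, default_effects

        d = self.design
        if d.effects is not None:
            effects = [
                Effect(
                    parameter=e.parameter, multiplier=e.multiplier, group=e.group,
                    condition=e.condition,
                    lipid_class=LipidClass(e.lipid_class) if e.lipid_class else None,
                    channel=e.channel, species=e.species,
                )
                for e in d.effects
            ]
        elif d.null:
            effects = []
        else:
            effects = default_effects()
        base = default_design(effects=effects, paired=d.paired, seed=self.seed)
        base.between_subject_cv = d.between_subject_cv
        if d.arms is not None:
            arms: dict[str, dict[tuple[str, str], int]] = {}
            for arm, cells in d.arms.items():
                parsed: dict[tuple[str, str], int] = {}
                for key, n in cells.items():
                    try:
                        group, condition = key.split("/")
                    except ValueError:
                        raise ConfigurationError(
                            f"design cell key {key!r} must be 'GROUP/CONDITION'"
                        ) from None
                    parsed[(group, condition)] = n
                arms[arm] = parsed
            base = StudyDesign(
                arms=arms, effects=effects, between_subject_cv=d.between_subject_cv,
                paired=d.paired, seed=self.seed,
            )
        return base
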