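"""End-to-end analysis: peak lists -> composition, flux, amounts, statistics.

This module glues the processing stages together for whole studies,
either on in-memory simulations or on files listed in a manifest.  The
endpoint table it produces is tidy (one row per sample x endpoint) and
feeds the comparison layer directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .composition import aggregate_group, composition, fractional_incorporation
from .errors import DataError
from .io import RunConfig, shotgun_scan_type
from .processing import assign_peaks, correct_13C
from .quantify import (
    default_internal_standards,
    mrm_measurements_from_table,
    quantify_mrm,
    quantify_shotgun,
)
from .registry import (
    HEAD_GROUP_SCANS,
    Label,
    LipidClass,
    enumerate_species,
)
from .simulate import (
    ENDOGENOUS,
    NEWLY_SYNTHESISED,
    PHOSPHOLIPID_ARM,
    SHOTGUN_ARM,
    SPHINGOLIPID_ARM,
    SHOTGUN_CLASSES,
    SimulatedSample,
)
from .stats import ComparisonSpec, compare_study

#: Candidate lattice for the head-group scans (even-carbon biological species).
HEAD_GROUP_LATTICE = dict(carbon_range=(28, 44), db_range=(0, 6))


def head_group_candidates(lipid_class: LipidClass, label: Label):
    return enumerate_species(
        lipid_class, HEAD_GROUP_LATTICE["carbon_range"], HEAD_GROUP_LATTICE["db_range"], label
    )


@dataclass
class SampleAnalysis:
    """All per-sample results in tidy form."""

    composition: pd.DataFrame = field(default_factory=pd.DataFrame)
    incorporation: pd.DataFrame = field(default_factory=pd.DataFrame)
    mrm_amounts: pd.DataFrame = field(default_factory=pd.DataFrame)
    shotgun_totals: pd.DataFrame = field(default_factory=pd.DataFrame)
    shotgun_pi: pd.DataFrame = field(default_factory=pd.DataFrame)
    warnings: list[str] = field(default_factory=list)


def analyse_sample(sample: SimulatedSample, config: RunConfig) -> SampleAnalysis:
    """Process one sample's scans into composition/flux/amount rows."""
    out = SampleAnalysis()
    meta = {
        "sample_id": sample.sample_id, "arm": sample.arm, "group": sample.group,
        "condition": sample.condition, "subject_id": sample.subject_id,
    }
    comp_rows, inc_rows = [], []
    if sample.arm == PHOSPHOLIPID_ARM:
        corrected_by_channel = {}
        for name, scan_def in HEAD_GROUP_SCANS.items():
            peaks = sample.peak_lists.get(name)
            if peaks is None:
                raise DataError(f"sample {sample.sample_id}: missing scan {name}")
            cand = head_group_candidates(scan_def.lipid_class, scan_def.label)
            corrected = correct_13C(
                assign_peaks(peaks, cand, config.tolerance, config.mass_mode),
                config.noise.p_13c, mass_mode=config.mass_mode,
            )
            channel = ENDOGENOUS if scan_def.label is Label.NONE else NEWLY_SYNTHESISED
            corrected_by_channel[(scan_def.lipid_class, channel)] = corrected
            table = composition(corrected, scan_def.lipid_class, channel)
            for row in table.table.itertuples():
                comp_rows.append({
                    **meta, "lipid_class": scan_def.lipid_class.value, "channel": channel,
                    "species": row.species, "mole_percent": row.mole_percent,
                    "quantifiable": row.quantifiable,
                })
        for cls in (LipidClass.PC, LipidClass.PS, LipidClass.PI):
            inc = fractional_incorporation(
                corrected_by_channel[(cls, ENDOGENOUS)],
                corrected_by_channel[(cls, NEWLY_SYNTHESISED)],
                cls,
            )
            inc_rows.append({
                **meta, "lipid_class": cls.value,
                "incorporation_percent": inc.percent, "undefined": inc.undefined,
            })
    elif sample.arm == SPHINGOLIPID_ARM:
        if sample.mrm is None:
            raise DataError(f"sample {sample.sample_id}: missing MRM table")
        measurements = mrm_measurements_from_table(sample.mrm)
        result = quantify_mrm(measurements, sample.protein_mg, config.mrm_is_pmol_per_mg)
        amounts = result.species_amounts.assign(**meta)
        totals = result.class_totals.rename(columns={"total": "amount"})
        totals["species"] = totals["lipid_class"]
        out.mrm_amounts = pd.concat([amounts, totals.assign(**meta)], ignore_index=True)
    elif sample.arm == SHOTGUN_ARM:
        class_peaks = {}
        for cls in SHOTGUN_CLASSES:
            pl = sample.peak_lists.get(shotgun_scan_type(cls))
            if pl is not None:
                class_peaks[cls] = pl
        result = quantify_shotgun(
            class_peaks, default_internal_standards(), sample.protein_mg,
            tolerance=config.tolerance, p=config.noise.p_13c, mass_mode=config.mass_mode,
        )
        out.warnings.extend(result.warnings)
        out.shotgun_totals = result.class_totals.assign(**meta)
        if result.pi_composition is not None:
            out.shotgun_pi = result.pi_composition.table.assign(
                **meta, lipid_class=LipidClass.PI.value
            )
    out.composition = pd.DataFrame(comp_rows)
    out.incorporation = pd.DataFrame(inc_rows)
    return out


def analyse_samples(samples: list[SimulatedSample], config: RunConfig) -> SampleAnalysis:
    """Concatenate per-sample analyses across a study."""
    parts = [analyse_sample(s, config) for s in samples]
    out = SampleAnalysis()
    for attr in ("composition", "incorporation", "mrm_amounts", "shotgun_totals", "shotgun_pi"):
        frames = [getattr(p, attr) for p in parts if not getattr(p, attr).empty]
        setattr(out, attr, pd.concat(frames, ignore_index=True) if frames else pd.DataFrame())
    for p in parts:
        out.warnings.extend(p.warnings)
    return out


def endpoint_table(analysis: SampleAnalysis) -> pd.DataFrame:
    """Tidy endpoint rows: one value per sample per endpoint."""
    frames = []
    if not analysis.composition.empty:
        df = analysis.composition.copy()
        df["endpoint_type"] = "mole_percent"
        df["endpoint"] = df["lipid_class"] + "|" + df["channel"] + "|" + df["species"]
        df["value"] = df["mole_percent"]
        frames.append(df[["sample_id", "arm", "group", "condition", "subject_id",
                          "endpoint_type", "endpoint", "value"]])
    if not analysis.incorporation.empty:
        df = analysis.incorporation.copy()
        df["endpoint_type"] = "incorporation"
        df["endpoint"] = "incorporation|" + df["lipid_class"]
        df["value"] = df["incorporation_percent"]
        frames.append(df[["sample_id", "arm", "group", "condition", "subject_id",
                          "endpoint_type", "endpoint", "value"]])
    if not analysis.mrm_amounts.empty:
        df = analysis.mrm_amounts.copy()
        df["endpoint_type"] = "amount"
        df["endpoint"] = "amount|" + df["species"]
        df["value"] = df["amount"]
        frames.append(df[["sample_id", "arm", "group", "condition", "subject_id",
                          "endpoint_type", "endpoint", "value"]])
    if not analysis.shotgun_totals.empty:
        df = analysis.shotgun_totals.copy()
        df["endpoint_type"] = "class_total"
        df["endpoint"] = "total|" + df["lipid_class"]
        df["value"] = df["total"]
        frames.append(df[["sample_id", "arm", "group", "condition", "subject_id",
                          "endpoint_type", "endpoint", "value"]])
    if not analysis.shotgun_pi.empty:
        df = analysis.shotgun_pi.copy()
        df["endpoint_type"] = "shotgun_pi_mole_percent"
        df["endpoint"] = "shotgun_pi|" + df["species"]
        df["value"] = df["mole_percent"]
        frames.append(df[["sample_id", "arm", "group", "condition", "subject_id",
                          "endpoint_type", "endpoint", "value"]])
    if not frames:
        return pd.DataFrame(columns=["sample_id", "arm", "group", "condition",
                                     "subject_id", "endpoint_type", "endpoint", "value"])
    return pd.concat(frames, ignore_index=True)


def filter_quantifiable(endpoints: pd.DataFrame, min_percent: float = 2.0) -> pd.DataFrame:
    """Drop mole-% endpoints below the quantifiability threshold.

    Species under 2 % of their class total are detected but not
    considered quantifiable, so they are excluded from hypothesis
    testing; the rule is applied on the study-wide mean of each
    endpoint.  Non-percentage endpoints pass through untouched.
    """
    percent_types = {"mole_percent", "shotgun_pi_mole_percent"}
    is_pct = endpoints["endpoint_type"].isin(percent_types)
    means = endpoints[is_pct].groupby(["arm", "endpoint"])["value"].transform("mean")
    keep = (~is_pct) | (means.reindex(endpoints.index) > min_percent)
    return endpoints[keep]


def default_comparison_specs(
    endpoints: pd.DataFrame,
    alpha_macrophage: float = 0.05,
    alpha_shotgun: float = 0.01,
    paired_stimulation: bool = False,
) -> list[ComparisonSpec]:
    """The study's planned comparisons, derived from the data present.

    Per arm: HC vs CD within each condition (unpaired), and stimulated
    vs unstimulated within each group (paired only when the design
    recorded subject pairing).  The shotgun arm uses the stricter
    threshold.
    """
    specs = []
    for arm in sorted(endpoints["arm"].unique()):
        alpha = alpha_shotgun if arm == SHOTGUN_ARM else alpha_macrophage
        sub = endpoints[endpoints["arm"] == arm]
        for condition in sorted(sub["condition"].unique()):
            specs.append(ComparisonSpec(
                name=f"{arm}:{condition}:HC_vs_CD", group_col="group",
                group_a="HC", group_b="CD", alpha=alpha,
                filters={"arm": arm, "condition": condition},
            ))
        conditions = sorted(sub["condition"].unique())
        if len(conditions) == 2:
            for group in sorted(sub["group"].unique()):
                specs.append(ComparisonSpec(
                    name=f"{arm}:{group}:unstim_vs_HkEc", group_col="condition",
                    group_a="unstim", group_b="HkEc", alpha=alpha,
                    paired=paired_stimulation,
                    filters={"arm": arm, "group": group},
                ))
    return specs


def analyse_study(
    samples: list[SimulatedSample], config: RunConfig, paired_stimulation: bool = False
) -> dict[str, pd.DataFrame]:
    """Full study analysis: per-sample tables, group aggregates, statistics."""
    analysis = analyse_samples(samples, config)
    endpoints = endpoint_table(analysis)
    if endpoints.empty:
        return {
            "composition": analysis.composition, "incorporation": analysis.incorporation,
            "mrm_amounts": analysis.mrm_amounts, "shotgun_totals": analysis.shotgun_totals,
            "shotgun_pi": analysis.shotgun_pi, "endpoints": endpoints,
            "aggregates": pd.DataFrame(), "stats": pd.DataFrame(),
            "rejected_specs": pd.DataFrame({"message": []}),
            "warnings": pd.DataFrame({"message": analysis.warnings}),
        }
    testable = filter_quantifiable(endpoints) if config.quantifiable_only else endpoints
    specs = default_comparison_specs(
        testable, config.alpha_macrophage, config.alpha_shotgun, paired_stimulation
    )
    results, rejected = compare_study(testable, specs)
    endpoints_g = endpoints.copy()
    endpoints_g["cell"] = endpoints_g["group"] + "/" + endpoints_g["condition"]
    aggregates = aggregate_group(
        endpoints_g, value_col="value", group_col="cell", key_cols=("arm", "endpoint")
    )
    return {
        "composition": analysis.composition,
        "incorporation": analysis.incorporation,
        "mrm_amounts": analysis.mrm_amounts,
        "shotgun_totals": analysis.shotgun_totals,
        "shotgun_pi": analysis.shotgun_pi,
        "endpoints": endpoints,
        "aggregates": aggregates,
        "stats": results,
        "rejected_specs": pd.DataFrame({"message": rejected}),
        "warnings": pd.DataFrame({"message": analysis.warnings}),
    }
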