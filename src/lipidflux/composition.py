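"""Mole-percent composition tables and fractional label incorporation.

Composition assumes equal ESI response within a class (head-group scans
detect every species of the class through the same diagnostic
fragment); optional per-species response factors can be supplied.  A
species is flagged quantifiable when it exceeds 2 % of the class total;
the flag affects reporting only - totals, denominators and
incorporation always use all species, and filtered tables are not
renormalized.

Fractional incorporation of a deuterated head-group substrate,

    phi = 100 * sum(L) / (sum(L) + sum(E)),

with L and E the corrected labelled- and endogenous-channel
intensities, is the class's synthesis-rate readout over the labelling
window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .processing import CorrectedIntensities
from .registry import LipidClass, LipidSpecies, format_species

QUANTIFIABLE_PERCENT = 2.0  # strict: exactly 2 % is not quantifiable


@dataclass
class CompositionTable:
    """Per-species mole-% of one class channel in one sample."""

    lipid_class: LipidClass
    channel: str
    table: pd.DataFrame  # columns: species, mole_percent, quantifiable
    empty_channel: bool = False

    def mole_percent(self, species_text: str) -> float:
        rows = self.table.loc[self.table["species"] == species_text, "mole_percent"]
        if rows.empty:
            raise KeyError(species_text)
        return float(rows.iloc[0])


@dataclass
class IncorporationResult:
    """Fractional incorporation (%) of a label into one class."""

    lipid_class: LipidClass
    percent: float
    undefined: bool = False


def composition(
    corrected: CorrectedIntensities,
    lipid_class: LipidClass,
    channel: str,
    response_factors: dict[LipidSpecies, float] | None = None,
    min_percent: float = QUANTIFIABLE_PERCENT,
) -> CompositionTable:
    """Mole-% of each species within its class channel.

    Per-species response factors (if given) multiply intensities before
    normalization.  All-zero channels yield a flagged empty result, not
    an exception.
    """
    items = sorted(corrected.intensities.items(), key=lambda kv: format_species(kv[0]))
    values = []
    names = []
    for sp, inten in items:
        factor = response_factors.get(sp, 1.0) if response_factors else 1.0
        names.append(format_species(sp))
        values.append(inten * factor)
    values = np.asarray(values, dtype=float)
    total = values.sum()
    if total <= 0:
        table = pd.DataFrame({"species": names, "mole_percent": 0.0, "quantifiable": False})
        return CompositionTable(lipid_class, channel, table, empty_channel=True)
    percent = 100.0 * values / total
    table = pd.DataFrame({
        "species": names,
        "mole_percent": percent,
        "quantifiable": percent > min_percent,
    })
    return CompositionTable(lipid_class, channel, table)


def fractional_incorporation(
    endogenous: CorrectedIntensities,
    labelled: CorrectedIntensities,
    lipid_class: LipidClass,
) -> IncorporationResult:
    """100 * sum(labelled) / (sum(labelled) + sum(endogenous))."""
    total_l = labelled.total()
    total_e = endogenous.total()
    if total_l + total_e <= 0:
        return IncorporationResult(lipid_class, float("nan"), undefined=True)
    if total_l == 0:
        return IncorporationResult(lipid_class, 0.0)
    return IncorporationResult(lipid_class, 100.0 * total_l / (total_l + total_e))


def aggregate_group(
    tidy: pd.DataFrame,
    value_col: str = "value",
    group_col: str = "group",
    key_cols: tuple[str, ...] = ("species",),
    sample_col: str = "sample_id",
) -> pd.DataFrame:
    """Per-key mean and SEM (sd/sqrt(n)) per group.

    The key union is taken across samples; a sample missing a key is
    zero-filled before aggregation, so every group statistic is over the
    same n.  Groups with n < 2 are flagged with an undefined SEM.
    """
    if tidy.empty:
        return pd.DataFrame(columns=[group_col, *key_cols, "mean", "sem", "n", "sem_defined"])
    key_cols = list(key_cols)
    wide = tidy.pivot_table(
        index=[group_col, sample_col], columns=key_cols, values=value_col,
        aggfunc="sum", fill_value=0.0,
    )
    out = []
    for group, block in wide.groupby(level=group_col):
        n = len(block)
        means = block.mean(axis=0)
        sems = block.sem(axis=0, ddof=1) if n >= 2 else means * np.nan
        for key in wide.columns:
            key_tuple = key if isinstance(key, tuple) else (key,)
            out.append({
                group_col: group,
                **dict(zip(key_cols, key_tuple)),
                "mean": float(means[key]),
                "sem": float(sems[key]) if n >= 2 else float("nan"),
                "n": n,
                "sem_defined": n >= 2,
            })
    return pd.DataFrame(out)
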