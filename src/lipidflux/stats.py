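"""Two-group comparisons with paired or unpaired Student t-tests.

The study's statistical layer is deliberately simple: per-endpoint
(species mole-%, incorporation %, or absolute amount) two-tailed
Student t-tests with pooled variance, paired where the design provides
subject pairing, at a significance threshold of 0.05 for the macrophage
arms and 0.01 for the shotgun arm, with no multiplicity correction.  A
clearly-labelled Benjamini-Hochberg adjusted column is appended for
modern use but plays no part in the significance flags.  Welch's
unequal-variance variant is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError

__all__ = ["TTestResult", "ComparisonSpec", "student_t", "pooled_t_arrays", "compare_groups"]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False  # zero variance with unequal means


def pooled_t_arrays(
    a: np.ndarray, b: np.ndarray, welch: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised two-sample t over the last axis of ``a`` and ``b``.

    Returns (t, df, two-tailed p).  Zero pooled variance gives t = 0 /
    p = 1 at equal means and p -> 0 at unequal means (handled by the
    scalar wrapper; here the division produces inf and p = 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.shape[-1], b.shape[-1]
    ma, mb = a.mean(axis=-1), b.mean(axis=-1)
    va, vb = a.var(axis=-1, ddof=1), b.var(axis=-1, ddof=1)
    if welch:
        se2 = va / na + vb / nb
        df = se2**2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se2 = sp2 * (1.0 / na + 1.0 / nb)
        df = np.full_like(ma, float(na + nb - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
    diff_zero = np.isclose(ma, mb)
    t = np.where(np.isnan(t) & diff_zero, 0.0, t)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where((t == 0.0) & (se2 == 0.0), 1.0, p)
    return t, df, p


def student_t(a, b, paired: bool = False, welch: bool = False) -> TTestResult:
    """Two-tailed Student t-test.

    Unpaired: two-sample pooled-variance t with df = n_a + n_b - 2
    (Welch's df behind the flag).  Paired: one-sample t on the
    differences with df = n - 1.  Degenerate zero-variance cases are
    flagged rather than raising.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigurationError("t-test requires n >= 2 per group")
    if paired:
        if a.size != b.size:
            raise ConfigurationError("paired test requires equal n")
        d = a - b
        n = d.size
        sd = d.std(ddof=1)
        df = n - 1
        if sd == 0:
            if np.isclose(d.mean(), 0.0):
                return TTestResult(0.0, df, 1.0)
            return TTestResult(float(np.sign(d.mean()) * np.inf), df, 0.0, degenerate=True)
        t = d.mean() / (sd / np.sqrt(n))
        return TTestResult(float(t), df, float(2.0 * sps.t.sf(abs(t), df)))
    t, df, p = pooled_t_arrays(a, b, welch=welch)
    t, df, p = float(t), float(df), float(p)
    degenerate = np.isinf(t)
    return TTestResult(t, int(round(df)) if not welch else df, p, bool(degenerate))


@dataclass(frozen=True)
class ComparisonSpec:
    """One planned comparison over a tidy endpoint table.

    ``filters`` restricts the endpoint rows (column -> required value);
    remaining rows are split by ``group_col`` into ``group_a`` vs
    ``group_b`` and tested per endpoint key.
    """

    name: str
    group_col: str
    group_a: str
    group_b: str
    alpha: float = 0.05
    paired: bool = False
    filters: dict[str, object] = field(default_factory=dict)
    welch: bool = False


def compare_groups(
    tidy: pd.DataFrame,
    spec: ComparisonSpec,
    value_col: str = "value",
    key_cols: tuple[str, ...] = ("endpoint",),
    sample_col: str = "sample_id",
    subject_col: str = "subject_id",
    bh_column: bool = True,
) -> pd.DataFrame:
    """Run one ComparisonSpec; one result row per endpoint key.

    The significance flag is ``p < alpha`` (strict).  A paired spec
    requires matching subject keys across the two groups; mismatched
    keys fall back to the unpaired test, recorded in the ``paired``
    column of the result.
    """
    df = tidy
    for col, val in spec.filters.items():
        df = df[df[col] == val]
    df = df[df[spec.group_col].isin([spec.group_a, spec.group_b])]
    rows = []
    key_cols = list(key_cols)
    for key, block in df.groupby(key_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        a = block[block[spec.group_col] == spec.group_a]
        b = block[block[spec.group_col] == spec.group_b]
        if len(a) < 2 or len(b) < 2:
            continue
        paired = spec.paired
        av, bv = a[value_col].to_numpy(), b[value_col].to_numpy()
        if paired:
            merged = a.merge(b, on=subject_col, suffixes=("_a", "_b"))
            if len(merged) == len(a) == len(b) and len(merged) >= 2:
                av = merged[f"{value_col}_a"].to_numpy()
                bv = merged[f"{value_col}_b"].to_numpy()
            else:
                paired = False  # pairing keys absent: unpaired fallback
        res = student_t(av, bv, paired=paired, welch=spec.welch)
        rows.append({
            "comparison": spec.name,
            **dict(zip(key_cols, key)),
            "group_a": spec.group_a, "group_b": spec.group_b,
            "n_a": len(av), "n_b": len(bv),
            "mean_a": float(np.mean(av)), "sem_a": float(sps.sem(av)),
            "mean_b": float(np.mean(bv)), "sem_b": float(sps.sem(bv)),
            "t": res.t, "df": res.df, "p": res.p,
            "alpha": spec.alpha,
            "significant": bool(res.p < spec.alpha),
            "paired": paired,
            "degenerate": res.degenerate,
        })
    out = pd.DataFrame(rows)
    if bh_column and not out.empty:
        out["p_bh"] = sps.false_discovery_control(out["p"].clip(0, 1), method="bh")
    return out


def compare_study(
    tidy: pd.DataFrame,
    specs: list[ComparisonSpec],
    **kwargs,
) -> tuple[pd.DataFrame, list[str]]:
    """Run every spec; returns (results table, rejected-spec messages).

    A paired spec whose pairing keys are entirely absent from the table
    is rejected with a message rather than silently skipped.
    """
    frames = []
    rejected = []
    subject_col = kwargs.get("subject_col", "subject_id")
    for spec in specs:
        if spec.paired and subject_col not in tidy.columns:
            rejected.append(f"spec {spec.name!r} rejected: no pairing column {subject_col!r}")
            continue
        res = compare_groups(tidy, spec, **kwargs)
        if not res.empty:
            frames.append(res)
    results = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return results, rejected
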