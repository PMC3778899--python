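"""Operating characteristics of the pipeline under replicated simulation.

Because the study's subject-level data are synthetic by construction,
the pipeline's statistical behaviour is validated by its operating
characteristics: incorporation-recovery error at realistic noise,
empirical type-I error of the species-level tests under a null design,
and the detection rate and direction of the encoded group and
stimulation effects at the study's sample sizes.  These routines run
the full simulate -> assign -> correct -> compose -> test chain per
replicate, with light-weight bookkeeping so thousands of species-level
tests stay cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .composition import fractional_incorporation
from .pipeline import head_group_candidates
from .processing import assign_peaks, correct_13C
from .quantify import mrm_measurements_from_table, quantify_mrm
from .registry import HEAD_GROUP_SCANS, Label, LipidClass
from .simulate import (
    ENDOGENOUS,
    NEWLY_SYNTHESISED,
    NoiseModel,
    PHOSPHOLIPID_ARM,
    SPHINGOLIPID_ARM,
    StudyDesign,
    default_design,
    default_effects,
    simulate_study,
)
from .stats import pooled_t_arrays

QUANTIFIABLE_PERCENT = 2.0


def _phospholipid_endpoints(sample, tolerance=0.5, p=0.0107) -> dict[str, float]:
    """Species mole-% and incorporation endpoints of one macrophage sample."""
    out: dict[str, float] = {}
    totals: dict[tuple[LipidClass, str], float] = {}
    for name, scan_def in HEAD_GROUP_SCANS.items():
        cand = head_group_candidates(scan_def.lipid_class, scan_def.label)
        corrected = correct_13C(
            assign_peaks(sample.peak_lists[name], cand, tolerance), p
        )
        channel = ENDOGENOUS if scan_def.label is Label.NONE else NEWLY_SYNTHESISED
        total = corrected.total()
        totals[(scan_def.lipid_class, channel)] = total
        if total > 0:
            for sp, value in corrected.intensities.items():
                key = f"{scan_def.lipid_class.value}|{channel}|{sp.carbons}:{sp.double_bonds}"
                out[key] = 100.0 * value / total
    for cls in (LipidClass.PC, LipidClass.PS, LipidClass.PI):
        e = totals.get((cls, ENDOGENOUS), 0.0)
        l = totals.get((cls, NEWLY_SYNTHESISED), 0.0)
        if e + l > 0:
            out[f"incorporation|{cls.value}"] = 100.0 * l / (e + l)
    return out


def _endpoint_matrix(samples, endpoints_fn):
    """(endpoint names, value matrix [n_samples, n_endpoints]) with zero fill."""
    dicts = [endpoints_fn(s) for s in samples]
    names = sorted(set().union(*dicts))
    mat = np.zeros((len(dicts), len(names)))
    for i, d in enumerate(dicts):
        for j, name in enumerate(names):
            mat[i, j] = d.get(name, 0.0)
    return names, mat


def _quantifiable_mask(names, mat, min_percent=QUANTIFIABLE_PERCENT):
    """Keep incorporation endpoints plus species above the 2 % rule."""
    means = mat.mean(axis=0)
    return np.array([
        name.startswith("incorporation|") or means[j] > min_percent
        for j, name in enumerate(names)
    ])


def phi_recovery_errors(
    n_samples: int = 200,
    seed: int = 0,
    lipid_class: LipidClass = LipidClass.PI,
    noise: NoiseModel | None = None,
) -> np.ndarray:
    """Absolute error of per-sample recovered incorporation (fraction scale).

    Simulates macrophage samples at the default noise level and compares
    each sample's measured fractional incorporation with that sample's
    own ground truth.
    """
    design = StudyDesign(
        arms={PHOSPHOLIPID_ARM: {("HC", "unstim"): n_samples}},
        effects=[], seed=seed,
    )
    sim = simulate_study(design, noise=noise if noise is not None else NoiseModel())
    scans = {LipidClass.PC: ("P184+", "P193+"), LipidClass.PI: ("P241-", "P247-"),
             LipidClass.PS: ("NL87-", "NL90-")}[lipid_class]
    label = {LipidClass.PC: Label.D9_CHOLINE, LipidClass.PI: Label.D6_INOSITOL,
             LipidClass.PS: Label.D3_SERINE}[lipid_class]
    errors = []
    cand_e = head_group_candidates(lipid_class, Label.NONE)
    cand_l = head_group_candidates(lipid_class, label)
    for sample in sim.samples:
        endo = correct_13C(assign_peaks(sample.peak_lists[scans[0]], cand_e), 0.0107)
        lab = correct_13C(assign_peaks(sample.peak_lists[scans[1]], cand_l), 0.0107)
        res = fractional_incorporation(endo, lab, lipid_class)
        truth = sample.truth.profiles[lipid_class].incorporation
        errors.append(abs(res.percent / 100.0 - truth))
    return np.asarray(errors)


def null_type_i_error(
    n_tests: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    n_hc: int = 7,
    n_cd: int = 9,
    noise: NoiseModel | None = None,
) -> tuple[int, int]:
    """(rejections, tests run) for HC-vs-CD species tests under the null.

    Replicates the unstimulated macrophage comparison with every effect
    removed until at least ``n_tests`` quantifiable species-level
    endpoints have been tested.
    """
    noise = noise if noise is not None else NoiseModel()
    rejections = 0
    total = 0
    rep = 0
    root = np.random.SeedSequence(seed)
    while total < n_tests:
        rep_seed = int(root.spawn(1)[0].generate_state(1)[0] % (2**31))
        design = StudyDesign(
            arms={PHOSPHOLIPID_ARM: {("HC", "unstim"): n_hc, ("CD", "unstim"): n_cd}},
            effects=[], seed=rep_seed,
        )
        sim = simulate_study(design, noise=noise)
        hc = [s for s in sim.samples if s.group == "HC"]
        cd = [s for s in sim.samples if s.group == "CD"]
        names, mat = _endpoint_matrix(hc + cd, _phospholipid_endpoints)
        keep = _quantifiable_mask(names, mat)
        species_only = np.array([not n.startswith("incorporation|") for n in names])
        keep &= species_only
        a = mat[: len(hc)][:, keep].T
        b = mat[len(hc):][:, keep].T
        _, _, p = pooled_t_arrays(a, b)
        rejections += int((p < alpha).sum())
        total += int(p.size)
        rep += 1
    return rejections, total


@dataclass
class DetectionRates:
    """Per-endpoint fraction of replicates flagged in the stated direction."""

    n_replicates: int
    rates: dict[str, float]


def effect_detection_rates(
    n_replicates: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    noise: NoiseModel | None = None,
) -> DetectionRates:
    """Replicate the full study and score the encoded findings.

    Endpoints scored (all at the study's own sample sizes):

    * newly-synthesised PI 16:0/18:1 mole-% lower in CD than HC
      (unstimulated macrophages);
    * C16:0, C24:0 and C24:1 ceramide amounts lower after bacterial
      stimulation (healthy-control macrophages);
    * D9-choline incorporation into PC higher after stimulation
      (healthy-control macrophages).

    A replicate counts as a detection when the two-tailed pooled t-test
    is significant at ``alpha`` and the group means order matches.
    """
    noise = noise if noise is not None else NoiseModel()
    keys = ["new_PI_16:0/18:1_CD_down", "Cer 16:0_HkEc_down", "Cer 24:0_HkEc_down",
            "Cer 24:1_HkEc_down", "PC_incorporation_HkEc_up"]
    hits = {k: 0 for k in keys}
    root = np.random.SeedSequence(seed)
    for _ in range(n_replicates):
        rep_seed = int(root.spawn(1)[0].generate_state(1)[0] % (2**31))
        design = default_design(seed=rep_seed)
        design.arms = {
            PHOSPHOLIPID_ARM: design.arms[PHOSPHOLIPID_ARM],
            SPHINGOLIPID_ARM: {("HC", "unstim"): 7, ("HC", "HkEc"): 7},
        }
        sim = simulate_study(design, noise=noise)

        phospho = sim.by_arm(PHOSPHOLIPID_ARM)
        cells = {}
        for s in phospho:
            cells.setdefault((s.group, s.condition), []).append(s)
        hc_u = [_phospholipid_endpoints(s) for s in cells[("HC", "unstim")]]
        cd_u = [_phospholipid_endpoints(s) for s in cells[("CD", "unstim")]]
        hc_s = [_phospholipid_endpoints(s) for s in cells[("HC", "HkEc")]]

        pi_key = "PI|newly_synthesised|34:1"
        a = np.array([d[pi_key] for d in hc_u])
        b = np.array([d[pi_key] for d in cd_u])
        t, _, p = pooled_t_arrays(a, b)
        if p < alpha and b.mean() < a.mean():
            hits[keys[0]] += 1

        inc_key = "incorporation|PC"
        a = np.array([d[inc_key] for d in hc_u])
        b = np.array([d[inc_key] for d in hc_s])
        t, _, p = pooled_t_arrays(a, b)
        if p < alpha and b.mean() > a.mean():
            hits[keys[4]] += 1

        sphingo = sim.by_arm(SPHINGOLIPID_ARM)
        amounts = {}
        for s in sphingo:
            res = quantify_mrm(mrm_measurements_from_table(s.mrm), s.protein_mg, 40.0)
            amounts.setdefault(s.condition, []).append(
                res.species_amounts.set_index("species")["amount"]
            )
        for species in ("Cer 16:0", "Cer 24:0", "Cer 24:1"):
            a = np.array([v[species] for v in amounts["unstim"]])
            b = np.array([v[species] for v in amounts["HkEc"]])
            t, _, p = pooled_t_arrays(a, b)
            if p < alpha and b.mean() < a.mean():
                hits[f"{species}_HkEc_down"] += 1
    return DetectionRates(n_replicates, {k: hits[k] / n_replicates for k in keys})
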