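"""Isotope envelopes, scan simulation and whole-study generation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from lipidflux.errors import ConfigurationError
from lipidflux.registry import HEAD_GROUP_SCANS, Label, LipidClass, parse_species
from lipidflux.simulate import (
    Effect,
    NoiseModel,
    PHOSPHOLIPID_ARM,
    SPHINGOLIPID_ARM,
    apply_effects,
    default_design,
    default_lipidome,
    isotope_envelope,
    null_design,
    simulate_mrm,
    simulate_scan,
    simulate_study,
)


def binomial_envelope_oracle(n, p):
    """Explicit binomial-pmf envelope, truncated at M+2, relative to M0."""
    pmf = sps.binom.pmf([0, 1, 2], n, p)
    return pmf / pmf[0]


class TestIsotopeEnvelope:
    def test_m1_ratio_example(self):
        env = isotope_envelope(42, 0.0107)
        assert env[1] == pytest.approx(0.454, abs=5e-4)
        assert env[1] == pytest.approx(binomial_envelope_oracle(42, 0.0107)[1], rel=1e-12)

    def test_m2_ratio_example(self):
        env = isotope_envelope(44, 0.0107)
        assert env[2] == pytest.approx(0.1107, abs=5e-5)
        assert env[2] == pytest.approx(binomial_envelope_oracle(44, 0.0107)[2], rel=1e-12)

    @given(st.integers(1, 60))
    def test_p_zero_is_pure_m0(self, n):
        assert np.allclose(isotope_envelope(n, 0.0), [1.0, 0.0, 0.0])

    @given(st.integers(1, 120), st.floats(1e-4, 0.03))
    def test_matches_binomial_oracle(self, n, p):
        assert np.allclose(isotope_envelope(n, p), binomial_envelope_oracle(n, p), rtol=1e-9)

    @given(st.integers(2, 50), st.floats(1e-4, 0.019))
    def test_decreasing_at_natural_abundance_scale(self, n, p):
        # M0 > M+1 > M+2 wherever n*p/(1-p) < 1, which covers natural
        # 13C abundance for every lipid in range
        env = isotope_envelope(n, p)
        assert env[0] > env[1] > env[2]

    def test_nonpositive_carbons_rejected(self):
        with pytest.raises(ConfigurationError):
            isotope_envelope(0, 0.01)


class TestSimulateScan:
    def test_equal_fractions_equal_peaks(self, lipidome, noise_off_p0):
        lip = default_lipidome()
        lip.profiles[LipidClass.PC].endogenous = {
            parse_species("PC 32:0"): 0.5, parse_species("PC 36:2"): 0.5,
        }
        pl = simulate_scan(lip, HEAD_GROUP_SCANS["P184+"], noise_off_p0, seed=0)
        assert len(pl) == 2
        assert pl.intensity[0] == pytest.approx(pl.intensity[1])

    def test_zero_incorporation_gives_empty_labelled_scan(self, noise_off_p0):
        lip = default_lipidome()
        lip.profiles[LipidClass.PC].incorporation = 0.0
        pl = simulate_scan(lip, HEAD_GROUP_SCANS["P193+"], noise_off_p0, seed=0)
        assert len(pl) == 0

    def test_class_absent_gives_empty_list(self, noise_off_p0):
        lip = default_lipidome()
        del lip.profiles[LipidClass.PI]
        pl = simulate_scan(lip, HEAD_GROUP_SCANS["P241-"], noise_off_p0, seed=0)
        assert len(pl) == 0

    def test_deterministic_under_seed(self, lipidome):
        noise = NoiseModel()
        a = simulate_scan(lipidome, HEAD_GROUP_SCANS["P184+"], noise, seed=42)
        b = simulate_scan(lipidome, HEAD_GROUP_SCANS["P184+"], noise, seed=42)
        c = simulate_scan(lipidome, HEAD_GROUP_SCANS["P184+"], noise, seed=43)
        assert np.array_equal(a.mz, b.mz) and np.array_equal(a.intensity, b.intensity)
        assert not np.array_equal(a.intensity, c.intensity)

    def test_intensity_conservation_noise_off_p0(self, lipidome, noise_off_p0):
        phi = lipidome.profiles[LipidClass.PI].incorporation
        endo = simulate_scan(lipidome, HEAD_GROUP_SCANS["P241-"], noise_off_p0, 0, gain=1e6)
        lab = simulate_scan(lipidome, HEAD_GROUP_SCANS["P247-"], noise_off_p0, 0, gain=1e6)
        assert endo.intensity.sum() == pytest.approx((1 - phi) * 1e6, rel=1e-12)
        assert lab.intensity.sum() == pytest.approx(phi * 1e6, rel=1e-12)

    def test_coincident_isotopologues_merge(self, lipidome, noise_off):
        # with the 13C envelope on, M+2 of PI 38:5 lands on M0 of PI 38:4:
        # one centroid, summed intensity
        pl = simulate_scan(lipidome, HEAD_GROUP_SCANS["P241-"], noise_off, 0)
        assert len(np.unique(np.round(pl.mz, 3))) == len(pl)


class TestEffects:
    def test_unknown_species_named_in_error(self, lipidome):
        eff = Effect("fraction", 0.5, lipid_class=LipidClass.PI,
                     channel="newly_synthesised", species="PI 40:0")
        with pytest.raises(ConfigurationError, match="PI 40:0"):
            apply_effects(lipidome, [eff], "HC", "unstim")

    def test_unknown_parameter_rejected(self, lipidome):
        with pytest.raises(ConfigurationError, match="nonsense"):
            apply_effects(lipidome, [Effect("nonsense", 0.5)], "HC", "unstim")

    def test_fraction_effect_renormalizes(self, lipidome):
        eff = Effect("fraction", 0.65, group="CD", lipid_class=LipidClass.PI,
                     channel="newly_synthesised", species="PI 16:0/18:1")
        cd = apply_effects(lipidome, [eff], "CD", "unstim")
        hc = apply_effects(lipidome, [eff], "HC", "unstim")
        key = parse_species("PI 16:0/18:1", Label.D6_INOSITOL)
        assert cd.profiles[LipidClass.PI].newly_synthesised[key] < \
            hc.profiles[LipidClass.PI].newly_synthesised[key]
        assert sum(cd.profiles[LipidClass.PI].newly_synthesised.values()) == pytest.approx(1.0)

    def test_condition_effect_scopes_to_condition(self, lipidome):
        eff = Effect("phi", 1.6, condition="HkEc", lipid_class=LipidClass.PC)
        stim = apply_effects(lipidome, [eff], "HC", "HkEc")
        unstim = apply_effects(lipidome, [eff], "HC", "unstim")
        assert stim.profiles[LipidClass.PC].incorporation == pytest.approx(
            1.6 * unstim.profiles[LipidClass.PC].incorporation
        )


class TestSimulateStudy:
    def test_sample_counts_match_design(self):
        sim = simulate_study(default_design(seed=0), noise=NoiseModel())
        sphingo = sim.by_arm(SPHINGOLIPID_ARM)
        counts = {}
        for s in sphingo:
            counts[(s.group, s.condition)] = counts.get((s.group, s.condition), 0) + 1
        assert counts == {("HC", "unstim"): 7, ("CD", "unstim"): 8,
                          ("HC", "HkEc"): 7, ("CD", "HkEc"): 12}

    def test_equal_seeds_bit_identical(self):
        design = default_design(seed=7)
        a = simulate_study(design, noise=NoiseModel())
        b = simulate_study(design, noise=NoiseModel())
        sa = a.by_arm(PHOSPHOLIPID_ARM)[0]
        sb = b.by_arm(PHOSPHOLIPID_ARM)[0]
        for name in sa.peak_lists:
            assert np.array_equal(sa.peak_lists[name].mz, sb.peak_lists[name].mz)
            assert np.array_equal(sa.peak_lists[name].intensity, sb.peak_lists[name].intensity)

    def test_different_seeds_differ(self):
        a = simulate_study(default_design(seed=1), noise=NoiseModel())
        b = simulate_study(default_design(seed=2), noise=NoiseModel())
        sa = a.by_arm(PHOSPHOLIPID_ARM)[0].peak_lists["P184+"]
        sb = b.by_arm(PHOSPHOLIPID_ARM)[0].peak_lists["P184+"]
        assert not np.array_equal(sa.intensity, sb.intensity)

    def test_small_cells_rejected(self):
        design = default_design(seed=0)
        design.arms[PHOSPHOLIPID_ARM][("HC", "unstim")] = 1
        with pytest.raises(ConfigurationError):
            simulate_study(design, noise=NoiseModel())

    def test_doubled_phi_raises_recovered_incorporation(self):
        """Round-trip sign check: a higher true phi under stimulation
        shows up as higher measured incorporation."""
        from lipidflux.io import RunConfig
        from lipidflux.pipeline import analyse_samples

        effects = [Effect("phi", 2.0, condition="HkEc", lipid_class=LipidClass.PC)]
        design = null_design(seed=3)
        design.effects = effects
        design.arms = {PHOSPHOLIPID_ARM: {("HC", "unstim"): 4, ("HC", "HkEc"): 4}}
        sim = simulate_study(design, noise=NoiseModel())
        analysis = analyse_samples(sim.samples, RunConfig())
        inc = analysis.incorporation
        pc = inc[inc["lipid_class"] == "PC"]
        mean_by_cond = pc.groupby("condition")["incorporation_percent"].mean()
        assert mean_by_cond["HkEc"] > mean_by_cond["unstim"]

    def test_paired_design_shares_subjects_across_conditions(self):
        design = default_design(seed=5, paired=True)
        design.arms = {PHOSPHOLIPID_ARM: {("HC", "unstim"): 3, ("HC", "HkEc"): 3}}
        sim = simulate_study(design, noise=NoiseModel())
        subjects = {}
        for s in sim.samples:
            subjects.setdefault(s.subject_id, set()).add(s.condition)
        assert all(conds == {"unstim", "HkEc"} for conds in subjects.values())


class TestSimulateMrm:
    def test_areas_scale_with_truth(self, lipidome, noise_off):
        table = simulate_mrm(lipidome, noise_off, seed=0)
        assert table["is_flag"].sum() == 1
        c16 = table.loc[table["analyte"] == "Cer 16:0", "area"].iloc[0]
        c18 = table.loc[table["analyte"] == "Cer 18:0", "area"].iloc[0]
        assert c16 / c18 == pytest.approx(220.0 / 40.0, rel=1e-12)
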