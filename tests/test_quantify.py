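"""Internal-standard quantification: MRM panel and shotgun scans."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lipidflux.errors import ConfigurationError, DataError
from lipidflux.io import shotgun_scan_type
from lipidflux.quantify import (
    MrmMeasurement,
    default_internal_standards,
    mrm_measurements_from_table,
    quantify_mrm,
    quantify_shotgun,
)
from lipidflux.registry import LipidClass, parse_species
from lipidflux.simulate import (
    NoiseModel,
    default_lipidome,
    simulate_mrm,
    simulate_shotgun_scan,
)


def mrm(analyte, area, is_flag=False, rf=1.0):
    return MrmMeasurement(parse_species(analyte), 500.0, 264.3, area, is_flag, rf)


class TestQuantifyMrm:
    def test_unit_ratio_returns_spike_amount(self):
        res = quantify_mrm([mrm("Cer 17:0", 1000.0, is_flag=True),
                            mrm("Cer 16:0", 1000.0)], protein_mg=0.5,
                           is_amount_per_mg=40.0)
        row = res.species_amounts.iloc[0]
        assert row["amount"] == pytest.approx(40.0)
        assert row["units"] == "pmol/mg"

    def test_zero_area_zero_amount(self):
        res = quantify_mrm([mrm("Cer 17:0", 1000.0, is_flag=True),
                            mrm("Cer 16:0", 0.0)], 0.5, 40.0)
        assert res.species_amounts["amount"].iloc[0] == 0.0

    def test_missing_is_rejected(self):
        with pytest.raises(DataError, match="internal standard"):
            quantify_mrm([mrm("Cer 16:0", 10.0)], 0.5, 40.0)

    def test_zero_is_area_rejected(self):
        with pytest.raises(DataError):
            quantify_mrm([mrm("Cer 17:0", 0.0, is_flag=True),
                          mrm("Cer 16:0", 10.0)], 0.5, 40.0)

    def test_bad_protein_mass(self):
        with pytest.raises(ConfigurationError):
            quantify_mrm([mrm("Cer 17:0", 1.0, is_flag=True)], 0.0, 40.0)

    @given(st.floats(0.1, 10.0))
    def test_doubling_all_areas_invariant(self, c):
        base = [mrm("Cer 17:0", 1000.0, is_flag=True), mrm("Cer 16:0", 700.0),
                mrm("Cer 24:1", 300.0)]
        scaled = [mrm("Cer 17:0", 1000.0 * c, is_flag=True), mrm("Cer 16:0", 700.0 * c),
                  mrm("Cer 24:1", 300.0 * c)]
        a = quantify_mrm(base, 0.5, 40.0).species_amounts["amount"]
        b = quantify_mrm(scaled, 0.5, 40.0).species_amounts["amount"]
        assert np.allclose(a, b)

    def test_total_ceramide_excludes_dihydro_by_default(self):
        ms = [mrm("Cer 17:0", 100.0, is_flag=True), mrm("Cer 16:0", 100.0),
              mrm("DHCer 16:0", 100.0)]
        res = quantify_mrm(ms, 0.5, 40.0)
        totals = res.class_totals.set_index("lipid_class")["total"]
        assert totals["total_ceramide"] == pytest.approx(40.0)
        res2 = quantify_mrm(ms, 0.5, 40.0, include_dihydro_in_total=True)
        totals2 = res2.class_totals.set_index("lipid_class")["total"]
        assert totals2["total_ceramide"] == pytest.approx(80.0)

    def test_noise_free_round_trip(self, lipidome, noise_off):
        """Simulated panel areas quantify back to the generator truth."""
        table = simulate_mrm(lipidome, noise_off, seed=0)
        res = quantify_mrm(mrm_measurements_from_table(table),
                           lipidome.protein_mg, is_amount_per_mg=40.0)
        got = res.species_amounts.set_index("species")["amount"]
        for sp, truth in lipidome.sphingolipid_pmol.items():
            assert got[str(sp)] == pytest.approx(truth, rel=1e-9)


def shotgun_peaks(lipidome, noise, seed=0):
    is_table = default_internal_standards()
    out = {}
    for cls in lipidome.shotgun:
        entry = is_table.get(cls)
        out[cls] = simulate_shotgun_scan(
            lipidome, cls, noise, seed, is_species=entry.species if entry else None,
            is_amount_per_mg=entry.amount_per_mg if entry else 0.0,
        )
    return out


class TestQuantifyShotgun:
    def test_unit_ratio_returns_spike_amount(self, noise_off_p0):
        lip = default_lipidome()
        # a single PC species at exactly the standard's amount
        lip.shotgun = {LipidClass.PC: type(lip.shotgun[LipidClass.PC])(
            15.0, {parse_species("PC 34:1"): 1.0})}
        peaks = shotgun_peaks(lip, noise_off_p0)
        res = quantify_shotgun(peaks, protein_mg=lip.protein_mg)
        row = res.species_amounts.set_index("species")
        assert row.loc["PC 34:1", "amount"] == pytest.approx(15.0, rel=1e-9)

    def test_noise_free_recovery_all_is_classes(self, lipidome, noise_off):
        peaks = shotgun_peaks(lipidome, noise_off)
        res = quantify_shotgun(peaks, protein_mg=lipidome.protein_mg)
        got = res.species_amounts.set_index(["lipid_class", "species"])["amount"]
        for cls, entry in default_internal_standards().items():
            truth_cls = lipidome.shotgun[cls]
            for sp, frac in truth_cls.fractions.items():
                # assignment reports at total acyl composition, not sn alias
                key = f"{cls.value} {sp.carbons}:{sp.double_bonds}"
                assert got[(cls.value, key)] == pytest.approx(
                    truth_cls.total * frac, rel=1e-6)
        totals = res.class_totals.set_index("lipid_class")["total"]
        assert totals["PC"] == pytest.approx(60.0, rel=1e-6)
        assert totals["Cer"] == pytest.approx(500.0, rel=1e-6)

    def test_pi_mole_percent_matches_composition(self, lipidome, noise_off):
        """Cross-module consistency: the shotgun PI mole-% equals
        composition() of the same corrected intensities."""
        from lipidflux.composition import composition
        from lipidflux.processing import assign_peaks, correct_13C
        from lipidflux.quantify import _default_candidates

        peaks = shotgun_peaks(lipidome, noise_off)
        res = quantify_shotgun(peaks, protein_mg=lipidome.protein_mg)
        corrected = correct_13C(
            assign_peaks(peaks[LipidClass.PI], _default_candidates(LipidClass.PI)),
            p=0.0107)
        direct = composition(corrected, LipidClass.PI, "endogenous")
        merged = res.pi_composition.table.merge(direct.table, on="species")
        assert np.allclose(merged["mole_percent_x"], merged["mole_percent_y"])
        # and it recovers the generator's dominant species
        assert res.pi_composition.table.set_index("species").loc[
            "PI 38:4", "mole_percent"] == pytest.approx(42.9, rel=1e-6)

    def test_missing_class_scan_warns_and_omits(self, lipidome, noise_off):
        peaks = shotgun_peaks(lipidome, noise_off)
        del peaks[LipidClass.PE]
        res = quantify_shotgun(peaks, protein_mg=lipidome.protein_mg)
        assert any("PE" in w for w in res.warnings)
        assert "PE" not in set(res.class_totals["lipid_class"])

    def test_empty_scans_all_zero_flagged(self):
        from lipidflux.io import PeakList

        peaks = {cls: PeakList("s", shotgun_scan_type(cls), "+",
                               np.empty(0), np.empty(0))
                 for cls in default_internal_standards()}
        res = quantify_shotgun(peaks, protein_mg=0.5)
        assert res.all_zero
        assert (res.class_totals["total"] == 0).all()

    def test_cd_effect_reduces_pi_species(self, noise_off):
        from lipidflux.simulate import apply_effects, default_effects

        template = default_lipidome()
        cd = apply_effects(template, default_effects(), "CD", "unstim")
        hc = apply_effects(template, default_effects(), "HC", "unstim")
        res_cd = quantify_shotgun(shotgun_peaks(cd, noise_off), protein_mg=0.5)
        res_hc = quantify_shotgun(shotgun_peaks(hc, noise_off), protein_mg=0.5)
        pct_cd = res_cd.pi_composition.table.set_index("species").loc[
            "PI 34:1", "mole_percent"]
        pct_hc = res_hc.pi_composition.table.set_index("species").loc[
            "PI 34:1", "mole_percent"]
        assert pct_cd < pct_hc
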