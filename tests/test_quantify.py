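"""Peak matching, internal-standard quantification, mol% normalization,
calibration and the OD-vs-content outlier filter."""

import numpy as np
import pytest

from memphys.lipid_model import default_chemistry, parse_shorthand, species_mz
from memphys.quantify import (
    PeakList,
    QuantifiedLipidome,
    StandardMix,
    build_library,
    fit_calibration,
    match_peaks,
    mol_percent_polar,
    od_outlier_filter,
    quantify_calibrated,
    quantify_internal_standard,
)

CHEM = default_chemistry()


def _tiny_library():
    species = [parse_shorthand(s) for s in
               ("PC(34:1)", "PC(36:2)", "PE(34:1)")]
    return build_library(species)


class TestMatchPeaks:
    def test_within_tolerance_assigned(self):
        lib = _tiny_library()
        target = lib[0]
        pk = PeakList(target.adduct.polarity,
                      np.array([target.mz * (1 + 2e-6)]), np.array([100.0]))
        res = match_peaks(pk, lib)
        assert len(res.assignments) == 1
        assert res.assignments[0].entry.species == target.species
        assert res.assignments[0].ppm_error == pytest.approx(2.0, abs=0.01)

    def test_outside_tolerance_unassigned(self):
        lib = _tiny_library()
        pk = PeakList("positive", np.array([lib[0].mz * (1 + 5e-6)]),
                      np.array([100.0]))
        res = match_peaks(pk, lib)
        assert not res.assignments and res.unassigned == [0]

    def test_exact_match_zero_ppm(self):
        lib = _tiny_library()
        pk = PeakList("positive", np.array([lib[0].mz]), np.array([1.0]))
        res = match_peaks(pk, lib)
        assert res.assignments[0].ppm_error == 0.0

    def test_most_intense_peak_wins_entry(self):
        lib = _tiny_library()
        mz = lib[0].mz
        pk = PeakList("positive",
                      np.array([mz * (1 - 1e-6), mz * (1 + 1e-6)]),
                      np.array([10.0, 99.0]))
        res = match_peaks(pk, lib)
        assert len(res.assignments) == 1
        assert res.assignments[0].intensity == 99.0

    def test_ambiguous_library_flagged_not_assigned(self):
        from memphys.quantify import LibraryEntry
        lib = _tiny_library()
        twin = LibraryEntry(parse_shorthand("PG(33:2)"), lib[0].adduct,
                            lib[0].mz * (1 + 1e-7))
        pk = PeakList("positive", np.array([lib[0].mz]), np.array([5.0]))
        res = match_peaks(pk, lib + [twin])
        assert res.ambiguous and not res.assignments

    def test_empty_library_raises(self):
        pk = PeakList("positive", np.array([700.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            match_peaks(pk, [])

    def test_matching_scale_free_under_small_drift(self):
        lib = _tiny_library()
        rng = np.random.default_rng(0)
        jitter = rng.uniform(-2e-6, 2e-6, size=len(lib))
        mz = np.array([e.mz for e in lib]) * (1 + jitter)
        pk = PeakList("any", mz, np.ones(len(lib)))
        base = {a.peak_index: a.entry.species
                for a in match_peaks(pk, lib).assignments}
        drifted = PeakList("any", mz * (1 + 0.4e-6), pk.intensity)
        after = {a.peak_index: a.entry.species
                 for a in match_peaks(drifted, lib).assignments}
        assert base == after


class TestInternalStandard:
    def test_ratio_one_returns_standard_amount(self):
        table = {"PC(15:0/18:1-d7)": 1000.0, "PC(34:1)": 1000.0}
        lp = quantify_internal_standard(table)
        assert lp.amounts["PC(34:1)"] == pytest.approx(35.0)

    def test_linearity(self):
        table = {"PE(15:0/18:1-d7)": 500.0, "PE(34:1)": 1000.0}
        lp = quantify_internal_standard(table)
        assert lp.amounts["PE(34:1)"] == pytest.approx(48.0)

    def test_missing_standard_reports_class_and_continues(self):
        table = {"PC(15:0/18:1-d7)": 100.0, "PC(34:1)": 50.0,
                 "PI(34:1)": 50.0}  # no PI standard present
        lp = quantify_internal_standard(table)
        assert "PI" in lp.unquantified_classes
        assert "PC(34:1)" in lp.amounts

    def test_lyso_class_borrows_parent_standard(self):
        table = {"PC(15:0/18:1-d7)": 100.0, "LPC(18:1)": 50.0}
        lp = quantify_internal_standard(table)
        assert lp.amounts["LPC(18:1)"] == pytest.approx(17.5)

    def test_doubling_intensities_doubles_pmol_not_molpct(self):
        table = {"PC(15:0/18:1-d7)": 100.0, "PC(34:1)": 60.0,
                 "PE(15:0/18:1-d7)": 100.0, "PE(34:1)": 40.0}
        lp1 = mol_percent_polar(quantify_internal_standard(table))
        doubled = {k: (v * 2 if "-d7" not in k else v)
                   for k, v in table.items()}
        lp2 = mol_percent_polar(quantify_internal_standard(doubled))
        for lbl in lp1.amounts:
            assert lp2.amounts[lbl] == pytest.approx(2 * lp1.amounts[lbl])
            assert lp2.mol_percent[lbl] == pytest.approx(
                lp1.mol_percent[lbl], abs=1e-12)


class TestMolPercent:
    def test_storage_excluded_from_denominator(self):
        lp = QuantifiedLipidome("s", {"PC(34:1)": 10.0, "PE(34:1)": 10.0,
                                      "TG(50:1)": 123.0})
        mol_percent_polar(lp)
        assert lp.mol_percent["PC(34:1)"] == pytest.approx(50.0)
        assert lp.mol_percent["PE(34:1)"] == pytest.approx(50.0)
        assert lp.mol_percent["TG(50:1)"] == pytest.approx(615.0)

    def test_single_polar_species_is_100(self):
        lp = QuantifiedLipidome("s", {"PI(34:1)": 3.0})
        mol_percent_polar(lp)
        assert lp.mol_percent["PI(34:1)"] == 100.0

    def test_all_zero_polar_raises(self):
        lp = QuantifiedLipidome("s", {"PC(34:1)": 0.0, "TG(50:1)": 5.0})
        with pytest.raises(ValueError):
            mol_percent_polar(lp)

    def test_polar_sum_conserved(self, rng):
        labels = [f"PC({c}:0)" for c in range(24, 44, 2)]
        lp = QuantifiedLipidome(
            "s", dict(zip(labels, rng.uniform(0.1, 10, len(labels)))))
        mol_percent_polar(lp)
        assert sum(lp.mol_percent.values()) == pytest.approx(100.0,
                                                             abs=1e-9)


class TestCalibration:
    def test_collinear_points_exact(self):
        x = np.arange(1.0, 7.0)
        curve = fit_calibration(x, 2.0 * x + 0.5)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)
        conc, below = quantify_calibrated(curve, 2.0 * 3.3 + 0.5)
        assert conc == pytest.approx(3.3)
        assert not below

    def test_through_origin_inversion(self):
        curve = fit_calibration(np.array([0.0, 1.0]), np.array([0.0, 2.0]))
        conc, _ = quantify_calibrated(curve, 1.5)
        assert conc == pytest.approx(0.75)

    def test_below_range_flagged(self):
        curve = fit_calibration(np.arange(1.0, 7.0), np.arange(1.0, 7.0))
        conc, below = quantify_calibrated(curve, -0.5)
        assert below and conc < 0

    def test_slope_unbiased_under_noise(self, rng):
        x = np.arange(1.0, 7.0)
        slopes = []
        for _ in range(1000):
            y = 2.0 * x + rng.normal(0, 0.1, x.size)
            slopes.append(fit_calibration(x, y).slope)
        se = 0.1 / np.sqrt(np.sum((x - x.mean()) ** 2)) / np.sqrt(1000)
        assert np.mean(slopes) == pytest.approx(2.0, abs=4 * se)

    def test_per_od_and_zero_slope(self):
        curve = fit_calibration(np.arange(1.0, 7.0), np.arange(1.0, 7.0))
        conc, _ = quantify_calibrated(curve, 4.0, od=2.0)
        assert conc == pytest.approx(2.0)
        from memphys.quantify import CalibrationCurve
        flat = CalibrationCurve(np.arange(6.0), np.ones(6), 0.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            quantify_calibrated(flat, 1.0)


class TestOdOutlierFilter:
    def test_on_line_nothing_excluded(self):
        od = np.array([0.4, 0.5, 0.6, 0.7, 0.8])
        res = od_outlier_filter(od, 2 * od + 1)
        assert res.excluded.size == 0 and not res.skipped
        assert res.slope == pytest.approx(2.0)

    def test_gross_outlier_excluded(self):
        od = np.array([0.4, 0.5, 0.6, 0.7, 0.8, 0.6])
        content = 2 * od + 1
        content[-1] *= 10
        res = od_outlier_filter(od, content)
        assert list(res.excluded) == [5]
        assert res.slope == pytest.approx(2.0)

    def test_outlier_agrees_with_leave_one_out_oracle(self, rng):
        od = rng.uniform(0.3, 0.9, 8)
        content = 2 * od + 1 + rng.normal(0, 0.05, 8)
        content[3] += 2.0
        # brute-force externally studentized residuals
        import statsmodels.api as sm
        flagged = []
        for i in range(8):
            keep = np.delete(np.arange(8), i)
            fit = sm.OLS(content[keep], sm.add_constant(od[keep])).fit()
            pred = fit.params[0] + fit.params[1] * od[i]
            h = (1 / keep.size
                 + (od[i] - od[keep].mean()) ** 2
                 / np.sum((od[keep] - od[keep].mean()) ** 2))
            se = np.sqrt(fit.mse_resid * (1 + h))
            if abs(content[i] - pred) / se > 2.5:
                flagged.append(i)
        res = od_outlier_filter(od, content)
        assert sorted(res.excluded) == flagged == [3]

    def test_too_few_samples_skipped(self):
        with pytest.warns(UserWarning):
            res = od_outlier_filter(np.array([0.4, 0.5, 0.6]),
                                    np.array([1.0, 1.2, 1.4]))
        assert res.skipped and res.excluded.size == 0

    def test_degenerate_predictor_skipped(self):
        with pytest.warns(UserWarning):
            res = od_outlier_filter(np.full(5, 0.5),
                                    np.array([1.0, 2, 3, 4, 5]))
        assert res.skipped


def test_library_respects_acquisition_window():
    # LPE(6:0) ionizes below the 350 Th scan floor and must be dropped
    assert species_mz(parse_shorthand("LPE(6:0)"),
                      CHEM.adducts["[M-H]-"]) < 350
    species = [parse_shorthand("LPE(6:0)"), parse_shorthand("PE(34:1)")]
    lib = build_library(species)
    assert all(350 <= e.mz <= 1200 for e in lib)
    assert not any(e.species.lipid_class == "LPE" for e in lib)


def test_tidy_frame_round_trip():
    lp = QuantifiedLipidome("s1", {"PC(34:1)": 12.0, "TG(50:1)": 3.0})
    mol_percent_polar(lp)
    back = QuantifiedLipidome.from_frame(lp.to_frame())
    assert back.amounts == pytest.approx(lp.amounts)
    assert back.mol_percent == pytest.approx(lp.mol_percent)
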