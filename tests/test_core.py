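"""Deterministic exposure equations, descriptive statistics and screening."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vegrisk as vr
from vegrisk.core import InvalidInputError, ConfigurationError

from conftest import make_category_samples


finite_pos = st.floats(0.01, 1e6, allow_nan=False, allow_infinity=False)


class TestWaterContent:
    @pytest.mark.parametrize(
        "fresh,dry,expected",
        [(100.0, 10.0, 0.90), (50.0, 50.0, 0.0), (80.0, 6.4, 0.92)],
    )
    def test_examples(self, fresh, dry, expected):
        assert vr.water_content(fresh, dry) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("fresh,dry", [(0.0, 0.0), (-1.0, 0.0), (10.0, 11.0)])
    def test_invalid(self, fresh, dry):
        with pytest.raises(InvalidInputError):
            vr.water_content(fresh, dry, sample="X1")

    def test_error_names_sample(self):
        with pytest.raises(InvalidInputError, match="X1"):
            vr.water_content(-1.0, 0.0, sample="X1")


class TestFreshWeightConversion:
    @pytest.mark.parametrize(
        "c_dw,w,expected", [(1.0, 0.0, 1.0), (4.5, 0.9, 0.45), (0.0, 0.5, 0.0)]
    )
    def test_examples(self, c_dw, w, expected):
        assert vr.fw_from_dw(c_dw, w) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("c_dw,w", [(1.0, 1.0), (1.0, 1.2), (-0.1, 0.5), (1.0, -0.1)])
    def test_invalid(self, c_dw, w):
        with pytest.raises(InvalidInputError):
            vr.fw_from_dw(c_dw, w)

    @given(
        c_dw=finite_pos,
        fresh=st.floats(1.0, 1e4),
        frac=st.floats(0.01, 0.99),
    )
    @settings(derandomize=True, max_examples=100)
    def test_round_trip_through_water_content(self, c_dw, fresh, frac):
        """fw_from_dw composed with the measured water content recovers the
        dry-weight concentration: C_fw * fresh/dry == C_dw."""
        dry = fresh * frac
        w = vr.water_content(fresh, dry)
        c_fw = vr.fw_from_dw(c_dw, w)
        assert c_fw * fresh / dry == pytest.approx(c_dw, rel=1e-9)


class TestBcf:
    @pytest.mark.parametrize(
        "veg,soil,expected",
        [(2.0, 2.0, 1.0), (0.33, 3.59, 0.091922), (0.0, 100.0, 0.0)],
    )
    def test_examples(self, veg, soil, expected):
        assert vr.bcf(veg, soil) == pytest.approx(expected, rel=1e-4)

    def test_zero_soil_names_site(self):
        with pytest.raises(InvalidInputError, match="S9"):
            vr.bcf(1.0, 0.0, site="S9")


class TestEdi:
    @pytest.mark.parametrize(
        "c,ir,bw,ef,ed,expected",
        [
            (0.45, 200.0, 30.0, 365.0, 10.0, 3.0),
            (0.45, 0.0, 30.0, 365.0, 10.0, 0.0),
            (0.45, 200.0, 30.0, 182.5, 10.0, 1.5),
        ],
    )
    def test_examples(self, c, ir, bw, ef, ed, expected):
        assert vr.edi(c, ir, bw, ef, ed) == pytest.approx(expected, rel=1e-12)

    @given(ed1=st.floats(0.1, 70), ed2=st.floats(0.1, 70))
    @settings(derandomize=True, max_examples=50)
    def test_exposure_duration_cancels(self, ed1, ed2):
        """AT = ED*365 makes the intake invariant to exposure duration."""
        assert vr.edi(0.5, 150, 60, 350, ed1) == vr.edi(0.5, 150, 60, 350, ed2)

    @given(c=finite_pos, ir=finite_pos, k=st.floats(0.1, 10))
    @settings(derandomize=True, max_examples=50)
    def test_linear_in_concentration_and_intake(self, c, ir, k):
        base = vr.edi(c, ir, 60, 365, 1)
        assert vr.edi(k * c, ir, 60, 365, 1) == pytest.approx(k * base, rel=1e-9)
        assert vr.edi(c, k * ir, 60, 365, 1) == pytest.approx(k * base, rel=1e-9)

    @pytest.mark.parametrize("bw,ed", [(0.0, 1.0), (-5.0, 1.0), (60.0, 0.0)])
    def test_invalid(self, bw, ed):
        with pytest.raises(InvalidInputError):
            vr.edi(0.5, 100, bw, 365, ed)


class TestThqHi:
    @pytest.mark.parametrize(
        "intake,rfd,expected",
        [(0.3, 0.3, 1.0), (2.99, 0.3, 9.9667), (0.0, 1.0, 0.0)],
    )
    def test_thq_examples(self, intake, rfd, expected):
        assert vr.thq(intake, rfd) == pytest.approx(expected, abs=5e-4)

    def test_thq_requires_positive_rfd(self):
        with pytest.raises(ConfigurationError):
            vr.thq(1.0, 0.0)

    def test_hi_additivity(self):
        assert vr.hazard_index({"As": 1.0, "Cd": 1.0}) == 2.0
        assert vr.hazard_index({"As": 0.0}) == 0.0

    def test_hi_group_mean_intakes(self):
        """HI of the per-metal THQs computed from one group's mean intakes."""
        thqs = {"As": 9.967, "Cd": 2.64, "Cu": 0.183, "Pb": 1.431, "Zn": 0.105}
        assert vr.hazard_index(thqs) == pytest.approx(14.33, abs=5e-3)

    def test_hi_permutation_invariant(self):
        thqs = {"As": 1.2, "Cd": 3.4, "Pb": 0.7}
        reordered = dict(reversed(list(thqs.items())))
        assert vr.hazard_index(thqs) == vr.hazard_index(reordered)

    def test_hi_empty_errors(self):
        with pytest.raises(InvalidInputError):
            vr.hazard_index({})


class TestDescribe:
    def test_small_sample_summary(self):
        d = vr.describe([1.0, 2.0, 3.0, 4.0], "x")
        assert d.n == 4
        assert (d.min, d.max) == (1.0, 4.0)
        assert d.median == 2.5  # mean of the two central order statistics
        assert d.mean == 2.5
        assert d.sd == pytest.approx(np.std([1, 2, 3, 4], ddof=1))
        assert d.cv_percent == pytest.approx(100 * d.sd / d.mean)
        assert 0 <= d.normality_p <= 1

    def test_constant_input(self):
        d = vr.describe([5.0, 5.0, 5.0], "x")
        assert d.sd == 0.0
        assert d.cv_percent == 0.0
        assert d.normality_p is None  # Shapiro-Wilk undefined at zero variance

    def test_tiny_sample_skips_normality(self):
        d = vr.describe([1.0, 2.0], "x")
        assert d.normality_p is None
        assert d.min <= d.median <= d.max

    def test_normality_p_detects_lognormal(self):
        rng = np.random.default_rng(3)
        skewed = np.exp(rng.normal(0, 1, 200))
        gauss = rng.normal(0, 1, 200)
        assert vr.describe(skewed, "s").normality_p < 0.01
        assert vr.describe(gauss, "g").normality_p > 0.01

    def test_cv_percent_printed_pairs(self):
        assert vr.cv_percent(116.76, 63.73) == pytest.approx(54.58, abs=0.005)
        assert vr.cv_percent(196.96, 165.11) == pytest.approx(83.83, abs=0.005)


class TestExceedance:
    @pytest.mark.parametrize(
        "values,threshold,expected",
        [
            ([1, 2, 3, 4], 2.5, 50.0),
            ([0.1, 0.2], 0.5, 0.0),
            ([0.6, 0.4, 0.7, 0.2, 0.9], 0.5, 60.0),
            ([0.5, 0.5], 0.5, 0.0),  # ties are non-exceeding
        ],
    )
    def test_examples(self, values, threshold, expected):
        assert vr.exceedance_rate(values, threshold) == expected

    @given(
        values=st.lists(st.floats(0, 10, allow_nan=False), min_size=1, max_size=50),
        threshold=st.floats(0.1, 10),
    )
    @settings(derandomize=True, max_examples=100)
    def test_matches_brute_force_count(self, values, threshold):
        expected = 100.0 * sum(1 for v in values if v > threshold) / len(values)
        assert vr.exceedance_rate(values, threshold) == pytest.approx(expected)

    def test_empty_errors(self):
        with pytest.raises(InvalidInputError):
            vr.exceedance_rate([], 1.0)


class TestCategoryMeanRatio:
    def test_leafy_over_other_categories(self):
        samples = make_category_samples(
            "Pb",
            {
                "leafy": [0.98, 0.98],
                "legume": [0.19, 0.19],
                "fruit": [0.22, 0.22],
            },
        )
        assert vr.category_mean_ratio(samples, "Pb", "leafy", "legume") == pytest.approx(
            5.16, abs=0.005
        )
        assert vr.category_mean_ratio(samples, "Pb", "leafy", "fruit") == pytest.approx(
            4.45, abs=0.005
        )

    def test_identical_categories_give_unity(self):
        samples = make_category_samples("Cd", {"leafy": [0.2, 0.4]})
        assert vr.category_mean_ratio(samples, "Cd", "leafy", "leafy") == 1.0

    def test_empty_category_errors(self):
        samples = make_category_samples("Cd", {"leafy": [0.2]})
        with pytest.raises(InvalidInputError):
            vr.category_mean_ratio(samples, "Cd", "leafy", "fruit")


class TestRecords:
    def test_inconsistent_fresh_dry_concentrations_rejected(self):
        with pytest.raises(InvalidInputError, match="S1"):
            vr.SampleRecord(
                site_id="S1", village="V1", veg_species="x", veg_category="leafy",
                soil_conc={"Cd": 1.0}, veg_conc_fw={"Cd": 0.5},
                veg_conc_dw={"Cd": 1.0}, water_content_w=0.9,
            )

    def test_consistent_record_accepted(self):
        rec = vr.SampleRecord(
            site_id="S1", village="V1", veg_species="x", veg_category="leafy",
            soil_conc={"Cd": 1.0}, veg_conc_fw={"Cd": 0.1},
            veg_conc_dw={"Cd": 1.0}, water_content_w=0.9,
        )
        assert rec.veg_conc_fw["Cd"] == pytest.approx(0.1)

    def test_dry_mass_cannot_exceed_fresh(self):
        with pytest.raises(InvalidInputError):
            vr.SampleRecord(
                site_id="S2", village="V1", veg_species="x", veg_category="leafy",
                soil_conc={}, veg_conc_fw={}, fresh_mass=100.0, dry_mass=120.0,
            )

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(bw=0.0, ir=100, ed=10, ef=365),
            dict(bw=50, ir=-1, ed=10, ef=365),
            dict(bw=50, ir=100, ed=0, ef=365),
            dict(bw=50, ir=100, ed=10, ef=0),
            dict(bw=50, ir=100, ed=10, ef=400),
        ],
    )
    def test_exposure_record_validation(self, kwargs):
        with pytest.raises(InvalidInputError):
            vr.ExposureRecord(person_id="P1", group="adults", **kwargs)

    def test_age_must_match_group_bounds(self):
        with pytest.raises(InvalidInputError):
            vr.ExposureRecord(
                person_id="P1", group="children", bw=25, ir=100, ed=5, ef=365, age=15
            )


class TestCensoring:
    def test_substitutes_half_detection_limit(self):
        out = vr.substitute_censored([1.0, None, 2.0, None], lod=0.2)
        assert out == [1.0, 0.1, 2.0, 0.1]

    def test_requires_positive_lod(self):
        with pytest.raises(ConfigurationError):
            vr.substitute_censored([1.0], lod=0.0)
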