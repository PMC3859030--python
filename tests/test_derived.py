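"""Renal estimating equations, BMI, and reference-range flagging."""

import dataclasses
import itertools

import pytest
from hypothesis import given, settings, strategies as st

from hlmstage import (
    DomainError,
    RangeFlag,
    RenalPanel,
    Sex,
    bmi,
    cockcroft_gault,
    flag_reference_ranges,
    smdrd_gfr,
    umol_to_mgdl,
)
from hlmstage.derived import derive_renal


class TestCockcroftGault:
    def test_hand_evaluated_male(self):
        # (140 - 40) * 72 / (72 * 1.0) = 100
        assert cockcroft_gault(1.0, 40, 72.0, Sex.MALE) == pytest.approx(100.0)

    def test_female_is_male_scaled(self):
        assert cockcroft_gault(1.0, 40, 72.0, Sex.FEMALE) == pytest.approx(85.0)

    @given(
        scr=st.floats(0.3, 8.0),
        age=st.floats(18, 100),
        weight=st.floats(40, 150),
    )
    @settings(max_examples=200, derandomize=True)
    def test_sex_ratio_is_constant(self, scr, age, weight):
        male = cockcroft_gault(scr, age, weight, Sex.MALE)
        female = cockcroft_gault(scr, age, weight, Sex.FEMALE)
        assert female / male == pytest.approx(0.85, rel=1e-12)

    @given(
        scr=st.floats(0.3, 8.0),
        age=st.floats(18, 100),
        weight=st.floats(40, 150),
        sex=st.sampled_from(list(Sex)),
    )
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_each_argument(self, scr, age, weight, sex):
        base = cockcroft_gault(scr, age, weight, sex)
        assert cockcroft_gault(scr * 1.1, age, weight, sex) < base
        if age + 5 < 140:
            assert cockcroft_gault(scr, age + 5, weight, sex) < base
        assert cockcroft_gault(scr, age, weight * 1.1, sex) > base

    @pytest.mark.parametrize(
        "kwargs, parameter",
        [
            (dict(scr=0.0, age=40, weight=72.0), "scr"),
            (dict(scr=1.0, age=17, weight=72.0), "age"),
            (dict(scr=1.0, age=141, weight=72.0), "age"),
            (dict(scr=1.0, age=40, weight=-1.0), "weight"),
        ],
    )
    def test_domain_errors_name_the_parameter(self, kwargs, parameter):
        with pytest.raises(DomainError) as exc:
            cockcroft_gault(sex=Sex.MALE, **kwargs)
        assert exc.value.parameter == parameter

    def test_agrees_with_bruteforce_grid(self):
        """Closed form vs an independently written evaluation over 10^4 points."""
        grid = itertools.product(
            [0.5, 0.8, 1.0, 1.3, 2.0, 3.0, 4.5, 6.0, 7.5, 9.0],
            [18, 25, 35, 45, 55, 65, 75, 85, 95, 110],
            [40, 50, 60, 70, 80, 90, 100, 115, 130, 150],
            [Sex.FEMALE, Sex.MALE],
        )
        for scr, age, weight, sex in grid:
            expected = (140 - age) * weight
            expected = expected / 72.0 / scr
            if sex is Sex.FEMALE:
                expected = expected * 85 / 100
            got = cockcroft_gault(scr, age, weight, sex)
            assert abs(got - expected) <= 1e-9 * abs(expected)


class TestSimplifiedMDRD:
    def test_hand_evaluated_male(self):
        # 186 * 1.0^-1.154 * 50^-0.203
        assert smdrd_gfr(1.0, 50, Sex.MALE) == pytest.approx(
            186.0 * 50 ** -0.203, rel=1e-12
        )
        assert smdrd_gfr(1.0, 50, Sex.MALE) == pytest.approx(84.3, abs=0.25)

    def test_female_and_ethnicity_ratios(self):
        male = smdrd_gfr(1.2, 63, Sex.MALE)
        assert smdrd_gfr(1.2, 63, Sex.FEMALE) / male == pytest.approx(0.742)
        assert smdrd_gfr(1.2, 63, Sex.MALE, black_ethnicity=True) / male == (
            pytest.approx(1.21)
        )

    @given(
        scr=st.floats(0.3, 8.0),
        k=st.floats(1.05, 3.0),
        age=st.floats(18, 100),
    )
    @settings(max_examples=200, derandomize=True)
    def test_scale_equivariance_in_creatinine(self, scr, k, age):
        ratio = smdrd_gfr(scr * k, age, Sex.MALE) / smdrd_gfr(scr, age, Sex.MALE)
        assert ratio == pytest.approx(k ** -1.154, rel=1e-9)

    @given(scr=st.floats(0.3, 8.0), age=st.floats(18, 99))
    @settings(max_examples=200, derandomize=True)
    def test_decreasing_in_creatinine_and_age(self, scr, age):
        base = smdrd_gfr(scr, age, Sex.MALE)
        assert smdrd_gfr(scr * 1.1, age, Sex.MALE) < base
        assert smdrd_gfr(scr, age + 1, Sex.MALE) < base

    def test_diagnostics_mode_allows_unit_age_term(self):
        assert smdrd_gfr(1.0, 1, Sex.MALE, check_ranges=False) == pytest.approx(186.0)
        with pytest.raises(DomainError):
            smdrd_gfr(1.0, 1, Sex.MALE)  # range checks on by default

    def test_agrees_with_bruteforce_grid(self):
        import math

        grid = itertools.product(
            [0.4 + 0.35 * i for i in range(25)],
            [18 + 4 * i for i in range(25)],
            [Sex.FEMALE, Sex.MALE],
            [False, True],
        )
        for scr, age, sex, black in grid:
            expected = 186.0 * math.exp(-1.154 * math.log(scr) - 0.203 * math.log(age))
            if sex is Sex.FEMALE:
                expected *= 0.742
            if black:
                expected *= 1.21
            got = smdrd_gfr(scr, age, sex, black_ethnicity=black)
            assert abs(got - expected) <= 1e-9 * abs(expected)


class TestBMI:
    @pytest.mark.parametrize(
        "weight, height, expected",
        [(80.0, 2.0, 20.0), (72.0, 1.8, 72.0 / 1.8**2), (23.5, 1.0, 23.5)],
    )
    def test_values(self, weight, height, expected):
        assert bmi(weight, height) == pytest.approx(expected, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            bmi(0.0, 1.7)
        with pytest.raises(DomainError):
            bmi(70.0, -1.0)


class TestUnitConversion:
    def test_umol_per_l_to_mg_per_dl(self):
        assert umol_to_mgdl(88.4) == pytest.approx(1.0)
        assert umol_to_mgdl(115.0) == pytest.approx(115.0 / 88.4)


class TestReferenceFlags:
    def test_creatinine_boundary_is_within(self, demographics, config, healthy_record):
        renal = RenalPanel(serum_creatinine=1.3)
        derived, _ = flag_reference_ranges(
            renal, demographics, healthy_record.cardiac, config
        )
        assert derived.scr_flag is RangeFlag.WITHIN

    def test_male_clearance_just_below_reference(self, demographics, config):
        renal = RenalPanel(measured_clcr=94.0)
        derived = derive_renal(renal, demographics, config)
        assert derived.clcr_flag is RangeFlag.BELOW

    def test_measured_clearance_preferred_over_estimate(self, demographics, config):
        # scr 0.8 -> CG estimate ~111 (within); measured value wins
        renal = RenalPanel(serum_creatinine=0.8, measured_clcr=60.0)
        derived = derive_renal(renal, demographics, config)
        assert derived.clcr_cg == pytest.approx((140 - 60) * 80 / (72 * 0.8))
        assert derived.clcr_flag is RangeFlag.BELOW

    def test_missing_measurements_flag_unknown(self, demographics, config):
        derived = derive_renal(RenalPanel(), demographics, config)
        assert derived.scr_flag is RangeFlag.UNKNOWN
        assert derived.clcr_flag is RangeFlag.UNKNOWN
        assert derived.bun_flag is RangeFlag.UNKNOWN
        assert derived.cystatin_flag is RangeFlag.UNKNOWN
        assert derived.clcr_cg is None and derived.gfr_smdrd is None

    def test_sex_specific_clearance_interval(self, demographics, config):
        female = dataclasses.replace(demographics, sex=Sex.FEMALE)
        renal = RenalPanel(measured_clcr=80.0)  # within 57-115, below 95-145
        assert derive_renal(renal, female, config).clcr_flag is RangeFlag.WITHIN
        assert derive_renal(renal, demographics, config).clcr_flag is RangeFlag.BELOW

    def test_every_configured_interval_contains_its_boundaries(self, config):
        for iv in (config.scr_normal, config.clcr_normal_female,
                   config.clcr_normal_male, config.lvdd_normal, config.lvsd_normal):
            assert iv.flag(iv.lower) is RangeFlag.WITHIN
            assert iv.flag(iv.upper) is RangeFlag.WITHIN
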