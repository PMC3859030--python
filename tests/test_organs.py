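"""Per-organ malfunction detection and the M0-M3 count mapping."""

import dataclasses
import itertools

import pytest

from hlmstage import (
    ABSENT,
    HepaticPanel,
    NeuroPanel,
    Organ,
    OrganStatus,
    PRESENT,
    RangeFlag,
    UNKNOWN,
    assess_brain,
    assess_kidney,
    assess_liver,
    stage_m,
)
from hlmstage.derived import DerivedRenal


def renal(clcr=RangeFlag.WITHIN, gfr=90.0, scr=RangeFlag.WITHIN,
          bun=RangeFlag.WITHIN, cys=RangeFlag.WITHIN, clcr_cg=110.0):
    return DerivedRenal(clcr_cg=clcr_cg, gfr_smdrd=gfr, clcr_flag=clcr,
                        scr_flag=scr, bun_flag=bun, cystatin_flag=cys)


class TestKidney:
    def test_low_clearance_triggers(self, config):
        status = assess_kidney(renal(clcr=RangeFlag.BELOW), config)
        assert status.malfunction is PRESENT
        assert "creatinine_clearance_below_reference" in status.evidence

    def test_low_gfr_triggers(self, config):
        status = assess_kidney(renal(gfr=55.0), config)
        assert status.malfunction is PRESENT
        assert "smdrd_gfr_below_cutoff" in status.evidence

    def test_elevated_cystatin_triggers(self, config):
        status = assess_kidney(renal(cys=RangeFlag.ABOVE), config)
        assert status.malfunction is PRESENT

    def test_bun_alone_is_supportive_only(self, config):
        status = assess_kidney(renal(bun=RangeFlag.ABOVE), config)
        assert status.malfunction is ABSENT
        assert status.evidence == ()
        assert "bun_elevated" in status.supportive

    def test_abnormal_creatinine_with_normal_clearance_does_not_trigger(self, config):
        status = assess_kidney(renal(scr=RangeFlag.ABOVE), config)
        assert status.malfunction is ABSENT
        assert "serum_creatinine_outside_reference" in status.supportive

    def test_all_inputs_missing_is_unknown(self, config):
        empty = DerivedRenal(clcr_cg=None, gfr_smdrd=None,
                             clcr_flag=RangeFlag.UNKNOWN, scr_flag=RangeFlag.UNKNOWN,
                             bun_flag=RangeFlag.UNKNOWN,
                             cystatin_flag=RangeFlag.UNKNOWN)
        assert assess_kidney(empty, config).malfunction is UNKNOWN

    def test_high_clearance_is_not_malfunction(self, config):
        assert assess_kidney(renal(clcr=RangeFlag.ABOVE), config).malfunction is ABSENT


def hepatic(**overrides):
    base = {f.name: ABSENT for f in dataclasses.fields(HepaticPanel)
            if f.name != "on_anticoagulants"}
    base["on_anticoagulants"] = False
    base.update(overrides)
    return HepaticPanel(**base)


class TestLiver:
    def test_single_abnormal_lab_does_not_trigger(self, config):
        status = assess_liver(hepatic(alp_elevated=PRESENT), config)
        assert status.malfunction is ABSENT
        assert status.supportive == ("alp_elevated",)

    def test_two_abnormal_labs_trigger(self, config):
        status = assess_liver(
            hepatic(total_bilirubin_elevated=PRESENT, albumin_decreased=PRESENT),
            config,
        )
        assert status.malfunction is PRESENT
        assert set(status.evidence) == {"bilirubin_elevated", "albumin_decreased"}

    def test_ascites_alone_triggers(self, config):
        status = assess_liver(hepatic(ascites=PRESENT), config)
        assert status.malfunction is PRESENT
        assert status.evidence == ("ascites",)

    def test_inr_excluded_under_anticoagulation(self, config):
        panel = hepatic(inr_abnormal=PRESENT, ggt_elevated=PRESENT,
                        on_anticoagulants=True)
        assert assess_liver(panel, config).malfunction is ABSENT
        panel = hepatic(inr_abnormal=PRESENT, ggt_elevated=PRESENT)
        assert assess_liver(panel, config).malfunction is PRESENT

    def test_all_flags_unknown_is_unknown(self, config):
        assert assess_liver(HepaticPanel(), config).malfunction is UNKNOWN

    def test_lab_count_matches_combinatorial_oracle(self, config):
        """Verdicts over all subsets of four labs agree with a count oracle."""
        labs = ("total_bilirubin_elevated", "alt_elevated",
                "alp_elevated", "albumin_decreased")
        for mask in itertools.product([PRESENT, ABSENT], repeat=4):
            panel = hepatic(**dict(zip(labs, mask)))
            expected = PRESENT if sum(v is PRESENT for v in mask) >= 2 else ABSENT
            assert assess_liver(panel, config).malfunction is expected


class TestBrain:
    def test_depression_alone_triggers(self):
        status = assess_brain(NeuroPanel(depression=PRESENT))
        assert status.malfunction is PRESENT
        assert status.evidence == ("depression",)

    @pytest.mark.parametrize(
        "hypo, dep, expected",
        [
            (ABSENT, ABSENT, ABSENT),
            (UNKNOWN, ABSENT, UNKNOWN),  # Kleene OR: unknown is not absent
            (UNKNOWN, UNKNOWN, UNKNOWN),
            (PRESENT, UNKNOWN, PRESENT),
        ],
    )
    def test_tristate_or_semantics(self, hypo, dep, expected):
        panel = NeuroPanel(cerebral_hypoperfusion=hypo, depression=dep)
        assert assess_brain(panel).malfunction is expected


def status(organ, malfunction, attributable=UNKNOWN):
    evidence = ("criterion",) if malfunction is PRESENT else ()
    return OrganStatus(organ=organ, malfunction=malfunction, evidence=evidence,
                       attributable_to_hf=attributable)


class TestStageM:
    @pytest.mark.parametrize("n_present, expected", [(0, 0), (1, 1), (2, 2), (3, 3)])
    def test_count_mapping(self, n_present, expected):
        organs = list(Organ)
        statuses = [
            status(o, PRESENT if i < n_present else ABSENT)
            for i, o in enumerate(organs)
        ]
        assert stage_m(statuses) == expected

    def test_permutation_invariant(self):
        statuses = [status(Organ.KIDNEY, PRESENT), status(Organ.LIVER, ABSENT),
                    status(Organ.BRAIN, PRESENT)]
        for perm in itertools.permutations(statuses):
            assert stage_m(list(perm)) == 2

    def test_unknown_malfunction_does_not_count(self):
        statuses = [status(Organ.KIDNEY, UNKNOWN), status(Organ.LIVER, UNKNOWN)]
        assert stage_m(statuses) == 0

    def test_attribution_positively_ruled_out_excludes_organ(self):
        with_hf = [status(Organ.KIDNEY, PRESENT, attributable=UNKNOWN)]
        assert stage_m(with_hf) == 1
        without = [status(Organ.KIDNEY, PRESENT, attributable=ABSENT)]
        assert stage_m(without) == 0

    def test_duplicate_organ_rejected(self):
        statuses = [status(Organ.KIDNEY, PRESENT), status(Organ.KIDNEY, ABSENT)]
        with pytest.raises(ValueError, match="duplicate"):
            stage_m(statuses)

    def test_malfunction_without_evidence_rejected(self):
        with pytest.raises(ValueError, match="evidence"):
            OrganStatus(organ=Organ.LIVER, malfunction=PRESENT, evidence=())
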