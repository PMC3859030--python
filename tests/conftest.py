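import pytest

from hlmstage import (
    ABSENT,
    CardiacPanel,
    Demographics,
    HemodynamicPanel,
    HepaticPanel,
    NeuroPanel,
    PatientRecord,
    PreviousMI,
    PulmonarySigns,
    ReferenceConfig,
    RenalPanel,
    Sex,
)


@pytest.fixture
def config():
    return ReferenceConfig()


@pytest.fixture
def demographics():
    return Demographics(age=60, sex=Sex.MALE, black_ethnicity=False,
                        weight=80.0, height=1.75)


@pytest.fixture
def healthy_record(demographics):
    """A fully observed record with no abnormal finding anywhere."""
    return PatientRecord(
        patient_id="healthy",
        demographics=demographics,
        cardiac=CardiacPanel(
            ejection_fraction=60.0,
            systolic_dysfunction=ABSENT,
            diastolic_dysfunction=ABSENT,
            lv_hypertrophy=ABSENT,
            previous_mi=PreviousMI.NONE,
            lv_end_diastolic_diameter=50.0,
            lv_end_systolic_diameter=31.0,
            lv_remodeling=ABSENT,
            rv_dysfunction=ABSENT,
        ),
        hemodynamics=HemodynamicPanel(mpap_rest=18.0, pawp=8.0),
        pulmonary=PulmonarySigns(
            clinical_congestion_signs=ABSENT, pulmonary_edema=ABSENT,
            pleural_effusion=ABSENT, cardiac_lung=ABSENT,
            abnormal_valsalva=ABSENT, orthostatic_bp_abnormal=ABSENT,
            nitroglycerin_response_abnormal=ABSENT,
        ),
        # scr 0.8 puts the Cockcroft-Gault clearance at ~111 mL/min,
        # inside the male reference interval
        renal=RenalPanel(serum_creatinine=0.8, bun=14.0, cystatin_c=0.8),
        hepatic=HepaticPanel(
            total_bilirubin_elevated=ABSENT, alt_elevated=ABSENT,
            ast_elevated=ABSENT, alp_elevated=ABSENT, ggt_elevated=ABSENT,
            albumin_decreased=ABSENT, inr_abnormal=ABSENT,
            on_anticoagulants=False, ascites=ABSENT,
            portal_flow_reduced=ABSENT, ivc_noncollapsing=ABSENT,
        ),
        neuro=NeuroPanel(cerebral_hypoperfusion=ABSENT, depression=ABSENT),
    )
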