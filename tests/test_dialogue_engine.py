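"""Engine execution: scenarios, single steps, substitution, termination."""

import pytest

from codel import fixtures as fx
from codel.dialogue_engine import (
    DoctorPolicy,
    PatientPolicy,
    PatientStance,
    Session,
    SessionConfig,
    run_session,
    step,
    substitute_alternative,
    transcript_from_json,
    transcript_to_json,
)
from codel.errors import (
    IllegalPair,
    NoAlternativeAvailable,
    NotYourTurn,
    TurnLimitExceeded,
)
from codel.speech_acts import Proposition, SpeechActKind, SpeechActMessage

A = SpeechActKind


def acts(t):
    return [m.act.value for m in t.messages]


# ---------------------------------------------------------------------------
# Canonical scenarios (regression suite)
# ---------------------------------------------------------------------------

def test_compliant_patient_yields_question_resolution(af_transcripts):
    t = af_transcripts["scenario1"]
    assert acts(t) == ["assert", "question", "justify", "accept"]
    assert t.final_status == "agreed"


def test_persuadable_patient_yields_persuasion_sequence(af_transcripts):
    t = af_transcripts["scenario2"]
    assert acts(t) == ["assert", "rebuttal", "persuade", "accept"]
    assert t.final_status == "agreed"


def test_firm_patient_triggers_plan_substitution(af_transcripts):
    t = af_transcripts["scenario3"]
    assert acts(t) == ["assert", "rebuttal", "persuade", "refuse",
                       "retract", "assert", "accept"]
    assert t.final_plan == ("cardiac_ultrasound", "surgical_ablation")
    assert "cardiac_angiography" not in t.final_plan


def test_every_transcript_passes_pairwise_legality(af_transcripts, emily_transcript):
    for t in [*af_transcripts.values(), emily_transcript]:
        assert t.audit() == []


def test_transcripts_start_with_doctor_assert(af_transcripts, emily_transcript):
    for t in [*af_transcripts.values(), emily_transcript]:
        first = t.messages[0]
        assert first.act is A.ASSERT and first.sender_role == "doctor"


def test_agreed_iff_last_act_accept(af_transcripts, emily_transcript):
    for t in [*af_transcripts.values(), emily_transcript]:
        assert (t.final_status == "agreed") == (t.messages[-1].act is A.ACCEPT)


def test_determinism_byte_equal_serialization(af_fixture):
    _, configs = af_fixture
    for cfg in configs.values():
        a = transcript_to_json(fx.run_config(cfg))
        b = transcript_to_json(fx.run_config(cfg))
        assert a == b


def test_justify_and_persuade_argument_ids_resolve(af_kb, af_transcripts):
    for t in af_transcripts.values():
        for m in t.messages:
            for arg_id in m.argument_ids:
                af_kb.argument(arg_id)  # raises KeyError if dangling


# ---------------------------------------------------------------------------
# Emily (depression) case
# ---------------------------------------------------------------------------

def test_emily_reaches_agreement_on_cbt_alone(emily_transcript):
    t = emily_transcript
    assert t.final_status == "agreed"
    assert t.final_plan == ("cbt",)


def test_emily_refuses_after_persuasion(emily_transcript):
    seq = acts(emily_transcript)
    i = seq.index("persuade")
    assert seq[i + 1] == "refuse"


def test_mandatory_intervention_without_alternative_ends_no_agreement(af_kb, protocols):
    doctor_p, patient_p = protocols
    # a patient who flatly refuses the (mandatory, alternative-less) ablation
    patient = PatientPolicy(
        af_kb, stances={"surgical_ablation": PatientStance("refuse")})
    t = run_session(doctor_p, patient_p, af_kb, DoctorPolicy(af_kb), patient)
    assert t.final_status == "no_agreement"
    assert t.messages[-1].act is A.RETRACT
    assert t.audit() == []


# ---------------------------------------------------------------------------
# Single-step granularity
# ---------------------------------------------------------------------------

def _fresh_session(af_kb, protocols, **patient_kw):
    doctor_p, patient_p = protocols
    return Session(doctor_p, patient_p, af_kb, DoctorPolicy(af_kb),
                   PatientPolicy(af_kb, **patient_kw), SessionConfig())


def _doctor_assert(af_kb):
    return SpeechActMessage(
        A.ASSERT, Proposition(af_kb.condition, af_kb.recommended_plan),
        "doctor", "patient")


def test_step_first_move(af_kb, protocols):
    s = _fresh_session(af_kb, protocols, question_budget=1)
    step(s, _doctor_assert(af_kb))
    assert s.status == "running"
    assert s.turn_count == 1


def test_step_rejects_patient_moving_first(af_kb, protocols):
    s = _fresh_session(af_kb, protocols)
    with pytest.raises(NotYourTurn):
        step(s, SpeechActMessage(
            A.QUESTION, Proposition(af_kb.condition, af_kb.recommended_plan),
            "patient", "doctor"))


def test_step_rejects_justify_after_assert(af_kb, protocols):
    s = _fresh_session(af_kb, protocols, question_budget=1)
    step(s, _doctor_assert(af_kb))
    with pytest.raises(IllegalPair):
        step(s, SpeechActMessage(
            A.JUSTIFY, Proposition(af_kb.condition, af_kb.recommended_plan),
            "patient", "doctor", ("angio_s1",)))
    assert s.status == "violated"


def test_step_accept_after_persuade_reaches_agreement(af_kb, protocols):
    s = _fresh_session(
        af_kb, protocols,
        stances={"cardiac_angiography": PatientStance("oppose", cite=["angio_a3"])},
        profile="open")
    step(s, _doctor_assert(af_kb))
    step(s, SpeechActMessage(
        A.REBUTTAL, Proposition(af_kb.condition, ("cardiac_angiography",)),
        "patient", "doctor", ("angio_a3",)))
    step(s, SpeechActMessage(
        A.PERSUADE, Proposition(af_kb.condition, ("cardiac_angiography",)),
        "doctor", "patient", ("angio_s1", "angio_s2", "angio_s3", "angio_s4")))
    step(s, SpeechActMessage(
        A.ACCEPT, Proposition(af_kb.condition, af_kb.recommended_plan),
        "patient", "doctor"))
    assert s.status == "agreed"


def test_turn_limit_enforced(af_kb, protocols):
    doctor_p, patient_p = protocols
    # enough question budget to exceed the cap through question-justify cycles
    patient = PatientPolicy(af_kb, question_budget=100)
    with pytest.raises(TurnLimitExceeded):
        run_session(doctor_p, patient_p, af_kb, DoctorPolicy(af_kb), patient,
                    SessionConfig(max_turns=10))


# ---------------------------------------------------------------------------
# Plan substitution
# ---------------------------------------------------------------------------

def test_substitute_replaces_in_place(af_kb):
    plan = Proposition("atrial_fibrillation",
                       ("cardiac_angiography", "surgical_ablation"))
    out = substitute_alternative(af_kb, plan, "cardiac_angiography")
    assert out.plan == ("cardiac_ultrasound", "surgical_ablation")


def test_substitute_drops_optional_when_exhausted(depression_kb):
    plan = Proposition("major_depression", ("cbt", "antidepressant"))
    out = substitute_alternative(
        depression_kb, plan, "antidepressant", already_rejected={"ssri"})
    assert out.plan == ("cbt",)


def test_substitute_errors(af_kb):
    plan = Proposition("atrial_fibrillation",
                       ("cardiac_angiography", "surgical_ablation"))
    with pytest.raises(ValueError):
        substitute_alternative(af_kb, plan, "cardiac_ultrasound")
    with pytest.raises(NoAlternativeAvailable):
        substitute_alternative(af_kb, plan, "surgical_ablation")


# ---------------------------------------------------------------------------
# Transcript JSON
# ---------------------------------------------------------------------------

def test_transcript_json_roundtrip(emily_transcript):
    text = transcript_to_json(emily_transcript)
    back = transcript_from_json(text)
    assert acts(back) == acts(emily_transcript)
    assert back.final_status == emily_transcript.final_status
    assert transcript_to_json(back) == text


def test_transcript_schema_validation_rejects_malformed():
    with pytest.raises(ValueError):
        transcript_from_json('{"messages": []}')
    with pytest.raises(ValueError):
        transcript_from_json(
            '{"metadata": {}, "final_status": "agreed", "messages": '
            '[{"turn": 5, "sender_role": "doctor", "receiver_role": "patient", '
            '"act": "assert", "subject": "c", "plan": ["x"], "argument_ids": []}]}')


def test_surface_text_is_template_realized(af_kb, af_transcripts):
    t = af_transcripts["scenario1"]
    justify = next(m for m in t.messages if m.act is A.JUSTIFY)
    assert justify.surface_text
    assert af_kb.argument("angio_s1").text in justify.surface_text
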