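"""Grammar, parser, serializer and static checker for protocol sources."""

import random

import pytest

from codel.cli import KNOWN_PREDICATES
from codel.errors import ProtocolSyntaxError, UnknownActKind
from codel.protocol_lang import (
    Call,
    Or,
    Step,
    Then,
    check_protocol,
    parse_protocol,
    serialize,
)
from helpers import random_protocol


def test_parse_single_receive_step():
    src = "a(patient(),P) :: assert(disease, surgery1 + surgery2) <= a(doctor(),D)"
    proto = parse_protocol(src)
    assert len(proto.clauses) == 1
    step = proto.entry.body
    assert isinstance(step, Step)
    assert step.kind == "receive"
    assert step.act.value == "assert"
    assert step.args == (("disease",), ("surgery1", "surgery2"))
    assert step.peer.role_name == "doctor"
    assert proto.entry.header.agent_var == "P"


def test_parse_guarded_send_step():
    src = ("a(patient(),P) :: question(disease, surgery1 + surgery2) => a(doctor(),D)"
           " <- interested_in(disease, surgery1 + surgery2)")
    step = parse_protocol(src).entry.body
    assert step.kind == "send"
    assert step.guard.predicate_name == "interested_in"
    assert len(step.guard.arguments) == 2
    assert step.guard.arguments[1] == ("surgery1", "surgery2")


def test_then_binds_tighter_than_or_and_right_associates():
    src = """
    a(r(),X) ::
        assert(p) => a(q(),Y)
        then accept(p) <= a(q(),Y)
        or refuse(p) <= a(q(),Y)
    """
    body = parse_protocol(src).entry.body
    assert isinstance(body, Or)
    assert isinstance(body.branches[0], Then)
    assert isinstance(body.branches[1], Step)


def test_parse_errors():
    with pytest.raises(ProtocolSyntaxError):
        parse_protocol("")
    with pytest.raises(ProtocolSyntaxError):
        parse_protocol("a(doctor(),D) :: assert(x) => ")
    with pytest.raises(ProtocolSyntaxError):
        parse_protocol("b(doctor(),D) :: assert(x) => a(p(),P)")
    with pytest.raises(UnknownActKind):
        parse_protocol("a(doctor(),D) :: greet(x) => a(p(),P)")


def test_syntax_error_reports_position():
    try:
        parse_protocol("a(doctor(),D) ::\n  assert(x) => ??")
    except ProtocolSyntaxError as exc:
        assert exc.line == 2
        assert exc.column is not None
    else:  # pragma: no cover
        pytest.fail("expected a syntax error")


def test_comments_and_whitespace_are_ignored():
    src = "# heading\na(r(),X) ::  # trailing\n    accept(p) <= a(q(),Y)\n"
    assert isinstance(parse_protocol(src).entry.body, Step)


def test_bundled_protocols_roundtrip(protocols):
    for proto in protocols:
        assert parse_protocol(serialize(proto)) == proto
        once = serialize(parse_protocol(serialize(proto)))
        assert once == serialize(proto)  # normalization is idempotent


def test_roundtrip_random_asts():
    rng = random.Random(20260925)
    for _ in range(300):
        proto = random_protocol(rng)
        text = serialize(proto)
        assert parse_protocol(text) == proto
        assert serialize(parse_protocol(text)) == text


def test_bundled_bundle_is_clean(protocols):
    doctor, patient = protocols
    assert check_protocol(doctor, patient, KNOWN_PREDICATES) == []


def test_checker_flags_assert_justify_reply():
    doctor = parse_protocol(
        "a(doctor(),D) :: assert(d, x) => a(patient(),P) "
        "then justify(d, x, s) <= a(patient(),P)")
    patient = parse_protocol(
        "a(patient(),P) :: assert(d, x) <= a(doctor(),D) "
        "then justify(d, x, s) => a(doctor(),D)")
    violations = check_protocol(doctor, patient)
    pair_violations = [v for v in violations if v.code == "illegal-pair"]
    assert pair_violations
    assert all("assert" in v.message and "justify" in v.message for v in pair_violations)


def test_checker_flags_unmatched_send():
    doctor = parse_protocol(
        "a(doctor(),D) :: assert(d, x) => a(patient(),P) "
        "then rebuttal(x, r) <= a(patient(),P) "
        "then persuade(x, s) => a(patient(),P)")
    patient = parse_protocol(
        "a(patient(),P) :: assert(d, x) <= a(doctor(),D) "
        "then rebuttal(x, r) => a(doctor(),D)")
    violations = check_protocol(doctor, patient)
    assert any(v.code == "unmatched-message" and "persuade" in v.message
               for v in violations)


def test_checker_flags_unknown_guard_predicate():
    doctor = parse_protocol(
        "a(doctor(),D) :: assert(d, x) => a(patient(),P) <- crystal_ball(x)")
    patient = parse_protocol("a(patient(),P) :: assert(d, x) <= a(doctor(),D)")
    violations = check_protocol(doctor, patient, frozenset({"has_support"}))
    assert any(v.code == "unknown-predicate" for v in violations)


def test_checker_warns_on_ambiguous_or():
    doctor = parse_protocol(
        "a(doctor(),D) :: (assert(d, x) => a(patient(),P) "
        "or assert(d, y) => a(patient(),P))")
    patient = parse_protocol("a(patient(),P) :: assert(d, x) <= a(doctor(),D)")
    violations = check_protocol(doctor, patient)
    warnings = [v for v in violations if v.severity == "warning"]
    assert any(v.code == "ambiguous-or" for v in warnings)


def test_or_node_requires_two_branches():
    with pytest.raises(ValueError):
        Or((Call.__new__(Call),))
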