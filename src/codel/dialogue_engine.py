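"""Two-agent protocol execution: a turn-taking speech-act state machine.

The engine runs a doctor protocol and a patient protocol in lockstep.
Each agent holds a cursor into its protocol AST (a continuation stack of
pending terms); at every point the engine enumerates the send steps the
agent whose turn it is may execute (OR branches whose guards hold), asks
that agent's policy to pick one and fill in the concrete message, checks
interaction-pair legality against the previous message, and advances
both cursors — the speaker through its send step, the listener through
the matching receive.  Turn-taking is strictly alternating with a single
message in flight; the one sanctioned exception is the compound
retract-then-assert, two consecutive messages by the same speaker.

A dialogue is *agreed* exactly when its last act is an acceptance.  If a
refused intervention has no admissible alternative and is not optional,
the doctor withdraws the assertion and the session ends *no_agreement*.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable

from .argument_base import GuidelineKB, find_arguments, propose_alternative
from .errors import (
    IllegalPair,
    NoAlternativeAvailable,
    NotYourTurn,
    ProtocolViolation,
    TurnLimitExceeded,
    UnknownIntervention,
)
from .personality import (
    BeliefState,
    PersonalityProfile,
    apply_arguments,
    decide,
    flipped,
    get_profile,
)
from .protocol_lang import Call, Constraint, Or, Protocol, Step, Then, Term
from .speech_acts import Proposition, SpeechActKind, SpeechActMessage, validate_pair

__all__ = [
    "SessionConfig", "Session", "Transcript", "Policy", "DoctorPolicy",
    "PatientPolicy", "PatientStance", "run_session", "step",
    "substitute_alternative", "transcript_to_json", "transcript_from_json",
    "validate_transcript_dict", "TemplateRealizer",
]

logger = logging.getLogger(__name__)

DOCTOR = "doctor"
PATIENT = "patient"

_MAX_EXPANSION_DEPTH = 64


# ---------------------------------------------------------------------------
# Plan substitution
# ---------------------------------------------------------------------------

def substitute_alternative(
    kb: GuidelineKB,
    plan: Proposition,
    rejected: str,
    already_rejected: frozenset[str] | set[str] = frozenset(),
) -> Proposition:
    """Replace a rejected intervention in a plan with its best alternative.

    The highest-priority alternative (authored order) not previously
    rejected takes the rejected intervention's position in the plan.  If
    no alternative remains and the intervention is flagged optional in
    the KB, it is dropped from the plan; if it is mandatory,
    :class:`NoAlternativeAvailable` is raised and the session ends
    without agreement.
    """
    if rejected not in plan.plan:
        raise ValueError(f"{rejected!r} is not part of the plan {list(plan.plan)}")
    iv = kb.intervention(rejected)
    alt = propose_alternative(kb, rejected, already_rejected | {rejected})
    if alt is not None:
        return plan.replace_intervention(rejected, alt)
    if iv.optional:
        dropped = plan.drop_intervention(rejected)
        if not dropped.plan:
            raise NoAlternativeAvailable(
                f"dropping optional {rejected!r} would leave an empty plan")
        return dropped
    raise NoAlternativeAvailable(
        f"no admissible alternative for mandatory intervention {rejected!r}")


# ---------------------------------------------------------------------------
# Transcript
# ---------------------------------------------------------------------------

@dataclass
class Transcript:
    """Ordered, role-attributed record of one dialogue session."""

    messages: list[SpeechActMessage] = field(default_factory=list)
    final_status: str = "running"
    metadata: dict = field(default_factory=dict)

    @property
    def acts(self) -> list[SpeechActKind]:
        return [m.act for m in self.messages]

    @property
    def final_plan(self) -> tuple[str, ...]:
        """The plan carried by the last plan-bearing message."""
        for m in reversed(self.messages):
            if m.content.plan:
                return m.content.plan
        return ()

    def audit(self) -> list[tuple[int, SpeechActKind, SpeechActKind]]:
        """Positions of illegal adjacent pairs (same-speaker rule honoured)."""
        from .speech_acts import audit_transcript_acts

        return audit_transcript_acts((m.sender_role, m.act) for m in self.messages)


_TRANSCRIPT_REQUIRED = ("metadata", "messages", "final_status")
_MESSAGE_REQUIRED = ("turn", "sender_role", "receiver_role", "act", "subject", "plan",
                     "argument_ids")


def transcript_to_json(t: Transcript) -> str:
    """Serialize a transcript to its canonical JSON form (byte-stable)."""
    doc = {
        "metadata": t.metadata,
        "messages": [
            {
                "turn": i + 1,
                "sender_role": m.sender_role,
                "receiver_role": m.receiver_role,
                "act": m.act.value,
                "subject": m.content.subject,
                "plan": list(m.content.plan),
                "argument_ids": list(m.argument_ids),
                "surface_text": m.surface_text,
            }
            for i, m in enumerate(t.messages)
        ],
        "final_status": t.final_status,
    }
    return json.dumps(doc, indent=2, sort_keys=False, ensure_ascii=False) + "\n"


def validate_transcript_dict(doc: object) -> None:
    """Check a parsed transcript document against the published schema."""
    if not isinstance(doc, dict):
        raise ValueError("transcript document must be a JSON object")
    for key in _TRANSCRIPT_REQUIRED:
        if key not in doc:
            raise ValueError(f"transcript is missing required key {key!r}")
    if not isinstance(doc["messages"], list):
        raise ValueError("'messages' must be a list")
    for i, rec in enumerate(doc["messages"]):
        if not isinstance(rec, dict):
            raise ValueError(f"message {i}: must be an object")
        for key in _MESSAGE_REQUIRED:
            if key not in rec:
                raise ValueError(f"message {i}: missing required key {key!r}")
        if rec["act"] not in {k.value for k in SpeechActKind}:
            raise ValueError(f"message {i}: unknown act {rec['act']!r}")
        if rec["turn"] != i + 1:
            raise ValueError(f"message {i}: turn numbering must be consecutive from 1")


def transcript_from_json(text: str) -> Transcript:
    """Parse and validate a transcript JSON document."""
    doc = json.loads(text)
    validate_transcript_dict(doc)
    messages = [
        SpeechActMessage(
            act=SpeechActKind(rec["act"]),
            content=Proposition(rec["subject"], tuple(rec["plan"])),
            sender_role=rec["sender_role"],
            receiver_role=rec["receiver_role"],
            argument_ids=tuple(rec["argument_ids"]),
            surface_text=rec.get("surface_text"),
        )
        for rec in doc["messages"]
    ]
    return Transcript(messages, doc["final_status"], doc["metadata"])


# ---------------------------------------------------------------------------
# Text realization hook
# ---------------------------------------------------------------------------

class TemplateRealizer:
    """Default surface-text hook: templates filled from KB argument text.

    Any callable ``(message, kb) -> str`` can replace it, e.g. an external
    language-model backend; the engine core never depends on one.
    """

    def __call__(self, msg: SpeechActMessage, kb: GuidelineKB) -> str:
        plan = " + ".join(msg.content.plan)
        args = "; ".join(kb.argument(a).text for a in msg.argument_ids)
        templates = {
            SpeechActKind.ASSERT: f"For {msg.content.subject}, I recommend: {plan}.",
            SpeechActKind.QUESTION: f"Could you tell me more about {plan}?",
            SpeechActKind.JUSTIFY: f"Certainly. {args}",
            SpeechActKind.REBUTTAL: f"I have concerns about {plan}: {args}",
            SpeechActKind.PERSUADE: f"Please consider {plan}: {args}",
            SpeechActKind.ACCEPT: f"I agree to proceed with {plan}.",
            SpeechActKind.REFUSE: f"I cannot accept {plan}.",
            SpeechActKind.RETRACT: f"I withdraw my recommendation of {plan}.",
        }
        return templates[msg.act]


# ---------------------------------------------------------------------------
# Cursor over a protocol AST
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Option:
    """One executable next step: the step, pending guards, and the residual
    continuation stack after taking it."""

    step: Step
    guards: tuple[Constraint, ...]
    residual: tuple[Term, ...]


def _enumerate_options(proto: Protocol, stack: tuple[Term, ...], depth: int = 0) -> list[_Option]:
    if depth > _MAX_EXPANSION_DEPTH:
        raise ProtocolViolation("protocol expansion too deep (unguarded call cycle?)")
    if not stack:
        return []
    head, rest = stack[0], stack[1:]
    if isinstance(head, Step):
        guards = (head.guard,) if head.guard else ()
        return [_Option(head, guards, rest)]
    if isinstance(head, Call):
        clause = proto.clause(head.agent.role_name)
        opts = _enumerate_options(proto, (clause.body,) + rest, depth + 1)
        extra = (head.guard,) if head.guard else ()
        return [_Option(o.step, extra + o.guards, o.residual) for o in opts]
    if isinstance(head, Then):
        return _enumerate_options(proto, (head.first, head.rest) + rest, depth + 1)
    if isinstance(head, Or):
        out: list[_Option] = []
        for b in head.branches:
            out.extend(_enumerate_options(proto, (b,) + rest, depth + 1))
        return out
    raise TypeError(type(head))


# ---------------------------------------------------------------------------
# Policies
# ---------------------------------------------------------------------------

class Policy:
    """Behaviour of one role: guard predicates, message choice, observation.

    A policy, offered the set of protocol-legal next steps, must select
    one of them (returning a concrete message) or decline by returning
    ``None``, which ends the session without agreement.
    """

    role: str

    def eval_predicate(self, session: "Session", constraint: Constraint) -> bool:
        raise NotImplementedError

    def choose(self, session: "Session", options: list[_Option]) -> SpeechActMessage | None:
        raise NotImplementedError

    def observe(self, session: "Session", msg: SpeechActMessage) -> None:
        """Called for every message of the session, both sent and received."""


class DoctorPolicy(Policy):
    """Guideline-driven doctor: justify questions with KB support arguments,
    persuade rebuttals, and retract + substitute after a refusal."""

    role = DOCTOR

    def __init__(self, kb: GuidelineKB):
        self.kb = kb
        self.plan = Proposition(kb.condition, kb.recommended_plan)
        self.pending_plan: Proposition | None = self.plan
        self.contested: str | None = None
        self.rejected: set[str] = set()

    # -- guard predicates -------------------------------------------------
    def eval_predicate(self, session: "Session", c: Constraint) -> bool:
        if c.predicate_name == "has_support":
            return any(find_arguments(self.kb, p, "support") for p in self.plan.plan)
        if c.predicate_name == "has_alternative":
            return self.pending_plan is not None
        raise KeyError(f"doctor policy has no predicate {c.predicate_name!r}")

    # -- behaviour --------------------------------------------------------
    def observe(self, session: "Session", msg: SpeechActMessage) -> None:
        if msg.sender_role == self.role:
            if msg.act is SpeechActKind.ASSERT:
                self.plan = msg.content
            return
        if msg.act is SpeechActKind.REBUTTAL:
            self.contested = msg.content.plan[0]
        elif msg.act is SpeechActKind.REFUSE:
            targets = [p for p in msg.content.plan if p in self.plan.plan] or (
                [self.contested] if self.contested else [])
            if not targets:
                raise ProtocolViolation("refuse does not identify any plan intervention")
            self.rejected.update(targets)
            new_plan: Proposition | None = self.plan
            try:
                for t in targets:
                    new_plan = substitute_alternative(
                        self.kb, new_plan, t, frozenset(self.rejected))
            except NoAlternativeAvailable:
                new_plan = None
            self.pending_plan = new_plan
            self.contested = None

    def choose(self, session: "Session", options: list[_Option]) -> SpeechActMessage | None:
        by_act = {o.step.act: o for o in options}
        if SpeechActKind.RETRACT in by_act:
            return self._msg(SpeechActKind.RETRACT, self.plan)
        if SpeechActKind.ASSERT in by_act:
            assert self.pending_plan is not None
            return self._msg(SpeechActKind.ASSERT, self.pending_plan)
        if SpeechActKind.JUSTIFY in by_act:
            ids = tuple(
                a.id for p in self.plan.plan for a in find_arguments(self.kb, p, "support"))
            return self._msg(SpeechActKind.JUSTIFY, self.plan, ids)
        if SpeechActKind.PERSUADE in by_act and self.contested:
            ids = tuple(a.id for a in find_arguments(self.kb, self.contested, "support"))
            sub = Proposition(self.plan.subject, (self.contested,))
            return self._msg(SpeechActKind.PERSUADE, sub, ids)
        return None

    def _msg(self, act: SpeechActKind, content: Proposition,
             argument_ids: tuple[str, ...] = ()) -> SpeechActMessage:
        return SpeechActMessage(act, content, self.role, PATIENT, argument_ids)


@dataclass
class PatientStance:
    """Configured attitude toward one intervention.

    ``attitude`` is "oppose" (will rebut once; open to persuasion per the
    personality model) or "refuse" (rejects outright whenever asserted).
    ``cite`` selects which KB against-arguments the patient holds when
    rebutting: "all" or an explicit list of argument ids; the cited
    weights form the initial aligned mass of the oppose-stance belief.
    """

    attitude: str
    cite: str | list[str] = "all"

    def __post_init__(self) -> None:
        if self.attitude not in ("oppose", "refuse"):
            raise ValueError(f"attitude must be oppose/refuse, got {self.attitude!r}")


class PatientPolicy(Policy):
    """Patient with a question budget, per-intervention stances, and a
    personality profile driving the response to persuasion."""

    role = PATIENT

    def __init__(
        self,
        kb: GuidelineKB,
        profile: str | dict | PersonalityProfile = "neutral",
        stances: dict[str, PatientStance] | None = None,
        question_budget: int = 0,
    ):
        self.kb = kb
        self.profile = get_profile(profile)
        self.stances = dict(stances or {})
        self.question_budget = int(question_budget)
        self.beliefs: dict[str, BeliefState] = {}
        self.contested: set[str] = set()
        self.persuaded: bool | None = None  # None until a persuade arrives
        self.current_plan: tuple[str, ...] = ()
        for name in self.stances:
            kb.intervention(name)  # fail fast on unknown interventions

    # -- stance helpers ---------------------------------------------------
    def _opposed_pending(self) -> str | None:
        for p in self.current_plan:
            s = self.stances.get(p)
            if s and s.attitude == "oppose" and p not in self.contested:
                return p
        return None

    def _hard_refused(self) -> str | None:
        for p in self.current_plan:
            s = self.stances.get(p)
            if s and s.attitude == "refuse":
                return p
        return None

    def _cited_arguments(self, intervention: str) -> list:
        spec = self.stances[intervention].cite
        against = find_arguments(self.kb, intervention, "against")
        if spec == "all":
            return against
        by_id = {a.id: a for a in against}
        try:
            return [by_id[i] for i in spec]
        except KeyError as exc:
            raise UnknownIntervention(
                f"cited argument {exc.args[0]!r} is not an against-argument of "
                f"{intervention!r}") from None

    # -- guard predicates -------------------------------------------------
    def eval_predicate(self, session: "Session", c: Constraint) -> bool:
        name = c.predicate_name
        if name == "interested_in":
            return self.question_budget > 0
        if name == "opposes":
            return self._opposed_pending() is not None
        if name == "rejects_outright":
            return self._hard_refused() is not None
        if name == "satisfied":
            return (self._hard_refused() is None and self._opposed_pending() is None
                    and self.question_budget <= 0)
        if name == "persuaded":
            return self.persuaded is True
        if name == "unpersuaded":
            return self.persuaded is False
        raise KeyError(f"patient policy has no predicate {name!r}")

    # -- behaviour --------------------------------------------------------
    def observe(self, session: "Session", msg: SpeechActMessage) -> None:
        if msg.sender_role == self.role:
            # own messages: commit the side effects of the chosen act
            if msg.act is SpeechActKind.QUESTION:
                self.question_budget -= 1
            elif msg.act is SpeechActKind.REBUTTAL:
                target = msg.content.plan[0]
                self.contested.add(target)
                self.beliefs[target] = BeliefState(
                    "oppose",
                    aligned_mass=sum(self.kb.argument(a).weight for a in msg.argument_ids))
            return
        if msg.act is SpeechActKind.ASSERT:
            self.current_plan = msg.content.plan
            self.persuaded = None
        elif msg.act is SpeechActKind.PERSUADE:
            target = msg.content.plan[0]
            belief = self.beliefs.get(target, BeliefState("oppose"))
            new_args = [self.kb.argument(a) for a in msg.argument_ids]
            belief = apply_arguments(belief, new_args, "opposing")
            if decide(belief, self.profile) == "flip_stance":
                belief = flipped(belief)
                self.persuaded = True
            else:
                self.persuaded = False
            self.beliefs[target] = belief

    def choose(self, session: "Session", options: list[_Option]) -> SpeechActMessage | None:
        by_act = {o.step.act: o for o in options}
        subject = self.kb.condition
        plan = Proposition(subject, self.current_plan)
        hard = self._hard_refused()
        if SpeechActKind.REFUSE in by_act and hard is not None:
            return self._msg(SpeechActKind.REFUSE, Proposition(subject, (hard,)))
        if SpeechActKind.REFUSE in by_act and self.persuaded is False:
            target = next(iter(
                p for p in self.current_plan if p in self.contested), None)
            content = Proposition(subject, (target,)) if target else plan
            return self._msg(SpeechActKind.REFUSE, content)
        if SpeechActKind.QUESTION in by_act and self.question_budget > 0:
            return self._msg(SpeechActKind.QUESTION, plan)
        opposed = self._opposed_pending()
        if SpeechActKind.REBUTTAL in by_act and opposed is not None:
            cited = self._cited_arguments(opposed)
            return self._msg(
                SpeechActKind.REBUTTAL, Proposition(subject, (opposed,)),
                tuple(a.id for a in cited))
        if SpeechActKind.ACCEPT in by_act:
            return self._msg(SpeechActKind.ACCEPT, plan)
        return None

    def _msg(self, act: SpeechActKind, content: Proposition,
             argument_ids: tuple[str, ...] = ()) -> SpeechActMessage:
        return SpeechActMessage(act, content, self.role, DOCTOR, argument_ids)


# ---------------------------------------------------------------------------
# Session
# ---------------------------------------------------------------------------

@dataclass
class SessionConfig:
    max_turns: int = 50
    seed: int = 0
    realize_text: bool = True


@dataclass
class Session:
    doctor_protocol: Protocol
    patient_protocol: Protocol
    kb: GuidelineKB
    doctor_policy: Policy
    patient_policy: Policy
    config: SessionConfig = field(default_factory=SessionConfig)
    realizer: Callable[[SpeechActMessage, GuidelineKB], str] | None = None

    status: str = "running"
    transcript: Transcript = field(default_factory=Transcript)
    doctor_stack: tuple[Term, ...] = ()
    patient_stack: tuple[Term, ...] = ()

    def __post_init__(self) -> None:
        self.doctor_stack = (self.doctor_protocol.entry.body,)
        self.patient_stack = (self.patient_protocol.entry.body,)
        if self.realizer is None and self.config.realize_text:
            self.realizer = TemplateRealizer()
        self.transcript.metadata.setdefault("seed", self.config.seed)
        self.transcript.metadata.setdefault("condition", self.kb.condition)

    @property
    def turn_count(self) -> int:
        return len(self.transcript.messages)

    def policy_for(self, role: str) -> Policy:
        return self.doctor_policy if role == DOCTOR else self.patient_policy

    # -- option enumeration ----------------------------------------------
    def _guards_hold(self, role: str, option: _Option) -> bool:
        policy = self.policy_for(role)
        return all(policy.eval_predicate(self, g) for g in option.guards)

    def _options(self, role: str, kind: str, guarded: bool = True) -> list[_Option]:
        proto = self.doctor_protocol if role == DOCTOR else self.patient_protocol
        stack = self.doctor_stack if role == DOCTOR else self.patient_stack
        opts = [o for o in _enumerate_options(proto, stack) if o.step.kind == kind]
        if guarded:
            opts = [o for o in opts if self._guards_hold(role, o)]
        return opts

    def expected_speaker(self) -> str | None:
        """The role holding the turn, or None when the dialogue has ended."""
        doc = self._options(DOCTOR, "send")
        pat = self._options(PATIENT, "send")
        if doc and not pat:
            return DOCTOR
        if pat and not doc:
            return PATIENT
        if not doc and not pat:
            return None
        # Both have sends (should not occur with disjoint protocols):
        # fall back to alternation — the receiver of the last message replies.
        last = self.transcript.messages[-1] if self.transcript.messages else None
        return last.receiver_role if last else DOCTOR

    def legal_next_acts(self, role: str) -> frozenset[SpeechActKind]:
        return frozenset(o.step.act for o in self._options(role, "send"))

    # -- termination ------------------------------------------------------
    def _finalize_if_ended(self) -> None:
        if self.status != "running":
            return
        if self.transcript.messages and \
                self.transcript.messages[-1].act is SpeechActKind.ACCEPT:
            self.status = "agreed"
        elif self.expected_speaker() is None:
            self.status = "no_agreement"
        self.transcript.final_status = self.status

    def end(self, status: str) -> None:
        self.status = status
        self.transcript.final_status = status


def step(session: Session, chosen_act: SpeechActMessage) -> Session:
    """Apply one message to the session (single-transition granularity).

    Raises :class:`NotYourTurn`, :class:`IllegalPair`,
    :class:`ProtocolViolation` or :class:`TurnLimitExceeded`; on success
    the history is extended, cursors advance, and status is updated.
    """
    if session.status != "running":
        raise ProtocolViolation(f"session already ended with status {session.status!r}")
    if session.turn_count >= session.config.max_turns:
        session.end("violated")
        raise TurnLimitExceeded(f"max_turns={session.config.max_turns} reached")
    speaker = session.expected_speaker()
    if speaker is None:
        raise ProtocolViolation("no agent can move; the dialogue has ended")
    if chosen_act.sender_role != speaker:
        raise NotYourTurn(f"it is the {speaker}'s turn, not the {chosen_act.sender_role}'s")

    last = session.transcript.messages[-1] if session.transcript.messages else None
    if last is not None:
        same = last.sender_role == chosen_act.sender_role
        verdict = validate_pair(last.act, chosen_act.act, same_speaker=same)
        if not verdict.legal:
            session.end("violated")
            raise IllegalPair(
                f"({last.act.value}, {chosen_act.act.value}): {verdict.rationale}")

    send_opts = [o for o in session._options(speaker, "send")
                 if o.step.act is chosen_act.act]
    if not send_opts:
        session.end("violated")
        raise ProtocolViolation(
            f"{speaker} may not send {chosen_act.act.value} at this point")
    listener = PATIENT if speaker == DOCTOR else DOCTOR
    recv_opts = [o for o in session._options(listener, "receive")
                 if o.step.act is chosen_act.act]
    if not recv_opts:
        session.end("violated")
        raise ProtocolViolation(
            f"{listener} protocol has no receive matching {chosen_act.act.value}")

    if session.realizer is not None and chosen_act.surface_text is None:
        chosen_act = SpeechActMessage(
            chosen_act.act, chosen_act.content, chosen_act.sender_role,
            chosen_act.receiver_role, chosen_act.argument_ids,
            session.realizer(chosen_act, session.kb))

    if speaker == DOCTOR:
        session.doctor_stack = send_opts[0].residual
        session.patient_stack = recv_opts[0].residual
    else:
        session.patient_stack = send_opts[0].residual
        session.doctor_stack = recv_opts[0].residual

    session.transcript.messages.append(chosen_act)
    session.doctor_policy.observe(session, chosen_act)
    session.patient_policy.observe(session, chosen_act)
    logger.info("turn %d: %s -> %s %s(%s)", session.turn_count,
                chosen_act.sender_role, chosen_act.receiver_role,
                chosen_act.act.value, " + ".join(chosen_act.content.plan))
    session._finalize_if_ended()
    return session


def run_session(
    doctor_ast: Protocol,
    patient_ast: Protocol,
    kb: GuidelineKB,
    doctor_policy: Policy,
    patient_policy: Policy,
    config: SessionConfig | None = None,
) -> Transcript:
    """Execute the two protocols to completion and return the transcript.

    Deterministic given the seed and inputs; every adjacent act pair in
    the result is legal (same-speaker retract → assert included).
    """
    config = config or SessionConfig()
    session = Session(doctor_ast, patient_ast, kb, doctor_policy, patient_policy, config)
    session.transcript.metadata.setdefault("max_turns", config.max_turns)
    while session.status == "running":
        if session.turn_count >= config.max_turns:
            raise TurnLimitExceeded(f"max_turns={config.max_turns} reached")
        speaker = session.expected_speaker()
        if speaker is None:
            session._finalize_if_ended()
            break
        options = session._options(speaker, "send")
        msg = session.policy_for(speaker).choose(session, options)
        if msg is None:
            session.end("no_agreement")
            break
        step(session, msg)
    return session.transcript
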