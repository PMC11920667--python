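"""Speech-act kinds and the legal interaction-pair constraint registry.

Shared decision-making dialogues are built from eight performatives
(assert, accept, refuse, question, justify, rebuttal, persuade, retract).
Acts do not combine freely: a constraint table declares which ordered
(previous, next) pairs form coherent exchanges, and two pairings are
explicitly prohibited as violations of behavioural logic — answering a
*refuse* with *persuade* (a refusal is a definitive rejection that admits
no response), and answering an *assert* with *justify* (one agent cannot
supply the justification for another agent's assertion).

The registry holds exactly 14 legal response pairs.  One compound row —
*refuse → retract + assert* — is encoded as the legal pair
``(refuse, retract)`` plus a *same-speaker continuation*: an agent that
has just retracted may immediately follow up with a fresh assertion based
on the remaining alternatives.  The continuation is not a response pair,
so it is excluded from :func:`allowed_responses`; pass
``same_speaker=True`` to :func:`validate_pair` to admit it when auditing
transcripts.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "SpeechActKind",
    "Proposition",
    "SpeechActMessage",
    "PairRegistry",
    "PairValidation",
    "DECISION_ACTS",
    "legal_pairs",
    "validate_pair",
    "allowed_responses",
    "audit_transcript_acts",
]


class SpeechActKind(str, enum.Enum):
    """The eight performatives of the decision-making process."""

    ASSERT = "assert"
    ACCEPT = "accept"
    REFUSE = "refuse"
    QUESTION = "question"
    JUSTIFY = "justify"
    REBUTTAL = "rebuttal"
    PERSUADE = "persuade"
    RETRACT = "retract"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The two acts that settle a negotiation round: accept or reject.
DECISION_ACTS = frozenset({SpeechActKind.ACCEPT, SpeechActKind.REFUSE})


@dataclass(frozen=True)
class Proposition:
    """A decision proposition: a condition plus an ordered treatment plan.

    ``plan`` is the conjunction of interventions (the "surgery1 + surgery2"
    form).  Order is preserved for display but insignificant for equality.
    Rebuttal and persuade messages may carry a sub-plan (typically the
    single contested intervention).
    """

    subject: str
    plan: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "plan", tuple(self.plan))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Proposition):
            return NotImplemented
        return self.subject == other.subject and set(self.plan) == set(other.plan)

    def __hash__(self) -> int:
        return hash((self.subject, frozenset(self.plan)))

    def replace_intervention(self, old: str, new: str) -> "Proposition":
        """Return a copy with ``old`` swapped for ``new`` in place."""
        return Proposition(self.subject, tuple(new if p == old else p for p in self.plan))

    def drop_intervention(self, old: str) -> "Proposition":
        return Proposition(self.subject, tuple(p for p in self.plan if p != old))


@dataclass(frozen=True)
class SpeechActMessage:
    """One performative exchanged between the two roles.

    Justify and persuade must carry at least one supporting argument
    reference — they exist to "provide reasonable explanations".
    """

    act: SpeechActKind
    content: Proposition
    sender_role: str
    receiver_role: str
    argument_ids: tuple[str, ...] = ()
    surface_text: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "argument_ids", tuple(self.argument_ids))
        if self.sender_role == self.receiver_role:
            raise ValueError("sender_role and receiver_role must differ")
        if self.act in (SpeechActKind.JUSTIFY, SpeechActKind.PERSUADE) and not self.argument_ids:
            raise ValueError(f"{self.act.value} messages must carry at least one argument id")
        if self.act in (SpeechActKind.ASSERT, SpeechActKind.RETRACT) and not self.content.plan:
            raise ValueError(f"{self.act.value} messages require a non-empty plan")


# The 14 legal response pairs with their rationale (table row order preserved).
_LEGAL_ROWS: tuple[tuple[SpeechActKind, SpeechActKind, str], ...] = (
    (SpeechActKind.ASSERT, SpeechActKind.ACCEPT,
     "The receiver evaluates the assertion as reasonable and feasible and sends an "
     "acceptance to explicitly express agreement."),
    (SpeechActKind.ASSERT, SpeechActKind.REFUSE,
     "The receiver cannot accept the assertion and sends a rejection to explicitly "
     "indicate non-acceptance."),
    (SpeechActKind.ASSERT, SpeechActKind.QUESTION,
     "The receiver explores the rationality of the assertion further by sending a "
     "challenge message."),
    (SpeechActKind.ASSERT, SpeechActKind.REBUTTAL,
     "The receiver disagrees with the assertion and sends a rebuttal."),
    (SpeechActKind.REFUSE, SpeechActKind.RETRACT,
     "The agent that receives a rejection withdraws its previous assertion and may "
     "then choose to send a new assertion based on the current alternatives."),
    (SpeechActKind.QUESTION, SpeechActKind.JUSTIFY,
     "The challenged agent sends a confirmation containing supporting arguments to "
     "alleviate the challenge."),
    (SpeechActKind.JUSTIFY, SpeechActKind.QUESTION,
     "Doubts remaining after a confirmation can be pursued with further inquiries."),
    (SpeechActKind.JUSTIFY, SpeechActKind.REBUTTAL,
     "The receiver of the confirmation disagrees with the supporting information and "
     "sends a rebuttal."),
    (SpeechActKind.REBUTTAL, SpeechActKind.PERSUADE,
     "The rebutted agent sends a persuasive message to try to change the other "
     "party's mind and guide it toward accepting the assertion."),
    (SpeechActKind.PERSUADE, SpeechActKind.QUESTION,
     "Doubts about the persuasion argument are raised with a questioning message."),
    (SpeechActKind.PERSUADE, SpeechActKind.ACCEPT,
     "A receiver that deems the persuasive argument valid sends an acceptance: it has "
     "been persuaded and agrees to the assertion."),
    (SpeechActKind.PERSUADE, SpeechActKind.REFUSE,
     "A receiver that deems the persuasive argument invalid sends a rejection: it is "
     "not persuaded and refuses the assertion."),
    (SpeechActKind.JUSTIFY, SpeechActKind.ACCEPT,
     "After evaluating the confirmation and finding no objection, the agent accepts "
     "the assertion."),
    (SpeechActKind.JUSTIFY, SpeechActKind.REFUSE,
     "An agent that still cannot accept the confirmation's contents rejects the "
     "assertion."),
)

_CONTINUATION = (SpeechActKind.RETRACT, SpeechActKind.ASSERT)
_CONTINUATION_RATIONALE = (
    "Same-speaker continuation of the refuse-retract row: after withdrawing its "
    "assertion the agent may immediately propose a new plan from the alternatives."
)


@dataclass(frozen=True)
class PairRegistry:
    """Immutable table of legal interaction pairs.

    ``legal`` is the 14-row response relation; ``continuations`` holds the
    one same-speaker follow-up (retract → assert); ``terminal`` lists acts
    with no legal successor of any kind.
    """

    legal: frozenset[tuple[SpeechActKind, SpeechActKind]]
    continuations: frozenset[tuple[SpeechActKind, SpeechActKind]]
    terminal: frozenset[SpeechActKind]
    rationale: dict[tuple[SpeechActKind, SpeechActKind], str] = field(compare=False, default_factory=dict)

    def to_records(self) -> list[dict]:
        """Export the registry as plain records (single source of truth for docs)."""
        recs = [
            {"prev": p.value, "next": n.value, "relation": "response", "description": d}
            for p, n, d in _LEGAL_ROWS
        ]
        recs.append({
            "prev": _CONTINUATION[0].value, "next": _CONTINUATION[1].value,
            "relation": "same_speaker_continuation", "description": _CONTINUATION_RATIONALE,
        })
        return recs

    def to_json(self) -> str:
        return json.dumps(self.to_records(), indent=2)

    @staticmethod
    def from_records(records: Iterable[dict]) -> "PairRegistry":
        legal, cont, rationale = set(), set(), {}
        for rec in records:
            pair = (SpeechActKind(rec["prev"]), SpeechActKind(rec["next"]))
            rationale[pair] = rec.get("description", "")
            if rec.get("relation") == "same_speaker_continuation":
                cont.add(pair)
            else:
                legal.add(pair)
        successors = {p for p, _ in legal} | {p for p, _ in cont}
        terminal = frozenset(k for k in SpeechActKind if k not in successors)
        return PairRegistry(frozenset(legal), frozenset(cont), terminal, rationale)


_REGISTRY = PairRegistry.from_records(
    [{"prev": p.value, "next": n.value, "description": d} for p, n, d in _LEGAL_ROWS]
    + [{"prev": _CONTINUATION[0].value, "next": _CONTINUATION[1].value,
        "relation": "same_speaker_continuation", "description": _CONTINUATION_RATIONALE}]
)


def legal_pairs() -> PairRegistry:
    """Return the immutable interaction-pair registry (14 response rows)."""
    return _REGISTRY


@dataclass(frozen=True)
class PairValidation:
    legal: bool
    rationale: str

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.legal


def _coerce(kind: SpeechActKind | str) -> SpeechActKind:
    if isinstance(kind, SpeechActKind):
        return kind
    try:
        return SpeechActKind(kind)
    except ValueError as exc:
        from .errors import UnknownActKind

        raise UnknownActKind(f"not a speech-act kind: {kind!r}") from exc


def validate_pair(
    prev: SpeechActKind | str,
    next: SpeechActKind | str,
    *,
    same_speaker: bool = False,
) -> PairValidation:
    """Check whether ``(prev, next)`` is a permissible interaction pair.

    With ``same_speaker=True`` the retract → assert continuation is also
    admitted; by default only the 14 response pairs are legal.
    """
    prev, next = _coerce(prev), _coerce(next)
    pair = (prev, next)
    if pair in _REGISTRY.legal:
        return PairValidation(True, _REGISTRY.rationale[pair])
    if same_speaker and pair in _REGISTRY.continuations:
        return PairValidation(True, _REGISTRY.rationale[pair])
    if pair == (SpeechActKind.REFUSE, SpeechActKind.PERSUADE):
        return PairValidation(False, "A refuse expresses a definitive rejection that admits "
                                     "no response; persuading after it is logically invalid.")
    if pair == (SpeechActKind.ASSERT, SpeechActKind.JUSTIFY):
        return PairValidation(False, "An agent cannot reply to another agent's assertion by "
                                     "supplying its justification; this violates behavioural logic.")
    return PairValidation(False, f"({prev.value}, {next.value}) is not a permissible interaction pair.")


def allowed_responses(prev: SpeechActKind | str) -> frozenset[SpeechActKind]:
    """All acts that may legally answer ``prev`` (different speaker)."""
    prev = _coerce(prev)
    return frozenset(n for p, n in _REGISTRY.legal if p == prev)


def audit_transcript_acts(
    acts: Iterable[tuple[str, SpeechActKind | str]],
) -> list[tuple[int, SpeechActKind, SpeechActKind]]:
    """Audit adjacent pairs of ``(sender_role, act)`` records for legality.

    Returns the list of offending positions; empty means fully legal.
    The same-speaker continuation is honoured when adjacent records share
    a sender role.
    """
    seq = [(role, _coerce(act)) for role, act in acts]
    bad = []
    for i in range(1, len(seq)):
        (prev_role, prev_act), (role, act) = seq[i - 1], seq[i]
        if not validate_pair(prev_act, act, same_speaker=prev_role == role).legal:
            bad.append((i, prev_act, act))
    return bad
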