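"""Shared test utilities: seeded random protocol-AST generation."""

from __future__ import annotations

import random

from codel.protocol_lang import (
    AgentHeader,
    Call,
    Clause,
    Constraint,
    Or,
    Protocol,
    Step,
    Then,
)
from codel.speech_acts import SpeechActKind

_ACTS = list(SpeechActKind)
_SYMBOLS = [f"sym{i}" for i in range(8)] + ["disease", "surgery1", "surgery2"]


def _header(rng: random.Random, roles: list[str]) -> AgentHeader:
    return AgentHeader(
        role_name=rng.choice(roles),
        knowledge=tuple(rng.sample(_SYMBOLS, rng.randint(0, 2))),
        agent_var=rng.choice(["D", "P", "X", "Agent1"]),
    )


def _conj(rng: random.Random) -> tuple[str, ...]:
    return tuple(rng.choice(_SYMBOLS) for _ in range(rng.randint(1, 3)))


def _guard(rng: random.Random) -> Constraint | None:
    if rng.random() < 0.4:
        return Constraint(
            rng.choice(["interested_in", "has_support", "satisfied", "p"]),
            tuple(_conj(rng) for _ in range(rng.randint(0, 2))))
    return None


def _step(rng: random.Random, roles: list[str]) -> Step:
    return Step(
        kind=rng.choice(["send", "receive"]),
        act=rng.choice(_ACTS),
        args=tuple(_conj(rng) for _ in range(rng.randint(0, 3))),
        peer=_header(rng, roles),
        guard=_guard(rng),
    )


def _term(rng: random.Random, roles: list[str], depth: int):
    kinds = ["step", "call"]
    if depth > 0:
        kinds += ["then", "or"]
    kind = rng.choice(kinds)
    if kind == "step":
        return _step(rng, roles)
    if kind == "call":
        return Call(_header(rng, roles), _guard(rng))
    if kind == "then":  # right-associated chain, as the parser normalizes
        first = _term(rng, roles, 0) if rng.random() < 0.7 else Or(
            tuple(_term(rng, roles, 0) for _ in range(2)))
        return Then(first, _term(rng, roles, depth - 1))
    return Or(tuple(_term(rng, roles, depth - 1) for _ in range(rng.randint(2, 3))))


def random_protocol(rng: random.Random) -> Protocol:
    """A random, syntactically valid protocol AST (for roundtrip testing)."""
    n = rng.randint(1, 3)
    roles = [f"role{i}" for i in range(n)]
    return Protocol(tuple(
        Clause(AgentHeader(roles[i],
                           tuple(rng.sample(_SYMBOLS, rng.randint(0, 2))), "X"),
               _term(rng, roles, rng.randint(1, 3)))
        for i in range(n)))
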