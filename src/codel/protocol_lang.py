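"""Concrete syntax, parser, serializer and static checker for CoDeL protocols.

A CoDeL protocol file defines the behaviour of one role as a set of
clauses in the Lightweight-Social-Calculus style::

    # doctor, opening clause
    a(doctor(guideline), D) ::
        assert(disease, plan) => a(patient(), P)
        then a(doctor_responding(), D)

Each clause is ``<agent header> :: <body>``.  The body composes steps with
``then`` (sequence; the clause before it must continue with the clause
after it) and ``or`` (committed choice; only one branch is selected),
with ``then`` binding tighter than ``or``.  Steps are message sends
(``msg => a(peer(), X)``) or receives (``msg <= a(peer(), X)``); a trailing
``<- pred(args)`` attaches a guard constraint that must resolve true for
the step to execute.  A bare agent header in a body position is a role
call — the protocol continues as that role's clause, which is how the
feedback loops of the interaction model (repeated questioning, renewed
assertion after a retraction) are expressed.

The ASCII dialect transliterates the publication glyphs deterministically:
"⇒" → "=>", "⇐" → "<=", "←" → "<-", and multi-word predicate names use
underscores.  Files are UTF-8 with ``#`` line comments, extension
``.codel``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator

from .errors import ProtocolSyntaxError, UnknownActKind
from .speech_acts import SpeechActKind, validate_pair

__all__ = [
    "AgentHeader", "Constraint", "Step", "Call", "Then", "Or", "Clause",
    "Protocol", "Violation", "parse_protocol", "serialize", "check_protocol",
]

ACT_NAMES = frozenset(k.value for k in SpeechActKind)
_IDENT = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")


# ---------------------------------------------------------------------------
# AST
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgentHeader:
    """``a(role(knowledge...), Var)`` — role name, intrinsic knowledge, agent id."""

    role_name: str
    knowledge: tuple[str, ...] = ()
    agent_var: str = "X"

    def __post_init__(self) -> None:
        object.__setattr__(self, "knowledge", tuple(self.knowledge))


@dataclass(frozen=True)
class Constraint:
    """A guard predicate ``name(arg, ...)`` that must resolve true.

    Each argument is a conjunction of symbols, so guards range over whole
    plans: ``interested_in(disease, surgery1 + surgery2)`` is a 2-ary
    guard whose second argument is the plan conjunction.
    """

    predicate_name: str
    arguments: tuple[tuple[str, ...], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "arguments", tuple(tuple(a) for a in self.arguments))


# A message argument is a conjunction of symbols ("surgery1 + surgery2").
MsgArg = tuple[str, ...]


@dataclass(frozen=True)
class Step:
    """A single send or receive of an act pattern to/from a peer."""

    kind: str  # "send" | "receive"
    act: SpeechActKind
    args: tuple[MsgArg, ...]
    peer: AgentHeader
    guard: Constraint | None = None
    line: int | None = field(default=None, compare=False)
    column: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in ("send", "receive"):
            raise ValueError(f"step kind must be send/receive, got {self.kind!r}")
        object.__setattr__(self, "args", tuple(tuple(a) for a in self.args))


@dataclass(frozen=True)
class Call:
    """A role call: continue as the named role's clause."""

    agent: AgentHeader
    guard: Constraint | None = None


@dataclass(frozen=True)
class Then:
    """Sequence: ``first`` must continue with ``rest`` (right-associated)."""

    first: "Term"
    rest: "Term"


@dataclass(frozen=True)
class Or:
    """Committed choice between two or more alternative branches."""

    branches: tuple["Term", ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "branches", tuple(self.branches))
        if len(self.branches) < 2:
            raise ValueError("an OR node needs at least two branches")


Term = Step | Call | Then | Or


@dataclass(frozen=True)
class Clause:
    """One role clause: agent header plus a step tree."""

    header: AgentHeader
    body: Term


@dataclass(frozen=True)
class Protocol:
    """A parsed protocol file: the clauses of one role, entry clause first."""

    clauses: tuple[Clause, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "clauses", tuple(self.clauses))
        if not self.clauses:
            raise ValueError("a protocol needs at least one clause")

    @property
    def entry(self) -> Clause:
        return self.clauses[0]

    def clause(self, role_name: str) -> Clause:
        for c in self.clauses:
            if c.header.role_name == role_name:
                return c
        raise KeyError(role_name)

    @property
    def role_names(self) -> frozenset[str]:
        return frozenset(c.header.role_name for c in self.clauses)


# ---------------------------------------------------------------------------
# Tokenizer
# ---------------------------------------------------------------------------

_TOKEN_SPEC = [
    ("DCOLON", r"::"),
    ("SEND", r"=>"),
    ("RECV", r"<="),
    ("GUARD", r"<-"),
    ("LPAR", r"\("),
    ("RPAR", r"\)"),
    ("COMMA", r","),
    ("PLUS", r"\+"),
    ("IDENT", r"[A-Za-z_][A-Za-z0-9_]*"),
]
_MASTER = re.compile("|".join(f"(?P<{n}>{p})" for n, p in _TOKEN_SPEC))


@dataclass(frozen=True)
class _Tok:
    type: str
    value: str
    line: int
    column: int


def _tokenize(text: str) -> Iterator[_Tok]:
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0]
        pos = 0
        while pos < len(line):
            if line[pos].isspace():
                pos += 1
                continue
            m = _MASTER.match(line, pos)
            if not m:
                raise ProtocolSyntaxError(f"unexpected character {line[pos]!r}", lineno, pos + 1)
            yield _Tok(m.lastgroup, m.group(), lineno, pos + 1)
            pos = m.end()


class _Parser:
    """Recursive-descent parser for the grammar above (LL(2))."""

    def __init__(self, text: str):
        self.toks = list(_tokenize(text))
        self.i = 0

    def _peek(self, k: int = 0) -> _Tok | None:
        j = self.i + k
        return self.toks[j] if j < len(self.toks) else None

    def _next(self) -> _Tok:
        tok = self._peek()
        if tok is None:
            last = self.toks[-1] if self.toks else None
            raise ProtocolSyntaxError(
                "unexpected end of input",
                last.line if last else 1, last.column if last else 1)
        self.i += 1
        return tok

    def _expect(self, type_: str, what: str | None = None) -> _Tok:
        tok = self._next()
        if tok.type != type_:
            raise ProtocolSyntaxError(
                f"expected {what or type_}, found {tok.value!r}", tok.line, tok.column)
        return tok

    def parse(self) -> Protocol:
        if not self.toks:
            raise ProtocolSyntaxError("empty protocol source", 1, 1)
        clauses = []
        while self._peek() is not None:
            clauses.append(self._clause())
        return Protocol(tuple(clauses))

    def _clause(self) -> Clause:
        header = self._agent()
        self._expect("DCOLON", "'::'")
        body = self._or_expr()
        return Clause(header, body)

    def _agent(self) -> AgentHeader:
        tok = self._expect("IDENT", "agent header 'a(...)'")
        if tok.value != "a":
            raise ProtocolSyntaxError(
                f"malformed agent header: expected 'a', found {tok.value!r}", tok.line, tok.column)
        self._expect("LPAR")
        role = self._expect("IDENT", "role name").value
        self._expect("LPAR")
        knowledge = []
        if self._peek() and self._peek().type == "IDENT":
            knowledge.append(self._next().value)
            while self._peek() and self._peek().type == "COMMA":
                self._next()
                knowledge.append(self._expect("IDENT", "knowledge symbol").value)
        self._expect("RPAR")
        self._expect("COMMA", "',' before agent id")
        var = self._expect("IDENT", "agent id").value
        self._expect("RPAR")
        return AgentHeader(role, tuple(knowledge), var)

    def _or_expr(self) -> Term:
        branches = [self._then_expr()]
        while self._at_keyword("or"):
            self._next()
            branches.append(self._then_expr())
        return branches[0] if len(branches) == 1 else Or(tuple(branches))

    def _then_expr(self) -> Term:
        terms = [self._term()]
        while self._at_keyword("then"):
            self._next()
            terms.append(self._term())
        node = terms[-1]
        for t in reversed(terms[:-1]):  # right-associate
            node = Then(t, node)
        return node

    def _at_keyword(self, kw: str) -> bool:
        tok = self._peek()
        return tok is not None and tok.type == "IDENT" and tok.value == kw

    def _term(self) -> Term:
        tok = self._peek()
        if tok is None:
            raise ProtocolSyntaxError("unexpected end of input in clause body", 1, 1)
        if tok.type == "LPAR":
            self._next()
            inner = self._or_expr()
            self._expect("RPAR", "')'")
            return inner
        if tok.type != "IDENT":
            raise ProtocolSyntaxError(f"expected a step, found {tok.value!r}", tok.line, tok.column)
        if tok.value == "a":
            agent = self._agent()
            return Call(agent, self._maybe_guard())
        return self._step()

    def _step(self) -> Step:
        tok = self._expect("IDENT", "act name")
        if tok.value not in ACT_NAMES:
            raise UnknownActKind(
                f"unknown act kind {tok.value!r} at line {tok.line}, column {tok.column}")
        act = SpeechActKind(tok.value)
        self._expect("LPAR")
        args: list[MsgArg] = []
        if self._peek() and self._peek().type == "IDENT":
            args.append(self._conjunction())
            while self._peek() and self._peek().type == "COMMA":
                self._next()
                args.append(self._conjunction())
        self._expect("RPAR")
        d = self._next()
        if d.type not in ("SEND", "RECV"):
            raise ProtocolSyntaxError(f"expected '=>' or '<=', found {d.value!r}", d.line, d.column)
        peer = self._agent()
        return Step(
            kind="send" if d.type == "SEND" else "receive",
            act=act, args=tuple(args), peer=peer,
            guard=self._maybe_guard(), line=tok.line, column=tok.column)

    def _conjunction(self) -> MsgArg:
        parts = [self._expect("IDENT", "symbol").value]
        while self._peek() and self._peek().type == "PLUS":
            self._next()
            parts.append(self._expect("IDENT", "symbol").value)
        return tuple(parts)

    def _maybe_guard(self) -> Constraint | None:
        tok = self._peek()
        if tok is None or tok.type != "GUARD":
            return None
        self._next()
        name = self._expect("IDENT", "guard predicate name").value
        self._expect("LPAR")
        args: list[MsgArg] = []
        if self._peek() and self._peek().type == "IDENT":
            args.append(self._conjunction())
            while self._peek() and self._peek().type == "COMMA":
                self._next()
                args.append(self._conjunction())
        self._expect("RPAR")
        return Constraint(name, tuple(args))


def parse_protocol(text: str) -> Protocol:
    """Parse CoDeL source into a :class:`Protocol` AST.

    Raises :class:`ProtocolSyntaxError` with line/column on malformed
    input and :class:`UnknownActKind` for act names outside the eight.
    """
    return _Parser(text).parse()


# ---------------------------------------------------------------------------
# Serializer (normalized layout; parse∘serialize = identity on ASTs)
# ---------------------------------------------------------------------------

def _ser_agent(a: AgentHeader) -> str:
    return f"a({a.role_name}({', '.join(a.knowledge)}), {a.agent_var})"


def _ser_guard(g: Constraint | None) -> str:
    if g is None:
        return ""
    return f" <- {g.predicate_name}({', '.join(' + '.join(a) for a in g.arguments)})"


def _ser_term(t: Term, indent: int) -> str:
    pad = "    " * indent
    if isinstance(t, Step):
        arrow = "=>" if t.kind == "send" else "<="
        args = ", ".join(" + ".join(a) for a in t.args)
        return f"{pad}{t.act.value}({args}) {arrow} {_ser_agent(t.peer)}{_ser_guard(t.guard)}"
    if isinstance(t, Call):
        return f"{pad}{_ser_agent(t.agent)}{_ser_guard(t.guard)}"
    if isinstance(t, Then):
        return f"{_ser_term(t.first, indent)}\n{pad}then\n{_ser_term(t.rest, indent)}"
    if isinstance(t, Or):
        inner = f"\n{pad}or\n".join(_ser_term(b, indent + 1) for b in t.branches)
        return f"{pad}(\n{inner}\n{pad})"
    raise TypeError(type(t))


def serialize(protocol: Protocol) -> str:
    """Render a Protocol back to normalized CoDeL source (stable layout)."""
    out = []
    for c in protocol.clauses:
        out.append(f"{_ser_agent(c.header)} ::")
        out.append(_ser_term(c.body, 1))
        out.append("")
    return "\n".join(out)


# ---------------------------------------------------------------------------
# Static checker
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    """One static-check finding. ``severity`` is "error" or "warning"."""

    code: str
    message: str
    severity: str = "error"


def _iter_steps(t: Term) -> Iterator[Step]:
    if isinstance(t, Step):
        yield t
    elif isinstance(t, Then):
        yield from _iter_steps(t.first)
        yield from _iter_steps(t.rest)
    elif isinstance(t, Or):
        for b in t.branches:
            yield from _iter_steps(b)


def _iter_calls(t: Term) -> Iterator[Call]:
    if isinstance(t, Call):
        yield t
    elif isinstance(t, Then):
        yield from _iter_calls(t.first)
        yield from _iter_calls(t.rest)
    elif isinstance(t, Or):
        for b in t.branches:
            yield from _iter_calls(b)


def _iter_guards(t: Term) -> Iterator[Constraint]:
    for s in _iter_steps(t):
        if s.guard:
            yield s.guard
    for c in _iter_calls(t):
        if c.guard:
            yield c.guard


def _first_events(proto: Protocol, t: Term, seen: frozenset[str]) -> set[tuple[SpeechActKind, str, bool]]:
    """First (act, kind, guarded) events reachable from term ``t``.

    Role calls are expanded through the clause table; ``seen`` breaks
    recursion through cycles of calls.
    """
    if isinstance(t, Step):
        return {(t.act, t.kind, t.guard is not None)}
    if isinstance(t, Call):
        if t.agent.role_name in seen or t.agent.role_name not in proto.role_names:
            return set()
        clause = proto.clause(t.agent.role_name)
        return _first_events(proto, clause.body, seen | {t.agent.role_name})
    if isinstance(t, Then):
        return _first_events(proto, t.first, seen)
    if isinstance(t, Or):
        out: set[tuple[SpeechActKind, str, bool]] = set()
        for b in t.branches:
            out |= _first_events(proto, b, seen)
        return out
    raise TypeError(type(t))


def _adjacent_pairs(proto: Protocol) -> Iterator[tuple[Step, SpeechActKind, str]]:
    """Yield (step, following act, following kind) for every adjacency,
    following THEN sequencing, OR branching and role calls one level deep."""

    def walk(t: Term, followers: set[tuple[SpeechActKind, str, bool]]) -> Iterator:
        if isinstance(t, Step):
            for act, kind, _ in followers:
                yield t, act, kind
        elif isinstance(t, Call):
            return
        elif isinstance(t, Then):
            yield from walk(t.first, _first_events(proto, t.rest, frozenset()))
            yield from walk(t.rest, followers)
        elif isinstance(t, Or):
            for b in t.branches:
                yield from walk(b, followers)

    for clause in proto.clauses:
        yield from walk(clause.body, set())
    # adjacencies across a role call boundary: last step before the call vs
    # the called clause's first events — covered by Then(first=..., rest=Call)
    # in walk above via _first_events' call expansion.


def check_protocol(
    doctor: Protocol,
    patient: Protocol,
    known_predicates: set[str] | frozenset[str] | None = None,
) -> list[Violation]:
    """Statically check a doctor/patient protocol bundle.

    Checks (a) send/receive matching between the two protocols (same act,
    compatible argument pattern, i.e. same arity), (b) legality of every
    adjacent act pair along THEN/OR paths including pairs across role
    calls (send-send adjacency is checked under the same-speaker rule),
    (c) registration of every guard predicate, and (d) act/guard
    disjointness of OR branches (ambiguity is a warning).  Violations are
    returned as data; an empty list means the bundle is clean.
    """
    violations: list[Violation] = []

    # (a) message matching
    def signatures(p: Protocol, kind: str) -> set[tuple[SpeechActKind, int]]:
        return {(s.act, len(s.args)) for c in p.clauses for s in _iter_steps(c.body) if s.kind == kind}

    for name, src, dst in (("doctor", doctor, patient), ("patient", patient, doctor)):
        recvs = signatures(dst, "receive")
        for act, arity in sorted(signatures(src, "send"), key=lambda x: x[0].value):
            if (act, arity) not in recvs:
                violations.append(Violation(
                    "unmatched-message",
                    f"{name} sends {act.value}/{arity} but the counterpart has no "
                    f"matching receive"))

    # (b) pair legality along paths
    for name, proto in (("doctor", doctor), ("patient", patient)):
        seen_pairs = set()
        for step, nxt_act, nxt_kind in _adjacent_pairs(proto):
            # send-send: this role speaks twice; receive-receive: the peer does.
            same_speaker = step.kind == nxt_kind
            key = (step.act, nxt_act, same_speaker)
            if key in seen_pairs:
                continue
            seen_pairs.add(key)
            result = validate_pair(step.act, nxt_act, same_speaker=same_speaker)
            if not result.legal:
                violations.append(Violation(
                    "illegal-pair",
                    f"{name}: ({step.act.value}, {nxt_act.value}) along a protocol path "
                    f"is not a permissible interaction pair"))

    # (c) guard predicates
    if known_predicates is not None:
        for name, proto in (("doctor", doctor), ("patient", patient)):
            for clause in proto.clauses:
                for g in _iter_guards(clause.body):
                    if g.predicate_name not in known_predicates:
                        violations.append(Violation(
                            "unknown-predicate",
                            f"{name}: guard predicate {g.predicate_name}/"
                            f"{len(g.arguments)} is not registered"))

    # (c') dangling role calls
    for name, proto in (("doctor", doctor), ("patient", patient)):
        for clause in proto.clauses:
            for call in _iter_calls(clause.body):
                if call.agent.role_name not in proto.role_names:
                    violations.append(Violation(
                        "unknown-role",
                        f"{name}: role call a({call.agent.role_name}(), ...) has no clause"))

    # (d) OR-branch disjointness (warning only)
    def check_or(proto: Protocol, name: str, t: Term) -> None:
        if isinstance(t, Or):
            firsts = [frozenset(_first_events(proto, b, frozenset())) for b in t.branches]
            for i in range(len(firsts)):
                for j in range(i + 1, len(firsts)):
                    shared = {(a, k) for a, k, g in firsts[i] if not g} & \
                             {(a, k) for a, k, g in firsts[j] if not g}
                    if shared:
                        acts = ", ".join(a.value for a, _ in sorted(shared, key=lambda x: x[0].value))
                        violations.append(Violation(
                            "ambiguous-or",
                            f"{name}: OR branches are not act- or guard-disjoint ({acts})",
                            severity="warning"))
            for b in t.branches:
                check_or(proto, name, b)
        elif isinstance(t, Then):
            check_or(proto, name, t.first)
            check_or(proto, name, t.rest)

    for name, proto in (("doctor", doctor), ("patient", patient)):
        for clause in proto.clauses:
            check_or(proto, name, clause.body)

    return violations
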