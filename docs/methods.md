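# Methods

This note records the model implemented by `codel`, the choices made where the
design was genuinely open, and what the bundled fixtures do and do not
demonstrate.

## Dialogue model

A consultation is a two-role dialogue (doctor, patient) over a decision
proposition: a condition plus an ordered plan of interventions (the
`surgery1 + surgery2` conjunction; order is preserved for display and ignored
for equality, since nothing in the model distinguishes plan orderings). Every
message is one of eight speech acts, and adjacent messages must form one of 14
legal interaction pairs. The pair table is stored as data with a one-line
rationale per row (exportable via `speech_acts.PairRegistry.to_records`), so
the registry, the static checker, and the documentation share one source of
truth.

Two structural conventions need stating:

* **Refuse–retract + assert.** The compound row is encoded as the response
  pair (refuse, retract) plus a *same-speaker continuation* (retract, assert).
  `validate_pair` treats the continuation as legal only when told the two
  messages share a speaker; `allowed_responses` exposes the pure response
  relation, which is what makes `accept` and `retract` the acts with no
  responder. Transcript audits pass the speaker identity per adjacency.
* **Termination.** A dialogue is `agreed` iff its last act is `accept`. When a
  refused intervention is mandatory and its alternatives are exhausted, the
  doctor still retracts (the refusal must be honoured) but cannot re-assert,
  and the session ends `no_agreement`. Representing failed negotiation
  explicitly is a deliberate extension: the named decision modes all end in
  acceptance, so such transcripts classify as mode X.

## Protocol language

Protocols are text (`.codel`, UTF-8, `#` comments), one role per file, in an
ASCII transliteration of the publication glyphs ("⇒"→`=>`, "⇐"→`<=`,
"←"→`<-`; identifiers use underscores). The grammar is LL with `then`
(sequence, right-associated) binding tighter than `or` (committed choice);
parenthesisation groups alternatives. Guards are predicates over agent state
and message content; each guard argument may itself be a plan conjunction, so
`interested_in(disease, surgery1 + surgery2)` is 2-ary. Unknown guard
predicates are a *static* error when a predicate table is supplied to the
checker — "must resolve to true to execute" demands explicit semantics, so
there is no runtime default-true.

Loops (repeated questioning, renewed assertion after retraction) are expressed
as role calls, the coordination-calculus idiom: a bare `a(role(), X)` term
continues as that role's clause. The bundled `doctor.codel` / `patient.codel`
are **reconstructions**: the original full protocol listings exist only as
figures, so the shipped files were rebuilt from the generic interaction model
and the three scenario walkthroughs, and are labelled as such in their
headers. The static checker verifies send/receive matching (same act, same
arity), pair legality along all paths including across role-call boundaries
(send–send or receive–receive adjacency is checked under the same-speaker
rule), guard registration, and OR-branch disjointness (overlap among
unguarded branches is an ambiguity warning, not an error).

The serializer emits a normalized layout; `parse ∘ serialize` is the identity
on ASTs and `serialize ∘ parse` is idempotent on normalized sources, which the
suite checks on the bundled files and on randomly generated ASTs.

## Engine and policies

Each agent's cursor is a continuation stack over its AST; OR branches commit
on the act actually sent or received. The engine enforces turn alternation
(with the retract→assert exception), pair legality, guard satisfaction, and
send/receive matching at run time, and raises typed errors otherwise. The
default `max_turns` is 50: the question–justify and rebuttal–persuade rows
permit unbounded cycles and no bound is inherited, so a configurable loop
guard is required; exceeding it raises rather than silently truncating.

The canonical **doctor policy** asserts the KB's recommended plan, justifies
questions with the support arguments of every plan intervention, persuades a
rebuttal with the contested intervention's support arguments, and on refusal
retracts and substitutes via the KB (first non-rejected alternative, in
authored order; drop the intervention if optional and exhausted — mandatory
plus exhausted ends the session). The **patient policy** carries a question
budget, a per-intervention stance map, and a personality profile. Stances are
`oppose` (rebut once, citing a configured subset of the KB's
against-arguments; open to persuasion) or `refuse` (outright rejection
whenever asserted — used for interventions the patient has ruled out as a
class). Choice priority when several branches are open: hard refusal, then
questioning while budget remains, then rebutting an uncontested opposed
intervention, then acceptance.

Refuse messages carry the *specific refused intervention(s)* as their content
sub-plan rather than the whole plan. This is how the doctor — who cannot read
the patient's mind — identifies the substitution target, and it is the one
place the implementation refines the generic `Refuse(surgery1 + surgery2)`
form.

All policy choices are deterministic; the seed is threaded through the session
and recorded in transcript metadata so that fixture transcripts are byte-stable
across runs.

### The depression (Emily) walkthrough

The narrative "the doctor recommended an SSRI, Emily still declined, the
doctor suggested CBT alone" is operationalised as: the persuade for
`antidepressant` carries its KB support arguments (one of which recommends a
modern SSRI); Emily's persistent profile keeps her oppose stance, so she
refuses; the doctor substitutes the SSRI (the antidepressant's listed
alternative) and re-asserts `cbt + ssri`; Emily's class-level `refuse` stance
on `ssri` rejects it outright; the SSRI has no further alternative and is
optional, so it is dropped and `cbt` alone is asserted and accepted. The run
is 12 acts, ends `agreed` with final plan `[cbt]`, and classifies as mode C.

## Personality model

The keep/flip forces are a **reconstruction**: the published equations are
unreadable in the available source, so the implementation commits to the
simplest form consistent with every prose constraint — K is a fixed baseline
attached to the belief set; K1 linearly strengthens the aligned (Arg+) mass;
K2 linearly strengthens the opposing (Arg−) mass; K3 amplifies whichever side
the current evaluation favours (aligned at a tie). Argument sets are
*stance-relative*: a patient opposing an intervention counts the KB's
against-arguments they cite as aligned mass, and incoming persuasion support
arguments as opposing mass. Ties keep the prior stance — persistence is the
default of belief. Units are argument-weight units; all bundled arguments
weigh 1.0 because the source ranks none above another.

Verified properties: the flip indicator is monotone non-increasing in K1 and
non-decreasing in K2 (everywhere), and with K = K3 = 0 the decision reduces to
the gain-weighted mass ratio. One frequently assumed property is *not* true
and is deliberately not asserted: at balanced masses, varying K3 can change
the outcome (it strengthens keeping, so it can rescue a stance that openness
would otherwise flip); what holds, and is tested, is that at balance raising
K3 never causes a flip.

Preset profiles (`persistent` K1 = 2, K2 = 0.2; `open` K1 = 0.2, K2 = 2;
`critical` K3 = 2; all with K = 1, remaining gains 0.5 or 0.2/0.5 as listed in
`personality.PROFILE_PRESETS`) are package defaults for the three qualitative
archetypes — any run configuration may override them numerically.

## Fixtures: what they show and what they do not

The bundled cases are *executable transcriptions of two published case
narratives*, not clinical data. The KB argument texts are verbatim from the
cases' guideline tables; the scenario policies (question budgets, cited
argument subsets, profiles) are the minimal configurations that realise the
narrated behaviours — e.g. the persuadable patient cites only the pain
argument (aligned mass 1 against 4 support arguments: an open profile flips),
while the firm patient holds all six against-arguments (mass 6 against 4: a
persistent profile keeps). Passing tests therefore demonstrate that the
formal machinery reproduces the narrated dialogues exactly and behaves
monotonically under personality variation; they say nothing about real
consultations, natural-language understanding (the engine is symbolic;
surface text is a template-filled annotation, with the realizer exposed as a
hook for external text generators), or the clinical merit of the guideline
content.

Problem sizes used by the suite and the acceptance script: dialogues of 4–12
acts, a 10×10×3 personality grid evaluated through the closed-form decision
rule, a 2×5 grid through full engine runs, 1,000 random ASTs for round-trip
checking, and exhaustive enumeration of legal act sequences to length 8 (101
sequences) for mode-exclusion checking — all desk-scale.

## Known limitations

* Exactly two roles; no multi-party or nested protocol composition.
* The committed-choice semantics resolves OR by the first matching branch;
  branch ambiguity is surfaced by the checker as a warning rather than
  resolved probabilistically.
* Beliefs are tracked per intervention, one proposition at a time; there is no
  belief network across interventions and no learning of personality
  parameters from transcripts.
* Pattern variables in protocol messages are documentation-level: matching is
  by act kind and arity, not unification.
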