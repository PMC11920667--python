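# codel

A protocol language and execution engine for doctor–patient **shared
decision-making** (SDM). `codel` implements the Collaborative Decision
Description Language (CoDeL): dialogues between a physician and a patient are
modelled as exchanges of typed **speech acts**, regulated by a protocol written
in a role-based coordination-calculus style, grounded in a clinical-guideline
argument base, and personalised through a weighted belief-update model. It is
aimed at health-informatics and multi-agent-systems researchers who want
executable, auditable models of consultation dialogues.

## The model

**Speech acts.** Eight performatives carry the decision process: *assert,
accept, refuse, question, justify, rebuttal, persuade, retract*. Acts combine
only into sanctioned interaction pairs — a constraint table of exactly 14 legal
(previous, next) response pairs, e.g. *assert–question*, *rebuttal–persuade*,
*persuade–accept*. Two pairings are prohibited outright as violations of
behavioural logic: *refuse–persuade* (a refusal is definitive and admits no
response) and *assert–justify* (one party cannot supply the justification for
the other's assertion). The compound row *refuse–retract + assert* is encoded
as the pair (refuse, retract) plus a same-speaker continuation permitting the
retracting agent to immediately re-assert from the remaining alternatives.

**Protocols.** Each role's behaviour is a `.codel` protocol: clauses of the
form `a(role(K), Id) :: body`, where the body composes message sends
(`msg => a(peer(), X)`), receives (`msg <= a(peer(), X)`), sequencing (`then`),
committed choice (`or`), guard constraints (`<- predicate(args)`), and role
calls for loops. A static checker verifies send/receive matching between the
doctor and patient protocols, pair legality along every path, and guard
registration.

**Argument base.** Interventions live in a YAML knowledge base with verbatim
guideline support/against arguments, ordered alternatives, and an `optional`
flag. Justifications and persuasions attach argument identifiers from the KB;
after a refusal the engine substitutes the first non-rejected alternative, or
drops the intervention if it is optional and its alternatives are exhausted.

**Personality.** Whether persuasion flips a patient's stance is decided by
comparing two forces over the accumulated aligned (Arg+) and opposing (Arg−)
argument masses, shaped by a baseline K and three trait gains — persistence
K1, openness K2, critical thinking K3:

```
sign = +1 if aligned ≥ opposing else −1
keep = K + (1 + K1)·aligned  + K3·aligned·[sign = +1]
flip =     (1 + K2)·opposing + K3·opposing·[sign = −1]
```

The stance flips iff `flip > keep`; ties keep the prior stance. (The published
equations survive only as figures; this linear-gain form is a documented
reconstruction — see `docs/methods.md`.)

**Decision modes.** Transcripts classify into reusable modes:
**A** `assert (question justify)+ accept` (question resolution),
**B** rebuttal answered by successful persuasion, ending in acceptance,
**C** plan substitution after a retraction, ending in acceptance, and
**X** for everything else, including failed negotiations.

## Worked example

Two clinical cases ship with the package: atrial fibrillation (patient David;
recommended plan cardiac angiography + surgical ablation, ultrasound as the
angiography alternative) and major depression (patient Emily; CBT + optional
antidepressant with an SSRI alternative). Materialise them and run the three
canonical atrial-fibrillation scenarios plus the Emily case:

```console
$ codel fixtures --outdir fxdemo --seed 0
af_scenario1_compliant: agreed, mode A, 4 acts
af_scenario2_persuadable: agreed, mode B, 4 acts
af_scenario3_firm: agreed, mode C, 7 acts
depression_emily: agreed, mode C, 12 acts
fixtures written to fxdemo
```

Scenario 1 is the compliant patient (`assert, question, justify, accept` — 4
speech acts, mode A). Scenario 2's patient rebuts the angiography citing its
pain argument but, with an open personality (K2 = 2), is persuaded: mode B.
Scenario 3's persistent patient (K1 = 2) holds all six against-arguments,
refuses, and the doctor retracts and substitutes cardiac ultrasound: mode C
with final plan `cardiac_ultrasound + surgical_ablation`. Emily questions,
rebuts the antidepressant, refuses both it and the SSRI substitute, and agrees
once the doctor proposes CBT alone (final plan `cbt`).

A personality sweep shows how the trait gains move the persuasion boundary —
raising persistence K1 is the only way a scenario-2 patient ends up refusing
(which then forces the mode-C substitution path):

```console
$ codel sweep --k1 0,1,2,4 --k2 0,2 --k3 0.5
    K1     K2     K3  decision  mode
   0.0    0.0    0.5  accept    B
   ...
   4.0    0.0    0.5  refuse    C
   4.0    2.0    0.5  accept    B
# 7/8 grid points flip to accept
```

Other verbs: `codel validate [doctor.codel patient.codel]` statically checks a
protocol bundle, `codel run config.yaml` executes a YAML run configuration and
writes a transcript JSON, and `codel classify transcript.json` labels it (exit
code 0 for modes A/B/C, 10 for X).

## Layout

```
src/codel/
  speech_acts.py      # 8 performatives + 14-pair legality registry
  protocol_lang.py    # .codel grammar, parser, serializer, static checker
  dialogue_engine.py  # two-agent turn-taking execution, policies, transcripts
  argument_base.py    # guideline KB: interventions, arguments, alternatives
  personality.py      # K/K1/K2/K3 belief update
  mode_classifier.py  # decision modes A/B/C/X
  fixtures.py, cli.py # bundled cases, run configs, command-line interface
  data/               # doctor/patient protocols + the two KBs
```
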