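"""Classify a dialogue transcript into reusable decision modes A, B, C or X.

Speech-act sequences abstract into recurring decision patterns:

* **Mode A** — question resolution: ``assert (question justify)+ accept``,
  with no rebuttal, refusal or retraction.  The patient's questions are
  answered and the plan is accepted.  Any number of question-justify
  rounds counts as one resolution cycle.
* **Mode B** — successful persuasion: the transcript contains a rebuttal
  and a persuade, ends in acceptance, and contains no retraction.
* **Mode C** — plan substitution: the doctor retracted an assertion and
  re-proposed from the alternatives; the transcript contains a retract
  and ends agreed.
* **Mode X** — everything else, including any dialogue that does not end
  in agreement.  The catalogue is open-ended: X is the extension point,
  not a failure label.

The classifier is total over legal transcripts and the three named
patterns are pairwise disjoint by construction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .dialogue_engine import Transcript
from .errors import IllegalTranscript
from .speech_acts import SpeechActKind

__all__ = ["ModeLabel", "classify", "is_mode_a", "is_mode_b", "is_mode_c"]

_MODE_A = re.compile(r"^assert(?: question justify)+ accept$")


def _act_names(acts: list[SpeechActKind]) -> list[str]:
    return [a.value for a in acts]


def is_mode_a(acts: list[SpeechActKind]) -> bool:
    return bool(_MODE_A.match(" ".join(_act_names(acts))))


def is_mode_b(acts: list[SpeechActKind]) -> bool:
    return (SpeechActKind.REBUTTAL in acts and SpeechActKind.PERSUADE in acts
            and SpeechActKind.RETRACT not in acts
            and bool(acts) and acts[-1] is SpeechActKind.ACCEPT)


def is_mode_c(acts: list[SpeechActKind]) -> bool:
    return (SpeechActKind.RETRACT in acts
            and bool(acts) and acts[-1] is SpeechActKind.ACCEPT)


@dataclass(frozen=True)
class ModeLabel:
    label: str  # "A" | "B" | "C" | "X"
    evidence: tuple[str, ...] = ()


def classify(t: Transcript) -> ModeLabel:
    """Assign exactly one decision-mode label to a legal transcript.

    Raises :class:`IllegalTranscript` if any adjacent pair is illegal
    (under the same-speaker retract → assert rule).
    """
    bad = t.audit()
    if bad:
        i, prev, nxt = bad[0]
        raise IllegalTranscript(
            f"illegal pair ({prev.value}, {nxt.value}) at position {i}")
    acts = t.acts
    agreed = bool(acts) and acts[-1] is SpeechActKind.ACCEPT and \
        t.final_status in ("agreed", "running")
    if not agreed:
        return ModeLabel("X", ("dialogue did not end in acceptance",))
    if is_mode_a(acts):
        rounds = (len(acts) - 2) // 2
        return ModeLabel("A", (
            "opening assert", f"{rounds} question-justify round(s)", "closing accept"))
    if is_mode_c(acts):
        n = sum(1 for a in acts if a is SpeechActKind.RETRACT)
        return ModeLabel("C", (
            f"{n} retraction(s) with plan substitution", "closing accept"))
    if is_mode_b(acts):
        return ModeLabel("B", ("rebuttal answered by persuasion", "closing accept"))
    return ModeLabel("X", ("agreed, but matches no named pattern",))
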