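"""Guideline-derived argument base: interventions, arguments, alternatives.

The knowledge base is the single place clinical content lives.  Each
intervention carries a rationale, weighted support arguments
(advantages) and against arguments (disadvantages and side effects)
transcribed verbatim from the relevant guideline material, an ordered
list of alternative interventions, and an ``optional`` flag.  The
dialogue engine stays domain-agnostic: it looks up arguments to attach
to justify/persuade acts and alternatives to substitute after a refusal.

File format (YAML, UTF-8)::

    condition: atrial_fibrillation
    recommended_plan: [cardiac_angiography, surgical_ablation]
    interventions:
      cardiac_angiography:
        rationale: "..."
        optional: false
        alternatives: [cardiac_ultrasound]
        support:
          - {id: angio_s1, text: "...", weight: 1.0}
        against:
          - {id: angio_a1, text: "...", weight: 1.0}

All weights default to 1.0: the source material ranks no argument above
another, so unweighted counts are the faithful reading; the field exists
so the personality model has a graded input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

import yaml

from .errors import DanglingAlternative, KBSchemaError, UnknownIntervention

__all__ = [
    "Argument", "Intervention", "GuidelineKB",
    "load_kb", "save_kb", "find_arguments", "propose_alternative",
]

POLARITIES = ("support", "against")


@dataclass(frozen=True)
class Argument:
    """One guideline argument for or against an intervention."""

    id: str
    polarity: str  # "support" | "against"
    text: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.polarity not in POLARITIES:
            raise KBSchemaError(f"argument {self.id!r}: polarity must be support/against")
        if not self.weight > 0:
            raise KBSchemaError(f"argument {self.id!r}: weight must be positive")


@dataclass(frozen=True)
class Intervention:
    name: str
    rationale: str = ""
    support: tuple[Argument, ...] = ()
    against: tuple[Argument, ...] = ()
    alternatives: tuple[str, ...] = ()
    optional: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "support", tuple(self.support))
        object.__setattr__(self, "against", tuple(self.against))
        object.__setattr__(self, "alternatives", tuple(self.alternatives))


@dataclass(frozen=True)
class GuidelineKB:
    """All interventions known for one condition, plus the recommended plan."""

    condition: str
    interventions: dict[str, Intervention] = field(default_factory=dict)
    recommended_plan: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "recommended_plan", tuple(self.recommended_plan))
        self._validate()

    def _validate(self) -> None:
        seen_ids: set[str] = set()
        for name, iv in self.interventions.items():
            if iv.name != name:
                raise KBSchemaError(f"intervention key {name!r} does not match name {iv.name!r}")
            for arg in iv.support + iv.against:
                if arg.id in seen_ids:
                    raise KBSchemaError(f"duplicate argument id {arg.id!r}")
                seen_ids.add(arg.id)
            for alt in iv.alternatives:
                if alt not in self.interventions:
                    raise DanglingAlternative(
                        f"intervention {name!r} lists undefined alternative {alt!r}")
        for p in self.recommended_plan:
            if p not in self.interventions:
                raise KBSchemaError(f"recommended_plan names undefined intervention {p!r}")

    def intervention(self, name: str) -> Intervention:
        try:
            return self.interventions[name]
        except KeyError:
            raise UnknownIntervention(
                f"intervention {name!r} is not defined for condition {self.condition!r}") from None

    def argument(self, argument_id: str) -> Argument:
        for iv in self.interventions.values():
            for arg in iv.support + iv.against:
                if arg.id == argument_id:
                    return arg
        raise KeyError(argument_id)

    @property
    def argument_ids(self) -> frozenset[str]:
        return frozenset(
            a.id for iv in self.interventions.values() for a in iv.support + iv.against)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _args_from_records(records: object, polarity: str, where: str) -> tuple[Argument, ...]:
    if records is None:
        return ()
    if not isinstance(records, list):
        raise KBSchemaError(f"{where}: {polarity} must be a list")
    out = []
    for rec in records:
        if not isinstance(rec, dict) or "id" not in rec or "text" not in rec:
            raise KBSchemaError(f"{where}: each {polarity} argument needs 'id' and 'text'")
        out.append(Argument(
            id=str(rec["id"]), polarity=polarity, text=str(rec["text"]),
            weight=float(rec.get("weight", 1.0))))
    return tuple(out)


def load_kb(source: str | Path | IO[str]) -> GuidelineKB:
    """Load and validate a knowledge base from a YAML file, path or stream.

    Errors name the offending record (:class:`KBSchemaError`,
    :class:`DanglingAlternative`).
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = yaml.safe_load(source)
    if not isinstance(raw, dict):
        raise KBSchemaError("KB file must contain a mapping at top level")
    for key in ("condition", "interventions"):
        if key not in raw:
            raise KBSchemaError(f"KB file is missing required key {key!r}")
    interventions: dict[str, Intervention] = {}
    ivs = raw["interventions"]
    if not isinstance(ivs, dict):
        raise KBSchemaError("'interventions' must be a mapping name -> record")
    for name, rec in ivs.items():
        rec = rec or {}
        if not isinstance(rec, dict):
            raise KBSchemaError(f"intervention {name!r}: record must be a mapping")
        interventions[name] = Intervention(
            name=name,
            rationale=str(rec.get("rationale", "")),
            support=_args_from_records(rec.get("support"), "support", f"intervention {name!r}"),
            against=_args_from_records(rec.get("against"), "against", f"intervention {name!r}"),
            alternatives=tuple(rec.get("alternatives") or ()),
            optional=bool(rec.get("optional", False)),
        )
    return GuidelineKB(
        condition=str(raw["condition"]),
        interventions=interventions,
        recommended_plan=tuple(raw.get("recommended_plan") or ()),
    )


def save_kb(kb: GuidelineKB, target: str | Path | IO[str] | None = None) -> str:
    """Write a KB to YAML in normalized form; returns the YAML text."""
    doc = {
        "condition": kb.condition,
        "recommended_plan": list(kb.recommended_plan),
        "interventions": {
            name: {
                "rationale": iv.rationale,
                "optional": iv.optional,
                "alternatives": list(iv.alternatives),
                "support": [
                    {"id": a.id, "text": a.text, "weight": a.weight} for a in iv.support],
                "against": [
                    {"id": a.id, "text": a.text, "weight": a.weight} for a in iv.against],
            }
            for name, iv in kb.interventions.items()
        },
    }
    text = yaml.safe_dump(doc, sort_keys=False, allow_unicode=True, width=88)
    if isinstance(target, (str, Path)):
        Path(target).write_text(text, encoding="utf-8")
    elif target is not None:
        target.write(text)
    return text


# ---------------------------------------------------------------------------
# Queries
# ---------------------------------------------------------------------------

def find_arguments(kb: GuidelineKB, intervention: str, polarity: str) -> list[Argument]:
    """Arguments of the requested polarity for an intervention, authored order."""
    if polarity not in POLARITIES:
        raise ValueError(f"polarity must be one of {POLARITIES}, got {polarity!r}")
    iv = kb.intervention(intervention)
    return list(iv.support if polarity == "support" else iv.against)


def propose_alternative(
    kb: GuidelineKB, rejected: str, already_rejected: Iterable[str] = (),
) -> str | None:
    """First listed alternative of ``rejected`` not itself already rejected.

    Alternatives are tried in authored order; returns ``None`` when the
    list is exhausted (the engine then applies its drop-if-optional rule).
    """
    excluded = set(already_rejected)
    for alt in kb.intervention(rejected).alternatives:
        if alt not in excluded:
            return alt
    return None
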