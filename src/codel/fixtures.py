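"""Bundled cases, canonical policy presets, and run configuration.

Two clinical cases ship with the package:

* **Atrial fibrillation (David)** — recommended plan cardiac angiography
  + surgical ablation, with cardiac ultrasound as the angiography
  alternative.  Three canonical patient policies reproduce the three
  decision scenarios: a compliant patient who questions once and accepts
  (mode A), a hesitant but persuadable patient who rebuts the
  angiography once (mode B), and a firm patient who is never persuaded,
  forcing substitution by cardiac ultrasound (mode C).
* **Major depression (Emily)** — recommended plan CBT + antidepressant
  (optional, SSRI alternative).  Emily questions, rebuts the
  antidepressant, resists persuasion, refuses the SSRI substitute
  outright, and agrees once the doctor proposes CBT alone.

The bundled ``.codel`` protocol files and KB YAML files live under
``codel/data`` and are loaded through :mod:`importlib.resources`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .argument_base import GuidelineKB, load_kb
from .dialogue_engine import (
    DoctorPolicy,
    PatientPolicy,
    PatientStance,
    SessionConfig,
    Transcript,
    run_session,
)
from .mode_classifier import classify
from .personality import PersonalityProfile, get_profile
from .protocol_lang import Protocol, parse_protocol

__all__ = [
    "RunConfig", "bundled_protocols", "bundled_kb",
    "build_af_fixture", "build_depression_fixture", "run_config", "sweep",
]


def _data_text(name: str) -> str:
    return resources.files("codel.data").joinpath(name).read_text(encoding="utf-8")


def bundled_protocols() -> tuple[Protocol, Protocol]:
    """The bundled (doctor, patient) protocol pair."""
    return parse_protocol(_data_text("doctor.codel")), \
        parse_protocol(_data_text("patient.codel"))


def bundled_kb(case: str) -> GuidelineKB:
    """Load a bundled KB: "atrial_fibrillation" or "depression"."""
    import io

    return load_kb(io.StringIO(_data_text(f"{case}.kb.yaml")))


@dataclass
class RunConfig:
    """Everything needed to execute one session reproducibly."""

    name: str
    kb: GuidelineKB
    doctor_protocol: Protocol
    patient_protocol: Protocol
    patient_profile: str | dict | PersonalityProfile = "neutral"
    patient_stances: dict[str, PatientStance] = field(default_factory=dict)
    question_budget: int = 0
    max_turns: int = 50
    seed: int = 0


def run_config(cfg: RunConfig) -> Transcript:
    """Execute a run configuration and return its transcript."""
    doctor = DoctorPolicy(cfg.kb)
    patient = PatientPolicy(
        cfg.kb, profile=cfg.patient_profile, stances=cfg.patient_stances,
        question_budget=cfg.question_budget)
    transcript = run_session(
        cfg.doctor_protocol, cfg.patient_protocol, cfg.kb, doctor, patient,
        SessionConfig(max_turns=cfg.max_turns, seed=cfg.seed))
    profile = get_profile(cfg.patient_profile)
    transcript.metadata.update({
        "run": cfg.name,
        "protocols": ["doctor.codel", "patient.codel"],
        "patient_profile": {
            "K": profile.K, "K1": profile.K1, "K2": profile.K2, "K3": profile.K3},
    })
    return transcript


def build_af_fixture(seed: int = 0) -> tuple[GuidelineKB, dict[str, RunConfig]]:
    """The atrial-fibrillation KB plus the three canonical scenario configs.

    * ``scenario1`` — compliant patient: one question round, then accept.
    * ``scenario2`` — hesitant but persuadable: rebuts the angiography
      citing the pain argument, flips under persuasion (open profile).
    * ``scenario3`` — firm: holds every against-argument, keeps the
      oppose stance (persistent profile), forcing the ultrasound
      substitution.
    """
    kb = bundled_kb("atrial_fibrillation")
    doctor, patient = bundled_protocols()
    common = dict(kb=kb, doctor_protocol=doctor, patient_protocol=patient, seed=seed)
    configs = {
        "scenario1": RunConfig(
            name="af_scenario1_compliant", question_budget=1, **common),
        "scenario2": RunConfig(
            name="af_scenario2_persuadable", patient_profile="open",
            patient_stances={
                "cardiac_angiography": PatientStance("oppose", cite=["angio_a3"])},
            **common),
        "scenario3": RunConfig(
            name="af_scenario3_firm", patient_profile="persistent",
            patient_stances={"cardiac_angiography": PatientStance("oppose", cite="all")},
            **common),
    }
    return kb, configs


def build_depression_fixture(seed: int = 0) -> tuple[GuidelineKB, RunConfig]:
    """The depression KB plus the Emily run configuration."""
    kb = bundled_kb("depression")
    doctor, patient = bundled_protocols()
    cfg = RunConfig(
        name="depression_emily", kb=kb, doctor_protocol=doctor,
        patient_protocol=patient, patient_profile="persistent",
        patient_stances={
            "antidepressant": PatientStance("oppose", cite="all"),
            "ssri": PatientStance("refuse"),
        },
        question_budget=1, seed=seed)
    return kb, cfg


def sweep(
    k1_grid: list[float],
    k2_grid: list[float],
    k3_grid: list[float],
    scenario: RunConfig,
    K: float = 1.0,
) -> list[dict]:
    """Run a scenario across a personality grid.

    Returns one record per (K1, K2, K3) with the final decision of the
    contested intervention ("accept" or "refuse"), the overall session
    status, and the decision-mode label.  Deterministic given the
    scenario's seed.
    """
    rows = []
    for k1 in k1_grid:
        for k2 in k2_grid:
            for k3 in k3_grid:
                cfg = RunConfig(
                    name=f"{scenario.name}_K1={k1}_K2={k2}_K3={k3}",
                    kb=scenario.kb,
                    doctor_protocol=scenario.doctor_protocol,
                    patient_protocol=scenario.patient_protocol,
                    patient_profile=PersonalityProfile(K=K, K1=k1, K2=k2, K3=k3),
                    patient_stances=dict(scenario.patient_stances),
                    question_budget=scenario.question_budget,
                    max_turns=scenario.max_turns,
                    seed=scenario.seed,
                )
                t = run_config(cfg)
                acts = [m.act.value for m in t.messages]
                flipped_to_accept = "persuade" in acts and \
                    acts[acts.index("persuade") + 1] == "accept"
                rows.append({
                    "K1": k1, "K2": k2, "K3": k3,
                    "decision": "accept" if flipped_to_accept else "refuse",
                    "status": t.final_status,
                    "mode": classify(t).label,
                })
    return rows


def load_run_config_file(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML file (paths resolved relative to it).

    Schema::

        name: my_run
        kb: path/to/kb.yaml            # or "bundled:atrial_fibrillation"
        protocols: {doctor: d.codel, patient: p.codel}   # or "bundled"
        patient:
          profile: open                # preset name or {K, K1, K2, K3}
          question_budget: 1
          stances:
            cardiac_angiography: {attitude: oppose, cite: [angio_a3]}
        max_turns: 50
        seed: 0
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    base = path.parent
    kb_spec = raw["kb"]
    if isinstance(kb_spec, str) and kb_spec.startswith("bundled:"):
        kb = bundled_kb(kb_spec.split(":", 1)[1])
    else:
        kb = load_kb(base / kb_spec)
    protos = raw.get("protocols", "bundled")
    if protos == "bundled":
        doctor, patient = bundled_protocols()
    else:
        doctor = parse_protocol((base / protos["doctor"]).read_text(encoding="utf-8"))
        patient = parse_protocol((base / protos["patient"]).read_text(encoding="utf-8"))
    pat = raw.get("patient", {})
    stances = {
        name: PatientStance(rec["attitude"], rec.get("cite", "all"))
        for name, rec in (pat.get("stances") or {}).items()
    }
    return RunConfig(
        name=str(raw.get("name", path.stem)),
        kb=kb, doctor_protocol=doctor, patient_protocol=patient,
        patient_profile=pat.get("profile", "neutral"),
        patient_stances=stances,
        question_budget=int(pat.get("question_budget", 0)),
        max_turns=int(raw.get("max_turns", 50)),
        seed=int(raw.get("seed", 0)),
    )
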