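"""Personality-weighted belief update for stance keeping vs. flipping.

Each agent holds a stance toward a proposition together with two
accumulated argument masses: ``aligned_mass`` (Σ weights of the Arg+ set,
arguments consistent with the current stance) and ``opposing_mass``
(Σ weights of the Arg− set).  Whether an incoming batch of counter-
arguments flips the stance is decided by comparing two forces shaped by
four personality parameters:

* ``K``  — fixed degree of the belief set (a stance-inertia baseline);
* ``K1`` — persistence gain: strengthens the aligned set; the higher K1,
  the less likely the agent is to change its view;
* ``K2`` — openness gain: strengthens the opposing set; the greater the
  willingness to accept opposing views, the more likely the flip;
* ``K3`` — critical-thinking amplification: boosts whichever side the
  agent's current evaluation of the arguments favours.

The published equations survive only as low-resolution figures, so the
algebra here is a documented linear-gain reconstruction that satisfies
every stated qualitative constraint::

    sign  = +1 if aligned_mass >= opposing_mass else -1
    keep  = K + (1 + K1) * aligned  + (K3 * aligned  if sign == +1 else 0)
    flip  =     (1 + K2) * opposing + (K3 * opposing if sign == -1 else 0)

The stance flips iff ``flip > keep``; ties keep the prior stance
(persistence is the default of belief).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable

from .argument_base import Argument

__all__ = [
    "PersonalityProfile", "BeliefState", "PROFILE_PRESETS", "get_profile",
    "evaluation_sign", "keep_force", "flip_force", "decide", "apply_arguments",
]


@dataclass(frozen=True)
class PersonalityProfile:
    """Baseline K plus the three trait gains (persistence, openness, critique)."""

    K: float = 1.0
    K1: float = 0.0
    K2: float = 0.0
    K3: float = 0.0

    def __post_init__(self) -> None:
        for name in ("K", "K1", "K2", "K3"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")


#: Numeric presets for the three qualitative archetypes.  The source
#: defines the archetypes only qualitatively; these values are package
#: defaults, overridable in any run configuration.
PROFILE_PRESETS: dict[str, PersonalityProfile] = {
    "persistent": PersonalityProfile(K=1.0, K1=2.0, K2=0.2, K3=0.5),
    "open": PersonalityProfile(K=1.0, K1=0.2, K2=2.0, K3=0.5),
    "critical": PersonalityProfile(K=1.0, K1=0.5, K2=0.5, K3=2.0),
    "neutral": PersonalityProfile(K=1.0, K1=0.0, K2=0.0, K3=0.0),
}


def get_profile(spec: str | dict | PersonalityProfile) -> PersonalityProfile:
    """Resolve a preset name, parameter mapping, or profile instance."""
    if isinstance(spec, PersonalityProfile):
        return spec
    if isinstance(spec, str):
        try:
            return PROFILE_PRESETS[spec]
        except KeyError:
            raise KeyError(
                f"unknown profile preset {spec!r}; known: {sorted(PROFILE_PRESETS)}") from None
    return PersonalityProfile(**{k: float(v) for k, v in spec.items()})


@dataclass(frozen=True)
class BeliefState:
    """Current stance plus accumulated Arg+ / Arg− masses (stance-relative)."""

    stance: str  # "support" | "oppose"
    aligned_mass: float = 0.0
    opposing_mass: float = 0.0

    def __post_init__(self) -> None:
        if self.stance not in ("support", "oppose"):
            raise ValueError(f"stance must be support/oppose, got {self.stance!r}")
        if self.aligned_mass < 0 or self.opposing_mass < 0:
            raise ValueError("argument masses are sums of positive weights, hence >= 0")


def evaluation_sign(b: BeliefState) -> int:
    """+1 when the agent's evaluation favours its own side, else −1.

    The exact tie (including the no-arguments-yet state) counts as +1:
    absent a dominant counter-case, the evaluation sides with the
    standing belief.
    """
    return 1 if b.aligned_mass >= b.opposing_mass else -1


def keep_force(b: BeliefState, p: PersonalityProfile) -> float:
    """Force holding the current stance in place."""
    f = p.K + (1.0 + p.K1) * b.aligned_mass
    if evaluation_sign(b) == 1:
        f += p.K3 * b.aligned_mass
    return f


def flip_force(b: BeliefState, p: PersonalityProfile) -> float:
    """Force pushing the agent to adopt the opposite stance."""
    f = (1.0 + p.K2) * b.opposing_mass
    if evaluation_sign(b) == -1:
        f += p.K3 * b.opposing_mass
    return f


def decide(b: BeliefState, p: PersonalityProfile) -> str:
    """Return ``"flip_stance"`` iff flip strictly exceeds keep, else ``"keep_stance"``."""
    return "flip_stance" if flip_force(b, p) > keep_force(b, p) else "keep_stance"


def flipped(b: BeliefState) -> BeliefState:
    """The belief state after a stance flip: the argument sides swap roles."""
    return BeliefState(
        stance="support" if b.stance == "oppose" else "oppose",
        aligned_mass=b.opposing_mass,
        opposing_mass=b.aligned_mass,
    )


def apply_arguments(
    b: BeliefState, new_args: Iterable[Argument], relative_polarity: str,
) -> BeliefState:
    """Accumulate argument weights on one side of the belief state.

    ``relative_polarity`` is "aligned" (consistent with the current
    stance) or "opposing".  The stance itself never changes here; stance
    changes happen only through :func:`decide`.
    """
    if relative_polarity not in ("aligned", "opposing"):
        raise ValueError(f"relative_polarity must be aligned/opposing, got {relative_polarity!r}")
    total = 0.0
    for arg in new_args:
        if arg.weight <= 0:
            raise ValueError(f"argument {arg.id!r} has non-positive weight")
        total += arg.weight
    if relative_polarity == "aligned":
        return replace(b, aligned_mass=b.aligned_mass + total)
    return replace(b, opposing_mass=b.opposing_mass + total)
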