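"""Personality-weighted belief update: forces, decisions, monotonicity."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codel.argument_base import Argument
from codel.personality import (
    PROFILE_PRESETS,
    BeliefState,
    PersonalityProfile,
    apply_arguments,
    decide,
    evaluation_sign,
    flip_force,
    flipped,
    get_profile,
    keep_force,
)


def test_evaluation_sign():
    assert evaluation_sign(BeliefState("oppose", 3.0, 1.0)) == 1
    assert evaluation_sign(BeliefState("oppose", 0.0, 0.0)) == 1  # tie convention
    assert evaluation_sign(BeliefState("oppose", 1.0, 2.5)) == -1


@pytest.mark.parametrize("profile,aligned,opposing,keep,flip,outcome", [
    # balanced baseline: forces tie, prior stance holds
    (PersonalityProfile(K=1, K1=0, K2=0, K3=0), 2.0, 3.0, 3.0, 3.0, "keep_stance"),
    # strong persistence shields a minority aligned mass
    (PersonalityProfile(K=0, K1=10, K2=0, K3=0), 1.0, 3.0, 11.0, 3.0, "keep_stance"),
    # strong openness flips even a balanced state
    (PersonalityProfile(K=0, K1=0, K2=10, K3=0), 1.0, 1.0, 1.0, 11.0, "flip_stance"),
])
def test_force_hand_computations(profile, aligned, opposing, keep, flip, outcome):
    b = BeliefState("oppose", aligned, opposing)
    assert keep_force(b, profile) == pytest.approx(keep)
    assert flip_force(b, profile) == pytest.approx(flip)
    assert decide(b, profile) == outcome


def test_critical_thinking_amplifies_evaluation_favoured_side():
    p = PersonalityProfile(K=0, K1=0, K2=0, K3=2)
    winning = BeliefState("oppose", 3.0, 1.0)  # evaluation favours aligned
    assert keep_force(winning, p) == pytest.approx(3.0 + 2 * 3.0)
    assert flip_force(winning, p) == pytest.approx(1.0)
    losing = BeliefState("oppose", 1.0, 3.0)  # evaluation favours opposing
    assert keep_force(losing, p) == pytest.approx(1.0)
    assert flip_force(losing, p) == pytest.approx(3.0 + 2 * 3.0)


def test_parameters_must_be_finite_nonnegative():
    with pytest.raises(ValueError):
        PersonalityProfile(K1=-0.1)
    with pytest.raises(ValueError):
        PersonalityProfile(K=float("inf"))


def test_presets():
    assert set(PROFILE_PRESETS) >= {"persistent", "open", "critical"}
    assert PROFILE_PRESETS["persistent"].K1 > PROFILE_PRESETS["persistent"].K2
    assert PROFILE_PRESETS["open"].K2 > PROFILE_PRESETS["open"].K1
    assert get_profile("open") is PROFILE_PRESETS["open"]
    assert get_profile({"K": 1, "K1": 2}) == PersonalityProfile(1, 2, 0, 0)
    with pytest.raises(KeyError):
        get_profile("stubborn")


def test_apply_arguments_additivity():
    b = BeliefState("oppose", 2.0, 3.0)
    one = Argument("a1", "against", "t", 1.0)
    assert apply_arguments(b, [one], "aligned") == BeliefState("oppose", 3.0, 3.0)
    assert apply_arguments(b, [], "opposing") == b
    zero = BeliefState("oppose", 0.0, 0.0)
    two = [Argument("a2", "support", "t", 0.5), Argument("a3", "support", "t", 1.5)]
    assert apply_arguments(zero, two, "opposing") == BeliefState("oppose", 0.0, 2.0)
    # stance never changes through accumulation
    assert apply_arguments(b, two, "opposing").stance == "oppose"


def test_flipped_swaps_sides():
    b = BeliefState("oppose", 1.0, 4.0)
    f = flipped(b)
    assert f.stance == "support"
    assert (f.aligned_mass, f.opposing_mass) == (4.0, 1.0)


_mass = st.floats(min_value=0.0, max_value=50.0, allow_nan=False)
_gain = st.floats(min_value=0.0, max_value=10.0, allow_nan=False)


@settings(max_examples=200, derandomize=True)
@given(aligned=_mass, opposing=_mass, k=_gain, k1a=_gain, k1b=_gain,
       k2=_gain, k3=_gain)
def test_flip_indicator_monotone_nonincreasing_in_persistence(
        aligned, opposing, k, k1a, k1b, k2, k3):
    lo, hi = sorted([k1a, k1b])
    b = BeliefState("oppose", aligned, opposing)
    flip_lo = decide(b, PersonalityProfile(k, lo, k2, k3)) == "flip_stance"
    flip_hi = decide(b, PersonalityProfile(k, hi, k2, k3)) == "flip_stance"
    assert flip_hi <= flip_lo


@settings(max_examples=200, derandomize=True)
@given(aligned=_mass, opposing=_mass, k=_gain, k1=_gain, k2a=_gain,
       k2b=_gain, k3=_gain)
def test_flip_indicator_monotone_nondecreasing_in_openness(
        aligned, opposing, k, k1, k2a, k2b, k3):
    lo, hi = sorted([k2a, k2b])
    b = BeliefState("oppose", aligned, opposing)
    flip_lo = decide(b, PersonalityProfile(k, k1, lo, k3)) == "flip_stance"
    flip_hi = decide(b, PersonalityProfile(k, k1, hi, k3)) == "flip_stance"
    assert flip_hi >= flip_lo


@settings(max_examples=100, derandomize=True)
@given(mass=_mass, k=_gain, k1=_gain, k2=_gain,
       k3a=_gain, k3b=_gain)
def test_k3_favours_keeping_at_balanced_masses(mass, k, k1, k2, k3a, k3b):
    # at an exact mass tie the evaluation favours the aligned side, so K3
    # only ever strengthens keeping: raising it can never cause a flip
    lo, hi = sorted([k3a, k3b])
    b = BeliefState("oppose", mass, mass)
    flip_lo = decide(b, PersonalityProfile(k, k1, k2, lo)) == "flip_stance"
    flip_hi = decide(b, PersonalityProfile(k, k1, k2, hi)) == "flip_stance"
    assert flip_hi <= flip_lo


@settings(max_examples=200, derandomize=True)
@given(aligned=st.floats(min_value=0.01, max_value=50), opposing=_mass,
       k1=_gain, k2=_gain)
def test_scale_property_without_baseline_and_critique(aligned, opposing, k1, k2):
    # with K = K3 = 0 the decision depends only on the gain-weighted ratio
    b = BeliefState("oppose", aligned, opposing)
    expected = (1 + k2) * opposing > (1 + k1) * aligned
    assert (decide(b, PersonalityProfile(0, k1, k2, 0)) == "flip_stance") == expected
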