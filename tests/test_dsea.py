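"""The drug set enrichment running sum: closed forms, oracle, invariants."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epilit.cooccurrence import RankedDrugList
from epilit.dsea import dsea_curve, dsea_max, dsea_profile
from epilit.fixtures import gen_reference_set
from epilit.prioritize import ReferenceSet


def oracle_curve(n, s, match_positions, convention="corrected"):
    """Independent step-by-step evaluation of the running sum."""
    scores = []
    x = 0.0
    tau = 0
    for i in range(1, n + 1):
        if i in match_positions:
            tau += 1
            t = min(tau, s - 1)
            if s == 1:
                inc = 0.0
            elif convention == "corrected":
                inc = math.log((s + t) / (s - t))
            else:
                inc = math.log((s - t) / (s + t))
        else:
            inc = math.log((n - tau) / (n + tau))
        x += inc
        scores.append(x)
    return scores


def test_zero_matches_gives_zero_curve():
    ranked, ref = gen_reference_set(5, [], set_size=2)
    curve = dsea_curve(ranked, ref)
    assert curve.scores == [0.0] * 6
    assert dsea_max(curve) == (0.0, 1)


def test_single_match_closed_form():
    ranked = RankedDrugList("l", ["d1"], [1])
    ref = ReferenceSet("r", frozenset({"d1", "r2", "r3"}))
    corrected = dsea_curve(ranked, ref, "corrected")
    assert corrected.increments[0] == pytest.approx(math.log(2))
    verbatim = dsea_curve(ranked, ref, "verbatim")
    assert verbatim.increments[0] == pytest.approx(-math.log(2))


def test_hand_derived_six_element_curve():
    ranked, ref = gen_reference_set(6, [1, 2, 4], set_size=4)
    curve = dsea_curve(ranked, ref, "corrected")
    expected = [0.5108, 1.6094, 0.9163, 2.8622, 1.7636, 0.6650]
    assert curve.scores[1:] == pytest.approx(expected, abs=5e-5)
    assert dsea_max(curve) == (pytest.approx(2.8622, abs=5e-5), 4)
    assert curve.scores[1:] == pytest.approx(oracle_curve(6, 4, {1, 2, 4}))


def test_matches_the_independent_oracle_everywhere():
    for convention in ("corrected", "verbatim"):
        for positions in [{1}, {3, 4}, {1, 2, 3}, {2, 5, 7, 8}, set(range(1, 9))]:
            n, s = 8, max(len(positions), 4)
            ranked, ref = gen_reference_set(n, sorted(positions), set_size=s)
            curve = dsea_curve(ranked, ref, convention)
            assert curve.scores[1:] == pytest.approx(
                oracle_curve(n, s, positions, convention)), (convention, positions)


def test_strictly_decreasing_curve_peaks_at_one():
    ranked, ref = gen_reference_set(4, [1], set_size=1)
    # with S=1 the bonus degenerates to 0 and every miss is negative
    curve = dsea_curve(ranked, ref)
    assert dsea_max(curve)[1] == 1


def test_tau_clamp_when_reference_exhausted():
    # every position matches and S < N: after the S-th match the bonus
    # keeps using tau = S - 1 and stays finite
    ranked, ref = gen_reference_set(3, [1, 2, 3], set_size=3)
    curve = dsea_curve(ranked, ref, "corrected")
    assert all(math.isfinite(x) for x in curve.scores)
    assert curve.increments[2] == pytest.approx(math.log(5))  # t clamped to 2


def test_degenerate_reference_larger_than_list():
    ranked, ref = gen_reference_set(4, [1, 2, 3, 4], set_size=6)
    curve = dsea_curve(ranked, ref)
    assert all(math.isfinite(x) for x in curve.scores)
    assert curve.tau == [1, 2, 3, 4]


def test_validation_errors():
    ranked = RankedDrugList("l", ["a"], [1])
    with pytest.raises(ValueError):
        dsea_curve(RankedDrugList("l", [], []), ReferenceSet("r", frozenset({"x"})))
    with pytest.raises(ValueError):
        dsea_curve(ranked, ReferenceSet("r", frozenset({"x"})), "bogus")


@st.composite
def _instances(draw):
    n = draw(st.integers(2, 20))
    positions = draw(st.sets(st.integers(1, n), max_size=n))
    extra = draw(st.integers(0, 3))
    return n, sorted(positions), len(positions) + extra


@given(_instances())
@settings(max_examples=150, deadline=None)
def test_sign_and_conservation_invariants(instance):
    n, positions, s = positions_s = instance
    if s == 0:
        s = 1
        positions = [1]
    ranked, ref = gen_reference_set(n, positions, set_size=s)
    curve = dsea_curve(ranked, ref, "corrected")
    for inc, hit in zip(curve.increments, curve.is_match):
        if hit:
            assert inc >= 0.0
            if s > 1:
                assert inc > 0.0
        else:
            assert inc <= 0.0
    # running maximum sits on a match position whenever any match exists
    if any(curve.is_match) and s > 1:
        assert curve.is_match[curve.max_position - 1]
    # conservation: x_N equals the increment sum
    assert curve.scores[-1] == pytest.approx(sum(curve.increments), abs=1e-9)
    # tau bookkeeping
    assert curve.tau == sorted(curve.tau)
    assert curve.tau[-1] <= min(n, s)


def test_prefix_stability():
    ranked, ref = gen_reference_set(10, [2, 5, 9], set_size=3)
    short = RankedDrugList("s", ranked.drugs[:6], ranked.counts[:6])
    # same match pattern over the shared prefix, same N => identical prefix
    full = dsea_curve(ranked, ref)
    m = 6
    prefix_only = dsea_curve(
        RankedDrugList("p", ranked.drugs[:m] + [f"pad{i}" for i in range(4)],
                       ranked.counts[:m] + [0] * 4), ref)
    assert full.scores[:m + 1] == pytest.approx(prefix_only.scores[:m + 1])


def test_curve_depends_only_on_match_pattern():
    ranked, ref = gen_reference_set(7, [2, 4], set_size=3)
    relabeled = RankedDrugList("x", [f"other{i}" for i in range(7)],
                               ranked.counts)
    ref2 = ReferenceSet("r2", frozenset({"other1", "other3", "extra"}))
    a = dsea_curve(ranked, ref)
    b = dsea_curve(relabeled, ref2)
    assert a.scores == pytest.approx(b.scores)


def test_profile_long_table(toy_corpus):
    lists = {
        "one": RankedDrugList("one", ["a", "b"], [2, 1]),
        "two": RankedDrugList("two", ["b", "a"], [2, 1]),
    }
    ref = ReferenceSet("r", frozenset({"a", "pad"}))
    curves, maxima = dsea_profile(lists, ref)
    assert set(curves["list"]) == {"one", "two"}
    assert len(curves) == 4
    assert set(maxima.columns) >= {"list", "max_score", "max_position"}
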