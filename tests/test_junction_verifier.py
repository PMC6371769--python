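"""Two-round verification rule, threshold calibration and promotion."""

from __future__ import annotations

import pytest
from hypothesis import given, settings, strategies as st

from refchrom import junction_verifier as jv
from refchrom.evidence import JunctionCoverage


def _test(jid="j1", interval=0, round1="untested", round2=(), coverage=None):
    cov = None
    if coverage is not None:
        cov = JunctionCoverage("s", 0, 1000, coverage, float("nan"))
    return jv.JunctionTest(jid, "s", "a", "b", interval, cov, round1,
                           tuple(round2))


class TestSelectTestable:
    def test_break_interval_strictly_below_cap(self):
        tests = [_test("a", 5_999), _test("b", 6_000), _test("c", 6_001)]
        assert [t.junction_id for t in jv.select_testable(tests)] == ["a"]

    def test_empty_input(self):
        assert jv.select_testable([]) == []


class TestClassify:
    def test_round1_amplified_is_confirmed(self):
        out, c = jv.classify([_test(round1="amplified")])
        assert out[0].status == "confirmed"
        assert c.amplified_regions == 1

    def test_failed_round1_amplified_alternative_is_chimeric(self):
        out, c = jv.classify([_test(round1="none", round2=("amplified",))])
        assert out[0].status == "chimeric"
        assert c.amplified_alternatives == 1

    def test_unexpected_size_counts_as_round1_failure(self):
        out, _ = jv.classify([_test(round1="unexpected_size",
                                    round2=("amplified",))])
        assert out[0].status == "chimeric"

    def test_all_alternatives_failed_gives_two_ambiguous(self):
        out, c = jv.classify([_test(round1="none", round2=("none", "none"))])
        assert out[0].status == "ambiguous"
        assert c.ambiguous_adjacencies == 2

    def test_round2_with_amplified_round1_is_an_error(self):
        with pytest.raises(ValueError, match="round-2"):
            jv.classify([_test(round1="amplified", round2=("none",))])

    def test_count_identities(self):
        tests = ([_test(f"c{i}", round1="amplified") for i in range(3)]
                 + [_test(f"k{i}", round1="none", round2=("amplified",))
                    for i in range(2)]
                 + [_test("a0", round1="none", round2=("none", "none"))])
        _, c = jv.classify(tests)
        assert c.amplified_regions + c.non_amplified_regions == c.tested_regions
        assert (c.amplified_alternatives + c.non_amplified_alternatives
                == c.tested_alternatives)
        assert c.ambiguous_adjacencies == c.non_amplified_alternatives


class TestCalibrateThreshold:
    def _mk(self, confirmed, others):
        tests = [_test(f"c{i}", round1="amplified", coverage=c)
                 for i, c in enumerate(confirmed)]
        tests += [_test(f"x{i}", round1="none", round2=("amplified",),
                        coverage=c) for i, c in enumerate(others)]
        out, _ = jv.classify(tests)
        return out

    def test_separated_classes(self):
        thr = jv.calibrate_threshold(self._mk([220, 300], [50, 120]))
        assert thr.spanning_pairs == 220

    def test_single_confirmed_above_all_chimeric(self):
        thr = jv.calibrate_threshold(self._mk([100], [20]))
        assert thr.spanning_pairs == 100

    def test_interleaved_takes_minimal_confirmed_above_all_chimeric(self):
        thr = jv.calibrate_threshold(self._mk([220, 400, 500], [250]))
        assert thr.spanning_pairs == 400

    def test_no_separating_threshold_errors(self):
        with pytest.raises(ValueError, match="no separating threshold"):
            jv.calibrate_threshold(self._mk([100, 200], [300]))

    def test_percent_uses_median(self):
        thr = jv.calibrate_threshold(self._mk([220, 300], [50]),
                                     median_coverage=415.0)
        assert thr.percent == pytest.approx(100 * 220 / 415)

    def test_needs_both_classes(self):
        with pytest.raises(ValueError, match="calibration needs"):
            jv.calibrate_threshold(self._mk([100], []))


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.tuples(st.booleans(), st.integers(0, 400)),
                min_size=2, max_size=20))
def test_calibration_equals_exhaustive_cut_search(table):
    """The calibrated threshold equals a brute-force search over every
    observed coverage value."""
    confirmed = [c for ok, c in table if ok]
    others = [c for ok, c in table if not ok]
    tests = [_test(f"c{i}", round1="amplified", coverage=c)
             for i, c in enumerate(confirmed)]
    tests += [_test(f"x{i}", round1="none", round2=("amplified",), coverage=c)
              for i, c in enumerate(others)]
    classified, _ = jv.classify(tests)

    # brute force: smallest observed confirmed coverage c such that every
    # test with coverage >= c is confirmed
    brute = None
    for c in sorted(confirmed):
        if all(o < c for o in others):
            brute = c
            break
    if not confirmed or not others:
        with pytest.raises(ValueError):
            jv.calibrate_threshold(classified)
    elif brute is None:
        with pytest.raises(ValueError, match="no separating"):
            jv.calibrate_threshold(classified)
    else:
        assert jv.calibrate_threshold(classified).spanning_pairs == brute


class TestPromoteReliable:
    def _confirmed(self, jid, cov):
        out, _ = jv.classify([_test(jid, round1="amplified", coverage=cov)])
        return out[0]

    def test_confirmed_below_threshold_promoted(self):
        adjs = jv.promote_reliable([self._confirmed("j", 99)], 100)
        assert len(adjs) == 1
        assert adjs[0].source == "verified_junction"
        assert (adjs[0].sf_id_1, adjs[0].end_1) == ("a", "tail")

    def test_confirmed_at_threshold_not_promoted(self):
        assert jv.promote_reliable([self._confirmed("j", 100)], 100) == []

    def test_chimeric_never_promoted(self):
        out, _ = jv.classify([_test("j", round1="none", round2=("amplified",),
                                    coverage=1)])
        assert jv.promote_reliable(out, 100) == []
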