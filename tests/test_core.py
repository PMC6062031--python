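"""Split-search unit and property tests."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splitmatch.baselines import brute_force_find_all
from splitmatch.core import (
    count_occurrences,
    find_all,
    map_left_window,
    split_pattern,
)


@pytest.mark.parametrize(
    "pattern,p1,p2",
    [
        ("OGEM", "OG", "EM"),
        ("A", "", "A"),
        ("WORLD", "WO", "RLD"),
        ("AB", "A", "B"),
        ("ABC", "A", "BC"),
    ],
)
def test_split_halves(pattern, p1, p2):
    ps = split_pattern(pattern)
    assert (ps.p1, ps.p2) == (p1, p2)
    assert ps.p1 + ps.p2 == pattern
    assert ps.m1 == len(pattern) // 2
    assert ps.m2 == len(pattern) - len(pattern) // 2


def test_split_rule_all_lengths():
    """Even split; odd lengths put the extra character in the right half."""
    for m in range(1, 65):
        ps = split_pattern("x" * m)
        assert ps.m1 == m // 2 and ps.m2 == -(-m // 2)
        assert ps.m2 - ps.m1 in (0, 1) and ps.m2 >= 1


def test_split_rejects_empty():
    with pytest.raises(ValueError):
        split_pattern("")


def test_map_left_window_worked_example():
    # anchor 'M' at text index 6 with right half "EM" maps the left window
    # so that its last character sits at index 4
    assert map_left_window(6, 2) == 4
    assert "HELOGEMLED"[3:5] == "OG"


def test_map_left_window_at_text_start():
    for m in range(2, 20):
        m1, m2 = m // 2, -(-m // 2)
        assert map_left_window(m - 1, m2) == m1 - 1


def test_map_left_window_rejects_out_of_range():
    with pytest.raises(ValueError):
        map_left_window(1, 2)


def test_worked_example_occurrence_and_trace():
    occ, stats = find_all("OGEM", "HELOGEMLED")
    assert [(o.start, o.end) for o in occ] == [(3, 7)]
    # paper-style sweep of the right half from the text start: the anchor
    # probes E, L, O, G, E before the first hit on M at index 6
    occ2, stats2 = find_all("OGEM", "HELOGEMLED", anchor_from="text_start", trace=True)
    assert [o.start for o in occ2] == [3]
    assert stats2.anchor_trace[:6] == list("ELOGEM")
    assert stats2.anchor_trace[:6].index("M") == 5


@pytest.mark.parametrize(
    "pattern,text,starts",
    [
        ("AA", "AAAA", [0, 1, 2]),
        ("ZZ", "HELLO", []),
        ("A", "A", [0]),
        ("ABAB", "ABABAB", [0, 2]),
    ],
)
def test_find_all_examples(pattern, text, starts):
    occ, stats = find_all(pattern, text)
    assert [o.start for o in occ] == starts
    assert stats.matches == len(starts)
    assert all(text[o.start : o.end] == pattern for o in occ)


def test_find_all_degenerate_inputs():
    assert find_all("ABC", "AB")[0] == []  # m > n: empty, not an error
    occ, stats = find_all("A", "")
    assert occ == [] and stats.alignments == 0
    with pytest.raises(ValueError):
        find_all("", "ABC")


def test_dominance_pair_comparison_counts():
    """The constructed pair shows neither algorithm universally dominates
    and that per-phase instrumentation is exact."""
    n = 1000
    for pattern, split_total, brute_total in [("AAB", n - 2, 3 * (n - 2)),
                                              ("BAA", 3 * (n - 2), n - 2)]:
        _, s = find_all(pattern, "A" * n)
        _, b = brute_force_find_all(pattern, "A" * n)
        assert s.total_cmps == split_total
        assert b.total_cmps == brute_total


def test_stats_invariants_on_random_cases(small_random_cases):
    for cases in small_random_cases.values():
        for pattern, text in cases:
            occ, stats = find_all(pattern, text)
            m, n = len(pattern), len(text)
            assert stats.alignments == max(0, n - m + 1)
            assert stats.anchor_cmps == stats.alignments
            assert stats.total_cmps == stats.anchor_cmps + stats.p2_cmps + stats.p1_cmps
            assert stats.alignments <= stats.total_cmps <= m * stats.alignments \
                or stats.alignments == 0


def test_oracle_equivalence_random_cases(small_random_cases):
    for cases in small_random_cases.values():
        for pattern, text in cases:
            occ, _ = find_all(pattern, text)
            ref, _ = brute_force_find_all(pattern, text)
            assert [o.start for o in occ] == [o.start for o in ref]


def test_anchor_modes_agree_on_occurrences(small_random_cases):
    """Whole-window and text-start anchor sweeps find the same matches."""
    for cases in small_random_cases.values():
        for pattern, text in cases[:20]:
            a, _ = find_all(pattern, text)
            b, _ = find_all(pattern, text, anchor_from="text_start")
            assert a == b


def test_left_window_identity_on_all_windows(small_random_cases):
    """pmap = s + m1 - 1 for every window of every case."""
    for cases in small_random_cases.values():
        for pattern, text in cases[:20]:
            m = len(pattern)
            if m == 1:
                continue  # empty left half: no window to map
            m1, m2 = m // 2, m - m // 2
            for s in range(len(text) - m + 1):
                i0 = s + m - 1
                assert map_left_window(i0, m2) == s + m1 - 1


@settings(max_examples=200, derandomize=True)
@given(
    pattern=st.text(alphabet="AB", min_size=1, max_size=8),
    text=st.text(alphabet="AB", max_size=80),
)
def test_property_matches_brute_force(pattern, text):
    occ, _ = find_all(pattern, text)
    ref, _ = brute_force_find_all(pattern, text)
    assert [o.start for o in occ] == [o.start for o in ref]
    for o in occ:
        assert text[o.start : o.end] == pattern


def test_byte_and_codepoint_agree_on_ascii(small_random_cases):
    for pattern, text in small_random_cases[4][:30]:
        a, _ = find_all(pattern, text)
        b, _ = find_all(pattern.encode("ascii"), text.encode("ascii"))
        assert [o.start for o in a] == [o.start for o in b]


def test_count_occurrences():
    assert count_occurrences("OGEM", "HELOGEMLED") == 1
    assert count_occurrences("AA", "AAAA") == 3
    for p in ("X", "XY", "XYZ"):
        assert count_occurrences(p, p) == 1
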