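"""Instrumented classical exact-matching comparators.

Brute force, Boyer–Moore (strong good-suffix + bad-character), Horspool
(bad-character only) and Quick Search, each returning the complete
overlapping occurrence set and :class:`~splitmatch.core.SearchStats`.
Brute force doubles as the correctness oracle for every other algorithm.

Comparison accounting: the first character comparison of each examined
window counts as the anchor comparison (so ``anchor_cmps == alignments``
for all algorithms), the remainder as ``p2_cmps``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import Occurrence, SearchStats, Symbols, _source_id, _symbols

__all__ = [
    "BadCharTable",
    "GoodSuffixTable",
    "brute_force_find_all",
    "build_horspool_table",
    "build_quick_search_table",
    "build_good_suffix_table",
    "horspool_find_all",
    "boyer_moore_find_all",
    "quick_search_find_all",
]


@dataclass(frozen=True)
class BadCharTable:
    """Bad-character shift table: explicit entries plus a default shift.

    Horspool variant: shifts in [1, m], default m.
    Quick Search variant: shifts in [1, m+1], default m+1.
    """

    shifts: dict = field(default_factory=dict)
    default_shift: int = 1

    def shift(self, symbol) -> int:
        return self.shifts.get(symbol, self.default_shift)

    @property
    def n_entries(self) -> int:
        """Stored slots: specific entries plus the recorded default."""
        return len(self.shifts) + 1


@dataclass(frozen=True)
class GoodSuffixTable:
    """Per-position good-suffix shifts (strong rule).

    ``shifts[j]`` is the shift applied on a mismatch at pattern index
    ``j`` (i.e. the suffix ``pattern[j+1:]`` matched); ``match_shift`` is
    the shift after a full match (the pattern's period).  All entries are
    in [1, m].
    """

    shifts: tuple
    match_shift: int

    @property
    def n_entries(self) -> int:
        return len(self.shifts) + 1


def _check_pattern(pattern) -> None:
    if len(pattern) < 1:
        raise ValueError("empty pattern")


def brute_force_find_all(pattern: Symbols, text) -> tuple[list[Occurrence], SearchStats]:
    """Exhaustive window-by-window search, left-to-right verification.

    Unit shift after every window; this is the ground-truth oracle for
    every other algorithm's occurrence set.
    """
    _check_pattern(pattern)
    t, sid = _symbols(text), _source_id(text)
    m, n = len(pattern), len(t)
    stats = SearchStats()
    occ: list[Occurrence] = []
    for s in range(n - m + 1):
        stats.alignments += 1
        j = 0
        while j < m:
            if j == 0:
                stats.anchor_cmps += 1
            else:
                stats.p2_cmps += 1
            if t[s + j] != pattern[j]:
                break
            j += 1
        if j == m:
            occ.append(Occurrence(start=s, end=s + m, source_id=sid))
            stats.matches += 1
    return occ, stats


def build_horspool_table(pattern: Symbols) -> BadCharTable:
    """Horspool bad-character table.

    For each symbol in ``pattern[0:m-1]`` the shift is ``m - 1 - i`` with
    ``i`` its rightmost index in that prefix; every other symbol shifts
    by ``m``.
    """
    _check_pattern(pattern)
    m = len(pattern)
    shifts = {}
    for i in range(m - 1):
        shifts[pattern[i]] = m - 1 - i
    return BadCharTable(shifts=shifts, default_shift=m)


def build_quick_search_table(pattern: Symbols) -> BadCharTable:
    """Quick Search bad-character table, keyed on the symbol just past the
    window: shift ``m - i`` for the rightmost index ``i`` of each pattern
    symbol, default ``m + 1``."""
    _check_pattern(pattern)
    m = len(pattern)
    shifts = {}
    for i in range(m):
        shifts[pattern[i]] = m - i
    return BadCharTable(shifts=shifts, default_shift=m + 1)


def _suffix_lengths(pattern) -> list[int]:
    # suff[i] = length of the longest suffix of pattern[:i+1] that is also
    # a suffix of the whole pattern (classic Boyer–Moore preprocessing)
    m = len(pattern)
    suff = [0] * m
    suff[m - 1] = m
    g = m - 1
    f = m - 1
    for i in range(m - 2, -1, -1):
        if i > g and suff[i + m - 1 - f] < i - g:
            suff[i] = suff[i + m - 1 - f]
        else:
            if i < g:
                g = i
            f = i
            while g >= 0 and pattern[g] == pattern[g + m - 1 - f]:
                g -= 1
            suff[i] = f - g
    return suff


def build_good_suffix_table(pattern: Symbols) -> GoodSuffixTable:
    """Strong good-suffix table for Boyer–Moore."""
    _check_pattern(pattern)
    m = len(pattern)
    suff = _suffix_lengths(pattern)
    shifts = [m] * m
    j = 0
    for i in range(m - 1, -1, -1):
        if suff[i] == i + 1:  # pattern[:i+1] is a border of the pattern
            while j < m - 1 - i:
                if shifts[j] == m:
                    shifts[j] = m - 1 - i
                j += 1
    for i in range(m - 1):
        shifts[m - 1 - suff[i]] = m - 1 - i
    # shift after a full match = the pattern's period
    match_shift = shifts[0] if m > 1 else 1
    return GoodSuffixTable(shifts=tuple(shifts), match_shift=match_shift)


def horspool_find_all(pattern: Symbols, text) -> tuple[list[Occurrence], SearchStats]:
    """Horspool search: right-to-left verification, bad-character shift
    keyed on the text symbol under the window's last position."""
    _check_pattern(pattern)
    t, sid = _symbols(text), _source_id(text)
    m, n = len(pattern), len(t)
    stats = SearchStats()
    occ: list[Occurrence] = []
    if m > n:
        return occ, stats
    table = build_horspool_table(pattern)
    s = 0
    while s <= n - m:
        stats.alignments += 1
        j = m - 1
        while j >= 0:
            if j == m - 1:
                stats.anchor_cmps += 1
            else:
                stats.p2_cmps += 1
            if t[s + j] != pattern[j]:
                break
            j -= 1
        if j < 0:
            occ.append(Occurrence(start=s, end=s + m, source_id=sid))
            stats.matches += 1
        s += table.shift(t[s + m - 1])
    return occ, stats


def boyer_moore_find_all(pattern: Symbols, text) -> tuple[list[Occurrence], SearchStats]:
    """Boyer–Moore: right-to-left verification, shift = max(good suffix,
    bad character), floor 1."""
    _check_pattern(pattern)
    t, sid = _symbols(text), _source_id(text)
    m, n = len(pattern), len(t)
    stats = SearchStats()
    occ: list[Occurrence] = []
    if m > n:
        return occ, stats
    # bad-character distances over pattern[:m-1], default m
    bc = {pattern[i]: m - 1 - i for i in range(m - 1)}
    gs = build_good_suffix_table(pattern)
    s = 0
    while s <= n - m:
        stats.alignments += 1
        j = m - 1
        while j >= 0:
            if j == m - 1:
                stats.anchor_cmps += 1
            else:
                stats.p2_cmps += 1
            if t[s + j] != pattern[j]:
                break
            j -= 1
        if j < 0:
            occ.append(Occurrence(start=s, end=s + m, source_id=sid))
            stats.matches += 1
            s += gs.match_shift
        else:
            bad = bc.get(t[s + j], m) - (m - 1 - j)
            s += max(gs.shifts[j], bad, 1)
    return occ, stats


def quick_search_find_all(pattern: Symbols, text) -> tuple[list[Occurrence], SearchStats]:
    """Quick Search: left-to-right verification, shift keyed on the text
    symbol immediately after the window (default shift m+1 at text end)."""
    _check_pattern(pattern)
    t, sid = _symbols(text), _source_id(text)
    m, n = len(pattern), len(t)
    stats = SearchStats()
    occ: list[Occurrence] = []
    if m > n:
        return occ, stats
    table = build_quick_search_table(pattern)
    s = 0
    while s <= n - m:
        stats.alignments += 1
        j = 0
        while j < m:
            if j == 0:
                stats.anchor_cmps += 1
            else:
                stats.p2_cmps += 1
            if t[s + j] != pattern[j]:
                break
            j += 1
        if j == m:
            occ.append(Occurrence(start=s, end=s + m, source_id=sid))
            stats.matches += 1
        if s + m < n:
            s += table.shift(t[s + m])
        else:
            s += table.default_shift
    return occ, stats
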