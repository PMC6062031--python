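"""Split-pattern exact search.

The query pattern ``p`` is divided into a left half ``p1`` (length
``m1 = floor(m/2)``) and a right half ``p2`` (length ``m2 = ceil(m/2)``;
an odd-length pattern gives the extra character to the right half).  The
search anchors on the *last* character of ``p2``: at each text position the
anchor character is compared first, the remaining right-half characters are
verified right-to-left only on an anchor hit, and the left half is then
checked within the window ending at ``pmap = i0 - m2`` (the last index of
the left-half window, where ``i0`` is the anchor's text index).  The window
always advances by exactly one position — the method uses no precomputed
shift tables, which is the point: its auxiliary space is zero.

All searches report the complete overlapping occurrence set and carry full
comparison instrumentation so that algorithms can be compared by counted
work rather than wall-clock time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

__all__ = [
    "PatternSplit",
    "Occurrence",
    "SearchStats",
    "split_pattern",
    "map_left_window",
    "find_all",
    "count_occurrences",
]

#: Anything searchable: a decoded string, raw bytes, or any indexable
#: sequence of comparable symbols.
Symbols = Union[str, bytes, Sequence]


@dataclass(frozen=True)
class PatternSplit:
    """A pattern with its two halves.

    Invariants: ``p1 + p2 == pattern``, ``m1 = floor(m/2)``,
    ``m2 = ceil(m/2)``; ``p1`` is empty only for a single-character pattern.
    """

    pattern: Symbols
    p1: Symbols
    p2: Symbols

    @property
    def m(self) -> int:
        return len(self.pattern)

    @property
    def m1(self) -> int:
        return len(self.p1)

    @property
    def m2(self) -> int:
        return len(self.p2)


@dataclass(frozen=True)
class Occurrence:
    """A match location, 0-based half-open: ``text[start:end] == pattern``."""

    start: int
    end: int
    source_id: str = ""


@dataclass
class SearchStats:
    """Comparison accounting for one full-text search.

    ``alignments`` counts windows (anchor probes) examined; exactly one
    anchor comparison is spent per window, so ``anchor_cmps == alignments``.
    ``p2_cmps`` are the remaining right-half comparisons, ``p1_cmps`` the
    left-half comparisons.
    """

    alignments: int = 0
    anchor_cmps: int = 0
    p2_cmps: int = 0
    p1_cmps: int = 0
    matches: int = 0
    #: anchor probe characters, recorded only when tracing is requested
    anchor_trace: Optional[list] = field(default=None, repr=False)

    @property
    def total_cmps(self) -> int:
        return self.anchor_cmps + self.p2_cmps + self.p1_cmps


def _symbols(text) -> Symbols:
    # corpus_io.Text quacks via .symbols; plain sequences pass through
    return getattr(text, "symbols", text)


def _source_id(text) -> str:
    return getattr(text, "source_id", "")


def split_pattern(pattern: Symbols) -> PatternSplit:
    """Split ``pattern`` into its left and right halves.

    The right half gets the extra character when the length is odd:
    ``"OGEM"`` → ``("OG", "EM")``, ``"WORLD"`` → ``("WO", "RLD")``,
    ``"A"`` → ``("", "A")``.

    Raises
    ------
    ValueError
        If the pattern is empty (no defined split).
    """
    m = len(pattern)
    if m < 1:
        raise ValueError("cannot split an empty pattern")
    m1 = m // 2
    return PatternSplit(pattern=pattern, p1=pattern[:m1], p2=pattern[m1:])


def map_left_window(i0: int, m2: int) -> int:
    """Map an anchor hit to the left-half window.

    Given the text index ``i0`` where the right half's last character
    matched and the right-half length ``m2``, returns ``pmap = i0 - m2``,
    the text index of the *last* character of the left-half window.  For a
    window starting at ``s`` this equals ``s + m1 - 1``.

    Raises
    ------
    ValueError
        If ``i0 < m2`` (the left window would extend past the text start).
    """
    if i0 < m2:
        raise ValueError(
            f"anchor index {i0} < right-half length {m2}: "
            "left window would extend past the text start"
        )
    return i0 - m2


def find_all(
    pattern: Symbols,
    text,
    *,
    anchor_from: str = "window",
    trace: bool = False,
) -> tuple[list[Occurrence], SearchStats]:
    """Find every occurrence of ``pattern`` in ``text`` by split search.

    Returns the complete, ascending, overlapping occurrence list together
    with :class:`SearchStats`.  The scan uses unit shifts only — no
    preprocessing and no skip table.

    Parameters
    ----------
    pattern
        Nonempty symbol sequence.
    text
        A :class:`~splitmatch.corpus_io.Text`, ``str``, ``bytes`` or any
        indexable symbol sequence.
    anchor_from
        ``"window"`` (default): the anchor sweeps full-pattern windows,
        ``i0 = m-1 .. n-1``, so ``alignments = n - m + 1``.
        ``"text_start"``: the right half alone is swept from the start of
        the text, ``i0 = m2-1 .. n-1``; the leading probes where the left
        half cannot fit are counted as alignments but can never yield an
        occurrence.  Both modes return the identical occurrence set.
    trace
        Record the anchor probe character of every window in
        ``stats.anchor_trace``.

    Raises
    ------
    ValueError
        If the pattern is empty or ``anchor_from`` is unknown.
    """
    if anchor_from not in ("window", "text_start"):
        raise ValueError(f"unknown anchor_from: {anchor_from!r}")
    split = split_pattern(pattern)  # rejects the empty pattern
    t = _symbols(text)
    sid = _source_id(text)
    m, m1, m2 = split.m, split.m1, split.m2
    p1, p2 = split.p1, split.p2
    n = len(t)

    stats = SearchStats(anchor_trace=[] if trace else None)
    occurrences: list[Occurrence] = []
    if m > n:
        return occurrences, stats

    anchor = p2[m2 - 1]
    first_i0 = m - 1 if anchor_from == "window" else m2 - 1
    for i0 in range(first_i0, n):
        stats.alignments += 1
        stats.anchor_cmps += 1
        if trace:
            stats.anchor_trace.append(t[i0])
        if t[i0] != anchor:
            continue
        s = i0 - m + 1  # window start; may be negative in text_start mode
        # verify the rest of p2 right-to-left from the anchor
        ok = True
        for j in range(m2 - 2, -1, -1):
            stats.p2_cmps += 1
            if t[s + m1 + j] != p2[j]:
                ok = False
                break
        if not ok:
            continue
        if s < 0:
            # right half matched but the full window does not fit
            continue
        # left half within the window ending at pmap, right-to-left
        if m1 > 0:
            pmap = map_left_window(i0, m2)
            assert pmap == s + m1 - 1
            for j in range(m1 - 1, -1, -1):
                stats.p1_cmps += 1
                if t[s + j] != p1[j]:
                    ok = False
                    break
        if ok:
            occurrences.append(Occurrence(start=s, end=s + m, source_id=sid))
            stats.matches += 1
    return occurrences, stats


def count_occurrences(pattern: Symbols, text) -> int:
    """Number of (overlapping) occurrences of ``pattern`` in ``text``."""
    occurrences, _ = find_all(pattern, text)
    return len(occurrences)
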