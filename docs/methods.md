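# Methods

## The split search

The query `p` of length `m` is divided as `p = p1 · p2` with
`m1 = ⌊m/2⌋` and `m2 = ⌈m/2⌉`; an odd-length query gives the larger half
to `p2`, and a single-character query has an empty `p1`. The scan slides a
window of length `m` left-to-right with unit shifts. At each window the
anchor — the last character of `p2`, at text index `i0 = s + m − 1` — is
compared first. Only on an anchor hit are the remaining `m2 − 1`
right-half characters verified right-to-left, after which `p1` is verified
right-to-left inside the window whose last index is the position mapping
`pmap = i0 − m2 = s + m1 − 1`. The shift is +1 after an anchor miss, a
partial-verify miss, and a full match alike, so the complete overlapping
occurrence set is reported and no preprocessing of any kind is performed:
the algorithm's auxiliary space is identically zero.

Two readings of the scan's starting point are defensible, and both are
implemented behind `find_all(..., anchor_from=...)`:

* `"window"` (default): the anchor sweeps full-pattern windows,
  `i0 = m−1 … n−1`, so `alignments = n − m + 1` and the analytic
  comparison-count fixtures below hold exactly.
* `"text_start"`: the right half alone is swept from the beginning of the
  text, `i0 = m2−1 … n−1`, reproducing the narrated worked example (for
  `"OGEM"` in `"HELOGEMLED"` the anchor probes E, L, O, G, E before the
  first hit on M at index 6). Leading probes where the left half cannot
  fit are counted but cannot yield an occurrence.

Both modes return the identical occurrence set; only the comparison
attribution of the leading probes differs. The related ambiguity of where
to resume after a hit is resolved as +1 (resuming *at* the hit would not
terminate).

### Instrumentation

`SearchStats` separates comparisons by phase: `anchor_cmps` (exactly one
per window examined, so `anchor_cmps = alignments`), `p2_cmps` (remaining
right-half), `p1_cmps` (left-half). Two constructed fixtures pin the
accounting and show that neither the split search nor brute force
dominates universally: on `'A'×n`, the pattern `"AAB"` (anchor `B` never
matches) costs the split search `n−2` comparisons against `3(n−2)` for
brute force, while `"BAA"` (anchor always matches, left half always fails)
reverses the two counts exactly.

## Comparators

Brute force (left-to-right verification, unit shift) is the ground-truth
oracle. Horspool shifts by the bad-character rule keyed on the text symbol
under the window's last position (shifts in `[1, m]`, default `m`). Quick
Search keys on the symbol just past the window (shifts in `[1, m+1]`,
default `m+1`). Boyer–Moore combines the strong good-suffix rule with the
bad-character rule (`shift = max(gs, bc, 1)`; after a full match it shifts
by the pattern's period). The strong good-suffix preprocessing is the
classical suffix-length construction; its correctness is anchored in the
tests to an independent try-every-shift computation, exhaustively for all
patterns of length ≤ 8 over `{A,B}` and length ≤ 5 over `{A,C,G,T}` plus
2000 seeded longer DNA patterns (the full 4-letter enumeration to length 8
adds nothing but runtime to a unit suite). All comparators report the
complete overlapping occurrence set; their first comparison per window is
attributed to `anchor_cmps` so that `anchor_cmps = alignments` holds
uniformly.

Turbo-BM, SSM/BMT-style hybrids, hashing and bit-parallel methods are out
of scope; the benchmark registry (`bench.ALGORITHMS`) is name-keyed so
they can be plugged in without harness changes.

## Portable benchmarking

Wall-clock milliseconds and JVM heap profiles do not transfer across
machines, so the harness reports counted work. Each
(corpus × pattern × algorithm) cell is run `repeats = 10` times with the
mean wall time recorded for orientation only; the asserted metrics are
total comparisons, alignments examined, occurrence count, and `aux_space`
— the number of precomputed table slots an algorithm stores (specific
bad-character entries plus the recorded default; Boyer–Moore adds its
`m`-entry good-suffix table and match shift; split and brute force store
nothing, hence 0). A cell whose algorithm raises is logged and skipped so
one failure cannot abort a suite. Pattern-length categories are short 1–4,
medium 5–8, long ≥ 9 characters (a conflicting 4–7 reading of "medium"
exists; the prose definition is used).

## Synthetic corpora

The generators stand in for natural-language and biological corpora at
desk scale; all are pure functions of parameters and seed (numpy
`default_rng`).

* `gen_uniform_text(alphabet, n, seed)` — i.i.d. uniform symbols; named
  alphabets of size 2 (binary), 4 (DNA), 20 (protein) and 64 cover the
  regimes from highly repetitive to near-unique anchors.
* `gen_zipf_text(vocab_size, n_words, exponent, seed)` — a space-separated
  word stream whose rank-frequency follows a truncated Zipf law; exponent
  defaults to 1.0, the classical value for natural language. Default
  vocabulary 1000 words, word lengths 2–8 lowercase letters.
* `plant_pattern(text, pattern, k, seed)` — overwrites `k` seeded
  non-overlapping windows. Ground truth is then the brute-force oracle on
  the modified text, never `k` itself: planting can create accidental
  occurrences or overlap-merge with the background (e.g. two adjacent
  plants of `"AA"` yield three overlapping occurrences).
* `sample_patterns(text, category, count, seed)` — substrings of the
  corpus itself, guaranteeing at least one true occurrence per query.

What these fixtures do *not* model: real word-length and n-gram
statistics of any specific language, diacritic composition, or genomic
repeat structure. Passing tests therefore establish algorithmic
correctness and exact comparison accounting, not performance claims on
any particular natural corpus.

## Text handling

Texts are decoded to code points by default and every comparison is per
code point; a byte mode searches the raw (newline-normalized) byte stream
for reproducing byte-level behaviour of single-byte or UTF-encoded data —
for pure-ASCII inputs the two modes provably agree. No Unicode
normalization is applied unless NFC is requested. Coordinates are 0-based
half-open internally and in JSON/BED; TSV offers 1-based inclusive
rendering. Searches are case-sensitive unless case-folding is requested.
FASTA records are searched independently (no cross-record windows);
minus-strand motif scanning searches the reverse-complemented query
against the forward sequence and reports forward coordinates with
strand `-`.

## Problem sizes

The randomized equivalence suite uses 1000 seeded cases per alphabet size
in {2, 4, 20, 64} with `1 ≤ m ≤ 12` and `m ≤ n ≤ 300`; half the queries
are true substrings of their text so matches actually occur.
Planted-pattern recovery uses a 10^5-symbol DNA corpus and a 10^4-word
Zipf stream with five plants per length category. These sizes exercise
every code path (overlap, self-overlap, anchor-rare and anchor-common
regimes) while keeping the full suite in the tens of seconds.

## Known limitations

* Unit shift makes the split search Θ(n) windows always; it wins on
  comparison count only when the anchor character is locally rare, and
  the `"BAA"` fixture shows the losing regime.
* `aux_space` counts table *entries*, not bytes; it is a proxy, not a
  heap measurement.
* Multi-pattern, approximate and normalization-aware matching are out of
  scope.
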