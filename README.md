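# splitmatch

Exact pattern matching by query splitting, with instrumented classical
comparators and a portable benchmark harness.

## The problem and the method

Exact matching — reporting every position `s` of a text `t` (length `n`)
where a query `p` (length `m`) occurs verbatim — underlies motif scanning
in DNA and protein sequences, text retrieval and intrusion detection.
Classical fast algorithms (Boyer–Moore, Horspool, Quick Search) buy their
speed with precomputed shift tables, i.e. auxiliary memory per query.

The split search here takes the opposite trade. The query is divided into
two halves,

    p = p1 · p2,   m1 = ⌊m/2⌋,  m2 = ⌈m/2⌉

(an odd-length query puts the extra character in the right half). At each
window the *last* character of `p2` — the anchor — is compared first
against `t[i0]`; only on an anchor hit are the remaining right-half
characters verified right-to-left, after which the left half is checked in
the window whose last index is given by the position mapping

    pmap = i0 − m2   ( = s + m1 − 1 for a window starting at s).

The window then advances by exactly one position. No table is ever built:
the algorithm's auxiliary space is zero, and most windows cost a single
character comparison whenever the anchor character is locally rare.

Because machine timings are hardware-bound, the package benchmarks by
counted work instead: character comparisons per phase, windows examined,
and an auxiliary-space proxy (precomputed table slots per algorithm). The
comparators — brute force, Boyer–Moore (strong good suffix + bad
character), Horspool, Quick Search — are instrumented the same way, and
brute force doubles as the correctness oracle.

## Worked example

```sh
$ splitmatch split OGEM
pattern='OGEM' m=4
p1='OG' m1=2
p2='EM' m2=2

$ printf 'HELOGEMLED' > t.txt
$ splitmatch search OGEM t.txt --format json --stats
{
  "pattern": "OGEM",
  "algorithm": "split",
  "coordinates": "0-based, half-open",
  "stats": {
    "alignments": 7,
    "anchor_cmps": 7,
    "p2_cmps": 1,
    "p1_cmps": 2,
    "total_cmps": 10,
    "matches": 1
  },
  "occurrences": [
    {"source_id": "t.txt", "start": 3, "end": 7}
  ]
}
```

All 7 windows of the length-10 text were examined, each paying one anchor
comparison; only the window at `s = 3` survived the anchor, costing one
further right-half comparison (`E`) and two left-half comparisons
(`G`, `O`), for 10 comparisons in total and the single match
`t[3:7] = "OGEM"`.

The same interface searches FASTA (per record, optionally both strands
with BED output) and raw bytes:

```sh
splitmatch search ACGT genome.fa --fasta --both-strands --format bed
splitmatch search OGEM corpus.txt --algo horspool --byte-mode
splitmatch benchmark --config suite.yaml --format markdown
splitmatch generate --profile dna --n 100000 --seed 1 --plant TTAGGG --k 3
```

The library mirrors the CLI: `splitmatch.find_all(pattern, text)` returns
`(occurrences, stats)`, `splitmatch.run_suite(...)` the benchmark records.

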