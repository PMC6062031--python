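"""Readers and writers for the formats the tool touches.

Plain-text corpora (any Python codec, code-point or byte mode), FASTA
records (via Biopython), one-pattern-per-line lists, and occurrence output
in TSV / JSON / BED.  Coordinates are 0-based half-open internally and in
JSON/BED; TSV offers an optional 1-based inclusive rendering.
"""

from __future__ import annotations

import json
import unicodedata
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

from Bio import SeqIO

from .core import Occurrence, SearchStats

__all__ = [
    "Text",
    "FastaRecord",
    "read_text",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "read_patterns",
    "write_occurrences",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass(frozen=True)
class Text:
    """A searchable symbol sequence with its provenance.

    ``symbols`` is a ``str`` of code points (mode ``"codepoint"``) or raw
    ``bytes`` (mode ``"byte"``).
    """

    symbols: Union[str, bytes]
    source_id: str = ""
    encoding: str = "utf-8"
    mode: str = "codepoint"

    def __post_init__(self):
        if self.mode not in ("codepoint", "byte"):
            raise ValueError(f"unknown mode: {self.mode!r}")
        if self.mode == "byte" and not isinstance(self.symbols, bytes):
            raise TypeError("byte mode requires bytes symbols")

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class FastaRecord:
    id: str
    description: str
    sequence: str


def read_text(
    path,
    encoding: str = "utf-8",
    mode: str = "codepoint",
    *,
    nfc: bool = False,
) -> Text:
    """Read a whole file as one searchable :class:`Text`.

    Universal newline translation is applied in both modes; newlines then
    remain ordinary symbols of the searched text.  In code-point mode an
    undecodable byte raises with its offset named; ``nfc=True`` applies
    Unicode NFC normalization after decoding (off by default).
    """
    path = Path(path)
    raw = path.read_bytes()
    raw = raw.replace(b"\r\n", b"\n").replace(b"\r", b"\n")
    if mode == "byte":
        return Text(symbols=raw, source_id=path.name, encoding=encoding, mode="byte")
    if mode != "codepoint":
        raise ValueError(f"unknown mode: {mode!r}")
    try:
        decoded = raw.decode(encoding)
    except UnicodeDecodeError as exc:
        raise ValueError(
            f"{path}: undecodable byte at offset {exc.start} under {encoding!r}"
        ) from exc
    if nfc:
        decoded = unicodedata.normalize("NFC", decoded)
    return Text(symbols=decoded, source_id=path.name, encoding=encoding, mode="codepoint")


def read_fasta(path) -> list[FastaRecord]:
    """Read a (possibly line-wrapped, multi-record) FASTA file.

    Records with an empty sequence are skipped with a warning; sequence
    data before any header is an error.
    """
    records: list[FastaRecord] = []
    with open(path) as handle:
        # reject leading sequence data explicitly (parsers vary here)
        for line in handle:
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise ValueError(f"{path}: sequence data before any FASTA header")
            break
        handle.seek(0)
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq)
            if not seq:
                warnings.warn(f"{path}: record {rec.id!r} has an empty sequence; skipped")
                continue
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            records.append(FastaRecord(id=rec.id, description=desc, sequence=seq))
    return records


def write_fasta(records: Iterable[FastaRecord], path, width: int = 60) -> None:
    """Write records as wrapped FASTA."""
    with open(path, "w") as handle:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            handle.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


def reverse_complement(sequence: str) -> str:
    """Reverse-complement a DNA sequence over A/C/G/T/N (case preserved).

    Raises
    ------
    ValueError
        Naming the first offending symbol and its position.
    """
    for i, ch in enumerate(sequence):
        if ch not in "ACGTNacgtn":
            raise ValueError(
                f"non-ACGTN symbol {ch!r} at position {i} in sequence"
            )
    return sequence.translate(_COMPLEMENT)[::-1]


def read_patterns(path, encoding: str = "utf-8") -> list[str]:
    """Read a one-pattern-per-line file.

    Lines are stripped of the trailing newline only (internal spaces are
    preserved verbatim), blank lines are skipped, order is kept.

    Raises
    ------
    ValueError
        If no usable pattern remains.
    """
    patterns: list[str] = []
    with open(path, encoding=encoding, newline=None) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if line == "":
                continue
            patterns.append(line)
    if not patterns:
        raise ValueError(f"{path}: no usable patterns")
    return patterns


def write_occurrences(
    occurrences: Sequence[Occurrence],
    stats: SearchStats,
    format: str,
    *,
    pattern: str = "",
    algorithm: str = "",
    one_based: bool = False,
    strand: str = "+",
    fasta_source: bool = False,
) -> str:
    """Serialize an occurrence set (with its search stats) to a string.

    ``format`` is ``"tsv"``, ``"json"`` or ``"bed"``.  JSON and BED are
    0-based half-open; TSV switches to 1-based inclusive coordinates under
    ``one_based=True``.  BED requires a FASTA source (record ids become the
    BED chromosome column).
    """
    if format == "bed":
        if not fasta_source:
            raise ValueError("BED output requires a FASTA source")
        lines = [
            f"{o.source_id}\t{o.start}\t{o.end}\t{pattern}\t0\t{strand}"
            for o in occurrences
        ]
        return "\n".join(lines) + ("\n" if lines else "")
    if format == "json":
        payload = {
            "pattern": pattern,
            "algorithm": algorithm,
            "coordinates": "0-based, half-open",
            "stats": {
                "alignments": stats.alignments,
                "anchor_cmps": stats.anchor_cmps,
                "p2_cmps": stats.p2_cmps,
                "p1_cmps": stats.p1_cmps,
                "total_cmps": stats.total_cmps,
                "matches": stats.matches,
            },
            "occurrences": [
                {"source_id": o.source_id, "start": o.start, "end": o.end}
                for o in occurrences
            ],
        }
        return json.dumps(payload, indent=2) + "\n"
    if format == "tsv":
        header = "#source_id\tpattern\tstart\tend\talgorithm\ttotal_cmps"
        rows = [header]
        for o in occurrences:
            start, end = (o.start + 1, o.end) if one_based else (o.start, o.end)
            rows.append(
                f"{o.source_id}\t{pattern}\t{start}\t{end}\t{algorithm}\t{stats.total_cmps}"
            )
        return "\n".join(rows) + "\n"
    raise ValueError(f"unknown output format: {format!r}")
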