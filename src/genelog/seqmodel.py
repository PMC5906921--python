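"""Sequence records, chunked-message encoding, GC counting, back-markers.

The repository stores each sequence as one message, or — for sequences
longer than the 100,000-nt chunk threshold — as a series of chunk messages.
The chunk key carries ``accession/index/count`` so a consumer can tell when
it holds every piece, but the *partitioning* bytes are the accession alone:
all chunks of one sequence land in one partition, in append order, and can
be reassembled by any single group member.

GC content is the fraction of unambiguous bases that are G or C, i.e.
(G+C)/(A+C+G+T); Ns and other ambiguity codes are counted separately and
excluded from the denominator. Counts are additive across chunks, so
per-chunk results aggregate exactly to the whole-sequence value.

A *back-marker* is a sentinel message appended at the end of each partition
once a producer has finished a sweep; a consumer that has seen the marker
on every partition knows it has touched everything.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import IO, Iterable, Iterator

from .logstore import Message, Topic

__all__ = [
    "SequenceRecord",
    "SequenceChunk",
    "BaseCounts",
    "BackMarker",
    "FastaFormatError",
    "read_fasta",
    "write_fasta",
    "chunk_sequence",
    "reassemble",
    "encode_chunk_message",
    "decode_chunk_message",
    "accession_partitioning_bytes",
    "gc_counts",
    "gc_fraction",
    "BACK_MARKER_PREFIX",
    "is_back_marker",
    "parse_back_marker",
    "emit_back_markers",
    "sweep_complete",
]

DEFAULT_CHUNK_SIZE = 100_000
BACK_MARKER_PREFIX = b"\x00FOG/"

_KEY_SEPARATOR = "/"


class FastaFormatError(ValueError):
    def __init__(self, message: str, line_number: int) -> None:
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class SequenceRecord:
    """A FASTA record: accession (first header token), description, residues."""

    accession: str
    description: str
    residues: str


@dataclass(frozen=True)
class SequenceChunk:
    """A bounded slice of one record: index ``chunk_index`` of ``chunk_count``."""

    accession: str
    chunk_index: int
    chunk_count: int
    residues: str

    def __post_init__(self) -> None:
        if not 0 <= self.chunk_index < self.chunk_count:
            raise ValueError(
                f"chunk_index {self.chunk_index} out of range for "
                f"chunk_count {self.chunk_count}"
            )


# -- FASTA I/O -------------------------------------------------------------


def read_fasta(stream: IO[str]) -> Iterator[SequenceRecord]:
    """Stream records from FASTA text, one at a time.

    Line wrapping is removed, CRLF tolerated, blank lines skipped. Residue
    content before the first header raises :class:`FastaFormatError` with
    the offending line number.
    """
    accession: str | None = None
    description = ""
    parts: list[str] = []
    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\r\n")
        if not line.strip():
            continue
        if line.startswith(">"):
            if accession is not None:
                yield SequenceRecord(accession, description, "".join(parts))
            header = line[1:].strip()
            if not header:
                raise FastaFormatError("empty FASTA header", line_no)
            accession, _, description = header.partition(" ")
            description = description.strip()
            parts = []
        else:
            if accession is None:
                raise FastaFormatError(
                    "sequence data before first '>' header", line_no
                )
            parts.append(line.strip())
    if accession is not None:
        yield SequenceRecord(accession, description, "".join(parts))


def write_fasta(records: Iterable[SequenceRecord], stream: IO[str],
                line_width: int = 70) -> int:
    """Write standard FASTA; inverse of :func:`read_fasta`. Returns count."""
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    count = 0
    for rec in records:
        header = rec.accession
        if rec.description:
            header += " " + rec.description
        stream.write(f">{header}\n")
        residues = rec.residues
        for i in range(0, len(residues), line_width):
            stream.write(residues[i : i + line_width] + "\n")
        count += 1
    return count


# -- chunking and message encoding -----------------------------------------


def chunk_sequence(record: SequenceRecord,
                   chunk_size: int = DEFAULT_CHUNK_SIZE) -> list[SequenceChunk]:
    """Slice a record into ceil(len/chunk_size) chunks.

    A record no longer than ``chunk_size`` yields a single chunk; an empty
    record yields a single empty chunk. All chunks but the last have length
    exactly ``chunk_size``, so concatenation restores the original residues.
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    residues = record.residues
    n = max(1, -(-len(residues) // chunk_size))
    return [
        SequenceChunk(record.accession, i, n,
                      residues[i * chunk_size : (i + 1) * chunk_size])
        for i in range(n)
    ]


def reassemble(chunks: Iterable[SequenceChunk]) -> SequenceRecord:
    """Concatenate one accession's chunks in index order.

    Raises ValueError naming the missing indices if the set is incomplete,
    or on duplicate indices / inconsistent chunk counts.
    """
    chunks = list(chunks)
    if not chunks:
        raise ValueError("no chunks to reassemble")
    accession = chunks[0].accession
    count = chunks[0].chunk_count
    for c in chunks:
        if c.accession != accession:
            raise ValueError(f"mixed accessions: {accession!r} and {c.accession!r}")
        if c.chunk_count != count:
            raise ValueError(
                f"conflicting chunk counts for {accession!r}: {count} and {c.chunk_count}"
            )
    seen = {c.chunk_index for c in chunks}
    if len(seen) != len(chunks):
        raise ValueError(f"duplicate chunk indices for {accession!r}")
    missing = sorted(set(range(count)) - seen)
    if missing:
        raise ValueError(f"incomplete sequence {accession!r}: missing chunks {missing}")
    ordered = sorted(chunks, key=lambda c: c.chunk_index)
    return SequenceRecord(accession, "", "".join(c.residues for c in ordered))


def encode_chunk_message(chunk: SequenceChunk) -> tuple[bytes, bytes]:
    """Chunk -> (key, value): key ``accession/index/count``, value residues."""
    if _KEY_SEPARATOR in chunk.accession:
        raise ValueError(
            f"accession {chunk.accession!r} contains reserved separator "
            f"{_KEY_SEPARATOR!r}"
        )
    if chunk.accession.startswith("\x00"):
        raise ValueError("accession may not start with the reserved byte 0")
    key = f"{chunk.accession}/{chunk.chunk_index}/{chunk.chunk_count}".encode()
    return key, chunk.residues.encode()


def decode_chunk_message(key: bytes, value: bytes) -> SequenceChunk:
    accession, index, count = key.decode().rsplit(_KEY_SEPARATOR, 2)
    return SequenceChunk(accession, int(index), int(count), value.decode())


def accession_partitioning_bytes(key: bytes) -> bytes:
    """Partitioning bytes for a chunk key: the accession alone.

    Used as the producer's custom key extractor so every chunk of a sequence
    maps to the same partition regardless of chunk index.
    """
    return key.split(_KEY_SEPARATOR.encode(), 1)[0]


# -- GC counting ------------------------------------------------------------


@dataclass(frozen=True)
class BaseCounts:
    """Per-base tallies; ``other`` holds Ns and ambiguity codes."""

    a: int = 0
    c: int = 0
    g: int = 0
    t: int = 0
    other: int = 0

    def __add__(self, rhs: "BaseCounts") -> "BaseCounts":
        return BaseCounts(self.a + rhs.a, self.c + rhs.c, self.g + rhs.g,
                          self.t + rhs.t, self.other + rhs.other)

    @property
    def total(self) -> int:
        return self.a + self.c + self.g + self.t + self.other


def gc_counts(residues: str) -> BaseCounts:
    """Case-insensitive base counts; additive over concatenation."""
    upper = residues.upper()
    a = upper.count("A")
    c = upper.count("C")
    g = upper.count("G")
    t = upper.count("T")
    return BaseCounts(a, c, g, t, len(upper) - a - c - g - t)


def gc_fraction(counts: BaseCounts) -> float | None:
    """(G+C)/(A+C+G+T); ``None`` (not 0) when no unambiguous bases exist."""
    denominator = counts.a + counts.c + counts.g + counts.t
    if denominator == 0:
        return None
    return (counts.g + counts.c) / denominator


# -- back-markers ------------------------------------------------------------


@dataclass(frozen=True)
class BackMarker:
    topic: str
    partition: int
    sweep_id: str


def _marker_key(sweep_id: str) -> bytes:
    return BACK_MARKER_PREFIX + sweep_id.encode()


def is_back_marker(key: bytes | None) -> bool:
    return key is not None and key.startswith(BACK_MARKER_PREFIX)


def parse_back_marker(msg: Message) -> BackMarker:
    if not is_back_marker(msg.key):
        raise ValueError("message is not a back-marker")
    payload = json.loads(msg.value.decode())
    return BackMarker(topic=payload["topic"], partition=payload["partition"],
                      sweep_id=payload["sweep_id"])


def emit_back_markers(topic: Topic, sweep_id: str) -> dict[int, int]:
    """Append exactly one end-of-sweep marker to every partition.

    Returns the marker offset per partition. A sweep id already marked on a
    partition is an error (a sweep ends once).
    """
    key = _marker_key(sweep_id)
    offsets: dict[int, int] = {}
    for p in range(topic.n_partitions):
        for msg in topic.read(p):
            if msg.key == key:
                raise ValueError(
                    f"sweep {sweep_id!r} already marked on partition {p} of "
                    f"topic {topic.name!r}"
                )
    for p in range(topic.n_partitions):
        value = json.dumps(
            {"topic": topic.name, "partition": p, "sweep_id": sweep_id}
        ).encode()
        offsets[p] = topic.append(p, key, value)
    return offsets


def sweep_complete(seen: Iterable[BackMarker], topic: Topic,
                   sweep_id: str) -> bool:
    """True iff a marker for ``sweep_id`` was observed from every partition."""
    partitions = {
        m.partition for m in seen
        if m.topic == topic.name and m.sweep_id == sweep_id
    }
    return partitions >= set(range(topic.n_partitions))
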