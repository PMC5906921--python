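"""Average nucleotide identity (ANI) over topics, OrthoANI-style.

Both genomes are cut into fixed-length fragments (1020 nt by default, the
OrthoANI convention; the trailing remainder is discarded). Each query
fragment is matched against every subject fragment and vice versa; only
*reciprocal* best matches — query fragment q whose best subject is s, where
s's best query is q in turn — contribute to the ANI, which is the running
arithmetic mean of the reciprocal pairs' identities.

The pipeline runs over the log store: fragments are streamed into two
topics, one consumer group per direction computes best matches into two
match topics, one direction is materialized as an indexed lookup table, the
other is scanned against it for reciprocity, and the surviving pairs feed a
running average. Completion is by back-markers.

The default matcher is ungapped positionwise identity (matches divided by
fragment length, case-insensitive, N never matches); an external aligner
can be plugged in through the ``matcher`` callable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .agents import AgentConfig, run_agents
from .coordination import PartitionerConfig, Producer
from .logstore import LogStore, Message, TopicSpec
from .seqmodel import (
    SequenceRecord,
    accession_partitioning_bytes,
    emit_back_markers,
    is_back_marker,
)

__all__ = [
    "DEFAULT_FRAGMENT_LENGTH",
    "Fragment",
    "MatchRecord",
    "AniState",
    "fragment_genome",
    "positionwise_identity",
    "best_match",
    "reciprocal_pairs",
    "update_ani",
    "compute_ani",
]

DEFAULT_FRAGMENT_LENGTH = 1020

Matcher = Callable[[str, str], float]
FragmentId = tuple[str, int]


@dataclass(frozen=True)
class Fragment:
    """An exactly fragment_length-nt window of one genome."""

    genome_id: str
    fragment_index: int
    residues: str

    @property
    def id(self) -> FragmentId:
        return (self.genome_id, self.fragment_index)


@dataclass(frozen=True)
class MatchRecord:
    """Best match of one query fragment against a subject fragment set."""

    query: FragmentId
    subject: FragmentId
    identity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity {self.identity} outside [0, 1]")


@dataclass(frozen=True)
class AniState:
    """Running average over reciprocal-pair identities."""

    reciprocal_count: int = 0
    identity_sum: float = 0.0

    @property
    def running_mean(self) -> float | None:
        if self.reciprocal_count == 0:
            return None
        return self.identity_sum / self.reciprocal_count


def fragment_genome(record: SequenceRecord,
                    fragment_length: int = DEFAULT_FRAGMENT_LENGTH) -> list[Fragment]:
    """floor(len/L) half-open windows of exactly L nt; remainder dropped."""
    if fragment_length < 1:
        raise ValueError("fragment_length must be >= 1")
    n = len(record.residues) // fragment_length
    return [
        Fragment(record.accession, i,
                 record.residues[i * fragment_length : (i + 1) * fragment_length])
        for i in range(n)
    ]


def positionwise_identity(query: str, subject: str) -> float:
    """Ungapped identity: matching positions / fragment length.

    Case-insensitive; an N matches nothing, itself included.
    """
    if len(query) != len(subject):
        raise ValueError("fragments must have equal length")
    if not query:
        return 0.0
    q = query.upper()
    s = subject.upper()
    matches = sum(1 for x, y in zip(q, s) if x == y and x != "N")
    return matches / len(q)


def best_match(query: Fragment, subjects: Sequence[Fragment],
               matcher: Matcher = positionwise_identity) -> MatchRecord:
    """Subject fragment with maximal identity to the query.

    Ties break toward the lowest (genome_id, fragment_index).
    """
    if not subjects:
        raise ValueError("subject fragment set is empty")
    best: Fragment | None = None
    best_identity = -1.0
    for subject in subjects:
        identity = matcher(query.residues, subject.residues)
        if identity > best_identity or (
            identity == best_identity and best is not None and subject.id < best.id
        ):
            best = subject
            best_identity = identity
    assert best is not None
    return MatchRecord(query=query.id, subject=best.id, identity=best_identity)


def reciprocal_pairs(forward: Iterable[MatchRecord],
                     reverse: Iterable[MatchRecord]) -> list[MatchRecord]:
    """Keep forward matches whose subject maps straight back to the query.

    ``reverse`` is materialized as an indexed lookup table keyed by its
    query fragment (the forward direction's subject). The emitted identity
    is the mean of the two directional identities, making the result
    symmetric in query and subject.
    """
    table: dict[FragmentId, MatchRecord] = {m.query: m for m in reverse}
    out: list[MatchRecord] = []
    for fwd in forward:
        back = table.get(fwd.subject)
        if back is not None and back.subject == fwd.query:
            out.append(MatchRecord(query=fwd.query, subject=fwd.subject,
                                   identity=(fwd.identity + back.identity) / 2))
    return out


def update_ani(state: AniState, pair: MatchRecord) -> AniState:
    """Fold one reciprocal pair into the running average (order-independent)."""
    return AniState(reciprocal_count=state.reciprocal_count + 1,
                    identity_sum=state.identity_sum + pair.identity)


# -- message encodings --------------------------------------------------------


def _encode_fragment(frag: Fragment) -> tuple[bytes, bytes]:
    if "/" in frag.genome_id:
        raise ValueError(f"genome id {frag.genome_id!r} contains reserved '/'")
    return (f"{frag.genome_id}/{frag.fragment_index}".encode(),
            frag.residues.encode())


def _decode_fragment(key: bytes, value: bytes) -> Fragment:
    genome_id, _, index = key.decode().rpartition("/")
    return Fragment(genome_id, int(index), value.decode())


def _encode_match(m: MatchRecord) -> tuple[bytes, bytes]:
    value = json.dumps({
        "query": list(m.query), "subject": list(m.subject),
        "identity": m.identity,
    }).encode()
    return f"{m.query[0]}/{m.query[1]}".encode(), value


def _decode_match(value: bytes) -> MatchRecord:
    d = json.loads(value.decode())
    return MatchRecord(query=(d["query"][0], int(d["query"][1])),
                       subject=(d["subject"][0], int(d["subject"][1])),
                       identity=float(d["identity"]))


# -- pipeline orchestration ---------------------------------------------------


def _load_fragments(store: LogStore, record: SequenceRecord, topic_name: str,
                    fragment_length: int, n_partitions: int) -> list[Fragment]:
    topic = store.create_topic(TopicSpec(name=topic_name, n_partitions=n_partitions))
    producer = Producer(PartitionerConfig(key_extractor=accession_partitioning_bytes))
    fragments = fragment_genome(record, fragment_length)
    for frag in fragments:
        producer.produce(topic, *_encode_fragment(frag))
    emit_back_markers(topic, sweep_id=f"{topic_name}-load")
    return fragments


def _read_matches(store: LogStore, topic_name: str) -> list[MatchRecord]:
    topic = store.topic(topic_name)
    out = []
    for p in range(topic.n_partitions):
        for msg in topic.read(p):
            if not is_back_marker(msg.key):
                out.append(_decode_match(msg.value))
    return out


def compute_ani(store: LogStore, query: SequenceRecord, subject: SequenceRecord,
                *, fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
                matcher: Matcher = positionwise_identity, n_agents: int = 1,
                n_partitions: int | None = None,
                topic_prefix: str = "ani") -> AniState:
    """End-to-end ANI of two genomes through the log store.

    Fragments both genomes into two topics, runs one consumer group per
    direction (query->subject and subject->query) appending best matches to
    two match topics, builds the reverse lookup table, intersects for
    reciprocal pairs and streams them through :func:`update_ani`. Back-
    markers terminate each stage. Returns the final state; the mean is
    ``None`` (undefined, not 0) when no reciprocal pairs exist.
    """
    n_partitions = n_partitions or max(1, n_agents)
    q_name, s_name = f"{topic_prefix}.query", f"{topic_prefix}.subject"
    query_frags = _load_fragments(store, query, q_name, fragment_length, n_partitions)
    subject_frags = _load_fragments(store, subject, s_name, fragment_length, n_partitions)
    if not query_frags or not subject_frags:
        return AniState()

    fwd_name, rev_name = f"{topic_prefix}.fwd", f"{topic_prefix}.rev"
    store.create_topic(TopicSpec(name=fwd_name, n_partitions=n_partitions))
    store.create_topic(TopicSpec(name=rev_name, n_partitions=n_partitions))

    def direction_handler(subjects: list[Fragment]):
        def handle(msg: Message):
            frag = _decode_fragment(msg.key, msg.value)
            yield _encode_match(best_match(frag, subjects, matcher))
        return handle

    run_agents(store,
               AgentConfig(group=f"{topic_prefix}-fwd", instruction_topic=q_name,
                           output_topic=fwd_name, parallelization=n_agents),
               direction_handler(subject_frags), n_agents)
    run_agents(store,
               AgentConfig(group=f"{topic_prefix}-rev", instruction_topic=s_name,
                           output_topic=rev_name, parallelization=n_agents),
               direction_handler(query_frags), n_agents)

    pairs = reciprocal_pairs(_read_matches(store, fwd_name),
                             _read_matches(store, rev_name))
    state = AniState()
    for pair in pairs:
        state = update_ani(state, pair)
    return state
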