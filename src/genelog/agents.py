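"""Autonomous streaming agents: instructions in, data out.

An *agent* is a small program that joins a consumer group on an instruction
(or data) topic, handles each message it is assigned, and appends its
outputs to another topic through the producer partitioner. Work spreads
across agents because the topic's partitions spread across the group; the
instruction topic is conventionally created with as many partitions as the
intended level of parallelization.

Two completion mechanisms are provided, mirroring the two ways to know a
stream is "done": *back-markers* (a sentinel at the end of every partition;
an agent stops once it has seen the marker on each of its partitions) and
*output equilibrium* (the output topic's size stops changing over
consecutive observation windows — by default two consecutive 10-second
windows).

Delivery is at-least-once; handlers key their outputs by their input's key,
so redelivered messages overwrite rather than duplicate, and a compaction
pass on the output topic restores exactly-once semantics for aggregates.
Handler failures are recorded on a ``<topic>.errors`` topic and processing
continues.
"""

from __future__ import annotations

import json
import threading
import time
import traceback
from dataclasses import dataclass, field
from typing import IO, Callable, Iterable, Iterator

from .coordination import ConsumerGroup, PartitionerConfig, Producer
from .logstore import LogStore, Message, Topic, TopicSpec
from .seqmodel import (
    BaseCounts,
    accession_partitioning_bytes,
    chunk_sequence,
    decode_chunk_message,
    encode_chunk_message,
    gc_counts,
    gc_fraction,
    is_back_marker,
    read_fasta,
)

__all__ = [
    "Instruction",
    "AgentConfig",
    "AgentReport",
    "EquilibriumConfig",
    "EquilibriumEvent",
    "GcResult",
    "publish_instructions",
    "run_agent",
    "run_agents",
    "local_file_fetcher",
    "make_loader_handler",
    "gc_handler",
    "encode_gc_result",
    "decode_gc_result",
    "aggregate_gc",
    "aggregate_gc_topic",
    "equilibrium_reached",
    "detect_equilibrium",
]

Handler = Callable[[Message], Iterable[tuple[bytes, bytes]]]
Fetcher = Callable[[str], IO[str]]


@dataclass(frozen=True)
class Instruction:
    """One unit of work: a job id and a text payload (a source locator for
    the loader agent)."""

    job_id: str
    payload: str
    issued_at: int = 0


@dataclass
class AgentConfig:
    group: str
    instruction_topic: str
    output_topic: str | None = None
    parallelization: int = 1
    poll_batch: int = 32

    def __post_init__(self) -> None:
        if self.parallelization < 1:
            raise ValueError("parallelization must be >= 1")
        if self.poll_batch < 1:
            raise ValueError("poll_batch must be >= 1")

    @property
    def error_topic(self) -> str:
        return f"{self.instruction_topic}.errors"


@dataclass
class AgentReport:
    member: str
    jobs_done: int = 0
    messages_out: int = 0
    errors: int = 0


def publish_instructions(store: LogStore, topic_name: str,
                         instructions: Iterable[Instruction],
                         producer: Producer | None = None) -> int:
    """Write instructions to a topic with the default partitioning strategy.

    Incremental numeric job ids spread evenly over the partitions, the way
    a load sweep is started.
    """
    topic = store.topic(topic_name)
    producer = producer or Producer()
    n = 0
    for ins in instructions:
        producer.produce(topic, ins.job_id.encode(), ins.payload.encode())
        n += 1
    return n


def _chunk_producer() -> Producer:
    # chunk-keyed outputs partition by accession so one sequence's chunks
    # co-locate in one partition
    return Producer(PartitionerConfig(key_extractor=accession_partitioning_bytes))


def run_agent(store: LogStore, config: AgentConfig, handler: Handler, *,
              member: str = "agent-0", group: ConsumerGroup | None = None,
              producer: Producer | None = None,
              stop: threading.Event | None = None,
              idle_sleep: float = 0.001) -> AgentReport:
    """Consume the instruction topic until every assigned partition's
    back-marker is seen (or ``stop`` is set); outputs go to the output topic.

    A member left with no partitions (more agents than partitions) idles and
    returns an empty report, mirroring surplus consumers in a group.
    """
    group = group or ConsumerGroup(store, config.group, config.instruction_topic)
    assignment = group.join(member)
    producer = producer or _chunk_producer()
    out_topic = store.topic(config.output_topic) if config.output_topic else None
    report = AgentReport(member=member)
    assigned = set(assignment.partitions_of(member))
    if not assigned:
        return report
    done_partitions: set[int] = set()
    while done_partitions < set(group.assignment.partitions_of(member)):
        if stop is not None and stop.is_set():
            break
        batch = group.poll(member, config.poll_batch)
        if not batch:
            time.sleep(idle_sleep)
            continue
        for partition, msg in batch:
            if is_back_marker(msg.key):
                done_partitions.add(partition)
            else:
                try:
                    outputs = list(handler(msg))
                except Exception:
                    _record_failure(store, config, msg)
                    report.errors += 1
                else:
                    for key, value in outputs:
                        if out_topic is not None:
                            producer.produce(out_topic, key, value)
                        report.messages_out += 1
                    report.jobs_done += 1
            group.commit(member, partition, msg.offset + 1)
    return report


def run_agents(store: LogStore, config: AgentConfig, handler: Handler,
               n_agents: int, *, stop: threading.Event | None = None) -> list[AgentReport]:
    """Run ``n_agents`` agents as threads in one consumer group.

    All members join before any polling starts, so the assignment is fixed
    for the whole run.
    """
    if n_agents < 1:
        raise ValueError("n_agents must be >= 1")
    group = ConsumerGroup(store, config.group, config.instruction_topic)
    members = [f"{config.group}-agent-{i}" for i in range(n_agents)]
    for m in members:
        group.join(m)
    reports: list[AgentReport] = [None] * n_agents  # type: ignore[list-item]

    def work(i: int) -> None:
        reports[i] = run_agent(store, config, handler, member=members[i],
                               group=group, producer=_chunk_producer(), stop=stop)

    threads = [threading.Thread(target=work, args=(i,), daemon=True)
               for i in range(n_agents)]
    for t in threads:
        t.start()
    for t in threads:
        t.join()
    return reports


def _record_failure(store: LogStore, config: AgentConfig, msg: Message) -> None:
    spec = TopicSpec(name=config.error_topic,
                     n_partitions=1, replication_factor=1)
    errors = store.ensure_topic(spec)
    payload = json.dumps({
        "key": msg.key.decode(errors="replace") if msg.key else None,
        "offset": msg.offset,
        "error": traceback.format_exc(limit=3),
    }).encode()
    errors.append(0, msg.key, payload)


# -- the loader agent --------------------------------------------------------


def local_file_fetcher(locator: str) -> IO[str]:
    """Default fetcher: the instruction payload is a local FASTA path.

    The seam where a network fetcher (FTP download, archive unpacking,
    format conversion) would plug in.
    """
    return open(locator, "r", encoding="ascii")


def make_loader_handler(fetcher: Fetcher = local_file_fetcher,
                        chunk_size: int = 100_000) -> Handler:
    """Handler that resolves an instruction payload to a FASTA stream and
    emits every record as encoded chunk messages (one per <=chunk_size nt
    slice)."""

    def loader_handler(msg: Message) -> Iterator[tuple[bytes, bytes]]:
        locator = (msg.value or b"").decode()
        with fetcher(locator) as stream:
            for record in read_fasta(stream):
                for chunk in chunk_sequence(record, chunk_size):
                    yield encode_chunk_message(chunk)

    return loader_handler


# -- the GC-content agent -----------------------------------------------------


@dataclass(frozen=True)
class GcResult:
    """GC tally for one chunk (or, after aggregation, one whole accession)."""

    accession: str
    chunk_index: int | None
    chunk_count: int
    counts: BaseCounts
    fraction: float | None


def encode_gc_result(result: GcResult) -> tuple[bytes, bytes]:
    idx = 0 if result.chunk_index is None else result.chunk_index
    key = f"{result.accession}/{idx}/{result.chunk_count}".encode()
    value = json.dumps({
        "accession": result.accession,
        "chunk_index": result.chunk_index,
        "chunk_count": result.chunk_count,
        "a": result.counts.a, "c": result.counts.c, "g": result.counts.g,
        "t": result.counts.t, "other": result.counts.other,
        "fraction": result.fraction,
    }).encode()
    return key, value


def decode_gc_result(value: bytes) -> GcResult:
    d = json.loads(value.decode())
    return GcResult(
        accession=d["accession"], chunk_index=d["chunk_index"],
        chunk_count=d["chunk_count"],
        counts=BaseCounts(d["a"], d["c"], d["g"], d["t"], d["other"]),
        fraction=d["fraction"],
    )


def gc_handler(msg: Message) -> Iterator[tuple[bytes, bytes]]:
    """One GC result per chunk message, keyed by the chunk key so redelivery
    is idempotent; counts stay additive for downstream aggregation."""
    chunk = decode_chunk_message(msg.key, msg.value)
    counts = gc_counts(chunk.residues)
    result = GcResult(accession=chunk.accession, chunk_index=chunk.chunk_index,
                      chunk_count=chunk.chunk_count, counts=counts,
                      fraction=gc_fraction(counts))
    yield encode_gc_result(result)


def aggregate_gc(results: Iterable[GcResult]) -> Iterator[GcResult]:
    """Fold chunk-level results into whole-accession results.

    Emits an accession once all ``chunk_count`` distinct chunk indices have
    been observed; duplicate deliveries of a chunk are ignored. Conflicting
    chunk counts for one accession raise ValueError.
    """
    pending: dict[str, dict[int, BaseCounts]] = {}
    expected: dict[str, int] = {}
    emitted: set[str] = set()
    for r in results:
        acc = r.accession
        if acc in expected and expected[acc] != r.chunk_count:
            raise ValueError(
                f"conflicting chunk counts for {acc!r}: "
                f"{expected[acc]} and {r.chunk_count}"
            )
        expected[acc] = r.chunk_count
        if acc in emitted or r.chunk_index is None:
            continue
        parts = pending.setdefault(acc, {})
        parts.setdefault(r.chunk_index, r.counts)
        if len(parts) == expected[acc]:
            total = BaseCounts()
            for i in sorted(parts):
                total = total + parts[i]
            emitted.add(acc)
            del pending[acc]
            yield GcResult(accession=acc, chunk_index=None,
                           chunk_count=expected[acc], counts=total,
                           fraction=gc_fraction(total))


def aggregate_gc_topic(store: LogStore, topic_name: str) -> list[GcResult]:
    """Aggregate an entire results topic (markers skipped)."""
    topic = store.topic(topic_name)

    def stream() -> Iterator[GcResult]:
        for p in range(topic.n_partitions):
            for msg in topic.read(p):
                if not is_back_marker(msg.key):
                    yield decode_gc_result(msg.value)

    return list(aggregate_gc(stream()))


# -- equilibrium completion ---------------------------------------------------


@dataclass
class EquilibriumConfig:
    """Completion by output equilibrium: the topic's size must be unchanged
    over ``consecutive_windows`` back-to-back windows of ``window_seconds``
    (defaults: two 10-second windows). ``sleep`` is injectable so tests and
    the benchmark can use logical or shortened windows."""

    window_seconds: float = 10.0
    consecutive_windows: int = 2
    sleep: Callable[[float], None] = time.sleep

    def __post_init__(self) -> None:
        if self.window_seconds <= 0:
            raise ValueError("window_seconds must be > 0")
        if self.consecutive_windows < 1:
            raise ValueError("consecutive_windows must be >= 1")


@dataclass(frozen=True)
class EquilibriumEvent:
    complete: bool
    size: int
    samples: tuple[int, ...]

    @property
    def windows_elapsed(self) -> int:
        return max(0, len(self.samples) - 1)


def equilibrium_reached(samples: Iterable[int], consecutive_windows: int) -> bool:
    """True iff the sample sequence ends with ``consecutive_windows``
    unchanged inter-sample periods (i.e. consecutive_windows+1 equal
    trailing samples)."""
    samples = list(samples)
    if len(samples) < consecutive_windows + 1:
        return False
    tail = samples[-(consecutive_windows + 1):]
    return all(s == tail[0] for s in tail)


def detect_equilibrium(topic: Topic, config: EquilibriumConfig | None = None,
                       max_windows: int | None = None) -> EquilibriumEvent:
    """Sample the topic size each window until it stops changing.

    Returns a completion event with the stable size, or — when
    ``max_windows`` periods elapse first — a distinguishable timeout event.
    """
    config = config or EquilibriumConfig()
    samples: list[int] = [topic.size()]
    windows = 0
    while not equilibrium_reached(samples, config.consecutive_windows):
        if max_windows is not None and windows >= max_windows:
            return EquilibriumEvent(complete=False, size=samples[-1],
                                    samples=tuple(samples))
        config.sleep(config.window_seconds)
        samples.append(topic.size())
        windows += 1
    return EquilibriumEvent(complete=True, size=samples[-1],
                            samples=tuple(samples))
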