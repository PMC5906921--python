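"""File-backed partitioned append-only log store.

A *topic* is a named set of N partitions; each partition is an ordered,
offset-addressed log persisted as one append-only binary segment file.
Messages are (key, value) byte pairs; a keyed message with an absent value
is a *tombstone* that marks the key for deletion at the next compaction.
Topics flagged ``compacted`` may be rewritten so that only the youngest
message per key survives (keeping its original offset); keyless messages
are exempt. Replication is modelled as placement metadata over simulated
brokers — the arithmetic of "R copies on distinct machines" — not as byte
copies.

Segment record layout (little-endian)::

    [record_length u32][offset u64][timestamp u64]
    [key_length i32 (-1 = no key)][key bytes]
    [value_length i32 (-1 = tombstone)][value bytes]

``record_length`` counts every byte after itself, so a partially written
tail record is detected and truncated when the store is reopened.
"""

from __future__ import annotations

import bisect
import json
import os
import struct
import threading
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

__all__ = [
    "Message",
    "TopicSpec",
    "ReplicaPlacement",
    "CompactionReport",
    "Topic",
    "LogStore",
    "TopicExistsError",
    "UnknownTopicError",
    "ConfigurationError",
    "surviving_replicas",
    "max_tolerable_failures",
]

_HEADER = struct.Struct("<QQ")  # offset, timestamp
_U32 = struct.Struct("<I")
_I32 = struct.Struct("<i")

DEFAULT_N_BROKERS = 7


class TopicExistsError(ValueError):
    """A topic with this name already exists in the store."""


class UnknownTopicError(KeyError):
    """No topic with this name exists in the store."""


class ConfigurationError(ValueError):
    """Operation incompatible with the topic's configuration."""


def _default_clock() -> int:
    return int(time.time() * 1000)


@dataclass(frozen=True)
class Message:
    """Immutable unit of storage: optional key, optional value, offset, timestamp.

    A present key with an absent (``None``) value is a tombstone.
    """

    key: bytes | None
    value: bytes | None
    offset: int
    timestamp: int

    @property
    def is_tombstone(self) -> bool:
        return self.key is not None and self.value is None


@dataclass(frozen=True)
class TopicSpec:
    """Topic configuration: partition count N, replication factor R, compaction flag."""

    name: str
    n_partitions: int
    replication_factor: int = 1
    compacted: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("topic name must be non-empty")
        if "/" in self.name or self.name.startswith("_"):
            raise ValueError(f"invalid topic name {self.name!r}")
        if self.n_partitions < 1:
            raise ValueError(f"n_partitions must be >= 1, got {self.n_partitions}")
        if self.replication_factor < 1:
            raise ValueError(
                f"replication_factor must be >= 1, got {self.replication_factor}"
            )


@dataclass(frozen=True)
class ReplicaPlacement:
    """Simulated placement of one partition's R replicas on distinct brokers."""

    topic: str
    partition: int
    broker_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(set(self.broker_ids)) != len(self.broker_ids):
            raise ValueError("replica broker ids must be distinct")


@dataclass(frozen=True)
class CompactionReport:
    topic: str
    partition: int
    messages_before: int
    messages_removed_superseded: int
    keys_deleted_by_tombstone: int
    tombstones_removed: int
    messages_after: int


def _encode_record(msg: Message) -> bytes:
    key = msg.key
    value = msg.value
    body = bytearray(_HEADER.pack(msg.offset, msg.timestamp))
    if key is None:
        body += _I32.pack(-1)
    else:
        body += _I32.pack(len(key)) + key
    if value is None:
        body += _I32.pack(-1)
    else:
        body += _I32.pack(len(value)) + value
    return _U32.pack(len(body)) + bytes(body)


def _scan_segment(path: Path) -> tuple[list[Message], int]:
    """Read every complete record; return (messages, valid byte length).

    A truncated tail (crash mid-append) is ignored and its start position
    returned so the caller can truncate the file.
    """
    messages: list[Message] = []
    if not path.exists():
        return messages, 0
    data = path.read_bytes()
    pos = 0
    n = len(data)
    while pos + 4 <= n:
        (rec_len,) = _U32.unpack_from(data, pos)
        end = pos + 4 + rec_len
        if end > n or rec_len < _HEADER.size + 8:
            break  # truncated or corrupt tail
        offset, timestamp = _HEADER.unpack_from(data, pos + 4)
        p = pos + 4 + _HEADER.size
        (klen,) = _I32.unpack_from(data, p)
        p += 4
        key = None if klen < 0 else data[p : p + max(klen, 0)]
        p += max(klen, 0)
        (vlen,) = _I32.unpack_from(data, p)
        p += 4
        value = None if vlen < 0 else data[p : p + max(vlen, 0)]
        messages.append(Message(key=key, value=value, offset=offset, timestamp=timestamp))
        pos = end
    return messages, pos


@dataclass
class _Partition:
    path: Path
    messages: list[Message] = field(default_factory=list)
    offsets: list[int] = field(default_factory=list)  # parallel to messages
    next_offset: int = 0
    writer: object = None  # lazily opened append handle

    def write_record(self, data: bytes) -> None:
        if self.writer is None:
            self.writer = open(self.path, "ab")
        self.writer.write(data)
        self.writer.flush()

    def close_writer(self) -> None:
        if self.writer is not None:
            self.writer.close()
            self.writer = None


class Topic:
    """Handle to one topic: append, read, end offsets, compaction."""

    def __init__(self, store: "LogStore", spec: TopicSpec,
                 placements: list[ReplicaPlacement], directory: Path) -> None:
        self._store = store
        self.spec = spec
        self.placements = placements
        self._dir = directory
        self._lock = threading.RLock()
        self._partitions: list[_Partition] = []
        for i in range(spec.n_partitions):
            self._partitions.append(_Partition(path=directory / f"{i}.log"))

    @property
    def name(self) -> str:
        return self.spec.name

    @property
    def n_partitions(self) -> int:
        return self.spec.n_partitions

    def _check_partition(self, partition: int) -> _Partition:
        if not 0 <= partition < self.spec.n_partitions:
            raise IndexError(
                f"partition {partition} out of range for topic {self.name!r} "
                f"with {self.spec.n_partitions} partitions"
            )
        return self._partitions[partition]

    def append(self, partition: int, key: bytes | None, value: bytes | None) -> int:
        """Durably append a message; returns its offset."""
        part = self._check_partition(partition)
        with self._lock:
            offset = part.next_offset
            msg = Message(key=key, value=value, offset=offset,
                          timestamp=self._store.clock())
            part.write_record(_encode_record(msg))
            part.messages.append(msg)
            part.offsets.append(offset)
            part.next_offset = offset + 1
            return offset

    def read(self, partition: int, from_offset: int = 0,
             max_count: int | None = None) -> list[Message]:
        """Retained messages with offset >= from_offset, in offset order.

        Reading never deletes; past-the-end reads return an empty list.
        """
        if from_offset < 0:
            raise ValueError("from_offset must be >= 0")
        part = self._check_partition(partition)
        with self._lock:
            start = bisect.bisect_left(part.offsets, from_offset)
            if max_count is None:
                return part.messages[start:]
            return part.messages[start : start + max_count]

    def end_offsets(self) -> dict[int, int]:
        """Per-partition next offset to be assigned."""
        with self._lock:
            return {i: p.next_offset for i, p in enumerate(self._partitions)}

    def size(self) -> int:
        """Sum of end offsets — the quantity equilibrium detection samples."""
        return sum(self.end_offsets().values())

    def retained_count(self, partition: int) -> int:
        part = self._check_partition(partition)
        with self._lock:
            return len(part.messages)

    def compact(self, partition: int) -> CompactionReport:
        """Rewrite one partition keeping only the youngest message per key.

        If the youngest message for a key is a tombstone, every message for
        that key (the tombstone included) is dropped. Keyless messages are
        never removed. Surviving messages keep their offsets and order. The
        rewrite goes to a temp file then atomically renames, so concurrent
        readers never observe a half-compacted segment.
        """
        if not self.spec.compacted:
            raise ConfigurationError(
                f"topic {self.name!r} is not configured for compaction"
            )
        part = self._check_partition(partition)
        with self._lock:
            before = list(part.messages)
            youngest: dict[bytes, Message] = {}
            for msg in before:
                if msg.key is not None:
                    youngest[msg.key] = msg
            survivors: list[Message] = []
            superseded = 0
            tombstones_removed = 0
            deleted_keys: set[bytes] = set()
            for msg in before:
                if msg.key is None:
                    survivors.append(msg)
                    continue
                latest = youngest[msg.key]
                if latest.is_tombstone:
                    deleted_keys.add(msg.key)
                    if msg is latest:
                        tombstones_removed += 1
                    else:
                        superseded += 1
                elif msg is latest:
                    survivors.append(msg)
                else:
                    superseded += 1
            part.close_writer()
            tmp = part.path.with_suffix(".log.tmp")
            with open(tmp, "wb") as fh:
                for msg in survivors:
                    fh.write(_encode_record(msg))
                fh.flush()
                os.fsync(fh.fileno())
            os.replace(tmp, part.path)
            part.messages = survivors
            part.offsets = [m.offset for m in survivors]
            self._store._write_topic_meta(self)
            return CompactionReport(
                topic=self.name,
                partition=partition,
                messages_before=len(before),
                messages_removed_superseded=superseded,
                keys_deleted_by_tombstone=len(deleted_keys),
                tombstones_removed=tombstones_removed,
                messages_after=len(survivors),
            )

    def _load_from_disk(self, next_offsets: Mapping[str, int] | None) -> None:
        for i, part in enumerate(self._partitions):
            msgs, valid_len = _scan_segment(part.path)
            if part.path.exists() and valid_len < part.path.stat().st_size:
                with open(part.path, "r+b") as fh:  # drop crash-torn tail
                    fh.truncate(valid_len)
            part.messages = msgs
            part.offsets = [m.offset for m in msgs]
            scanned_next = msgs[-1].offset + 1 if msgs else 0
            meta_next = int(next_offsets.get(str(i), 0)) if next_offsets else 0
            part.next_offset = max(scanned_next, meta_next)


class LogStore:
    """A directory of topics plus simulated broker metadata.

    Parameters
    ----------
    root : path
        Store directory; created if absent. Layout is
        ``<root>/<topic>/<partition>.log`` plus ``<root>/<topic>/meta.json``.
    n_brokers : int
        Size of the simulated broker pool replicas are placed on.
    clock : callable -> int
        Millisecond timestamp source, injectable for deterministic tests.
    """

    def __init__(self, root: str | os.PathLike, n_brokers: int = DEFAULT_N_BROKERS,
                 clock: Callable[[], int] | None = None) -> None:
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)
        if n_brokers < 1:
            raise ValueError("n_brokers must be >= 1")
        self.n_brokers = n_brokers
        self.clock = clock or _default_clock
        self._topics: dict[str, Topic] = {}
        self._lock = threading.RLock()
        for meta_path in sorted(self.root.glob("*/meta.json")):
            self._open_existing(meta_path)

    # -- topic lifecycle ---------------------------------------------------

    def create_topic(self, spec: TopicSpec) -> Topic:
        with self._lock:
            if spec.name in self._topics:
                raise TopicExistsError(f"topic {spec.name!r} already exists")
            if spec.replication_factor > self.n_brokers:
                raise ConfigurationError(
                    f"replication factor {spec.replication_factor} exceeds "
                    f"broker count {self.n_brokers}"
                )
            placements = round_robin_placements(
                spec.name, spec.n_partitions, spec.replication_factor, self.n_brokers
            )
            directory = self.root / spec.name
            directory.mkdir(parents=True, exist_ok=True)
            topic = Topic(self, spec, placements, directory)
            self._topics[spec.name] = topic
            self._write_topic_meta(topic)
            return topic

    def close(self) -> None:
        """Close open segment writers (reads stay in memory)."""
        with self._lock:
            for topic in self._topics.values():
                for part in topic._partitions:
                    part.close_writer()

    def ensure_topic(self, spec: TopicSpec) -> Topic:
        """Create the topic, or return the existing handle of the same name."""
        with self._lock:
            if spec.name in self._topics:
                return self._topics[spec.name]
            return self.create_topic(spec)

    def topic(self, name: str) -> Topic:
        try:
            return self._topics[name]
        except KeyError:
            raise UnknownTopicError(f"unknown topic {name!r}") from None

    def has_topic(self, name: str) -> bool:
        return name in self._topics

    def topics(self) -> list[str]:
        return sorted(self._topics)

    def end_offsets(self, name: str) -> dict[int, int]:
        return self.topic(name).end_offsets()

    # -- persistence -------------------------------------------------------

    def _write_topic_meta(self, topic: Topic) -> None:
        meta = {
            "spec": {
                "name": topic.spec.name,
                "n_partitions": topic.spec.n_partitions,
                "replication_factor": topic.spec.replication_factor,
                "compacted": topic.spec.compacted,
            },
            "placements": {
                str(p.partition): list(p.broker_ids) for p in topic.placements
            },
            "next_offsets": {str(i): n for i, n in topic.end_offsets().items()},
        }
        tmp = topic._dir / "meta.json.tmp"
        tmp.write_text(json.dumps(meta, indent=1))
        os.replace(tmp, topic._dir / "meta.json")

    def _open_existing(self, meta_path: Path) -> None:
        meta = json.loads(meta_path.read_text())
        spec = TopicSpec(**meta["spec"])
        placements = [
            ReplicaPlacement(spec.name, int(idx), tuple(brokers))
            for idx, brokers in sorted(meta["placements"].items(), key=lambda kv: int(kv[0]))
        ]
        topic = Topic(self, spec, placements, meta_path.parent)
        topic._load_from_disk(meta.get("next_offsets"))
        self._topics[spec.name] = topic


# -- replication arithmetic ----------------------------------------------


def round_robin_placements(topic: str, n_partitions: int, replication: int,
                           n_brokers: int) -> list[ReplicaPlacement]:
    """Partition i's R replicas go on brokers i, i+1, ..., i+R-1 (mod B)."""
    if replication > n_brokers:
        raise ValueError("replication factor exceeds broker count")
    return [
        ReplicaPlacement(topic, i, tuple((i + j) % n_brokers for j in range(replication)))
        for i in range(n_partitions)
    ]


def surviving_replicas(placements: Iterable[ReplicaPlacement],
                       failed_brokers: set[int]) -> dict[tuple[str, int], int]:
    """Per-partition count of replicas outside the failed set.

    A data-loss event is any partition whose count is 0.
    """
    return {
        (p.topic, p.partition): len(set(p.broker_ids) - failed_brokers)
        for p in placements
    }


def max_tolerable_failures(placements: Sequence[ReplicaPlacement],
                           broker_ids: Sequence[int]) -> int:
    """Largest k such that EVERY k-broker failure leaves >=1 replica of every
    partition, found by exhaustive enumeration of failure sets."""
    placements = list(placements)
    best = 0
    for k in range(1, len(broker_ids) + 1):
        safe = all(
            min(surviving_replicas(placements, set(failed)).values(), default=1) >= 1
            for failed in combinations(broker_ids, k)
        )
        if safe:
            best = k
        else:
            break
    return best
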