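"""Producer partitioning and consumer-group coordination.

Producers pick a destination partition from the message key with a
deterministic hash (FNV-1a 64-bit), so the same key always lands in the
same partition, on any platform; keyless messages are spread round-robin.
Consumer groups divide a topic's partitions among their members so each
partition is read by exactly one member at a time, which preserves
per-partition order and lets a group "drain" a topic in parallel. Committed
offsets are persisted per group so a new owner resumes where the previous
one left off after a rebalance or a restart.
"""

from __future__ import annotations

import json
import logging
import os
import threading
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

from .logstore import LogStore, Message, Topic

__all__ = [
    "FNV_OFFSET_BASIS",
    "FNV_PRIME",
    "fnv1a_64",
    "PartitionerConfig",
    "partition_for_key",
    "Producer",
    "Assignment",
    "GroupState",
    "assign_partitions",
    "rebalance",
    "ConsumerGroup",
]

logger = logging.getLogger(__name__)

FNV_OFFSET_BASIS = 0xCBF29CE484222325
FNV_PRIME = 0x100000001B3


def fnv1a_64(data: bytes) -> int:
    """FNV-1a 64-bit hash — deterministic across runs and platforms."""
    h = FNV_OFFSET_BASIS
    for byte in data:
        h ^= byte
        h = (h * FNV_PRIME) & 0xFFFFFFFFFFFFFFFF
    return h


@dataclass
class PartitionerConfig:
    """Partitioning strategy for a producer.

    ``default-hash`` hashes the key (keyless messages go round-robin);
    ``round-robin`` ignores keys entirely. ``key_extractor``, when set, maps
    the key to the bytes actually hashed — e.g. the accession part of a
    chunk key, so all chunks of one sequence co-locate in one partition.
    """

    strategy: str = "default-hash"
    key_extractor: Callable[[bytes], bytes] | None = None
    _counter: int = field(default=0, repr=False)

    def __post_init__(self) -> None:
        if self.strategy not in ("default-hash", "round-robin"):
            raise ValueError(f"unknown partitioning strategy {self.strategy!r}")

    def _next_round_robin(self, n_partitions: int) -> int:
        p = self._counter % n_partitions
        self._counter += 1
        return p


def partition_for_key(key: bytes | None, n_partitions: int,
                      config: PartitionerConfig | None = None) -> int:
    """Destination partition for a message key.

    Present key: FNV-1a hash of the partitioning bytes, modulo N.
    Absent key (or round-robin strategy): producer-local counter modulo N.
    """
    if n_partitions < 1:
        raise ValueError("n_partitions must be >= 1")
    if config is None:
        config = partition_for_key.__dict__.setdefault(
            "_shared_config", PartitionerConfig()
        )
    if key is None or config.strategy == "round-robin":
        return config._next_round_robin(n_partitions)
    data = config.key_extractor(key) if config.key_extractor else key
    return fnv1a_64(data) % n_partitions


class Producer:
    """Appends messages to a topic, choosing the partition from the key."""

    def __init__(self, config: PartitionerConfig | None = None) -> None:
        self.config = config or PartitionerConfig()

    def produce(self, topic: Topic, key: bytes | None,
                value: bytes | None) -> tuple[int, int]:
        """Append; returns (partition, offset)."""
        partition = partition_for_key(key, topic.n_partitions, self.config)
        offset = topic.append(partition, key, value)
        return partition, offset


# -- assignment ----------------------------------------------------------


@dataclass(frozen=True)
class Assignment:
    """Disjoint division of a topic's partitions among group members."""

    group: str
    topic: str
    member_partitions: dict[str, tuple[int, ...]]

    def partitions_of(self, member: str) -> tuple[int, ...]:
        return self.member_partitions.get(member, ())

    def owner_of(self, partition: int) -> str | None:
        for member, parts in self.member_partitions.items():
            if partition in parts:
                return member
        return None


@dataclass
class GroupState:
    group: str
    members: list[str]
    committed: dict[tuple[str, int], int] = field(default_factory=dict)


def assign_partitions(n_partitions: int, member_ids: Sequence[str],
                      strategy: str = "range", *, group: str = "",
                      topic: str = "") -> Assignment:
    """Divide partitions 0..N-1 among members; sizes differ by at most 1.

    ``range``: members sorted lexicographically each get a contiguous block,
    the first N mod M members getting one extra partition. ``round-robin``:
    partitions are dealt to the sorted members in turn. Both are pure
    functions of (N, sorted member ids).
    """
    members = sorted(set(member_ids))
    if not members:
        raise ValueError("consumer group must have at least one member")
    if n_partitions < 1:
        raise ValueError("n_partitions must be >= 1")
    result: dict[str, tuple[int, ...]] = {}
    if strategy == "range":
        base, extra = divmod(n_partitions, len(members))
        start = 0
        for i, member in enumerate(members):
            count = base + (1 if i < extra else 0)
            result[member] = tuple(range(start, start + count))
            start += count
    elif strategy == "round-robin":
        dealt: dict[str, list[int]] = {m: [] for m in members}
        for p in range(n_partitions):
            dealt[members[p % len(members)]].append(p)
        result = {m: tuple(ps) for m, ps in dealt.items()}
    else:
        raise ValueError(f"unknown assignment strategy {strategy!r}")
    return Assignment(group=group, topic=topic, member_partitions=result)


def rebalance(state: GroupState, joined: set[str], left: set[str],
              n_partitions: int, strategy: str = "range",
              topic: str = "") -> tuple[GroupState, Assignment]:
    """Stop-the-world reassignment after a membership change.

    Committed offsets are preserved per (topic, partition), so the new owner
    of a partition resumes from the previous owner's commit.
    """
    if joined & left:
        raise ValueError("a member cannot both join and leave")
    members = sorted((set(state.members) | joined) - left)
    if not members:
        raise ValueError("rebalance would leave the group empty")
    new_state = GroupState(group=state.group, members=members,
                           committed=dict(state.committed))
    assignment = assign_partitions(n_partitions, members, strategy,
                                   group=state.group, topic=topic)
    return new_state, assignment


# -- consumer group runtime ----------------------------------------------


class ConsumerGroup:
    """Cooperating readers of one topic, with persisted commits.

    Commits are explicit and at-least-once: ``commit(partition, offset)``
    records the next offset to read; on rebalance or reopen, fetch positions
    reset to the committed offsets, so uncommitted messages are redelivered.
    Group state lives at ``<store_root>/_groups/<group>.json``.
    """

    def __init__(self, store: LogStore, group: str, topic_name: str,
                 strategy: str = "range") -> None:
        self._store = store
        self._topic = store.topic(topic_name)
        self._strategy = strategy
        self._lock = threading.RLock()
        self._state = GroupState(group=group, members=[])
        self._assignment: Assignment | None = None
        self._positions: dict[int, int] = {}
        self._rotation: dict[str, int] = {}
        self._path = store.root / "_groups" / f"{group}.json"
        if self._path.exists():
            self._load()

    @property
    def group(self) -> str:
        return self._state.group

    @property
    def topic(self) -> Topic:
        return self._topic

    @property
    def assignment(self) -> Assignment | None:
        return self._assignment

    def committed(self, partition: int) -> int:
        return self._state.committed.get((self._topic.name, partition), 0)

    # -- membership ------------------------------------------------------

    def join(self, member: str) -> Assignment:
        with self._lock:
            if member not in self._state.members:
                self._state, self._assignment = rebalance(
                    self._state, {member}, set(), self._topic.n_partitions,
                    self._strategy, topic=self._topic.name,
                )
                self._reset_positions()
            assert self._assignment is not None
            return self._assignment

    def leave(self, member: str) -> Assignment | None:
        with self._lock:
            if member in self._state.members:
                if len(self._state.members) == 1:
                    self._state.members.remove(member)
                    self._assignment = None
                    self._positions.clear()
                    return None
                self._state, self._assignment = rebalance(
                    self._state, set(), {member}, self._topic.n_partitions,
                    self._strategy, topic=self._topic.name,
                )
                self._reset_positions()
            return self._assignment

    def _reset_positions(self) -> None:
        # at-least-once: after any membership change every fetch position
        # falls back to the last committed offset
        self._positions = {
            p: self.committed(p) for p in range(self._topic.n_partitions)
        }

    # -- consumption -------------------------------------------------------

    def poll(self, member: str, max_count: int = 100) -> list[tuple[int, Message]]:
        """Up to max_count messages from the member's partitions.

        Each partition's messages arrive in offset order; the starting
        partition rotates between polls so no assigned partition starves.
        """
        with self._lock:
            if self._assignment is None or member not in self._assignment.member_partitions:
                raise ValueError(f"member {member!r} holds no assignment in group "
                                 f"{self.group!r}")
            parts = self._assignment.partitions_of(member)
            if not parts:
                return []
            start = self._rotation.get(member, 0) % len(parts)
            out: list[tuple[int, Message]] = []
            for i in range(len(parts)):
                if len(out) >= max_count:
                    break
                p = parts[(start + i) % len(parts)]
                pos = self._positions.get(p, self.committed(p))
                msgs = self._topic.read(p, from_offset=pos,
                                        max_count=max_count - len(out))
                if msgs:
                    self._positions[p] = msgs[-1].offset + 1
                    out.extend((p, m) for m in msgs)
            self._rotation[member] = start + 1
            return out

    def commit(self, member: str, partition: int, offset: int) -> bool:
        """Record the next offset to read for a partition; monotone.

        A commit below the current committed offset is ignored with a
        warning (returns False). Commits persist across rebalances and
        store reopens.
        """
        with self._lock:
            if (self._assignment is None
                    or partition not in self._assignment.partitions_of(member)):
                raise ValueError(
                    f"member {member!r} does not own partition {partition} of "
                    f"topic {self._topic.name!r}"
                )
            key = (self._topic.name, partition)
            current = self._state.committed.get(key, 0)
            if offset < current:
                logger.warning(
                    "ignoring non-monotonic commit %d < %d on %s[%d]",
                    offset, current, self._topic.name, partition,
                )
                return False
            self._state.committed[key] = offset
            self._persist()
            return True

    # -- persistence -------------------------------------------------------

    def _persist(self) -> None:
        self._path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "group": self._state.group,
            "committed": {
                f"{t}/{p}": off for (t, p), off in self._state.committed.items()
            },
        }
        tmp = self._path.with_suffix(".json.tmp")
        tmp.write_text(json.dumps(payload, indent=1))
        os.replace(tmp, self._path)

    def _load(self) -> None:
        payload = json.loads(self._path.read_text())
        committed: dict[tuple[str, int], int] = {}
        for key, off in payload.get("committed", {}).items():
            t, _, p = key.rpartition("/")
            committed[(t, int(p))] = int(off)
        self._state = GroupState(group=payload["group"], members=[],
                                 committed=committed)
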