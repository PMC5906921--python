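"""Agent framework: instruction handling, loader and GC agents, aggregation
and equilibrium completion."""

import json

import pytest
from hypothesis import given, settings, strategies as st

from genelog.agents import (
    AgentConfig,
    EquilibriumConfig,
    GcResult,
    Instruction,
    aggregate_gc,
    aggregate_gc_topic,
    decode_gc_result,
    detect_equilibrium,
    equilibrium_reached,
    gc_handler,
    make_loader_handler,
    publish_instructions,
    run_agent,
    run_agents,
)
from genelog.logstore import LogStore, Message, TopicSpec
from genelog.seqmodel import (
    BaseCounts,
    SequenceRecord,
    chunk_sequence,
    emit_back_markers,
    encode_chunk_message,
    gc_counts,
    gc_fraction,
    is_back_marker,
    write_fasta,
)


def _setup(store, n_partitions, payloads, output_partitions=None):
    instructions = store.create_topic(
        TopicSpec(name="in", n_partitions=n_partitions))
    output = store.create_topic(
        TopicSpec(name="out", n_partitions=output_partitions or n_partitions))
    publish_instructions(
        store, "in",
        (Instruction(job_id=str(i), payload=p) for i, p in enumerate(payloads)))
    emit_back_markers(instructions, "sweep")
    return instructions, output


def _echo_handler(msg: Message):
    yield msg.key, msg.value


class TestRunAgent:
    def test_single_agent_handles_all_instructions(self, store):
        _setup(store, 4, [f"job{i}" for i in range(4)])
        config = AgentConfig(group="g", instruction_topic="in", output_topic="out")
        report = run_agent(store, config, _echo_handler)
        assert report.jobs_done == 4 and report.errors == 0

    def test_four_agents_partition_the_work_exactly_once(self, store):
        _, output = _setup(store, 4, [f"job{i}" for i in range(8)])
        config = AgentConfig(group="g", instruction_topic="in",
                             output_topic="out", parallelization=4)
        reports = run_agents(store, config, _echo_handler, n_agents=4)
        assert sum(r.jobs_done for r in reports) == 8
        delivered = [m.key for p in range(4) for m in output.read(p)]
        assert sorted(delivered) == sorted(b"%d" % i for i in range(8))

    def test_surplus_agents_idle_without_changing_results(self, store):
        _, output = _setup(store, 2, ["a", "b", "c"])
        config = AgentConfig(group="g", instruction_topic="in",
                             output_topic="out")
        reports = run_agents(store, config, _echo_handler, n_agents=5)
        assert sum(r.jobs_done for r in reports) == 3
        assert sum(1 for r in reports if r.jobs_done == 0) >= 3
        delivered = {m.key for p in range(2) for m in output.read(p)}
        assert delivered == {b"0", b"1", b"2"}

    def test_handler_failure_goes_to_error_topic(self, store):
        _setup(store, 1, [f"job{i}" for i in range(8)])

        def flaky(msg: Message):
            if msg.key == b"3":
                raise RuntimeError("boom")
            yield msg.key, msg.value

        config = AgentConfig(group="g", instruction_topic="in", output_topic="out")
        report = run_agent(store, config, flaky)
        assert report.jobs_done == 7 and report.errors == 1
        errors = store.topic("in.errors").read(0)
        assert len(errors) == 1
        assert json.loads(errors[0].value)["key"] == "3"


class TestLoaderAgent:
    def _write_fasta(self, path, lengths):
        records = [SequenceRecord(f"s{i}", "", "ACGT" * (n // 4) + "A" * (n % 4))
                   for i, n in enumerate(lengths)]
        with open(path, "w") as fh:
            write_fasta(records, fh)
        return records

    def test_chunk_count_is_ceil_sum(self, store, tmp_path):
        path = tmp_path / "in.fasta"
        self._write_fasta(path, [50, 100_000, 150_000])
        _, output = _setup(store, 1, [str(path)])
        config = AgentConfig(group="g", instruction_topic="in", output_topic="out")
        report = run_agent(store, config, make_loader_handler())
        assert report.messages_out == 1 + 1 + 2
        assert sum(1 for m in output.read(0) if not is_back_marker(m.key)) == 4

    def test_empty_fasta_is_success_with_no_output(self, store, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        _setup(store, 1, [str(path)])
        config = AgentConfig(group="g", instruction_topic="in", output_topic="out")
        report = run_agent(store, config, make_loader_handler())
        assert report.jobs_done == 1 and report.messages_out == 0

    def test_missing_file_is_a_failed_instruction(self, store, tmp_path):
        _setup(store, 1, [str(tmp_path / "absent.fasta")])
        config = AgentConfig(group="g", instruction_topic="in", output_topic="out")
        report = run_agent(store, config, make_loader_handler())
        assert report.errors == 1
        assert store.topic("in.errors").read(0)


class TestGcAgent:
    def test_simple_chunk_fraction(self):
        key, value = encode_chunk_message(
            chunk_sequence(SequenceRecord("s", "", "ATGC"))[0])
        ((out_key, out_value),) = gc_handler(
            Message(key=key, value=value, offset=0, timestamp=0))
        result = decode_gc_result(out_value)
        assert out_key == key
        assert result.fraction == 0.5

    def test_all_n_chunk_has_missing_fraction(self):
        key, value = encode_chunk_message(
            chunk_sequence(SequenceRecord("s", "", "N" * 40))[0])
        ((_, out_value),) = gc_handler(
            Message(key=key, value=value, offset=0, timestamp=0))
        result = decode_gc_result(out_value)
        assert result.fraction is None and result.counts.other == 40

    def test_chunked_sequence_aggregates_to_whole(self):
        residues = "ACGTGGCCAATT" * 2_000
        rec = SequenceRecord("s", "", residues)
        results = []
        for chunk in chunk_sequence(rec, 10_000):
            key, value = encode_chunk_message(chunk)
            ((_, out),) = gc_handler(
                Message(key=key, value=value, offset=0, timestamp=0))
            results.append(decode_gc_result(out))
        (agg,) = aggregate_gc(results)
        assert agg.counts == gc_counts(residues)
        assert agg.fraction == gc_fraction(gc_counts(residues))


class TestAggregation:
    def _result(self, acc, index, count, counts):
        return GcResult(accession=acc, chunk_index=index, chunk_count=count,
                        counts=counts, fraction=gc_fraction(counts))

    def test_single_chunk_passes_through(self):
        (out,) = aggregate_gc([self._result("a", 0, 1, BaseCounts(g=2, c=2))])
        assert out.accession == "a" and out.fraction == 1.0

    def test_out_of_order_chunks_aggregate_once(self):
        parts = [self._result("a", i, 3, BaseCounts(a=1, g=i)) for i in (2, 0, 1)]
        (out,) = aggregate_gc(parts)
        assert out.counts == BaseCounts(a=3, g=3)
        assert out.chunk_index is None

    def test_duplicate_delivery_is_idempotent(self):
        parts = [self._result("a", 0, 2, BaseCounts(a=1)),
                 self._result("a", 0, 2, BaseCounts(a=1)),
                 self._result("a", 1, 2, BaseCounts(c=1))]
        (out,) = aggregate_gc(parts)
        assert out.counts == BaseCounts(a=1, c=1)

    def test_conflicting_chunk_counts_rejected(self):
        parts = [self._result("a", 0, 2, BaseCounts(a=1)),
                 self._result("a", 1, 3, BaseCounts(c=1))]
        with pytest.raises(ValueError, match="conflicting chunk counts"):
            list(aggregate_gc(parts))

    def test_incomplete_accession_not_emitted(self):
        parts = [self._result("a", 0, 3, BaseCounts(a=1))]
        assert list(aggregate_gc(parts)) == []


class TestEquilibrium:
    def test_defaults_match_two_ten_second_windows(self):
        config = EquilibriumConfig()
        assert config.window_seconds == 10.0
        assert config.consecutive_windows == 2

    def test_three_equal_samples_complete(self, store):
        t = store.create_topic(TopicSpec(name="t", n_partitions=1))
        for _ in range(5):
            t.append(0, None, b"v")
        event = detect_equilibrium(
            t, EquilibriumConfig(window_seconds=10, consecutive_windows=2,
                                 sleep=lambda s: None))
        assert event.complete and event.size == 5
        assert event.samples == (5, 5, 5)

    def test_growth_then_stability(self, store):
        t = store.create_topic(TopicSpec(name="t", n_partitions=1))
        for _ in range(3):
            t.append(0, None, b"v")
        calls = {"n": 0}

        def logical_sleep(_):
            if calls["n"] == 0:
                for _ in range(2):
                    t.append(0, None, b"v")
            calls["n"] += 1

        event = detect_equilibrium(
            t, EquilibriumConfig(window_seconds=10, consecutive_windows=2,
                                 sleep=logical_sleep))
        assert event.complete and event.samples == (3, 5, 5, 5)

    def test_strictly_increasing_times_out(self, store):
        t = store.create_topic(TopicSpec(name="t", n_partitions=1))
        event = detect_equilibrium(
            t, EquilibriumConfig(window_seconds=1, consecutive_windows=2,
                                 sleep=lambda s: t.append(0, None, b"v")),
            max_windows=10)
        assert not event.complete
        assert event.windows_elapsed == 10

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(samples=st.lists(st.integers(0, 3), min_size=1, max_size=12),
           consecutive=st.integers(1, 4))
    def test_fires_iff_trailing_windows_unchanged(self, samples, consecutive):
        expected = (len(samples) > consecutive
                    and len(set(samples[-(consecutive + 1):])) == 1)
        assert equilibrium_reached(samples, consecutive) is expected


class TestEndToEnd:
    def test_loader_then_gc_conserves_counts(self, store, tmp_path):
        rng_lengths = [500, 2_500, 7_001]
        records = [SequenceRecord(f"s{i}", "", "ACGTTGCA" * (n // 8) + "G" * (n % 8))
                   for i, n in enumerate(rng_lengths)]
        path = tmp_path / "corpus.fasta"
        with open(path, "w") as fh:
            write_fasta(records, fh)
        instructions = store.create_topic(TopicSpec(name="in", n_partitions=2))
        sequences = store.create_topic(TopicSpec(name="seq", n_partitions=2))
        results = store.create_topic(TopicSpec(name="gc", n_partitions=2))
        publish_instructions(store, "in", [Instruction("0", str(path))])
        emit_back_markers(instructions, "s")
        run_agents(store, AgentConfig(group="load", instruction_topic="in",
                                      output_topic="seq"),
                   make_loader_handler(chunk_size=2_000), n_agents=2)
        emit_back_markers(sequences, "s")
        run_agents(store, AgentConfig(group="gc", instruction_topic="seq",
                                      output_topic="gc"),
                   gc_handler, n_agents=2)
        expected_chunks = sum(-(-n // 2_000) for n in rng_lengths)
        data = [m for p in range(2) for m in sequences.read(p)
                if not is_back_marker(m.key)]
        assert len(data) == expected_chunks
        aggregates = {r.accession: r for r in aggregate_gc_topic(store, "gc")}
        assert set(aggregates) == {"s0", "s1", "s2"}
        for rec in records:
            assert aggregates[rec.accession].counts == gc_counts(rec.residues)
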