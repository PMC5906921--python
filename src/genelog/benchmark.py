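"""Synthetic corpora and the scaled-down scalability experiment.

The experiment compares two ways of computing per-sequence GC content over
a corpus of FASTA files: a *baseline* — one process, a thread pool, flat
files parsed in memory — and the *pipeline* — loader agents chunking
sequences into a topic, GC agents streaming results into another, with
completion detected by output equilibrium. Load (the number of input
files) is scaled in tandem with the parallelization level T/A (threads for
the baseline, agents for the pipeline); a scalable system shows a flat
elapsed-time response, so the least-squares slope of elapsed time against
T/A is the scalability figure of merit. Timing is hardware-bound and
informational; the benchmark's correctness surface is that both modes
produce identical per-accession GC results, equal to the generator's
manifest ground truth.

The generator emulates a reference-sequence snapshot at desk scale:
deterministic for a seed, with a manifest carrying exact per-record base
counts so every downstream result can be checked against ground truth.
Defaults are 4 files of 250 records at a mean length of 20,000 nt (about
20 MB) — minutes, not hours, on one CPU; tests use smaller corpora.
"""

from __future__ import annotations

import json
import threading
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .agents import (
    AgentConfig,
    EquilibriumConfig,
    EquilibriumEvent,
    GcResult,
    Instruction,
    aggregate_gc_topic,
    detect_equilibrium,
    gc_handler,
    make_loader_handler,
    publish_instructions,
    run_agents,
)
from .logstore import LogStore, TopicSpec
from .seqmodel import (
    BaseCounts,
    DEFAULT_CHUNK_SIZE,
    emit_back_markers,
    gc_counts,
    gc_fraction,
    read_fasta,
)

__all__ = [
    "FixedLength",
    "UniformLength",
    "MixedLength",
    "SyntheticSpec",
    "ManifestRecord",
    "Manifest",
    "generate_corpus",
    "BenchmarkRow",
    "run_baseline",
    "run_pipeline",
    "ScalabilityReport",
    "scalability_report",
    "run_experiment",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# -- length distributions ----------------------------------------------------


@dataclass(frozen=True)
class FixedLength:
    """Every record exactly ``length`` nt."""

    length: int = 20_000

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.full(n, self.length, dtype=np.int64)


@dataclass(frozen=True)
class UniformLength:
    """Record lengths uniform on [lo, hi]."""

    lo: int = 10_000
    hi: int = 30_000

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.integers(self.lo, self.hi + 1, size=n, dtype=np.int64)


@dataclass(frozen=True)
class MixedLength:
    """Mostly short records plus a fraction longer than the chunk threshold,
    so a corpus exercises both one-message and multi-chunk sequences."""

    short_lo: int = 10_000
    short_hi: int = 30_000
    long_fraction: float = 0.1
    long_lo: int = DEFAULT_CHUNK_SIZE + 1
    long_hi: int = 250_000

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        is_long = rng.random(n) < self.long_fraction
        if n > 0 and not is_long.any():
            is_long[0] = True  # contract: a mixed corpus holds >=1 long record
        lengths = rng.integers(self.short_lo, self.short_hi + 1, size=n,
                               dtype=np.int64)
        n_long = int(is_long.sum())
        lengths[is_long] = rng.integers(self.long_lo, self.long_hi + 1,
                                        size=n_long, dtype=np.int64)
        return lengths


@dataclass(frozen=True)
class SyntheticSpec:
    """A stated synthetic world: file/record counts, length law, GC target."""

    n_files: int = 4
    records_per_file: int = 250
    length_distribution: FixedLength | UniformLength | MixedLength = field(
        default_factory=UniformLength
    )
    gc_target: float = 0.5
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_files < 0 or self.records_per_file < 0:
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.gc_target <= 1.0:
            raise ValueError("gc_target must lie in [0, 1]")


@dataclass(frozen=True)
class ManifestRecord:
    accession: str
    path: str
    length: int
    counts: BaseCounts

    @property
    def fraction(self) -> float | None:
        return gc_fraction(self.counts)


@dataclass(frozen=True)
class Manifest:
    """Ground truth for a generated corpus: per-record lengths and counts."""

    seed: int
    gc_target: float
    files: tuple[str, ...]
    records: tuple[ManifestRecord, ...]

    @property
    def total_length(self) -> int:
        return sum(r.length for r in self.records)

    @property
    def realized_gc(self) -> float | None:
        total = BaseCounts()
        for r in self.records:
            total = total + r.counts
        return gc_fraction(total)

    def save(self, path: Path) -> None:
        payload = {
            "seed": self.seed,
            "gc_target": self.gc_target,
            "files": list(self.files),
            "records": [
                {"accession": r.accession, "path": r.path, "length": r.length,
                 "a": r.counts.a, "c": r.counts.c, "g": r.counts.g,
                 "t": r.counts.t, "other": r.counts.other}
                for r in self.records
            ],
        }
        path.write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: Path) -> "Manifest":
        d = json.loads(path.read_text())
        return cls(
            seed=d["seed"], gc_target=d["gc_target"], files=tuple(d["files"]),
            records=tuple(
                ManifestRecord(r["accession"], r["path"], r["length"],
                               BaseCounts(r["a"], r["c"], r["g"], r["t"],
                                          r["other"]))
                for r in d["records"]
            ),
        )


def generate_corpus(spec: SyntheticSpec, out_dir: str | Path) -> Manifest:
    """Write ``n_files`` FASTA files plus ``manifest.json`` with exact counts.

    Fully deterministic for a seed: bases are drawn i.i.d. with
    P(G) = P(C) = gc_target/2, so the realized corpus GC fraction
    concentrates around the target (within ~±0.01 for >=1e6 nt).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_target
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    files: list[str] = []
    records: list[ManifestRecord] = []
    for f in range(spec.n_files):
        path = out / f"synthetic_{f:02d}.fasta"
        lengths = spec.length_distribution.sample(rng, spec.records_per_file)
        with open(path, "w", encoding="ascii") as fh:
            for r, length in enumerate(lengths):
                accession = f"SYN{f:02d}R{r:04d}"
                arr = rng.choice(_BASES, size=int(length), p=probs)
                residues = arr.tobytes().decode("ascii")
                fh.write(f">{accession} synthetic length={int(length)}\n")
                for i in range(0, len(residues), 70):
                    fh.write(residues[i : i + 70] + "\n")
                records.append(ManifestRecord(
                    accession=accession, path=str(path), length=int(length),
                    counts=gc_counts(residues),
                ))
        files.append(str(path))
    manifest = Manifest(seed=spec.seed, gc_target=spec.gc_target,
                        files=tuple(files), records=tuple(records))
    manifest.save(out / "manifest.json")
    return manifest


# -- the two modes -------------------------------------------------------------


@dataclass(frozen=True)
class BenchmarkRow:
    """One grid cell: parallelization level T/A, load, elapsed time."""

    mode: str  # "baseline" | "pipeline"
    parallelization: int
    load_units: int  # number of input files
    elapsed_seconds: float
    sequences_processed: int
    valid: bool = True


def _gc_of_file(path: str) -> dict[str, GcResult]:
    out: dict[str, GcResult] = {}
    with open(path, "r", encoding="ascii") as fh:
        for record in read_fasta(fh):
            counts = gc_counts(record.residues)
            out[record.accession] = GcResult(
                accession=record.accession, chunk_index=None, chunk_count=1,
                counts=counts, fraction=gc_fraction(counts),
            )
    return out


def run_baseline(files: Sequence[str],
                 n_threads: int) -> tuple[BenchmarkRow, dict[str, GcResult]]:
    """Single-process flat-file mode: a thread pool splits the files, parses
    them and computes whole-record GC in memory — no log store involved."""
    if n_threads < 1:
        raise ValueError("n_threads must be >= 1")
    t0 = time.perf_counter()
    results: dict[str, GcResult] = {}
    with ThreadPoolExecutor(max_workers=n_threads) as pool:
        for per_file in pool.map(_gc_of_file, files):
            results.update(per_file)
    elapsed = time.perf_counter() - t0
    row = BenchmarkRow(mode="baseline", parallelization=n_threads,
                       load_units=len(files), elapsed_seconds=elapsed,
                       sequences_processed=len(results))
    return row, results


def run_pipeline(files: Sequence[str], n_agents: int, store: LogStore, *,
                 chunk_size: int = DEFAULT_CHUNK_SIZE,
                 equilibrium: EquilibriumConfig | None = None,
                 max_windows: int = 600,
                 ) -> tuple[BenchmarkRow, dict[str, GcResult]]:
    """Full loader -> GC flow over the log store for one grid cell.

    The instruction topic is created with as many partitions as agents (the
    deployment coupling), instructions carry incremental numeric keys so
    they spread evenly, loader completion is by back-markers, and the run's
    elapsed time stops when the results topic reaches equilibrium. The
    default observation window is shortened to 0.1 s — the detector's own
    default of two 10-second windows is impractical per desk-scale grid
    cell — without changing the rule.
    """
    if n_agents < 1:
        raise ValueError("n_agents must be >= 1")
    equilibrium = equilibrium or EquilibriumConfig(window_seconds=0.1,
                                                   consecutive_windows=2)
    instructions = store.create_topic(
        TopicSpec(name="loader.instructions", n_partitions=n_agents))
    sequences = store.create_topic(
        TopicSpec(name="refseq", n_partitions=n_agents))
    results = store.create_topic(
        TopicSpec(name="gc.results", n_partitions=n_agents))

    t0 = time.perf_counter()
    publish_instructions(
        store, instructions.name,
        (Instruction(job_id=str(i), payload=path) for i, path in enumerate(files)),
    )
    emit_back_markers(instructions, sweep_id="load")

    event_box: list[EquilibriumEvent] = []

    def watch() -> None:
        event_box.append(detect_equilibrium(results, equilibrium,
                                            max_windows=max_windows))

    loader_cfg = AgentConfig(group="loaders", instruction_topic=instructions.name,
                             output_topic=sequences.name, parallelization=n_agents)
    run_agents(store, loader_cfg, make_loader_handler(chunk_size=chunk_size),
               n_agents)
    emit_back_markers(sequences, sweep_id="load")

    gc_cfg = AgentConfig(group="gc", instruction_topic=sequences.name,
                         output_topic=results.name, parallelization=n_agents)
    watcher = threading.Thread(target=watch, daemon=True)
    watcher.start()
    run_agents(store, gc_cfg, gc_handler, n_agents)
    watcher.join()
    event = event_box[0]
    elapsed = time.perf_counter() - t0

    aggregated = {r.accession: r for r in aggregate_gc_topic(store, results.name)}
    row = BenchmarkRow(mode="pipeline", parallelization=n_agents,
                       load_units=len(files), elapsed_seconds=elapsed,
                       sequences_processed=len(aggregated),
                       valid=event.complete)
    return row, aggregated


# -- the report -----------------------------------------------------------------


@dataclass(frozen=True)
class ScalabilityReport:
    rows: tuple[BenchmarkRow, ...]
    slopes: dict[str, float]  # mode -> least-squares slope of elapsed vs T/A
    verdicts: dict[str, str]  # mode -> "flat" | "rising" | "falling"


def scalability_report(rows: Sequence[BenchmarkRow],
                       flat_tolerance: float = 0.25) -> ScalabilityReport:
    """Least-squares slope of elapsed time against T/A per mode.

    Scalability is inversely proportional to the slope: a flat line means
    added load is fully absorbed by added parallelization. A mode with
    fewer than 3 parallelization levels gets no slope (rows only). The
    verdict is informational: "flat" when the elapsed-time swing implied by
    the slope stays within ``flat_tolerance`` of the mean elapsed time.
    """
    slopes: dict[str, float] = {}
    verdicts: dict[str, str] = {}
    modes = sorted({r.mode for r in rows})
    for mode in modes:
        mode_rows = [r for r in rows if r.mode == mode and r.valid]
        levels = np.array([r.parallelization for r in mode_rows], dtype=float)
        elapsed = np.array([r.elapsed_seconds for r in mode_rows], dtype=float)
        if len(set(levels.tolist())) < 3:
            continue
        slope = float(np.polyfit(levels, elapsed, 1)[0])
        slopes[mode] = slope
        mean = float(elapsed.mean())
        swing = abs(slope) * (levels.max() - levels.min())
        if mean > 0 and swing <= flat_tolerance * mean:
            verdicts[mode] = "flat"
        else:
            verdicts[mode] = "rising" if slope > 0 else "falling"
    return ScalabilityReport(rows=tuple(rows), slopes=slopes, verdicts=verdicts)


def format_table(report: ScalabilityReport) -> str:
    """Aligned text table, one row per T/A level, one column per mode."""
    levels = sorted({r.parallelization for r in report.rows})
    modes = sorted({r.mode for r in report.rows})
    by_cell = {(r.mode, r.parallelization): r for r in report.rows}
    header = ["T/A"] + [f"{m} (s)" for m in modes] + ["files", "sequences"]
    lines = ["\t".join(header)]
    for level in levels:
        cells = [str(level)]
        any_row = None
        for m in modes:
            r = by_cell.get((m, level))
            cells.append(f"{r.elapsed_seconds:.2f}" if r else "")
            any_row = any_row or r
        cells.append(str(any_row.load_units if any_row else ""))
        cells.append(str(any_row.sequences_processed if any_row else ""))
        lines.append("\t".join(cells))
    for mode, slope in sorted(report.slopes.items()):
        lines.append(f"# slope[{mode}] = {slope:.3f} s per T/A "
                     f"({report.verdicts[mode]})")
    return "\n".join(lines)


def run_experiment(out_dir: str | Path, levels: Sequence[int] = (1, 2, 4),
                   spec: SyntheticSpec | None = None, *,
                   chunk_size: int = DEFAULT_CHUNK_SIZE,
                   equilibrium: EquilibriumConfig | None = None,
                   ) -> tuple[ScalabilityReport, dict[int, bool]]:
    """The whole grid: generate max(levels) files once, then for each level
    T run the baseline with T threads and the pipeline with T agents over
    the first T files (load scaled in tandem with parallelization).

    Returns the report plus, per level, whether baseline and pipeline
    produced identical per-accession GC results (the correctness surface).
    """
    out = Path(out_dir)
    spec = spec or SyntheticSpec(n_files=max(levels))
    if spec.n_files < max(levels):
        raise ValueError("spec.n_files must cover the largest level")
    manifest = generate_corpus(spec, out / "corpus")
    rows: list[BenchmarkRow] = []
    agreement: dict[int, bool] = {}
    for level in levels:
        files = list(manifest.files[:level])
        base_row, base_results = run_baseline(files, n_threads=level)
        store = LogStore(out / f"store_T{level}")
        pipe_row, pipe_results = run_pipeline(
            files, level, store, chunk_size=chunk_size, equilibrium=equilibrium)
        rows.extend([base_row, pipe_row])
        agreement[level] = _same_results(base_results, pipe_results)
    return scalability_report(rows), agreement


def _same_results(a: dict[str, GcResult], b: dict[str, GcResult]) -> bool:
    if set(a) != set(b):
        return False
    return all(a[k].counts == b[k].counts and a[k].fraction == b[k].fraction
               for k in a)
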