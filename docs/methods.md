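# Methods

## The storage model

A topic with N partitions is stored as N append-only binary segment files
plus one JSON metadata file (topic spec, replica placements, next offsets).
Each record is self-delimiting —
`[record_length u32][offset u64][timestamp u64][key_length i32][key]
[value_length i32][value]`, little-endian, with −1 marking an absent key or
value — so a crash mid-append leaves a recognisably torn tail that is
truncated on reopen, and everything before it is intact. Appends go through
a persistent buffered handle and are flushed per record; reads are served
from an in-memory index rebuilt by scanning the segments at open, so a read
at a given (partition, offset) returns the same message until compaction
removes it. Offsets are assigned at append, strictly increasing per
partition, and are *never renumbered*: compaction leaves gaps. Timestamps
come from an injectable millisecond clock so tests are deterministic.

Compaction applies to topics flagged for it, per partition: the youngest
message per key survives with its original offset; if the youngest message
for a key is a tombstone (present key, absent value), every message for
that key — tombstone included — is dropped in the same pass. There is no
tombstone retention period: readers that need to observe deletions must
read before compaction runs (a grace period is a possible extension, not
implemented). Keyless messages have no identity to supersede and are
exempt. The rewrite goes to a temporary file and is atomically renamed, so
a concurrent reader never sees a half-compacted segment.

Replication is deliberately *not* byte copies: the safety claim being
modelled is placement arithmetic — R replicas of each partition on R
distinct brokers means no R−1 simultaneous broker failures can destroy all
copies. The store assigns placements round-robin (partition i on brokers
i…i+R−1 mod B) and exposes `surviving_replicas` /
`max_tolerable_failures`, which verify the claim by exhaustive enumeration
of failure sets rather than by simulation.

## Coordination

The default partitioner hashes the key with FNV-1a 64-bit
(offset basis 0xcbf29ce484222325, prime 0x100000001b3) modulo the partition
count. FNV-1a was chosen over Kafka's murmur2 because it is trivially
portable and bit-for-bit reproducible in a few lines; nothing downstream
depends on which deterministic hash is used. A pluggable key extractor maps
the key to the bytes actually hashed — chunked sequences use it to hash the
accession only, so all chunks of one sequence co-partition. Keyless
messages round-robin over a producer-local counter.

Assignment is a pure function of (N, sorted member ids, strategy). Range
(the default) gives sorted members contiguous blocks with the first
N mod M members taking one extra; round-robin deals partitions in turn.
Both keep sizes within 1 of each other. Rebalancing is stop-the-world:
membership changes recompute the whole assignment, and committed offsets —
persisted as JSON per group under `_groups/` — carry over so a partition's
new owner resumes at the previous owner's commit. Delivery is therefore
at-least-once; exactly-once is approximated by keying outputs by their
input's key, which makes redelivery overwrite rather than duplicate (and a
compaction pass on the output topic removes the physical duplicates).

## Chunking and GC

Sequences at most 100,000 nt long travel as one message; longer ones as
ceil(len/100,000) chunks, all but the last exactly 100,000 nt, keyed
`accession/index/count`. Compaction by the full chunk key would be safe
(each chunk is its own key) but re-publication of a *shorter* version of a
sequence would leave stale high-index chunks behind, so sequence topics
default to non-compacted and a re-publication belongs in a new sweep.
Reassembly sorts by index and reports missing indices by name.

GC content is (G+C)/(A+C+G+T), case-insensitive, with Ns and IUPAC
ambiguity codes tallied as `other` and excluded from the denominator — the
standard convention. A sequence with no unambiguous base has an *undefined*
fraction, reported as missing rather than 0. Base counts are additive over
concatenation, which is what makes per-chunk computation exact: the
aggregator sums counts first and divides once.

## Agents and completion

An agent joins a consumer group, polls its assigned partitions, applies a
handler per message, appends the handler's keyed outputs via the
partitioner, and commits after each message. Handler exceptions append a
diagnostic record to `<instruction topic>.errors` and processing continues;
errors never silently vanish. The single-machine runner executes agents as
threads; the store's locks make concurrent appends safe.

Completion: a producer that has finished a sweep appends one back-marker
per partition (key prefix `\x00FOG/` + sweep id — data keys may not start
with byte 0, so the namespace cannot collide). An agent stops when it has
seen the marker on every partition it owns. The alternative rule, used for
measuring the pipeline, is output equilibrium: sample the output topic's
size (the sum of per-partition end offsets) every window and declare the
stream complete when the size is unchanged over a configured number of
back-to-back windows — two 10-second windows by default. "Unchanged over
two consecutive windows" means three equal successive samples; the
detector's sleep is injectable, so tests drive it with a logical clock and
the benchmark shortens the window without changing the rule. The loader
stage uses back-markers and the GC stage equilibrium; the choice is
asymmetric because the loader's input (an instruction list) has a definite
end, while the sequence stream is best treated as open-ended.

## ANI

Fragment length defaults to 1020 nt, the OrthoANI convention; the trailing
remainder below one fragment is discarded, so a genome shorter than the
fragment length contributes nothing and the ANI of such a pair is
undefined (missing, not 0). The default matcher is ungapped positionwise
identity — matches/fragment_length, case-insensitive, N matching nothing,
itself included — which keeps the pipeline deterministic at desk scale; a
BLAST-like aligner can be plugged in through the matcher seam. Ties in
best-match selection break toward the lowest (genome id, fragment index).
When the two directional identities of a reciprocal pair differ, the pair
contributes their arithmetic mean, which makes compute_ani symmetric in
query and subject. The running mean is a pure fold (count, sum), so it is
order-independent and equals the batch mean.

## Synthetic data and the benchmark

The generator draws bases i.i.d. with P(G)=P(C)=gc_target/2, writes plain
FASTA, and records exact per-record base counts in a manifest — the ground
truth every downstream result is checked against. It is fully deterministic
for a seed. Length laws: fixed, uniform, or a mix in which a stated
fraction of records exceeds the 100,000-nt chunk threshold (at least one
long record is forced so the multi-chunk path is always exercised).
Defaults — 4 files × 250 records × mean 20,000 nt, ~20 MB — keep a full
grid to minutes on one CPU; the test suite uses smaller corpora and says
so. What the generator does *not* emulate: real base composition (GC skew
along the sequence, repeats, ambiguity codes), header conventions beyond
`accession description`, and compressed archives. A green end-to-end test
therefore establishes the plumbing (chunking, partitioning, delivery,
aggregation) and the arithmetic, not biological realism.

The benchmark reproduces the *shape* of the scalability experiment: for
each level T, the baseline parses T files with T threads in memory while
the pipeline runs T loader and T GC agents over a store, load thus growing
in tandem with parallelization. Elapsed time for the pipeline runs from the
first instruction to equilibrium of the results topic. The report fits a
least-squares slope of elapsed versus T (requiring ≥3 levels) per mode; a
"flat" verdict means the slope-implied swing stays within 25 % of the mean
elapsed time. Absolute times and verdicts are informational — they are
hardware-bound — whereas baseline/pipeline result equality is asserted.

## Known limitations

Single-process, single-host: brokers, leader election and networked
replication are out of scope by design. Reads hold each partition's
retained messages in memory, which caps practical topic size well below
the multi-gigabyte snapshots the design targets conceptually. Commits are
explicit; there is no heartbeat-based failure detection, so a stalled
agent blocks its partitions until its thread returns. The ANI matcher is
ungapped, so indels degrade identity faster than an aligner would; the
value is comparable between runs of this package, not to published
aligner-based ANI figures.
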