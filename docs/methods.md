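# Methods

This note documents the data model, algorithms, binary formats and design
choices behind `gffindex`, and what the synthetic test data does and does not
establish about behaviour on real annotation files.

## Data model

A GFF3 file is treated as an ordered list of feature lines, each with a byte
span `[byte_start, byte_end)` in the source file. Parsing assumes
well-formed input: validation is limited to column count, integer
coordinates with `1 ≤ start ≤ end`, strand/phase vocabulary, and `key=value`
attribute syntax (values percent-decoded). Directive lines are skipped; a
`##FASTA` directive terminates feature parsing and its byte offset is
recorded. Coordinates are 1-based inclusive everywhere inside the package;
BED (0-based half-open) and SAM (0-based starts via pysam) are converted at
their parsing boundaries only.

Features are numbered 0..n−1 in order of appearance. `Parent` attributes are
resolved against the ID table in a second pass, so forward references are
legal; chasing parent links yields each feature's *root*. A root plus all
its descendants is an **annotation block** — the minimal complete gene or
transcript model and the unit of extraction and region retrieval. Block
numbers equal root feature numbers, so block order is file order.

Edge policies (all deliberate, all deterministic):

* Features without an `ID` are numbered and block-assigned but cannot be
  looked up by ID (GFF3 permits ID-less leaves such as exons).
* Duplicate `ID` definitions: the last wins for Parent resolution, with a
  warning — except lines of a discontinuous feature (same type, same
  `Parent`), which legitimately share one ID and resolve together.
* Multiple `Parent` values: the first listed parent decides block
  membership; a warning names features whose listed parents resolve to
  different roots.
* A parent cycle or a `Parent` naming an undefined ID is an error.
* Cross-seqid members stay in their root's block but are region-indexed
  under the seqid where they actually lie, so region queries find them where
  they are.

A block's `byte_ranges` are the maximal byte-contiguous runs of its member
lines: an uninterrupted model has one range; interleaved models get one
range per run, and concatenating them reproduces the member lines exactly,
each once, in file order. Blocks therefore partition the feature set.

## Binary index formats

All integers are little-endian and fixed-width: feature/block numbers and
string lengths `u32` (builds refuse files with ≥ 2³² features), byte offsets
and element counts `u64`. A string is `u32` length + raw UTF-8 bytes; an
optional string uses length sentinel `0xFFFFFFFF` for "absent". Every file
starts with a 24-byte header:

```
magic "GIDX" (4 bytes) | format_version u32 | source_size u64 | source_checksum u64
```

`source_checksum` packs CRC-32 of the full source bytes into the high word
and the low 32 bits of the file size into the low word. It is recomputed at
load time; any mismatch raises a stale-index error rather than answering
from an outdated bundle. CRC-32 is not collision-proof, but combined with
the exact size it is ample for detecting accidental edits, and it is cheap
enough to recompute on every load.

Payloads after the header:

* `.fts` — `u64 n`, then n optional ID strings; then a sorted type string
  table (`u64 count` + strings) and n `u32` indices into it.
* `.prt` — `u64 n`, n × `u32 parent` (sentinel `0xFFFFFFFF` = none),
  n × `u32 root`.
* `.gof` — `u64 n_blocks`, then per block: `u32 block_no`, `u64 n_ranges`,
  n_ranges × (`u64 start`, `u64 end`), blocks in file order, ranges sorted
  and non-overlapping.
* `.atn` — `u64 n_keys`, per key: key string, `u64 n_values`, values sorted
  by raw UTF-8 bytes within the key.
* `.a2f` — same key framing; per value a `u64` count + `u32` feature
  numbers (aligned with the `.atn` value order; consistency is checked when
  both are loaded).
* `.sqs` — `u64 n` + seqid strings in order of first appearance. The region
  query path needs this table to translate the `.rix` directory's seqid
  positions, which is why it sits with the interval-tree files.
* `.rit` — fixed 36-byte node records (`i64 start, end, max_end`,
  `u32 left, right` with sentinel, `u32 block_no`), all seqids' node arrays
  concatenated, each array in in-order (= sorted) sequence.
* `.rix` — `u64 n_seqids`, per seqid: `u32` seqid-table position,
  `u64` byte offset into the `.rit` payload, `u64` node count, `u32` root
  index (sentinel for an empty tree). Offsets are strictly increasing and
  tile the payload.

Every iteration order feeding these payloads is deterministic, so two builds
from an identical source are byte-identical — which the test suite asserts —
and index files can be content-compared across machines.

Loads are cached per `(path, kind, fingerprint)` within a process, so
repeated queries share one in-memory copy of each table. An audit hook
(`store.audit_loads`) records which kinds an operation requested; the tests
use it to pin the per-subcommand load sets (extract: `.fts/.prt/.gof`;
search: `.atn/.a2f/.fts/.prt/.gof`; intersect:
`.gof/.prt/.sqs/.rit/.rix`). `.rit` node arrays are read lazily per seqid
using the `.rix` directory, so querying one chromosome never pages in
another's nodes.

## Interval trees

One tree per seqid, over one interval per block (the envelope of the block's
members on that seqid) — not one per feature. This keeps N small, and
feature-level refinement happens after block retrieval by re-parsing the few
member lines, which mirrors how the byte-range design makes re-parsing
cheap. The tree is built once by recursive median split of the intervals
sorted by `(start, end, block_no)` (ties broken for full determinism), which
gives depth `⌈log₂(N+1)⌉` with no rebalancing machinery; the index is
write-once/read-many, so a static structure is the right trade. Node `i` of
the flat array is the i-th sorted interval, making the in-order layout free
and the serialized form trivially seekable.

A query visits a node only when its subtree's `max_end` reaches the query
start, and never descends right once `start > q_end`. The suite checks two
operational properties on randomized instances (up to 10⁴ intervals, 10³
queries per fixture): exact agreement with a linear-scan oracle, and an
instrumented visit budget `visits ≤ 2(⌊log₂N⌋+1) + 4k` for every tested
query, the measurable form of the O(log N + k) claim. The budget is checked
on every tested query rather than proven for adversarial inputs; pathological
nestings could exceed it, random genomic-scale interval sets do not.

## Extraction and search

`extract_by_ids` maps IDs → feature numbers (`.fts`) → roots (`.prt`) →
byte ranges (`.gof`) and streams block bytes directly from the source file.
Duplicate resolutions are emitted once, blocks in file order, after a
`##gff-version 3` header. Unknown IDs warn (the CLI exits nonzero only when
*all* IDs were unknown); `strict` upgrades them to errors.
`feature-line` mode filters the block's lines to those carrying the
requested ID — which keeps all segments of a discontinuous feature.

`search_attribute` requires the key to have been indexed (default keys `ID`
and `Name`; the CLI's `--attr-keys` takes a comma list). Exact mode is a
binary search of the key's byte-sorted value table; fuzzy mode is a
case-insensitive substring scan of the same table. "Fuzzy" is deliberately
minimal — substring, not edit distance — because it is predictable,
explainable, and a superset of exact matching (asserted as a property test).

`intersect` buckets regions by seqid and sorts by start, loads each
requested seqid's tree once, and emits the deduplicated union of hit blocks
in file order, so output bytes are invariant under permutation of the input
regions. Block mode (default) returns whole models; feature mode re-parses
member lines and keeps those individually overlapping ≥1 region, coordinates
unclipped. Regions on unindexed seqids legally return zero hits.

## Coverage breadth and depth

Alignments become reference-space intervals: CIGAR `M/=/X/D` consume and
cover reference, `N` splits the read into one interval per spliced segment,
`I/S/H/P` consume none. `D` counting as covered keeps reference-span
semantics; a flag (`splice_aware=False`) lets `N` span instead for users
matching other conventions. Default filters drop unmapped, secondary
(0x100) and supplementary (0x800) records and keep duplicates (0x400), with
a flag to drop them. Intervals are bucketed and sorted per seqid, so sorted
and shuffled inputs give identical results by construction.

Breadth: merge the per-seqid intervals into a disjoint set — bookended
intervals (`end+1 == next start`) merge so a perfectly tiled target has
breadth exactly 1 — then sweep targets and merged intervals co-linearly with
two cursors. `covered_bases` is the summed overlap; `breadth =
covered_bases / length` exactly. Depth: a difference array over the work
slice, prefix-summed once, gives every target's `depth_sum` (each
overlapping base of each alignment counted once per alignment) in O(slice +
targets); histogram mode tallies bases per integer depth from the same
array.

Work is partitioned into slices cut only at coordinates interior to no
target: overlapping targets always share a slice and an over-long target
stretches its slice rather than being split. Every alignment interval is
assigned to every slice it overlaps (via a prefix-max-of-ends array, so long
reads reaching a slice from far back are not missed). Per-slice results
concatenated in slice order are therefore byte-identical to single-slice
processing — the suite asserts identity across slice sizes {1 kb, 10 kb, ∞}
and 1 vs 4 workers. Workers are threads over independent slices; output
order is restored to target input order regardless.

Targets default to GFF features of one type (default `gene`), re-read
through the `.gof` byte ranges; a BED file can substitute.

## Synthetic data

`gffindex.synthetic` generates the three input kinds deterministically from
a seed (same seed ⇒ byte-identical files):

* **GFF3**: nested gene → mRNA → exon/CDS models laid left-to-right on a
  two-contig megabase-scale toy genome; gene lengths 1–20 kb with 0.2–5 kb
  gaps, 30 % of genes multi-transcript, 2–5 exons per transcript, CDS
  segments sharing a discontinuous-feature ID, 30 % of exons ID-less, gene
  and transcript `Name` symbols, percent-encoded `Note` values, and a
  configurable fraction of adjacent gene pairs interleaved line-wise to
  force multi-range blocks. A manifest records every feature's root, block
  and span for oracle checks.
* **BED4**: uniform starts, configurable length range (default 2–20 kb,
  desk-scale versions of large random-bin workloads).
* **SAM**: primary mapped 100 bp reads, ~20–25 % spliced (`M-N-M` with
  50–5,000 bp gaps), coordinate-sorted or shuffled, written through pysam.

What this emulates: hierarchy depth, interleaved models, ID-less and
discontinuous features, spliced alignments, sorted/unsorted inputs. What it
does not: malformed or dialect (GTF/GFF2) input, cross-seqid parentage,
alignment mismatches/quality (irrelevant to interval math), pathological
interval nestings, and real-genome scale. Passing tests therefore establish
correctness of the index/query algebra under realistic structure, not
performance on, or tolerance of, arbitrary real-world files. Test and
acceptance problem sizes (hundreds of models, 10³–10⁴ intervals, reads and
queries per fixture) were chosen to exercise every code path at desk scale.

## Known limitations

* GFF3 only; GTF/GFF2 are rejected by column semantics, not detected.
* Attribute search covers only keys chosen at index time; new keys need a
  re-index.
* The visit-budget property is validated empirically, not proven
  worst-case.
* Fingerprint collisions (CRC-32 + size) are theoretically possible; a
  byte-level comparison is not attempted.
* Threads share the GIL; the worker knob guarantees result invariance and
  bounded memory per slice rather than linear speedups in this
  implementation.
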