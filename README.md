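# gffindex

Model-aware binary indexing and fast random-access queries over GFF3 genome
annotations.

Genome annotation files keep growing — more noncoding elements, more isoforms,
more tissue-specific transcripts — and most GFF tooling still answers queries
by re-reading and re-parsing the whole file. `gffindex` builds a compact
binary index bundle next to a GFF3 source once, then answers four kinds of
query by reading only the byte ranges it needs from the original file:

* **extract** — resolve any feature ID (a gene, transcript, exon or CDS) to
  its complete *annotation block*: the parentless root feature plus all of its
  descendants, i.e. the minimal complete gene model. Output lines are copied
  verbatim from the source, never re-serialized.
* **search** — exact (binary-search) or fuzzy (case-insensitive substring)
  queries over attribute values such as `Name`, mapped back to whole blocks.
* **intersect** — BED-driven region queries against per-chromosome augmented
  interval trees over block spans. A region that touches an intron still
  returns the whole gene model, which is the difference between model-aware
  retrieval and plain coordinate clipping.
* **coverage / depth** — exact per-target coverage breadth (fraction of bases
  with ≥1 overlapping read) and depth (per-base overlapping-read count,
  summed and averaged) from SAM/BAM alignments, via interval merging,
  two-pointer sweeps and difference arrays over independently processed
  genome slices.

It is intended for people who operate on large annotation sets from pipelines
or notebooks: the importable API is the primary surface, with a thin
`gffindex` CLI over the same functions.

## The index bundle

Eight little-endian binary files are written next to the source (`<gff>.fts`
… `<gff>.rix`), each self-describing with a magic number, format version and
a fingerprint of the source file (CRC-32 of the contents combined with the
byte size) so stale indices fail loudly:

| file | contents |
|---|---|
| `.fts` | string feature IDs and types, in order of appearance |
| `.prt` | parent and root links — the feature hierarchy |
| `.gof` | annotation block → byte-offset range(s) in the source GFF |
| `.atn` | byte-sorted attribute-value tables per indexed key |
| `.a2f` | attribute value → feature numbers |
| `.sqs` | seqid table, order of first appearance |
| `.rit` | interval-tree nodes, laid out sequentially per seqid |
| `.rix` | per-seqid directory of offsets into `.rit` |

Features are referred to throughout by their *feature number* — the 0-based
order of appearance in the file — which keeps the fixed-width tables small.
Each subcommand loads only the subset of files its query path needs, and the
`.rix` directory lets a region query read exactly one chromosome's node
array out of `.rit`.

Region queries use an augmented interval tree: a balanced BST over block
spans sorted by start, where every node stores the maximum end coordinate in
its subtree. A query for `[qs, qe]` reports exactly the blocks with
`start ≤ qe` and `end ≥ qs`, pruning every subtree whose `max_end < qs` and
skipping right children once `start > qe` — O(log N + k) visits instead of a
linear scan.

## Worked example

```python
import sys
from gffindex import build_index_bundle, write_bundle, load_bundle, extract_by_ids
from gffindex.synthetic import generate_gff3

fx = generate_gff3("toy.gff3", n_genes=10, seed=1)   # deterministic toy annotation
write_bundle(build_index_bundle("toy.gff3"))          # eight .fts/.prt/... files

bundle = load_bundle("toy.gff3", {"fts", "prt", "gof"})
extract_by_ids(["mRNA00003.0"], bundle, "toy.gff3", sys.stdout.buffer)
```

prints (abridged):

```
##gff-version 3
chr2	synth	gene	8145	19253	.	-	.	ID=gene00003;Name=SYM00003;Note=transporter%2C ABC-type
chr2	synth	mRNA	8145	19253	.	-	.	ID=mRNA00003.0;Parent=gene00003;Name=SYM00003-RA
chr2	synth	exon	8346	10907	.	-	.	ID=exon00003.0.0;Parent=mRNA00003.0
chr2	synth	CDS	8346	10907	.	-	0	ID=CDS00003.0;Parent=mRNA00003.0
...
```

One transcript ID was requested; the full 12-line gene block came back,
byte-identical to the source lines, because extraction resolves the ID up to
its parentless root and streams the root's indexed byte ranges. The same
operations are available from the shell:

```
gffindex index     -i toy.gff3
gffindex extract   -i toy.gff3 -f mRNA00003.0
gffindex search    -i toy.gff3 -k Name -p sym00003 --fuzzy
gffindex intersect -i toy.gff3 -r chr2:9000-9100
gffindex coverage  -i toy.gff3 -b reads.sam --target-type gene
```

The `examples/` directory has one short narrative script per capability.

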