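"""Deterministic synthetic annotation, interval and alignment generators.

These stand in for real genome annotations and sequencing runs so the whole
query stack can be exercised with no downloads: nested gene -> mRNA ->
exon/CDS models with ID/Parent/Name attributes, BED4 interval files, and
reference-aligned SAM reads (plain M and spliced M-N-M CIGARs).  Every
generator is a pure function of its parameters and seed: the same call
produces byte-identical files.

``generate_gff3`` also emits a ground-truth manifest (one row per feature
line, in file order, with the feature's root and block assignment) that test
oracles compare against the parser's own hierarchy resolution.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from urllib.parse import quote

import pysam

# default study conditions: a two-contig toy genome of megabase scale, dense
# enough that random 20-kb-ish queries usually hit several gene models
DEFAULT_SEQIDS = ("chr1", "chr2")
DEFAULT_SEQID_LENGTH = 1_000_000


@dataclass
class ManifestRow:
    feature_index: int  # appearance order in the file
    feature_id: str | None
    ftype: str
    seqid: str
    start: int
    end: int
    root_index: int
    block_no: int  # equals root_index


@dataclass
class GffFixture:
    path: str
    manifest: list[ManifestRow]
    gene_ids: list[str]
    block_spans: dict[int, tuple[str, int, int]]  # block -> (seqid, lo, hi)


@dataclass
class _Proto:
    gene_no: int
    ftype: str
    seqid: str
    start: int
    end: int
    attrs: list[tuple[str, str]]


def _fmt_attrs(attrs: list[tuple[str, str]]) -> str:
    safe = "".join(
        c for c in map(chr, range(33, 127)) if c not in ";=&,%"
    )
    return ";".join(f"{k}={quote(v, safe=safe + ' ')}" for k, v in attrs)


def generate_gff3(
    path,
    n_genes: int = 50,
    seqids: tuple[str, ...] = DEFAULT_SEQIDS,
    seed: int = 0,
    interleave_fraction: float = 0.1,
    multi_transcript_p: float = 0.3,
    seqid_length: int = DEFAULT_SEQID_LENGTH,
    with_fasta: bool = False,
    write_manifest: bool = True,
) -> GffFixture:
    """Write a nested-model GFF3 file plus its ground-truth manifest.

    Genes are laid down left to right per contig with random gaps; each gene
    carries 1+ mRNAs, each mRNA 2-5 exons and a (sometimes multi-line) CDS.
    A ``Name`` attribute on genes and mRNAs feeds attribute-search tests, and
    a share of exons deliberately lack IDs, as real annotations do.  A
    fraction of adjacent gene pairs have their lines interleaved so blocks
    with multiple byte ranges occur.  ``with_fasta`` appends a small
    ``##FASTA`` section to exercise the parsing boundary.
    """
    rng = random.Random(seed)
    genes: list[list[_Proto]] = []
    gene_ids: list[str] = []
    cursor = {s: 1 for s in seqids}
    for g in range(n_genes):
        seqid = seqids[g % len(seqids)] if seqids else "chr1"
        gap = rng.randint(200, 5000)
        length = rng.randint(1_000, 20_000)
        start = cursor[seqid] + gap
        if start + length > seqid_length:
            start = rng.randint(1, max(1, seqid_length - length))
        end = start + length - 1
        cursor[seqid] = max(cursor[seqid], end)
        gid = f"gene{g:05d}"
        gene_ids.append(gid)
        lines: list[_Proto] = [_Proto(
            g, "gene", seqid, start, end,
            [("ID", gid), ("Name", f"SYM{g:05d}"),
             ("Note", rng.choice(["hypothetical protein", "kinase; putative",
                                  "transporter, ABC-type"]))],
        )]
        n_tx = 1 + (rng.randint(1, 2) if rng.random() < multi_transcript_p else 0)
        for t in range(n_tx):
            tid = f"mRNA{g:05d}.{t}"
            lines.append(_Proto(
                g, "mRNA", seqid, start, end,
                [("ID", tid), ("Parent", gid), ("Name", f"SYM{g:05d}-R{chr(65 + t)}")],
            ))
            n_exons = rng.randint(2, 5)
            bounds = sorted(rng.sample(range(start, end), 2 * n_exons))
            cds_id = f"CDS{g:05d}.{t}"
            for x in range(n_exons):
                es, ee = bounds[2 * x], bounds[2 * x + 1]
                if ee < es:
                    es, ee = ee, es
                attrs = [("Parent", tid)]
                if rng.random() < 0.7:
                    attrs.insert(0, ("ID", f"exon{g:05d}.{t}.{x}"))
                lines.append(_Proto(g, "exon", seqid, es, ee, attrs))
                if x > 0 or n_exons == 1 or rng.random() < 0.8:
                    lines.append(_Proto(
                        g, "CDS", seqid, es, ee,
                        [("ID", cds_id), ("Parent", tid)],
                    ))
        genes.append(lines)

    # interleave a fraction of adjacent gene pairs line-wise
    ordered: list[_Proto] = []
    i = 0
    while i < len(genes):
        if i + 1 < len(genes) and rng.random() < interleave_fraction:
            a, b = genes[i], genes[i + 1]
            woven: list[_Proto] = []
            for k in range(max(len(a), len(b))):
                if k < len(a):
                    woven.append(a[k])
                if k < len(b):
                    woven.append(b[k])
            ordered.extend(woven)
            i += 2
        else:
            ordered.extend(genes[i])
            i += 1

    root_index = {}
    for idx, proto in enumerate(ordered):
        if proto.ftype == "gene":
            root_index[proto.gene_no] = idx

    manifest: list[ManifestRow] = []
    block_spans: dict[int, tuple[str, int, int]] = {}
    out_lines = ["##gff-version 3"]
    for idx, p in enumerate(ordered):
        root = root_index[p.gene_no]
        fid = dict(p.attrs).get("ID")
        manifest.append(ManifestRow(idx, fid, p.ftype, p.seqid, p.start, p.end,
                                    root, root))
        if root not in block_spans:
            block_spans[root] = (p.seqid, p.start, p.end)
        else:
            s, lo, hi = block_spans[root]
            block_spans[root] = (s, min(lo, p.start), max(hi, p.end))
        strand = "+" if p.gene_no % 2 == 0 else "-"
        phase = "0" if p.ftype == "CDS" else "."
        out_lines.append(
            f"{p.seqid}\tsynth\t{p.ftype}\t{p.start}\t{p.end}\t.\t{strand}"
            f"\t{phase}\t{_fmt_attrs(p.attrs)}"
        )

    with open(path, "w") as fh:
        fh.write("\n".join(out_lines) + "\n")
        if with_fasta:
            fh.write("##FASTA\n")
            for s in seqids:
                fh.write(f">{s}\n{'ACGT' * 15}\n")

    if write_manifest:
        with open(f"{path}.manifest.tsv", "w") as fh:
            fh.write("feature_index\tfeature_id\tftype\tseqid\tstart\tend"
                     "\troot_index\tblock_no\n")
            for r in manifest:
                fh.write(f"{r.feature_index}\t{r.feature_id or '.'}\t{r.ftype}"
                         f"\t{r.seqid}\t{r.start}\t{r.end}\t{r.root_index}"
                         f"\t{r.block_no}\n")

    return GffFixture(path=str(path), manifest=manifest, gene_ids=gene_ids,
                      block_spans=block_spans)


def generate_bed(
    path,
    n: int = 100,
    seqids: tuple[str, ...] = DEFAULT_SEQIDS,
    length_range: tuple[int, int] = (2_000, 20_000),
    seed: int = 0,
    seqid_length: int = DEFAULT_SEQID_LENGTH,
) -> str:
    """Write a BED4 file of uniformly placed intervals (0-based half-open)."""
    rng = random.Random(seed)
    with open(path, "w") as fh:
        for i in range(n):
            seqid = rng.choice(seqids)
            length = rng.randint(*length_range)
            start = rng.randint(0, max(0, seqid_length - length - 1))
            fh.write(f"{seqid}\t{start}\t{start + length}\tregion{i:05d}\n")
    return str(path)


def generate_alignments(
    path,
    n_reads: int = 500,
    seqids: tuple[str, ...] = DEFAULT_SEQIDS,
    read_len: int = 100,
    spliced_p: float = 0.2,
    coord_sorted: bool = True,
    seed: int = 0,
    seqid_length: int = DEFAULT_SEQID_LENGTH,
) -> str:
    """Write a SAM file of primary mapped reads; optionally shuffled.

    A ``spliced_p`` share of reads carries an M-N-M CIGAR (intron gap of
    50-5,000 bp); the rest are plain ``<read_len>M``.  With
    ``coord_sorted=False`` records are shuffled and the header says
    ``SO:unknown``; downstream results must not depend on the order.
    """
    rng = random.Random(seed)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate" if coord_sorted else "unknown"},
        "SQ": [{"SN": s, "LN": seqid_length} for s in seqids],
    }
    reads = []
    for i in range(n_reads):
        tid = rng.randrange(len(seqids))
        if rng.random() < spliced_p and read_len >= 2:
            left = rng.randint(1, read_len - 1)
            gap = rng.randint(50, 5_000)
            cigar = [(0, left), (3, gap), (0, read_len - left)]
            span = read_len + gap
        else:
            cigar = [(0, read_len)]
            span = read_len
        pos = rng.randint(0, max(0, seqid_length - span - 1))  # 0-based
        reads.append((tid, pos, cigar, i))
    if coord_sorted:
        reads.sort(key=lambda r: (r[0], r[1], r[3]))
    else:
        rng.shuffle(reads)

    with pysam.AlignmentFile(str(path), "wh", header=header) as sam:
        for tid, pos, cigar, i in reads:
            a = pysam.AlignedSegment(sam.header)
            a.query_name = f"read{i:06d}"
            a.flag = 0
            a.reference_id = tid
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigartuples = cigar
            a.query_sequence = "A" * read_len
            sam.write(a)
    return str(path)
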