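"""Coverage breadth and depth of gene targets from a SAM file.

Breadth is the fraction of a target's bases touched by at least one read;
depth sums, per base, how many reads overlap it.  Both are computed exactly
with interval merging and two-pointer/difference-array sweeps — here over the
gene features drawn from the annotation index.
"""

import tempfile
from pathlib import Path

from gffindex import build_index_bundle, load_bundle, write_bundle
from gffindex import coverage as cov
from gffindex.synthetic import generate_alignments, generate_gff3

with tempfile.TemporaryDirectory() as tmp:
    gff = Path(tmp) / "toy.gff3"
    generate_gff3(gff, n_genes=6, seed=4, seqids=("chr1",),
                  seqid_length=100_000)
    write_bundle(build_index_bundle(gff))
    sam = generate_alignments(Path(tmp) / "reads.sam", n_reads=3_000,
                              seed=5, seqids=("chr1",), seqid_length=100_000,
                              spliced_p=0.2)

    bundle = load_bundle(gff, {"gof"})
    targets = cov.targets_from_index(bundle, gff, target_type="gene")
    intervals = cov.alignments_to_intervals(sam)

    rows = cov.coverage_table(targets, intervals)
    drows = cov.depth_table(targets, intervals)
    print(cov.format_coverage_table(rows), end="")
    print(cov.format_depth_table(drows), end="")
    print(f"-> {len(rows)} gene targets; a breadth of 1 means every base of "
          f"the gene is covered; mean_depth is reads-per-base averaged over "
          f"the gene")
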