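"""Exact and fuzzy attribute search over the indexed value tables.

Gene symbols live in the `Name` attribute; the index stores each key's values
in a byte-sorted table, so an exact query is a binary search and a fuzzy
query is a case-insensitive substring scan of the same table.
"""

import io
import tempfile
from pathlib import Path

from gffindex import build_index_bundle, load_bundle, search_attribute, write_bundle
from gffindex.synthetic import generate_gff3

with tempfile.TemporaryDirectory() as tmp:
    gff = Path(tmp) / "toy.gff3"
    generate_gff3(gff, n_genes=10, seed=1)
    write_bundle(build_index_bundle(gff))  # default indexed keys: ID, Name
    bundle = load_bundle(gff, {"atn", "a2f", "fts", "prt", "gof"})

    sink = io.BytesIO()
    exact = search_attribute("Name", "SYM00007", bundle, gff, sink)
    print(f"exact  'SYM00007'  -> values {exact.matched_values}, "
          f"{exact.n_blocks} block(s)")

    fuzzy = search_attribute("Name", "sym00007", bundle, gff, io.BytesIO(),
                             mode="fuzzy")
    # fuzzy also catches the transcript names SYM00007-RA, -RB, ...
    print(f"fuzzy  'sym00007'  -> values {fuzzy.matched_values}, "
          f"{fuzzy.n_blocks} block(s)")
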