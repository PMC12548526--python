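"""ID-based model extraction and attribute search.

Both operations resolve hits to annotation blocks and copy the block bytes
verbatim from the source GFF via the ``.gof`` byte ranges — output lines are
byte-identical to source lines, never re-serialized.  Blocks are streamed to
the output in file order as soon as they are resolved, and each block is
emitted at most once however many query IDs or attribute values land in it.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import BinaryIO, Iterable

from .errors import NotIndexedError, UnknownIdError
from .model import parse_feature_line
from .store import IndexBundle

logger = logging.getLogger(__name__)

GFF_VERSION_LINE = b"##gff-version 3\n"


@dataclass
class ExtractReport:
    n_blocks: int = 0
    n_lines: int = 0
    unknown_ids: list[str] = field(default_factory=list)
    matched_ids: list[str] = field(default_factory=list)


def read_block_bytes(gff, ranges: list[tuple[int, int]]) -> bytes:
    chunks = []
    for lo, hi in ranges:
        gff.seek(lo)
        chunks.append(gff.read(hi - lo))
    return b"".join(chunks)


def _emit_blocks(
    block_nos: Iterable[int], bundle: IndexBundle, gff, out: BinaryIO,
    line_filter=None,
) -> tuple[int, int]:
    """Write blocks (deduplicated, ascending = file order); returns counts."""
    n_blocks = 0
    n_lines = 0
    for block_no in sorted(set(block_nos)):
        ranges = bundle.block_map.ranges.get(block_no)
        if ranges is None:
            continue
        raw = read_block_bytes(gff, ranges)
        if line_filter is None:
            out.write(raw)
            n_lines += raw.count(b"\n")
        else:
            for line in raw.splitlines(keepends=True):
                if line_filter(line):
                    out.write(line)
                    n_lines += 1
        n_blocks += 1
    return n_blocks, n_lines


def extract_by_ids(
    ids: list[str],
    bundle: IndexBundle,
    gff_path=None,
    out: BinaryIO = None,
    mode: str = "block",
    strict: bool = False,
) -> ExtractReport:
    """Retrieve the full annotation block for each requested feature ID.

    Any member ID of a model resolves, via the hierarchy, to the whole block
    rooted at its parentless ancestor.  ``mode="feature-line"`` instead emits
    only the line(s) carrying the requested ID itself (a discontinuous
    feature such as a multi-line CDS keeps all of its lines).

    Unknown IDs are warnings by default; ``strict=True`` turns the first one
    into :class:`UnknownIdError`.  An ``##gff-version 3`` header is always
    prepended.
    """
    if mode not in ("block", "feature-line"):
        raise ValueError(f"unknown mode {mode!r}")
    table = bundle.feature_table
    id_map = table.id_to_num()
    report = ExtractReport()
    wanted_blocks: list[int] = []
    wanted_ids: set[str] = set()
    for fid in ids:
        num = id_map.get(fid)
        if num is None:
            if strict:
                raise UnknownIdError(f"unknown feature ID {fid!r}")
            logger.warning("unknown feature ID %r", fid)
            report.unknown_ids.append(fid)
            continue
        report.matched_ids.append(fid)
        wanted_blocks.append(table.root_of[num])
        wanted_ids.add(fid)

    path = gff_path if gff_path is not None else bundle.gff_path
    out.write(GFF_VERSION_LINE)
    with open(path, "rb") as gff:
        if mode == "block":
            line_filter = None
        else:
            def line_filter(line: bytes) -> bool:
                rec = parse_feature_line(line, 0, 0)
                return rec.feature_id in wanted_ids
        report.n_blocks, report.n_lines = _emit_blocks(
            wanted_blocks, bundle, gff, out, line_filter
        )
    return report


@dataclass
class SearchReport:
    n_blocks: int = 0
    n_lines: int = 0
    matched_values: list[str] = field(default_factory=list)
    matched_features: list[int] = field(default_factory=list)


def search_attribute(
    key: str,
    pattern: str,
    bundle: IndexBundle,
    gff_path=None,
    out: BinaryIO = None,
    mode: str = "exact",
) -> SearchReport:
    """Exact or fuzzy attribute query over the value tables built at index time.

    Exact mode binary-searches the key's byte-sorted value table for an exact
    match; fuzzy mode is a case-insensitive substring scan of the same table
    (so exact matches are always a subset of fuzzy matches of the same
    pattern).  Matched values map through the value->feature table to blocks,
    emitted deduplicated in file order.  No match is an empty, successful
    result.
    """
    if mode not in ("exact", "fuzzy"):
        raise ValueError(f"unknown mode {mode!r}")
    attr = bundle.attribute_index
    if key not in attr.keys:
        raise NotIndexedError(
            f"attribute key {key!r} was not indexed (indexed keys: "
            f"{', '.join(attr.keys) or 'none'}); re-run indexing with "
            f"--attr-keys including {key!r}"
        )
    values = attr.values[key]
    report = SearchReport()
    positions: list[int] = []
    if mode == "exact":
        # values are sorted by raw UTF-8 bytes; str comparison of the encoded
        # forms matches that order
        enc = [v.encode("utf-8") for v in values]
        i = bisect_left(enc, pattern.encode("utf-8"))
        if i < len(values) and values[i] == pattern:
            positions.append(i)
    else:
        needle = pattern.casefold()
        positions = [i for i, v in enumerate(values) if needle in v.casefold()]

    feature_nums: list[int] = []
    for i in positions:
        report.matched_values.append(values[i])
        feature_nums.extend(attr.features[key][i])
    report.matched_features = sorted(set(feature_nums))

    table = bundle.feature_table
    block_nos = [table.root_of[n] for n in report.matched_features]
    path = gff_path if gff_path is not None else bundle.gff_path
    out.write(GFF_VERSION_LINE)
    with open(path, "rb") as gff:
        report.n_blocks, report.n_lines = _emit_blocks(block_nos, bundle, gff, out)
    return report
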