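"""BED-driven region intersection against the block interval trees.

Input regions are pre-bucketed by seqid and sorted by start, so each seqid's
tree is loaded and queried once with only its own regions; the union of hit
blocks is emitted deduplicated in file order.  BED coordinates (0-based,
half-open) are converted to the 1-based inclusive convention used internally
at the parsing boundary and nowhere else.
"""

from __future__ import annotations

import re
from bisect import bisect_right
from dataclasses import dataclass
from typing import BinaryIO

from .errors import InvalidQueryError, MalformedBedError
from .extract import GFF_VERSION_LINE, read_block_bytes
from .model import parse_feature_line
from .store import IndexBundle


@dataclass(frozen=True)
class QueryRegion:
    seqid: str
    start: int  # 1-based inclusive (converted from BED)
    end: int  # inclusive
    name: str | None = None


def parse_bed4(path) -> list[QueryRegion]:
    """Parse a BED3/BED4 file into 1-based inclusive query regions.

    ``chr1  99  200  x`` becomes ``(chr1, 100, 200, x)``.  Zero-length BED
    intervals (chromStart == chromEnd) are rejected: they denote insertion
    points, not ranges.
    """
    regions: list[QueryRegion] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3 or len(cols) > 4:
                raise MalformedBedError(
                    f"expected 3 or 4 columns, found {len(cols)}", line_no
                )
            try:
                start0 = int(cols[1])
                end0 = int(cols[2])
            except ValueError:
                raise MalformedBedError(
                    f"non-integer coordinates {cols[1]!r}..{cols[2]!r}", line_no
                ) from None
            if start0 < 0 or start0 > end0:
                raise MalformedBedError(
                    f"chromStart {start0} > chromEnd {end0}", line_no
                )
            if start0 == end0:
                raise MalformedBedError(
                    f"zero-length interval at {start0}", line_no
                )
            regions.append(QueryRegion(
                seqid=cols[0], start=start0 + 1, end=end0,
                name=cols[3] if len(cols) == 4 else None,
            ))
    return regions


_REGION_RE = re.compile(r"^(?P<seqid>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def parse_region_string(text: str) -> QueryRegion:
    """Parse a 1-based inclusive ``chr:start-end`` region string."""
    m = _REGION_RE.match(text)
    if not m:
        raise InvalidQueryError(
            f"region {text!r} is not of the form chr:start-end"
        )
    start = int(m.group("start"))
    end = int(m.group("end"))
    if start < 1 or start > end:
        raise InvalidQueryError(f"region {text!r}: need 1 <= start <= end")
    return QueryRegion(seqid=m.group("seqid"), start=start, end=end)


@dataclass
class RegionHit:
    region: QueryRegion
    n_blocks: int


def _merge_sorted(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def intersect(
    regions: list[QueryRegion],
    bundle: IndexBundle,
    gff_path=None,
    out: BinaryIO = None,
    mode: str = "block",
) -> list[RegionHit]:
    """Emit the annotation blocks overlapping any query region.

    ``mode="block"`` writes whole blocks verbatim (the model-aware default:
    a region landing in an intron still returns the complete gene model);
    ``mode="feature"`` re-parses the member lines of hit blocks and keeps
    only features whose own span overlaps at least one query region —
    coordinates are never clipped, lines stay verbatim.

    Regions on seqids absent from the index contribute zero hits, reported
    but not an error.  Returns per-region hit counts in input order; output
    bytes are invariant under permutations of the input regions.
    """
    if mode not in ("block", "feature"):
        raise ValueError(f"unknown mode {mode!r}")
    by_seqid: dict[str, list[int]] = {}
    for idx, r in enumerate(regions):
        by_seqid.setdefault(r.seqid, []).append(idx)

    hits = [RegionHit(region=r, n_blocks=0) for r in regions]
    all_blocks: set[int] = set()
    region_spans: dict[str, list[tuple[int, int]]] = {}
    for seqid, idxs in by_seqid.items():
        idxs.sort(key=lambda i: (regions[i].start, regions[i].end))
        tree = bundle.tree_store.get_tree(seqid) if bundle.tree_store else None
        spans = [(regions[i].start, regions[i].end) for i in idxs]
        region_spans[seqid] = _merge_sorted(spans)
        if tree is None:
            continue
        for i in idxs:
            blocks, _ = tree.query(regions[i].start, regions[i].end)
            hits[i].n_blocks = len(blocks)
            all_blocks.update(blocks)

    path = gff_path if gff_path is not None else bundle.gff_path
    out.write(GFF_VERSION_LINE)

    def overlaps_any(seqid: str, start: int, end: int) -> bool:
        merged = region_spans.get(seqid)
        if not merged:
            return False
        # rightmost merged span starting at or before `end`
        j = bisect_right(merged, (end, float("inf"))) - 1
        return j >= 0 and merged[j][1] >= start

    with open(path, "rb") as gff:
        for block_no in sorted(all_blocks):
            ranges = bundle.block_map.ranges.get(block_no)
            if ranges is None:
                continue
            raw = read_block_bytes(gff, ranges)
            if mode == "block":
                out.write(raw)
            else:
                for line in raw.splitlines(keepends=True):
                    rec = parse_feature_line(line, 0, 0)
                    if overlaps_any(rec.seqid, rec.start, rec.end):
                        out.write(line)
    return hits
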