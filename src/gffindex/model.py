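"""GFF3 stream parsing, byte-offset tracking, feature hierarchy, annotation blocks.

The parser keeps the byte span of every feature line so downstream queries can
copy annotation text verbatim from the source file instead of re-serializing
records.  Coordinates stay 1-based inclusive (GFF3 native) throughout; format
conversions happen only at I/O boundaries (BED input, SAM input).

An *annotation block* is a parentless (root) feature together with all of its
descendants — the minimal complete gene/transcript model and the unit of
extraction and region retrieval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator
from urllib.parse import unquote

from .errors import DanglingParentError, HierarchyCycleError, MalformedLineError

logger = logging.getLogger(__name__)

VALID_STRANDS = frozenset({"+", "-", ".", "?"})


@dataclass(slots=True)
class FeatureRecord:
    """One parsed GFF3 feature line plus its byte span in the source file."""

    seqid: str
    source: str
    ftype: str
    start: int  # 1-based, inclusive
    end: int  # inclusive
    score: str | None
    strand: str
    phase: int | None
    attributes: dict[str, str]  # preserves file key order; values %-decoded
    byte_start: int  # offset of the first byte of the line
    byte_end: int  # one past the terminating newline
    line_no: int

    @property
    def feature_id(self) -> str | None:
        return self.attributes.get("ID")

    @property
    def parent_ids(self) -> list[str]:
        raw = self.attributes.get("Parent")
        if raw is None:
            return []
        return [p for p in raw.split(",") if p]


@dataclass
class FeatureTable:
    """Numeric feature numbers in order of appearance, with hierarchy links.

    ``parent_of[i]`` is the feature number of i's (first listed) parent, or
    ``None`` for roots; ``root_of[i]`` is the parentless ancestor reached by
    chasing parent links (``root_of[i] == i`` exactly for roots).
    """

    n_features: int
    string_ids: list[str | None]
    parent_of: list[int | None]
    root_of: list[int]
    ftype_of: list[str]
    _id_to_num: dict[str, int] | None = field(default=None, repr=False)

    def id_to_num(self) -> dict[str, int]:
        """String ID -> feature number (last definition wins for duplicates)."""
        if self._id_to_num is None:
            mapping: dict[str, int] = {}
            for num, sid in enumerate(self.string_ids):
                if sid is not None:
                    mapping[sid] = num
            self._id_to_num = mapping
        return self._id_to_num


@dataclass
class AnnotationBlock:
    """A root feature plus all descendants, with its source byte ranges.

    ``byte_ranges`` is the minimal list of maximal byte-contiguous runs of
    member lines: a fully contiguous model yields exactly one range, and
    concatenating the source bytes of the ranges reproduces the member lines,
    each once, in file order.
    """

    block_no: int  # equals the root's feature number
    seqid: str  # the root's seqid
    span_start: int  # min start over members (bp, 1-based)
    span_end: int  # max end over members
    byte_ranges: list[tuple[int, int]]
    members: list[int]  # feature numbers, in file order
    # Per-seqid member envelopes used by the region index; normally just
    # {seqid: (span_start, span_end)} but cross-seqid members are indexed
    # under the seqid where they actually lie.
    seqid_spans: dict[str, tuple[int, int]] = field(default_factory=dict)


@dataclass
class ScanResult:
    records: list[FeatureRecord]
    seqids: list[str]  # order of first appearance
    fasta_boundary: int | None  # byte offset of the ##FASTA directive, if any


def _parse_attributes(raw: str, line_no: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in raw.rstrip(";").split(";"):
        item = item.strip()
        if not item:
            continue
        key, sep, value = item.partition("=")
        if not sep:
            raise MalformedLineError(f"attribute {item!r} lacks '='", line_no)
        attrs[unquote(key)] = unquote(value)
    return attrs


def parse_feature_line(line: bytes, byte_start: int, line_no: int) -> FeatureRecord:
    """Parse one physical GFF3 feature line (raw bytes, newline included).

    The caller guarantees the line is not a directive/comment and not inside a
    ``##FASTA`` section.  Attribute values are percent-decoded per the GFF3
    escaping rules and their file order is preserved.
    """
    byte_end = byte_start + len(line)
    text = line.decode("utf-8").rstrip("\r\n")
    cols = text.split("\t")
    if len(cols) != 9:
        raise MalformedLineError(
            f"expected 9 tab-separated columns, found {len(cols)}", line_no
        )
    seqid, source, ftype, start_s, end_s, score, strand, phase_s, attr_s = cols
    try:
        start = int(start_s)
        end = int(end_s)
    except ValueError:
        raise MalformedLineError(
            f"non-integer coordinates {start_s!r}..{end_s!r}", line_no
        ) from None
    if start < 1 or start > end:
        raise MalformedLineError(
            f"invalid coordinates {start}..{end} (need 1 <= start <= end)", line_no
        )
    if strand not in VALID_STRANDS:
        raise MalformedLineError(f"invalid strand {strand!r}", line_no)
    if phase_s in (".", ""):
        phase: int | None = None
    elif phase_s in ("0", "1", "2"):
        phase = int(phase_s)
    else:
        raise MalformedLineError(f"invalid phase {phase_s!r}", line_no)
    return FeatureRecord(
        seqid=seqid,
        source=source,
        ftype=ftype,
        start=start,
        end=end,
        score=None if score == "." else score,
        strand=strand,
        phase=phase,
        attributes=_parse_attributes(attr_s, line_no),
        byte_start=byte_start,
        byte_end=byte_end,
        line_no=line_no,
    )


def iter_feature_lines(path) -> Iterator[tuple[bytes, int, int]]:
    """Yield (raw line, byte offset, line number) for every physical line.

    Stops before yielding anything at or after a ``##FASTA`` directive; the
    final item yielded is a sentinel ``(b"", fasta_offset, line_no)`` in that
    case so callers can record the boundary.
    """
    offset = 0
    line_no = 0
    with open(path, "rb") as fh:
        for raw in fh:
            line_no += 1
            if raw.startswith(b"##FASTA"):
                yield b"", offset, line_no
                return
            yield raw, offset, line_no
            offset += len(raw)


def scan_gff(path) -> ScanResult:
    """Single forward scan of a GFF3 file: the index-build pass.

    Records byte spans for every feature line, the seqid order of first
    appearance, and the byte offset of a trailing ``##FASTA`` section if
    present.  Comment and directive lines are skipped; malformed feature
    lines raise with their line number.
    """
    records: list[FeatureRecord] = []
    seqids: list[str] = []
    seen: set[str] = set()
    fasta_boundary: int | None = None
    for raw, offset, line_no in iter_feature_lines(path):
        if raw == b"":
            fasta_boundary = offset
            break
        stripped = raw.strip()
        if not stripped or stripped.startswith(b"#"):
            continue
        rec = parse_feature_line(raw, offset, line_no)
        records.append(rec)
        if rec.seqid not in seen:
            seen.add(rec.seqid)
            seqids.append(rec.seqid)
    return ScanResult(records=records, seqids=seqids, fasta_boundary=fasta_boundary)


def resolve_hierarchy(records: Iterable[FeatureRecord]) -> FeatureTable:
    """Assign feature numbers by appearance and resolve Parent links to roots.

    Resolution is two-pass so forward references (a child line preceding its
    parent's line) are legal.  Duplicate ID definitions: the last one wins,
    with a warning.  A feature listing several parents is attached to the
    first; if the listed parents resolve to different roots a warning names
    the feature.
    """
    records = list(records)
    n = len(records)
    string_ids: list[str | None] = [None] * n
    id_to_num: dict[str, int] = {}
    for i, rec in enumerate(records):
        fid = rec.feature_id
        string_ids[i] = fid
        if fid is not None:
            if fid in id_to_num:
                # lines of a discontinuous feature (same type, same Parent)
                # legitimately share one ID; anything else is sloppy input
                prev = records[id_to_num[fid]]
                if (prev.ftype, prev.attributes.get("Parent")) != (
                    rec.ftype, rec.attributes.get("Parent")
                ):
                    logger.warning(
                        "duplicate ID %r (feature #%d and #%d); "
                        "last definition wins",
                        fid, id_to_num[fid], i,
                    )
            id_to_num[fid] = i

    parent_of: list[int | None] = [None] * n
    all_parents: list[list[int]] = [[] for _ in range(n)]
    for i, rec in enumerate(records):
        pids = rec.parent_ids
        if not pids:
            continue
        nums = []
        for pid in pids:
            if pid not in id_to_num:
                raise DanglingParentError(pid, rec.line_no)
            nums.append(id_to_num[pid])
        parent_of[i] = nums[0]
        all_parents[i] = nums

    root_of: list[int] = [-1] * n
    for i in range(n):
        if root_of[i] != -1:
            continue
        chain = []
        j = i
        on_path: set[int] = set()
        while root_of[j] == -1 and parent_of[j] is not None:
            if j in on_path:
                raise HierarchyCycleError(j)
            on_path.add(j)
            chain.append(j)
            j = parent_of[j]
        root = j if parent_of[j] is None else root_of[j]
        root_of[j] = root
        for k in chain:
            root_of[k] = root

    for i, nums in enumerate(all_parents):
        if len(nums) > 1 and len({root_of[p] for p in nums}) > 1:
            logger.warning(
                "feature #%d (%s) lists parents resolving to different roots; "
                "first parent wins for block membership",
                i, string_ids[i] or records[i].ftype,
            )

    table = FeatureTable(
        n_features=n,
        string_ids=string_ids,
        parent_of=parent_of,
        root_of=root_of,
        ftype_of=[r.ftype for r in records],
    )
    table._id_to_num = id_to_num
    return table


def delineate_blocks(
    table: FeatureTable, records: list[FeatureRecord]
) -> list[AnnotationBlock]:
    """Group features into annotation blocks, one per root, in root order.

    Byte ranges are merged wherever consecutive member lines are byte-adjacent
    in the source file, so an uninterrupted model yields a single range and
    interleaved models yield one range per contiguous run.
    """
    members_of: dict[int, list[int]] = {}
    for i in range(table.n_features):
        members_of.setdefault(table.root_of[i], []).append(i)

    blocks: list[AnnotationBlock] = []
    for root in sorted(members_of):
        member_nums = members_of[root]  # already in file order
        root_rec = records[root]
        ranges: list[tuple[int, int]] = []
        span_start = None
        span_end = None
        seqid_spans: dict[str, tuple[int, int]] = {}
        for i in member_nums:
            rec = records[i]
            if rec.seqid != root_rec.seqid:
                logger.warning(
                    "feature #%d on %s belongs to block rooted on %s; kept in "
                    "the block, region-indexed under its own seqid",
                    i, rec.seqid, root_rec.seqid,
                )
            if ranges and ranges[-1][1] == rec.byte_start:
                ranges[-1] = (ranges[-1][0], rec.byte_end)
            else:
                ranges.append((rec.byte_start, rec.byte_end))
            span_start = rec.start if span_start is None else min(span_start, rec.start)
            span_end = rec.end if span_end is None else max(span_end, rec.end)
            lo, hi = seqid_spans.get(rec.seqid, (rec.start, rec.end))
            seqid_spans[rec.seqid] = (min(lo, rec.start), max(hi, rec.end))
        blocks.append(
            AnnotationBlock(
                block_no=root,
                seqid=root_rec.seqid,
                span_start=span_start,
                span_end=span_end,
                byte_ranges=ranges,
                members=member_nums,
                seqid_spans=seqid_spans,
            )
        )
    return blocks
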