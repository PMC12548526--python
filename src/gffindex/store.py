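"""Binary serialization of the index bundle, with staleness detection.

Eight files sit next to the source GFF3, one per table:

========  =======================================================
``.fts``  string feature IDs in appearance order, plus feature types
``.prt``  parent and root links (the feature hierarchy)
``.gof``  annotation block -> byte-offset range(s) in the source GFF
``.atn``  sorted attribute-value tables per indexed key
``.a2f``  attribute value -> feature numbers
``.sqs``  seqid table in order of first appearance
``.rit``  interval-tree nodes, laid out sequentially per seqid
``.rix``  per-seqid directory of byte offsets into ``.rit``
========  =======================================================

Everything is little-endian with fixed widths: feature/block numbers and
string lengths are 32-bit, byte offsets and element counts 64-bit, strings a
32-bit length plus raw UTF-8 bytes.  Each file opens with a 24-byte header
(magic, format version, source size, source fingerprint) so a bundle built
from a since-modified GFF fails loudly instead of answering stale queries.

The fingerprint is CRC-32 of the full source bytes packed with the low 32
bits of the file size into one 64-bit word — cheap to recompute at load time
and sensitive to any in-place edit.

Loads are cached per (file, kind, fingerprint) within the process, so every
subcommand sharing a bundle reuses one in-memory copy; ``audit_loads`` records
which index kinds an operation touched, which the test suite uses to verify
that each query path loads only the tables it needs.
"""

from __future__ import annotations

import os
import struct
import zlib
from contextlib import contextmanager
from dataclasses import dataclass, field
from typing import BinaryIO, Iterable

from . import intervals as iv
from .errors import (
    CapacityError,
    FormatError,
    MissingIndexError,
    StaleIndexError,
)
from .model import AnnotationBlock, FeatureTable, scan_gff, resolve_hierarchy, delineate_blocks

MAGIC = b"GIDX"
FORMAT_VERSION = 1
U32_MAX = 0xFFFFFFFF
NONE_U32 = 0xFFFFFFFF

ALL_KINDS = ("fts", "prt", "gof", "atn", "a2f", "sqs", "rit", "rix")

_HEADER = struct.Struct("<4sIQQ")


def source_fingerprint(path) -> tuple[int, int]:
    """(size, 64-bit fingerprint) of the source file.

    Fingerprint = CRC-32 of the full contents in the high word, low 32 bits
    of the byte size in the low word.
    """
    crc = 0
    size = 0
    with open(path, "rb") as fh:
        while True:
            chunk = fh.read(1 << 20)
            if not chunk:
                break
            crc = zlib.crc32(chunk, crc)
            size += len(chunk)
    return size, ((crc & U32_MAX) << 32) | (size & U32_MAX)


@dataclass(frozen=True)
class IndexHeader:
    format_version: int
    source_size: int
    source_checksum: int

    def pack(self) -> bytes:
        return _HEADER.pack(MAGIC, self.format_version, self.source_size,
                            self.source_checksum)

    @classmethod
    def unpack(cls, buf: bytes, path) -> "IndexHeader":
        if len(buf) < _HEADER.size:
            raise FormatError(f"{path}: truncated header")
        magic, version, size, checksum = _HEADER.unpack(buf[: _HEADER.size])
        if magic != MAGIC:
            raise FormatError(f"{path}: bad magic {magic!r}")
        if version != FORMAT_VERSION:
            raise FormatError(f"{path}: unsupported format version {version}")
        return cls(version, size, checksum)


# ---------------------------------------------------------------------------
# primitive writers/readers

def _w_u32(out: bytearray, v: int) -> None:
    out += struct.pack("<I", v)


def _w_u64(out: bytearray, v: int) -> None:
    out += struct.pack("<Q", v)


def _w_str(out: bytearray, s: str) -> None:
    raw = s.encode("utf-8")
    if len(raw) > U32_MAX:
        raise CapacityError("string exceeds 32-bit length")
    _w_u32(out, len(raw))
    out += raw


def _w_opt_str(out: bytearray, s: str | None) -> None:
    if s is None:
        _w_u32(out, NONE_U32)
    else:
        _w_str(out, s)


class _Reader:
    def __init__(self, buf: bytes, path):
        self.buf = buf
        self.pos = 0
        self.path = path

    def take(self, n: int) -> bytes:
        if self.pos + n > len(self.buf):
            raise FormatError(f"{self.path}: truncated payload")
        chunk = self.buf[self.pos: self.pos + n]
        self.pos += n
        return chunk

    def u32(self) -> int:
        return struct.unpack("<I", self.take(4))[0]

    def u64(self) -> int:
        return struct.unpack("<Q", self.take(8))[0]

    def string(self) -> str:
        return self.take(self.u32()).decode("utf-8")

    def opt_string(self) -> str | None:
        n = self.u32()
        if n == NONE_U32:
            return None
        return self.take(n).decode("utf-8")


# ---------------------------------------------------------------------------
# tables

@dataclass
class BlockOffsetMap:
    """Block number -> sorted, non-overlapping byte ranges in the source GFF."""

    ranges: dict[int, list[tuple[int, int]]]  # insertion order = block order

    def block_nos(self) -> list[int]:
        return list(self.ranges)


@dataclass
class AttributeIndex:
    """Per-key sorted value tables (.atn) and value -> feature lists (.a2f).

    Values are sorted lexicographically by their raw UTF-8 bytes within each
    key, enabling binary search for exact queries; ``features[key][i]`` lists
    the feature numbers carrying ``values[key][i]`` under ``key``.
    """

    keys: list[str]
    values: dict[str, list[str]]
    features: dict[str, list[list[int]]]


@dataclass
class IndexBundle:
    """All (or a requested subset of) index tables for one GFF3 file."""

    gff_path: str
    header: IndexHeader
    feature_table: FeatureTable | None = None
    block_map: BlockOffsetMap | None = None
    attribute_index: AttributeIndex | None = None
    seqids: list[str] | None = None
    tree_store: iv.IntervalTreeStore | None = None
    blocks: list[AnnotationBlock] | None = None  # in-memory builds only


# ---------------------------------------------------------------------------
# building

DEFAULT_ATTRIBUTE_KEYS = ("ID", "Name")


def build_index_bundle(
    gff_path, attribute_keys: Iterable[str] = DEFAULT_ATTRIBUTE_KEYS
) -> IndexBundle:
    """One forward scan of the GFF producing every table of the bundle."""
    gff_path = os.fspath(gff_path)
    scan = scan_gff(gff_path)
    table = resolve_hierarchy(scan.records)
    if table.n_features > U32_MAX:
        raise CapacityError("feature count exceeds the 32-bit index width")
    blocks = delineate_blocks(table, scan.records)

    block_map = BlockOffsetMap(ranges={b.block_no: list(b.byte_ranges) for b in blocks})

    keys = list(attribute_keys)
    values: dict[str, list[str]] = {}
    features: dict[str, list[list[int]]] = {}
    for key in keys:
        bucket: dict[str, list[int]] = {}
        for num, rec in enumerate(scan.records):
            val = rec.attributes.get(key)
            if val is not None:
                bucket.setdefault(val, []).append(num)
        ordered = sorted(bucket, key=lambda v: v.encode("utf-8"))
        values[key] = ordered
        features[key] = [bucket[v] for v in ordered]
    attr_index = AttributeIndex(keys=keys, values=values, features=features)

    per_seqid: dict[str, list[tuple[int, int, int]]] = {s: [] for s in scan.seqids}
    for b in blocks:
        for seqid, (lo, hi) in b.seqid_spans.items():
            per_seqid.setdefault(seqid, []).append((lo, hi, b.block_no))
    tree_store = iv.build_tree_store(per_seqid)

    size, checksum = source_fingerprint(gff_path)
    header = IndexHeader(FORMAT_VERSION, size, checksum)
    return IndexBundle(
        gff_path=gff_path,
        header=header,
        feature_table=table,
        block_map=block_map,
        attribute_index=attr_index,
        seqids=list(scan.seqids),
        tree_store=tree_store,
        blocks=blocks,
    )


# ---------------------------------------------------------------------------
# writing

def index_path(gff_path, kind: str) -> str:
    return f"{os.fspath(gff_path)}.{kind}"


def _payload_fts(b: IndexBundle) -> bytes:
    t = b.feature_table
    out = bytearray()
    _w_u64(out, t.n_features)
    for sid in t.string_ids:
        _w_opt_str(out, sid)
    types = sorted(set(t.ftype_of))
    _w_u64(out, len(types))
    for ty in types:
        _w_str(out, ty)
    tpos = {ty: i for i, ty in enumerate(types)}
    for ty in t.ftype_of:
        _w_u32(out, tpos[ty])
    return bytes(out)


def _payload_prt(b: IndexBundle) -> bytes:
    t = b.feature_table
    out = bytearray()
    _w_u64(out, t.n_features)
    for p in t.parent_of:
        _w_u32(out, NONE_U32 if p is None else p)
    for r in t.root_of:
        _w_u32(out, r)
    return bytes(out)


def _payload_gof(b: IndexBundle) -> bytes:
    out = bytearray()
    _w_u64(out, len(b.block_map.ranges))
    for block_no, ranges in b.block_map.ranges.items():
        _w_u32(out, block_no)
        _w_u64(out, len(ranges))
        for lo, hi in ranges:
            _w_u64(out, lo)
            _w_u64(out, hi)
    return bytes(out)


def _payload_atn(b: IndexBundle) -> bytes:
    a = b.attribute_index
    out = bytearray()
    _w_u64(out, len(a.keys))
    for key in a.keys:
        _w_str(out, key)
        _w_u64(out, len(a.values[key]))
        for v in a.values[key]:
            _w_str(out, v)
    return bytes(out)


def _payload_a2f(b: IndexBundle) -> bytes:
    a = b.attribute_index
    out = bytearray()
    _w_u64(out, len(a.keys))
    for key in a.keys:
        _w_str(out, key)
        _w_u64(out, len(a.features[key]))
        for nums in a.features[key]:
            _w_u64(out, len(nums))
            for n in nums:
                _w_u32(out, n)
    return bytes(out)


def _payload_sqs(b: IndexBundle) -> bytes:
    out = bytearray()
    _w_u64(out, len(b.seqids))
    for s in b.seqids:
        _w_str(out, s)
    return bytes(out)


def _payloads_rit_rix(b: IndexBundle) -> tuple[bytes, bytes]:
    seqid_pos = {s: i for i, s in enumerate(b.seqids)}
    rit = bytearray()
    entries: list[tuple[int, int, int, int]] = []
    for s in b.seqids:
        tree = b.tree_store.trees.get(s)
        if tree is None:
            tree = iv.build_tree([])
        offset = len(rit)
        rit += iv.serialize_nodes(tree)
        root = NONE_U32 if tree.root is None else tree.root
        entries.append((seqid_pos[s], offset, len(tree), root))
    rix = bytearray()
    _w_u64(rix, len(entries))
    for pos, offset, count, root in entries:
        _w_u32(rix, pos)
        _w_u64(rix, offset)
        _w_u64(rix, count)
        _w_u32(rix, root)
    return bytes(rit), bytes(rix)


def write_bundle(bundle: IndexBundle, base_path=None) -> list[str]:
    """Write all eight index files next to the source; returns their paths.

    Building twice from an identical source yields byte-identical files: all
    iteration orders feeding the payloads are deterministic.
    """
    base = os.fspath(base_path) if base_path is not None else bundle.gff_path
    rit, rix = _payloads_rit_rix(bundle)
    payloads = {
        "fts": _payload_fts(bundle),
        "prt": _payload_prt(bundle),
        "gof": _payload_gof(bundle),
        "atn": _payload_atn(bundle),
        "a2f": _payload_a2f(bundle),
        "sqs": _payload_sqs(bundle),
        "rit": rit,
        "rix": rix,
    }
    header = bundle.header.pack()
    written = []
    for kind in ALL_KINDS:
        path = index_path(base, kind)
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(payloads[kind])
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# loading

_CACHE: dict[tuple[str, str, int], object] = {}
_AUDIT_STACK: list[list[str]] = []


@contextmanager
def audit_loads():
    """Collect the index kinds requested while the context is active."""
    log: list[str] = []
    _AUDIT_STACK.append(log)
    try:
        yield log
    finally:
        _AUDIT_STACK.pop()


def _record(kind: str) -> None:
    for log in _AUDIT_STACK:
        if kind not in log:
            log.append(kind)


def clear_cache() -> None:
    _CACHE.clear()


def _read_indexed_file(base: str, kind: str, expect: IndexHeader) -> _Reader:
    path = index_path(base, kind)
    if not os.path.exists(path):
        raise MissingIndexError(f".{kind}", path)
    with open(path, "rb") as fh:
        buf = fh.read()
    header = IndexHeader.unpack(buf, path)
    if (header.source_size, header.source_checksum) != (
        expect.source_size, expect.source_checksum
    ):
        raise StaleIndexError(
            f"{path}: index was built from a different version of {base}; "
            f"re-run indexing"
        )
    return _Reader(buf[_HEADER.size:], path)


def _load_fts(base: str, expect: IndexHeader) -> FeatureTable:
    r = _read_indexed_file(base, "fts", expect)
    n = r.u64()
    string_ids = [r.opt_string() for _ in range(n)]
    n_types = r.u64()
    types = [r.string() for _ in range(n_types)]
    ftype_of = [types[r.u32()] for _ in range(n)]
    return FeatureTable(
        n_features=n, string_ids=string_ids,
        parent_of=[None] * n, root_of=list(range(n)), ftype_of=ftype_of,
    )


def _load_prt(base: str, expect: IndexHeader) -> tuple[list[int | None], list[int]]:
    r = _read_indexed_file(base, "prt", expect)
    n = r.u64()
    parent_of: list[int | None] = []
    for _ in range(n):
        v = r.u32()
        parent_of.append(None if v == NONE_U32 else v)
    root_of = [r.u32() for _ in range(n)]
    return parent_of, root_of


def _load_gof(base: str, expect: IndexHeader) -> BlockOffsetMap:
    r = _read_indexed_file(base, "gof", expect)
    n = r.u64()
    ranges: dict[int, list[tuple[int, int]]] = {}
    for _ in range(n):
        block_no = r.u32()
        m = r.u64()
        ranges[block_no] = [(r.u64(), r.u64()) for _ in range(m)]
    return BlockOffsetMap(ranges=ranges)


def _load_atn_a2f(base: str, expect: IndexHeader,
                  want_atn: bool, want_a2f: bool) -> AttributeIndex:
    keys: list[str] = []
    values: dict[str, list[str]] = {}
    features: dict[str, list[list[int]]] = {}
    if want_atn:
        r = _read_indexed_file(base, "atn", expect)
        for _ in range(r.u64()):
            key = r.string()
            keys.append(key)
            values[key] = [r.string() for _ in range(r.u64())]
    if want_a2f:
        r = _read_indexed_file(base, "a2f", expect)
        a2f_keys = []
        for _ in range(r.u64()):
            key = r.string()
            a2f_keys.append(key)
            features[key] = [
                [r.u32() for _ in range(r.u64())] for _ in range(r.u64())
            ]
        if want_atn and a2f_keys != keys:
            raise FormatError(f"{base}: .atn and .a2f disagree on indexed keys")
        if not want_atn:
            keys = a2f_keys
    return AttributeIndex(keys=keys, values=values, features=features)


def _load_sqs(base: str, expect: IndexHeader) -> list[str]:
    r = _read_indexed_file(base, "sqs", expect)
    return [r.string() for _ in range(r.u64())]


def _load_rix(base: str, expect: IndexHeader, seqids: list[str]) -> iv.IntervalTreeStore:
    r = _read_indexed_file(base, "rix", expect)
    rit_path = index_path(base, "rit")
    if not os.path.exists(rit_path):
        raise MissingIndexError(".rit", rit_path)
    with open(rit_path, "rb") as fh:
        IndexHeader.unpack(fh.read(_HEADER.size), rit_path)
    store = iv.IntervalTreeStore(rit_path=rit_path,
                                 rit_payload_start=_HEADER.size)
    for _ in range(r.u64()):
        pos = r.u32()
        offset = r.u64()
        count = r.u64()
        root = r.u32()
        if pos >= len(seqids):
            raise FormatError(f"{base}.rix: seqid position {pos} out of range")
        store.directory[seqids[pos]] = iv.TreeDirectoryEntry(
            seqid_pos=pos, node_offset=offset, node_count=count,
            root_index=None if root == NONE_U32 else root,
        )
    return store


def load_bundle(gff_path, needed: Iterable[str]) -> IndexBundle:
    """Load the requested index kinds for a GFF3 file, reusing cached tables.

    ``needed`` is a subset of ``{"fts","prt","gof","atn","a2f","sqs","rit",
    "rix"}``; requesting ``rit`` implies ``rix`` (the directory is needed to
    address the node payload, which itself is then read per-seqid on demand).
    Raises :class:`MissingIndexError` when a file is absent and
    :class:`StaleIndexError` when the source changed since indexing.
    """
    base = os.fspath(gff_path)
    needed = set(needed)
    for kind in needed:
        if kind not in ALL_KINDS:
            raise ValueError(f"unknown index kind {kind!r}")
    if "rit" in needed:
        needed.add("rix")
    if "rix" in needed:
        needed.add("sqs")  # directory entries address seqid-table positions

    size, checksum = source_fingerprint(base)
    expect = IndexHeader(FORMAT_VERSION, size, checksum)
    bundle = IndexBundle(gff_path=base, header=expect)

    def cached(kind: str, loader):
        _record(kind)
        key = (os.path.abspath(base), kind, checksum)
        if key not in _CACHE:
            _CACHE[key] = loader()
        return _CACHE[key]

    if "sqs" in needed:
        bundle.seqids = cached("sqs", lambda: _load_sqs(base, expect))
    if "fts" in needed or "prt" in needed:
        table = None
        if "fts" in needed:
            table = cached("fts", lambda: _load_fts(base, expect))
        if "prt" in needed:
            parent_of, root_of = cached("prt", lambda: _load_prt(base, expect))
            if table is None:
                n = len(root_of)
                table = FeatureTable(
                    n_features=n, string_ids=[None] * n,
                    parent_of=parent_of, root_of=root_of, ftype_of=[""] * n,
                )
            else:
                table = FeatureTable(
                    n_features=table.n_features,
                    string_ids=table.string_ids,
                    parent_of=parent_of, root_of=root_of,
                    ftype_of=table.ftype_of,
                )
        bundle.feature_table = table
    if "gof" in needed:
        bundle.block_map = cached("gof", lambda: _load_gof(base, expect))
    if "atn" in needed or "a2f" in needed:
        want_atn = "atn" in needed
        want_a2f = "a2f" in needed
        if want_atn:
            _record("atn")
        if want_a2f:
            _record("a2f")
        key = (os.path.abspath(base), f"attr:{want_atn}:{want_a2f}", checksum)
        if key not in _CACHE:
            _CACHE[key] = _load_atn_a2f(base, expect, want_atn, want_a2f)
        bundle.attribute_index = _CACHE[key]
    if "rix" in needed:
        bundle.tree_store = cached(
            "rix", lambda: _load_rix(base, expect, bundle.seqids)
        )
        _record("rit")  # node payload is read from .rit on first per-seqid query
    return bundle


def ensure_indexed(gff_path, attribute_keys=DEFAULT_ATTRIBUTE_KEYS,
                   auto_index: bool = True) -> None:
    """Build (or rebuild) the bundle if any index file is missing or stale."""
    base = os.fspath(gff_path)
    try:
        size, checksum = source_fingerprint(base)
        expect = IndexHeader(FORMAT_VERSION, size, checksum)
        for kind in ALL_KINDS:
            _read_indexed_file(base, kind, expect)
        return
    except (MissingIndexError, StaleIndexError, FormatError):
        if not auto_index:
            raise
    bundle = build_index_bundle(base, attribute_keys)
    write_bundle(bundle)
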