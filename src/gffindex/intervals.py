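"""Augmented interval trees over annotation-block spans, one tree per seqid.

The tree is a static balanced binary search tree built by recursive median
split of the intervals sorted by ``(start, end, block_no)``.  Each node is
augmented with the maximum interval endpoint in its subtree, which lets an
overlap query prune any subtree whose ``max_end`` falls short of the query
start and skip right children once node starts exceed the query end — the
classic O(log N + k) search instead of a linear scan.

Nodes live in a flat array laid out in in-order (i.e. sorted) sequence, which
is also the on-disk layout: the ``.rit`` file is the concatenation of all
per-seqid node arrays and the ``.rix`` directory records, per seqid, the byte
offset, node count and root index, so a query loads only the one seqid's
byte range.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

from .errors import FormatError, InvalidIntervalError, InvalidQueryError

NO_NODE = 0xFFFFFFFF  # sentinel for an absent child / absent root

# start, end, max_end: signed 64-bit; left, right, block_no: unsigned 32-bit
_NODE = struct.Struct("<qqqIII")
NODE_SIZE = _NODE.size  # 36 bytes


@dataclass
class IntervalTree:
    """Flat-array balanced interval tree for a single seqid."""

    starts: list[int]
    ends: list[int]
    max_ends: list[int]
    lefts: list[int]  # node indices, NO_NODE when absent
    rights: list[int]
    block_nos: list[int]
    root: int | None

    def __len__(self) -> int:
        return len(self.starts)

    def query(
        self, q_start: int, q_end: int, counter: "VisitCounter | None" = None
    ) -> tuple[set[int], list[tuple[int, int, int]]]:
        """Blocks whose interval overlaps [q_start, q_end] (1-based inclusive).

        Overlap predicate: ``start <= q_end and end >= q_start``.  Returns the
        de-duplicated block-number set and the individual (start, end,
        block_no) intervals hit.  A ``VisitCounter`` records how many nodes
        the traversal touched.
        """
        if q_start > q_end:
            raise InvalidQueryError(f"query start {q_start} > end {q_end}")
        blocks: set[int] = set()
        hits: list[tuple[int, int, int]] = []
        if self.root is None or self.max_ends[self.root] < q_start:
            return blocks, hits
        stack = [self.root]
        visits = 0
        while stack:
            i = stack.pop()
            visits += 1
            left = self.lefts[i]
            # descend only into subtrees that can still contain an
            # interval ending at or after q_start
            if left != NO_NODE and self.max_ends[left] >= q_start:
                stack.append(left)
            if self.starts[i] <= q_end:
                if self.ends[i] >= q_start:
                    blocks.add(self.block_nos[i])
                    hits.append((self.starts[i], self.ends[i], self.block_nos[i]))
                right = self.rights[i]
                if right != NO_NODE and self.max_ends[right] >= q_start:
                    stack.append(right)
            # starts[i] > q_end: every start in the right subtree is larger
        if counter is not None:
            counter.visits += visits
        return blocks, hits

    def depth(self) -> int:
        if self.root is None:
            return 0
        best = 0
        stack = [(self.root, 1)]
        while stack:
            i, d = stack.pop()
            best = max(best, d)
            if self.lefts[i] != NO_NODE:
                stack.append((self.lefts[i], d + 1))
            if self.rights[i] != NO_NODE:
                stack.append((self.rights[i], d + 1))
        return best


@dataclass
class VisitCounter:
    visits: int = 0


def build_tree(intervals: list[tuple[int, int, int]]) -> IntervalTree:
    """Build a balanced tree from (start, end, block_no) triples.

    Input may be empty or unsorted; ties on start break by (end, block_no) so
    the layout is fully deterministic.  Depth is ``ceil(log2(N+1))`` by
    construction.
    """
    for s, e, _ in intervals:
        if s > e:
            raise InvalidIntervalError(f"interval start {s} > end {e}")
    ordered = sorted(intervals)
    n = len(ordered)
    starts = [iv[0] for iv in ordered]
    ends = [iv[1] for iv in ordered]
    block_nos = [iv[2] for iv in ordered]
    max_ends = [0] * n
    lefts = [NO_NODE] * n
    rights = [NO_NODE] * n

    def build(lo: int, hi: int) -> int:
        # nodes occupy their sorted positions, so in-order layout is free
        if lo >= hi:
            return NO_NODE
        mid = (lo + hi) // 2
        left = build(lo, mid)
        right = build(mid + 1, hi)
        lefts[mid] = left
        rights[mid] = right
        m = ends[mid]
        if left != NO_NODE:
            m = max(m, max_ends[left])
        if right != NO_NODE:
            m = max(m, max_ends[right])
        max_ends[mid] = m
        return mid

    root = build(0, n)
    return IntervalTree(
        starts=starts,
        ends=ends,
        max_ends=max_ends,
        lefts=lefts,
        rights=rights,
        block_nos=block_nos,
        root=None if root == NO_NODE else root,
    )


def serialize_nodes(tree: IntervalTree) -> bytes:
    """Fixed 36-byte records, one per node, in array (in-order) sequence."""
    out = bytearray()
    for i in range(len(tree)):
        out += _NODE.pack(
            tree.starts[i],
            tree.ends[i],
            tree.max_ends[i],
            tree.lefts[i],
            tree.rights[i],
            tree.block_nos[i],
        )
    return bytes(out)


def deserialize_nodes(payload: bytes, root: int | None) -> IntervalTree:
    if len(payload) % NODE_SIZE:
        raise FormatError(
            f"interval-tree payload of {len(payload)} bytes is not a "
            f"multiple of the {NODE_SIZE}-byte node record"
        )
    starts, ends, max_ends, lefts, rights, block_nos = [], [], [], [], [], []
    for rec in _NODE.iter_unpack(payload):
        starts.append(rec[0])
        ends.append(rec[1])
        max_ends.append(rec[2])
        lefts.append(rec[3])
        rights.append(rec[4])
        block_nos.append(rec[5])
    return IntervalTree(starts, ends, max_ends, lefts, rights, block_nos, root)


@dataclass
class TreeDirectoryEntry:
    seqid_pos: int  # position in the seqid table
    node_offset: int  # byte offset into the .rit payload (after the header)
    node_count: int
    root_index: int | None


@dataclass
class IntervalTreeStore:
    """Per-seqid interval trees, either in memory or lazily loaded from .rit.

    When backed by files, ``get_tree`` reads exactly the directory-recorded
    byte range of the requested seqid, so querying one chromosome never pages
    in another's nodes.
    """

    directory: dict[str, TreeDirectoryEntry] = field(default_factory=dict)
    trees: dict[str, IntervalTree] = field(default_factory=dict)
    rit_path: str | None = None
    rit_payload_start: int = 0  # byte offset of the payload within the file
    _read_log: list[str] | None = None  # audit hook: seqids actually read

    def get_tree(self, seqid: str) -> IntervalTree | None:
        """The tree for one seqid, or None for an unindexed seqid (legal)."""
        if seqid in self.trees:
            return self.trees[seqid]
        entry = self.directory.get(seqid)
        if entry is None:
            return None
        if self.rit_path is None:
            return None
        with open(self.rit_path, "rb") as fh:
            fh.seek(self.rit_payload_start + entry.node_offset)
            payload = fh.read(entry.node_count * NODE_SIZE)
        if self._read_log is not None:
            self._read_log.append(seqid)
        tree = deserialize_nodes(payload, entry.root_index)
        if len(tree) != entry.node_count:
            raise FormatError(
                f"{self.rit_path}: expected {entry.node_count} nodes for "
                f"{seqid}, read {len(tree)}"
            )
        self.trees[seqid] = tree
        return tree

    def query(
        self, seqid: str, q_start: int, q_end: int,
        counter: VisitCounter | None = None,
    ) -> tuple[set[int], list[tuple[int, int, int]]]:
        tree = self.get_tree(seqid)
        if tree is None:
            return set(), []
        return tree.query(q_start, q_end, counter)


def build_tree_store(per_seqid: dict[str, list[tuple[int, int, int]]]) -> IntervalTreeStore:
    store = IntervalTreeStore()
    for seqid, intervals in per_seqid.items():
        store.trees[seqid] = build_tree(intervals)
    return store
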