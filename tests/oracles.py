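"""Deliberately naive reference implementations used as independent oracles.

Nothing here shares code with the production algorithms: overlap queries are
linear scans, hierarchy resolution is repeated parent lookup, and coverage
is counted base by base in plain arrays.
"""

from __future__ import annotations


def brute_force_overlap(intervals, q_start, q_end):
    """Linear scan applying the overlap predicate to every interval.

    ``intervals`` is a list of (start, end, label); returns the label set.
    """
    return {
        label for s, e, label in intervals if s <= q_end and e >= q_start
    }


def transitive_root(parent_map: dict[int, int | None], node: int) -> int:
    """Follow parent links one at a time until a parentless node."""
    seen = set()
    while parent_map.get(node) is not None:
        if node in seen:
            raise RuntimeError("cycle")
        seen.add(node)
        node = parent_map[node]
    return node


def per_base_coverage(target, reads):
    """(covered_bases, depth_sum) for one target by per-base counting.

    ``target`` is (start, end) 1-based inclusive; ``reads`` a list of
    (start, end) alignment intervals on the same seqid.
    """
    t_start, t_end = target
    counts = [0] * (t_end - t_start + 1)
    for s, e in reads:
        for pos in range(max(s, t_start), min(e, t_end) + 1):
            counts[pos - t_start] += 1
    covered = sum(1 for c in counts if c > 0)
    depth_sum = sum(counts)
    return covered, depth_sum


def per_base_union(intervals):
    """Total covered bases of an interval union, via an explicit bitmap."""
    if not intervals:
        return 0
    lo = min(s for s, _ in intervals)
    hi = max(e for _, e in intervals)
    bitmap = bytearray(hi - lo + 1)
    for s, e in intervals:
        for pos in range(s, e + 1):
            bitmap[pos - lo] = 1
    return sum(bitmap)
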