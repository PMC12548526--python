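"""Coverage breadth and depth of targets from SAM/BAM alignments.

Breadth of a target is the fraction of its bases overlapped by >=1 alignment;
depth is the per-base count of overlapping alignments, reported as a sum and
a mean over the target.  Both are computed exactly with sweep algorithms:

* alignments become reference-space intervals (CIGAR M/=/X/D consume and
  cover reference; N splits a read into multiple intervals; I/S/H/P consume
  none),
* breadth merges the per-seqid intervals into a disjoint set and runs a
  two-pointer co-linear scan against the sorted targets,
* depth accumulates a difference array over each work slice and prefix-sums
  it once.

The target axis is partitioned into independent slices cut only at
coordinates outside every target, so per-slice results concatenate to exactly
the single-slice answer whatever the slice size or worker count; alignment
order (coordinate-sorted or shuffled) is likewise irrelevant because
intervals are bucketed and sorted per seqid before use.
"""

from __future__ import annotations

from bisect import bisect_left
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pysam

from .errors import FormatError, InvalidIntervalError
from .extract import read_block_bytes
from .model import parse_feature_line
from .store import IndexBundle

# CIGAR operation codes (pysam numeric encoding)
_REF_COVERING = {0, 2, 7, 8}  # M, D, =, X
_REF_SKIP = 3  # N


@dataclass(frozen=True)
class Target:
    target_id: str
    seqid: str
    start: int  # 1-based inclusive
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class CoverageRow:
    target_id: str
    seqid: str
    start: int
    end: int
    length: int
    covered_bases: int
    breadth: float


@dataclass
class DepthRow:
    target_id: str
    seqid: str
    start: int
    end: int
    length: int
    depth_sum: int
    mean_depth: float
    histogram: dict[int, int] | None = None  # depth -> number of bases


@dataclass
class AlignmentFilters:
    drop_unmapped: bool = True
    drop_secondary: bool = True
    drop_supplementary: bool = True
    drop_duplicates: bool = False
    splice_aware: bool = True  # N splits; flip off to span introns


def alignments_to_intervals(
    path, filters: AlignmentFilters | None = None
) -> dict[str, list[tuple[int, int]]]:
    """Per-seqid interval lists (1-based inclusive), sorted by (start, end).

    Each retained record contributes one interval per reference-consuming
    CIGAR run; results are identical for coordinate-sorted and shuffled
    input because everything is bucketed and sorted here.
    """
    filters = filters or AlignmentFilters()
    per_seqid: dict[str, list[tuple[int, int]]] = {}
    try:
        af = pysam.AlignmentFile(str(path), check_sq=True)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None
    with af:
        if not af.header.get("SQ"):
            raise FormatError(f"{path}: missing @SQ header lines")
        for rec in af.fetch(until_eof=True):
            if rec.is_unmapped and filters.drop_unmapped:
                continue
            if rec.is_secondary and filters.drop_secondary:
                continue
            if rec.is_supplementary and filters.drop_supplementary:
                continue
            if rec.is_duplicate and filters.drop_duplicates:
                continue
            if rec.reference_name is None or rec.cigartuples is None:
                continue
            seqid = rec.reference_name
            pos = rec.reference_start + 1  # to 1-based
            run_start = pos
            bucket = per_seqid.setdefault(seqid, [])
            for op, length in rec.cigartuples:
                if op in _REF_COVERING:
                    pos += length
                elif op == _REF_SKIP:
                    if filters.splice_aware:
                        if pos > run_start:
                            bucket.append((run_start, pos - 1))
                        pos += length
                        run_start = pos
                    else:
                        pos += length
            if pos > run_start:
                bucket.append((run_start, pos - 1))
    for bucket in per_seqid.values():
        bucket.sort()
    return per_seqid


def merge_intervals(sorted_intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or bookended (end+1 == next start) sorted intervals.

    Bookended merging makes the breadth of a perfectly tiled target exactly 1.
    Input must be sorted by start; covered-base totals are preserved.
    """
    merged: list[tuple[int, int]] = []
    prev_start = None
    for s, e in sorted_intervals:
        if s > e:
            raise InvalidIntervalError(f"interval start {s} > end {e}")
        if prev_start is not None and s < prev_start:
            raise InvalidIntervalError("merge_intervals requires start-sorted input")
        prev_start = s
        if merged and s <= merged[-1][1] + 1:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def breadth(
    targets: Sequence[Target], merged: Sequence[tuple[int, int]]
) -> list[CoverageRow]:
    """Two-pointer sweep of start-sorted targets against disjoint intervals.

    All targets and intervals must belong to one seqid.  The interval cursor
    only rewinds within the current target's window (needed when targets
    overlap each other), never before it.
    """
    rows: list[CoverageRow] = []
    j = 0
    n = len(merged)
    for t in targets:
        # retreat to the first interval that could overlap this target
        while j > 0 and merged[j - 1][1] >= t.start:
            j -= 1
        while j < n and merged[j][1] < t.start:
            j += 1
        covered = 0
        k = j
        while k < n and merged[k][0] <= t.end:
            lo = max(t.start, merged[k][0])
            hi = min(t.end, merged[k][1])
            if hi >= lo:
                covered += hi - lo + 1
            k += 1
        rows.append(CoverageRow(
            target_id=t.target_id, seqid=t.seqid, start=t.start, end=t.end,
            length=t.length, covered_bases=covered,
            breadth=covered / t.length,
        ))
    return rows


def depth(
    targets: Sequence[Target],
    intervals: Sequence[tuple[int, int]],
    report: str = "mean",
) -> list[DepthRow]:
    """Exact per-base depth over one seqid's targets via a difference array.

    ``depth_sum`` counts every base of every overlapping alignment interval
    once per interval; ``report="histogram"`` additionally tallies, per
    target, the number of bases at each integer depth.
    """
    if report not in ("mean", "histogram"):
        raise ValueError(f"unknown report {report!r}")
    if not targets:
        return []
    lo = min(t.start for t in targets)
    hi = max(t.end for t in targets)
    diff = [0] * (hi - lo + 3)
    for s, e in intervals:
        cs = max(s, lo)
        ce = min(e, hi)
        if cs > ce:
            continue
        diff[cs - lo] += 1
        diff[ce - lo + 1] -= 1
    depths = diff
    running = 0
    for i in range(len(diff)):
        running += diff[i]
        depths[i] = running

    # prefix sums for O(1) per-target depth_sum
    prefix = [0] * (hi - lo + 2)
    for i in range(hi - lo + 1):
        prefix[i + 1] = prefix[i] + depths[i]

    rows: list[DepthRow] = []
    for t in targets:
        dsum = prefix[t.end - lo + 1] - prefix[t.start - lo]
        hist = None
        if report == "histogram":
            hist = {}
            for i in range(t.start - lo, t.end - lo + 1):
                hist[depths[i]] = hist.get(depths[i], 0) + 1
        rows.append(DepthRow(
            target_id=t.target_id, seqid=t.seqid, start=t.start, end=t.end,
            length=t.length, depth_sum=dsum,
            mean_depth=dsum / t.length, histogram=hist,
        ))
    return rows


@dataclass
class Slice:
    seqid: str
    lo: int
    hi: int
    targets: list[Target]
    intervals: list[tuple[int, int]] = field(default_factory=list)


def partition_slices(
    targets_by_seqid: dict[str, list[Target]],
    intervals_by_seqid: dict[str, list[tuple[int, int]]],
    max_slice: int | None = None,
) -> list[Slice]:
    """Cut targets into independent work units of roughly ``max_slice`` bp.

    Cuts happen only at coordinates interior to no target: mutually
    overlapping targets always share a slice, and a single over-long target
    stretches its slice rather than being split.  Every alignment interval
    is assigned to every slice it overlaps, so per-slice results reconcile
    exactly with unpartitioned processing.
    """
    slices: list[Slice] = []
    for seqid in targets_by_seqid:
        targets = sorted(targets_by_seqid[seqid], key=lambda t: (t.start, t.end))
        if not targets:
            continue
        # chain overlapping targets into indivisible clusters
        clusters: list[list[Target]] = [[targets[0]]]
        cluster_end = targets[0].end
        for t in targets[1:]:
            if t.start <= cluster_end:
                clusters[-1].append(t)
            else:
                clusters.append([t])
            cluster_end = max(cluster_end, t.end)
        # pack clusters into slices up to max_slice bp
        cur: list[Target] = []
        cur_lo = cur_hi = None
        for cluster in clusters:
            c_lo = cluster[0].start
            c_hi = max(t.end for t in cluster)
            if cur and max_slice is not None and c_hi - cur_lo + 1 > max_slice:
                slices.append(Slice(seqid, cur_lo, cur_hi, cur))
                cur = []
                cur_lo = cur_hi = None
            cur.extend(cluster)
            cur_lo = c_lo if cur_lo is None else cur_lo
            cur_hi = c_hi if cur_hi is None else max(cur_hi, c_hi)
        if cur:
            slices.append(Slice(seqid, cur_lo, cur_hi, cur))

    # prefix max of interval ends lets a slice find every interval reaching
    # into it, not just contiguous runs of overlapping predecessors
    prefmax: dict[str, list[int]] = {}
    for seqid, ivs in intervals_by_seqid.items():
        acc, m = [], 0
        for _, e in ivs:
            m = max(m, e)
            acc.append(m)
        prefmax[seqid] = acc

    for sl in slices:
        ivs = intervals_by_seqid.get(sl.seqid, [])
        pm = prefmax.get(sl.seqid, [])
        j = bisect_left(ivs, (sl.lo, -1))
        while j > 0 and pm[j - 1] >= sl.lo:
            j -= 1
        for s, e in ivs[j:]:
            if s > sl.hi:
                break
            if e >= sl.lo:
                sl.intervals.append((s, e))
    return slices


def _targets_by_seqid(targets: Iterable[Target]) -> dict[str, list[Target]]:
    by: dict[str, list[Target]] = {}
    for t in targets:
        by.setdefault(t.seqid, []).append(t)
    return by


def _run_slices(slices: list[Slice], fn, workers: int) -> list:
    if workers <= 1:
        results = [fn(sl) for sl in slices]
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            results = list(pool.map(fn, slices))
    out = []
    for rows in results:
        out.extend(rows)
    return out


def _reorder(rows, targets: Sequence[Target]):
    by_key = {(r.target_id, r.seqid, r.start, r.end): r for r in rows}
    return [by_key[(t.target_id, t.seqid, t.start, t.end)] for t in targets]


def coverage_table(
    targets: Sequence[Target],
    intervals_by_seqid: dict[str, list[tuple[int, int]]],
    max_slice: int | None = None,
    workers: int = 1,
) -> list[CoverageRow]:
    """Breadth rows for all targets, in input order."""
    slices = partition_slices(_targets_by_seqid(targets), intervals_by_seqid,
                              max_slice)

    def work(sl: Slice) -> list[CoverageRow]:
        return breadth(sl.targets, merge_intervals(sl.intervals))

    return _reorder(_run_slices(slices, work, workers), targets)


def depth_table(
    targets: Sequence[Target],
    intervals_by_seqid: dict[str, list[tuple[int, int]]],
    max_slice: int | None = None,
    workers: int = 1,
    report: str = "mean",
) -> list[DepthRow]:
    """Depth rows for all targets, in input order."""
    slices = partition_slices(_targets_by_seqid(targets), intervals_by_seqid,
                              max_slice)

    def work(sl: Slice) -> list[DepthRow]:
        return depth(sl.targets, sl.intervals, report=report)

    return _reorder(_run_slices(slices, work, workers), targets)


def targets_from_index(
    bundle: IndexBundle, gff_path=None, target_type: str = "gene"
) -> list[Target]:
    """Targets of one feature type, drawn from the indexed annotation blocks.

    Member lines are re-read through the ``.gof`` byte ranges and filtered on
    the type column; a feature without an ID is named ``seqid:start-end``.
    Targets come back grouped by block, blocks in file order.
    """
    path = gff_path if gff_path is not None else bundle.gff_path
    targets: list[Target] = []
    with open(path, "rb") as gff:
        for block_no, ranges in bundle.block_map.ranges.items():
            raw = read_block_bytes(gff, ranges)
            for line in raw.splitlines(keepends=True):
                rec = parse_feature_line(line, 0, 0)
                if rec.ftype != target_type:
                    continue
                tid = rec.feature_id or f"{rec.seqid}:{rec.start}-{rec.end}"
                targets.append(Target(tid, rec.seqid, rec.start, rec.end))
    return targets


def targets_from_regions(regions) -> list[Target]:
    """Adapt parsed BED query regions into coverage targets."""
    return [
        Target(r.name or f"{r.seqid}:{r.start}-{r.end}", r.seqid, r.start, r.end)
        for r in regions
    ]


COVERAGE_COLUMNS = ("target_id", "seqid", "start", "end", "length",
                    "covered_bases", "breadth")
DEPTH_COLUMNS = ("target_id", "seqid", "start", "end", "length",
                 "depth_sum", "mean_depth")


def format_coverage_table(rows: Sequence[CoverageRow]) -> str:
    lines = ["\t".join(COVERAGE_COLUMNS)]
    for r in rows:
        lines.append(
            f"{r.target_id}\t{r.seqid}\t{r.start}\t{r.end}\t{r.length}"
            f"\t{r.covered_bases}\t{r.breadth:.6g}"
        )
    return "\n".join(lines) + "\n"


def format_depth_table(rows: Sequence[DepthRow]) -> str:
    lines = ["\t".join(DEPTH_COLUMNS)]
    for r in rows:
        lines.append(
            f"{r.target_id}\t{r.seqid}\t{r.start}\t{r.end}\t{r.length}"
            f"\t{r.depth_sum}\t{r.mean_depth:.6g}"
        )
    return "\n".join(lines) + "\n"
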