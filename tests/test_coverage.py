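"""Alignment intervals, merging, breadth/depth sweeps, slice partitioning."""

import random

import pytest

from gffindex import coverage as cov, errors, store
from gffindex.synthetic import generate_alignments, generate_gff3

from .oracles import per_base_coverage, per_base_union


def _t(tid, seqid, start, end):
    return cov.Target(tid, seqid, start, end)


class TestAlignmentsToIntervals:
    def test_plain_match_cigar_span(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:1000\n"
            "r1\t0\tchr1\t100\t60\t10M\t*\t0\t0\tAAAAAAAAAA\t*\n"
        )
        assert cov.alignments_to_intervals(sam) == {"chr1": [(100, 109)]}

    def test_splice_gap_splits_interval(self, tmp_path):
        sam = tmp_path / "n.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:1000\n"
            "r1\t0\tchr1\t100\t60\t5M3N5M\t*\t0\t0\tAAAAAAAAAA\t*\n"
        )
        assert cov.alignments_to_intervals(sam) == {"chr1": [(100, 104), (108, 112)]}

    def test_insertion_softclip_consume_no_reference(self, tmp_path):
        sam = tmp_path / "i.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:1000\n"
            "r1\t0\tchr1\t100\t60\t2S3M2I3M1D2M\t*\t0\t0\tAAAAAAAAAAAA\t*\n"
        )
        # ref span: 3M + 3M + 1D + 2M = 9 bases from 100
        assert cov.alignments_to_intervals(sam) == {"chr1": [(100, 108)]}

    def test_secondary_and_unmapped_excluded(self, tmp_path):
        sam = tmp_path / "f.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:1000\n"
            "r1\t0\tchr1\t100\t60\t5M\t*\t0\t0\tAAAAA\t*\n"
            "r2\t256\tchr1\t200\t60\t5M\t*\t0\t0\tAAAAA\t*\n"
            "r3\t2048\tchr1\t300\t60\t5M\t*\t0\t0\tAAAAA\t*\n"
            "r4\t4\t*\t0\t0\t*\t*\t0\t0\tAAAAA\t*\n"
        )
        assert cov.alignments_to_intervals(sam) == {"chr1": [(100, 104)]}

    def test_missing_sq_header_is_format_error(self, tmp_path):
        sam = tmp_path / "h.sam"
        sam.write_text("@HD\tVN:1.6\nr1\t0\tchr1\t100\t60\t5M\t*\t0\t0\tAAAAA\t*\n")
        with pytest.raises(errors.FormatError):
            cov.alignments_to_intervals(sam)

    def test_sorted_and_shuffled_inputs_agree(self, tmp_path):
        a = generate_alignments(tmp_path / "s.sam", n_reads=400, seed=13,
                                coord_sorted=True)
        b = generate_alignments(tmp_path / "u.sam", n_reads=400, seed=13,
                                coord_sorted=False)
        assert cov.alignments_to_intervals(a) == cov.alignments_to_intervals(b)


class TestMergeIntervals:
    def test_overlap_and_bookend_merge(self):
        assert cov.merge_intervals([(1, 50), (40, 60)]) == [(1, 60)]
        assert cov.merge_intervals([(1, 5), (6, 9)]) == [(1, 9)]  # bookended
        assert cov.merge_intervals([(1, 5), (7, 9)]) == [(1, 5), (7, 9)]

    def test_unsorted_input_rejected(self):
        with pytest.raises(errors.InvalidIntervalError):
            cov.merge_intervals([(10, 20), (1, 5)])

    def test_union_size_matches_bitmap_oracle(self):
        rng = random.Random(61)
        ivs = sorted(
            (s, s + rng.randint(0, 300))
            for s in (rng.randint(1, 10_000) for _ in range(2_000))
        )
        merged = cov.merge_intervals(ivs)
        assert sum(e - s + 1 for s, e in merged) == per_base_union(ivs)
        assert all(merged[i][1] + 1 < merged[i + 1][0]
                   for i in range(len(merged) - 1))
        assert len(merged) <= len(ivs)


class TestBreadthAndDepth:
    def test_worked_example(self):
        target = _t("t", "chr1", 1, 100)
        reads = [(1, 50), (40, 60)]
        row = cov.breadth([target], cov.merge_intervals(reads))[0]
        assert (row.covered_bases, row.breadth) == (60, 0.6)
        drow = cov.depth([target], reads)[0]
        assert drow.depth_sum == 71  # 50 + 21
        assert drow.mean_depth == pytest.approx(0.71)

    def test_no_alignments_is_zero(self):
        row = cov.breadth([_t("t", "c", 1, 100)], [])[0]
        assert (row.covered_bases, row.breadth) == (0, 0.0)
        assert cov.depth([_t("t", "c", 1, 100)], [])[0].depth_sum == 0

    def test_double_full_containment_means_depth_two(self):
        drow = cov.depth([_t("t", "c", 1, 100)], [(1, 100), (1, 100)])[0]
        assert drow.mean_depth == 2.0

    def test_histogram_counts_bases_per_depth(self):
        drow = cov.depth([_t("t", "c", 1, 100)], [(1, 50), (40, 60)],
                         report="histogram")[0]
        assert drow.histogram == {0: 40, 1: 49, 2: 11}
        assert sum(drow.histogram.values()) == 100
        assert sum(d * n for d, n in drow.histogram.items()) == drow.depth_sum

    def test_random_targets_match_per_base_oracle(self):
        rng = random.Random(71)
        reads = sorted(
            (s, s + rng.randint(0, 400))
            for s in (rng.randint(1, 50_000) for _ in range(1_500))
        )
        targets = [
            _t(f"t{i}", "chr1", s, s + rng.randint(10, 2_000))
            for i, s in enumerate(rng.randint(1, 50_000) for _ in range(300))
        ]
        targets.sort(key=lambda t: (t.start, t.end))
        merged = cov.merge_intervals(reads)
        rows = cov.breadth(targets, merged)
        drows = cov.depth(targets, reads)
        for t, row, drow in zip(targets, rows, drows):
            covered, dsum = per_base_coverage((t.start, t.end), reads)
            assert row.covered_bases == covered
            assert drow.depth_sum == dsum


class TestPartitioning:
    def _random_instance(self, seed):
        rng = random.Random(seed)
        targets = [
            _t(f"t{i}", rng.choice(("chr1", "chr2")), s, s + rng.randint(10, 5_000))
            for i, s in enumerate(rng.randint(1, 300_000) for _ in range(200))
        ]
        intervals = {}
        for seqid in ("chr1", "chr2"):
            intervals[seqid] = sorted(
                (s, s + rng.randint(0, 500))
                for s in (rng.randint(1, 300_000) for _ in range(2_000))
            )
        return targets, intervals

    def test_single_slice_is_identity(self):
        targets, intervals = self._random_instance(81)
        none_rows = cov.coverage_table(targets, intervals, max_slice=None)
        assert cov.format_coverage_table(none_rows) == cov.format_coverage_table(
            cov.coverage_table(targets, intervals, max_slice=10**12))

    def test_read_on_slice_boundary_counted_in_both(self):
        targets = [_t("a", "c", 1, 100), _t("b", "c", 201, 300)]
        intervals = {"c": [(90, 210)]}  # spans the cut between targets
        rows = cov.coverage_table(targets, intervals, max_slice=150)
        assert [r.covered_bases for r in rows] == [11, 10]
        drows = cov.depth_table(targets, intervals, max_slice=150)
        assert [r.depth_sum for r in drows] == [11, 10]

    def test_never_splits_an_overlong_target(self):
        targets = [_t("big", "c", 1, 10_000)]
        slices = cov.partition_slices({"c": targets}, {"c": []}, max_slice=100)
        assert len(slices) == 1 and slices[0].hi - slices[0].lo + 1 == 10_000

    @pytest.mark.parametrize("max_slice", [1_000, 10_000, None])
    @pytest.mark.parametrize("workers", [1, 4])
    def test_outputs_invariant_across_slices_and_workers(self, max_slice, workers):
        targets, intervals = self._random_instance(91)
        base = cov.format_depth_table(cov.depth_table(targets, intervals))
        got = cov.format_depth_table(
            cov.depth_table(targets, intervals, max_slice=max_slice,
                            workers=workers))
        assert got == base
        cbase = cov.format_coverage_table(cov.coverage_table(targets, intervals))
        cgot = cov.format_coverage_table(
            cov.coverage_table(targets, intervals, max_slice=max_slice,
                               workers=workers))
        assert cgot == cbase


class TestTargetsFromIndex:
    def test_gene_targets_match_manifest(self, tmp_path):
        fx = generate_gff3(tmp_path / "g.gff3", n_genes=15, seed=14)
        store.write_bundle(store.build_index_bundle(fx.path))
        bundle = store.load_bundle(fx.path, {"gof"})
        targets = cov.targets_from_index(bundle, fx.path, "gene")
        expected = {(m.feature_id, m.seqid, m.start, m.end)
                    for m in fx.manifest if m.ftype == "gene"}
        assert {(t.target_id, t.seqid, t.start, t.end)
                for t in targets} == expected
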