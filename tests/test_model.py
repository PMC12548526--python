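"""Parsing, byte fidelity, hierarchy resolution, and block delineation."""

import pytest

from gffindex import errors, model
from gffindex.synthetic import generate_gff3

from .oracles import transitive_root


def _rec(line: str, offset: int = 0, line_no: int = 1):
    return model.parse_feature_line(line.encode(), offset, line_no)


class TestParseFeatureLine:
    def test_direct_column_mapping(self):
        rec = _rec("chr1\t.\tgene\t100\t200\t.\t+\t.\tID=g1\n")
        assert (rec.seqid, rec.ftype, rec.start, rec.end) == ("chr1", "gene", 100, 200)
        assert rec.attributes == {"ID": "g1"}
        assert rec.byte_start == 0
        assert rec.byte_end == len("chr1\t.\tgene\t100\t200\t.\t+\t.\tID=g1\n")
        assert rec.score is None and rec.phase is None

    def test_percent_decoding(self):
        rec = _rec("chr1\t.\tgene\t1\t2\t.\t+\t.\tID=g1;Note=a%3Bb%2Cc%3Dd\n")
        assert rec.attributes["Note"] == "a;b,c=d"

    def test_attribute_order_preserved(self):
        rec = _rec("chr1\t.\tgene\t1\t2\t.\t+\t.\tZeta=1;Alpha=2;Mid=3\n")
        assert list(rec.attributes) == ["Zeta", "Alpha", "Mid"]

    @pytest.mark.parametrize("line", [
        "chr1\tgene\t100\t200\n",  # 4 columns
        "chr1\t.\tgene\t100\t200\t.\t+\t.\tID=g1\textra\n",  # 10 columns
        "chr1\t.\tgene\tx\t200\t.\t+\t.\tID=g1\n",  # non-integer
        "chr1\t.\tgene\t201\t200\t.\t+\t.\tID=g1\n",  # start > end
        "chr1\t.\tgene\t0\t200\t.\t+\t.\tID=g1\n",  # below 1
        "chr1\t.\tgene\t1\t2\t.\tZ\t.\tID=g1\n",  # bad strand
    ])
    def test_malformed_lines_rejected_with_line_number(self, line):
        with pytest.raises(errors.MalformedLineError) as exc:
            model.parse_feature_line(line.encode(), 0, 17)
        assert exc.value.line_no == 17


class TestScanGff:
    def test_fasta_section_terminates_parsing(self, tmp_path):
        text = (
            "##gff-version 3\n"
            "chr1\t.\tgene\t1\t10\t.\t+\t.\tID=a\n"
            "chr1\t.\tgene\t20\t30\t.\t+\t.\tID=b\n"
            "chr2\t.\tgene\t1\t5\t.\t+\t.\tID=c\n"
            "##FASTA\n>chr1\nACGT\n"
        )
        p = tmp_path / "x.gff3"
        p.write_text(text)
        scan = model.scan_gff(p)
        assert len(scan.records) == 3
        assert scan.seqids == ["chr1", "chr2"]
        assert scan.fasta_boundary == text.index("##FASTA")

    def test_comment_only_file_is_empty(self, tmp_path):
        p = tmp_path / "x.gff3"
        p.write_text("##gff-version 3\n# nothing here\n")
        scan = model.scan_gff(p)
        assert scan.records == [] and scan.seqids == []
        assert scan.fasta_boundary is None

    def test_byte_spans_reproduce_source_lines(self, tmp_path):
        fx = generate_gff3(tmp_path / "g.gff3", n_genes=25, seed=5,
                           with_fasta=True)
        raw = open(fx.path, "rb").read()
        scan = model.scan_gff(fx.path)
        assert len(scan.records) >= 100
        for rec in scan.records:
            line = raw[rec.byte_start:rec.byte_end]
            assert line.endswith(b"\n")
            # re-parsing the slice reproduces the record coordinates
            again = model.parse_feature_line(line, rec.byte_start, rec.line_no)
            assert (again.seqid, again.start, again.end) == (
                rec.seqid, rec.start, rec.end)


class TestResolveHierarchy:
    def _table(self, lines):
        recs = [_rec(l + "\n", line_no=i + 1) for i, l in enumerate(lines)]
        return recs, model.resolve_hierarchy(recs)

    def test_two_step_chain_roots_at_gene(self):
        _, t = self._table([
            "chr1\t.\tgene\t1\t100\t.\t+\t.\tID=g1",
            "chr1\t.\tmRNA\t1\t100\t.\t+\t.\tID=t1;Parent=g1",
            "chr1\t.\texon\t1\t50\t.\t+\t.\tParent=t1",
        ])
        assert t.root_of == [0, 0, 0]
        assert t.parent_of == [None, 0, 1]

    def test_parentless_feature_is_its_own_root(self):
        _, t = self._table(["chr1\t.\tregion\t1\t9\t.\t+\t.\tID=r"])
        assert t.root_of == [0] and t.parent_of == [None]

    def test_forward_reference_child_before_parent(self):
        _, t = self._table([
            "chr1\t.\tmRNA\t1\t10\t.\t+\t.\tID=t1;Parent=g1",
            "chr1\t.\tgene\t1\t10\t.\t+\t.\tID=g1",
        ])
        assert t.root_of == [1, 1]

    def test_dangling_parent_raises(self):
        with pytest.raises(errors.DanglingParentError) as exc:
            self._table(["chr1\t.\tmRNA\t1\t10\t.\t+\t.\tID=t1;Parent=ghost"])
        assert "ghost" in str(exc.value)

    def test_parent_cycle_raises(self):
        with pytest.raises(errors.HierarchyCycleError):
            self._table([
                "chr1\t.\ta\t1\t10\t.\t+\t.\tID=x;Parent=y",
                "chr1\t.\tb\t1\t10\t.\t+\t.\tID=y;Parent=x",
            ])

    def test_first_of_multiple_parents_wins(self):
        _, t = self._table([
            "chr1\t.\tgene\t1\t100\t.\t+\t.\tID=g1",
            "chr1\t.\tgene\t200\t300\t.\t+\t.\tID=g2",
            "chr1\t.\texon\t10\t20\t.\t+\t.\tID=e;Parent=g1,g2",
        ])
        assert t.root_of[2] == 0

    def test_random_forest_matches_transitive_closure_oracle(self, tmp_path):
        fx = generate_gff3(tmp_path / "f.gff3", n_genes=50, seed=9,
                           interleave_fraction=0.4)
        scan = model.scan_gff(fx.path)
        table = model.resolve_hierarchy(scan.records)
        # oracle: naive repeated parent-lookup over an independently built map
        last_def = {}
        for i, rec in enumerate(scan.records):
            if rec.feature_id is not None:
                last_def[rec.feature_id] = i
        parent_map = {
            i: (last_def[rec.parent_ids[0]] if rec.parent_ids else None)
            for i, rec in enumerate(scan.records)
        }
        for i in range(len(scan.records)):
            assert table.root_of[i] == transitive_root(parent_map, i)


class TestDelineateBlocks:
    def _blocks(self, lines):
        text = "\n".join(lines) + "\n"
        recs = []
        offset = 0
        for i, l in enumerate(lines):
            raw = (l + "\n").encode()
            recs.append(model.parse_feature_line(raw, offset, i + 1))
            offset += len(raw)
        table = model.resolve_hierarchy(recs)
        return text.encode(), recs, model.delineate_blocks(table, recs)

    def test_contiguous_model_yields_one_range(self):
        raw, _, blocks = self._blocks([
            "chr1\t.\tgene\t1\t100\t.\t+\t.\tID=g1",
            "chr1\t.\tmRNA\t1\t100\t.\t+\t.\tID=t1;Parent=g1",
            "chr1\t.\texon\t1\t40\t.\t+\t.\tParent=t1",
            "chr1\t.\texon\t60\t100\t.\t+\t.\tParent=t1",
        ])
        assert len(blocks) == 1
        b = blocks[0]
        assert b.byte_ranges == [(0, len(raw))]
        assert (b.span_start, b.span_end) == (1, 100)

    def test_interleaved_genes_get_two_ranges_each(self):
        raw, recs, blocks = self._blocks([
            "chr1\t.\tgene\t1\t100\t.\t+\t.\tID=g1",
            "chr1\t.\tgene\t200\t300\t.\t+\t.\tID=g2",
            "chr1\t.\tmRNA\t1\t100\t.\t+\t.\tID=t1;Parent=g1",
            "chr1\t.\tmRNA\t200\t300\t.\t+\t.\tID=t2;Parent=g2",
        ])
        assert [b.block_no for b in blocks] == [0, 1]
        assert all(len(b.byte_ranges) == 2 for b in blocks)
        # concatenated ranges reproduce exactly the member lines
        for b in blocks:
            joined = b"".join(raw[lo:hi] for lo, hi in b.byte_ranges)
            member_lines = b"".join(
                raw[recs[i].byte_start:recs[i].byte_end] for i in b.members)
            assert joined == member_lines

    def test_blocks_partition_features_on_random_fixture(self, tmp_path):
        fx = generate_gff3(tmp_path / "p.gff3", n_genes=30, seed=3,
                           interleave_fraction=0.5)
        scan = model.scan_gff(fx.path)
        table = model.resolve_hierarchy(scan.records)
        blocks = model.delineate_blocks(table, scan.records)
        raw = open(fx.path, "rb").read()
        seen = []
        for b in blocks:
            seen.extend(b.members)
            # per-line root-label oracle: group lines by root, diff bytes
            expected = b"".join(
                raw[r.byte_start:r.byte_end]
                for i, r in enumerate(scan.records) if table.root_of[i] == b.block_no
            )
            assert b"".join(raw[lo:hi] for lo, hi in b.byte_ranges) == expected
        assert sorted(seen) == list(range(table.n_features))
        assert [b.block_no for b in blocks] == sorted(b.block_no for b in blocks)
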