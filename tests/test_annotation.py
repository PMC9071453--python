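"""GTF loading and annotation sanitization."""

import pytest

from ripscape.annotation import (
    AnnotationError,
    GeneModel,
    TranscriptModel,
    derive_intron_regions,
    drop_readthrough_transcripts,
    load_annotation,
    merge_supplemental_genes,
    remove_shared_regions,
    sanitize,
    write_gtf,
)

from _oracles import brute_force_shared


def gtf_line(chrom, feature, start, end, strand, attrs):
    return f"{chrom}\ttest\t{feature}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}\n"


def make_gene(gene_id, chrom, strand, exon_chains, tags=None):
    """exon_chains: list of exon-interval lists, one per transcript."""
    tags = tags or [frozenset()] * len(exon_chains)
    txs = tuple(
        TranscriptModel(f"{gene_id}.t{i}", tuple(exons), frozenset(t))
        for i, (exons, t) in enumerate(zip(exon_chains, tags))
    )
    return GeneModel(gene_id, gene_id, "protein_coding", chrom, strand, txs)


class TestLoadAnnotation:
    def test_coordinates_become_zero_based_half_open(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(gtf_line("chr1", "exon", 101, 200, "+", 'gene_id "A"; transcript_id "A.t";'))
        ann = load_annotation(str(p))
        assert ann["A"].transcripts[0].exons == ((100, 200),)
        assert ann["A"].span_length == 100

    def test_empty_file_gives_empty_annotation(self, tmp_path):
        p = tmp_path / "empty.gtf"
        p.write_text("# just a header comment\n")
        assert load_annotation(str(p)) == {}

    @pytest.mark.parametrize(
        "line, message",
        [
            ("chr1\tonly\tthree\n", "9 tab-separated"),
            (gtf_line("chr1", "exon", 1, 100, "+", 'transcript_id "t";'), "gene_id"),
            (gtf_line("chr1", "exon", 0, 100, "+", 'gene_id "A"; transcript_id "t";'), "invalid coordinate"),
            (gtf_line("chr1", "exon", 1, 100, ".", 'gene_id "A"; transcript_id "t";'), "strand"),
        ],
    )
    def test_malformed_lines_name_the_line_number(self, tmp_path, line, message):
        p = tmp_path / "bad.gtf"
        p.write_text("# comment\n" + line)
        with pytest.raises(AnnotationError, match="line 2") as exc:
            load_annotation(str(p))
        assert message in str(exc.value)

    def test_opposite_strand_transcripts_of_one_gene_rejected(self, tmp_path):
        p = tmp_path / "strand.gtf"
        p.write_text(
            gtf_line("chr1", "exon", 1, 100, "+", 'gene_id "A"; transcript_id "t1";')
            + gtf_line("chr1", "exon", 200, 300, "-", 'gene_id "A"; transcript_id "t2";')
        )
        with pytest.raises(AnnotationError, match="both strands"):
            load_annotation(str(p))

    def test_zero_exon_genes_rejected(self, tmp_path):
        p = tmp_path / "noexon.gtf"
        p.write_text(gtf_line("chr1", "gene", 1, 100, "+", 'gene_id "A";'))
        assert load_annotation(str(p)) == {}

    def test_round_trip_through_write_gtf(self, tmp_path):
        g = make_gene("A", "chr1", "+", [[(100, 200), (800, 1000)]])
        p = tmp_path / "rt.gtf"
        write_gtf({"A": g}, str(p))
        again = load_annotation(str(p))
        assert again["A"].transcripts[0].exons == ((100, 200), (800, 1000))
        assert again["A"].strand == "+"


class TestMergeSupplemental:
    def test_union_by_gene_id_prefers_primary(self):
        a = make_gene("A", "chr1", "+", [[(0, 100)]])
        b1 = make_gene("B", "chr1", "+", [[(200, 300)]])
        b2 = make_gene("B", "chr1", "+", [[(400, 500)]])
        c = make_gene("C", "chr1", "+", [[(600, 700)]])
        merged, report = merge_supplemental_genes({"A": a, "B": b1}, {"B": b2, "C": c})
        assert set(merged) == {"A", "B", "C"}
        assert merged["B"].span == (200, 300)
        assert report.added == ["C"]
        assert report.conflicts == ["B"]

    def test_empty_supplement_is_identity(self):
        a = {"A": make_gene("A", "chr1", "+", [[(0, 100)]])}
        merged, report = merge_supplemental_genes(a, {})
        assert merged == a and report.added == []

    def test_coordinate_overlap_with_new_id_resolved_downstream(self):
        """A supplemental gene overlapping a primary one is added; the
        sanitizer then removes the shared space so regions stay disjoint."""
        a = make_gene("A", "chr1", "+", [[(0, 500)]])
        x = make_gene("X", "chr1", "+", [[(300, 800)]])
        merged, report = merge_supplemental_genes({"A": a}, {"X": x})
        assert report.added == ["X"]
        san = sanitize(merged)
        bases_a = {b for s, e in san.exonic["A"].union(san.intronic["A"]) for b in range(s, e)}
        bases_x = {b for s, e in san.exonic["X"].union(san.intronic["X"]) for b in range(s, e)}
        assert not bases_a & bases_x
        assert san.removed_shared["chr1"] == [(300, 500)]


class TestDropReadthrough:
    def test_tagged_transcript_removed_and_span_recomputed(self):
        g = make_gene(
            "A", "chr1", "+",
            [[(0, 100), (5000, 6000)], [(0, 100), (400, 500)]],
            tags=[{"readthrough_transcript"}, set()],
        )
        out, dropped_tx, dropped_genes = drop_readthrough_transcripts({"A": g})
        assert dropped_tx == ["A.t0"] and dropped_genes == []
        assert out["A"].span == (0, 500)

    def test_gene_whose_only_transcript_is_tagged_is_dropped(self):
        g = make_gene("A", "chr1", "+", [[(0, 100)]], tags=[{"readthrough_transcript"}])
        out, dropped_tx, dropped_genes = drop_readthrough_transcripts({"A": g})
        assert out == {} and dropped_genes == ["A"]

    def test_untagged_annotation_unchanged(self):
        ann = {"A": make_gene("A", "chr1", "+", [[(0, 100)]])}
        out, dropped_tx, dropped_genes = drop_readthrough_transcripts(ann)
        assert out == ann and not dropped_tx and not dropped_genes


class TestRemoveSharedRegions:
    def test_pairwise_overlap_blind(self):
        ann = {
            "A": make_gene("A", "chr1", "+", [[(100, 200)]]),
            "B": make_gene("B", "chr1", "+", [[(150, 250)]]),
        }
        san = remove_shared_regions(ann, "blind")
        assert san.removed_shared["chr1"] == [(150, 200)]
        assert san.exonic["A"].intervals == ((100, 150),)
        assert san.exonic["B"].intervals == ((200, 250),)

    def test_opposite_strands_kept_in_aware_mode(self):
        ann = {
            "A": make_gene("A", "chr1", "+", [[(100, 200)]]),
            "B": make_gene("B", "chr1", "-", [[(150, 250)]]),
        }
        san = remove_shared_regions(ann, "aware")
        assert san.removed_shared == {}
        assert san.exonic["A"].intervals == ((100, 200),)

    def test_triple_overlap_against_per_base_oracle(self):
        ann = {
            "A": make_gene("A", "chr1", "+", [[(0, 4000)]]),
            "B": make_gene("B", "chr1", "+", [[(3000, 7000)]]),
            "C": make_gene("C", "chr1", "-", [[(3500, 9000)]]),
        }
        san = remove_shared_regions(ann, "blind")
        assert san.removed_shared["chr1"] == brute_force_shared(ann)["chr1"]
        # any base covered >= 2x is gone from every gene
        shared = {b for s, e in san.removed_shared["chr1"] for b in range(s, e)}
        for gid in san.exonic:
            kept = {b for s, e in san.exonic[gid] for b in range(s, e)}
            assert not kept & shared

    def test_idempotent(self, default_sim):
        ann = default_sim.annotation
        ann2, _, _ = drop_readthrough_transcripts(ann)
        once = remove_shared_regions(ann2, "blind")
        # re-running on an annotation restricted to the surviving genes
        # removes nothing new
        again = remove_shared_regions({g: ann2[g] for g in once.genes}, "blind")
        assert again.removed_shared == once.removed_shared
        assert {g: s.intervals for g, s in again.exonic.items()} == {
            g: s.intervals for g, s in once.exonic.items()
        }


class TestDeriveIntronsAndInvariants:
    def test_single_transcript_subtraction(self):
        ann = {"A": make_gene("A", "chr1", "+", [[(0, 200), (800, 1000)]])}
        san = derive_intron_regions(remove_shared_regions(ann))
        assert san.intronic["A"].intervals == ((200, 800),)
        assert san.intronic["A"].total_length == 600

    def test_single_exon_gene_flagged_intronless(self):
        ann = {"A": make_gene("A", "chr1", "+", [[(0, 500)]])}
        san = derive_intron_regions(remove_shared_regions(ann))
        assert not san.intronic["A"]
        assert "A" in san.intronless

    def test_two_transcripts_use_exon_union(self):
        ann = {
            "A": make_gene("A", "chr1", "+", [[(0, 200), (800, 1000)], [(0, 300), (600, 1000)]])
        }
        san = derive_intron_regions(remove_shared_regions(ann))
        assert san.exonic["A"].intervals == ((0, 300), (600, 1000))
        assert san.intronic["A"].intervals == ((300, 600),)
        span_bases = set(range(0, 1000))
        ex = {b for s, e in san.exonic["A"] for b in range(s, e)}
        intr = {b for s, e in san.intronic["A"] for b in range(s, e)}
        assert ex | intr == span_bases and not ex & intr

    def test_full_sanitize_disjoint_and_conserving(self, default_sim, default_san):
        san = default_san
        per_chrom_owner: dict[str, dict[int, str]] = {}
        for gid in san.genes:
            region = san.exonic[gid].union(san.intronic[gid])
            owners = per_chrom_owner.setdefault(region.chrom, {})
            for s, e in region:
                for b in range(s, e):
                    assert b not in owners, f"base {b} claimed by {owners[b]} and {gid}"
                    owners[b] = gid
        for gid, g in san.genes.items():
            shared = san.removed_shared.get(g.chrom, [])
            s0, e0 = g.span
            lost = sum(min(e, e0) - max(s, s0) for s, e in shared if s < e0 and e > s0)
            assert (
                san.exonic[gid].total_length + san.intronic[gid].total_length + lost
                == g.span_length
            )

    def test_order_independence(self, default_sim):
        ann = default_sim.annotation
        reversed_ann = dict(reversed(list(ann.items())))
        a = sanitize(ann)
        b = sanitize(reversed_ann)
        assert set(a.genes) == set(b.genes)
        for g in a.genes:
            assert a.exonic[g].intervals == b.exonic[g].intervals
            assert a.intronic[g].intervals == b.intronic[g].intervals
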