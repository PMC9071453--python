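"""Read assignment, counting, TPM normalization, and the splicing ratio."""

import math

import numpy as np
import pytest

from ripscape.annotation import sanitize
from ripscape.quant import (
    AMBIGUOUS,
    UNASSIGNED,
    FeatureCounts,
    ReadAlignment,
    assign_read,
    combined_tpm,
    count_sample,
    merge_fragments,
    splicing_ratio,
)

from _oracles import brute_force_assign, gene_base_sets
from test_annotation import make_gene


@pytest.fixture(scope="module")
def toy_san():
    # gene A: exons [1000,2000) + [10000,11000), intron between; minus strand
    # neighbor far away so nothing overlaps
    ann = {
        "A": make_gene("A", "chr1", "+", [[(1000, 2000), (10000, 11000)]]),
        "B": make_gene("B", "chr1", "-", [[(20000, 22000)]]),
    }
    return sanitize(ann)


def fwd_read(blocks, read_id="r"):
    # reverse-stranded library: a '-' alignment implies a '+' strand transcript
    return ReadAlignment(read_id, "chr1", "-", tuple(blocks))


class TestAssignRead:
    def test_partial_exonic_overlap_above_threshold(self, toy_san):
        aln = fwd_read([(975, 1050)])  # 50 nt exonic, 25 intergenic... 50 >= 20
        assert assign_read(aln, toy_san) == ("A", "exonic")

    def test_overlap_below_min_overlap_unassigned(self, toy_san):
        aln = fwd_read([(985, 1060)])  # 60 exonic? no: [1000,1060) = 60 -> use 15 nt
        aln = fwd_read([(925, 1015)])  # 15 nt exonic only
        assert assign_read(aln, toy_san) == UNASSIGNED

    def test_larger_intronic_overlap_wins(self, toy_san):
        aln = fwd_read([(1970, 2045)])  # 30 exonic, 45 intronic
        assert assign_read(aln, toy_san) == ("A", "intronic")

    def test_tie_goes_exonic(self, toy_san):
        aln = fwd_read([(1960, 2040)])  # 40 exonic, 40 intronic
        assert assign_read(aln, toy_san) == ("A", "exonic")

    def test_wrong_strand_unassigned(self, toy_san):
        aln = ReadAlignment("r", "chr1", "+", ((1000, 1100),))  # implies '-' gene
        assert assign_read(aln, toy_san) == UNASSIGNED
        assert assign_read(aln, toy_san, strandedness="unstranded") == ("A", "exonic")

    def test_matches_brute_force_oracle_on_synthetic_reads(self, default_san, default_short_reads):
        reads, _ = default_short_reads
        base_sets = {g: gene_base_sets(default_san, g) for g in default_san.genes}
        for aln in reads[:1500]:
            got = assign_read(aln, default_san)
            want = brute_force_assign(aln, default_san, base_sets)
            assert got == want, aln.read_id


class TestCountSample:
    def test_empty_stream_all_zero(self, toy_san):
        fc = count_sample([], toy_san)
        assert fc.assigned == 0 and fc.total == 0

    def test_reads_inside_exons_counted(self, toy_san):
        reads = [fwd_read([(1100, 1175)], f"r{i}") for i in range(10)]
        fc = count_sample(reads, toy_san)
        assert fc.exonic("A") == 10 and fc.intronic("A") == 0
        assert fc.assigned + fc.unassigned + fc.ambiguous == fc.total == 10

    def test_mixed_sample_matches_generator_truth(self, default_cfg, default_sim):
        """On a clean annotation (no overlap pairs) every read's bucket
        equals the generator's planted compartment."""
        from dataclasses import replace
        from ripscape.simulate import simulate_annotation, simulate_short_read_alignments

        cfg = replace(default_cfg, overlap_pairs=0, readthrough_genes=0, dog_genes=0, n_genes=20)
        sim = simulate_annotation(cfg)
        san = sanitize(sim.annotation)
        reads, truth = simulate_short_read_alignments(cfg, sim)
        fc = count_sample(reads, san)
        want = truth.groupby(["gene_id", "compartment"]).size()
        for g in san.genes:
            assert fc.exonic(g) == want.get((g, "exonic"), 0)
            assert fc.intronic(g) == want.get((g, "intronic"), 0)
        assert fc.unassigned == 0

    def test_paired_mates_collapse_to_one_fragment(self, toy_san):
        mates = [
            ReadAlignment("frag1", "chr1", "-", ((1100, 1175),)),
            ReadAlignment("frag1", "chr1", "+", ((1300, 1375),)),
        ]
        fc = count_sample(mates, toy_san, paired=True)
        assert fc.total == 1 and fc.exonic("A") == 1
        merged = list(merge_fragments(iter(mates)))
        assert merged[0].blocks == ((1100, 1175), (1300, 1375))


class TestCombinedTpm:
    def test_joint_mode_two_gene_arithmetic(self):
        ann = {
            "A": make_gene("A", "chr1", "+", [[(0, 1000)]]),
            "B": make_gene("B", "chr1", "+", [[(5000, 6000)]]),
        }
        san = sanitize(ann)
        fc = FeatureCounts("s", {"A": [100, 0], "B": [300, 0]})
        tpm = combined_tpm(fc, san, mode="joint")
        assert tpm.tpm.at["A", "tpm_combined"] == pytest.approx(250_000)
        assert tpm.tpm.at["B", "tpm_combined"] == pytest.approx(750_000)

    def test_all_zero_counts_give_zero_tpm(self, toy_san):
        fc = FeatureCounts("s", {g: [0, 0] for g in toy_san.genes})
        tpm = combined_tpm(fc, toy_san)
        assert (tpm.tpm == 0).all().all()

    def test_three_gene_hand_oracle_both_modes(self):
        # A: exon 1 kb / intron 4 kb; B: exon 2 kb intronless; C: exon 500 b / intron 500 b
        ann = {
            "A": make_gene("A", "chr1", "+", [[(0, 1000), (5000, 5000 + 0)]]),
            "B": make_gene("B", "chr1", "+", [[(10000, 12000)]]),
            "C": make_gene("C", "chr1", "+", [[(20000, 20500), (21000, 21000)]]),
        }
        ann["A"] = make_gene("A", "chr1", "+", [[(0, 500), (4500, 5000)]])  # exon 1 kb, intron 4 kb
        ann["C"] = make_gene("C", "chr1", "+", [[(20000, 20250), (20750, 21000)]])  # exon 500, intron 500
        san = sanitize(ann)
        fc = FeatureCounts("s", {"A": [10, 8], "B": [40, 0], "C": [5, 1]})
        # hand-computed rates (reads per kb): A: ex 10/1=10, in 8/4=2; B: 40/2=20; C: ex 5/0.5=10, in 1/0.5=2
        joint = combined_tpm(fc, san, mode="joint")
        total = 10 + 2 + 20 + 10 + 2  # 44
        assert joint.tpm.at["A", "tpm_exonic"] == pytest.approx(1e6 * 10 / total)
        assert joint.tpm.at["A", "tpm_intronic"] == pytest.approx(1e6 * 2 / total)
        assert joint.tpm.at["C", "tpm_combined"] == pytest.approx(1e6 * 12 / total)
        split = combined_tpm(fc, san, mode="split")
        assert split.tpm.at["A", "tpm_exonic"] == pytest.approx(1e6 * 10 / 40)
        assert split.tpm.at["A", "tpm_intronic"] == pytest.approx(1e6 * 2 / 4)
        assert split.tpm.at["B", "tpm_intronic"] == 0

    def test_count_on_zero_length_region_is_an_error(self):
        ann = {"A": make_gene("A", "chr1", "+", [[(0, 1000)]])}  # intronless
        san = sanitize(ann)
        fc = FeatureCounts("s", {"A": [0, 5]})
        with pytest.raises(ValueError, match="zero-length"):
            combined_tpm(fc, san)

    def test_scale_invariance(self, default_san):
        rng = np.random.default_rng(0)
        counts = {g: [int(rng.integers(0, 100)), int(rng.integers(0, 50))] for g in default_san.genes}
        for g in default_san.intronless:
            counts[g][1] = 0
        t1 = combined_tpm(FeatureCounts("s", counts), default_san)
        t2 = combined_tpm(FeatureCounts("s", {g: [7 * a, 7 * b] for g, (a, b) in counts.items()}), default_san)
        assert np.allclose(t1.tpm.to_numpy(), t2.tpm.to_numpy())

    def test_joint_normalization_sums_to_one_million(self, default_san, default_short_reads):
        reads, _ = default_short_reads
        fc = count_sample(reads, default_san)
        tpm = combined_tpm(fc, default_san)
        total = tpm.tpm[["tpm_exonic", "tpm_intronic"]].to_numpy().sum()
        assert total == pytest.approx(1e6, rel=1e-6)


class TestSplicingRatio:
    def make_pair(self, san, counts):
        fc = FeatureCounts("s", counts)
        tpm = combined_tpm(fc, san)
        return fc, tpm

    def test_length_normalized_arithmetic(self):
        # exonic 80 reads / 2 kb, intronic 40 reads / 8 kb -> (40/8)/(80/2) = 0.125
        ann = {"A": make_gene("A", "chr1", "+", [[(0, 1000), (9000, 10000)]])}
        san = sanitize(ann)  # exon 2 kb, intron 8 kb
        fc, tpm = self.make_pair(san, {"A": [80, 40]})
        df = splicing_ratio(fc, tpm, fc, tpm, san)
        assert df.at["A", "ratio_a"] == pytest.approx(0.125)

    def test_zero_intronic_reads_mean_fully_spliced(self):
        ann = {"A": make_gene("A", "chr1", "+", [[(0, 1000), (9000, 10000)]])}
        san = sanitize(ann)
        fc, tpm = self.make_pair(san, {"A": [80, 0]})
        df = splicing_ratio(fc, tpm, fc, tpm, san)
        assert df.at["A", "ratio_a"] == 0.0

    def test_intronless_and_low_tpm_genes_ineligible(self, default_san, default_short_reads):
        reads, _ = default_short_reads
        fc = count_sample(reads, default_san)
        tpm = combined_tpm(fc, default_san)
        df = splicing_ratio(fc, tpm, fc, tpm, default_san, tpm_min=1.0)
        for g in default_san.intronless:
            assert not df.at[g, "eligible_a"]
            assert math.isnan(df.at[g, "ratio_a"])
        low = tpm.tpm.index[tpm.tpm.tpm_combined < 1.0]
        assert not df.loc[low, "eligible_a"].any()
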