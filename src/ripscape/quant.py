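"""Short-read assignment, counting, TPM, and the intron/exon splicing ratio.

Reads are assigned at gene level to an *exonic* or *intronic* bucket by
total block overlap against the sanitized interval sets, with a minimum
overlap of 20 bases (featureCounts-style ``--minOverlap 20`` semantics).
Because sanitization makes per-gene regions disjoint, a qualifying read can
match at most one gene; matching two is an internal-consistency error.

TPM is computed separately for exonic and intronic regions and summed per
gene. Two normalization modes exist: 'joint' (default) spends a single 1e6
budget across all exonic+intronic length-normalized rates; 'split' gives
the exonic and intronic families 1e6 each.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd
import pysam

from .annotation import SanitizedAnnotation
from .intervals import merge_intervals, overlap_length


@dataclass(frozen=True)
class ReadAlignment:
    """Carrier for one alignment (or one merged paired-end fragment)."""

    read_id: str
    chrom: str
    strand: str  # strand of the alignment: + or -
    blocks: tuple[tuple[int, int], ...]
    mapq: int = 60
    secondary: bool = False
    supplementary: bool = False
    unmapped: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(merge_intervals(self.blocks)))


def read_alignments(path: str, region: str | None = None) -> Iterator[ReadAlignment]:
    """Stream alignments from SAM/BAM via pysam.

    Random access (region != None) requires an indexed BAM.
    """
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode) as fh:
        if region is not None:
            if not fh.has_index():
                raise OSError(f"{path}: random access requested but no index found")
            it: Iterable[pysam.AlignedSegment] = fh.fetch(region=region)
        else:
            it = fh
        for seg in it:
            yield ReadAlignment(
                read_id=seg.query_name,
                chrom=seg.reference_name or "*",
                strand="-" if seg.is_reverse else "+",
                blocks=tuple() if seg.is_unmapped else tuple(seg.get_blocks()),
                mapq=seg.mapping_quality,
                secondary=seg.is_secondary,
                supplementary=seg.is_supplementary,
                unmapped=seg.is_unmapped,
            )


def merge_fragments(alignments: Iterable[ReadAlignment]) -> Iterator[ReadAlignment]:
    """Collapse paired mates sharing a read_id into one fragment.

    Fragment blocks are the union of mate blocks; secondary/supplementary
    and unmapped records are passed through untouched (they are skipped by
    the counters). Strand is taken from the first mate seen, so upstream
    callers should orient read1 to the fragment strand convention.
    """
    pending: dict[str, ReadAlignment] = {}
    for aln in alignments:
        if aln.unmapped or aln.secondary or aln.supplementary:
            yield aln
            continue
        prev = pending.pop(aln.read_id, None)
        if prev is None:
            pending[aln.read_id] = aln
        else:
            yield ReadAlignment(
                read_id=prev.read_id,
                chrom=prev.chrom,
                strand=prev.strand,
                blocks=prev.blocks + aln.blocks,
                mapq=min(prev.mapq, aln.mapq),
            )
    yield from pending.values()


UNASSIGNED = ("__unassigned__", "")
AMBIGUOUS = ("__ambiguous__", "")


def effective_strand(aln_strand: str, strandedness: str) -> str | None:
    """Transcript strand implied by the alignment under the library chemistry."""
    if strandedness == "unstranded":
        return None
    if strandedness == "forward":
        return aln_strand
    if strandedness == "reverse":
        return "-" if aln_strand == "+" else "+"
    raise ValueError(f"unknown strandedness {strandedness!r}")


def assign_read(
    aln: ReadAlignment,
    ann: SanitizedAnnotation,
    min_overlap: int = 20,
    strandedness: str = "reverse",
) -> tuple[str, str]:
    """Assign one alignment to (gene_id, 'exonic'|'intronic'), or UNASSIGNED/AMBIGUOUS.

    Candidate features are the per-gene exonic and intronic sets overlapping
    the read blocks by >= min_overlap on the strand the library chemistry
    implies. Within one gene the larger overlap wins; ties go exonic.
    """
    if aln.unmapped or aln.secondary or aln.supplementary:
        raise ValueError("assign_read expects primary mapped alignments")
    strand = effective_strand(aln.strand, strandedness)
    blocks = list(aln.blocks)
    candidates: dict[str, dict[str, int]] = {}
    for g in ann.genes_on(aln.chrom, strand):
        gs, ge = g.span
        if blocks[-1][1] <= gs or blocks[0][0] >= ge:
            continue
        for bucket, sets in (("exonic", ann.exonic), ("intronic", ann.intronic)):
            ov = sets[g.gene_id].overlap_length(blocks)
            if ov >= min_overlap:
                candidates.setdefault(g.gene_id, {})[bucket] = ov
    if not candidates:
        return UNASSIGNED
    if len(candidates) > 1:
        return AMBIGUOUS
    gene_id, buckets = next(iter(candidates.items()))
    if len(buckets) == 1:
        return (gene_id, next(iter(buckets)))
    # exonic wins ties
    return (gene_id, "exonic" if buckets["exonic"] >= buckets["intronic"] else "intronic")


@dataclass
class FeatureCounts:
    sample_id: str
    counts: dict[str, list[int]] = field(default_factory=dict)  # gene_id -> [exonic, intronic]
    unassigned: int = 0
    ambiguous: int = 0
    total: int = 0

    def exonic(self, gene_id: str) -> int:
        return self.counts.get(gene_id, [0, 0])[0]

    def intronic(self, gene_id: str) -> int:
        return self.counts.get(gene_id, [0, 0])[1]

    @property
    def assigned(self) -> int:
        return sum(c[0] + c[1] for c in self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_id": g, "exonic_count": c[0], "intronic_count": c[1]}
            for g, c in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["gene_id", "exonic_count", "intronic_count"])


def count_sample(
    alignments: Iterable[ReadAlignment],
    ann: SanitizedAnnotation,
    min_overlap: int = 20,
    strandedness: str = "reverse",
    sample_id: str = "sample",
    paired: bool = False,
    strict: bool = True,
) -> FeatureCounts:
    """Tally assign_read over one sample's alignment stream.

    With strict=True an ambiguous assignment (two genes claiming one read)
    raises, since sanitization should make it impossible.
    """
    fc = FeatureCounts(sample_id=sample_id)
    for g in ann.genes:
        fc.counts[g] = [0, 0]
    if paired:
        alignments = merge_fragments(alignments)
    for aln in alignments:
        if aln.unmapped or aln.secondary or aln.supplementary:
            continue
        fc.total += 1
        gene_id, bucket = assign_read(aln, ann, min_overlap=min_overlap, strandedness=strandedness)
        if (gene_id, bucket) == UNASSIGNED:
            fc.unassigned += 1
        elif (gene_id, bucket) == AMBIGUOUS:
            if strict:
                raise RuntimeError(
                    f"read {aln.read_id} matches two genes: annotation is not sanitized"
                )
            fc.ambiguous += 1
        else:
            fc.counts[gene_id][0 if bucket == "exonic" else 1] += 1
    return fc


@dataclass
class TpmTable:
    sample_id: str
    tpm: pd.DataFrame  # index gene_id; columns tpm_exonic, tpm_intronic, tpm_combined
    mode: str
    rate_sum: float  # joint-mode normalization denominator (reads per kb, summed)

    def combined(self, gene_id: str) -> float:
        return float(self.tpm.at[gene_id, "tpm_combined"]) if gene_id in self.tpm.index else 0.0


def combined_tpm(fc: FeatureCounts, ann: SanitizedAnnotation, mode: str = "joint") -> TpmTable:
    """Length-normalized TPM per gene, exonic + intronic summed.

    rate(g, r) = count / (region_length / 1000). 'joint': one 1e6 budget over
    all rates; 'split': exonic and intronic families normalized to 1e6 each.
    """
    if mode not in ("joint", "split"):
        raise ValueError(f"mode must be 'joint' or 'split', got {mode!r}")
    genes = sorted(ann.genes)
    rates = {"exonic": {}, "intronic": {}}
    for g in genes:
        for bucket, sets, count in (
            ("exonic", ann.exonic, fc.exonic(g)),
            ("intronic", ann.intronic, fc.intronic(g)),
        ):
            length = sets[g].total_length
            if count > 0 and length == 0:
                raise ValueError(f"gene {g}: nonzero {bucket} count on zero-length region")
            rates[bucket][g] = count / (length / 1000.0) if length else 0.0

    joint_sum = sum(rates["exonic"].values()) + sum(rates["intronic"].values())
    out = {}
    for bucket in ("exonic", "intronic"):
        denom = joint_sum if mode == "joint" else sum(rates[bucket].values())
        out[bucket] = {g: (1e6 * r / denom if denom else 0.0) for g, r in rates[bucket].items()}
    df = pd.DataFrame(
        {
            "tpm_exonic": [out["exonic"][g] for g in genes],
            "tpm_intronic": [out["intronic"][g] for g in genes],
        },
        index=pd.Index(genes, name="gene_id"),
    )
    df["tpm_combined"] = df["tpm_exonic"] + df["tpm_intronic"]
    return TpmTable(sample_id=fc.sample_id, tpm=df, mode=mode, rate_sum=joint_sum)


def splicing_ratio(
    fc_a: FeatureCounts,
    tpm_a: TpmTable,
    fc_b: FeatureCounts,
    tpm_b: TpmTable,
    ann: SanitizedAnnotation,
    tpm_min: float = 1.0,
) -> pd.DataFrame:
    """Per-gene intron/exon density ratio in each of two samples.

    ratio = (intronic_count / intronic_length) / (exonic_count / exonic_length);
    0 = fully spliced, 1 = intronic density equals exonic (unspliced-like).
    Eligible genes are intron-bearing with combined TPM >= tpm_min in BOTH
    samples and nonzero exonic counts in the sample being measured.
    """
    rows = []
    for g in sorted(ann.genes):
        ex_len = ann.exonic[g].total_length
        in_len = ann.intronic[g].total_length
        eligible_gene = (
            in_len > 0
            and ex_len > 0
            and tpm_a.combined(g) >= tpm_min
            and tpm_b.combined(g) >= tpm_min
        )
        row: dict[str, object] = {"gene_id": g}
        for label, fc in (("a", fc_a), ("b", fc_b)):
            ex, intr = fc.exonic(g), fc.intronic(g)
            if eligible_gene and ex > 0:
                row[f"ratio_{label}"] = (intr / in_len) / (ex / ex_len)
                row[f"eligible_{label}"] = True
            else:
                row[f"ratio_{label}"] = float("nan")
                row[f"eligible_{label}"] = False
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")
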