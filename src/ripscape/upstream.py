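"""Upstream-readthrough (DoG) contamination filter.

Transcription that runs past a gene's terminator can spill into the next
gene downstream, making that neighbor look bound/expressed when the signal
is really readthrough. The filter quantifies intergenic signal in the 2000
bp immediately upstream of each gene (strand-aware, intervening genes
subtracted) and flags the gene when BOTH hold:

* ratio: upstream TPM >= 20% of the gene's own combined TPM, and
* breadth: >= 70% of the (effective) upstream region is covered.

Genes flagged in either the input or the IP sample are removed from that
IP-vs-input comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import pandas as pd

from .annotation import GeneModel, SanitizedAnnotation
from .intervals import IntervalSet, merge_intervals, subtract_intervals
from .quant import ReadAlignment, TpmTable

RATIO_MIN = 0.20
BREADTH_MIN = 0.70


@dataclass(frozen=True)
class UpstreamRegion:
    gene_id: str
    region: IntervalSet
    nominal_length: int = 2000

    @property
    def effective_length(self) -> int:
        return self.region.total_length


@dataclass(frozen=True)
class UpstreamScore:
    gene_id: str
    breadth: float
    upstream_tpm: float
    gene_tpm: float
    ratio: float
    flagged: bool
    evaluable: bool
    effective_length: int


def build_upstream_region(
    gene: GeneModel,
    ann: SanitizedAnnotation,
    flank: int = 2000,
    chrom_sizes: dict[str, int] | None = None,
) -> UpstreamRegion:
    """Strand-aware upstream flank minus every other gene's span.

    + strand gene [s,e) -> [s-flank, s) clipped at 0; - strand -> [e, e+flank)
    clipped at the chromosome end when known. bedtools `flank -l 2000 -r 0 -s`
    then `subtract` semantics.
    """
    s, e = gene.span
    if gene.strand == "+":
        lo, hi = max(0, s - flank), s
    else:
        lo, hi = e, e + flank
        if chrom_sizes and gene.chrom in chrom_sizes:
            hi = min(hi, chrom_sizes[gene.chrom])
    region = [(lo, hi)] if hi > lo else []
    other_spans = [g.span for g in ann.genes_on(gene.chrom)]
    region = subtract_intervals(merge_intervals(region), merge_intervals(other_spans))
    return UpstreamRegion(gene.gene_id, IntervalSet(gene.chrom, gene.strand, tuple(region)), flank)


def collect_intergenic_alignments(
    alignments: Iterable[ReadAlignment],
    ann: SanitizedAnnotation,
) -> Iterator[ReadAlignment]:
    """Alignments whose blocks touch no gene's exonic or intronic set."""
    for aln in alignments:
        if aln.unmapped or aln.secondary or aln.supplementary:
            continue
        hit = False
        for g in ann.genes_on(aln.chrom):
            if (
                ann.exonic[g.gene_id].overlap_length(aln.blocks) > 0
                or ann.intronic[g.gene_id].overlap_length(aln.blocks) > 0
            ):
                hit = True
                break
        if not hit:
            yield aln


def decide_flag(ratio: float, breadth: float, ratio_min: float = RATIO_MIN, breadth_min: float = BREADTH_MIN) -> bool:
    """Inclusive thresholds: 20% ratio or more AND 70% breadth or more."""
    return ratio >= ratio_min and breadth >= breadth_min


def score_upstream(
    region: UpstreamRegion,
    intergenic: Iterable[ReadAlignment],
    gene_tpm: float,
    rate_sum: float,
    strand_policy: str = "antisense_of_flank",
    ratio_min: float = RATIO_MIN,
    breadth_min: float = BREADTH_MIN,
) -> UpstreamScore:
    """Coverage breadth and TPM ratio of one upstream region.

    strand_policy mirrors `bedtools coverage -S -split` under a
    reverse-stranded library: 'antisense_of_flank' retains alignments on the
    strand opposite the flank's (i.e. sense transcription reads);
    'sense_of_flank' the same strand; 'unstranded' all. upstream_tpm uses
    the region's effective length and the same joint normalization
    denominator (rate_sum) as the sample's gene TPMs.
    """
    eff = region.effective_length
    if eff == 0 or gene_tpm <= 0:
        return UpstreamScore(region.gene_id, 0.0, 0.0, gene_tpm, 0.0, False, False, eff)

    flank_strand = region.region.strand
    retained_blocks: list[tuple[int, int]] = []
    count = 0
    for aln in intergenic:
        if aln.chrom != region.region.chrom:
            continue
        if strand_policy == "antisense_of_flank" and aln.strand == flank_strand:
            continue
        if strand_policy == "sense_of_flank" and aln.strand != flank_strand:
            continue
        if region.region.overlap_length(aln.blocks) > 0:
            count += 1
            retained_blocks.extend(aln.blocks)

    covered = region.region.overlap_length(retained_blocks)
    breadth = covered / eff
    upstream_rate = count / (eff / 1000.0)
    upstream_tpm = 1e6 * upstream_rate / rate_sum if rate_sum else 0.0
    ratio = upstream_tpm / gene_tpm
    return UpstreamScore(
        gene_id=region.gene_id,
        breadth=breadth,
        upstream_tpm=upstream_tpm,
        gene_tpm=gene_tpm,
        ratio=ratio,
        flagged=decide_flag(ratio, breadth, ratio_min, breadth_min),
        evaluable=True,
        effective_length=eff,
    )


def score_sample(
    alignments: Iterable[ReadAlignment],
    ann: SanitizedAnnotation,
    tpm: TpmTable,
    flank: int = 2000,
    strand_policy: str = "antisense_of_flank",
    ratio_min: float = RATIO_MIN,
    breadth_min: float = BREADTH_MIN,
    chrom_sizes: dict[str, int] | None = None,
) -> dict[str, UpstreamScore]:
    """Score every gene of one sample against its upstream flank."""
    intergenic = list(collect_intergenic_alignments(alignments, ann))
    scores: dict[str, UpstreamScore] = {}
    for gene_id in sorted(ann.genes):
        region = build_upstream_region(ann.genes[gene_id], ann, flank, chrom_sizes)
        scores[gene_id] = score_upstream(
            region,
            intergenic,
            gene_tpm=tpm.combined(gene_id),
            rate_sum=tpm.rate_sum,
            strand_policy=strand_policy,
            ratio_min=ratio_min,
            breadth_min=breadth_min,
        )
    return scores


def apply_filter(
    scores_input: dict[str, UpstreamScore],
    scores_ip: dict[str, UpstreamScore],
) -> set[str]:
    """Genes flagged in either condition are removed from that IP comparison."""
    if set(scores_input) != set(scores_ip):
        raise ValueError("input and IP score sets cover different gene universes")
    return {g for g, s in scores_input.items() if s.flagged} | {
        g for g, s in scores_ip.items() if s.flagged
    }


def scores_to_frame(scores: dict[str, UpstreamScore]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": s.gene_id,
            "effective_length": s.effective_length,
            "breadth": s.breadth,
            "upstream_tpm": s.upstream_tpm,
            "gene_tpm": s.gene_tpm,
            "ratio": s.ratio,
            "flagged": s.flagged,
            "evaluable": s.evaluable,
        }
        for _, s in sorted(scores.items())
    ]
    return pd.DataFrame(rows)
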