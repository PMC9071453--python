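"""Synthetic annotations, alignments, tail tables, and differential tables.

The generator plants every pathology the pipeline exists to handle —
overlapping gene pairs (same- and opposite-strand), readthrough-tagged
transcripts spanning two genes, intronless genes and processed
pseudogenes, stranded short reads with exonic/intronic/upstream-readthrough
components, and long reads with per-condition poly(A) tail distributions,
intron retention, QC-tag mixtures, and MAPQ-0/supplementary/mitochondrial
contaminants — and records complete per-gene and per-read ground truth so
recovery can be asserted.

Alignments are synthesized directly (blocks, flags, MAPQ, strand); there is
no sequence-level simulation, because the pipeline consumes alignments.
Identical (seed, config) gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import (
    GeneModel,
    RawAnnotation,
    READTHROUGH_TAG,
    TranscriptModel,
    write_gtf,
)
from .intervals import merge_intervals, intersect_intervals, overlap_length, subtract_intervals
from .quant import ReadAlignment


@dataclass(frozen=True)
class TailCondition:
    """Per-condition poly(A) tail distribution: truncated Normal(mode, sd).

    ip=True applies the binding floor (a poly(A) binding protein cannot hold
    a tail shorter than its footprint, so IP-like samples carry essentially
    no tails below ~15 nt); total-fraction conditions truncate at 0 only.
    """

    mode: float
    sd: float = 40.0
    ip: bool = True


@dataclass
class SimulationConfig:
    seed: int = 0
    # annotation geometry
    n_chromosomes: int = 2
    n_genes: int = 50
    overlap_pairs: int = 5
    readthrough_genes: int = 2
    intronless_fraction: float = 0.10
    pseudogene_fraction: float = 0.06
    exon_length_range: tuple[int, int] = (150, 400)
    intron_length_range: tuple[int, int] = (200, 1200)
    max_exons: int = 10
    intergenic_gap: int = 3000  # keeps 2 kb upstream flanks clean of neighbors
    overlap_bases: int = 400  # planted shared span per overlapping pair
    # short-read expression
    expression_mean_log: float = 5.0  # log fragments per gene (log-normal)
    expression_sd_log: float = 0.6
    unspliced_beta: tuple[float, float] | None = (2.0, 5.0)
    unspliced_fraction: float | None = None  # fixed value overrides the Beta draw
    read_length: int = 75
    # upstream-readthrough planting
    dog_genes: int = 5
    upstream_ratio: float = 0.4
    upstream_breadth: float = 1.0
    # long reads
    conditions: dict[str, TailCondition] = field(
        default_factory=lambda: {
            "nuclear_pabpn_ip": TailCondition(mode=230.0, sd=40.0, ip=True),
            "cytoplasm_pabpc_ip": TailCondition(mode=80.0, sd=40.0, ip=True),
        }
    )
    long_reads_per_gene: int = 200
    retention_prob: float = 0.2
    qc_reject_fraction: float = 0.10
    mapq0_fraction: float = 0.05
    supplementary_fraction: float = 0.03
    mito_fraction: float = 0.05
    tail_floor: float = 15.0
    # differential table
    n_diff_genes: int = 1000
    diff_enriched_fraction: float = 0.25
    diff_depleted_fraction: float = 0.25

    def validate(self) -> None:
        for name in (
            "intronless_fraction",
            "pseudogene_fraction",
            "qc_reject_fraction",
            "mapq0_fraction",
            "supplementary_fraction",
            "mito_fraction",
            "upstream_breadth",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.unspliced_fraction is not None and not 0.0 <= self.unspliced_fraction <= 1.0:
            raise ValueError("unspliced_fraction outside [0, 1]")


@dataclass
class SimulatedAnnotation:
    annotation: RawAnnotation
    chrom_sizes: dict[str, int]
    gene_truth: pd.DataFrame  # expression, unspliced_fraction, dog flag, biotype, overlap role
    planted_shared: dict[str, list[tuple[int, int]]]  # chrom -> intended shared intervals
    readthrough_transcripts: list[str]


def _make_gene(
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    strand: str,
    start: int,
    n_exons: int,
    cfg: SimulationConfig,
    biotype: str,
) -> GeneModel:
    exons = []
    pos = start
    for i in range(n_exons):
        elen = int(rng.integers(*cfg.exon_length_range))
        exons.append((pos, pos + elen))
        pos += elen
        if i < n_exons - 1:
            pos += int(rng.integers(*cfg.intron_length_range))
    t = TranscriptModel(f"{gene_id}.t1", tuple(exons))
    return GeneModel(gene_id, gene_id.replace("GSYN", "SYN"), biotype, chrom, strand, (t,))


def simulate_annotation(cfg: SimulationConfig) -> SimulatedAnnotation:
    """Place genes along synthetic chromosomes with planted pathologies.

    Genes sit in a row separated by `intergenic_gap`, except planted
    overlap-pair members which invade the previous gene by `overlap_bases`.
    Readthrough transcripts are extra transcripts (tagged) bridging a gene
    and its right neighbor. Errors out if the requested structure cannot be
    packed (more special genes than genes).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    n_special = 2 * cfg.overlap_pairs + 2 * cfg.readthrough_genes + cfg.dog_genes
    if n_special > n:
        raise ValueError(
            f"cannot pack {cfg.overlap_pairs} overlap pairs, {cfg.readthrough_genes} "
            f"readthrough genes and {cfg.dog_genes} DoG genes into {n} genes; "
            "raise n_genes or reduce the planted counts"
        )

    # role assignment: overlap pairs use consecutive indices at the front,
    # then readthrough donors (with their right neighbor reserved), then DoG.
    roles = ["plain"] * n
    idx = 0
    pair_second: list[int] = []
    for _ in range(cfg.overlap_pairs):
        roles[idx], roles[idx + 1] = "overlap_a", "overlap_b"
        pair_second.append(idx + 1)
        idx += 2
    for _ in range(cfg.readthrough_genes):
        roles[idx], roles[idx + 1] = "readthrough_donor", "readthrough_acceptor"
        idx += 2
    for _ in range(cfg.dog_genes):
        roles[idx] = "dog"
        idx += 1

    # shuffle non-pair structure by chromosome assignment only; linear layout
    # keeps geometry auditable and deterministic.
    ann: RawAnnotation = {}
    chrom_pos = {f"chr{i + 1}": cfg.intergenic_gap for i in range(cfg.n_chromosomes)}
    chroms = list(chrom_pos)
    planted_shared: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    readthrough_tx: list[str] = []
    rows = []
    prev_gene: GeneModel | None = None
    prev_chrom_i = -1
    for i in range(n):
        chrom = chroms[(i * cfg.n_chromosomes) // n]
        role = roles[i]
        biotype = "protein_coding"
        n_exons = int(rng.integers(2, cfg.max_exons + 1))
        if role == "plain":
            u = rng.random()
            if u < cfg.pseudogene_fraction:
                biotype, n_exons = "processed_pseudogene", 1
            elif u < cfg.pseudogene_fraction + cfg.intronless_fraction:
                n_exons = 1
        strand = "+" if rng.random() < 0.5 else "-"
        new_chrom = chroms.index(chrom) != prev_chrom_i
        start = chrom_pos[chrom]
        if role == "overlap_b" and not new_chrom and prev_gene is not None:
            start = prev_gene.span[1] - cfg.overlap_bases
            # alternate same- and opposite-strand overlap pairs
            strand = prev_gene.strand if (i // 2) % 2 == 0 else ("-" if prev_gene.strand == "+" else "+")
        gene = _make_gene(rng, f"GSYN{i:04d}", chrom, strand, start, n_exons, cfg, biotype)
        if role == "overlap_b" and not new_chrom and prev_gene is not None:
            shared = intersect_intervals([prev_gene.span], [gene.span])
            planted_shared[chrom].extend(shared)
        ann[gene.gene_id] = gene
        chrom_pos[chrom] = gene.span[1] + cfg.intergenic_gap
        expr = float(np.exp(rng.normal(cfg.expression_mean_log, cfg.expression_sd_log)))
        if cfg.unspliced_fraction is not None:
            uf = cfg.unspliced_fraction
        elif cfg.unspliced_beta is not None and n_exons > 1:
            uf = float(rng.beta(*cfg.unspliced_beta))
        else:
            uf = 0.0
        if n_exons == 1:
            uf = 0.0
        rows.append(
            {
                "gene_id": gene.gene_id,
                "chrom": chrom,
                "strand": strand,
                "biotype": biotype,
                "n_exons": n_exons,
                "role": role,
                "expression": expr,
                "unspliced_fraction": uf,
                "dog": role == "dog",
            }
        )
        prev_gene, prev_chrom_i = gene, chroms.index(chrom)

    # readthrough transcripts: bridge donor -> acceptor with one exon in each
    gene_list = list(ann.values())
    for i, role in enumerate(roles):
        if role != "readthrough_donor":
            continue
        donor, acceptor = gene_list[i], gene_list[i + 1]
        if donor.chrom != acceptor.chrom:
            continue
        tid = f"{donor.gene_id}.rt"
        exons = (donor.transcripts[0].exons[0], acceptor.transcripts[0].exons[-1])
        rt = TranscriptModel(tid, exons, frozenset({READTHROUGH_TAG}))
        ann[donor.gene_id] = replace(donor, transcripts=donor.transcripts + (rt,))
        readthrough_tx.append(tid)

    chrom_sizes = {c: pos + cfg.intergenic_gap for c, pos in chrom_pos.items()}
    chrom_sizes["chrM"] = 16569
    return SimulatedAnnotation(
        annotation=ann,
        chrom_sizes=chrom_sizes,
        gene_truth=pd.DataFrame(rows).set_index("gene_id"),
        planted_shared={c: merge_intervals(v) for c, v in planted_shared.items() if v},
        readthrough_transcripts=readthrough_tx,
    )


def _mature_blocks(exons: Sequence[tuple[int, int]], mat_start: int, length: int) -> list[tuple[int, int]]:
    """Map a [mat_start, mat_start+length) slice of the mature transcript
    back to genomic blocks across the exon chain."""
    blocks = []
    offset = 0
    remaining = length
    for s, e in exons:
        w = e - s
        if mat_start < offset + w and remaining > 0:
            lo = s + max(0, mat_start - offset)
            hi = min(e, lo + remaining)
            blocks.append((lo, hi))
            remaining -= hi - lo
        offset += w
        if remaining <= 0:
            break
    return blocks


def _read_strand(gene_strand: str) -> str:
    # reverse-stranded (dUTP) single-end convention: alignment antisense to gene
    return "-" if gene_strand == "+" else "+"


def simulate_short_read_alignments(
    cfg: SimulationConfig,
    sim: SimulatedAnnotation,
) -> tuple[list[ReadAlignment], pd.DataFrame]:
    """Stranded short reads: spliced (exonic), unspliced (pre-mRNA), and
    planted upstream-readthrough coverage for DoG genes.

    Per-gene fragment counts follow the planted expression; each fragment is
    spliced with probability 1 - unspliced_fraction (drawn uniformly on the
    mature transcript) and otherwise uniform on the unspliced pre-mRNA.
    DoG genes receive upstream reads tiled over `upstream_breadth` of the
    2 kb flank, in number calibrated so upstream TPM / gene TPM reaches
    `upstream_ratio` under the pipeline's length normalization.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    L = cfg.read_length
    reads: list[ReadAlignment] = []
    truth_rows = []

    def emit(read_id: str, gene_id: str, chrom: str, strand: str, blocks, compartment: str):
        reads.append(ReadAlignment(read_id, chrom, strand, tuple(blocks), mapq=255))
        truth_rows.append(
            {
                "read_id": read_id,
                "gene_id": gene_id,
                "compartment": compartment,
                "start": blocks[0][0],
            }
        )

    k = 0
    for gene_id, g in sim.annotation.items():
        info = sim.gene_truth.loc[gene_id]
        n_frags = max(1, int(round(info["expression"])))
        uf = float(info["unspliced_fraction"])
        primary = next(t for t in g.transcripts if not t.is_readthrough)
        exons = list(primary.exons)
        exon_union = merge_intervals(exons)
        mature_len = sum(e - s for s, e in exons)
        span_s, span_e = g.span
        strand = _read_strand(g.strand)
        n_exonic = n_intronic = 0
        for _ in range(n_frags):
            unspliced = rng.random() < uf
            if unspliced and span_e - span_s > L:
                start = int(rng.integers(span_s, span_e - L))
                blocks = [(start, start + L)]
            else:
                unspliced = False
                if mature_len <= L:
                    blocks = exons
                else:
                    ms = int(rng.integers(0, mature_len - L))
                    blocks = _mature_blocks(exons, ms, L)
            ex_ov = overlap_length(exon_union, blocks)
            tot = sum(e - s for s, e in blocks)
            compartment = "exonic" if ex_ov >= tot - ex_ov else "intronic"
            if compartment == "exonic":
                n_exonic += 1
            else:
                n_intronic += 1
            emit(f"sr{k:07d}", gene_id, g.chrom, strand, blocks, compartment)
            k += 1

        if info["dog"]:
            # calibrate upstream read count against this gene's length-normalized rate
            ex_len = sum(e - s for s, e in exon_union)
            intr = subtract_intervals([g.span], exon_union)
            in_len = sum(e - s for s, e in intr)
            rate = n_exonic / (ex_len / 1000.0)
            if in_len:
                rate += n_intronic / (in_len / 1000.0)
            flank_len = 2000
            covered = int(cfg.upstream_breadth * flank_len)
            n_up = int(np.ceil(cfg.upstream_ratio * rate * flank_len / 1000.0))
            n_up = max(n_up, int(np.ceil(covered / (L - 1))) + 1)
            if g.strand == "+":
                flank_lo = span_s - flank_len
            else:
                flank_lo = span_e
            # tile n_up reads across the covered prefix of the flank
            step = (covered - L) / (n_up - 1) if n_up > 1 else 0.0
            for j in range(n_up):
                start = flank_lo + int(round(j * step))
                emit(f"sr{k:07d}", gene_id, g.chrom, strand, [(start, start + L)], "upstream")
                k += 1

    truth = pd.DataFrame(truth_rows).set_index("read_id")
    return reads, truth


def simulate_long_reads(
    cfg: SimulationConfig,
    sim: SimulatedAnnotation,
    condition: str,
) -> tuple[list[ReadAlignment], pd.DataFrame, pd.DataFrame]:
    """Long spliced reads plus the tail-estimate table for one condition.

    Returns (alignments, tail_table, truth). Truth labels each read's gene,
    retained-intron count, contaminant category (clean / mapq0 /
    supplementary / mito), QC tag, and planted tail length.
    """
    cond = cfg.conditions[condition]
    cond_i = sorted(cfg.conditions).index(condition)
    rng = np.random.default_rng(cfg.seed + 101 + cond_i)
    floor = cfg.tail_floor if cond.ip else 0.0
    reads: list[ReadAlignment] = []
    tail_rows = []
    truth_rows = []
    reject_cycle = ["READ_FAILED_LOAD", "SUFFCLIP", "NOREGION"]
    k = 0
    for gene_id, g in sim.annotation.items():
        primary = next(t for t in g.transcripts if not t.is_readthrough)
        exons = list(primary.exons)
        n_introns = len(exons) - 1
        for _ in range(cfg.long_reads_per_gene):
            read_id = f"lr_{condition}_{k:07d}"
            k += 1
            # tail: truncated Normal via redraw
            tail = float(rng.normal(cond.mode, cond.sd))
            while tail < floor or tail < 0:
                tail = float(rng.normal(cond.mode, cond.sd))
            tail = round(tail, 2)
            retained = [j for j in range(n_introns) if rng.random() < cfg.retention_prob]
            blocks = list(exons)
            for j in retained:
                # bridge the intron: merge exon j and j+1 into one block
                blocks[j] = (blocks[j][0], exons[j + 1][1])
            blocks = merge_intervals(blocks)
            u = rng.random()
            if u < cfg.mito_fraction:
                category = "mito"
                aln = ReadAlignment(read_id, "chrM", "+", ((100, 1100),), mapq=60)
            elif u < cfg.mito_fraction + cfg.mapq0_fraction:
                category = "mapq0"
                aln = ReadAlignment(read_id, g.chrom, g.strand, tuple(blocks), mapq=0)
            elif u < cfg.mito_fraction + cfg.mapq0_fraction + cfg.supplementary_fraction:
                category = "supplementary"
                aln = ReadAlignment(read_id, g.chrom, g.strand, tuple(blocks), mapq=60, supplementary=True)
            else:
                category = "clean"
                aln = ReadAlignment(read_id, g.chrom, g.strand, tuple(blocks), mapq=60)
            if rng.random() < cfg.qc_reject_fraction:
                qc_tag = reject_cycle[int(rng.integers(0, 3))]
            else:
                qc_tag = "PASS"
            reads.append(aln)
            tail_rows.append({"readname": read_id, "qc_tag": qc_tag, "polya_length": tail})
            truth_rows.append(
                {
                    "read_id": read_id,
                    "condition": condition,
                    "gene_id": gene_id if category != "mito" else "",
                    "retained_introns": len(retained) if category == "clean" else 0,
                    "category": category,
                    "qc_tag": qc_tag,
                    "tail_length": tail,
                }
            )
    return reads, pd.DataFrame(tail_rows), pd.DataFrame(truth_rows).set_index("read_id")


def simulate_differential_table(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Differential table with planted enriched/depleted/ns labels.

    ns rows include the hard cases on purpose: log2FC exactly at +/-0.5
    (strict inequality), sub-threshold baseMean, missing padj, and
    non-significant padj.
    """
    rng = np.random.default_rng(cfg.seed + 201)
    n = cfg.n_diff_genes
    n_enr = int(n * cfg.diff_enriched_fraction)
    n_dep = int(n * cfg.diff_depleted_fraction)
    rows = []
    for i in range(n):
        gene_id = f"GDIFF{i:05d}"
        if i < n_enr:
            label = "enriched"
            base = float(rng.uniform(51, 2000))
            lfc = float(rng.uniform(0.6, 4.0))
            padj = float(rng.uniform(1e-10, 0.01))
        elif i < n_enr + n_dep:
            label = "depleted"
            base = float(rng.uniform(51, 2000))
            lfc = -float(rng.uniform(0.6, 4.0))
            padj = float(rng.uniform(1e-10, 0.01))
        else:
            label = "ns"
            kind = i % 4
            if kind == 0:  # boundary log2FC, otherwise significant-looking
                base = float(rng.uniform(51, 2000))
                lfc = 0.5 if i % 8 == 0 else -0.5
                padj = float(rng.uniform(1e-10, 0.01))
            elif kind == 1:  # baseMean at or below the gate
                base = float(rng.uniform(1, 50))
                lfc = float(rng.uniform(-3, 3))
                padj = float(rng.uniform(1e-10, 0.01))
            elif kind == 2:  # missing padj (independent filtering)
                base = float(rng.uniform(51, 2000))
                lfc = float(rng.uniform(-3, 3))
                padj = float("nan")
            else:  # non-significant padj
                base = float(rng.uniform(51, 2000))
                lfc = float(rng.uniform(-3, 3))
                padj = float(rng.uniform(0.02, 1.0))
        rows.append(
            {
                "gene_id": gene_id,
                "baseMean": round(base, 3),
                "log2FoldChange": round(lfc, 4) if lfc not in (0.5, -0.5) else lfc,
                "padj": padj,
                "label": label,
            }
        )
    df = pd.DataFrame(rows)
    truth = df[["gene_id", "label"]].set_index("gene_id")
    return df.drop(columns="label"), truth


# ---------------------------------------------------------------------------
# serialization


def write_sam(
    alignments: Sequence[ReadAlignment],
    chrom_sizes: dict[str, int],
    path: str,
) -> None:
    """Deterministic coordinate-sorted SAM (text) for the given alignments."""
    chroms = list(chrom_sizes)
    order = {c: i for i, c in enumerate(chroms)}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for c in chroms:
            fh.write(f"@SQ\tSN:{c}\tLN:{chrom_sizes[c]}\n")
        for aln in sorted(alignments, key=lambda a: (order[a.chrom], a.blocks[0][0], a.read_id)):
            flag = 0
            if aln.strand == "-":
                flag |= 16
            if aln.secondary:
                flag |= 256
            if aln.supplementary:
                flag |= 2048
            cigar = []
            prev_end = None
            for s, e in aln.blocks:
                if prev_end is not None:
                    cigar.append(f"{s - prev_end}N")
                cigar.append(f"{e - s}M")
                prev_end = e
            seq_len = sum(e - s for s, e in aln.blocks)
            fh.write(
                f"{aln.read_id}\t{flag}\t{aln.chrom}\t{aln.blocks[0][0] + 1}\t{aln.mapq}\t"
                f"{''.join(cigar)}\t*\t0\t0\t{'A' * seq_len}\t*\n"
            )


def to_indexed_bam(sam_path: str, bam_path: str) -> str:
    """Convert a SAM to a coordinate-sorted indexed BAM (pysam)."""
    import pysam

    pysam.sort("-o", bam_path, sam_path)
    pysam.index(bam_path)
    return bam_path


def run_all(cfg: SimulationConfig, outdir: str) -> dict[str, str]:
    """Generate every synthetic artifact under `outdir`; returns path map."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}
    sim = simulate_annotation(cfg)
    paths["gtf"] = os.path.join(outdir, "annotation.gtf")
    write_gtf(sim.annotation, paths["gtf"])
    paths["gene_truth"] = os.path.join(outdir, "gene_truth.tsv")
    sim.gene_truth.to_csv(paths["gene_truth"], sep="\t")

    reads, truth = simulate_short_read_alignments(cfg, sim)
    paths["short_sam"] = os.path.join(outdir, "short_reads.sam")
    write_sam(reads, sim.chrom_sizes, paths["short_sam"])
    paths["short_truth"] = os.path.join(outdir, "short_read_truth.tsv")
    truth.to_csv(paths["short_truth"], sep="\t")

    for cond in sorted(cfg.conditions):
        lreads, tails, ltruth = simulate_long_reads(cfg, sim, cond)
        paths[f"long_sam_{cond}"] = os.path.join(outdir, f"long_reads_{cond}.sam")
        write_sam(lreads, sim.chrom_sizes, paths[f"long_sam_{cond}"])
        paths[f"tails_{cond}"] = os.path.join(outdir, f"tails_{cond}.tsv")
        tails.to_csv(paths[f"tails_{cond}"], sep="\t", index=False)
        paths[f"long_truth_{cond}"] = os.path.join(outdir, f"long_truth_{cond}.tsv")
        ltruth.to_csv(paths[f"long_truth_{cond}"], sep="\t")

    diff, dtruth = simulate_differential_table(cfg)
    paths["differential"] = os.path.join(outdir, "differential.tsv")
    diff.to_csv(paths["differential"], sep="\t", index=False)
    paths["diff_truth"] = os.path.join(outdir, "diff_truth.tsv")
    dtruth.to_csv(paths["diff_truth"], sep="\t")
    return paths
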