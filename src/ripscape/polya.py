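"""Long-read (nanopore direct-RNA) poly(A) tail statistics.

The pipeline consumes spliced long-read alignments and a per-read tail
table from an external raw-signal tail estimator (columns readname, qc_tag,
polya_length). Alignments are filtered `samtools view -bq 1 -F 2048`-style
(MAPQ 0 marks multi-mappers; supplementary records dropped), assigned to
the sanitized gene with the largest block overlap, purged of mitochondrial
reads, flagged for retained introns, and joined with QC-passing tail
estimates to give per-gene, per-condition tail-length statistics and the
cross-condition change in median tail length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import pandas as pd

from .annotation import SanitizedAnnotation
from .intervals import merge_intervals, overlap_length
from .quant import ReadAlignment

REJECT_TAGS = frozenset({"READ_FAILED_LOAD", "SUFFCLIP", "NOREGION"})
MITO_CHROMS = frozenset({"chrM", "MT"})


@dataclass(frozen=True)
class LongReadRecord:
    read_id: str
    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    mapq: int
    gene_id: str | None = None
    retained_introns: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(merge_intervals(self.blocks)))


def filter_long_alignments(alignments: Iterable[ReadAlignment]) -> Iterator[LongReadRecord]:
    """Keep primary alignments with MAPQ >= 1; drop MAPQ-0 (multi-mapping),
    supplementary, secondary, and unmapped records."""
    for aln in alignments:
        if aln.unmapped or aln.secondary or aln.supplementary or aln.mapq < 1:
            continue
        yield LongReadRecord(aln.read_id, aln.chrom, aln.strand, aln.blocks, aln.mapq)


def assign_long_read(
    rec: LongReadRecord,
    ann: SanitizedAnnotation,
    min_overlap: int = 20,
) -> LongReadRecord:
    """Largest-overlap gene assignment (featureCounts -L long-read mode)."""
    best_gene: str | None = None
    best_ov = 0
    blocks = list(rec.blocks)
    for g in ann.genes_on(rec.chrom):
        ov = ann.exonic[g.gene_id].overlap_length(blocks) + ann.intronic[g.gene_id].overlap_length(blocks)
        if ov >= min_overlap and ov > best_ov:
            best_gene, best_ov = g.gene_id, ov
    return replace(rec, gene_id=best_gene)


def remove_mitochondrial(
    records: Iterable[LongReadRecord],
    mito_chroms: frozenset[str] = MITO_CHROMS,
) -> tuple[list[LongReadRecord], int]:
    """Drop reads mapped to the mitochondrial genome; return (kept, n_removed)."""
    kept, removed = [], 0
    for r in records:
        if r.chrom in mito_chroms:
            removed += 1
        else:
            kept.append(r)
    return kept, removed


def flag_intron_retention(
    rec: LongReadRecord,
    ann: SanitizedAnnotation,
    intron_min_overlap: int = 20,
) -> LongReadRecord:
    """Count distinct intronic intervals of the assigned gene covered by
    >= intron_min_overlap read bases; >= 1 marks the read intron-containing."""
    if rec.gene_id is None:
        return rec
    blocks = list(rec.blocks)
    n = 0
    for iv in ann.intronic[rec.gene_id]:
        if overlap_length([iv], blocks) >= intron_min_overlap:
            n += 1
    return replace(rec, retained_introns=n)


def apply_polya_qc(estimates: pd.DataFrame, reject_tags: frozenset[str] = REJECT_TAGS) -> pd.DataFrame:
    """Drop tail estimates whose QC tag marks an unusable signal segment."""
    return estimates.loc[~estimates["qc_tag"].isin(reject_tags)].reset_index(drop=True)


def load_tail_table(path: str) -> pd.DataFrame:
    """Tail-estimation output: readname, qc_tag, polya_length."""
    df = pd.read_csv(path, sep="\t")
    required = {"readname", "qc_tag", "polya_length"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


@dataclass
class JoinLog:
    no_alignment: int = 0
    no_estimate: int = 0


def join_reads_and_tails(
    records: Iterable[LongReadRecord],
    estimates: pd.DataFrame,
    log: JoinLog | None = None,
) -> pd.DataFrame:
    """Per-read table (read_id, gene_id, retained_introns, tail_length).

    Reads lacking either a surviving alignment or a QC-passing estimate are
    dropped and counted in the log.
    """
    recs = [r for r in records if r.gene_id is not None]
    rec_df = pd.DataFrame(
        {
            "read_id": [r.read_id for r in recs],
            "gene_id": [r.gene_id for r in recs],
            "retained_introns": [r.retained_introns for r in recs],
        }
    )
    est = estimates.rename(columns={"readname": "read_id", "polya_length": "tail_length"})
    joined = rec_df.merge(est[["read_id", "tail_length"]], on="read_id", how="inner")
    if log is not None:
        log.no_estimate = len(rec_df) - len(joined)
        log.no_alignment = len(est) - len(joined)
    return joined


def gene_tail_statistics(
    per_read: pd.DataFrame,
    condition: str,
    min_reads: int = 10,
    stratify_introns: bool = False,
) -> pd.DataFrame:
    """Per-gene n/median/max tail length; genes under min_reads are omitted.

    Median for even n is the arithmetic midpoint of the two central values.
    With stratify_introns=True, statistics are additionally computed per
    (gene, intron-containing vs fully-spliced) stratum.
    """
    df = per_read.copy()
    keys = ["gene_id"]
    if stratify_introns:
        df["intron_containing"] = df["retained_introns"] >= 1
        keys.append("intron_containing")
    stats = (
        df.groupby(keys)["tail_length"]
        .agg(n_reads="count", median_tail="median", max_tail="max")
        .reset_index()
    )
    stats = stats.loc[stats["n_reads"] >= min_reads].reset_index(drop=True)
    stats.insert(1, "condition", condition)
    return stats


def tail_length_change(
    stats_a: pd.DataFrame,
    stats_b: pd.DataFrame,
    min_reads_each: int = 35,
) -> pd.DataFrame:
    """Per-gene delta of median tail length (B - A).

    Only genes with >= min_reads_each reads in BOTH conditions qualify;
    negative delta means the tail is shorter in condition B.
    """
    a = stats_a.loc[stats_a["n_reads"] >= min_reads_each, ["gene_id", "median_tail", "n_reads"]]
    b = stats_b.loc[stats_b["n_reads"] >= min_reads_each, ["gene_id", "median_tail", "n_reads"]]
    m = a.merge(b, on="gene_id", suffixes=("_a", "_b"))
    m["delta_median"] = m["median_tail_b"] - m["median_tail_a"]
    return m


def process_condition(
    alignments: Iterable[ReadAlignment],
    tail_table: pd.DataFrame,
    ann: SanitizedAnnotation,
    condition: str,
    min_overlap: int = 20,
    intron_min_overlap: int = 20,
    min_reads: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Full long-read pipeline for one condition.

    Returns (per_read_table, per_gene_stats, log_counts).
    """
    records = list(filter_long_alignments(alignments))
    records = [assign_long_read(r, ann, min_overlap) for r in records]
    records, n_mito = remove_mitochondrial(records)
    records = [flag_intron_retention(r, ann, intron_min_overlap) for r in records]
    estimates = apply_polya_qc(tail_table)
    log = JoinLog()
    per_read = join_reads_and_tails(records, estimates, log)
    stats = gene_tail_statistics(per_read, condition, min_reads=min_reads)
    counts = {
        "mitochondrial_removed": n_mito,
        "qc_rejected": len(tail_table) - len(estimates),
        "join_no_estimate": log.no_estimate,
        "join_no_alignment": log.no_alignment,
        "surviving_reads": len(per_read),
    }
    return per_read, stats, counts
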