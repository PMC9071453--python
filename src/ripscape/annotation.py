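"""GTF annotation loading and sanitization.

Overlapping gene annotations defeat unambiguous read assignment: a read at
a base claimed by two genes either gets thrown away or assigned by an
arbitrary precedence rule. The sanitizer makes assignment well-defined by
(1) dropping transcripts tagged ``readthrough_transcript`` (a readthrough
event spanning two genes should not mask both), (2) removing every base of
genomic space claimed by two or more gene spans, and (3) deriving disjoint
per-gene exonic and intronic interval sets from what survives.

Coordinates are GTF 1-based closed on disk and 0-based half-open in memory;
the conversion happens only at load/write time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from .intervals import IntervalSet, merge_intervals, multicov_regions, subtract_intervals

READTHROUGH_TAG = "readthrough_transcript"

_ATTR_RE = re.compile(r'(\S+)\s+"([^"]*)"\s*;')


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class TranscriptModel:
    transcript_id: str
    exons: tuple[tuple[int, int], ...]
    tags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(merge_intervals(self.exons)))

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def is_readthrough(self) -> bool:
        return READTHROUGH_TAG in self.tags


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    symbol: str
    biotype: str
    chrom: str
    strand: str
    transcripts: tuple[TranscriptModel, ...]

    @property
    def span(self) -> tuple[int, int]:
        """Hull of all transcript spans."""
        starts, ends = zip(*(t.span for t in self.transcripts))
        return (min(starts), max(ends))

    @property
    def span_length(self) -> int:
        s, e = self.span
        return e - s

    def exon_union(self) -> list[tuple[int, int]]:
        return merge_intervals(iv for t in self.transcripts for iv in t.exons)


RawAnnotation = dict[str, GeneModel]


def parse_gtf_attributes(attr_field: str) -> dict[str, list[str]]:
    attrs: dict[str, list[str]] = {}
    for key, value in _ATTR_RE.findall(attr_field):
        attrs.setdefault(key, []).append(value)
    return attrs


def load_annotation(path: str) -> RawAnnotation:
    """Parse a gencode-dialect GTF into gene models.

    Only ``exon`` features are required: transcript structure is rebuilt from
    them (gene/transcript lines, when present, contribute nothing beyond what
    the exons imply, and genes with zero exons are rejected by construction).

    Raises AnnotationError naming the offending line for malformed rows,
    missing gene_id, or inconsistent strand within a gene.
    """
    exons: dict[str, dict[str, list[tuple[int, int]]]] = {}
    meta: dict[str, dict[str, str]] = {}
    tx_tags: dict[str, set[str]] = {}
    tx_gene: dict[str, str] = {}
    gene_order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(f"line {lineno}: expected 9 tab-separated columns, got {len(fields)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_field = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise AnnotationError(f"line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}") from None
            if start < 1 or end < start:
                raise AnnotationError(f"line {lineno}: invalid coordinate range {start}-{end}")
            if strand not in "+-":
                raise AnnotationError(f"line {lineno}: strand must be + or -, got {strand!r}")
            attrs = parse_gtf_attributes(attr_field)
            if "gene_id" not in attrs:
                raise AnnotationError(f"line {lineno}: feature has no gene_id attribute")
            gene_id = attrs["gene_id"][0]

            if gene_id not in meta:
                meta[gene_id] = {
                    "symbol": attrs.get("gene_name", [gene_id])[0],
                    "biotype": attrs.get("gene_type", ["unknown"])[0],
                    "chrom": chrom,
                    "strand": strand,
                }
                gene_order.append(gene_id)
            else:
                m = meta[gene_id]
                if m["chrom"] != chrom:
                    raise AnnotationError(f"line {lineno}: gene {gene_id} spans chromosomes {m['chrom']} and {chrom}")
                if m["strand"] != strand:
                    raise AnnotationError(f"line {lineno}: gene {gene_id} has features on both strands")
                if m["biotype"] == "unknown" and "gene_type" in attrs:
                    m["biotype"] = attrs["gene_type"][0]
                if m["symbol"] == gene_id and "gene_name" in attrs:
                    m["symbol"] = attrs["gene_name"][0]

            if feature in ("transcript", "exon"):
                tid = attrs.get("transcript_id", [None])[0]
                if tid is None:
                    raise AnnotationError(f"line {lineno}: {feature} feature has no transcript_id attribute")
                tx_gene[tid] = gene_id
                tx_tags.setdefault(tid, set()).update(attrs.get("tag", []))
                if feature == "exon":
                    # GTF 1-based closed -> 0-based half-open
                    exons.setdefault(gene_id, {}).setdefault(tid, []).append((start - 1, end))

    ann: RawAnnotation = {}
    for gene_id in gene_order:
        if gene_id not in exons:
            continue  # zero-exon gene: rejected
        m = meta[gene_id]
        transcripts = tuple(
            TranscriptModel(tid, tuple(ivs), frozenset(tx_tags.get(tid, ())))
            for tid, ivs in exons[gene_id].items()
        )
        ann[gene_id] = GeneModel(gene_id, m["symbol"], m["biotype"], m["chrom"], m["strand"], transcripts)
    return ann


def write_gtf(ann: Mapping[str, GeneModel], path: str) -> None:
    """Write gene/transcript/exon features, converting back to 1-based closed."""
    with open(path, "w") as fh:
        for g in ann.values():
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.symbol}"; gene_type "{g.biotype}";'
            s, e = g.span
            fh.write(f"{g.chrom}\tripscape\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n")
            for t in g.transcripts:
                tattrs = attrs + f' transcript_id "{t.transcript_id}";'
                for tag in sorted(t.tags):
                    tattrs += f' tag "{tag}";'
                ts, te = t.span
                fh.write(f"{g.chrom}\tripscape\ttranscript\t{ts + 1}\t{te}\t.\t{g.strand}\t.\t{tattrs}\n")
                for xs, xe in t.exons:
                    fh.write(f"{g.chrom}\tripscape\texon\t{xs + 1}\t{xe}\t.\t{g.strand}\t.\t{tattrs}\n")


@dataclass
class MergeReport:
    added: list[str] = field(default_factory=list)
    conflicts: list[str] = field(default_factory=list)


def merge_supplemental_genes(
    primary: RawAnnotation,
    supplement: RawAnnotation,
    key_on_symbol: bool = False,
) -> tuple[RawAnnotation, MergeReport]:
    """Add supplemental genes absent from the primary annotation.

    Emulates reconciling a second annotation source (genes present in NCBI
    but missing from gencode): supplemental genes with a new gene_id (and,
    optionally, a new symbol) are added verbatim; id collisions defer to the
    primary and are logged as conflicts when coordinates differ.
    """
    merged = dict(primary)
    report = MergeReport()
    primary_symbols = {g.symbol for g in primary.values()} if key_on_symbol else set()
    for gene_id, gene in supplement.items():
        if gene_id in merged:
            if merged[gene_id].span != gene.span or merged[gene_id].chrom != gene.chrom:
                report.conflicts.append(gene_id)
            continue
        if key_on_symbol and gene.symbol in primary_symbols:
            continue
        merged[gene_id] = gene
        report.added.append(gene_id)
    return merged, report


def drop_readthrough_transcripts(ann: RawAnnotation) -> tuple[RawAnnotation, list[str], list[str]]:
    """Remove transcripts tagged readthrough_transcript.

    Returns (annotation, dropped_transcript_ids, dropped_gene_ids); genes
    whose every transcript carried the tag are dropped entirely and gene
    spans are implicitly recomputed from the surviving transcripts.
    """
    out: RawAnnotation = {}
    dropped_tx: list[str] = []
    dropped_genes: list[str] = []
    for gene_id, gene in ann.items():
        keep = tuple(t for t in gene.transcripts if not t.is_readthrough)
        dropped_tx.extend(t.transcript_id for t in gene.transcripts if t.is_readthrough)
        if keep:
            out[gene_id] = replace(gene, transcripts=keep)
        else:
            dropped_genes.append(gene_id)
    return out, dropped_tx, dropped_genes


@dataclass
class SanitizedAnnotation:
    """Per-gene disjoint exonic/intronic interval sets plus the audit trail."""

    genes: dict[str, GeneModel]
    exonic: dict[str, IntervalSet]
    intronic: dict[str, IntervalSet]
    removed_shared: dict[str, list[tuple[int, int]]]  # chrom (or chrom:strand) -> intervals
    dropped_readthrough: list[str] = field(default_factory=list)
    dropped_genes: list[str] = field(default_factory=list)
    intronless: set[str] = field(default_factory=set)
    strand_mode: str = "blind"

    def genes_on(self, chrom: str, strand: str | None = None) -> list[GeneModel]:
        return [
            g
            for g in self.genes.values()
            if g.chrom == chrom and (strand is None or g.strand == strand)
        ]

    def gene_region(self, gene_id: str) -> IntervalSet:
        """exonic union intronic for one gene."""
        return self.exonic[gene_id].union(self.intronic[gene_id])


def remove_shared_regions(ann: RawAnnotation, strand_mode: str = "blind") -> SanitizedAnnotation:
    """Delete every base claimed by >=2 gene spans; derive exonic sets.

    strand_mode 'blind' treats both strands as one genomic space (two genes
    overlapping antisense still lose the shared bases); 'aware' resolves
    overlaps per strand. Overlap is computed on gene spans, so an exon of one
    gene inside another gene's intron is removed from both.
    """
    if strand_mode not in ("blind", "aware"):
        raise ValueError(f"strand_mode must be 'blind' or 'aware', got {strand_mode!r}")

    def group_key(g: GeneModel) -> str:
        return g.chrom if strand_mode == "blind" else f"{g.chrom}:{g.strand}"

    spans_by_group: dict[str, list[tuple[int, int]]] = {}
    for g in ann.values():
        spans_by_group.setdefault(group_key(g), []).append(g.span)
    removed_shared = {key: multicov_regions(spans, 2) for key, spans in spans_by_group.items()}
    removed_shared = {k: v for k, v in removed_shared.items() if v}

    genes: dict[str, GeneModel] = {}
    exonic: dict[str, IntervalSet] = {}
    dropped: list[str] = []
    for gene_id, g in ann.items():
        shared = removed_shared.get(group_key(g), [])
        ex = subtract_intervals(g.exon_union(), shared)
        span_left = subtract_intervals([g.span], shared)
        if not span_left:
            dropped.append(gene_id)
            continue
        genes[gene_id] = g
        exonic[gene_id] = IntervalSet(g.chrom, g.strand, tuple(ex))

    return SanitizedAnnotation(
        genes=genes,
        exonic=exonic,
        intronic={},
        removed_shared=removed_shared,
        dropped_genes=dropped,
        strand_mode=strand_mode,
    )


def derive_intron_regions(san: SanitizedAnnotation) -> SanitizedAnnotation:
    """intronic = gene span - exon union - shared regions, per gene."""
    for gene_id, g in san.genes.items():
        key = g.chrom if san.strand_mode == "blind" else f"{g.chrom}:{g.strand}"
        shared = san.removed_shared.get(key, [])
        intr = subtract_intervals([g.span], g.exon_union())
        intr = subtract_intervals(intr, shared)
        san.intronic[gene_id] = IntervalSet(g.chrom, g.strand, tuple(intr))
        if not intr:
            san.intronless.add(gene_id)
    return san


def sanitize(
    primary: RawAnnotation,
    supplement: RawAnnotation | None = None,
    strand_mode: str = "blind",
) -> SanitizedAnnotation:
    """Full pipeline: merge supplement, drop readthrough, de-overlap, derive introns."""
    merge_report = MergeReport()
    ann = primary
    if supplement is not None:
        ann, merge_report = merge_supplemental_genes(ann, supplement)
    ann, dropped_tx, dropped_by_tag = drop_readthrough_transcripts(ann)
    san = remove_shared_regions(ann, strand_mode=strand_mode)
    san.dropped_readthrough = dropped_tx
    san.dropped_genes = dropped_by_tag + san.dropped_genes
    san.merge_report = merge_report  # type: ignore[attr-defined]
    return derive_intron_regions(san)


def write_region_bed(san: SanitizedAnnotation, which: str, path: str) -> None:
    """BED6 of per-gene exonic or intronic regions (name = gene_id)."""
    sets = san.exonic if which == "exonic" else san.intronic
    with open(path, "w") as fh:
        for gene_id in sorted(sets):
            ivset = sets[gene_id]
            for s, e in ivset:
                fh.write(f"{ivset.chrom}\t{s}\t{e}\t{gene_id}\t0\t{ivset.strand}\n")


def write_audit_report(san: SanitizedAnnotation, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("record_type\tvalue\n")
        for tid in san.dropped_readthrough:
            fh.write(f"dropped_transcript\t{tid}\n")
        for gid in san.dropped_genes:
            fh.write(f"dropped_gene\t{gid}\n")
        for key in sorted(san.removed_shared):
            for s, e in san.removed_shared[key]:
                fh.write(f"removed_shared\t{key}:{s}-{e}\n")
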