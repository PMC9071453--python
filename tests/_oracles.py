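"""Independent brute-force oracles: per-base set arithmetic, nothing shared
with the interval-sweep implementations they check."""

from __future__ import annotations

import numpy as np

from ripscape.annotation import RawAnnotation, SanitizedAnnotation
from ripscape.quant import ReadAlignment, effective_strand


def gene_base_sets(san: SanitizedAnnotation, gene_id: str) -> tuple[set[int], set[int]]:
    ex = {b for s, e in san.exonic[gene_id] for b in range(s, e)}
    intr = {b for s, e in san.intronic[gene_id] for b in range(s, e)}
    return ex, intr


def brute_force_shared(ann: RawAnnotation, strand_mode: str = "blind") -> dict[str, list[tuple[int, int]]]:
    """Bases claimed by >= 2 gene spans, via a literal per-base counter."""
    out: dict[str, list[tuple[int, int]]] = {}
    keys = {
        (g.chrom if strand_mode == "blind" else f"{g.chrom}:{g.strand}")
        for g in ann.values()
    }
    for key in sorted(keys):
        genes = [
            g
            for g in ann.values()
            if (g.chrom if strand_mode == "blind" else f"{g.chrom}:{g.strand}") == key
        ]
        hi = max(g.span[1] for g in genes)
        depth = np.zeros(hi + 1, dtype=np.int32)
        for g in genes:
            s, e = g.span
            depth[s:e] += 1
        mask = depth >= 2
        # run-length encode the mask into intervals
        ivs = []
        pos = 0
        while pos <= hi:
            if mask[pos]:
                start = pos
                while pos <= hi and mask[pos]:
                    pos += 1
                ivs.append((start, pos))
            else:
                pos += 1
        if ivs:
            out[key] = ivs
    return out


def brute_force_assign(
    aln: ReadAlignment,
    san: SanitizedAnnotation,
    base_sets: dict[str, tuple[set[int], set[int]]],
    min_overlap: int = 20,
    strandedness: str = "reverse",
) -> tuple[str, str]:
    """Literal per-base re-statement of the assignment rule."""
    strand = effective_strand(aln.strand, strandedness)
    read_bases = {b for s, e in aln.blocks for b in range(s, e)}
    candidates: dict[str, dict[str, int]] = {}
    for gene_id, g in san.genes.items():
        if g.chrom != aln.chrom or (strand is not None and g.strand != strand):
            continue
        ex, intr = base_sets[gene_id]
        ov_ex = len(read_bases & ex)
        ov_in = len(read_bases & intr)
        if ov_ex >= min_overlap:
            candidates.setdefault(gene_id, {})["exonic"] = ov_ex
        if ov_in >= min_overlap:
            candidates.setdefault(gene_id, {})["intronic"] = ov_in
    if not candidates:
        return ("__unassigned__", "")
    if len(candidates) > 1:
        return ("__ambiguous__", "")
    gene_id, buckets = next(iter(candidates.items()))
    if len(buckets) == 2 and buckets["intronic"] > buckets["exonic"]:
        return (gene_id, "intronic")
    return (gene_id, next(iter(buckets)) if len(buckets) == 1 else "exonic")


def expected_splicing_ratio(san: SanitizedAnnotation, gene_id: str, unspliced_fraction: float, read_length: int):
    """Exact expected intron/exon density ratio under the generator geometry.

    Enumerates every equally-likely read start (spliced starts on the mature
    transcript, unspliced starts on the pre-mRNA span) and applies the
    assignment rule, giving the expected exonic/intronic counts in closed
    form. Returns None for genes where the ratio is undefined.
    """
    g = san.genes[gene_id]
    L = read_length
    ex_ivs = list(san.exonic[gene_id])
    in_ivs = list(san.intronic[gene_id])
    l_ex = sum(e - s for s, e in ex_ivs)
    l_in = sum(e - s for s, e in in_ivs)
    if l_ex == 0 or l_in == 0:
        return None
    span_s, span_e = g.span
    span_len = span_e - span_s
    ex_ind = np.zeros(span_len, dtype=np.float64)
    in_ind = np.zeros(span_len, dtype=np.float64)
    for s, e in ex_ivs:
        ex_ind[s - span_s : e - span_s] = 1
    for s, e in in_ivs:
        in_ind[s - span_s : e - span_s] = 1

    def window_sums(ind):
        c = np.concatenate([[0.0], np.cumsum(ind)])
        return c[L:] - c[:-L]  # overlap of [s, s+L) for each start s

    # unspliced reads: uniform start on [span_s, span_e - L)
    ex_ov = window_sums(ex_ind)[: span_len - L]
    in_ov = window_sums(in_ind)[: span_len - L]
    pick_ex = (ex_ov >= 20) & (ex_ov >= in_ov)
    pick_in = (in_ov >= 20) & (in_ov > ex_ov)
    p_ex_u = pick_ex.mean()
    p_in_u = (pick_in & ~pick_ex).mean()

    # spliced reads: uniform start on the mature transcript; each mature base
    # maps to one genomic base, marked by whether it survived sanitization
    primary = next(t for t in g.transcripts if not t.is_readthrough)
    mature = np.concatenate(
        [ex_ind[s - span_s : e - span_s] for s, e in primary.exons]
    )
    if len(mature) <= L:
        p_ex_s = 1.0 if mature.sum() >= 20 else 0.0
    else:
        ms = window_sums(mature)[: len(mature) - L]
        p_ex_s = (ms >= 20).mean()

    u = unspliced_fraction
    e_cin = u * p_in_u
    e_cex = u * p_ex_u + (1 - u) * p_ex_s
    if e_cex == 0:
        return None
    return (e_cin / l_in) / (e_cex / l_ex)
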