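"""Enrichment/depletion classification of a differential-abundance table.

The differential table (gene_id, baseMean, log2FoldChange, padj) comes from
an external negative-binomial test; this module only applies the study
thresholds — enriched: log2FC > 0.5, padj <= 0.01, baseMean > 50; depleted:
log2FC < -0.5 with the same padj/baseMean gates — computes set overlaps
between two IPs, and applies the histone-background ratio filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

LFC_MIN = 0.5
PADJ_MAX = 0.01
BASEMEAN_MIN = 50.0
PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class DifferentialRecord:
    gene_id: str
    base_mean: float
    log2fc: float
    padj: float | None  # None = filtered out by the upstream tool


def classify_gene(
    rec: DifferentialRecord,
    lfc_min: float = LFC_MIN,
    padj_max: float = PADJ_MAX,
    basemean_min: float = BASEMEAN_MIN,
) -> str:
    """'enriched' | 'depleted' | 'ns'.

    Strict inequalities on log2fc and baseMean, non-strict on padj; a
    missing padj is never significant.
    """
    if rec.padj is None or (isinstance(rec.padj, float) and math.isnan(rec.padj)):
        return "ns"
    if rec.padj > padj_max or rec.base_mean <= basemean_min:
        return "ns"
    if rec.log2fc > lfc_min:
        return "enriched"
    if rec.log2fc < -lfc_min:
        return "depleted"
    return "ns"


def load_differential_table(path: str) -> list[DifferentialRecord]:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "baseMean", "log2FoldChange", "padj"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        DifferentialRecord(
            gene_id=str(r.gene_id),
            base_mean=float(r.baseMean),
            log2fc=float(r.log2FoldChange),
            padj=None if pd.isna(r.padj) else float(r.padj),
        )
        for r in df.itertuples()
    ]


def classify_table(
    records: Iterable[DifferentialRecord],
    removed: set[str] | None = None,
    **thresholds: float,
) -> pd.DataFrame:
    """Classify every gene; genes in `removed` (upstream-filter hits) are dropped."""
    removed = removed or set()
    rows = [
        {"gene_id": r.gene_id, "klass": classify_gene(r, **thresholds)}
        for r in records
        if r.gene_id not in removed
    ]
    return pd.DataFrame(rows, columns=["gene_id", "klass"])


def overlap_sets(classes_a: pd.DataFrame, classes_b: pd.DataFrame) -> dict[str, list[str]]:
    """Venn partition of enriched/depleted calls between two comparisons."""
    if set(classes_a.gene_id) != set(classes_b.gene_id):
        raise ValueError("class tables cover different gene universes")
    out: dict[str, list[str]] = {}
    for klass in ("enriched", "depleted"):
        a = set(classes_a.loc[classes_a.klass == klass, "gene_id"])
        b = set(classes_b.loc[classes_b.klass == klass, "gene_id"])
        out[f"{klass}_only_a"] = sorted(a - b)
        out[f"{klass}_only_b"] = sorted(b - a)
        out[f"{klass}_both"] = sorted(a & b)
    return out


def background_threshold_filter(
    tpm_ip: Mapping[str, float],
    tpm_input: Mapping[str, float],
    histone_ids: Sequence[str],
    summary: str = "median",
    pseudocount: float = PSEUDOCOUNT,
) -> list[str]:
    """Retain genes whose IP/input TPM ratio clears the histone background.

    Replication-dependent histone transcripts lack a poly(A) tail and are
    depleted from both IPs, so their IP/input ratio marks the background
    pulldown level; genes below the histone summary ratio are dropped.
    """
    present = [h for h in histone_ids if h in tpm_ip and h in tpm_input]
    if not present:
        raise ValueError("no histone gene found in the TPM tables")

    def ratio(g: str) -> float:
        return (tpm_ip[g] + pseudocount) / (tpm_input[g] + pseudocount)

    hist = sorted(ratio(h) for h in present)
    if summary == "median":
        n = len(hist)
        threshold = hist[n // 2] if n % 2 else (hist[n // 2 - 1] + hist[n // 2]) / 2
    elif summary == "max":
        threshold = hist[-1]
    else:
        raise ValueError(f"summary must be 'median' or 'max', got {summary!r}")
    return [g for g in tpm_ip if g in tpm_input and ratio(g) >= threshold]
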