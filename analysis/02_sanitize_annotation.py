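#!/usr/bin/env python
"""Sanitize the simulated annotation: drop readthrough transcripts, remove
genomic space claimed by two or more genes, derive exonic/intronic regions.

Writes the sanitized GTF, BED region files and the audit report under
results/annotation/.
"""

from pathlib import Path

from ripscape.annotation import (
    load_annotation,
    sanitize,
    write_audit_report,
    write_gtf,
    write_region_bed,
)

GTF = Path("scratch/sim/annotation.gtf")
OUT = Path("results/annotation")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    san = sanitize(load_annotation(str(GTF)))
    write_gtf(san.genes, str(OUT / "sanitized.gtf"))
    write_region_bed(san, "exonic", str(OUT / "exonic.bed"))
    write_region_bed(san, "intronic", str(OUT / "intronic.bed"))
    write_audit_report(san, str(OUT / "audit.tsv"))
    removed = sum(e - s for ivs in san.removed_shared.values() for s, e in ivs)
    print(f"{len(san.genes)} genes kept, {len(san.dropped_readthrough)} readthrough "
          f"transcripts dropped, {removed} bp of shared genomic space removed, "
          f"{len(san.intronless)} intronless genes")


if __name__ == "__main__":
    main()
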