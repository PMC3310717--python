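"""Shared test fixtures builders."""

from __future__ import annotations

from hapcon import ChromosomeMeta, HaplotypeMatrix, SnpRecord


def build_matrix(
    rows,
    groups=None,
    statuses=None,
    chrom: str = "chr1",
    bp_start: int = 100,
    bp_step: int = 10,
) -> HaplotypeMatrix:
    """Matrix from a list of allele strings ('?' = missing)."""
    rows = [list(r) for r in rows]
    n = len(rows)
    length = len(rows[0]) if rows else 0
    snps = [
        SnpRecord(id=f"rs{j + 1}", chrom=chrom, pos_bp=bp_start + j * bp_step)
        for j in range(length)
    ]
    chroms = [
        ChromosomeMeta(
            sample_id=f"S{i + 1:03d}",
            hap_index=1,
            group=groups[i] if groups else None,
            status=statuses[i] if statuses else "unknown",
        )
        for i in range(n)
    ]
    return HaplotypeMatrix.from_symbols(rows, snps, chroms)
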