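"""Readers and writers for phased haplotype data and results.

Supported formats:

* **Phased VCF** (via cyvcf2): each sample contributes two chromosome rows.
  Unphased genotypes (``/`` separator) and missing calls set *both* of the
  sample's alleles at that site to MISSING — with family phasing, a site
  whose phase cannot be resolved is unknown on both haplotypes.
* **Haplotype table**: a plain TSV dialect with one row per SNP
  (``id  chrom  pos_bp`` then one allele symbol per chromosome, ``?`` =
  missing), a header row of ``sample.hap`` chromosome labels, and optional
  ``#group`` / ``#status`` / ``#founder`` annotation rows.  Writes are
  byte-deterministic and round-trip exactly.
* **Genetic map**: whitespace-separated recombination-rate text with
  position (bp) and rate (cM/Mb) columns, with or without a leading
  chromosome column; a header line is tolerated.
* **BED3+** for candidate regions (0-based half-open starts; name = cohort,
  score = 10x the region's maximum percent congruent, rounded).

Coordinates are 1-based inclusive everywhere except BED output.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import EmptyRegionError, ParseError
from .matrix import (
    MISSING_TOKEN,
    ChromosomeMeta,
    GeneticMap,
    HaplotypeMatrix,
    SnpRecord,
)
from .scan import CandidateRegion

import pandas as pd


def _parse_region(region: str) -> tuple[str, int, int]:
    try:
        chrom, rng = region.rsplit(":", 1)
        lo, hi = rng.split("-")
        return chrom, int(lo.replace(",", "")), int(hi.replace(",", ""))
    except ValueError as exc:
        raise ValueError(f"malformed region {region!r}; expected chrom:start-end") from exc


def read_phased_vcf(
    path: str | Path,
    region: str | None = None,
    founders_only: bool = False,
    founder_ids: Iterable[str] | None = None,
) -> HaplotypeMatrix:
    """Read a phased-GT VCF into a haplotype matrix.

    Each sample yields two chromosomes (hap_index 1 = left of the ``|``
    separator).  Unphased ("/") or missing (".") genotypes map both of the
    sample's alleles at that site to MISSING.  Multi-allelic sites are kept
    with their actual REF/ALT allele strings.  ``region`` uses 1-based
    inclusive coordinates (``chrom:start-end``).

    A VCF carries no pedigree, so ``founders_only`` restricts to the
    samples named in ``founder_ids`` when given (and is a no-op otherwise);
    all retained chromosomes are marked as founders.
    """
    from cyvcf2 import VCF

    path = Path(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise ParseError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    keep = list(range(len(samples)))
    if founders_only and founder_ids is not None:
        wanted = set(founder_ids)
        keep = [i for i, s in enumerate(samples) if s in wanted]
        if not keep:
            raise ValueError("founder_ids matches no VCF sample")

    reg = _parse_region(region) if region else None
    snps: list[SnpRecord] = []
    site_symbols: list[list[str | None]] = []  # per site, per kept chromosome
    line_no = 0
    try:
        for var in vcf:
            line_no += 1
            if reg is not None:
                chrom, lo, hi = reg
                if var.CHROM != chrom or not lo <= var.POS <= hi:
                    continue
            alleles_here = [var.REF] + list(var.ALT)
            gts = var.genotypes
            col: list[str | None] = []
            for i in keep:
                g = gts[i]
                a, b, phased = g[0], g[1], g[-1]
                if not phased or a < 0 or b < 0:
                    col.extend([None, None])
                else:
                    col.extend([alleles_here[a], alleles_here[b]])
            snps.append(
                SnpRecord(
                    id=var.ID or f"{var.CHROM}:{var.POS}",
                    chrom=var.CHROM,
                    pos_bp=var.POS,
                )
            )
            site_symbols.append(col)
    except Exception as exc:
        if isinstance(exc, ParseError):
            raise
        raise ParseError(f"cannot parse VCF {path} near record {line_no}: {exc}") from exc
    if not snps:
        raise EmptyRegionError(
            f"no sites in {path}" + (f" within region {region}" if region else "")
        )

    rows = [
        [
            MISSING_TOKEN if site[2 * si + hap] is None else site[2 * si + hap]
            for site in site_symbols
        ]
        for si in range(len(keep))
        for hap in (0, 1)
    ]
    chromosomes = [
        ChromosomeMeta(sample_id=samples[i], hap_index=hap, founder=True)
        for i in keep
        for hap in (1, 2)
    ]
    return HaplotypeMatrix.from_symbols(rows, snps, chromosomes)


def write_haplotype_table(matrix: HaplotypeMatrix, path: str | Path) -> None:
    """Write the haplotype TSV dialect (byte-deterministic)."""
    path = Path(path)
    sym = matrix.to_symbols()
    with path.open("w", newline="\n") as fh:
        fh.write("id\tchrom\tpos_bp\t" + "\t".join(matrix.labels) + "\n")
        fh.write(
            "#group\t\t\t"
            + "\t".join(c.group if c.group is not None else "" for c in matrix.chromosomes)
            + "\n"
        )
        fh.write(
            "#status\t\t\t" + "\t".join(c.status for c in matrix.chromosomes) + "\n"
        )
        fh.write(
            "#founder\t\t\t"
            + "\t".join("1" if c.founder else "0" for c in matrix.chromosomes)
            + "\n"
        )
        for j, snp in enumerate(matrix.snps):
            fh.write(
                f"{snp.id}\t{snp.chrom}\t{snp.pos_bp}\t"
                + "\t".join(sym[:, j])
                + "\n"
            )


def read_haplotype_table(path: str | Path) -> HaplotypeMatrix:
    """Read the haplotype TSV dialect written by :func:`write_haplotype_table`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 3 or header[:3] != ["id", "chrom", "pos_bp"]:
        raise ParseError(f"{path}: row 1: expected header 'id\\tchrom\\tpos_bp\\t...'")
    labels = header[3:]
    n_chrom = len(labels)
    ann: dict[str, list[str]] = {}
    data_rows: list[tuple[int, list[str]]] = []
    for row_no, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if line.startswith("#"):
            key = parts[0][1:]
            vals = parts[3:]
            if len(vals) != n_chrom:
                raise ParseError(
                    f"{path}: row {row_no}: annotation '{key}' has {len(vals)} "
                    f"values for {n_chrom} chromosomes"
                )
            ann[key] = vals
            continue
        if len(parts) != 3 + n_chrom:
            raise ParseError(
                f"{path}: row {row_no}: expected {3 + n_chrom} columns, got {len(parts)}"
            )
        data_rows.append((row_no, parts))

    snps: list[SnpRecord] = []
    site_alleles: list[list[str]] = []
    for row_no, parts in data_rows:
        try:
            snps.append(SnpRecord(id=parts[0], chrom=parts[1], pos_bp=int(parts[2])))
        except ValueError as exc:
            raise ParseError(f"{path}: row {row_no}: {exc}") from exc
        site_alleles.append(parts[3:])

    chromosomes: list[ChromosomeMeta] = []
    groups = ann.get("group", [""] * n_chrom)
    statuses = ann.get("status", ["unknown"] * n_chrom)
    founders = ann.get("founder", ["1"] * n_chrom)
    for i, label in enumerate(labels):
        try:
            sample_id, hap = label.rsplit(".", 1)
            hap_index = int(hap)
        except ValueError as exc:
            raise ParseError(
                f"{path}: chromosome label {label!r} is not 'sample.hap'"
            ) from exc
        chromosomes.append(
            ChromosomeMeta(
                sample_id=sample_id,
                hap_index=hap_index,
                group=groups[i] or None,
                status=statuses[i],
                founder=founders[i] == "1",
            )
        )
    rows = [[site[i] for site in site_alleles] for i in range(n_chrom)]
    try:
        return HaplotypeMatrix.from_symbols(rows, snps, chromosomes)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_genetic_map(path: str | Path, chrom: str | None = None) -> GeneticMap:
    """Read a recombination-rate text file.

    Accepts ``pos rate [...]`` or ``chrom pos rate [...]`` whitespace-split
    columns with positions in bp and rates in cM/Mb; a header line is
    skipped.  Per-chromosome map files carry no chromosome column — pass
    ``chrom`` to label their entries.
    """
    path = Path(path)
    rows = []
    for line_no, line in enumerate(path.read_text().splitlines(), start=1):
        tokens = line.split()
        if not tokens:
            continue
        try:
            if _is_number(tokens[0]):
                if len(tokens) < 2:
                    raise ValueError("need position and rate columns")
                c = chrom or "unknown"
                pos, rate = float(tokens[0]), float(tokens[1])
            else:
                if len(tokens) >= 3 and _is_number(tokens[1]) and _is_number(tokens[2]):
                    c, pos, rate = tokens[0], float(tokens[1]), float(tokens[2])
                else:
                    continue  # header line
        except ValueError as exc:
            raise ParseError(f"{path}: line {line_no}: {exc}") from exc
        if rate < 0:
            raise ParseError(f"{path}: line {line_no}: negative rate {rate}")
        rows.append({"chrom": c, "pos_bp": int(pos), "rate_cM_per_Mb": rate})
    return GeneticMap(pd.DataFrame(rows, columns=["chrom", "pos_bp", "rate_cM_per_Mb"]))


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_regions_bed(regions: Sequence[CandidateRegion], path: str | Path) -> None:
    """Write candidate regions as BED3+ (name = cohort, score = 10x max %)."""
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        for r in regions:
            if r.start_bp >= r.end_bp:
                raise ValueError(
                    f"region {r.chrom}:{r.start_bp}-{r.end_bp}: start must precede end"
                )
            score = round(r.max_percent_congruent * 10)
            fh.write(f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t{r.cohort}\t{score}\n")
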