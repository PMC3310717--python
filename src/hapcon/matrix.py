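"""In-memory containers for phased haplotype data.

A :class:`HaplotypeMatrix` is a rectangular grid of allele codes with one row
per phased chromosome and one column per SNP.  Alleles are stored as small
integers indexing a sorted symbol alphabet; ``MISSING`` (= -1) marks alleles
that are missing or whose phase could not be resolved — the two are not
distinguished downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError

#: Integer code for a missing/unphased allele.
MISSING: int = -1

#: Token used for missing alleles in text formats.
MISSING_TOKEN: str = "?"


@dataclass(frozen=True)
class SnpRecord:
    """One SNP: marker name, chromosome label and 1-based physical position."""

    id: str
    chrom: str
    pos_bp: int

    def __post_init__(self) -> None:
        if self.pos_bp <= 0:
            raise ValueError(f"SNP {self.id}: pos_bp must be positive, got {self.pos_bp}")


@dataclass(frozen=True)
class ChromosomeMeta:
    """Metadata for one phased chromosome of one donor.

    ``hap_index`` is 1 or 2 (which of the donor's two phased haplotypes).
    ``status`` is ``"case"``, ``"control"`` or ``"unknown"``.
    """

    sample_id: str
    hap_index: int
    group: str | None = None
    status: str = "unknown"
    founder: bool = True

    def __post_init__(self) -> None:
        if self.hap_index not in (1, 2):
            raise ValueError(f"hap_index must be 1 or 2, got {self.hap_index}")
        if self.status not in ("case", "control", "unknown"):
            raise ValueError(f"status must be case/control/unknown, got {self.status!r}")

    @property
    def label(self) -> str:
        return f"{self.sample_id}.{self.hap_index}"


class HaplotypeMatrix:
    """Rectangular chromosomes x SNPs grid of allele codes.

    Parameters
    ----------
    alleles : array-like of int, shape (n_chromosomes, n_snps)
        Codes index ``alphabet``; ``MISSING`` (-1) marks missing/unphased.
    alphabet : sequence of str
        Allele symbols in strictly ascending order.  The order is the fixed
        total order used for deterministic tie-breaking everywhere.
    snps : sequence of SnpRecord
        Sorted by (chrom, pos_bp) with strictly increasing positions per chrom.
    chromosomes : sequence of ChromosomeMeta
        (sample_id, hap_index) pairs must be unique.
    """

    def __init__(
        self,
        alleles: np.ndarray,
        alphabet: Sequence[str],
        snps: Sequence[SnpRecord],
        chromosomes: Sequence[ChromosomeMeta],
    ) -> None:
        alleles = np.asarray(alleles, dtype=np.int16)
        if alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D grid")
        alphabet = tuple(str(a) for a in alphabet)
        if any(alphabet[i] >= alphabet[i + 1] for i in range(len(alphabet) - 1)):
            raise ValueError("alphabet must be strictly ascending")
        snps = list(snps)
        chromosomes = list(chromosomes)
        if alleles.shape != (len(chromosomes), len(snps)):
            raise ValueError(
                f"grid shape {alleles.shape} does not match "
                f"{len(chromosomes)} chromosomes x {len(snps)} SNPs"
            )
        if alleles.size and (alleles.min() < MISSING or alleles.max() >= len(alphabet)):
            raise ValueError("allele codes must lie in alphabet or be MISSING")
        labels = [(c.sample_id, c.hap_index) for c in chromosomes]
        if len(set(labels)) != len(labels):
            raise ValueError("(sample_id, hap_index) pairs must be unique")
        for prev, cur in zip(snps, snps[1:]):
            if prev.chrom == cur.chrom and cur.pos_bp <= prev.pos_bp:
                raise ValueError(
                    f"SNP positions must strictly increase per chrom: "
                    f"{prev.id}@{prev.pos_bp} then {cur.id}@{cur.pos_bp}"
                )
        self.alleles = alleles
        self.alphabet = alphabet
        self.snps = snps
        self.chromosomes = chromosomes

    # -- construction ------------------------------------------------------

    @classmethod
    def from_symbols(
        cls,
        rows: Iterable[Sequence[str]],
        snps: Sequence[SnpRecord],
        chromosomes: Sequence[ChromosomeMeta],
        missing_token: str = MISSING_TOKEN,
    ) -> "HaplotypeMatrix":
        """Build a matrix from rows of allele symbols (strings)."""
        rows = [list(r) for r in rows]
        symbols = sorted({a for r in rows for a in r if a != missing_token})
        code = {a: i for i, a in enumerate(symbols)}
        code[missing_token] = MISSING
        try:
            grid = np.array([[code[a] for a in r] for r in rows], dtype=np.int16)
        except KeyError as exc:  # pragma: no cover - defensive
            raise ValueError(f"unknown allele symbol {exc}") from exc
        if not rows:
            grid = np.empty((0, len(snps)), dtype=np.int16)
        return cls(grid, symbols, snps, chromosomes)

    # -- basic properties --------------------------------------------------

    @property
    def n_chromosomes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.chromosomes]

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos_bp for s in self.snps], dtype=np.int64)

    @property
    def snp_chroms(self) -> list[str]:
        return [s.chrom for s in self.snps]

    def missing_fraction(self) -> np.ndarray:
        """Per-chromosome fraction of MISSING cells."""
        if self.n_snps == 0:
            return np.zeros(self.n_chromosomes)
        return (self.alleles == MISSING).mean(axis=1)

    # -- conversion --------------------------------------------------------

    def to_symbols(self, missing_token: str = MISSING_TOKEN) -> np.ndarray:
        """Grid of allele symbol strings (dtype object)."""
        lut = np.array(list(self.alphabet) + [missing_token], dtype=object)
        return lut[self.alleles]  # MISSING == -1 wraps to the appended token

    def decode(self, codes: np.ndarray, missing_token: str = MISSING_TOKEN) -> list[str]:
        """Decode a 1-D array of codes to symbol strings."""
        return [missing_token if c == MISSING else self.alphabet[c] for c in codes]

    # -- subsetting --------------------------------------------------------

    def subset_snps(self, start: int, stop: int) -> "HaplotypeMatrix":
        """Columns ``start:stop`` (0-based half-open), all chromosomes."""
        if not (0 <= start < stop <= self.n_snps):
            raise ValueError(f"invalid SNP range [{start}, {stop})")
        return HaplotypeMatrix(
            self.alleles[:, start:stop].copy(), self.alphabet,
            self.snps[start:stop], self.chromosomes,
        )

    def subset_chromosomes(self, indices: Sequence[int]) -> "HaplotypeMatrix":
        """Row subset in the given order."""
        idx = list(indices)
        return HaplotypeMatrix(
            self.alleles[idx, :].copy(), self.alphabet,
            self.snps, [self.chromosomes[i] for i in idx],
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<HaplotypeMatrix {self.n_chromosomes} chromosomes x "
            f"{self.n_snps} SNPs, alphabet={self.alphabet}>"
        )


@dataclass
class GeneticMap:
    """Recombination-rate map: (chrom, pos_bp, rate_cM_per_Mb) rows.

    Rows are kept sorted by (chrom, pos_bp); rates must be non-negative.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "pos_bp", "rate_cM_per_Mb"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"genetic map needs columns {sorted(required)}")
        if (self.table["rate_cM_per_Mb"] < 0).any():
            bad = self.table[self.table["rate_cM_per_Mb"] < 0].iloc[0]
            raise ParseError(
                f"negative recombination rate {bad['rate_cM_per_Mb']} at "
                f"{bad['chrom']}:{bad['pos_bp']}"
            )
        self.table = (
            self.table.sort_values(["chrom", "pos_bp"], kind="stable")
            .reset_index(drop=True)
        )
        dup = self.table.duplicated(["chrom", "pos_bp"])
        if dup.any():
            row = self.table[dup].iloc[0]
            raise ParseError(f"duplicate map position {row['chrom']}:{row['pos_bp']}")

    def __len__(self) -> int:
        return len(self.table)

    def rates_in(self, chrom: str, start_bp: int, end_bp: int) -> np.ndarray:
        """Rates at map positions with start_bp <= pos <= end_bp on chrom."""
        t = self.table
        sel = (t["chrom"] == chrom) & (t["pos_bp"] >= start_bp) & (t["pos_bp"] <= end_bp)
        return t.loc[sel, "rate_cM_per_Mb"].to_numpy()
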