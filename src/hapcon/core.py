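"""Consensus derivation and congruence classification.

The algorithm identifies chromosomes that share a long, nearly identical
haplotype.  It interleaves two passes over a SNP span:

1. **Consensus derivation.**  A *derivation window* of ``derivation_window``
   (W) SNPs is positioned at the current point; the most frequent complete
   allele string of length W among the surviving chromosomes is found, and
   its first ``record_length`` (N) alleles are appended to the emerging
   consensus.  W > N gives a *look-ahead* that favours strings which stay
   identical beyond the recorded prefix, emphasising long haplotypes.
2. **Fuzzy filtering.**  As the consensus grows, every *filter window* of
   ``filter_window`` (F) SNPs starting on the lattice
   ``span_start + k * filter_offset`` is evaluated exactly once, as soon as
   the consensus covers it.  A chromosome is removed from further
   consideration when it mismatches the consensus at more than ``F - M``
   positions in any window (equivalently, fewer than ``min_matches`` (M)
   of the F SNPs match).  Missing/unphased alleles never count as
   mismatches, so the budget rule extends naturally to the short tail
   windows at the end of the span.

Chromosomes that survive every filter window are *congruent*.  Defaults
(W=30, N=10, F=30, M=20, offset=1) tolerate roughly one mismatching allele
in three — yet congruent chromosomes typically show >99% allele identity,
because a chromosome must match the emerging consensus repeatedly and
consistently across all overlapping windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConsensusDepletedError,
    NoEligibleChromosomesError,
    UnresolvableConsensusError,
)
from .matrix import MISSING, MISSING_TOKEN, HaplotypeMatrix

#: Codes of the identity grid produced by :func:`identity_matrix`.
MATCH: int = 1
MISMATCH: int = 0
ID_MISSING: int = -1


@dataclass(frozen=True)
class CongruenceParams:
    """Tunables of the congruence algorithm.

    Attributes
    ----------
    derivation_window : int
        W, look-ahead window length in SNPs (default 30).
    record_length : int
        N, number of consensus alleles recorded per iteration (default 10).
    filter_window : int
        F, filter-window length in SNPs (default 30).
    min_matches : int
        M, minimum matching SNPs per filter window (default 20); the
        allowed-mismatch budget is F - M.
    filter_offset : int
        O, spacing of filter-window starts in SNPs (default 1).
    max_missing_fraction : float
        Chromosomes whose MISSING fraction within the span exceeds this cap
        are excluded up front (default 1.0 = keep all).
    start_index : int
        First SNP index (0-based) of the analysis span.  Results depend on
        the start site, so it is an explicit parameter.
    """

    derivation_window: int = 30
    record_length: int = 10
    filter_window: int = 30
    min_matches: int = 20
    filter_offset: int = 1
    max_missing_fraction: float = 1.0
    start_index: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.record_length <= self.derivation_window:
            raise ValueError("need 1 <= record_length <= derivation_window")
        if not 1 <= self.min_matches <= self.filter_window:
            raise ValueError("need 1 <= min_matches <= filter_window")
        if self.filter_offset < 1:
            raise ValueError("filter_offset must be >= 1")
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must be in [0, 1]")
        if self.start_index < 0:
            raise ValueError("start_index must be >= 0")


@dataclass
class ConsensusResult:
    """Consensus string plus per-chromosome congruence over one span.

    ``span`` is the 0-based half-open SNP index range analysed.
    ``identity_pct`` is NaN for excluded chromosomes and for chromosomes
    with no non-missing allele in the span.
    """

    span: tuple[int, int]
    consensus: np.ndarray  # int16 allele codes, never MISSING
    alphabet: tuple[str, ...]
    congruent: np.ndarray  # bool per chromosome
    excluded: np.ndarray  # bool per chromosome (failed missingness cap)
    identity_pct: np.ndarray  # float per chromosome (%)
    percent_congruent: float
    params: CongruenceParams = field(repr=False)

    @property
    def n_eligible(self) -> int:
        return int((~self.excluded).sum())

    @property
    def n_congruent(self) -> int:
        return int(self.congruent.sum())

    @property
    def consensus_string(self) -> str:
        """Consensus as a concatenated symbol string (single-char symbols)."""
        return "".join(self.alphabet[c] for c in self.consensus)

    def consensus_symbols(self) -> list[str]:
        return [self.alphabet[c] for c in self.consensus]

    def to_frame(self, matrix: HaplotypeMatrix) -> pd.DataFrame:
        """Per-chromosome report (one row per chromosome of ``matrix``)."""
        return pd.DataFrame(
            {
                "chromosome": matrix.labels,
                "group": [c.group for c in matrix.chromosomes],
                "status": [c.status for c in matrix.chromosomes],
                "excluded": self.excluded,
                "congruent": self.congruent,
                "identity_pct": np.round(self.identity_pct, 4),
            }
        )


def _resolve_span(
    matrix: HaplotypeMatrix, params: CongruenceParams, span: tuple[int, int] | None
) -> tuple[int, int]:
    if span is None:
        span = (params.start_index, matrix.n_snps)
    start, stop = int(span[0]), int(span[1])
    if not (0 <= start < stop <= matrix.n_snps):
        raise ValueError(f"span [{start}, {stop}) outside matrix with {matrix.n_snps} SNPs")
    return start, stop


def eligible_chromosomes(
    matrix: HaplotypeMatrix,
    params: CongruenceParams,
    span: tuple[int, int] | None = None,
) -> np.ndarray:
    """Indices of chromosomes whose MISSING fraction within ``span`` is
    at most ``params.max_missing_fraction``."""
    start, stop = _resolve_span(matrix, params, span)
    sub = matrix.alleles[:, start:stop]
    frac = (sub == MISSING).mean(axis=1)
    # tolerate float fuzz so a cap of e.g. 0.25 keeps an exactly-25% row
    return np.flatnonzero(frac <= params.max_missing_fraction + 1e-12)


def window_mismatches(
    chrom_row: np.ndarray, consensus: np.ndarray, window_span: tuple[int, int]
) -> int:
    """Mismatch count in ``window_span``; MISSING alleles contribute zero."""
    s, e = window_span
    sub = np.asarray(chrom_row)[s:e]
    cons = np.asarray(consensus)[s:e]
    return int(((sub != cons) & (sub != MISSING)).sum())


def _modal_codes(
    alleles: np.ndarray, survivors: np.ndarray, s: int, e: int
) -> np.ndarray:
    """Most frequent complete allele string among survivors in columns [s, e).

    Survivors with a MISSING cell inside the window are left out of the
    frequency count (they remain survivors).  Ties break to the
    lexicographically smallest string under the alphabet order; if no
    survivor is complete, falls back to the per-column modal non-missing
    allele (column ties likewise break low).
    """
    sub = alleles[np.asarray(survivors), s:e]
    complete = ~(sub == MISSING).any(axis=1)
    if complete.any():
        rows = sub[complete]
        uniq, counts = np.unique(rows, axis=0, return_counts=True)
        # np.unique sorts rows lexicographically, so among the maximal-count
        # candidates the first is the smallest.
        best = counts.max()
        for i in range(len(uniq)):
            if counts[i] == best:
                return uniq[i].copy()
    out = np.empty(e - s, dtype=np.int16)
    for j in range(e - s):
        col = sub[:, j]
        col = col[col != MISSING]
        if col.size == 0:
            raise UnresolvableConsensusError(
                f"every survivor is missing at SNP column {s + j}"
            )
        vals, counts = np.unique(col, return_counts=True)
        out[j] = vals[counts == counts.max()].min()
    return out


def modal_string(
    matrix: HaplotypeMatrix,
    survivors: Sequence[int],
    window_span: tuple[int, int],
) -> str:
    """Most frequent allele string among ``survivors`` over ``window_span``.

    Returned as concatenated symbols (intended for single-character allele
    codes; use :func:`_modal_codes` for the raw code array).
    """
    survivors = np.asarray(sorted(survivors), dtype=np.intp)
    if survivors.size == 0:
        raise ValueError("survivors must be non-empty")
    s, e = window_span
    if not (0 <= s < e <= matrix.n_snps):
        raise ValueError(f"window [{s}, {e}) outside matrix")
    codes = _modal_codes(matrix.alleles, survivors, s, e)
    return "".join(matrix.alphabet[c] for c in codes)


def derive_consensus(
    matrix: HaplotypeMatrix,
    params: CongruenceParams | None = None,
    span: tuple[int, int] | None = None,
) -> ConsensusResult:
    """Run the iterative consensus/filter loop over ``span``.

    See the module docstring for the algorithm.  The consensus is derived
    from the *current survivors* only: once a chromosome is filtered out it
    no longer influences the emerging consensus, which makes the consensus
    self-reinforcing around the dominant extended haplotype.

    Raises
    ------
    NoEligibleChromosomesError
        If the missingness cap excludes every chromosome.
    UnresolvableConsensusError
        If some column has no non-missing survivor allele.
    ConsensusDepletedError
        If every survivor is filtered out before the consensus covers the
        span (cannot happen while at least one complete chromosome equals
        the consensus; observed only on unstructured inputs).
    """
    params = params or CongruenceParams()
    start, stop = _resolve_span(matrix, params, span)
    L = stop - start
    A = matrix.alleles[:, start:stop]
    n = A.shape[0]

    elig_idx = eligible_chromosomes(matrix, params, (start, stop))
    if elig_idx.size == 0:
        raise NoEligibleChromosomesError("missingness cap excluded every chromosome")
    excluded = np.ones(n, dtype=bool)
    excluded[elig_idx] = False

    W = params.derivation_window
    N = params.record_length
    F = params.filter_window
    O = params.filter_offset
    budget = F - params.min_matches

    survivors = elig_idx.copy()
    consensus = np.empty(L, dtype=np.int16)
    built = 0
    p = 0  # derivation-window start, relative to span start
    next_fs = 0  # next unevaluated filter-window start on the lattice

    while built < L:
        w_end = min(p + W, L)
        modal = _modal_codes(A, survivors, p, w_end)
        take = min(N, L - built)
        consensus[built : built + take] = modal[:take]
        built += take

        # evaluate every filter window now fully covered by the consensus;
        # once the consensus is complete, also the short tail windows
        fails = np.zeros(survivors.size, dtype=bool)
        while next_fs + F <= built or (built == L and next_fs < L):
            s = next_fs
            e = min(s + F, L)
            sub = A[survivors, s:e]
            mism = ((sub != consensus[s:e]) & (sub != MISSING)).sum(axis=1)
            fails |= mism > budget
            next_fs += O
        if fails.any():
            survivors = survivors[~fails]
            if survivors.size == 0 and built < L:
                raise ConsensusDepletedError(
                    f"all chromosomes filtered out after {built}/{L} consensus SNPs"
                )
        p += N

    congruent = np.zeros(n, dtype=bool)
    congruent[survivors] = True

    identity = np.full(n, np.nan)
    sub = A[elig_idx]
    nonmiss = (sub != MISSING).sum(axis=1)
    matches = ((sub == consensus) & (sub != MISSING)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(nonmiss > 0, 100.0 * matches / np.maximum(nonmiss, 1), np.nan)
    identity[elig_idx] = vals

    percent = 100.0 * congruent.sum() / elig_idx.size
    return ConsensusResult(
        span=(start, stop),
        consensus=consensus,
        alphabet=matrix.alphabet,
        congruent=congruent,
        excluded=excluded,
        identity_pct=identity,
        percent_congruent=float(percent),
        params=params,
    )


def allele_identity(
    chrom_row: np.ndarray, consensus: np.ndarray, span: tuple[int, int] | None = None
) -> float:
    """Percent of non-missing alleles equal to the consensus over ``span``.

    Returns NaN when every position in the span is missing.
    """
    row = np.asarray(chrom_row)
    cons = np.asarray(consensus)
    if span is not None:
        s, e = span
        row = row[s:e]
        cons = cons[s:e]
    if row.shape != cons.shape:
        raise ValueError("chromosome row and consensus spans differ in length")
    nonmiss = row != MISSING
    denom = int(nonmiss.sum())
    if denom == 0:
        return float("nan")
    return 100.0 * int((nonmiss & (row == cons)).sum()) / denom


def identity_matrix(
    matrix: HaplotypeMatrix,
    consensus: np.ndarray,
    span: tuple[int, int] | None = None,
) -> np.ndarray:
    """Grid [n_chromosomes x span length] coded MATCH/MISMATCH/ID_MISSING."""
    if span is None:
        span = (0, matrix.n_snps)
    s, e = span
    sub = matrix.alleles[:, s:e]
    cons = np.asarray(consensus)
    if cons.shape[0] != e - s:
        raise ValueError("consensus does not cover the span")
    out = np.full(sub.shape, MISMATCH, dtype=np.int8)
    out[sub == cons] = MATCH
    out[sub == MISSING] = ID_MISSING
    return out
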