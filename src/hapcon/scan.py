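"""Rolling congruence scans and candidate-region calling.

Percent congruence is recomputed independently inside sliding fixed-width
SNP windows (default 250 SNPs, starts every 50 SNPs), producing a profile
along a chromosome.  Candidate extended-haplotype regions are maximal runs
of at least ``min_contiguous`` lattice-adjacent windows whose congruence
strictly exceeds a cohort-wide percentile threshold (default the 99th
percentile of all observations for that cohort).

The window lattice is uniform: starts at SNP 1, 1+offset, 1+2*offset, ...
(1-based, per chromosome); partial windows at the chromosome end are not
emitted, so every observation summarises the same number of SNPs and the
percentile threshold compares like with like.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import CongruenceParams, derive_consensus
from .matrix import GeneticMap, HaplotypeMatrix


@dataclass(frozen=True)
class RollingWindow:
    """Congruence observed in one fixed-width window.

    ``start_index``/``end_index`` are 1-based inclusive SNP indices within
    the window's chromosome.
    """

    chrom: str
    start_index: int
    end_index: int
    start_bp: int
    end_bp: int
    n_eligible: int
    n_congruent: int
    percent_congruent: float


@dataclass(frozen=True)
class CandidateRegion:
    """A merged run of contiguous above-threshold windows."""

    cohort: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    length_mb: float
    n_windows: int
    max_percent_congruent: float


def window_starts(n_snps: int, window_snps: int, offset_snps: int) -> list[int]:
    """0-based start indices of the uniform window lattice.

    Windows extending past the last SNP are dropped, so the count is
    ``floor((n_snps - window_snps) / offset_snps) + 1``.
    """
    if window_snps > n_snps:
        raise ValueError(f"window of {window_snps} SNPs exceeds the {n_snps}-SNP matrix")
    if offset_snps < 1:
        raise ValueError("offset_snps must be >= 1")
    return list(range(0, n_snps - window_snps + 1, offset_snps))


def _chrom_runs(matrix: HaplotypeMatrix) -> list[tuple[str, int, int]]:
    """Contiguous (chrom, start, stop) column runs in SNP order."""
    runs: list[tuple[str, int, int]] = []
    chroms = matrix.snp_chroms
    i = 0
    while i < len(chroms):
        j = i
        while j < len(chroms) and chroms[j] == chroms[i]:
            j += 1
        runs.append((chroms[i], i, j))
        i = j
    return runs


def rolling_congruence(
    matrix: HaplotypeMatrix,
    window_snps: int = 250,
    offset_snps: int = 50,
    params: CongruenceParams | None = None,
) -> list[RollingWindow]:
    """Percent congruence per sliding window, per chromosome.

    Each window's congruence comes from a full, independent consensus
    derivation restricted to that window (the start site is the window
    start).  Windows that do not fit before a chromosome's last SNP are
    dropped.
    """
    params = params or CongruenceParams()
    positions = matrix.positions
    out: list[RollingWindow] = []
    for chrom, lo, hi in _chrom_runs(matrix):
        if hi - lo < window_snps:
            continue
        for s_local in window_starts(hi - lo, window_snps, offset_snps):
            s = lo + s_local
            e = s + window_snps
            res = derive_consensus(matrix, params, span=(s, e))
            out.append(
                RollingWindow(
                    chrom=chrom,
                    start_index=s_local + 1,
                    end_index=s_local + window_snps,
                    start_bp=int(positions[s]),
                    end_bp=int(positions[e - 1]),
                    n_eligible=res.n_eligible,
                    n_congruent=res.n_congruent,
                    percent_congruent=res.percent_congruent,
                )
            )
    if not out:
        raise ValueError("no chromosome holds a full window")
    return out


def percentile_threshold(values: Sequence[float], q: float) -> float:
    """Linear-interpolation percentile of ``values`` (the numpy default)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot take a percentile of an empty list")
    if not 0 <= q <= 100:
        raise ValueError("percentile must be in [0, 100]")
    return float(np.percentile(values, q, method="linear"))


def detect_candidate_regions(
    windows: Sequence[RollingWindow],
    threshold: float,
    min_contiguous: int = 2,
    cohort: str = "all",
) -> list[CandidateRegion]:
    """Merge maximal runs of lattice-adjacent windows above ``threshold``.

    "Above" is strict (>).  Contiguity means consecutive start indices on
    the lattice differ by exactly the scan offset (inferred from the window
    list); a single below-threshold window breaks a run.  Runs shorter than
    ``min_contiguous`` windows are discarded.
    """
    windows = list(windows)
    regions: list[CandidateRegion] = []
    # infer the lattice offset from consecutive windows of the same chrom
    diffs = [
        b.start_index - a.start_index
        for a, b in zip(windows, windows[1:])
        if a.chrom == b.chrom and b.start_index > a.start_index
    ]
    offset = min(diffs) if diffs else None

    run: list[RollingWindow] = []

    def flush() -> None:
        if len(run) >= min_contiguous:
            first, last = run[0], run[-1]
            regions.append(
                CandidateRegion(
                    cohort=cohort,
                    chrom=first.chrom,
                    start_bp=first.start_bp,
                    end_bp=last.end_bp,
                    n_snps=last.end_index - first.start_index + 1,
                    length_mb=(last.end_bp - first.start_bp) / 1e6,
                    n_windows=len(run),
                    max_percent_congruent=max(w.percent_congruent for w in run),
                )
            )
        run.clear()

    for w in windows:
        if w.percent_congruent > threshold:
            adjacent = (
                run
                and run[-1].chrom == w.chrom
                and offset is not None
                and w.start_index - run[-1].start_index == offset
            )
            if not adjacent:
                flush()
            run.append(w)
        else:
            flush()
    flush()
    return regions


def max_recomb_per_window(
    windows: Sequence[RollingWindow], gmap: GeneticMap
) -> pd.DataFrame:
    """Maximum recombination rate among map entries inside each window.

    Windows with no map entry get NaN.
    """
    rows = []
    for w in windows:
        rates = gmap.rates_in(w.chrom, w.start_bp, w.end_bp)
        rows.append(
            {
                "chrom": w.chrom,
                "start_bp": w.start_bp,
                "end_bp": w.end_bp,
                "percent_congruent": w.percent_congruent,
                "max_rate_cM_per_Mb": float(rates.max()) if rates.size else np.nan,
            }
        )
    return pd.DataFrame(rows)


def quadrant_classify(
    cong: Sequence[float],
    recomb: Sequence[float],
    cong_q: float = 90.0,
    recomb_q: float = 10.0,
) -> pd.DataFrame:
    """Label windows by joint congruence/recombination percentile position.

    A window is "high congruence" when its congruence strictly exceeds the
    ``cong_q``-th percentile of all congruence values, and "high
    recombination" when its rate strictly exceeds the ``recomb_q``-th
    percentile of all rates.  Windows in the (high, high) quadrant — high
    congruence despite appreciable recombination — are flagged, since low
    haplotype diversity there cannot be explained by suppressed
    recombination alone.
    """
    cong = np.asarray(cong, dtype=float)
    recomb = np.asarray(recomb, dtype=float)
    if cong.shape != recomb.shape:
        raise ValueError("congruence and recombination vectors differ in length")
    cong_thr = float(np.nanpercentile(cong, cong_q))
    recomb_thr = float(np.nanpercentile(recomb, recomb_q))
    high_c = cong > cong_thr
    high_r = recomb > recomb_thr
    return pd.DataFrame(
        {
            "high_congruence": high_c,
            "high_recombination": high_r,
            "flagged": high_c & high_r,
        }
    )


def windows_to_frame(windows: Sequence[RollingWindow]) -> pd.DataFrame:
    """Scan report: one row per window."""
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start_index": [w.start_index for w in windows],
            "end_index": [w.end_index for w in windows],
            "start_bp": [w.start_bp for w in windows],
            "end_bp": [w.end_bp for w in windows],
            "n_eligible": [w.n_eligible for w in windows],
            "n_congruent": [w.n_congruent for w in windows],
            "percent_congruent": [w.percent_congruent for w in windows],
        }
    )


def frame_to_windows(frame: pd.DataFrame) -> list[RollingWindow]:
    """Inverse of :func:`windows_to_frame` (used by the CLI)."""
    return [
        RollingWindow(
            chrom=str(r.chrom),
            start_index=int(r.start_index),
            end_index=int(r.end_index),
            start_bp=int(r.start_bp),
            end_bp=int(r.end_bp),
            n_eligible=int(r.n_eligible),
            n_congruent=int(r.n_congruent),
            percent_congruent=float(r.percent_congruent),
        )
        for r in frame.itertuples()
    ]


def regions_to_frame(regions: Sequence[CandidateRegion]) -> pd.DataFrame:
    """Region report: cohort, chrom, bp bounds, length in Mb and SNPs."""
    return pd.DataFrame(
        {
            "cohort": [r.cohort for r in regions],
            "chrom": [r.chrom for r in regions],
            "start_bp": [r.start_bp for r in regions],
            "end_bp": [r.end_bp for r in regions],
            "length_mb": [round(r.length_mb, 6) for r in regions],
            "n_snps": [r.n_snps for r in regions],
            "n_windows": [r.n_windows for r in regions],
            "max_percent_congruent": [r.max_percent_congruent for r in regions],
        }
    )
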