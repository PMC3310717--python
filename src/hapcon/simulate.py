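"""Synthetic phased-haplotype matrices with planted extended haplotypes.

The generator emulates the structure the congruence algorithm is built
for: a subset of chromosomes (*carriers*) share one founder haplotype
over a planted span, degraded by genotyping error, missing/unphased
calls, and optional recombination-style breakpoints after which a carrier
continues on a background haplotype.  Non-carriers are drawn from a small
pool of background founder haplotypes, so even the background exhibits
repeated haplotypes, as real cohorts do.

Ground truth (carrier flags, breakpoints, the planted string) is returned
alongside the matrix, making parameter-recovery experiments possible
without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import MISSING, ChromosomeMeta, HaplotypeMatrix, SnpRecord


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    Defaults mirror a dense SNP panel over a region with a common extended
    haplotype: a 0/1 (major/minor) alphabet, a carrier fraction of 0.6,
    0.01 per-allele genotyping-error probability, 8 distinct background
    founder haplotypes, and a 1 kb uniform marker spacing.
    """

    n_chromosomes: int
    n_snps: int
    alphabet: tuple[str, ...] = ("0", "1")
    carrier_fraction: float = 0.6
    planted_span: tuple[int, int] | None = None  # default: whole matrix
    n_background: int = 8
    error_rate: float = 0.01
    missing_rate: float = 0.0
    breakpoint_rate: float = 0.0
    chrom: str = "chr1"
    bp_start: int = 1_000_000
    bp_step: int = 1_000
    group: str | None = None
    case_fraction: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("carrier_fraction", "error_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.breakpoint_rate < 0:
            raise ValueError("breakpoint_rate must be >= 0")
        if self.n_background < 1:
            raise ValueError("n_background must be >= 1")
        if len(self.alphabet) < 2:
            raise ValueError("alphabet needs at least 2 symbols")


@dataclass
class SimTruth:
    """Ground truth for one simulated matrix."""

    carrier: np.ndarray  # bool per chromosome
    breakpoints: list[list[int]]  # per-chromosome SNP indices (0-based)
    founder_haplotype: str  # planted allele string over the planted span

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chromosome_index": np.arange(len(self.carrier)),
                "carrier": self.carrier,
                "breakpoints": [
                    ",".join(map(str, b)) for b in self.breakpoints
                ],
            }
        )


def simulate_matrix(config: SimConfig) -> tuple[HaplotypeMatrix, SimTruth]:
    """Generate a matrix plus ground truth, deterministically per seed.

    Carriers copy the founder haplotype over the planted span; breakpoints,
    error flips and missingness are then applied in that order.  Errors
    flip an allele to a uniformly random *different* symbol (a bit-flip for
    the binary alphabet).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, L = cfg.n_chromosomes, cfg.n_snps
    k = len(cfg.alphabet)
    span = cfg.planted_span or (0, L)
    s0, s1 = span
    if not 0 <= s0 < s1 <= L:
        raise ValueError(f"planted_span {span} outside [0, {L})")

    n_carriers = round(cfg.carrier_fraction * n)
    if cfg.carrier_fraction > 0 and n_carriers == 0:
        raise ValueError(
            "carrier_fraction > 0 but rounds to zero carriers; increase n_chromosomes"
        )

    founder = rng.integers(0, k, size=L, dtype=np.int16)
    pool = rng.integers(0, k, size=(cfg.n_background, L), dtype=np.int16)
    base_choice = rng.integers(0, cfg.n_background, size=n)
    grid = pool[base_choice].copy()

    carrier = np.zeros(n, dtype=bool)
    carrier[rng.choice(n, size=n_carriers, replace=False)] = True
    grid[carrier, s0:s1] = founder[s0:s1]

    breakpoints: list[list[int]] = [[] for _ in range(n)]
    if cfg.breakpoint_rate > 0:
        for i in np.flatnonzero(carrier):
            n_bp = rng.poisson(cfg.breakpoint_rate)
            if n_bp == 0:
                continue
            # breakpoints strictly inside the planted span
            if s1 - s0 < 2:
                continue
            pts = sorted(set(rng.integers(s0 + 1, s1, size=n_bp).tolist()))
            breakpoints[i] = pts
            for pt in pts:
                bg = pool[rng.integers(0, cfg.n_background)]
                grid[i, pt:s1] = bg[pt:s1]

    if cfg.error_rate > 0:
        flip = rng.random(grid.shape) < cfg.error_rate
        # add a random nonzero shift mod k: uniform over the other symbols
        shift = rng.integers(1, k, size=grid.shape, dtype=np.int16)
        grid = np.where(flip, (grid + shift) % k, grid).astype(np.int16)

    if cfg.missing_rate > 0:
        grid[rng.random(grid.shape) < cfg.missing_rate] = MISSING

    snps = [
        SnpRecord(id=f"snp{j + 1}", chrom=cfg.chrom, pos_bp=cfg.bp_start + j * cfg.bp_step)
        for j in range(L)
    ]
    statuses: list[str] = []
    for i in range(n):
        if cfg.case_fraction is None:
            statuses.append("unknown")
        else:
            statuses.append("case" if rng.random() < cfg.case_fraction else "control")
    chromosomes = [
        ChromosomeMeta(
            sample_id=f"S{i // 2 + 1:04d}",
            hap_index=i % 2 + 1,
            group=cfg.group,
            status=statuses[i],
        )
        for i in range(n)
    ]
    matrix = HaplotypeMatrix(grid, cfg.alphabet, snps, chromosomes)
    truth = SimTruth(
        carrier=carrier,
        breakpoints=breakpoints,
        founder_haplotype="".join(cfg.alphabet[c] for c in founder[s0:s1]),
    )
    return matrix, truth


def write_truth_table(truth: SimTruth, path: str | Path) -> None:
    """Write ground truth as TSV (header comment carries the planted string)."""
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        fh.write(f"# founder_haplotype={truth.founder_haplotype}\n")
        truth.to_frame().to_csv(fh, sep="\t", index=False)
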