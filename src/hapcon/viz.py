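"""Allele-identity plots, rolling-congruence tracks, and heat-map export.

Allele-identity plots use the field's visual convention: one column per
chromosome, one row per SNP; yellow cells match the consensus, blue cells
mismatch, white cells are missing/unphased, and congruent chromosomes get
a tick mark under their column.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import ListedColormap

from .core import ID_MISSING, MATCH, MISMATCH
from .scan import RollingWindow


@dataclass(frozen=True)
class PlotSpec:
    """Output path and styling for plots.

    The image format follows the path suffix (.png/.svg/.pdf).  Colors map
    MATCH/MISMATCH/MISSING cells; reference lines (value, linestyle) are
    drawn per cohort on rolling plots.
    """

    path: str | Path
    match_color: str = "gold"
    mismatch_color: str = "tab:blue"
    missing_color: str = "white"
    congruence_ticks: bool = True
    reference_styles: tuple[str, ...] = ("solid", "dotted", "dashed")

    def __post_init__(self) -> None:
        if len({self.match_color, self.mismatch_color, self.missing_color}) != 3:
            raise ValueError("MATCH/MISMATCH/MISSING colors must be distinct")


def _display_array(identity_grid: np.ndarray) -> np.ndarray:
    """Transpose the coded grid to plot orientation (rows = SNPs, columns =
    chromosomes) and remap codes to colormap indices 0/1/2."""
    tgrid = np.asarray(identity_grid).T
    display = np.empty(tgrid.shape, dtype=np.int8)
    display[tgrid == MISMATCH] = 0
    display[tgrid == MATCH] = 1
    display[tgrid == ID_MISSING] = 2
    return display


def _identity_figure(
    identity_grid: np.ndarray, congruent_flags: Sequence[bool], spec: PlotSpec
):
    grid = np.asarray(identity_grid)
    if grid.size == 0:
        raise ValueError("identity grid is empty")
    flags = np.asarray(congruent_flags, dtype=bool)
    if flags.shape[0] != grid.shape[0]:
        raise ValueError("congruent flags not aligned with grid rows")
    display = _display_array(grid)
    cmap = ListedColormap([spec.mismatch_color, spec.match_color, spec.missing_color])
    n_snps, n_chrom = display.shape
    fig, ax = plt.subplots(figsize=(max(3, n_chrom / 8), max(3, n_snps / 60)))
    ax.imshow(display, cmap=cmap, vmin=0, vmax=2, aspect="auto", interpolation="none")
    if spec.congruence_ticks:
        xs = np.flatnonzero(flags)
        ax.plot(xs, np.full(xs.shape, n_snps - 0.5), marker=7, linestyle="none",
                color="black", markersize=6, clip_on=False)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("SNP")
    ax.set_xticks([])
    ax.set_yticks([])
    return fig


def plot_identity(
    identity_grid: np.ndarray,
    congruent_flags: Sequence[bool],
    spec: PlotSpec,
) -> Path:
    """Render an allele-identity plot and save it to ``spec.path``.

    ``identity_grid`` is the [n_chromosomes x n_snps] coded grid from
    :func:`hapcon.core.identity_matrix`; it is transposed for display so
    columns are chromosomes and rows are SNPs.  Tick marks appear under
    exactly the congruent columns.
    """
    fig = _identity_figure(identity_grid, congruent_flags, spec)
    path = Path(spec.path)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return path


def _rolling_figure(
    series: Mapping[str, Sequence[RollingWindow]],
    thresholds: Mapping[str, float],
    spec: PlotSpec,
):
    if not series:
        raise ValueError("need at least one cohort series")
    fig, ax = plt.subplots(figsize=(8, 3.5))
    for k, (cohort, windows) in enumerate(series.items()):
        mid = [(w.start_bp + w.end_bp) / 2 for w in windows]
        pct = [w.percent_congruent for w in windows]
        ax.plot(mid, pct, label=cohort)
        if cohort in thresholds:
            style = spec.reference_styles[k % len(spec.reference_styles)]
            ax.axhline(thresholds[cohort], linestyle=style, color="grey")
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("percent congruent")
    ax.set_ylim(0, 100)
    ax.legend(loc="upper right", fontsize="small")
    return fig


def plot_rolling(
    series: Mapping[str, Sequence[RollingWindow]],
    thresholds: Mapping[str, float],
    spec: PlotSpec,
) -> Path:
    """Rolling-congruence track: percent congruent vs window midpoint (bp).

    One line per cohort plus one horizontal percentile reference line per
    cohort (solid for the first cohort, dotted for the second, ...).
    """
    fig = _rolling_figure(series, thresholds, spec)
    path = Path(spec.path)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return path


def export_identity_table(
    identity_grid: np.ndarray,
    path: str | Path,
    snp_ids: Sequence[str] | None = None,
    chromosome_ids: Sequence[str] | None = None,
) -> None:
    """Write the identity grid as a heat-map-ready TSV.

    Rows are SNPs, columns are chromosomes; cells are 1 (match), 0
    (mismatch) or NA (missing).  A leading comment line records the coding.
    """
    grid = np.asarray(identity_grid)
    n_chrom, n_snps = grid.shape
    if chromosome_ids is None:
        chromosome_ids = [f"chrom{i + 1}" for i in range(n_chrom)]
    if snp_ids is None:
        snp_ids = [f"snp{j + 1}" for j in range(n_snps)]
    cells = grid.T.astype(float)
    cells[grid.T == ID_MISSING] = np.nan
    frame = pd.DataFrame(cells, index=list(snp_ids), columns=list(chromosome_ids))
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        fh.write("# cell codes: 1 = match, 0 = mismatch, NA = missing\n")
        frame.to_csv(fh, sep="\t", na_rep="NA", float_format="%.0f", index_label="snp")


def read_identity_table(path: str | Path) -> np.ndarray:
    """Read back an exported identity table as the coded grid
    (chromosomes x SNPs, NA -> ID_MISSING)."""
    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    grid = frame.to_numpy(dtype=float).T
    out = np.full(grid.shape, ID_MISSING, dtype=np.int8)
    out[grid == 1] = MATCH
    out[grid == 0] = MISMATCH
    return out
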