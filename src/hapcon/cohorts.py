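"""Group-stratified congruence tables and paired profile comparison.

Chromosomes are stratified into haplotype groups (e.g. by shared HLA
alleles); congruence is computed independently per group, so one group's
result never depends on another's membership.  Groups below a size floor
(default 10 chromosomes) are skipped — percent congruence of a handful of
chromosomes is not meaningful.  Case/control tallies count congruent
chromosomes by disease status; chromosomes of unknown status are left out
of all four counts.

Two groups' rolling-congruence profiles over the same window lattice are
compared with a paired two-sided Wilcoxon signed-rank test.  Note the
windows of an overlapping lattice are not independent observations; the
p-value should be read as a descriptive contrast, not a calibrated
genome-wide test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import CongruenceParams, ConsensusResult, derive_consensus
from .matrix import HaplotypeMatrix


@dataclass(frozen=True)
class GroupCongruenceRow:
    group: str
    n_chromosomes: int
    n_congruent: int
    percent_congruent: float
    mean_identity_pct: float
    median_identity_pct: float
    n_case: int
    n_control: int
    n_case_congruent: int
    n_control_congruent: int


class CaseControlTally(NamedTuple):
    n_case_congruent: int
    n_control_congruent: int
    n_case: int
    n_control: int


class WilcoxonComparison(NamedTuple):
    statistic: float
    p_value: float
    mean_a: float
    mean_b: float


def case_control_tally(
    result: ConsensusResult, statuses: Sequence[str]
) -> CaseControlTally:
    """Count congruent chromosomes by case/control status.

    Chromosomes with unknown status are excluded from all four counts, so
    the congruent tallies sum to ``result.n_congruent`` only when every
    status is known.
    """
    statuses = list(statuses)
    if len(statuses) != len(result.congruent):
        raise ValueError("statuses not aligned with result")
    case = np.array([s == "case" for s in statuses])
    control = np.array([s == "control" for s in statuses])
    cong = result.congruent
    return CaseControlTally(
        n_case_congruent=int((case & cong).sum()),
        n_control_congruent=int((control & cong).sum()),
        n_case=int(case.sum()),
        n_control=int(control.sum()),
    )


def group_congruence_table(
    matrix: HaplotypeMatrix,
    params: CongruenceParams | None = None,
    span: tuple[int, int] | None = None,
    min_group_size: int = 10,
) -> pd.DataFrame:
    """One row per haplotype group with >= ``min_group_size`` chromosomes.

    Consensus derivation runs independently within each group over ``span``.
    Identity summaries (mean/median) are over the group's *congruent*
    chromosomes only.  Rows are sorted by descending percent congruent.
    """
    params = params or CongruenceParams()
    groups: dict[str, list[int]] = {}
    for i, meta in enumerate(matrix.chromosomes):
        if meta.group is not None:
            groups.setdefault(meta.group, []).append(i)

    rows: list[GroupCongruenceRow] = []
    for label in sorted(groups):
        idx = groups[label]
        if len(idx) < min_group_size:
            continue
        sub = matrix.subset_chromosomes(idx)
        res = derive_consensus(sub, params, span)
        tally = case_control_tally(res, [c.status for c in sub.chromosomes])
        ident = res.identity_pct[res.congruent]
        rows.append(
            GroupCongruenceRow(
                group=label,
                n_chromosomes=len(idx),
                n_congruent=res.n_congruent,
                percent_congruent=res.percent_congruent,
                mean_identity_pct=float(np.nanmean(ident)) if ident.size else np.nan,
                median_identity_pct=float(np.nanmedian(ident)) if ident.size else np.nan,
                n_case=tally.n_case,
                n_control=tally.n_control,
                n_case_congruent=tally.n_case_congruent,
                n_control_congruent=tally.n_control_congruent,
            )
        )
    if not rows:
        warnings.warn(
            f"no group reaches the size floor of {min_group_size} chromosomes",
            stacklevel=2,
        )
    frame = pd.DataFrame([r.__dict__ for r in rows])
    if len(frame):
        frame = frame.sort_values(
            "percent_congruent", ascending=False, kind="stable"
        ).reset_index(drop=True)
    return frame


def compare_rolling_wilcoxon(
    series_a: Sequence[float], series_b: Sequence[float]
) -> WilcoxonComparison:
    """Two-sided Wilcoxon signed-rank test on paired congruence profiles.

    Zero differences are dropped (Wilcoxon's convention); the exact null
    distribution is used when at most 25 nonzero differences remain,
    otherwise the normal approximation with continuity correction.  The
    statistic is the smaller signed-rank sum.  Also returns the two series
    means.  All-zero differences give p = 1.0 with a warning.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired series differ in length")
    if a.size < 6:
        raise ValueError("need at least 6 paired windows")
    diffs = a - b
    if np.all(diffs == 0):
        warnings.warn("all paired differences are zero; p-value is 1", stacklevel=2)
        return WilcoxonComparison(0.0, 1.0, float(a.mean()), float(b.mean()))
    n_eff = int(np.count_nonzero(diffs))
    method = "exact" if n_eff <= 25 else "approx"
    try:
        res = stats.wilcoxon(
            a, b, zero_method="wilcox", correction=True,
            alternative="two-sided", method=method,
        )
    except ValueError:
        # exact method rejects tied ranks in some scipy versions
        res = stats.wilcoxon(
            a, b, zero_method="wilcox", correction=True,
            alternative="two-sided", method="approx",
        )
    return WilcoxonComparison(
        float(res.statistic), float(res.pvalue), float(a.mean()), float(b.mean())
    )
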