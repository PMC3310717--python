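"""Consensus derivation, fuzzy filtering and allele-identity scoring."""

import numpy as np
import pytest
from helpers import build_matrix
from hypothesis import assume, given
from hypothesis import strategies as st
from oracle import naive_congruence

from hapcon import (
    ID_MISSING,
    MATCH,
    MISMATCH,
    CongruenceParams,
    HapconError,
    NoEligibleChromosomesError,
    UnresolvableConsensusError,
    allele_identity,
    derive_consensus,
    eligible_chromosomes,
    identity_matrix,
    modal_string,
    window_mismatches,
)
from hapcon.matrix import MISSING

SMALL = CongruenceParams(
    derivation_window=4, record_length=2, filter_window=3, min_matches=2
)


class TestEligibility:
    def test_default_cap_keeps_all(self):
        m = build_matrix(["0101", "????", "01?1"])
        idx = eligible_chromosomes(m, CongruenceParams())
        assert list(idx) == [0, 1, 2]

    def test_cap_excludes_heavily_missing(self):
        # 40% missing vs a 25% cap
        m = build_matrix(["0110101101", "01?01?1?01", "0?10?01?0?"])
        params = CongruenceParams(max_missing_fraction=0.25)
        assert list(eligible_chromosomes(m, params)) == [0]

    def test_cap_matches_direct_missing_scan(self):
        rng = np.random.default_rng(11)
        rows = [
            "".join(rng.choice(["0", "1", "?"], size=40, p=[0.48, 0.48, 0.04]))
            for _ in range(12)
        ]
        m = build_matrix(rows)
        params = CongruenceParams(max_missing_fraction=0.10)
        expected = [i for i, r in enumerate(rows) if r.count("?") / 40 <= 0.10]
        assert list(eligible_chromosomes(m, params)) == expected

    def test_empty_span_is_error(self):
        m = build_matrix(["01", "10"])
        with pytest.raises(ValueError):
            eligible_chromosomes(m, CongruenceParams(), span=(1, 1))


class TestModalString:
    def test_unanimous_window(self):
        m = build_matrix(["ACGT", "ACGT", "ACGT"])
        assert modal_string(m, [0, 1, 2], (0, 3)) == "ACG"

    def test_majority_wins(self):
        m = build_matrix(["ACG", "ACG", "ACG", "ACT", "ACT"])
        assert modal_string(m, range(5), (0, 3)) == "ACG"

    def test_tie_breaks_lexicographically(self):
        m = build_matrix(["AA", "AA", "CC", "CC"])
        assert modal_string(m, range(4), (0, 2)) == "AA"

    def test_incomplete_rows_skip_frequency_count(self):
        # the '?' row would change the majority if counted column-wise
        m = build_matrix(["AC", "GT", "GT", "A?"])
        assert modal_string(m, range(4), (0, 2)) == "GT"

    def test_columnwise_fallback_when_no_complete_row(self):
        m = build_matrix(["A?", "?T", "?T"])
        assert modal_string(m, range(3), (0, 2)) == "AT"

    def test_all_missing_column_raises(self):
        m = build_matrix(["A?", "C?"])
        with pytest.raises(UnresolvableConsensusError):
            modal_string(m, range(2), (0, 2))


@pytest.mark.parametrize(
    "row,cons,expected",
    [
        ("0101", "0101", 0),  # identical
        ("??" * 15, "01" * 15, 0),  # all missing is vacuously matched
        # 30-SNP window: 5 mismatches, 10 missing, 15 matches -> 5
        ("1" * 5 + "?" * 10 + "0" * 15, "0" * 30, 5),
    ],
)
def test_window_mismatches_ignores_missing(row, cons, expected):
    m = build_matrix([row])
    cons_codes = build_matrix([cons]).alleles[0]
    assert window_mismatches(m.alleles[0], cons_codes, (0, len(row))) == expected


class TestAlleleIdentity:
    def test_identical_is_100(self):
        m = build_matrix(["0101"])
        assert allele_identity(m.alleles[0], m.alleles[0]) == 100.0

    def test_large_span_two_decimal_value(self):
        # 1818 positions with 9 mismatches: 1809/1818 = 99.50% (2 dp)
        cons = np.zeros(1818, dtype=np.int16)
        row = cons.copy()
        row[:9] = 1
        assert round(allele_identity(row, cons), 2) == 99.50

    def test_missing_excluded_from_denominator(self):
        cons = np.zeros(10, dtype=np.int16)
        row = cons.copy()
        row[3] = MISSING
        row[7] = MISSING
        assert allele_identity(row, cons) == 100.0

    def test_all_missing_is_nan(self):
        cons = np.zeros(4, dtype=np.int16)
        row = np.full(4, MISSING, dtype=np.int16)
        assert np.isnan(allele_identity(row, cons))


class TestDeriveConsensus:
    def test_identical_chromosomes_all_congruent(self):
        rng = np.random.default_rng(0)
        hap = "".join(rng.choice(["0", "1"], size=120))
        m = build_matrix([hap] * 5)
        res = derive_consensus(m)  # defaults W=30 N=10 F=30 M=20 O=1
        assert res.congruent.all()
        assert res.percent_congruent == 100.0
        assert np.all(res.identity_pct == 100.0)
        assert res.consensus_string == hap

    def test_single_chromosome_is_congruent(self):
        m = build_matrix(["01101101"])
        res = derive_consensus(m, SMALL)
        assert res.congruent[0]
        assert res.identity_pct[0] == 100.0

    def test_shared_haplotype_recovered_from_noise(self):
        # 8 of 10 chromosomes share one haplotype with <=2 scattered
        # mismatches each; 2 are i.i.d. random
        rng = np.random.default_rng(42)
        hap = rng.integers(0, 2, size=120)
        rows = []
        for _ in range(8):
            r = hap.copy()
            for pos in rng.choice(120, size=2, replace=False):
                r[pos] = 1 - r[pos]
            rows.append("".join(map(str, r)))
        for _ in range(2):
            rows.append("".join(map(str, rng.integers(0, 2, size=120))))
        m = build_matrix(rows)
        res = derive_consensus(m)
        assert list(res.congruent) == [True] * 8 + [False] * 2
        assert res.consensus_string == "".join(map(str, hap))
        # independent straight-line re-execution agrees
        cons_o, cong_o, _ = naive_congruence(rows, 30, 10, 30, 20, 1)
        assert res.consensus_string == cons_o
        assert set(np.flatnonzero(res.congruent)) == cong_o

    def test_two_iteration_mechanics_small_parameters(self):
        # derivation window 9, record 3, filter window 3 needing 2 matches,
        # offset 1: scattered single mismatches survive, a 3-SNP burst and
        # an unrelated chromosome are eliminated
        rows = [
            "010110101101",
            "010110101101",
            "010110101101",
            "010110101101",
            "010010101101",  # one mismatch at SNP 4
            "011000101101",  # burst at SNPs 3-5
            "101001010010",  # unrelated
        ]
        params = CongruenceParams(
            derivation_window=9, record_length=3, filter_window=3, min_matches=2
        )
        res = derive_consensus(build_matrix(rows), params)
        assert res.consensus_string == "010110101101"
        assert list(res.congruent) == [True] * 5 + [False, False]
        assert res.percent_congruent == pytest.approx(100 * 5 / 7)

    def test_excluded_chromosomes_never_congruent(self):
        rows = ["01011010", "01011010", "0?0?1?1?"]
        params = CongruenceParams(
            derivation_window=4, record_length=2, filter_window=3,
            min_matches=2, max_missing_fraction=0.25,
        )
        res = derive_consensus(build_matrix(rows), params)
        assert res.excluded[2] and not res.congruent[2]
        assert np.isnan(res.identity_pct[2])
        # percent congruent is over eligible chromosomes only
        assert res.percent_congruent == 100.0

    def test_no_eligible_chromosome_raises(self):
        m = build_matrix(["??", "??"])
        with pytest.raises(NoEligibleChromosomesError):
            derive_consensus(
                m, CongruenceParams(
                    derivation_window=2, record_length=1, filter_window=2,
                    min_matches=1, max_missing_fraction=0.4,
                )
            )

    def test_span_restriction_changes_scope(self):
        rows = ["0000" + "1111", "0000" + "0000"]
        params = CongruenceParams(
            derivation_window=4, record_length=2, filter_window=4, min_matches=4
        )
        res = derive_consensus(build_matrix(rows), params, span=(0, 4))
        assert res.congruent.all()
        assert res.span == (0, 4)
        assert len(res.consensus) == 4


class TestIdentityMatrix:
    def test_identical_matrix_all_match(self):
        m = build_matrix(["0101", "0101"])
        res = derive_consensus(m, SMALL)
        grid = identity_matrix(m, res.consensus, res.span)
        assert (grid == MATCH).all()

    def test_missing_cell_coded_missing(self):
        m = build_matrix(["0101", "01?1"])
        res = derive_consensus(m, SMALL)
        grid = identity_matrix(m, res.consensus, res.span)
        assert grid[1, 2] == ID_MISSING
        assert (grid != ID_MISSING).sum() == 7

    def test_mismatch_counts_agree_with_allele_identity(self):
        rng = np.random.default_rng(5)
        rows = [
            "".join(rng.choice(["0", "1", "?"], size=30, p=[0.45, 0.45, 0.1]))
            for _ in range(6)
        ]
        m = build_matrix(rows)
        res = derive_consensus(
            m,
            CongruenceParams(
                derivation_window=6, record_length=3, filter_window=4, min_matches=1
            ),
        )
        grid = identity_matrix(m, res.consensus, res.span)
        for i in range(6):
            nonmiss = (grid[i] != ID_MISSING).sum()
            matches = (grid[i] == MATCH).sum()
            ident = allele_identity(m.alleles[i], res.consensus)
            if nonmiss:
                assert ident == pytest.approx(100.0 * matches / nonmiss)


# ---------------------------------------------------------------------------
# invariants

binary_rows = st.integers(2, 6).flatmap(
    lambda n: st.integers(8, 24).flatmap(
        lambda L: st.lists(
            st.text(alphabet="01", min_size=L, max_size=L), min_size=n, max_size=n
        )
    )
)


def _run(rows, params):
    try:
        return derive_consensus(build_matrix(rows), params)
    except HapconError:
        return None


@given(binary_rows)
def test_determinism(rows):
    """Identical inputs and parameters give identical results."""
    params = CongruenceParams(
        derivation_window=5, record_length=2, filter_window=4, min_matches=2
    )
    r1 = _run(rows, params)
    assume(r1 is not None)
    r2 = _run(rows, params)
    assert np.array_equal(r1.consensus, r2.consensus)
    assert np.array_equal(r1.congruent, r2.congruent)
    assert np.array_equal(r1.identity_pct, r2.identity_pct, equal_nan=True)


@given(binary_rows, st.randoms(use_true_random=False))
def test_row_permutation_invariance(rows, rnd):
    """Permuting chromosomes permutes flags and leaves the consensus fixed."""
    params = CongruenceParams(
        derivation_window=5, record_length=2, filter_window=4, min_matches=2
    )
    base = _run(rows, params)
    assume(base is not None)
    perm = list(range(len(rows)))
    rnd.shuffle(perm)
    permuted = _run([rows[i] for i in perm], params)
    assume(permuted is not None)
    assert permuted.consensus_string == base.consensus_string
    assert list(permuted.congruent) == [base.congruent[i] for i in perm]


@given(binary_rows)
def test_duplication_invariance(rows):
    """Duplicating every chromosome changes neither consensus nor flags."""
    params = CongruenceParams(
        derivation_window=5, record_length=2, filter_window=4, min_matches=2
    )
    base = _run(rows, params)
    assume(base is not None)
    doubled = _run([r for r in rows for _ in (0, 1)], params)
    assume(doubled is not None)
    assert doubled.consensus_string == base.consensus_string
    expected = [f for f in base.congruent for _ in (0, 1)]
    assert list(doubled.congruent) == expected
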