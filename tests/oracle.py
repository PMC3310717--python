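"""Independent brute-force re-implementation of the congruence loop.

Operates on plain Python strings ('?' = missing) with straight-line loops
and dict counting — no numpy, no shared code with the package.  Used as
the second route in equivalence tests.
"""

from __future__ import annotations


def naive_congruence(
    rows: list[str],
    W: int,
    N: int,
    F: int,
    M: int,
    O: int = 1,
    max_missing: float = 1.0,
) -> tuple[str, set[int], list[int]]:
    """Return (consensus, congruent indices, eligible indices).

    Raises ValueError on an unresolvable column or if every survivor is
    eliminated before the consensus covers the span.
    """
    span_len = len(rows[0])
    eligible = [
        i for i, r in enumerate(rows) if r.count("?") / span_len <= max_missing + 1e-12
    ]
    if not eligible:
        raise ValueError("no eligible chromosomes")
    survivors = list(eligible)
    consensus = ""
    next_start = 0
    p = 0
    budget = F - M
    while len(consensus) < span_len:
        w_end = min(p + W, span_len)
        complete = [rows[i][p:w_end] for i in survivors if "?" not in rows[i][p:w_end]]
        if complete:
            counts: dict[str, int] = {}
            for s in complete:
                counts[s] = counts.get(s, 0) + 1
            best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        else:
            best = ""
            for c in range(p, w_end):
                col = [rows[i][c] for i in survivors if rows[i][c] != "?"]
                if not col:
                    raise ValueError(f"unresolvable column {c}")
                cnt: dict[str, int] = {}
                for a in col:
                    cnt[a] = cnt.get(a, 0) + 1
                best += sorted(cnt.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        take = min(N, span_len - len(consensus))
        consensus += best[:take]

        failed: set[int] = set()
        while True:
            if next_start + F <= len(consensus):
                s, e = next_start, next_start + F
            elif len(consensus) == span_len and next_start < span_len:
                s, e = next_start, span_len
            else:
                break
            for i in survivors:
                mism = sum(
                    1
                    for c in range(s, e)
                    if rows[i][c] != "?" and rows[i][c] != consensus[c]
                )
                if mism > budget:
                    failed.add(i)
            next_start += O
        survivors = [i for i in survivors if i not in failed]
        if not survivors and len(consensus) < span_len:
            raise ValueError("all survivors eliminated")
        p += N
    return consensus, set(survivors), eligible


def naive_identity(row: str, consensus: str) -> float:
    """Percent of non-missing alleles equal to the consensus (NaN if none)."""
    nonmiss = [i for i, a in enumerate(row) if a != "?"]
    if not nonmiss:
        return float("nan")
    hits = sum(1 for i in nonmiss if row[i] == consensus[i])
    return 100.0 * hits / len(nonmiss)
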