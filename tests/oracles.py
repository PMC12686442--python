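"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's implementation paths: motif
classification is re-derived by explicit enumeration of anchors,
compositions and single-residue substitutions; the enrichment score is
evaluated position by position; hypergeometric tails are enumerated over all
draw outcomes.
"""

from __future__ import annotations

import itertools
from math import comb

HYDRO = set("FILV")
POS = set("KR")
NEG = set("ED")
PHOSPHO = set("STY")
STANDARD = set("ACDEFGHIKLMNPQRSTVWY")


def _counts_ok(residues: str) -> bool:
    h = sum(r in HYDRO for r in residues)
    p = sum(r in POS for r in residues)
    n = sum(r in NEG for r in residues)
    return h + p + n == 4 and 1 <= h <= 2 and 1 <= p <= 2 and n == 1


def brute_force_classify(window: str) -> set[tuple[str, str, int | None]]:
    """Every (class, anchor_terminus, window-relative ptm position) a 5-mer
    admits, by explicit enumeration."""
    w = window.upper()
    assert len(w) == 5
    if any(c not in STANDARD for c in w):
        return set()
    out: set[tuple[str, str, int | None]] = set()
    for terminus, a_idx in (("left", 0), ("right", 4)):
        rest_idx = [i for i in range(5) if i != a_idx]
        rest = "".join(w[i] for i in rest_idx)
        if w[a_idx] == "Q":
            if _counts_ok(rest):
                out.add(("canonical", terminus, None))
            else:
                # try substituting each S/T/Y by each acidic residue in turn
                for i in rest_idx:
                    if w[i] in PHOSPHO:
                        for acid in NEG:
                            sub = "".join(acid if j == i else w[j] for j in rest_idx)
                            if _counts_ok(sub):
                                out.add(("phospho_generated", terminus, i))
        elif w[a_idx] == "K":
            if _counts_ok(rest):
                out.add(("acetyl_generated", terminus, a_idx))
    return out


def brute_force_scan(sequence: str) -> list[tuple[int, str, str, int | None]]:
    """(start, class, terminus, absolute ptm position) for every window."""
    seq = sequence.upper()
    hits = []
    for start in range(len(seq) - 4):
        for cls, term, ptm in sorted(
            brute_force_classify(seq[start : start + 5]),
            key=lambda c: (c[0], c[1], -1 if c[2] is None else c[2]),
        ):
            hits.append((start, cls, term, None if ptm is None else start + ptm))
    return hits


def exhaustive_canonical_count() -> int:
    """Number of canonical 5-mers among all 20^5, by closed-form counting.

    Q at one terminus, remaining four residues an arrangement of h hydrophobic
    (4 letters), p positive (2), 1 negative (2) with (h,p) in {(2,1),(1,2)}.
    A window cannot be canonical at both termini (the second Q would be an
    unclassed residue), so the two anchor sides are disjoint.
    """
    from math import factorial

    per_side = 0
    for h, p in ((2, 1), (1, 2)):
        arrangements = factorial(4) // (factorial(h) * factorial(p) * factorial(1))
        per_side += arrangements * (4**h) * (2**p) * 2  # residue choices per class
    return 2 * per_side


def running_sum_es(ranked_ids, scores, members, exponent) -> float:
    """Evaluate the running sum at every position; return the signed max
    deviation."""
    n = len(ranked_ids)
    in_set = [g in set(members) for g in ranked_ids]
    nr = sum(abs(s) ** exponent for g, s in zip(ranked_ids, scores) if g in set(members))
    n_miss = n - sum(in_set)
    total, best = 0.0, 0.0
    for g, s, hit in zip(ranked_ids, scores, in_set):
        if hit:
            total += (abs(s) ** exponent) / nr if nr > 0 else 1.0 / sum(in_set)
        else:
            total -= 1.0 / n_miss
        if abs(total) > abs(best):
            best = total
    return best


def hypergeom_upper_tail(n_background: int, n_set: int, n_query: int, k_obs: int) -> float:
    """P(X >= k_obs) by enumerating every possible overlap count."""
    total = comb(n_background, n_query)
    acc = 0
    for k in range(k_obs, min(n_set, n_query) + 1):
        acc += comb(n_set, k) * comb(n_background - n_set, n_query - k)
    return acc / total


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided p by full enumeration of the conditional table set:
    sum the probabilities of all tables (fixed margins) no more likely than
    the observed one."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def table_p(x: int) -> float:
        return comb(row1, x) * comb(row2, col1 - x) / comb(n, col1)

    p_obs = table_p(a)
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    return sum(table_p(x) for x in range(lo, hi + 1) if table_p(x) <= p_obs * (1 + 1e-9))
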