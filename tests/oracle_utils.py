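"""Independent brute-force oracles used by the tests.

These deliberately re-derive results from first principles (exhaustive
loops, closed forms, full enumeration) without touching the library's own
search or ranking code paths.
"""

from itertools import combinations
from math import comb

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def oracle_explanations(junction_top, assay):
    """Exhaustive loop over all (trim, trim, insertion) tuples, re-checked
    by string equality, plus the single-mismatch pairing allele rule.

    Returns a set of (trim_left, trim_right, insertion, mm_pos) tuples.
    """
    J = junction_top
    lt, rt = assay.left_top, assay.right_top
    R = assay.right_end.overhang
    max_t1 = min(assay.max_deletion, len(lt) - len(assay.left_anchor))
    max_t2 = min(assay.max_deletion, len(rt) - len(assay.right_anchor))
    found = set()
    for t1 in range(max_t1 + 1):
        u = lt[: len(lt) - t1]
        for t2 in range(max_t2 + 1):
            v = rt[t2:]
            mid = len(J) - len(u) - len(v)
            if mid < 0 or mid > assay.max_insertion:
                continue
            ins = J[len(u): len(u) + mid]
            if u + ins + v == J:
                found.add((t1, t2, ins, None))
    # one tolerated pairing mismatch, junction letter = bottom-strand allele
    if len(J) > len(rt) and J.endswith(rt):
        u_len = len(J) - len(rt)
        t1 = len(lt) - u_len
        if 0 <= t1 <= max_t1:
            u0 = lt[:u_len]
            diffs = [i for i in range(u_len) if u0[i] != J[i]]
            if len(diffs) == 1:
                i = diffs[0]
                e = u_len - 1 - i
                def match(m):
                    return (u_len - 1 - m >= 0 and m < len(R)
                            and u0[u_len - 1 - m] == _COMP[R[m]])
                if (
                    e < len(R) - 1
                    and J[i] == _COMP[R[e]]
                    and all(match(m) for m in range(e))
                    and match(e + 1)
                ):
                    found.add((t1, 0, "", i))
    return found


def oracle_rank_key(expl):
    """The parsimony total order, restated independently."""
    ins = expl.insertion_top
    return (
        expl.trim_left_prot + expl.trim_right_rec + len(ins),
        -expl.mh_len,
        expl.mismatches_in_pairing,
        1 if (ins and not expl.templated_top) else 0,
        expl.trim_left_prot,
        expl.trim_right_rec,
        ins,
        -1 if expl.mm_pos is None else expl.mm_pos,
    )


def mann_whitney_enumeration(a, b):
    """Exact two-sided Mann-Whitney p by full enumeration of labelings.

    Requires no ties across the pooled sample.  Returns (U_a, p).
    """
    pooled = sorted(a) + sorted(b)
    assert len(set(a) | set(b)) == len(a) + len(b), "oracle requires no ties"
    na, nb = len(a), len(b)

    # U directly from its definition: pairs (x in A, y in B) with x > y
    def u_stat(xs, ys):
        return sum(1 for x in xs for y in ys if x > y)

    u_obs = u_stat(a, b)
    us = []
    for idx in combinations(range(na + nb), na):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(na + nb) if i not in set(idx)]
        us.append(u_stat(xs, ys))
    total = comb(na + nb, na)
    assert len(us) == total
    cdf = sum(1 for u in us if u <= u_obs) / total
    sf = sum(1 for u in us if u >= u_obs) / total
    return u_obs, min(1.0, 2 * min(cdf, sf))


def chi2_textbook(counts_a, counts_b):
    """Pearson chi-square from the textbook formula, no library call."""
    cols = len(counts_a)
    totals_col = [counts_a[j] + counts_b[j] for j in range(cols)]
    keep = [j for j in range(cols) if totals_col[j] > 0]
    na, nb = sum(counts_a), sum(counts_b)
    n = na + nb
    chi2 = 0.0
    for j in keep:
        for row_total, obs in ((na, counts_a[j]), (nb, counts_b[j])):
            exp = row_total * totals_col[j] / n
            chi2 += (obs - exp) ** 2 / exp
    df = (len(keep) - 1) * 1
    return chi2, df


def chi2_2x2_closed_form(a, b, c, d):
    """n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) for the 2x2 table [[a,b],[c,d]]."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    return n * (a * d - b * c) ** 2 / denom
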