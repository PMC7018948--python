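"""Independent brute-force oracles used by the test suite.

These deliberately re-derive expected results from first principles —
window-by-window definition checks for seed sites, exhaustive enumeration
of monotone pairings for local alignment, exact-fraction enumeration for
the Hardy–Weinberg test — and share no code path with the implementation.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import factorial

RC = {"A": "U", "U": "A", "G": "C", "C": "G"}


def revcomp(seq: str) -> str:
    return "".join(RC[b] for b in reversed(seq))


def oracle_seed_sites(seq: str, mirna_seq: str) -> set[tuple[str, int, int]]:
    """Every canonical site by direct window testing with explicit
    exclusions implementing the 8mer > 7mer-m8 > 7mer-A1 > 6mer hierarchy."""
    m6 = revcomp(mirna_seq[1:7])
    m7 = revcomp(mirna_seq[1:8])
    c8 = RC[mirna_seq[7]]
    n = len(seq)
    sites: set[tuple[str, int, int]] = set()
    for i in range(n - 5):
        if seq[i:i + 6] != m6:
            continue
        has_m8 = i >= 1 and seq[i - 1] == c8  # then seq[i-1 : i+6] == m7
        has_a = i + 6 < n and seq[i + 6] == "A"
        if has_m8 and has_a:
            sites.add(("8mer", i - 1, i + 7))
        elif has_m8:
            sites.add(("7mer-m8", i - 1, i + 6))
        elif has_a:
            sites.add(("7mer-A1", i, i + 7))
        else:
            sites.add(("6mer", i, i + 6))
    # consistency: each reported window really matches its definition
    for t, s, e in sites:
        if t == "8mer":
            assert seq[s:e] == m7 + "A"
        elif t == "7mer-m8":
            assert seq[s:e] == m7
        elif t == "7mer-A1":
            assert seq[s:e] == m6 + "A"
        else:
            assert seq[s:e] == m6
    return sites


def _pair_score(mb: str, tb: str, pos: int, params) -> float:
    duo = mb + tb
    if duo in ("AU", "UA", "GC", "CG"):
        s = params.match_score
    elif duo in ("GU", "UG"):
        s = params.wobble_score
    else:
        s = params.mismatch_score
    lo, hi = params.seed_span
    if lo <= pos <= hi:
        s *= params.seed_scale
    return s


def _gap_cost(d: int, params) -> float:
    if d == 0:
        return 0.0
    return params.gap_open + (d - 1) * params.gap_extend


def oracle_local_align_score(mirna_seq: str, target: str, params) -> float:
    """Best local alignment score by exhaustive enumeration.

    Every local alignment is a non-empty monotone matching of miRNA
    positions (3'→5') to target positions (5'→3'); unmatched bases strictly
    between consecutive matched pairs form affine gap runs. The maximum
    over all matchings equals the optimal local alignment score.
    """
    L = len(mirna_seq)
    mrev = mirna_seq[::-1]
    la, lb = len(mrev), len(target)
    best = 0.0
    for k in range(1, min(la, lb) + 1):
        for ia in combinations(range(la), k):
            pos = [L - i for i in ia]  # 1-based miRNA positions
            pair_part = []
            for t in range(k):
                pair_part.append((ia[t], pos[t]))
            for ib in combinations(range(lb), k):
                score = 0.0
                for t in range(k):
                    score += _pair_score(mrev[ia[t]], target[ib[t]], pos[t], params)
                for t in range(k - 1):
                    score += _gap_cost(ia[t + 1] - ia[t] - 1, params)
                    score += _gap_cost(ib[t + 1] - ib[t] - 1, params)
                if score > best:
                    best = score
    return best


def oracle_hwe_exact(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional HWE p-value with exact rational arithmetic."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    nb = 2 * n_bb + n_ab

    def prob(nab: int) -> Fraction:
        naa = (na - nab) // 2
        nbb = (nb - nab) // 2
        num = (
            Fraction(factorial(n), factorial(naa) * factorial(nab) * factorial(nbb))
            * Fraction(2 ** nab)
            * Fraction(factorial(na) * factorial(nb), factorial(2 * n))
        )
        return num

    support = range(na % 2, min(na, nb) + 1, 2)
    probs = {k: prob(k) for k in support}
    p_obs = probs[n_ab]
    return float(min(Fraction(1), sum(p for p in probs.values() if p <= p_obs)))
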