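"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive and self-contained: plain dynamic
programming, pair enumeration and hypergeometric tail sums, sharing no
code path with the package.
"""

from __future__ import annotations

from scipy.stats import hypergeom


def levenshtein_dp(a: str, b: str) -> int:
    """Classic O(len(a)*len(b)) edit-distance table."""
    n, m = len(a), len(b)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (a[i - 1] != b[j - 1]),
            )
        prev = cur
    return prev[m]


def indices_by_enumeration(sequences: dict[str, str]) -> dict:
    """Participation/self-referral/referral percentages from raw pair counts."""
    node: dict[str, int] = {}
    arcs: dict[tuple[str, str], int] = {}
    for seq in sequences.values():
        for ch in seq:
            node[ch] = node.get(ch, 0) + 1
        for i in range(len(seq) - 1):
            pair = (seq[i], seq[i + 1])
            arcs[pair] = arcs.get(pair, 0) + 1
    total = sum(node.values())
    participation = {d: 100.0 * node.get(d, 0) / total for d in "PND"}
    self_ref: dict[str, float | None] = {}
    referral: dict[tuple[str, str], float | None] = {}
    for d in "PND":
        out = sum(c for (a, _), c in arcs.items() if a == d)
        if out == 0:
            self_ref[d] = None
            for e in "PND":
                if e != d:
                    referral[(d, e)] = None
        else:
            self_ref[d] = 100.0 * arcs.get((d, d), 0) / out
            for e in "PND":
                if e != d:
                    referral[(d, e)] = 100.0 * arcs.get((d, e), 0) / out
    return {
        "node": node,
        "arcs": arcs,
        "participation": participation,
        "self_referral": self_ref,
        "referral": referral,
    }


def fisher_two_sided_by_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p: sum of hypergeometric probabilities not exceeding
    the observed table's probability (with the usual relative slack)."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    rv = hypergeom(n, r1, c1)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    p_obs = rv.pmf(a)
    total = 0.0
    for k in range(lo, hi + 1):
        pk = rv.pmf(k)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(total, 1.0)
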