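"""Independent reference implementations used only to check the package.

Each oracle is deliberately written from first principles (brute force,
enumeration, exact combinatorics) and shares no code path with the
implementation it validates.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Dict, List, Sequence, Tuple

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def nussinov_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Maximum number of non-crossing base pairs (Watson-Crick + G:U)."""
    n = len(seq)
    dp = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1][j]
            for k in range(i + min_loop + 1, j + 1):
                if (seq[i], seq[k]) in _PAIRS:
                    left = dp[i + 1][k - 1] if k - 1 > i else 0
                    right = dp[k + 1][j] if k + 1 <= j else 0
                    best = max(best, 1 + left + right)
            dp[i][j] = best
    return dp[0][n - 1] if n else 0


def naive_map(genome: Dict[str, str], tag: str) -> List[Tuple[str, int, str]]:
    """Character-by-character exact search of tag and its reverse complement."""
    rc = "".join(_COMP[c] for c in reversed(tag))
    out = []
    for chrom, seq in genome.items():
        for needle, strand in ((tag, "+"), (rc, "-")):
            for i in range(len(seq) - len(needle) + 1):
                if all(seq[i + k] == needle[k] for k in range(len(needle))):
                    out.append((chrom, i, strand))
    return sorted(out)


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> Fraction:
    """Exact P(X >= k) for a hypergeometric(N, K, n) variable."""
    total = Fraction(0)
    denom = math.comb(N, n)
    for i in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i), denom)
    return total


# ---------------------------------------------------------------------------
# brute-force duplex rule evaluation


def _position_class(x: str, y: str) -> str:
    if _COMP[x] == y:
        return "WC"
    if (x, y) in (("G", "T"), ("T", "G")):
        return "GU"
    return "MM"


def brute_duplex_verdicts(mirna: str, site: str, stack_energy) -> Tuple[bool, ...]:
    """Evaluate the six duplex predicates directly from their definitions.

    *stack_energy(pair_a, pair_b)* returns the stacking term for two
    adjacent pairs given as (miRNA base, opposite base) tuples, or None if
    either position is a mismatch.
    """
    L = len(mirna)
    opposite = site[::-1]
    cls = [_position_class(mirna[i], opposite[i]) for i in range(L)]
    w = {"WC": 0.0, "GU": 0.5, "MM": 1.0}

    r1 = sum(w[c] for c in cls) <= 4.0

    r2 = True
    for i in range(L - 2):
        if cls[i] != "WC" and cls[i + 1] != "WC" and cls[i + 2] != "WC":
            r2 = False

    r3 = True
    for pos in range(2, 12):  # 1-based positions (pos, pos+1) both in 2..12
        if cls[pos - 1] != "WC" and cls[pos] != "WC":
            r3 = False

    r4 = cls[9] == "WC" and cls[10] == "WC"

    r5 = sum(w[c] for c in cls[:12]) <= 2.5

    def energy(m: str, o: str) -> float:
        e = 0.0
        for i in range(len(m) - 1):
            term = stack_energy((m[i], o[i]), (m[i + 1], o[i + 1]))
            if term is not None:
                e += term
        return e

    perfect = energy(mirna, "".join(_COMP[c] for c in mirna))
    actual = energy(mirna, opposite)
    r6 = (abs(actual) / abs(perfect) if perfect else 0.0) >= 0.74

    return r1, r2, r3, r4, r5, r6
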