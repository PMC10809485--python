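"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths (and Biopython's
codon table): the genetic code is spelled out literally, pathway counting
enumerates orderings directly, Fisher p-values use exact rational
arithmetic, and alignment scores come from explicit enumeration of every
global alignment.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import permutations
from math import comb

# Standard genetic code, TCAG ordering, '*' = stop.
_ORDER = "TCAG"
_AA64 = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
GENETIC_CODE = {
    a + b + c: _AA64[16 * i + 4 * j + k]
    for i, a in enumerate(_ORDER)
    for j, b in enumerate(_ORDER)
    for k, c in enumerate(_ORDER)
}
SENSE = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")


def sites_by_enumeration(codon: str) -> tuple[Fraction, Fraction]:
    """(S, N) site fractions of one sense codon, counted one neighbour at
    a time; mutations to stops are nonsynonymous."""
    syn = 0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            neighbour = codon[:pos] + base + codon[pos + 1 :]
            if GENETIC_CODE[neighbour] != "*" and GENETIC_CODE[neighbour] == GENETIC_CODE[codon]:
                syn += 1
    s = Fraction(syn, 3)
    return s, 3 - s


def pathway_counts_by_enumeration(codon_a: str, codon_b: str):
    """Pathway-averaged (Nd, Sd) as exact fractions; None if every ordering
    crosses a stop codon."""
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return Fraction(0), Fraction(0)
    paths = []
    for order in permutations(diff):
        current, nd, sd, ok = codon_a, 0, 0, True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if GENETIC_CODE[nxt] == "*" and nxt != codon_b:
                ok = False
                break
            if GENETIC_CODE[current] == GENETIC_CODE[nxt]:
                sd += 1
            else:
                nd += 1
            current = nxt
        if ok and GENETIC_CODE[current] != "*":
            paths.append((nd, sd))
    if not paths:
        return None
    n = len(paths)
    return (
        Fraction(sum(p[0] for p in paths), n),
        Fraction(sum(p[1] for p in paths), n),
    )


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p as an exact rational: sum of hypergeometric
    probabilities of all same-margin tables no more probable than observed."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return Fraction(1)
    denom = comb(n, c1)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    probs = {
        k: Fraction(comb(r1, k) * comb(n - r1, c1 - k), denom) for k in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return sum((p for p in probs.values() if p <= p_obs), Fraction(0))


def align_score_by_enumeration(
    seq_a: str,
    seq_b: str,
    matrix,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """Best global alignment score by explicit enumeration of all
    alignments; internal gap of length L costs open + extend*L, end gaps
    are free.  ``matrix[(x, y)]`` gives substitution scores."""
    best = [float("-inf")]

    def walk(i, j, score, gap_state, gap_len, leading):
        # gap_state: 0 none, 1 gap in A (insertion), 2 gap in B (deletion)
        if i == len(seq_a) and j == len(seq_b):
            total = score
            if gap_state and not leading:
                # The final run is an end gap: refund its internal cost.
                total += gap_open + gap_extend * gap_len
            if total > best[0]:
                best[0] = total
            return
        if i < len(seq_a) and j < len(seq_b):
            walk(i + 1, j + 1, score + matrix[seq_a[i], seq_b[j]], 0, 0, False)
        if j < len(seq_b):  # gap in A
            lead = leading and i == 0
            cost = 0.0 if lead else (gap_extend if gap_state == 1 else gap_open + gap_extend)
            walk(i, j + 1, score - cost, 1, gap_len + 1 if gap_state == 1 else 1, lead)
        if i < len(seq_a):  # gap in B
            lead = leading and j == 0
            cost = 0.0 if lead else (gap_extend if gap_state == 2 else gap_open + gap_extend)
            walk(i + 1, j, score - cost, 2, gap_len + 1 if gap_state == 2 else 1, lead)

    walk(0, 0, 0.0, 0, 0, True)
    return best[0]
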