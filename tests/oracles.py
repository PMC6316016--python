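"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: translation goes through
Biopython's Seq.translate, diversity through explicit enumeration of allele
pairs, and the NG86 arithmetic is re-derived from scratch.
"""

from __future__ import annotations

import math
from functools import lru_cache
from itertools import combinations, permutations

import numpy as np
from Bio.Seq import Seq

BASES = "ACGT"


@lru_cache(maxsize=None)
def translate(codon: str) -> str:
    return str(Seq(codon).translate())


def is_stop(codon: str) -> bool:
    return translate(codon) == "*"


def sites_oracle(codon: str) -> tuple[float, float]:
    """Enumerate all 9 single-base mutants; stop-creating changes are nonsynonymous."""
    aa = translate(codon)
    syn = 0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if not is_stop(mut) and translate(mut) == aa:
                syn += 1
    return syn / 3, 3 - syn / 3


def diffs_oracle(a: str, b: str) -> tuple[float, float]:
    """Average (sd, nd) over stop-free orderings of the single-base steps."""
    pos = [i for i in range(3) if a[i] != b[i]]
    results = []
    for order in permutations(pos):
        cur, sd, nd = a, 0, 0
        ok = True
        for p in order:
            nxt = cur[:p] + b[p] + cur[p + 1 :]
            if is_stop(nxt):
                ok = False
                break
            if translate(nxt) == translate(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not results:
        raise ValueError("all pathways hit stops")
    return (sum(r[0] for r in results) / len(results),
            sum(r[1] for r in results) / len(results))


def kaks_oracle(seq_a: str, seq_b: str) -> dict:
    """Full NG86 + Jukes-Cantor estimate by direct enumeration."""
    assert len(seq_a) == len(seq_b) and len(seq_a) % 3 == 0
    s_a = s_b = sd = nd = 0.0
    n_codons = len(seq_a) // 3
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        s_a += sites_oracle(ca)[0]
        s_b += sites_oracle(cb)[0]
        d = diffs_oracle(ca, cb)
        sd += d[0]
        nd += d[1]
    s = (s_a + s_b) / 2
    n = 3 * n_codons - s
    ps = sd / s
    pn = nd / n
    ks = -0.75 * math.log(1 - 4 * ps / 3)
    ka = -0.75 * math.log(1 - 4 * pn / 3)
    return {"S": s, "N": n, "Sd": sd, "Nd": nd, "ps": ps, "pn": pn, "ks": ks, "ka": ka,
            "omega": (ka / ks) if ks > 0 else None}


def pi_bruteforce(calls: np.ndarray, positions: np.ndarray, start: int, end: int,
                  window_length: int | None = None) -> float:
    """Mean pairwise per-site differences over all allele-copy pairs.

    calls: (n_sites, n_samples) dosages with -1 missing.  Each diploid
    contributes two allele copies per site; at each site all pairs among the
    non-missing copies are compared and the mean difference count is summed,
    then divided by the window length.
    """
    if window_length is None:
        window_length = end - start
    total = 0.0
    for i in range(calls.shape[0]):
        if not (start <= positions[i] < end):
            continue
        copies: list[int] = []
        for dose in calls[i]:
            if dose < 0:
                continue
            copies.extend([1] * dose + [0] * (2 - dose))
        if len(copies) < 2:
            continue
        pairs = list(combinations(copies, 2))
        total += sum(abs(x - y) for x, y in pairs) / len(pairs)
    return total / window_length


def hudson_fst_oracle(p_a: float, p_b: float, n_a: int, n_b: int) -> float:
    """Single-site Hudson Fst from allele frequencies and haploid sample sizes."""
    within = (2 * p_a * (1 - p_a) * n_a / (n_a - 1) + 2 * p_b * (1 - p_b) * n_b / (n_b - 1)) / 2
    between = p_a * (1 - p_b) + p_b * (1 - p_a)
    return 1 - within / between


def window_count_closed_form(length: int, size: int, step: int) -> int:
    if length < size:
        return 1
    return (length - size) // step + 1
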