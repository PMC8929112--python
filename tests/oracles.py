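"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the implementation: the Viterbi oracle
enumerates every state path by depth-first search, and the diversity oracle
counts pairwise allele differences directly.
"""

from itertools import combinations

import numpy as np

from nlr_atlas.core import AMINO_ACIDS

_M, _I, _D = 0, 1, 2


def brute_force_best_score(hmm, seq):
    """Exhaustive max over all glocal alignments (model fully traversed,
    sequence local with free flanks). Returns (score, start, end) or None."""
    n, L = len(seq), hmm.length
    t = hmm.transitions
    lo = hmm.match_logodds
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}

    def emit(j, i):  # match state j+1 emitting residue seq[i]
        ch = seq[i]
        return 0.0 if ch == "X" else lo[j, aa_index[ch]]

    best = [None]

    def consider(score, start, end):
        if end < start:
            return  # path emitted nothing
        if best[0] is None or score > best[0][0]:
            best[0] = (score, start, end)

    def dfs(block, state, i, score, start):
        # exit once the whole model has been traversed
        if block == L:
            consider(score + t[L, state, _M], start, i)
        # match next block
        if block < L and i < n:
            dfs(block + 1, _M, i + 1,
                score + t[block, state, _M] + emit(block, i), start)
        # delete next block
        if block < L:
            dfs(block + 1, _D, i, score + t[block, state, _D], start)
        # insert at this block (emits background = 0 bits)
        if 1 <= block <= L and i < n:
            dfs(block, _I, i + 1, score + t[block, state, _I], start)

    for s in range(n + 1):
        dfs(0, _M, s, 0.0, s + 1)
    return best[0]


def brute_force_pi(site_alleles, window_length):
    """Mean pairwise differences per bp: for each site a list of 0/1 alleles
    (missing dropped), averaged over all allele pairs, summed over sites."""
    total = 0.0
    for alleles in site_alleles:
        pairs = list(combinations(alleles, 2))
        if not pairs:
            continue
        total += sum(a != b for a, b in pairs) / len(pairs)
    return total / window_length


def diploid_site_alleles(dosages):
    """Expand diploid alt dosages (-1 missing) into 0/1 allele lists."""
    out = []
    for d in dosages:
        if d < 0:
            continue
        out.extend([1] * d + [0] * (2 - d))
    return out
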