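"""NG86 Ka/Ks estimation on aligned coding pairs and Ks-based dating.

The estimator is Nei–Gojobori (1986) counting with the Jukes–Cantor
multiple-hit correction: synonymous site fractions per codon exclude changes
to stop codons from the denominator; codons differing at two or three
positions average the synonymous/nonsynonymous difference counts over all
orderings of minimal substitution pathways, skipping pathways that pass
through a stop codon. Divergence time follows the molecular-clock conversion
T = Ks / (2r), reported in MYA, with the grass synonymous substitution rate
r = 6.1e-9 substitutions/site/year as default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .core import ConfigError, FormatError

NUCLEOTIDES = "TCAG"
CODON_TO_AA = dict(standard_dna_table.forward_table)
STOP_CODONS = set(standard_dna_table.stop_codons)
SENSE_CODONS = tuple(sorted(CODON_TO_AA))  # 61 codons

#: Default synonymous substitution rate (substitutions/site/year).
DEFAULT_RATE = 6.1e-9


@dataclass(frozen=True)
class SubstitutionRate:
    r: float = DEFAULT_RATE

    def __post_init__(self):
        if not self.r > 0:
            raise ConfigError(f"substitution rate must be > 0, got {self.r}")


@dataclass
class CodonAlignmentPair:
    """Two aligned coding sequences, length divisible by 3, codon phase."""

    pair_id: str
    seq1: str
    seq2: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.seq1 = self.seq1.upper()
        self.seq2 = self.seq2.upper()
        if len(self.seq1) != len(self.seq2):
            raise FormatError(f"{self.pair_id}: unequal aligned lengths")
        if len(self.seq1) % 3:
            raise FormatError(f"{self.pair_id}: length not divisible by 3")


@dataclass
class KaKsResult:
    pair_id: str
    ka: float
    ks: float
    ratio: float            # NaN when Ks == 0 (undefined)
    n_sites: float
    s_sites: float
    n_diffs: float
    s_diffs: float
    n_codons: int
    time_mya: float
    saturated: bool = False

    @property
    def ratio_defined(self) -> bool:
        return math.isfinite(self.ratio)


# ------------------------------------------------------------ site counts


@lru_cache(maxsize=None)
def count_sites(codon: str) -> tuple[float, float]:
    """NG86 (nonsynonymous, synonymous) site counts for one sense codon.

    Per position: the synonymous fraction of the three single-nucleotide
    changes, with changes to stop codons excluded from the denominator.
    Always satisfies n + s = 3.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise FormatError(f"stop codon {codon} has no site counts")
    if codon not in CODON_TO_AA:
        raise FormatError(f"not a sense codon: {codon!r}")
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = tot = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            tot += 1
            if CODON_TO_AA[alt] == aa:
                syn += 1
        s += syn / tot if tot else 0.0
    return 3.0 - s, s


@lru_cache(maxsize=None)
def count_differences(codon1: str, codon2: str) -> Optional[tuple[float, float]]:
    """NG86 (nonsynonymous, synonymous) differences between two sense codons.

    Codons differing at k >= 2 positions average over all k! orderings of the
    single-step pathways; pathways through stop codons are skipped. Returns
    None when every pathway hits a stop (the codon pair is then excluded).
    """
    codon1, codon2 = codon1.upper(), codon2.upper()
    diff_pos = [i for i in range(3) if codon1[i] != codon2[i]]
    if not diff_pos:
        return 0.0, 0.0
    n_tot = s_tot = 0.0
    n_paths = 0
    for order in permutations(diff_pos):
        cur = codon1
        nd = sd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            n_tot += nd
            s_tot += sd
            n_paths += 1
    if n_paths == 0:
        return None
    return n_tot / n_paths, s_tot / n_paths


def jukes_cantor(p: float) -> float:
    """JC69 distance d = -(3/4) ln(1 - 4p/3); +inf at saturation p >= 3/4."""
    if p < 0:
        raise ValueError("proportion of differences cannot be negative")
    if p >= 0.75:
        return math.inf
    # max() guards a 1-ulp rounding below p for denormal-scale proportions
    return max(-0.75 * math.log1p(-4.0 * p / 3.0), p)


_SKIP_CHARS = set("-.N")


def kaks(pair: CodonAlignmentPair, rate: SubstitutionRate = SubstitutionRate()
         ) -> KaKsResult:
    """NG86 Ka/Ks for one aligned pair.

    Codons aligned against a gap or containing N in either sequence are
    excluded pairwise, as are stop codons and codon pairs whose every
    substitution pathway crosses a stop. Site counts are averaged over the
    two sequences; proportions are JC-corrected. The ratio is NaN when
    Ks = 0 and the result is flagged saturated when either proportion
    reaches 3/4.
    """
    s1_sites = s2_sites = 0.0
    n1_sites = n2_sites = 0.0
    nd = sd = 0.0
    n_codons = 0
    for i in range(0, len(pair.seq1), 3):
        c1, c2 = pair.seq1[i:i + 3], pair.seq2[i:i + 3]
        if _SKIP_CHARS & (set(c1) | set(c2)):
            continue
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            continue
        if c1 not in CODON_TO_AA or c2 not in CODON_TO_AA:
            raise FormatError(f"{pair.pair_id}: bad codon {c1!r}/{c2!r}")
        diffs = count_differences(c1, c2)
        if diffs is None:
            continue
        n1, s1 = count_sites(c1)
        n2, s2 = count_sites(c2)
        n1_sites += n1
        n2_sites += n2
        s1_sites += s1
        s2_sites += s2
        nd += diffs[0]
        sd += diffs[1]
        n_codons += 1
    if n_codons == 0:
        raise FormatError(f"{pair.pair_id}: no comparable codons")
    n_bar = (n1_sites + n2_sites) / 2.0
    s_bar = (s1_sites + s2_sites) / 2.0
    p_n = nd / n_bar if n_bar > 0 else 0.0
    p_s = sd / s_bar if s_bar > 0 else 0.0
    ka = jukes_cantor(p_n)
    ks = jukes_cantor(p_s)
    saturated = math.isinf(ka) or math.isinf(ks)
    ratio = ka / ks if ks > 0 and math.isfinite(ks) else math.nan
    t = divergence_time(ks, rate) if math.isfinite(ks) else math.inf
    return KaKsResult(pair.pair_id, ka, ks, ratio, n_bar, s_bar, nd, sd,
                      n_codons, t, saturated)


def divergence_time(ks: float, rate: SubstitutionRate | float = DEFAULT_RATE
                    ) -> float:
    """Ks-based divergence time in MYA: T = Ks / (2 r) x 1e-6."""
    r = rate.r if isinstance(rate, SubstitutionRate) else float(rate)
    if not r > 0:
        raise ConfigError(f"substitution rate must be > 0, got {r}")
    if ks < 0:
        raise ValueError("Ks cannot be negative")
    return ks / (2.0 * r) * 1e-6


def ks_histogram(results: list[KaKsResult], bin_width: float = 0.04
                 ) -> tuple[pd.DataFrame, Optional[tuple[float, float]]]:
    """Histogram of finite Ks values; returns (table, modal bin interval)."""
    if not bin_width > 0:
        raise ConfigError("bin width must be positive")
    ks = np.array([r.ks for r in results if math.isfinite(r.ks)])
    if ks.size == 0:
        return (pd.DataFrame(columns=["bin_start", "bin_end", "count"]), None)
    n_bins = int(np.floor(ks.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(ks, bins=edges)
    table = pd.DataFrame({
        "bin_start": edges[:-1], "bin_end": edges[1:], "count": counts,
    })
    peak = int(counts.argmax())
    return table, (float(edges[peak]), float(edges[peak + 1]))


def kaks_table(pairs: list[CodonAlignmentPair],
               rate: SubstitutionRate = SubstitutionRate()) -> pd.DataFrame:
    """Long-format per-pair table of NG86 results."""
    rows = []
    for p in pairs:
        r = kaks(p, rate)
        rows.append({
            "pair_id": r.pair_id, "ka": r.ka, "ks": r.ks, "ka_ks": r.ratio,
            "n_sites": r.n_sites, "s_sites": r.s_sites,
            "n_codons": r.n_codons, "time_mya": r.time_mya,
            "saturated": r.saturated,
        })
    return pd.DataFrame(rows)
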