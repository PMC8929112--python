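"""Windowed nucleotide diversity, Weir–Cockerham Fst, and sweep candidates.

π per window sums the unbiased per-site heterozygosity 2p(1-p)·n/(n-1)
(n = non-missing allele count) over window sites and divides by the window's
covered length in bp, so monomorphic and unobserved positions count as
zero-diversity sites. Fst is the Weir & Cockerham (1984) two-population
estimator, windowed as the ratio of summed variance components (a over
a+b+c); negative estimates are reported as computed.

Candidate sweep windows satisfy the joint rule: π-ratio (wild/domesticated
orientation) at or above its empirical 95th percentile AND Fst at or above
its own 95th percentile, both computed over all defined windows of the
comparison. Candidate windows are merged into swept regions and assigned to
genes by >= 1 bp overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd

from .core import ConfigError, GeneModel, GenotypeMatrix

DEFAULT_WINDOW_SIZE = 50_000
DEFAULT_STEP = 5_000
DEFAULT_QUANTILE = 0.95
MIN_DEFINED_WINDOWS = 20


@dataclass(frozen=True)
class ComparisonSpec:
    """One sweep comparison; numerator is the wild/ancestral-type group."""

    name: str
    group_numerator: str
    group_denominator: str

    def __post_init__(self):
        if self.group_numerator == self.group_denominator:
            raise ConfigError("comparison groups must be distinct")


@dataclass
class SweepWindow:
    chrom: str
    start: int
    end: int
    pi_a: float        # numerator (wild-type) group
    pi_b: float        # denominator (derived) group
    pi_ratio: float    # NaN when undefined
    fst: float
    candidate: bool = False


# ----------------------------------------------------------- statistics


def _pi_site_terms(gm: GenotypeMatrix, group: str) -> np.ndarray:
    """Per-site unbiased heterozygosity 2p(1-p)·n/(n-1); 0 where n < 2."""
    p, n_alleles, _ = gm.group_site_stats(group)
    terms = np.zeros(gm.n_sites)
    ok = n_alleles >= 2
    pn = p[ok]
    na = n_alleles[ok]
    terms[ok] = 2.0 * pn * (1.0 - pn) * na / (na - 1.0)
    return terms


def window_pi(gm: GenotypeMatrix, group: str, window: tuple[str, int, int],
              chrom_length: Optional[int] = None) -> float:
    """Per-site nucleotide diversity of one group over one window."""
    chrom, start, end = window
    if chrom_length is not None:
        end = min(end, chrom_length)
    length = end - start + 1
    if length <= 0:
        raise ConfigError("window length must be positive")
    mask = gm.site_mask(chrom, start, end)
    cols = gm.group_columns(group)
    if mask.any() and (gm.gt[np.ix_(mask, cols)] >= 0).sum() == 0:
        return float("nan")  # group entirely missing in a covered window
    return float(_pi_site_terms(gm, group)[mask].sum() / length)


def _wc_site_components(gm: GenotypeMatrix, group_a: str, group_b: str):
    """Weir–Cockerham (1984) per-site variance components (a, b, c).

    Sites unusable for the estimator (a group without calls, or a 0/0
    indeterminate correction with a single individual per group) get NaN
    components and are excluded from window sums.
    """
    p1, na1, h1 = gm.group_site_stats(group_a)
    p2, na2, h2 = gm.group_site_stats(group_b)
    n1, n2 = na1 / 2.0, na2 / 2.0  # individuals
    usable = (n1 >= 1) & (n2 >= 1)
    r = 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        n_bar = (n1 + n2) / r
        n_c = n1 + n2 - (n1**2 + n2**2) / (n1 + n2)
        p_bar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (n1 + n2)
        inner = p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0
        # 0/0 at n_bar == 1 resolves to 0 (e.g. fixed differences)
        corr = np.where(
            n_bar > 1, inner / np.maximum(n_bar - 1, 1e-300),
            np.where(np.abs(inner) < 1e-12, 0.0, np.nan),
        )
        a = n_bar / n_c * (s2 - corr)
        b = np.where(
            n_bar > 1,
            n_bar / np.maximum(n_bar - 1, 1e-300)
            * (p_bar * (1 - p_bar) - (r - 1) / r * s2
               - (2 * n_bar - 1) / (4 * n_bar) * h_bar),
            np.where(np.abs(inner) < 1e-12, 0.0, np.nan),
        )
        c = h_bar / 2.0
    bad = ~usable
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def window_fst(gm: GenotypeMatrix, group_a: str, group_b: str,
               window: tuple[str, int, int]) -> float:
    """Windowed WC84 Fst as ratio of summed components; NaN if no usable site."""
    chrom, start, end = window
    mask = gm.site_mask(chrom, start, end)
    a, b, c = _wc_site_components(gm, group_a, group_b)
    ok = mask & np.isfinite(a)
    if not ok.any():
        return float("nan")
    denom = (a[ok] + b[ok] + c[ok]).sum()
    if denom == 0:
        return float("nan")
    return float(a[ok].sum() / denom)


def genome_fst(gm: GenotypeMatrix, group_a: str, group_b: str,
               chroms: Optional[list[str]] = None) -> float:
    """Genome-wide (or chromosome-subset) WC84 Fst, ratio of sums."""
    a, b, c = _wc_site_components(gm, group_a, group_b)
    ok = np.isfinite(a)
    if chroms is not None:
        ok &= gm.sites["chrom"].isin(chroms).to_numpy()
    if not ok.any():
        return float("nan")
    denom = (a[ok] + b[ok] + c[ok]).sum()
    return float(a[ok].sum() / denom) if denom != 0 else float("nan")


# ----------------------------------------------------------------- scan


def window_starts(chrom_length: int, window_size: int, step: int) -> np.ndarray:
    """Start coordinates of the sliding tiling (1-based)."""
    n = max(1, (chrom_length - window_size) // step + 1)
    return 1 + step * np.arange(n)


def scan(gm: GenotypeMatrix, spec: ComparisonSpec,
         window_size: int = DEFAULT_WINDOW_SIZE, step: int = DEFAULT_STEP,
         chrom_lengths: Optional[dict[str, int]] = None) -> list[SweepWindow]:
    """All sliding windows with per-group π, π-ratio and Fst.

    Chromosome lengths default to the last observed site per chromosome.
    Ordered by (chrom, start). Windows truncated at chromosome ends keep
    their nominal span but use the covered length for π.
    """
    if not (window_size >= step > 0):
        raise ConfigError("need window_size >= step > 0")
    if chrom_lengths is None:
        chrom_lengths = {
            str(c): int(sub["pos"].max())
            for c, sub in gm.sites.groupby("chrom", sort=False)
        }
    pi_terms_a = _pi_site_terms(gm, spec.group_numerator)
    pi_terms_b = _pi_site_terms(gm, spec.group_denominator)
    a, b, c = _wc_site_components(
        gm, spec.group_numerator, spec.group_denominator)
    wc_ok = np.isfinite(a)
    a0 = np.where(wc_ok, a, 0.0)
    abc0 = np.where(wc_ok, a + b + c, 0.0)

    out: list[SweepWindow] = []
    positions = gm.sites["pos"].to_numpy()
    chrom_arr = gm.sites["chrom"].to_numpy()
    for chrom in sorted(chrom_lengths):
        clen = chrom_lengths[chrom]
        idx = np.flatnonzero(chrom_arr == chrom)
        pos = positions[idx]
        # prefix sums over this chromosome's sites
        cum_a = np.concatenate([[0.0], np.cumsum(pi_terms_a[idx])])
        cum_b = np.concatenate([[0.0], np.cumsum(pi_terms_b[idx])])
        cum_fa = np.concatenate([[0.0], np.cumsum(a0[idx])])
        cum_fd = np.concatenate([[0.0], np.cumsum(abc0[idx])])
        cum_ok = np.concatenate([[0], np.cumsum(wc_ok[idx].astype(int))])
        for start in window_starts(clen, window_size, step):
            end = start + window_size - 1
            covered = min(end, clen) - start + 1
            lo, hi = np.searchsorted(pos, [start, end + 1])
            pi_a = (cum_a[hi] - cum_a[lo]) / covered
            pi_b = (cum_b[hi] - cum_b[lo]) / covered
            ratio = pi_a / pi_b if pi_b > 0 else float("nan")
            n_ok = cum_ok[hi] - cum_ok[lo]
            denom = cum_fd[hi] - cum_fd[lo]
            fst = ((cum_fa[hi] - cum_fa[lo]) / denom
                   if n_ok > 0 and denom != 0 else float("nan"))
            out.append(SweepWindow(chrom, int(start), int(end),
                                   float(pi_a), float(pi_b), float(ratio),
                                   float(fst)))
    return out


def candidate_sweeps(windows: list[SweepWindow],
                     quantile: float = DEFAULT_QUANTILE) -> list[SweepWindow]:
    """Flag windows in the joint top tail of π-ratio and Fst (ties included)."""
    ratios = np.array([w.pi_ratio for w in windows])
    fsts = np.array([w.fst for w in windows])
    defined = np.isfinite(ratios) & np.isfinite(fsts)
    if defined.sum() < MIN_DEFINED_WINDOWS:
        raise ConfigError(
            f"only {int(defined.sum())} windows have defined π-ratio and Fst; "
            f"at least {MIN_DEFINED_WINDOWS} are required for empirical "
            f"quantile thresholds"
        )
    ratio_thr = float(np.quantile(ratios[defined], quantile))
    fst_thr = float(np.quantile(fsts[defined], quantile))
    if ratios[defined].max() == ratios[defined].min() and \
       fsts[defined].max() == fsts[defined].min():
        warnings.warn("degenerate statistic distributions: all defined "
                      "windows tie at the threshold")
    cands = []
    for w, ok, r, f in zip(windows, defined, ratios, fsts):
        w.candidate = bool(ok and r >= ratio_thr and f >= fst_thr)
        if w.candidate:
            cands.append(w)
    return cands


def merge_windows(candidates: list[SweepWindow]
                  ) -> list[tuple[str, int, int]]:
    """Merge overlapping/adjacent candidate windows into swept regions."""
    regions: list[tuple[str, int, int]] = []
    for w in sorted(candidates, key=lambda w: (w.chrom, w.start)):
        if regions and regions[-1][0] == w.chrom and w.start <= regions[-1][2] + 1:
            chrom, s, e = regions[-1]
            regions[-1] = (chrom, s, max(e, w.end))
        else:
            regions.append((w.chrom, w.start, w.end))
    return regions


@dataclass
class SweepGeneAssignment:
    assignments: dict[str, list[SweepWindow]] = field(default_factory=dict)
    regions: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def total_mbp(self) -> float:
        return sum(e - s + 1 for _, s, e in self.regions) / 1e6

    def subgenome_mbp(self) -> dict[str, float]:
        from .core import subgenome_of

        out: dict[str, float] = {}
        for chrom, s, e in self.regions:
            sg = subgenome_of(chrom)
            out[sg] = out.get(sg, 0.0) + (e - s + 1) / 1e6
        return out


def windows_to_genes(candidates: list[SweepWindow],
                     genes: list[GeneModel]) -> SweepGeneAssignment:
    """Genes overlapping >= 1 bp of any candidate window, plus merged regions."""
    result = SweepGeneAssignment(regions=merge_windows(candidates))
    by_chrom: dict[str, list[SweepWindow]] = {}
    for w in candidates:
        by_chrom.setdefault(w.chrom, []).append(w)
    for gene in genes:
        support = [
            w for w in by_chrom.get(gene.chrom, ())
            if w.start <= gene.end and gene.start <= w.end
        ]
        if support:
            result.assignments[gene.gene_id] = support
    return result


def comparison_overlap(gene_sets: dict[str, set[str]]) -> pd.DataFrame:
    """Venn-style subset counts over >= 2 comparisons.

    One row per non-empty subset of comparisons with the genes appearing in
    exactly that subset.
    """
    if len(gene_sets) < 2:
        raise ConfigError("need at least two comparisons")
    names = sorted(gene_sets)
    rows = []
    for k in range(1, len(names) + 1):
        for subset in combinations(names, k):
            inside = set.intersection(*(gene_sets[n] for n in subset))
            outside = set.union(
                *(gene_sets[n] for n in names if n not in subset), set())
            exact = inside - outside
            rows.append({
                "comparisons": "&".join(subset), "n_comparisons": k,
                "count": len(exact), "genes": ",".join(sorted(exact)),
            })
    return pd.DataFrame(rows)


def windows_frame(windows: list[SweepWindow]) -> pd.DataFrame:
    return pd.DataFrame([
        {"chrom": w.chrom, "start": w.start, "end": w.end, "pi_a": w.pi_a,
         "pi_b": w.pi_b, "pi_ratio": w.pi_ratio, "fst": w.fst,
         "candidate": w.candidate}
        for w in windows
    ])
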