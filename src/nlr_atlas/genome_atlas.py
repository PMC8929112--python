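"""Windowed genomic distribution and clustering of identified NLR genes.

The genome is tiled into disjoint windows (default 200 kb) by start
coordinate; a gene belongs to the window containing its start, so counts are
conserved. A window holding at least ``min_count`` NLRs (default 2) is a
gene cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .core import ConfigError, GeneModel

DEFAULT_WINDOW_SIZE = 200_000
DEFAULT_MIN_CLUSTER = 2


@dataclass
class WindowGrid:
    window_size: int
    counts: dict[tuple[str, int], int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def n_windows(self) -> int:
        """Number of windows holding at least one gene."""
        return len(self.counts)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"chrom": c, "window_index": w,
             "start": w * self.window_size + 1,
             "end": (w + 1) * self.window_size,
             "count": n}
            for (c, w), n in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows,
                            columns=["chrom", "window_index", "start", "end", "count"])


@dataclass
class ClusterSet:
    min_count: int
    clusters: list[tuple[str, int, int]]   # (chrom, window_index, count)
    nlr_in_clusters: int
    total_nlrs: int

    @property
    def clustered_fraction(self) -> float:
        return self.nlr_in_clusters / self.total_nlrs if self.total_nlrs else 0.0


def assign_windows(nlrs: list[GeneModel],
                   window_size: int = DEFAULT_WINDOW_SIZE,
                   known_chroms: list[str] | None = None) -> WindowGrid:
    """Assign each gene to the disjoint window containing its start."""
    if not window_size > 0:
        raise ConfigError("window size must be positive")
    if known_chroms is not None:
        unknown = sorted({g.chrom for g in nlrs} - set(known_chroms))
        if unknown:
            raise ConfigError(f"genes on unknown chromosomes: {unknown}")
    grid = WindowGrid(window_size)
    for g in nlrs:
        key = (g.chrom, (g.start - 1) // window_size)
        grid.counts[key] = grid.counts.get(key, 0) + 1
    return grid


def detect_clusters(grid: WindowGrid,
                    min_count: int = DEFAULT_MIN_CLUSTER) -> ClusterSet:
    if min_count < 1:
        raise ConfigError("min_count must be >= 1")
    clusters = [
        (c, w, n) for (c, w), n in sorted(grid.counts.items()) if n >= min_count
    ]
    return ClusterSet(min_count, clusters, sum(n for *_, n in clusters),
                      grid.total)


def _pct(count: int, total: int) -> float:
    """Percent rounded half-up to 2 decimals, from unrounded counts."""
    if total == 0:
        return float("nan")
    return float(
        (Decimal(count) * 100 / Decimal(total)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP)
    )


def subgenome_summary(nlrs: list[GeneModel]) -> pd.DataFrame:
    """Per-subgenome NLR counts with percent of total (2-decimal half-up)."""
    counts: dict[str, int] = {}
    for g in nlrs:
        counts[g.subgenome] = counts.get(g.subgenome, 0) + 1
    total = sum(counts.values())
    return pd.DataFrame(
        [{"subgenome": s, "count": n, "percent": _pct(n, total)}
         for s, n in sorted(counts.items())],
        columns=["subgenome", "count", "percent"],
    )


def chromosome_enrichment(nlrs: list[GeneModel],
                          all_genes: list[GeneModel]) -> pd.DataFrame:
    """Per-chromosome NLR count and percent of that chromosome's genes.

    Chromosomes with zero annotated genes report percent NaN (undefined)
    rather than raising.
    """
    nlr_ids = {g.gene_id for g in nlrs}
    gene_counts: dict[str, int] = {}
    nlr_counts: dict[str, int] = {}
    for g in all_genes:
        gene_counts[g.chrom] = gene_counts.get(g.chrom, 0) + 1
        if g.gene_id in nlr_ids:
            nlr_counts[g.chrom] = nlr_counts.get(g.chrom, 0) + 1
    for g in nlrs:  # NLRs on chromosomes missing from all_genes
        gene_counts.setdefault(g.chrom, 0)
        nlr_counts.setdefault(g.chrom, nlr_counts.get(g.chrom, 0))
    rows = []
    for chrom in sorted(gene_counts):
        n_nlr = nlr_counts.get(chrom, 0)
        n_genes = gene_counts[chrom]
        rows.append({
            "chrom": chrom, "nlr_count": n_nlr, "gene_count": n_genes,
            "percent_of_genes": _pct(n_nlr, n_genes) if n_genes else float("nan"),
        })
    return pd.DataFrame(rows,
                        columns=["chrom", "nlr_count", "gene_count",
                                 "percent_of_genes"])


def cluster_profile(grid: WindowGrid, thresholds=range(2, 6)) -> pd.DataFrame:
    """Clustered-NLR fraction across a range of cluster thresholds."""
    rows = []
    for k in thresholds:
        cs = detect_clusters(grid, k)
        rows.append({
            "min_count": k, "n_clusters": len(cs.clusters),
            "nlr_in_clusters": cs.nlr_in_clusters,
            "clustered_fraction": cs.clustered_fraction,
        })
    return pd.DataFrame(rows)
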