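"""Per-group SNP accounting and the occurrence-rate-of-SNPs (ORS) statistic.

ORS for a gene, group and region (genic span or 2 kb strand-aware promoter)
is the number of group SNPs in the region divided by the number of group
SNPs on the gene's chromosome. "Group SNP" means a site polymorphic within
the group — both alleles observed among the group's non-missing calls — so
diversity contrasts between wild and domesticated groups are meaningful;
counting sites that are simply non-reference is available via
``definition="nonref"``. A site with fewer than two non-missing genotype
calls in a group is uncountable for that group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core import ConfigError, GeneModel, GenotypeMatrix

DEFAULT_PROMOTER_LENGTH = 2000

REGIONS = ("genic", "promoter")


def _group_snp_mask(gm: GenotypeMatrix, group: str,
                    definition: str = "within") -> np.ndarray:
    """Boolean per-site mask of SNPs for a group under the chosen definition."""
    cols = gm.group_columns(group)
    sub = gm.gt[:, cols]
    missing = sub < 0
    n_ind = (~missing).sum(axis=1)
    alt = np.where(missing, 0, sub).sum(axis=1)
    countable = n_ind >= 2
    if definition == "within":
        # both alleles observed among non-missing calls
        poly = (alt > 0) & (alt < 2 * n_ind)
    elif definition == "nonref":
        poly = alt > 0
    else:
        raise ConfigError(f"unknown SNP definition {definition!r}")
    return countable & poly


def group_snp_count(gm: GenotypeMatrix, group: str,
                    region: Optional[tuple[str, int, int]] = None,
                    definition: str = "within") -> int:
    """Number of group SNPs genome-wide or within (chrom, start, end)."""
    mask = _group_snp_mask(gm, group, definition)
    if region is not None:
        chrom, start, end = region
        mask = mask & gm.site_mask(chrom, start, end)
    return int(mask.sum())


def promoter_region(gene: GeneModel,
                    length: int = DEFAULT_PROMOTER_LENGTH,
                    chrom_length: Optional[int] = None) -> tuple[str, int, int]:
    """Strand-aware upstream promoter span, clipped at chromosome edges.

    Returns (chrom, start, end), 1-based closed; at a chromosome edge the
    span may be empty (end < start).
    """
    if gene.strand == "+":
        start = max(1, gene.start - length)
        end = gene.start - 1
    else:
        start = gene.end + 1
        end = gene.end + length
        if chrom_length is not None:
            end = min(chrom_length, end)
    return gene.chrom, start, end


def ors(gene: GeneModel, group: str, region: str, gm: GenotypeMatrix,
        promoter_length: int = DEFAULT_PROMOTER_LENGTH,
        chrom_length: Optional[int] = None,
        definition: str = "within") -> float:
    """ORS of one gene for one group and region; NaN when the chromosome has
    no group SNPs."""
    if region not in REGIONS:
        raise ConfigError(f"region must be one of {REGIONS}")
    denom = group_snp_count(gm, group, (gene.chrom, 1, np.iinfo(np.int64).max),
                            definition)
    if denom == 0:
        return float("nan")
    if region == "genic":
        span = (gene.chrom, gene.start, gene.end)
    else:
        span = promoter_region(gene, promoter_length, chrom_length)
    num = group_snp_count(gm, group, span, definition)
    return num / denom


def ors_table(genes: list[GeneModel], groups: list[str], gm: GenotypeMatrix,
              promoter_length: int = DEFAULT_PROMOTER_LENGTH,
              chrom_lengths: Optional[dict[str, int]] = None,
              definition: str = "within") -> pd.DataFrame:
    """Long-format ORS table over genes x groups x {genic, promoter}.

    Columns: gene_id, group, region, snp_count, chrom_snp_count, ors.
    Vectorised: per-group SNP masks and per-chromosome totals are computed
    once, then gene spans are resolved by binary search on positions.
    """
    pos_by_chrom = {
        chrom: (sub.index.to_numpy(), sub["pos"].to_numpy())
        for chrom, sub in gm.sites.groupby("chrom", sort=False)
    }
    rows = []
    for group in groups:
        mask = _group_snp_mask(gm, group, definition)
        chrom_totals = {
            chrom: int(mask[idx].sum()) for chrom, (idx, _) in pos_by_chrom.items()
        }

        def span_count(chrom, start, end):
            if chrom not in pos_by_chrom or end < start:
                return 0
            idx, pos = pos_by_chrom[chrom]
            lo, hi = np.searchsorted(pos, [start, end + 1])
            return int(mask[idx[lo:hi]].sum())

        for gene in genes:
            denom = chrom_totals.get(gene.chrom, 0)
            clen = (chrom_lengths or {}).get(gene.chrom)
            for region in REGIONS:
                if region == "genic":
                    chrom, start, end = gene.chrom, gene.start, gene.end
                else:
                    chrom, start, end = promoter_region(
                        gene, promoter_length, clen)
                count = span_count(chrom, start, end)
                rows.append({
                    "gene_id": gene.gene_id, "group": group, "region": region,
                    "snp_count": count, "chrom_snp_count": denom,
                    "ors": count / denom if denom else float("nan"),
                })
    return pd.DataFrame(rows, columns=["gene_id", "group", "region",
                                       "snp_count", "chrom_snp_count", "ors"])


def no_snp_fraction(table: pd.DataFrame, groups: list[str],
                    region: str = "genic") -> float:
    """Percent of genes with zero SNPs in *every* listed group, per region."""
    sub = table[(table["region"] == region) & table["group"].isin(groups)]
    if sub.empty:
        raise ConfigError("ORS table has no rows for the requested groups")
    per_gene = sub.groupby("gene_id")["snp_count"].max()
    return 100.0 * float((per_gene == 0).mean())


def private_group_fraction(table: pd.DataFrame, focal_group: str,
                           other_groups: list[str],
                           region: str = "genic") -> float:
    """Percent of genes whose SNPs occur in the focal group and in no listed
    other group (denominator: all genes in the table)."""
    sub = table[table["region"] == region]
    if sub.empty:
        raise ConfigError("empty ORS table")
    counts = sub.pivot_table(index="gene_id", columns="group",
                             values="snp_count", aggfunc="first")
    for g in [focal_group, *other_groups]:
        if g not in counts.columns:
            raise ConfigError(f"group {g!r} absent from table")
    focal_has = counts[focal_group] > 0
    others_have = (counts[list(other_groups)] > 0).any(axis=1)
    return 100.0 * float((focal_has & ~others_have).mean())


@dataclass
class GroupTotals:
    """Per-group genome-wide and per-chromosome SNP totals."""

    table: pd.DataFrame  # columns: group, chrom, snp_count


def group_totals(gm: GenotypeMatrix, groups: Optional[list[str]] = None,
                 definition: str = "within") -> GroupTotals:
    groups = groups or gm.groups
    rows = []
    for group in groups:
        mask = _group_snp_mask(gm, group, definition)
        for chrom, sub in gm.sites.groupby("chrom", sort=False):
            rows.append({"group": group, "chrom": chrom,
                         "snp_count": int(mask[sub.index.to_numpy()].sum())})
    return GroupTotals(pd.DataFrame(rows))


def ors_heatmap_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Wide genes x (group, region) ORS matrix for heatmap-style output."""
    wide = table.pivot_table(index="gene_id", columns=["group", "region"],
                             values="ors", aggfunc="first")
    wide.columns = [f"{g}:{r}" for g, r in wide.columns]
    return wide
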