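"""Shared containers and helpers used across the analysis modules.

Coordinates follow GFF3 conventions internally: 1-based, closed intervals.
BED-style 0-based half-open coordinates appear only in files written by
:mod:`nlr_atlas.io`.
"""

from __future__ import annotations

import re
import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: Amino-acid alphabet used by the profile HMM (X is scored as background).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Chromosome-name pattern; anything that does not match is treated as a
#: scaffold and excluded from gene-level analyses.
CHROM_NAME_PATTERN = r"^chr|^\d+[A-D]$"

_SUBGENOME_RE = re.compile(r"^(?:chr)?\d+([A-D])")


class ConfigError(ValueError):
    """Raised when a configuration value violates its documented bounds."""


class FormatError(ValueError):
    """Raised when an input file or record is structurally invalid."""


def is_chromosome(name: str, pattern: str = CHROM_NAME_PATTERN) -> bool:
    return re.search(pattern, name) is not None


def subgenome_of(chrom: str) -> str:
    """Subgenome label (A/B/D) parsed from a wheat-style chromosome name.

    Unrecognised names (scaffolds, custom chromosome sets) map to ``"U"``.
    """
    m = _SUBGENOME_RE.match(chrom)
    return m.group(1) if m else "U"


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global seed by stable hashing.

    Toggling one pipeline stage must never perturb another stage's random
    stream, so each stage hashes its own name into the global seed.
    """
    return (int(global_seed) ^ zlib.crc32(stage.encode("utf-8"))) % (2**31)


@dataclass(frozen=True)
class GeneModel:
    """One gene's genomic placement (1-based, closed) plus subgenome label."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    subgenome: str = ""

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise FormatError(
                f"{self.gene_id}: invalid span {self.start}-{self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise FormatError(f"{self.gene_id}: strand must be + or -")
        if not self.subgenome:
            object.__setattr__(self, "subgenome", subgenome_of(self.chrom))

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str

    def __post_init__(self):
        if not self.id:
            raise FormatError("protein record with empty id")

    def __len__(self) -> int:
        return len(self.sequence)


class GenotypeMatrix:
    """Biallelic sites x samples diploid genotype matrix with a group panel.

    ``gt`` holds alt-allele dosage per individual (0, 1, 2) with -1 for a
    missing call. The panel maps every sample to a (group, lineage) pair.
    """

    def __init__(
        self,
        sites: pd.DataFrame,
        gt: np.ndarray,
        samples: list[str],
        panel: pd.DataFrame,
        metadata: Optional[dict] = None,
    ):
        gt = np.asarray(gt, dtype=np.int8)
        if gt.shape != (len(sites), len(samples)):
            raise FormatError(
                f"genotype shape {gt.shape} != (sites={len(sites)}, "
                f"samples={len(samples)})"
            )
        missing = set(samples) - set(panel.index)
        if missing:
            raise FormatError(f"samples missing from panel: {sorted(missing)[:5]}")
        for chrom, sub in sites.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if len(pos) > 1 and not np.all(np.diff(pos) > 0):
                raise FormatError(
                    f"positions not strictly increasing on {chrom}"
                )
        self.sites = sites.reset_index(drop=True)
        self.gt = gt
        self.samples = list(samples)
        self.panel = panel
        self.metadata = dict(metadata or {})
        self._col_of = {s: i for i, s in enumerate(self.samples)}

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def groups(self) -> list[str]:
        return list(pd.unique(self.panel["group"]))

    def group_columns(self, group: str) -> np.ndarray:
        names = self.panel.index[self.panel["group"] == group]
        if len(names) == 0:
            raise KeyError(f"unknown group: {group!r}")
        return np.array([self._col_of[s] for s in names if s in self._col_of])

    def site_mask(self, chrom: str, start: Optional[int] = None,
                  end: Optional[int] = None) -> np.ndarray:
        mask = (self.sites["chrom"] == chrom).to_numpy()
        if start is not None:
            mask &= self.sites["pos"].to_numpy() >= start
        if end is not None:
            mask &= self.sites["pos"].to_numpy() <= end
        return mask

    def group_site_stats(self, group: str):
        """Per-site (alt frequency, allele count, observed het) for a group.

        Sites where the group has no non-missing call get frequency NaN and
        allele count 0.
        """
        cols = self.group_columns(group)
        sub = self.gt[:, cols]
        missing = sub < 0
        n_ind = (~missing).sum(axis=1)
        alt = np.where(missing, 0, sub).sum(axis=1)
        n_alleles = 2 * n_ind
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            het = np.where(n_ind > 0, (sub == 1).sum(axis=1) / np.maximum(n_ind, 1), np.nan)
        return p, n_alleles, het


@dataclass
class ExpressionMatrix:
    """Genes x samples TPM-scale matrix plus the sample design sheet."""

    values: pd.DataFrame
    design: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if (self.values.to_numpy() < 0).any():
            raise FormatError("expression values must be non-negative")
        missing = set(self.values.columns) - set(self.design.index)
        if missing:
            raise FormatError(
                f"samples without a design row: {sorted(missing)[:5]}"
            )

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns
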