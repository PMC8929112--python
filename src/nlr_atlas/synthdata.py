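"""Synthetic inputs with known ground truth for every analysis stage.

The generator replaces the external resources a real run would use (an
annotated hexaploid genome, population resequencing genotypes, syntenic
pairs, inoculation transcriptomes) with desk-scale equivalents:

* gene models whose NLR subset carries the bundled NB-ARC seed consensus,
  placed with density increasing toward chromosome ends when
  ``telomere_bias`` > 0;
* biallelic diploid genotypes under a Balding–Nichols allele-frequency
  model (per-group beta draws around an ancestral frequency, parameterised
  by the divergence F), with planted low-diversity sweep regions produced
  by shrinking the derived group's heterozygosity by a known factor;
* codon-sequence pairs evolved from a common ancestor by event-level
  (Gillespie) simulation under a GY-style codon model with equal codon
  frequencies, so the true dN/dS and the realised substitution events are
  recorded as ground truth;
* TPM matrices with designed condition/timepoint/tissue effects on chosen
  responsive gene sets and multiplicative log-normal replicate noise.

Identical configurations (including seed) give byte-identical outputs; all
randomness flows through per-component seeds derived from ``cfg.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (ConfigError, ExpressionMatrix, GeneModel, GenotypeMatrix,
                   ProteinRecord, subgenome_of)
from .molevo import CODON_TO_AA, CodonAlignmentPair, SENSE_CODONS, STOP_CODONS

AA = "ACDEFGHIKLMNPQRSTVWY"

#: Planted class motifs; must match the regex rules in data/motifs.yaml.
CLASS_MOTIFS = {
    "TIR-NLR": "FLSFRGEDT",
    "CCR-NLR": "CADLQEL",
    "CC-NLR": "EDVID",
}
LRR_MOTIF = "LADLNLSHNKL"


@dataclass(frozen=True)
class GroupSpec:
    """One population group: sample size, optional π target, divergence F."""

    name: str
    n_samples: int
    theta: Optional[float] = None     # genome-mean π target; None = natural
    divergence: float = 0.1           # Balding–Nichols F in [0, 1)
    lineage: str = ""

    def __post_init__(self):
        if self.n_samples < 2:
            raise ConfigError(f"group {self.name!r}: need n_samples >= 2")
        if self.theta is not None and not (0 <= self.theta <= 1):
            raise ConfigError(f"group {self.name!r}: theta outside [0, 1]")
        if not (0 <= self.divergence < 1):
            raise ConfigError(f"group {self.name!r}: divergence outside [0, 1)")
        if not self.lineage:
            object.__setattr__(self, "lineage", self.name)


@dataclass(frozen=True)
class SweepRegion:
    """Planted sweep: the target group's heterozygosity is multiplied by
    ``reduction`` inside [start, end]. ``group`` None means the last-listed
    (most derived) group."""

    chrom: str
    start: int
    end: int
    reduction: float
    group: Optional[str] = None

    def __post_init__(self):
        if not (0 <= self.reduction <= 1):
            raise ConfigError("sweep reduction outside [0, 1]")
        if not (1 <= self.start <= self.end):
            raise ConfigError("invalid sweep span")


@dataclass(frozen=True)
class OmegaSetting:
    """One codon-simulation condition: target dN/dS and per-lineage branch
    length in expected substitutions per codon."""

    omega: float
    branch_length: float
    n_pairs: int = 200
    n_codons: int = 300
    kappa: float = 1.0    # ts/tv rate ratio; 1 keeps NG86 nearly unbiased

    def __post_init__(self):
        if self.omega < 0:
            raise ConfigError("omega must be non-negative")
        if self.branch_length < 0:
            raise ConfigError("branch length must be non-negative")


@dataclass(frozen=True)
class ExpressionSample:
    sample: str
    condition: str          # "inoculated" or "control"
    timepoint: float        # hours after inoculation
    tissue: str
    replicate: int
    experiment: str = "exp1"


@dataclass
class SimulationConfig:
    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"1A": 10_000_000, "1B": 10_000_000})
    n_genes: int = 500
    nlr_fraction: float = 0.1
    telomere_bias: float = 3.0
    n_sites: int = 20_000
    missing_rate: float = 0.02
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    group_specs: list[GroupSpec] = field(default_factory=lambda: [
        GroupSpec("wild", 50, divergence=0.15),
        GroupSpec("domesticated", 50, divergence=0.15),
    ])
    sweep_regions: list[SweepRegion] = field(default_factory=list)
    omega_settings: list[OmegaSetting] = field(
        default_factory=lambda: [OmegaSetting(0.2, 0.3)])
    expression_design: list[ExpressionSample] = field(default_factory=list)
    expression_fold: float = 8.0
    expression_noise_sigma: float = 0.4
    tissue_specific: dict[str, str] = field(default_factory=dict)
    tissue_fold: float = 10.0

    def validate(self) -> None:
        if not (0 <= self.nlr_fraction <= 1):
            raise ConfigError("nlr_fraction outside [0, 1]")
        if self.telomere_bias < 0:
            raise ConfigError("telomere_bias must be non-negative")
        if self.n_genes < 0 or self.n_sites < 0:
            raise ConfigError("n_genes and n_sites must be non-negative")
        if not (0 <= self.missing_rate < 1):
            raise ConfigError("missing_rate outside [0, 1)")
        for sw in self.sweep_regions:
            if sw.chrom not in self.chrom_lengths:
                raise ConfigError(
                    f"sweep region on unknown chromosome {sw.chrom!r}")
            target = sw.group or (self.group_specs[-1].name
                                  if self.group_specs else None)
            if target not in {g.name for g in self.group_specs}:
                raise ConfigError(f"sweep targets unknown group {target!r}")

    def rng(self, component: str) -> np.random.Generator:
        from .core import stage_seed

        return np.random.default_rng(stage_seed(self.seed, component))


# ------------------------------------------------------------ annotation


@dataclass
class AnnotationResult:
    genes: list[GeneModel]
    proteins: list[ProteinRecord]
    nlr_ids: set[str]
    classes: dict[str, str]     # ground-truth class per planted NLR


def _seed_consensus() -> str:
    from .domain_scan import build_profile_hmm, load_seed_alignment

    return build_profile_hmm(load_seed_alignment()).consensus()


def _telomere_start(rng, chrom_len: int, gene_len: int, bias: float) -> int:
    """Start position with density increasing toward chromosome ends.

    The fractional distance m to the nearest end is drawn from an
    exponential with rate ``bias`` truncated at 0.5 (uniform when bias=0).
    """
    if bias <= 0:
        m = rng.uniform(0, 0.5)
    else:
        u = rng.uniform()
        m = -math.log1p(-u * (1.0 - math.exp(-bias * 0.5))) / bias
    pos = m if rng.uniform() < 0.5 else 1.0 - m
    start = 1 + int(pos * (chrom_len - gene_len))
    return min(max(start, 1), max(chrom_len - gene_len, 1))


def generate_annotation(cfg: SimulationConfig) -> AnnotationResult:
    """Gene models plus a proteome with a planted NB-ARC subset."""
    cfg.validate()
    rng = cfg.rng("annotation")
    chroms = list(cfg.chrom_lengths)
    if cfg.n_genes == 0:
        return AnnotationResult([], [], set(), {})
    if not chroms:
        raise ConfigError("need at least one chromosome")
    consensus = _seed_consensus()
    n_nlr = int(round(cfg.n_genes * cfg.nlr_fraction))
    lengths = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()

    genes: list[GeneModel] = []
    proteins: list[ProteinRecord] = []
    nlr_ids: set[str] = set()
    classes: dict[str, str] = {}
    class_pool = ["TIR-NLR", "CC-NLR", "CCR-NLR", "NB-LRR"]
    for i in range(cfg.n_genes):
        gene_id = f"G{i + 1:06d}"
        chrom = chroms[rng.choice(len(chroms), p=probs)]
        is_nlr = i < n_nlr
        if is_nlr:
            nlr_class = class_pool[rng.integers(len(class_pool))]
            nterm = "".join(AA[k] for k in rng.integers(0, 20, rng.integers(30, 80)))
            cterm = "".join(AA[k] for k in rng.integers(0, 20, rng.integers(40, 120)))
            motif = CLASS_MOTIFS.get(nlr_class, "")
            seq = nterm + motif + consensus + cterm + LRR_MOTIF
            nlr_ids.add(gene_id)
            classes[gene_id] = nlr_class
        else:
            seq = "".join(AA[k] for k in rng.integers(0, 20, rng.integers(150, 400)))
        gene_len = 3 * len(seq) + 3
        clen = cfg.chrom_lengths[chrom]
        if is_nlr:
            start = _telomere_start(rng, clen, gene_len, cfg.telomere_bias)
        else:
            start = int(rng.integers(1, max(clen - gene_len, 1) + 1))
        strand = "+" if rng.uniform() < 0.5 else "-"
        genes.append(GeneModel(gene_id, chrom, start,
                               min(start + gene_len - 1, clen), strand,
                               subgenome_of(chrom)))
        proteins.append(ProteinRecord(gene_id, seq))
    return AnnotationResult(genes, proteins, nlr_ids, classes)


# ------------------------------------------------------------- genotypes


def _expected_het_uniform(a: float, b: float) -> float:
    """E[2p(1-p)] for p ~ Uniform(a, b)."""
    ep = (a + b) / 2.0
    ep2 = (a * a + a * b + b * b) / 3.0
    return 2.0 * (ep - ep2)


def _scale_heterozygosity(p: np.ndarray, factor: np.ndarray) -> np.ndarray:
    """Map frequencies toward the nearer fixation so 2p'(1-p') = c·2p(1-p).

    Exact for any c with c·2p(1-p) <= 1/2, which holds for all c <= 1.
    """
    h_target = np.clip(factor * 2.0 * p * (1.0 - p), 0.0, 0.5)
    low = 0.5 * (1.0 - np.sqrt(np.maximum(1.0 - 2.0 * h_target, 0.0)))
    return np.where(p <= 0.5, low, 1.0 - low)


def generate_genotypes(cfg: SimulationConfig,
                       genes: Optional[Sequence[GeneModel]] = None
                       ) -> GenotypeMatrix:
    """Diploid biallelic genotypes under Balding–Nichols with planted sweeps."""
    cfg.validate()
    if not cfg.group_specs:
        raise ConfigError("need at least one group spec")
    rng = cfg.rng("genotypes")
    chroms = sorted(cfg.chrom_lengths)
    lengths = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    genome_len = lengths.sum()

    # site positions, count per chromosome proportional to length
    alloc = rng.multinomial(cfg.n_sites, lengths / genome_len)
    site_chrom, site_pos = [], []
    for chrom, n in zip(chroms, alloc):
        L = cfg.chrom_lengths[chrom]
        pos = np.unique(rng.choice(L, size=min(n, L), replace=False) + 1)
        site_chrom.extend([chrom] * len(pos))
        site_pos.extend(pos.tolist())
    n_sites = len(site_pos)
    pos_arr = np.array(site_pos, dtype=np.int64)
    chrom_arr = np.array(site_chrom)

    a, b = cfg.ancestral_freq_range
    anc = rng.uniform(a, b, n_sites)
    nts = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, n_sites)) % 4

    natural_h0 = _expected_het_uniform(a, b)
    samples: list[str] = []
    panel_rows = []
    gt_blocks = []
    default_target = cfg.group_specs[-1].name
    for spec in cfg.group_specs:
        F = spec.divergence
        if F > 0:
            alpha = anc * (1 - F) / F
            beta = (1 - anc) * (1 - F) / F
            p_g = rng.beta(alpha, beta)
        else:
            p_g = anc.copy()
        if spec.theta is not None:
            natural = (1 - F) * natural_h0
            target_h = (cfg.n_sites and
                        spec.theta * genome_len / cfg.n_sites) or 0.0
            c = target_h / natural if natural > 0 else 0.0
            if c > 1:
                raise ConfigError(
                    f"group {spec.name!r}: theta={spec.theta} needs mean "
                    f"per-site heterozygosity {target_h:.3f} > achievable "
                    f"{natural:.3f}; increase n_sites")
            p_g = _scale_heterozygosity(p_g, np.full(n_sites, c))
        for sw in cfg.sweep_regions:
            target = sw.group or default_target
            if target != spec.name:
                continue
            in_region = ((chrom_arr == sw.chrom) & (pos_arr >= sw.start)
                         & (pos_arr <= sw.end))
            p_g[in_region] = _scale_heterozygosity(
                p_g[in_region], np.full(in_region.sum(), sw.reduction))
        gt = rng.binomial(2, p_g[:, None],
                          size=(n_sites, spec.n_samples)).astype(np.int8)
        if cfg.missing_rate > 0:
            miss = rng.uniform(size=gt.shape) < cfg.missing_rate
            gt[miss] = -1
        gt_blocks.append(gt)
        names = [f"{spec.name}_{k + 1:03d}" for k in range(spec.n_samples)]
        samples.extend(names)
        panel_rows.extend(
            {"sample": s, "group": spec.name, "lineage": spec.lineage}
            for s in names)

    sites = pd.DataFrame({
        "chrom": chrom_arr, "pos": pos_arr,
        "ref": nts[ref_idx], "alt": nts[alt_idx],
    })
    order = np.lexsort((pos_arr, chrom_arr))
    sites = sites.iloc[order].reset_index(drop=True)
    gt = (np.hstack(gt_blocks)[order] if gt_blocks
          else np.empty((n_sites, 0), dtype=np.int8))
    panel = pd.DataFrame(panel_rows).set_index("sample") if panel_rows else \
        pd.DataFrame(columns=["group", "lineage"])
    metadata = {
        "sweep_regions": [
            (sw.chrom, sw.start, sw.end, sw.reduction,
             sw.group or default_target) for sw in cfg.sweep_regions
        ],
        "divergence": {g.name: g.divergence for g in cfg.group_specs},
    }
    return GenotypeMatrix(sites, gt, samples, panel, metadata)


# ------------------------------------------------------------ codon pairs


def _codon_rate_tables(omega: float, kappa: float):
    """Per-codon total rates and jump tables for the GY-style model.

    Rates are normalised so the expected number of substitutions per codon
    per unit time is 1 under the uniform codon distribution.
    """
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    idx = {c: i for i, c in enumerate(SENSE_CODONS)}
    targets, rates = [], []
    for codon in SENSE_CODONS:
        t_list, r_list = [], []
        for pos in range(3):
            for nt in "ACGT":
                if nt == codon[pos]:
                    continue
                alt = codon[:pos] + nt + codon[pos + 1:]
                if alt in STOP_CODONS:
                    continue
                rate = kappa if (codon[pos], nt) in transitions else 1.0
                if CODON_TO_AA[alt] != CODON_TO_AA[codon]:
                    rate *= omega
                t_list.append(idx[alt])
                r_list.append(rate)
        targets.append(np.array(t_list, dtype=np.int64))
        rates.append(np.array(r_list))
    total = np.array([r.sum() for r in rates])
    mean_rate = total.mean()  # uniform codon frequencies
    if mean_rate > 0:
        total = total / mean_rate
        rates = [r / mean_rate for r in rates]
    cum = [np.cumsum(r) for r in rates]
    syn_mask = [
        np.array([CODON_TO_AA[SENSE_CODONS[t]] == CODON_TO_AA[c]
                  for t in ts])
        for c, ts in zip(SENSE_CODONS, targets)
    ]
    return total, targets, cum, syn_mask


def _evolve_branch(codons: np.ndarray, t: float, tables, rng
                   ) -> tuple[np.ndarray, int, int]:
    """Gillespie evolution of a codon vector for time t.

    Returns (descendant codons, synonymous events, nonsynonymous events).
    """
    total, targets, cum, syn_mask = tables
    out = codons.copy()
    n_syn = n_non = 0
    for i in range(len(out)):
        remaining = t
        cur = out[i]
        while True:
            rate = total[cur]
            if rate <= 0:
                break
            wait = rng.exponential(1.0 / rate)
            if wait > remaining:
                break
            remaining -= wait
            u = rng.uniform(0, cum[cur][-1])
            j = int(np.searchsorted(cum[cur], u))
            if syn_mask[cur][j]:
                n_syn += 1
            else:
                n_non += 1
            cur = targets[cur][j]
        out[i] = cur
    return out, n_syn, n_non


def generate_codon_pairs(cfg: SimulationConfig) -> list[CodonAlignmentPair]:
    """Codon-sequence pairs evolved from common ancestors at known dN/dS.

    Each pair's metadata records the condition (omega, branch length) and
    the realised synonymous/nonsynonymous substitution events on both
    lineages — the ground truth for estimator-recovery tests.
    """
    cfg.validate()
    if not cfg.omega_settings:
        raise ConfigError("omega_settings must be nonempty")
    rng = cfg.rng("codon_pairs")
    pairs: list[CodonAlignmentPair] = []
    for setting in cfg.omega_settings:
        tables = _codon_rate_tables(setting.omega, setting.kappa)
        for k in range(setting.n_pairs):
            anc = rng.integers(0, len(SENSE_CODONS), setting.n_codons)
            d1, s1, n1 = _evolve_branch(anc, setting.branch_length, tables, rng)
            d2, s2, n2 = _evolve_branch(anc, setting.branch_length, tables, rng)
            seq1 = "".join(SENSE_CODONS[i] for i in d1)
            seq2 = "".join(SENSE_CODONS[i] for i in d2)
            pairs.append(CodonAlignmentPair(
                f"omega{setting.omega:g}_pair{k + 1:04d}", seq1, seq2,
                metadata={
                    "omega": setting.omega,
                    "branch_length": setting.branch_length,
                    "kappa": setting.kappa,
                    "syn_events": s1 + s2,
                    "nonsyn_events": n1 + n2,
                }))
    return pairs


# -------------------------------------------------------------- expression


def generate_expression(cfg: SimulationConfig, responsive: set[str],
                        gene_ids: Optional[Sequence[str]] = None
                        ) -> ExpressionMatrix:
    """TPM matrix under the configured design with planted responsive genes.

    Responsive genes have inoculated-condition means elevated by
    ``cfg.expression_fold`` over controls; replicate noise is multiplicative
    log-normal with sigma ``cfg.expression_noise_sigma`` (0 = noiseless).
    """
    cfg.validate()
    if not cfg.expression_design:
        raise ConfigError("expression_design must be nonempty")
    rng = cfg.rng("expression")
    if gene_ids is None:
        gene_ids = [f"G{i + 1:06d}" for i in range(cfg.n_genes)]
    unknown = set(responsive) - set(gene_ids)
    if unknown:
        raise ConfigError(f"responsive ids not in gene set: {sorted(unknown)[:5]}")
    n_genes = len(gene_ids)
    design = pd.DataFrame(
        [{"sample": s.sample, "experiment": s.experiment,
          "condition": s.condition, "timepoint": s.timepoint,
          "tissue": s.tissue, "replicate": s.replicate}
         for s in cfg.expression_design]).set_index("sample")
    baseline = rng.lognormal(mean=1.0, sigma=1.0, size=n_genes)
    resp = np.array([g in responsive for g in gene_ids])
    values = np.empty((n_genes, len(cfg.expression_design)))
    for j, s in enumerate(cfg.expression_design):
        v = baseline.copy()
        if s.condition == "inoculated":
            v = np.where(resp, v * cfg.expression_fold, v)
        for gid, tissue in cfg.tissue_specific.items():
            if gid in gene_ids and s.tissue == tissue:
                v[gene_ids.index(gid)] *= cfg.tissue_fold
        if cfg.expression_noise_sigma > 0:
            v = v * rng.lognormal(0.0, cfg.expression_noise_sigma, n_genes)
        values[:, j] = v
    frame = pd.DataFrame(values, index=list(gene_ids),
                         columns=[s.sample for s in cfg.expression_design])
    return ExpressionMatrix(frame, design)


def default_expression_design(experiment: str = "inoculation",
                              timepoints=(24.0, 48.0, 72.0),
                              tissues=("leaf",),
                              n_replicates: int = 3) -> list[ExpressionSample]:
    """A paired inoculated/water-control time-course design."""
    design = []
    for tissue in tissues:
        for tp in timepoints:
            for cond in ("control", "inoculated"):
                for rep in range(1, n_replicates + 1):
                    design.append(ExpressionSample(
                        f"{experiment}_{tissue}_{cond}_{tp:g}h_r{rep}",
                        cond, tp, tissue, rep, experiment))
    return design
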