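"""Configured, logged, seeded orchestration of all analysis stages.

``run`` executes simulate -> scan -> atlas -> kaks -> ors -> sweep ->
express in dependency order, each stage reading only declared files and
writing its outputs plus a provenance sidecar (parameters, stage seed, input
checksums). A single global seed fans out to per-stage seeds by stable
hashing of stage names, so toggling one stage never perturbs another's
randomness; identical configs give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml

from . import domain_scan, expression, genome_atlas, io, molevo, popdiv, \
    sweep_scan, synthdata
from .core import ConfigError, stage_seed

log = logging.getLogger("nlr_atlas")

STAGES = ("simulate", "scan", "atlas", "kaks", "ors", "sweep", "express")


@dataclass
class RunConfig:
    outdir: Path
    seed: int = 0
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES})
    simulate: dict[str, Any] = field(default_factory=dict)
    scan: dict[str, Any] = field(default_factory=dict)
    atlas: dict[str, Any] = field(default_factory=dict)
    kaks: dict[str, Any] = field(default_factory=dict)
    ors: dict[str, Any] = field(default_factory=dict)
    sweep: dict[str, Any] = field(default_factory=dict)
    express: dict[str, Any] = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "outdir" not in raw:
            raise ConfigError("config must set outdir")
        raw["outdir"] = Path(raw["outdir"])
        cfg = cls(**raw)
        stages = {s: True for s in STAGES}
        stages.update(cfg.stages or {})
        bad = set(stages) - set(STAGES)
        if bad:
            raise ConfigError(f"unknown stages: {sorted(bad)}")
        cfg.stages = stages
        return cfg

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, False))

    def path(self, name: str) -> Path:
        """Resolve a named input/output file: explicit input wins, else the
        simulate stage's conventional location under outdir."""
        if name in self.inputs:
            return Path(self.inputs[name])
        return self.outdir / _DEFAULT_FILES[name]


_DEFAULT_FILES = {
    "proteins": "proteins.fa",
    "gff": "genes.gff3",
    "vcf": "snps.vcf",
    "panel": "panel.tsv",
    "pairs_cds": "pair_cds.fa",
    "pairs": "pairs.tsv",
    "tpm": "tpm.tsv",
    "design": "design.tsv",
    "nlr_ids": "nlr_ids.txt",
    "seed_alignment": "",
}


@dataclass
class Finding:
    level: str   # "warning" | "fatal"
    message: str


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def fatal(self) -> bool:
        return any(f.level == "fatal" for f in self.findings)

    def add(self, level: str, message: str) -> None:
        self.findings.append(Finding(level, message))


def validate_inputs(config: RunConfig) -> ValidationReport:
    """Structural checks of the enabled stages' inputs; reports, never raises
    (unless a file is unreadable at the OS level)."""
    report = ValidationReport()
    will_simulate = config.enabled("simulate")
    needs = {
        "scan": ["proteins", "gff"],
        "atlas": ["gff"],
        "kaks": ["pairs", "pairs_cds"],
        "ors": ["vcf", "panel", "gff"],
        "sweep": ["vcf", "panel"],
        "express": ["tpm", "design"],
    }
    required = set()
    for stage, files in needs.items():
        if config.enabled(stage):
            required.update(files)
    missing = []
    for name in sorted(required):
        p = config.path(name)
        if not will_simulate and not p.exists():
            missing.append(name)
            report.add("fatal", f"required input {name!r} not found: {p}")
    if missing or will_simulate:
        return report  # simulate will create them; or nothing more to check

    genes = chrom_lengths = None
    if "gff" in required:
        try:
            genes, chrom_lengths = io.read_gff3(config.path("gff"))
        except Exception as exc:  # structural problem
            report.add("fatal", f"GFF3 unreadable: {exc}")
    if "vcf" in required:
        try:
            panel = io.read_panel(config.path("panel"))
            gm = io.read_vcf(config.path("vcf"), panel)
        except Exception as exc:
            report.add("fatal", f"VCF/panel unreadable: {exc}")
        else:
            extra = set(panel.index) - set(gm.samples)
            if extra:
                report.add("fatal",
                           f"panel samples absent from VCF: {sorted(extra)[:5]}")
            if genes is not None:
                vcf_chroms = set(gm.sites["chrom"])
                gene_chroms = {g.chrom for g in genes}
                orphan = gene_chroms - vcf_chroms
                if orphan:
                    report.add("warning",
                               f"genes on chromosomes absent from VCF: "
                               f"{sorted(orphan)[:5]}")
    if "tpm" in required:
        try:
            tpm = io.read_expression(config.path("tpm"))
            design = io.read_design(config.path("design"))
        except Exception as exc:
            report.add("fatal", f"expression/design unreadable: {exc}")
        else:
            extra = set(tpm.columns) - set(design.index)
            if extra:
                report.add("fatal",
                           f"samples without design rows: {sorted(extra)[:5]}")
    return report


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _sidecar(config: RunConfig, stage: str, params: dict,
             inputs: list[Path], outputs: list[Path]) -> None:
    prov_dir = config.outdir / "provenance"
    prov_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "stage": stage,
        "seed": stage_seed(config.seed, stage),
        "parameters": {k: str(v) for k, v in sorted(params.items())},
        "inputs": {p.name: _sha256(p) for p in inputs if p.exists()},
        "outputs": {str(p.name): _sha256(p) for p in outputs if p.exists()},
    }
    with open(prov_dir / f"{stage}.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def demo_config_path() -> Path:
    """Bundled end-to-end demo configuration (small, seconds to run)."""
    from importlib import resources

    return Path(str(resources.files("nlr_atlas").joinpath(
        "data", "demo_config.yaml")))


def _sim_config(config: RunConfig) -> synthdata.SimulationConfig:
    params = dict(config.simulate)
    params.pop("responsive_genes", None)
    params.setdefault("seed", stage_seed(config.seed, "simulate"))
    auto = params.pop("expression_design_auto", None)
    if auto:
        design = []
        for exp in auto.get("experiments", ["exp1"]):
            design.extend(synthdata.default_expression_design(
                exp,
                timepoints=tuple(auto.get("timepoints", (24.0, 48.0, 72.0))),
                tissues=tuple(auto.get("tissues", ("leaf",))),
                n_replicates=int(auto.get("n_replicates", 3))))
        params["expression_design"] = design
    for key, cls in (("group_specs", synthdata.GroupSpec),
                     ("sweep_regions", synthdata.SweepRegion),
                     ("omega_settings", synthdata.OmegaSetting),
                     ("expression_design", synthdata.ExpressionSample)):
        if key in params:
            params[key] = [cls(**d) if isinstance(d, dict) else d
                           for d in params[key]]
    if "chrom_lengths" in params:
        params["chrom_lengths"] = {str(k): int(v)
                                   for k, v in params["chrom_lengths"].items()}
    return synthdata.SimulationConfig(**params)


@dataclass
class RunReport:
    stages: dict[str, dict] = field(default_factory=dict)

    def record(self, stage: str, **counts) -> None:
        self.stages[stage] = counts


def run(config: RunConfig) -> RunReport:
    """Execute all enabled stages in dependency order."""
    report = validate_inputs(config)
    if report.fatal:
        msgs = "; ".join(f.message for f in report.findings if f.level == "fatal")
        raise ConfigError(f"input validation failed: {msgs}")
    config.outdir.mkdir(parents=True, exist_ok=True)
    out = RunReport()

    if config.enabled("simulate"):
        _run_simulate(config, out)
    if config.enabled("scan"):
        _run_scan(config, out)
    if config.enabled("atlas"):
        _run_atlas(config, out)
    if config.enabled("kaks"):
        _run_kaks(config, out)
    if config.enabled("ors"):
        _run_ors(config, out)
    if config.enabled("sweep"):
        _run_sweep(config, out)
    if config.enabled("express"):
        _run_express(config, out)
    with open(config.outdir / "run_report.json", "w") as fh:
        json.dump(out.stages, fh, indent=2, sort_keys=True)
    return out


def _run_simulate(config: RunConfig, report: RunReport) -> None:
    cfg = _sim_config(config)
    ann = synthdata.generate_annotation(cfg)
    gm = synthdata.generate_genotypes(cfg, ann.genes)
    pairs = synthdata.generate_codon_pairs(cfg)
    outdir = config.outdir
    io.write_fasta(((p.id, p.sequence) for p in ann.proteins),
                   outdir / "proteins.fa")
    io.write_gff3(ann.genes, outdir / "genes.gff3", cfg.chrom_lengths)
    io.write_vcf(gm, outdir / "snps.vcf", cfg.chrom_lengths)
    io.write_panel(gm.panel, outdir / "panel.tsv")
    with open(outdir / "truth_nlr_ids.txt", "w") as fh:
        fh.write("".join(f"{g}\n" for g in sorted(ann.nlr_ids)))
    io.write_bed([(c, s, e, f"reduction={r};group={g}")
                  for c, s, e, r, g in gm.metadata["sweep_regions"]],
                 outdir / "truth_sweeps.bed")
    cds = []
    pair_rows = []
    for p in pairs:
        cds.append((f"{p.pair_id}|1", p.seq1))
        cds.append((f"{p.pair_id}|2", p.seq2))
        pair_rows.append((f"{p.pair_id}|1", f"{p.pair_id}|2"))
    io.write_fasta(cds, outdir / "pair_cds.fa")
    with open(outdir / "pairs.tsv", "w") as fh:
        fh.write("".join(f"{a}\t{b}\n" for a, b in pair_rows))
    if cfg.expression_design:
        resp = set(config.simulate.get("responsive_genes", ()))
        em = synthdata.generate_expression(cfg, resp)
        io.write_expression(em.values, outdir / "tpm.tsv")
        io.write_design(em.design, outdir / "design.tsv")
    outputs = [outdir / n for n in
               ("proteins.fa", "genes.gff3", "snps.vcf", "panel.tsv",
                "truth_nlr_ids.txt", "pair_cds.fa", "pairs.tsv",
                "tpm.tsv", "design.tsv")]
    _sidecar(config, "simulate", config.simulate, [], outputs)
    report.record("simulate", genes=len(ann.genes), nlrs=len(ann.nlr_ids),
                  sites=gm.n_sites, pairs=len(pairs))


def _run_scan(config: RunConfig, report: RunReport) -> None:
    params = dict(config.scan)
    proteins = io.read_fasta(config.path("proteins"))
    genes, _ = io.read_gff3(config.path("gff"))
    seed_path = params.pop("seed_alignment", None) or \
        config.inputs.get("seed_alignment") or None
    hmm = domain_scan.build_profile_hmm(
        domain_scan.load_seed_alignment(seed_path))
    threshold = float(params.pop("bit_threshold",
                                 domain_scan.DEFAULT_BIT_THRESHOLD))
    annotations = domain_scan.identify_nlrs(proteins, genes, hmm, threshold)
    rows = [{"gene_id": a.gene_id, "nlr_class": a.nlr_class,
             "score_bits": round(a.hits[0].score, 3),
             "start": a.hits[0].start, "end": a.hits[0].end}
            for a in annotations]
    io.write_table(pd.DataFrame(rows, columns=["gene_id", "nlr_class",
                                               "score_bits", "start", "end"]),
                   config.outdir / "nlr_hits.tsv")
    with open(config.outdir / "nlr_ids.txt", "w") as fh:
        fh.write("".join(f"{a.gene_id}\n" for a in annotations))
    _sidecar(config, "scan", {"bit_threshold": threshold},
             [config.path("proteins"), config.path("gff")],
             [config.outdir / "nlr_hits.tsv", config.outdir / "nlr_ids.txt"])
    report.record("scan", nlrs=len(annotations))


def _read_nlr_genes(config: RunConfig):
    genes, chrom_lengths = io.read_gff3(config.path("gff"))
    with open(config.path("nlr_ids")) as fh:
        ids = {line.strip() for line in fh if line.strip()}
    return [g for g in genes if g.gene_id in ids], genes, chrom_lengths


def _run_atlas(config: RunConfig, report: RunReport) -> None:
    window = int(config.atlas.get("window_size",
                                  genome_atlas.DEFAULT_WINDOW_SIZE))
    min_cluster = int(config.atlas.get("min_cluster",
                                       genome_atlas.DEFAULT_MIN_CLUSTER))
    nlrs, genes, _ = _read_nlr_genes(config)
    grid = genome_atlas.assign_windows(nlrs, window)
    clusters = genome_atlas.detect_clusters(grid, min_cluster)
    io.write_bed(
        [(c, w * window + 1, (w + 1) * window, n)
         for (c, w), n in sorted(grid.counts.items())],
        config.outdir / "nlr_windows.bed")
    io.write_table(genome_atlas.cluster_profile(grid),
                   config.outdir / "clusters.tsv")
    io.write_table(genome_atlas.subgenome_summary(nlrs),
                   config.outdir / "subgenome_summary.tsv")
    io.write_table(genome_atlas.chromosome_enrichment(nlrs, genes),
                   config.outdir / "chromosome_enrichment.tsv")
    _sidecar(config, "atlas",
             {"window_size": window, "min_cluster": min_cluster},
             [config.path("gff"), config.path("nlr_ids")],
             [config.outdir / n for n in
              ("nlr_windows.bed", "clusters.tsv", "subgenome_summary.tsv",
               "chromosome_enrichment.tsv")])
    report.record("atlas", windows=grid.n_windows,
                  clusters=len(clusters.clusters),
                  clustered_nlrs=clusters.nlr_in_clusters)


def _run_kaks(config: RunConfig, report: RunReport) -> None:
    rate = molevo.SubstitutionRate(float(config.kaks.get("rate",
                                                         molevo.DEFAULT_RATE)))
    bin_width = float(config.kaks.get("bin_width", 0.04))
    cds = {r.id: r.sequence for r in io.read_fasta(config.path("pairs_cds"))}
    pairs = []
    for g1, g2 in io.read_pairs_tsv(config.path("pairs")):
        if g1 not in cds or g2 not in cds:
            raise ConfigError(f"pair {g1}/{g2} missing from CDS FASTA")
        pairs.append(molevo.CodonAlignmentPair(f"{g1}~{g2}", cds[g1], cds[g2]))
    table = molevo.kaks_table(pairs, rate)
    results = [molevo.kaks(p, rate) for p in pairs]
    hist, peak = molevo.ks_histogram(results, bin_width)
    io.write_table(table, config.outdir / "kaks.tsv")
    io.write_table(
        hist, config.outdir / "ks_histogram.tsv",
        comments=[f"peak_bin={peak[0]:g}-{peak[1]:g}" if peak else "peak_bin=NA"])
    _sidecar(config, "kaks", {"rate": rate.r, "bin_width": bin_width},
             [config.path("pairs"), config.path("pairs_cds")],
             [config.outdir / "kaks.tsv", config.outdir / "ks_histogram.tsv"])
    report.record("kaks", pairs=len(pairs))


def _run_ors(config: RunConfig, report: RunReport) -> None:
    promoter = int(config.ors.get("promoter_length",
                                  popdiv.DEFAULT_PROMOTER_LENGTH))
    definition = str(config.ors.get("definition", "within"))
    panel = io.read_panel(config.path("panel"))
    gm = io.read_vcf(config.path("vcf"), panel)
    nlrs, _genes, chrom_lengths = _read_nlr_genes(config)
    groups = list(dict.fromkeys(panel["group"]))
    table = popdiv.ors_table(nlrs, groups, gm, promoter, chrom_lengths,
                             definition)
    io.write_table(table, config.outdir / "ors.tsv")
    io.write_table(popdiv.group_totals(gm, groups, definition).table,
                   config.outdir / "group_snp_totals.tsv")
    wide = popdiv.ors_heatmap_matrix(table)
    wide.to_csv(config.outdir / "ors_matrix.tsv", sep="\t",
                index_label="gene_id")
    _sidecar(config, "ors", {"promoter_length": promoter,
                             "definition": definition},
             [config.path("vcf"), config.path("panel"), config.path("gff"),
              config.path("nlr_ids")],
             [config.outdir / n for n in
              ("ors.tsv", "group_snp_totals.tsv", "ors_matrix.tsv")])
    report.record("ors", genes=table["gene_id"].nunique(), groups=len(groups))


def _run_sweep(config: RunConfig, report: RunReport) -> None:
    window = int(config.sweep.get("window_size", sweep_scan.DEFAULT_WINDOW_SIZE))
    step = int(config.sweep.get("step", sweep_scan.DEFAULT_STEP))
    quantile = float(config.sweep.get("quantile", sweep_scan.DEFAULT_QUANTILE))
    comparisons = [
        sweep_scan.ComparisonSpec(c["name"], c["numerator"], c["denominator"])
        if isinstance(c, dict) else c
        for c in config.sweep.get("comparisons", ())
    ]
    panel = io.read_panel(config.path("panel"))
    gm = io.read_vcf(config.path("vcf"), panel)
    if not comparisons:
        groups = list(dict.fromkeys(panel["group"]))
        if len(groups) < 2:
            raise ConfigError("sweep stage needs >= 2 groups")
        comparisons = [sweep_scan.ComparisonSpec(
            f"{groups[0]}_vs_{groups[1]}", groups[0], groups[1])]
    genes = chrom_lengths = None
    try:
        nlrs, genes, chrom_lengths = _read_nlr_genes(config)
    except FileNotFoundError:
        nlrs = []
    gene_sets: dict[str, set[str]] = {}
    outputs = []
    for spec in comparisons:
        windows = sweep_scan.scan(gm, spec, window, step, chrom_lengths)
        cands = sweep_scan.candidate_sweeps(windows, quantile)
        frame = sweep_scan.windows_frame(windows)
        path = config.outdir / f"sweep_windows_{spec.name}.tsv"
        io.write_table(frame, path)
        outputs.append(path)
        assignment = sweep_scan.windows_to_genes(cands, genes or [])
        bed = config.outdir / f"sweep_regions_{spec.name}.bed"
        io.write_bed(assignment.regions, bed)
        outputs.append(bed)
        gene_sets[spec.name] = set(assignment.assignments)
        report.record(f"sweep:{spec.name}", windows=len(windows),
                      candidates=len(cands),
                      swept_mbp=round(assignment.total_mbp, 3),
                      genes=len(assignment.assignments))
    if len(gene_sets) >= 2:
        io.write_table(sweep_scan.comparison_overlap(gene_sets),
                       config.outdir / "sweep_overlap.tsv")
        outputs.append(config.outdir / "sweep_overlap.tsv")
    _sidecar(config, "sweep",
             {"window_size": window, "step": step, "quantile": quantile},
             [config.path("vcf"), config.path("panel")], outputs)


def _run_express(config: RunConfig, report: RunReport) -> None:
    k = int(config.express.get("k", 4))
    fold = float(config.express.get("fold", 2.0))
    min_expr = float(config.express.get("min_expr",
                                        expression.DEFAULT_MIN_EXPR))
    values = io.read_expression(config.path("tpm"))
    design = io.read_design(config.path("design"))
    em = expression.ExpressionMatrix(values, design)
    collapsed = expression.collapse_replicates(em)
    z, flat = expression.scale_rows(collapsed.values)
    assignment = expression.cluster_patterns(z, min(k, len(z)))
    io.write_table(assignment.to_frame(), config.outdir / "patterns.tsv")
    z.to_csv(config.outdir / "scaled_matrix.tsv", sep="\t", index_label="gene")
    calls = {}
    for exp in pd.unique(design["experiment"]):
        sub = design[design["experiment"] == exp]
        if {"inoculated", "control"} <= set(sub["condition"]):
            calls[exp] = expression.responsive_genes(em, exp, fold, min_expr)
            with open(config.outdir / f"responsive_{exp}.txt", "w") as fh:
                fh.write("".join(f"{g}\n" for g in sorted(calls[exp])))
    if len(calls) >= 2:
        broad = expression.broad_spectrum(calls)
        with open(config.outdir / "broad_spectrum.txt", "w") as fh:
            fh.write("".join(f"{g}\n" for g in sorted(broad)))
    expression.plot_heatmap(z, assignment, config.outdir / "heatmap.png")
    _sidecar(config, "express",
             {"k": k, "fold": fold, "min_expr": min_expr, "flat_rows": len(flat)},
             [config.path("tpm"), config.path("design")],
             [config.outdir / "patterns.tsv",
              config.outdir / "scaled_matrix.tsv"])
    report.record("express", genes=len(z), patterns=assignment.k,
                  responsive={e: len(g) for e, g in calls.items()})
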