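# nlr-atlas

Tools for characterising the NLR (nucleotide-binding leucine-rich-repeat)
disease-resistance gene family of a polyploid plant genome and its wild
relatives: domain-based gene identification, genomic clustering, molecular
dating of syntenic paralogs, population diversity, selective-sweep scans,
and expression-pattern analysis. The package is aimed at plant
population/comparative genomicists who want each of these steps as a tested,
scriptable unit rather than a chain of one-off shell tools, and at anyone
who needs desk-scale synthetic data with known ground truth to validate such
a pipeline.

## What it computes

* **Domain scan** — a Durbin-style profile HMM is built from an NB-ARC seed
  alignment (match states at columns with < 50% gaps, +1 pseudocounts,
  log-odds emissions) and searched against a proteome by Viterbi dynamic
  programming, global in the model and local in the sequence. Genes with a
  hit ≥ the bit threshold are NLRs; regex motif rules assign the classes
  TIR-NLR, CCR-NLR, CC-NLR and NB-LRR.
* **Genome atlas** — disjoint 200 kb windows by gene start; a window with
  ≥ 2 NLRs is a gene cluster; per-subgenome and per-chromosome summaries.
* **Ka/Ks and dating** — Nei–Gojobori (1986) counting with Jukes–Cantor
  correction, d = −(3/4)·ln(1 − 4p/3), on aligned codon pairs; divergence
  time T = Ks / (2r) with r = 6.1 × 10⁻⁹ substitutions·site⁻¹·yr⁻¹.
* **ORS diversity** — occurrence rate of SNPs: for each gene, group and
  region (genic span or strand-aware 2 kb promoter), the group's SNP count
  in the region divided by its SNP count on the gene's chromosome.
* **Sweep scan** — π = Σ 2p̂(1−p̂)·n/(n−1) / window bp and Weir–Cockerham
  (1984) Fst as a ratio of summed variance components, in 50 kb windows
  with 5 kb steps; candidate sweeps are windows in the top 5% of both
  π_wild/π_domesticated and Fst; candidates are merged and assigned to
  genes by ≥ 1 bp overlap.
* **Expression patterns** — replicate means, per-gene z-scaling, complete-
  linkage Euclidean clustering cut into k patterns; responsive genes by a
  pseudo-count-stabilised inoculated/control fold change; broad-spectrum
  genes respond in ≥ 2 experiments.
* **Synthetic data** — every input above, generated with known ground
  truth: planted NB-ARC genes with telomere-biased placement, Balding–
  Nichols genotypes with planted sweeps, codon pairs evolved at a chosen
  dN/dS, and TPM matrices with planted responsive genes.

## Worked example

The numbered drivers under `analysis/` run the whole study on one seeded
synthetic dataset (written to `results/run/`):

```bash
cd analysis
python 01_simulate.py && python 02_scan_domains.py && python 04_kaks_dating.py
```

prints, among other lines:

```
  genes: 120 (18 planted NLRs; ids in truth_nlr_ids.txt)
  18 NLRs called; sensitivity 1.00, FDR 0.00
  class counts: {'TIR-NLR': 6, 'CC-NLR': 5, 'CCR-NLR': 4, 'NB-LRR': 3}
  30 pairs; mean Ka/Ks 0.239 (all < 1: True)
```

meaning: the profile HMM recovered exactly the 18 planted NB-ARC genes
(no false calls at the default 25-bit threshold), the motif rules split
them into the four canonical classes, and codon pairs simulated under
purifying selection (dN/dS = 0.2) are estimated at mean Ka/Ks ≈ 0.24 —
correctly below 1. `03`/`05`/`06`/`07` add the clustering atlas, ORS
tables, the sweep scan against the planted sweep, and expression patterns.
The same pipeline runs as one command via the CLI:

```bash
nlr-atlas run --config src/nlr_atlas/data/demo_config.yaml
```

with subcommands (`scan`, `atlas`, `kaks`, `ors`, `sweep`, `express`) for
individual steps on your own FASTA/GFF3/VCF/TSV inputs.

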