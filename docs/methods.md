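# Methods

This note documents the models implemented in `nlr_atlas`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Profile-HMM domain scan

The NB-ARC detector is a plain Durbin-style profile HMM, deliberately
simpler than HMMER's architecture so that every score is hand-checkable and
an exhaustive enumeration oracle is feasible in the tests.

* **Build.** Alignment columns with < 50% gap characters become match
  states. Match emissions take Laplace (+1) pseudocounts over the 20
  residues; transition counts between the match/insert/delete blocks take
  +1 pseudocounts over their three targets. The background distribution is
  the residue frequency of the whole alignment (+1 pseudocounts), flat if
  degenerate. Match emissions are scored as log₂-odds against this
  background.
* **Search semantics.** Global in the model, local in the sequence: a hit
  traverses every model position (match or delete) while flanking residues
  are consumed by free self-loops that emit at background, contributing
  zero bits. The score is the Viterbi best-path log-odds in bits. Insert
  states emit at background (zero bits) but pay their transition costs.
  Non-overlapping secondary hits are found by masking the best span and
  re-searching the flanks.
* **Consensus.** Defined per match state as the residue with the highest
  log-odds (not the highest raw probability), which guarantees an exact
  consensus copy outscores every point mutant for any background — the
  property the recovery tests rely on.
* **Threshold.** The default acceptance threshold is 25 bits. On the
  bundled synthetic seed alignment the exact consensus scores ≈ 145 bits
  and fixed-seed random or shuffled sequences score < 10 bits, so the
  threshold sits far from both; it is a config value, not a calibrated
  constant, because no gathering thresholds exist for a user-supplied seed
  alignment.
* **Seed alignment and motifs.** `data/nbarc_seed.synthetic.afa` is a
  synthetic NB-ARC-like alignment (12 rows, 62 match columns around
  P-loop/kinase-2/GLPL-style blocks); it is a fixture standing in for a
  curated domain seed, and users supply their own for real work. Class
  assignment (TIR > CCR > CC > NB-LRR by priority, motifs required
  N-terminal of the NB-ARC span, the LxxLxL LRR rule C-terminal) is driven
  by regexes in `data/motifs.yaml` — data, not code.
* **Isoforms and scaffolds.** One representative protein per gene (longest
  isoform). Genes whose sequence name fails the chromosome-name pattern
  (default `^chr|^\d+[A-D]$`) are treated as scaffold-located and dropped.

## Genome atlas

"Sliding" 200 kb windows are implemented as disjoint tiles indexed by
`floor((start − 1)/window)`: overlapping windows would double-count genes
and break percent-of-total arithmetic. A gene spanning a tile boundary
belongs to the tile containing its start, so counts are conserved exactly.
Percentages are rounded half-up to two decimals from unrounded counts.
Telomere proximity is reported as distance to the nearest chromosome end;
no telomere annotation is attempted.

## NG86 Ka/Ks and dating

Site counts per codon: the synonymous fraction of the three single-
nucleotide changes per position, with changes to stop codons excluded from
the denominator, so n + s = 3 exactly. Codons differing at ≥ 2 positions
average difference counts over all orderings of minimal substitution
pathways; pathways through stops are skipped, and a codon pair whose every
pathway hits a stop is excluded entirely (as are codons with gaps or N in
either sequence). Proportions are corrected with Jukes–Cantor
d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 is reported as +∞ with a saturation flag,
and Ka/Ks is NaN when Ks = 0. NG86-with-JC was chosen over ML (GY94)
estimation because it is fully specifiable and hand-checkable; the
simulator's κ default of 1 (below) keeps it nearly unbiased.

Divergence time is the molecular-clock conversion T = Ks/(2r), reported in
MYA, with r = 6.1 × 10⁻⁹ synonymous substitutions·site⁻¹·yr⁻¹ (the grass
rate) as default.

## ORS

A "group SNP" is a site polymorphic *within* the group — both alleles
observed among the group's non-missing calls — because that is what makes
wild-versus-domesticated diversity contrasts meaningful; counting sites
that are merely non-reference is available via `definition="nonref"`.
Missing genotypes are ignored per site; a site with < 2 non-missing calls
in a group is uncountable for that group. The promoter is the strand-aware
upstream 2 kb, clipped at chromosome edges (possibly empty); a SNP on a
gene's boundary base is genic (closed intervals). Chromosome denominators
are per-group; with a disjoint gene tiling of a chromosome the ORS values
sum to exactly 1.

## Sweep scan

π per window sums the unbiased per-site heterozygosity 2p̂(1−p̂)·n/(n−1)
(n = non-missing allele count) and divides by the window's covered length,
so monomorphic and unobserved positions count as zero-diversity sites;
windows truncated at a chromosome end keep their nominal span for tiling
but use the covered length. Fst is Weir–Cockerham (1984) with observed
heterozygosity, windowed as Σa / Σ(a+b+c); negative estimates are reported
as computed. The 0/0 indeterminate form of the finite-sample correction at
n̄ = 1 is resolved to 0, which preserves Fst = 1 for fixed differences with
a single diploid per group.

Candidates are windows at or above the empirical 95th percentile of both
the π-ratio (wild/domesticated orientation) and Fst, percentiles computed
per comparison over all defined windows genome-wide (ties included; ≥ 20
defined windows required, else the scan refuses). Per-subgenome swept-Mbp
summaries are derived afterwards from candidate locations, not from
per-subgenome quantiles. Candidate windows are merged into regions and
assigned to genes by ≥ 1 bp overlap.

## Expression

Replicates are collapsed by arithmetic mean per (experiment, condition,
timepoint, tissue) cell. Rows are z-scaled with the sample standard
deviation (ddof = 1); zero-variance rows are zeroed and flagged rather than
dropped. Clustering is agglomerative with Euclidean distance and complete
linkage — the documented defaults of the heatmap tools this mirrors — and
the tree is cut into a user-chosen k; no automatic k selection is
attempted because pattern counts are read off dendrograms by the analyst.
The partition (not the label numbering) is invariant to row order except
for exact distance ties, which are measure-zero on real-valued data.
Responsive calls use (mean_inoculated + ε)/(mean_control + ε) ≥ fold with
ε = 0.5 pseudo-TPM to stabilise low-expression ratios, plus a 1-TPM
minimum inoculated mean. Broad-spectrum = responsive in ≥ 2 experiments.

## Synthetic data: what it emulates and what it does not

The generator replaces the external inputs of a real study (annotated
hexaploid genome, resequencing genotypes of wild and domesticated groups,
syntenic pair lists, inoculation transcriptomes) with seeded desk-scale
equivalents. Defaults: two 10 Mb chromosomes, 500 genes, 10% NLRs,
telomere-bias 3 (exponential rate on the fractional distance to the nearer
chromosome end; 0 = uniform), 20 000 biallelic sites, 2% missing calls,
two groups of 50 diploids at Balding–Nichols F = 0.15, codon pairs at
ω = 0.2 with per-lineage branch length 0.3 substitutions/codon.

* **Genotypes.** Per site, an ancestral frequency p ~ U(0.05, 0.95); each
  group's frequency is Beta(p(1−F)/F, (1−p)(1−F)/F), giving closed-form
  expected Fst = F for recovery tests; genotypes are binomial(2, p_g).
  Groups may set a π target θ; the per-site heterozygosity is then rescaled
  exactly (closed-form map toward the nearer fixation) so genome-mean π
  equals θ in expectation, with a config error when θ is unachievable at
  the requested site count. Sweeps are planted by applying the same map
  with the reduction factor to the derived group inside the region —
  sufficient for the π/Fst statistics tested and vastly cheaper than
  coalescent simulation, but carrying no linkage, recombination or
  haplotype structure: passing recovery tests says nothing about
  haplotype-based sweep statistics on real data.
* **Codon pairs.** A GY-style continuous-time model over the 61 sense
  codons with equal codon frequencies and a single transition class κ
  (default 1, so the downstream NG86 estimator is approximately unbiased;
  raise κ to study its bias). Rates are normalised to one expected
  substitution per codon per unit branch length under the uniform codon
  distribution, and each lineage is evolved from the common ancestor by
  event-level (Gillespie) simulation so the realised synonymous and
  nonsynonymous event counts are stored as per-pair ground truth.
* **Expression.** Gene baselines are log-normal (median ≈ 2.7 TPM);
  responsive genes have inoculated-condition means multiplied by the
  configured fold (default 8); replicate noise is multiplicative
  log-normal (σ = 0.4; 0 gives the exact noiseless fold). Optional
  tissue-specific genes multiply one tissue's mean. There is no
  library-size variation, no count overdispersion and no correlation
  structure between genes.

Identical configurations (including seed) produce byte-identical outputs;
each component draws from its own seed stream derived by hashing the
component name into the global seed.

## Pipeline

Stages run in dependency order (simulate → scan → atlas → kaks → ors →
sweep → express), communicate only through declared files, and each writes
a provenance sidecar (parameters, stage seed, input/output checksums —
no timestamps, so reruns are byte-identical). Tabular outputs are TSV with
a header and `#` comments; coordinates are 1-based closed everywhere
except BED files (0-based half-open).

## Problem sizes used by the tests and acceptance script

Recovery suites run at: 20 000 sites over 2 × 10 Mb with 50 diploids per
group (Fst and sweep recovery; three planted 500 kb sweeps at reduction
0.05); 200 pairs × 300 codons per ω condition; a 120-gene / 4 000-site /
30-pair demo for the end-to-end determinism check. These sizes keep any
single check within a couple of minutes while leaving the Monte-Carlo
error comfortably inside the asserted tolerances (e.g. ±0.03 on Fst at
F = 0.2, ±25% on ω recovery).

## Known limitations

Diploid biallelic SNPs only (no indels, multi-allelic sites or polyploid
calls; subgenomes are independent chromosomes, homoeologues are not
modelled); no forward-algorithm E-values or integrated-domain detection in
the scanner; no ML codon models; no significance testing of ORS contrasts;
no composite-likelihood or haplotype sweep statistics; expression analysis
is descriptive (no differential-expression modelling).
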