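# Methods

This note documents the models and estimators the package implements, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions. All coordinates are 0-based
half-open internally; the 1-based convention appears only at the VCF
boundary.

## Breakpoint-read inversion genotyping

An inversion known from a genome-pair comparison has two breakpoints. For
each breakpoint and each reference arrangement we cut a *junction*: the
2L-bp sequence centred on the breakpoint (default flank L = 150, one read
length, so a junction-spanning read can anchor entirely within it). A read
supports a junction when the read or its reverse complement matches the
junction over a span crossing the breakpoint with at least m = 20 exactly
matched bases on each side. The m-base cores must be exact — a chance match
of a 40-bp core has probability ~4^-20 per offset — while the rest of the
overlap tolerates one mismatch per 50 bp, so substitution-type sequencing
errors in the flanks do not discard true support. Matching is exact-substring
based (the core is located with a string search, then the implied alignment
is verified), which makes counting equivalent to a brute-force all-offset
scanner; the equivalence is tested.

The per-sample statistic is the percent ratio r = 100·N_A/(N_A+N_B).
Classification uses closed intervals: r ∈ [80, 100] → same-as-A,
r ∈ [0, 20] → same-as-B, otherwise heterozygous; zero junction-spanning
reads give a no-call rather than an exception. Left- and right-breakpoint
ratios are reported separately for QC, but the classification input is the
pooled ratio (summed counts across sides): one genotype per sample is the
useful output, and pooling uses all junction-spanning evidence. Genotyping
is mapping-free by design — junction matching on raw reads replaces
short-read alignment while preserving the same support statistic — and
pre-computed per-junction counts from an external aligner can be fed
directly into `support_ratio`.

## Weir–Cockerham F_ST, π, and GDR calling

Sites are biallelic dosages {0, 1, 2, missing}; the standard input filters
are MAF ≥ 0.03 over non-missing calls and missing fraction ≤ 0.1. Per site,
with allele-sample sizes n_i = 2 × genotyped samples and alternate counts
j_i in the two groups, the package computes the Weir & Cockerham (1984)
two-population θ in its allele-count form (components a and b; θ = a/(a+b);
the within-individual c component is not separable from dosage data and is
collapsed into b). A fixed difference with complete data gives θ = 1;
identical frequencies give θ ≤ 0 with expectation 0. Negative per-site
values are retained, matching the estimator's definition. Sites monomorphic
across both groups, or with a group entirely missing, are undefined and
excluded from sums.

Nucleotide diversity is the unbiased pairwise form π = 2j(n−j)/(n(n−1)) per
site; windowed π divides the per-site sum by the window span in bp (a
documented convention — the denominator is not the variant count), so
invariant windows have π = 0.

Windows default to 100 kb sliding by 10 kb, starting at 0 with the last
start ≤ chromosome length − window. Windowed F_ST is reported in both forms:
the ratio of sums Σa/Σ(a+b) (the "weighted" value, used for GDRs and
genome-wide summaries) and the mean of per-site ratios. GDRs are windows
*strictly* above the empirical quantile (default 0.95, linear interpolation,
computed over defined windows only) merged when they overlap or share a
boundary; strict inequality makes the degenerate constant track yield no
calls, and merging reproduces one contiguous region from many overlapping
significant windows. The quantile is genome-wide, not per chromosome. A
minimum of 20 defined windows is required.

## Centromere profiling

ChIP enrichment: per-window fold = ((ip_w+1)/IP_total)/((input_w+1)/
INPUT_total) on matching 10-kb grids; the pseudocount of 1 keeps zero-input
windows finite and is negligible at realistic counts. Because both tracks
are normalised by their totals, the computed fold approaches the true
enrichment only when the enriched fraction of the genome is small — at
desk scale this matters, and tests place the enriched interval accordingly.
Domains are maximal runs of windows ≥ fold 2, bridging at most one
sub-threshold window, kept at span ≥ 100 kb; this is an explicitly
simplified domain caller operating at the 10-kb reporting grid, not a
read-level peak caller.

Satellite period detection collects, for every k-mer (k = 12) that recurs,
the distances between consecutive occurrences; the most frequent distance
(≤ 2000 bp) is the period candidate, accepted when its support fraction is
≥ 0.3 and at least 10 spacings were observed (the floor stops a handful of
chance recurrences in random sequence from fabricating a period). k = 12 is
small enough that a monomer copy at 2–5% divergence still carries several
intact k-mers.

Monomer extraction assumes substitution-only divergence (what the generator
plants; indel-aware alignment is out of scope). The phase offset in
[0, period) minimises the per-comparison Hamming cost of all monomers
against the first monomer at that phase — normalising per comparison
matters, since phases that shift a monomer off the end would otherwise win
on total cost — with ties (clean arrays, where every rotation is internally
consistent) resolved to the smallest phase. A boundary-free tandem array
determines its monomer only up to cyclic rotation, so "recovering the
planted unit" means recovering it at the anchor the phase search returns;
tests assert consensus == planted unit rotated by the recovered phase. The
consensus is the per-column majority base (ties broken alphabetically) and
the variant frequency is v_i = 1 − majority/depth, bounded by 0.75 for a
four-letter alphabet. Mutations that land on a column's majority base are
invisible to v, so the mean of v sits slightly below the planted mutation
rate; the test tolerance (±0.02 at rate 0.1) comes from simulating that
effect, not from 3/4 arithmetic.

The windowed identity matrix compares non-overlapping 2-kb windows by k-mer
(k = 15) Jaccard, taking the better of the forward and reverse-complement
comparison and mapping Jaccard to an identity estimate via the Mash
distance; this is a deliberately alignment-free estimate sufficient for the
homogenised-vs-diverged contrast, not a base-level alignment identity.

## PCA, GLM association, haplotypes

PCA standardises dosages per site by centring at 2p and scaling by
√(p(1−p)); monomorphic sites are dropped and missing calls mean-imputed
(contributing zero after centring). Coordinates come from the SVD of the
standardised matrix.

The association model is the fixed-effect GLM phenotype ~ intercept +
dosage + k PCs (default k = 2, mirroring the two components that separate
the demes). Because every site shares the covariate design, the scan
residualises phenotype and dosages against the covariates once
(Frisch–Waugh) and computes the dosage slope, t statistic and two-sided
p-value from the residualised regression — algebraically identical to
per-site least squares, which a test verifies to 1e-10 against an
independent lstsq fit. Constant-dosage sites are skipped. The threshold is
p* = α/n over tested sites; an effective number of independent sites can be
supplied instead when known (it is not computable from the genotype matrix
alone without an LD-pruning convention, which is deliberately not guessed).

Haplotype grouping concatenates dosage codes at the defining SNPs; any
missing call makes the sample unassigned. The two largest pattern groups are
labelled A and B, A being the higher-phenotype (tolerant) group when a
phenotype is supplied — labels follow phenotype, not allele identity. Group
comparison is the pooled-variance (Student) two-sample t-test, two-sided;
degenerate zero-variance cases return (0, 1) for equal means and (±inf, 0)
for unequal.

Phenotype formulas: relative conductivity is returned as printed in the
source protocol, (E2−E0)/(E1−E0), with a `conventional=True` switch for the
usual leakage fraction (E1−E0)/(E2−E0) — the printed form inverts the
convention and the intent is not guessed. Anthocyanin content is A535/FW.

## Synthetic-data generator

The generator emulates the study design the analyses assume:

- **Genome pair**: i.i.d. uniform ACGT chromosomes; genome B equals A with
  each inversion reverse-complemented and divergence SNPs applied *outside*
  inversions only, keeping junction sequences exact so error-free genotyper
  tests have a clean truth. Satellite arrays are planted as monomer × copies
  with i.i.d. substitutions.
- **Reads**: pair count = round(depth × genome/(2 × read length)), uniform
  fragment starts, Gaussian insert length (floored at the read length),
  random fragment strand, mate 2 reverse-complemented, i.i.d. substitution
  errors. No indels, no quality model, no GC or coverage bias, no Hi-C or
  long reads.
- **Panel**: Balding–Nichols — per site an ancestral frequency p ~
  U(0.05, 0.95), deme frequencies ~ Beta(p(1−F)/F, (1−p)(1−F)/F) with
  variance F·p(1−p), diploid dosages Binomial(2, p_deme), i.i.d.
  missingness. F is region-wise: a background value and a higher value
  inside the planted divergence block. Sites are exchangeable — there is no
  linkage, recombination map or coalescent genealogy — so the block's edges
  are sharp in a way real LD would blur. Deme sizes default to 31 inland /
  20 coastal; the study names 51 accessions and a 20-member coastal group,
  so the 31/20 split is an inference, recorded as such here. Inversion
  marker sites are perfectly correlated with the deme arrangement
  (inland = inverted B, coastal = reference A, the orientation the study's
  breakpoint data shows); causal sites encode a tolerant/sensitive
  haplotype carried by all-sensitive inland samples and 55%-tolerant
  coastal samples.
- **Phenotypes**: group mean + Gaussian noise truncated to [0, 100]
  (truncation, not resampling — a simple, documented bias at the extremes),
  with tolerant/sensitive survival defaults 91.83 ± 2.25% and 1.11 ± 1.57%.
- **ChIP tracks**: Poisson window counts at rate depth × window/read length,
  IP rate multiplied by the fold inside the centromere interval.

Every generator takes one seed and uses a single `numpy` Generator stream,
so identical spec + seed gives byte-identical outputs; seeds are recorded in
the truth metadata. Truth sets (inversion BED, planted-SNP VCF, per-sample
arrangement and haplotype TSV, metadata JSON) round-trip losslessly through
the package's writers and readers.

What passing tests on this generator do **not** show: robustness to indels
and misassembly around breakpoints, alignment artefacts (the genotyper never
maps reads), LD structure and ascertainment in real panels, or overdispersed
ChIP backgrounds.

## Problem sizes and determinism

Default test and demo problem sizes are chosen to exercise every code path
at desk scale: 40 kb–2 Mb chromosomes, 1 000–20 000 sites, panels of ~50
samples, 20-seed replicate suites for the stochastic claims. The
Balding–Nichols recovery checks use 20 000 sites, where the weighted
estimator's sampling error is well inside the ±0.03 acceptance band used
throughout. The pipeline writes a manifest with a config hash and SHA-256
digests of every output; rerunning the same config must reproduce the
digests exactly, and a test asserts this.

## Known limitations

- The genotyper counts substitution-mismatched reads but not indel-bearing
  ones; at real-data error profiles a small fraction of true support is
  lost (symmetrically for both references, leaving the ratio unbiased).
- The window quantile for GDRs is genome-wide; per-chromosome calling would
  change results on heterogeneous genomes.
- The simplified enrichment-domain caller has window-level resolution only.
- Monomer tools assume equal-length, indel-free monomers; higher-order
  repeat structure is out of scope.
- The GLM is a fixed-effect model; kinship/mixed-model confounding control
  beyond PCs is out of scope.
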