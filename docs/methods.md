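# Methods

This note records the statistical models, numerical choices and known
limitations of dupdiv, in the order of the pipeline stages.

## Coordinate and genotype conventions

All internal intervals are 0-based half-open; VCF positions are converted
from 1-based on read and back on write. Only biallelic SNPs are retained
from VCF input (multiallelic and non-SNP records are skipped with a logged
count). Genotypes are unphased alternate-allele dosages in {0, 1, 2} with
missing coded −1; every statistic is allele-frequency based, so phase is
ignored. Missing calls are excluded site-wise from allele counts
(complete-case per site) and never imputed — the simplest defensible
treatment for frequency-based statistics. Aligned codon pairs drop whole
codons containing any gap or ambiguity character (preserving the reading
frame); a shared terminal stop codon is trimmed, any other stop is an
error.

## Ka/Ks (NG86) and duplication dating

The estimator is Nei–Gojobori (1986) with Jukes–Cantor correction:

* Per sense codon, each position contributes the fraction of its three
  possible single-base changes that are synonymous; changes creating stop
  codons count as nonsynonymous. The synonymous and nonsynonymous site
  counts of a codon always sum to 3; totals are averaged over the two
  sequences.
* Observed codon differences are classified directly when single, and by
  averaging over all orderings of single-base steps when multiple, with
  pathways passing through stop codons excluded and the average
  renormalized over the remainder. A (rare) codon pair whose pathways all
  pass through stops raises an explicit error.
* pn = Nd/N and ps = Sd/S are corrected with d = −(3/4)·ln(1 − (4/3)p).
  A proportion ≥ 3/4 makes the correction undefined and raises an error
  naming the affected rate. ω = Ka/Ks; when Ks = 0 with Ka > 0, ω is
  reported as +inf (a flag, not an exception); when both are 0 it is None.

NG86 was chosen over maximum-likelihood codon models because it is fully
specified, exactly checkable against brute-force enumeration, and adequate
for the dating logic; Ks values computed elsewhere (e.g. by ML methods) can
be fed directly into the dating step. Duplication age is T = Ks/(2λ). λ —
the neutral substitution rate per silent site per year — has **no
default**: published plant rates span roughly 1×10⁻⁹ to 2×10⁻⁸ and the
choice dominates the result, so it must be supplied. Only the standard
genetic code is supported.

## Sweep scan

Windows are [k·step, k·step + size) for k = 0 … floor((L−size)/step), with
size 20 kb and step 2 kb by default (a chromosome shorter than one window
yields a single truncated window). Per-site diversity uses the unbiased
estimator (n/(n−1))·2p(1−p) over the n non-missing allele copies; windowed
π divides the summed site values by the **full window length in bp** (the
standard windowed convention), so SNP density and per-site heterozygosity
both affect π. Windows with fewer than `min_snps` (default 3) SNPs are
flagged unevaluated and excluded from ranking.

π ratios default to ancestral-over-derived (wild/landrace for the
domestication contrast, landrace/improved for improvement) so that a sweep
in the derived population produces a **high** ratio; the orientation is a
recorded flag because the two conventions coexist in the literature. A
pseudocount (default 10⁻⁶) guards against zero denominators and is recorded
in the output metadata.

F_ST is the Hudson ratio-of-sums estimator: within-population
heterozygosity (mean of the two populations' unbiased values) and
between-population diversity p_a(1−p_b) + p_b(1−p_a) are each summed over a
window's usable sites before dividing, 1 − Σwithin/Σbetween. It can be
slightly negative near zero differentiation. Hudson was preferred to
Weir–Cockerham as the most reproducible windowed choice.

Outlier thresholds are empirical genome-wide quantiles (linear
interpolation) over all evaluated windows — top 1% and top 5% by default —
with ≥ comparison at the cutoff, so top-1% windows are always also top-5%.
An all-equal (degenerate) statistic distribution is flagged and emits no
calls. A gene's tier per contrast is the highest tier among windows whose
half-open interval intersects the gene.

**Implication of empirical thresholds:** ~1% of windows always exceed the
top-1% cutoff even in pure noise, and any genomic point is overlapped by
size/step = 10 windows (~2% of the windows of a 1-Mb scan). A gene in a
no-structure panel therefore still has a ~5% chance per contrast of
overlapping a noise outlier; gene-level calls should always be read against
this baseline (the acceptance checks quantify it).

## Synthetic populations

The generator targets the statistical structure the scan assumes rather
than a demographic history:

* SNP positions are uniform without replacement. Wild allele frequencies
  follow a truncated neutral-like SFS, density ∝ 1/p on (ε, 1−ε) with
  ε = 0.05 by default. Given a target wild per-site diversity θ (default
  0.003, a typical wild-soybean value), the SNP count is calibrated as
  n = θ·L / E[2p(1−p)] so that expected windowed π equals θ; the estimator
  is unbiased, so no further correction is needed. An explicit SNP density
  may be supplied instead; it is rejected when it would require mean site
  heterozygosity above the mathematical maximum of 0.5.
* Landrace frequencies derive from wild, and improved from landrace, by a
  Balding–Nichols drift kernel: Beta with mean p and variance F·p(1−p)
  (defaults F = 0.10 for domestication, 0.05 for improvement), which
  multiplies expected heterozygosity by 1−F and yields F_ST-like
  differentiation without a coalescent.
* A sweep tract pushes the target population's frequencies to fixation with
  probability 1−ρ (to 1 with probability p, else 0, preserving the mean),
  multiplying expected heterozygosity by ρ. This is heterozygosity
  thinning, not hitchhiking: it produces exactly the π-ratio signal the
  scan interprets, at trivial cost, but no linked-site structure.
* Genotypes are binomial(2, p) draws per sample; the default sample sizes
  62/130/110 emulate a 302-accession wild/landrace/improved panel.

What the generator does **not** emulate: linkage disequilibrium,
recombination, realistic site-frequency spectra after selection, genotyping
error, or missingness patterns. Passing recovery tests therefore shows the
statistics and classification logic are correct, not that the scan is
well-powered on real resequencing data.

## Codon-pair and expression generators

Codon pairs start from a uniform random stop-free codon sequence; Poisson
numbers of synonymous and nonsynonymous single-base changes (means
Ks·S and ω·Ks·N under the ancestor's NG86 site counts) are applied at
random positions, never creating stops, with each change classified in its
current codon context and true counts recorded. Multiple hits at one site
are possible, so the NG86 estimate is mildly shrunk at high divergence.

Expression tables draw per-cultivar, per-gene expression from log-normal
distributions (positive and right-skewed, matching the 2^−ΔΔCt scale;
defaults mean 1, SD 0.5); the trait is intercept + Σβ_g·expr_g + Gaussian
noise (defaults intercept 10, noise SD 1). Replicates (default 3) add small
multiplicative log-normal noise (CV 0.05) to expression; the trait is a
cultivar-level phenotype and constant across replicates.
`beta_for_target_r2` converts a desired population R² for a single active
gene into its effect size. Optional promoter-genotype groups shift the
first gene's expression additively for the group-summary stage.

## Expression–trait statistics

Replicates are always collapsed to cultivar means first (the emulated
measurements are per-cultivar with technical replicates). Pearson r carries
a two-sided t-test p-value; with log-normal predictors at n = 30 this test
is mildly anticonservative (measured ≈1.8% rejections at nominal 1% under
the null), which the null-control tests allow for. Zero-variance input
yields a flagged undefined result.

The trait model is OLS on intercept + 3 main effects + 3 pairwise products;
it requires more cultivars than parameters and reports an error naming
collinear columns on rank deficiency. Expression enters on its reported
relative scale by default (a log2 flag is available in the CLI).

Variance contributions use the LMG decomposition over the three main
effects: the average over all 3! predictor orderings of each gene's
sequential R² increment. The shares telescope to the main-effects-model R²
(an exact identity, verified to 10⁻⁸), equal marginal R² exactly for
mutually orthogonal (centered) predictors, and are permutation-symmetric.
Interaction terms are reported separately from the partition. LMG was
chosen because a single-predictor R² cannot represent "percent of variance
explained" coherently for correlated predictors; the method label is
recorded in the output.

Genotype-group summaries report per-group means and dispersions with
pairwise two-sided Mann–Whitney tests, as descriptive output (no
multiple-testing selection is applied).

## Pipeline and reproducibility

Each run derives per-stage seeds deterministically from one global seed via
a seed sequence; identical config + seed reproduce byte-identical TSVs.
The manifest lists every stage, parameter, derived seed and output file,
and is validated for completeness. Reports are regenerated from the output
TSVs only.

## Problem sizes

The test suite and the acceptance script use a 1-Mb chromosome (~9,800
SNPs, 302 samples, 491 windows) for scan-level checks, 100–300-codon pairs
for Ka/Ks, and 15–30-cultivar panels for expression analyses — sizes chosen
so that every recovery check is well-powered while the full suite runs in
well under a minute.

## Known limitations

* NG86 ignores transition/transversion bias and codon-frequency effects;
  ML codon methods typically give slightly different Ks.
* No haplotype-based sweep statistics (XP-CLR, XP-EHH, iHS); the scan is
  frequency-based only.
* The drift kernel is exchangeable across sites; no LD, so window
  statistics are less autocorrelated than in real data.
* Empirical outlier thresholds guarantee outliers exist; they rank, they do
  not test. Gene-level calls inherit the ~5%-per-contrast noise floor
  described above.
* Multi-chromosome scans must currently be run per chromosome.
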