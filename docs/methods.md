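# Methods

`foniokit` re-implements, as a tested library, the population-genomic
inference stack used to ask whether two cultivated lineages — here white
and black fonio millet (*Digitaria exilis*, *D. iburua*) and their wild
relatives (*D. longiflora*, *D. ternata*) — were domesticated
independently and without gene flow.  Raw sequencing data are replaced by
a built-in coalescent generator, so every analysis can be exercised,
validated and benchmarked on data whose truth is known.

## Coalescent generator

The generator runs the standard n-coalescent with piecewise-constant
diploid population sizes.  Backward in time, lineages within a population
of size N coalesce at rate k(k−1)/2 per 2N generations; a *split* moves
the derived population's lineages into the ancestral population; a
*bottleneck* is a size reduction over a time interval.  Mutations follow
the infinite-sites model, dropped on branches as a Poisson process with
rate μ per bp per generation.  Loci and windows are internally
non-recombining and mutually unlinked; genotypes pair consecutive
haplotypes into diploids.

Two equivalent simulation paths share one demographic-event
representation:

* a Python path that returns full genealogies (window trees, haplotypes,
  FASTA sequences, genotype matrices), and
* a numba-compiled kernel that accumulates, per population pair, the
  expected branch length carrying each joint derived-allele-count class —
  the quantity the SFS likelihood needs.  The kernel is validated against
  the Python path, against closed forms (E[T2] = 2N; Watterson's
  E[S] = θ a_{n−1} L; the folded neutral spectrum ∝ 1/i + 1/(n−i);
  dxy ≈ 2μ(T + 2N_anc)) and against msprime as an independent oracle
  (means of π, S and dxy within three Monte-Carlo standard errors).

Default conditions mirror the study system: μ = 6.5 × 10⁻⁹ per bp per
generation, one-year generation time (an annual grass), two
cultivated/wild pairs with within-pair divergences of 25,000 (white) and
10,000 (black) generations and a deep between-pair divergence
(300,000 generations — old enough that window genealogies sort the pairs
essentially always), no migration anywhere.  Because the study's fitted
effective sizes are not printed in its main text, sizes are package
choices informed by the reported sequential-coalescent trajectories:
wild and ancestral N = 20,000; cultivated lineages carry a
post-divergence bottleneck at N = 2,000 that ends 2,000 generations ago
with an expansion to N = 10,000.  Sample sizes for the demographic
experiments are the study panel's: 21 + 8 diploids (white pair), 19 + 6
(black pair).

Partial self-fertilisation (white fonio selfs at ~99%) can be emulated by
rescaling N to N/(1+F) with F = s/(2−s); it is off by default and no
explicit selfing genealogies are simulated.

The generator emulates neutral, error-free data: no recombination within
windows, no gene flow, no sequencing error, no reference-mapping bias.
Passing tests therefore validate the *inference machinery*, not the
robustness of the method to those real-data complications.

## Genotype QC

Filters run in a fixed order: (1) mask genotypes below a depth threshold
(default 2, only when depths are present); (2) drop loci missing in more
than 5% of individuals; (3) drop individuals with more than 40% missing
data; (4) drop loci with minor-allele frequency ≤ 0.05 computed on the
retained individuals.  The MAF rule is strict ("keep iff MAF > cutoff")
everywhere, including the k-mer table.  The locus-missingness filter runs
before the individual filter; the order is a package convention, recorded
so filter reports are reproducible.

## Diversity statistics

Sliding windows default to 50 kb width and 10 kb step, 1-based closed
intervals.  Per window and population (after dropping loci missing in
more than 20% of that population's individuals): S, π (mean pairwise
difference from pairwise-complete allele counts, the unbiased
c(n−c)/C(n,2) per-site form), Watterson's θ = S/a_{n−1} with n the median
haploid sample size among used loci, and Tajima's D with the standard
variance constants (undefined, reported NaN, when S = 0, n < 3 or the
variance estimate is non-positive).  Per-site values divide by the full
window length; the number of SNPs actually used is reported so users can
re-normalise by accessible sites if they prefer.

dxy averages per-site differences over all cross-population allele pairs;
da = dxy − (π_A + π_B)/2 holds identically in the output.  One estimator
subtlety: dxy between a population and itself equals 2p̂q̂ while π carries
the n/(n−1) correction, so da(A, A) = −π/n rather than exactly zero — an
O(1/n) small-sample term, tested as such.

LD decay reports binned mean r² (squared Pearson correlation of genotype
codes, pairwise-complete) for intra-chromosomal pairs within 500 kb,
1 kb bins by default; monomorphic pairs are skipped and counted.

## Folded spectra

Spectra are folded to minor-allele counts (ancestral states unknown).
Sites must be genotyped in at least 80% of each population's individuals
(jointly, for a pair); sites with more calls are down-sampled
hypergeometrically with a fixed seed to the target haploid size, so every
site contributes to a single-dimension spectrum.  The joint spectrum
folds by the *total* minor allele; ties (count exactly half) keep the
variant whose population-A count is the smaller.

## k-mer diversity

Sequences decompose into canonical 31-mers (lexicographic minimum of the
k-mer and its reverse complement; k odd so no k-mer is self-complementary;
windows containing N are skipped).  Presence/absence across individuals
is filtered like an allele: minor allele count ≥ 2 and frequency > 0.05.
A strand-support filter (k-mer seen in both orientations in ≥ 20% of its
carriers) exists for sequencing-read input, where fragments sample both
strands; it is off by default because strand-resolved FASTA input cannot
satisfy it.  The Jaccard procedure splits the table into 100 random
sub-tables of 10,000 k-mers and computes, per within-group pair, the
dissimilarity 1 − |A∩B|/|A∪B| over k-mers present in at least one of the
two within the sub-table.

## Structure

PCA mean-imputes missing genotypes and fixes component signs by the
largest loading.  Ancestry follows the sNMF idea: the dosage matrix
(0/1/2 rescaled to [0, 1]) is factorised as Q·F with Q rows on the
probability simplex and F in [0, 1].  The optimiser is alternating
projected gradient descent with backtracking line search — monotone in
the masked least-squares objective by construction, with exact simplex
projection every iteration.  Missing dosages never enter the residuals
(PCA's mean imputation is a documented asymmetry).  Model choice masks a
random 5% of observed genotypes per run and scores the binomial
cross-entropy of their predictions; ten independent runs per K by
default, best run kept, K chosen by minimum mean cross-entropy (ties to
the smaller K).  No sparsity penalty is applied by default.  Individuals
join a cluster when their largest coefficient reaches 0.6, else they are
labelled admixed.

## Topology analyses

Per-window trees are neighbour-joining (scikit-bio's canonical NJ,
negative branch lengths clipped to zero) on genotype p-distances
(mean |code difference|/2 over pairwise-complete loci); windows with
fewer than a minimum number of SNPs (default 20) or fewer than four
usable tips are skipped.

Topology weighting: for four groups there are three unrooted pairings.
For each tree, one tip per group is drawn; the induced quartet topology
is decided by the four-point condition on topological (unit-branch-
length) path distances — for a binary tree the minimal sum identifies
the split, with ties shared equally.  Combinations are enumerated
exhaustively when their count allows (the study-scale panel gives
21·8·19·6 = 19,152 per window, vectorised), else sampled uniformly.
Both headline summaries are reported: the mean weight of each topology
and the fraction of windows where it carries the maximum weight.

The population tree uses the migration-free drift model: after centring
each SNP's population frequencies on their across-population mean and
scaling by √(p̄(1−p̄)), the covariance of two populations equals the
drift shared on their root path.  The within-population sampling variance
p̂(1−p̂)/(2n), averaged over SNPs, is subtracted from the diagonal.
Because centring is a linear projection, the fitted model is projected
the same way; branch lengths are non-negative least squares, topologies
are scanned exhaustively (≤ 6 populations), and near-equal fits are
resolved by a scale-invariant string order.  Support comes from a block
bootstrap (contiguous SNP blocks of 500–1000, resampled with
replacement; majority-rule consensus over canonical unrooted
bipartitions).

## Demographic inference

The composite likelihood treats each pair's folded joint SFS classes as
multinomial counts under expected proportions estimated by coalescent
simulation (branch-length weighting by default; literal mutation
dropping available as a cross-check).  Monomorphic classes are excluded
by default — under infinite sites the polymorphic proportions carry the
shape information — but an invariant-site mode exists (per-site class
probabilities μ·E[B_c]) and is what makes absolute sizes identifiable in
single-population settings; expected proportions are floored at 10⁻¹²;
pairs contribute additively to the total log-likelihood.  AIC = 2k − 2lnL̂
ranks models.

The optimiser honours the published schedule: per cycle a batch of
proposals is drawn from the current search ranges (uniform or
log-uniform per the prior); after three consecutive non-improving cycles
the ranges re-centre on the incumbent and shrink by 50%, clipped to the
prior box; 40 cycles by default.  All evaluations within a run share one
stream of simulated genealogies (common random numbers), so candidates
are compared on the same Monte-Carlo draw; independent runs vary the
stream.  A Nelder–Mead `polish` on the CRN surface is available for
local refinement.  Parametric bootstrap: pseudo-observed spectra are
simulated at the point estimates (observed per-pair site totals by
default), refitted with the optimiser initialised at the point values,
and percentile intervals reported; fewer than ten successful refits
flags the intervals unreliable.

The divergence-time recovery experiments add a search protocol tuned to
the geometry of this model: T is strongly correlated with the ancestral
and bottleneck sizes along a curved likelihood ridge, and Monte-Carlo
noise between *distant* parameter values defeats purely local search.
The protocol therefore (1) profiles T on a coarse grid with nuisance
sizes refitted per point, (2) runs the 40-cycle optimiser from the
profile optimum, and (3) alternates a fine CRN profile scan of T
(relative likelihoods along a one-parameter scan are smooth) with a
simplex refit of the nuisance sizes, three times.  Arbitration and final
reporting use higher-precision evaluations (up to 6 × 10⁴ genealogies).

## Problem sizes

The canned experiments run at: 500 windows of 50 kb for topology
weighting; 10⁴ unlinked SNPs for the covariance tree; 5 × 10⁴ unlinked
polymorphic sites and ~10⁷ total simulated genealogies per divergence-
time refit; 3 × 10⁴ sites for the bottleneck-versus-constant AIC
comparison; 20 windows of 15 kb (with full FASTA emission and k-mer
tables) for the diversity-ordering check.  These sizes give Monte-Carlo
uncertainties comfortably inside the tolerances the tests assert, and
are the package's reference desk scale.

## Known limitations

* No recombination within windows and no migration events — matching the
  accepted study models, but not extensible to gene-flow scenarios
  without extending the event grammar.
* The composite likelihood ignores linkage between sites within a locus;
  this is the standard SFS approximation and is exact here only because
  the generator simulates unlinked sites.
* Divergence-time estimates at desk scale carry a ~5–10% Monte-Carlo/
  optimiser uncertainty on top of data noise; the tests allow 15%.
* The drift-tree model is the linearised (small-drift) approximation;
  very long branches would need the full transformation Treemix applies.
* The k-mer stage holds tables in memory — appropriate for the simulated
  scale, not for decomposing hundreds of millions of read k-mers.
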