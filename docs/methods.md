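# Methods

This note documents the statistical models and numerical conventions behind
`popcons`, the choices made where several defensible conventions exist, and
what the synthetic-data tests do and do not demonstrate about real data.

## Genotype model and conventions

All analyses operate on a biallelic locus × sample matrix of alternate-allele
dosages {0, 1, 2} with a missing code. Positions are 1-based (VCF
convention) and all window arithmetic uses base-pair differences of these
positions. Every statistic is symmetric in allele labels, so which allele
the dosage counts is arbitrary but fixed. Pairwise statistics use
pairwise-complete observations; nothing is imputed, ever — a pair of samples
or loci with no co-called observations yields an explicitly undefined (NaN)
entry rather than a guess.

## QC cascade

Stages run in the order: locus call rate (< 0.90 removed), minor allele
count (< 3 removed), excess observed heterozygosity (> 0.6 removed, the
signature of erroneously merged paralogs), within-locality relative removal
(kinship β > 0.25), LD pruning (|r| > 0.5 within 100 kb), sample
missingness (> 25% removed), technical-replicate concordance and removal.
All removal conditions are strict inequalities.

Because sample removals shift locus call rates and allele counts slightly,
a single pass does not leave a matrix that jointly satisfies every
threshold. The cascade is therefore **iterated to a fixed point** (two
passes almost always suffice); the final matrix passes every filter
idempotently. The report records each pass's stages.

**Kinship** uses the allele-matching (β) estimator: per pair, the mean over
co-called loci of the probability that one random allele from each
individual matches, (x_i·x_j + (2−x_i)(2−x_j))/4, centred on the mean
matching M_B over all distinct pairs: β = (M − M_B)/(1 − M_B). β ≈ 0.25
for parent–offspring or full sibs, ≈ 0.5 for duplicates. Two conventions
matter:

* For *relative removal* the reference M_B is computed **within each
  locality**. With a range-wide M_B, population structure makes every
  within-locality pair look related (their matching exceeds the
  between-locality average) and the filter would decimate localities.
* Declared technical replicates are exempt from kinship removal; they are
  validated and removed by the dedicated replicate stage instead.

When several pairs exceed the threshold, the member with more missing data
is removed first (ties broken toward the later column), repeating until no
pair violates — this keeps the maximum amount of information.

**LD pruning** scans loci in genomic order per scaffold and removes a locus
whose |Pearson r| of dosages with any *kept* earlier locus within the window
exceeds the threshold; removed loci trigger no further removals. Whether
the statistic is r or r² is a config switch (`squared=`), since published
pipelines vary; the default thresholds |r|.

## Diversity

Per locus within a population with alt frequency p̂ over 2n_c called gene
copies: A = observed alleles; A_E = 1/(p̂² + (1−p̂)²); H_O = het calls /
called genotypes; H_E = 2p̂(1−p̂) · 2n_c/(2n_c − 1) (Nei's unbiased
small-sample factor — exposed behind the `unbiased` switch because tools
differ in the exact correction); F_IS = 1 − H_O/H_E averaged over
polymorphic loci (the ratio-of-means alternative is a switch). Tables
report means and standard errors over loci. Monomorphic loci are retained
(A = A_E = 1, H = 0) and excluded only from the F_IS mean.

SNP-panel heterozygosities are conditioned on variant sites and thus
inflated by ascertainment. Per-site ("autosomal") heterozygosity divides
instead by all callable sites — an explicit input, since the upstream
catalogue of invariant sites is outside this package's scope — with
invariant sites contributing zeros; values are conventionally displayed
×1000.

## Structure

Prevosti distance between individuals is half the mean absolute difference
in within-individual allele frequencies over co-called loci (= |x_i − x_j|/2
per biallelic locus). PCoA double-centres the squared distance matrix,
eigendecomposes, and scales eigenvectors by √eigenvalue; percent variance
per axis is its eigenvalue over the **sum of positive eigenvalues** (the
matrix need not be Euclidean; negative eigenvalues are excluded from the
denominator and never produce coordinates).

Pairwise F_ST is Weir–Cockerham θ for two populations with unequal sample
sizes, computed per locus from genotype counts (including observed
heterozygosity, so it is not a haploid approximation) and aggregated as the
ratio of sums of the among-population variance component a to the total
a + b + c — the standard multi-locus estimator, not a mean of per-locus
ratios. Negative estimates are reported as computed. Significance comes
from resampling loci with replacement (default 1000 replicates); the
one-sided p-value is the fraction of replicates with θ ≤ 0 (a percentile-CI
alternative is a switch; the choice only matters near θ = 0).

## LD-based Ne trajectories

At drift–recombination equilibrium, E[r²] ≈ 1/(α + 4N_e·c) for loci at
recombination fraction c, with α = 2.2 under the mutation-rate modifier
(α = 1 for pure drift); pairs at c reflect N_e about t = 1/(2c) generations
ago. The estimator:

* filters loci to within-population MAF ≥ 0.05 and call rate ≥ 0.5;
* computes genotype-correlation r² per same-scaffold pair and subtracts the
  unphased finite-sample term 1/n (n = co-called individuals);
* maps physical to genetic distance with a uniform 1 cM/Mb rate (no
  species map exists; configurable);
* bins pairs into 8 log-spaced bins over c ∈ [0.0005, 0.25], merging bins
  below 50 pairs rightward, and inverts
  N_e = (1/(4c̄)) · (1/mean r²_adj − α) per bin, dropping bins whose LD sits
  at or below the α floor;
* scales t to years with a generation time of 1.95 years (the study
  species' estimate) and brackets uncertainty with an individual-dropout
  bootstrap (default 10% dropped, 10 replicates; populations are eligible
  when ⌈0.9·n⌉ ≥ 5, so n = 5 runs on subsets of 4).

**Known limitation.** The inversion is calibrated for tightly linked pairs.
Against the forward Wright–Fisher oracle, point estimates at constant
N_e = 100 land within a factor of two (typically +20–70%) in bins with
c ≤ 0.02, and degrade toward the unlinked-loci regime (E[r²] → ~1/(3N))
at large c. The dropout envelope quantifies sampling noise only — it
brackets the point estimate, not this method bias — so trajectories should
be read as relative trends, not absolute censuses. Recovery tests
accordingly restrict the scan to c ≤ 0.01.

## Prioritisation

Rarefied allelic richness at a locus is the expected number of distinct
alleles in a hypergeometric draw of g gene copies,
AR_g = Σ_a [1 − C(N−N_a, g)/C(N, g)], computed with log-gamma for
stability and verified against exhaustive enumeration. "10 alleles" means
g = 10 gene copies (5 diploids). Loci with fewer than g called copies in
any population of the comparison are excluded so all values share a locus
set.

Leave-one-out contributions pool all genotyped individuals as one
collection: contribution_i = (AR(t) − AR(−i)) / (AR(t) − 1), the drop in
pooled rarefied AR normalised by the polymorphic excess above the
monomorphic floor of 1 (dividing by AR(t) instead is a switch). Values may
be negative: a strongly drifted population can pull pooled frequencies
toward fixation faster than its private alleles add richness.

Max-coverage selection enumerates all C(n_pops, budget) subsets exactly for
up to 20 populations (greedy fallback above, with a logged notice) and
returns every tied optimum. The resampled procedure draws 4 individuals
per population per iteration (100 iterations), rebuilds the allele × 
population incidence (an allele is "in" a population when observed at least
once among the drawn individuals; each biallelic locus contributes two
allele features), solves each budget, and tallies optima — ties split an
iteration's weight equally so tallies sum to the iteration count. The
conserved union's AR is rarefied at min(g, 2·4·budget), since a budget-1
draw holds only 8 gene copies.

## Synthetic data: what it does and does not emulate

The hierarchical generator draws, per locus, an ancestral frequency uniform
on (0.05, 0.95), then lineage frequencies by Balding–Nichols
Beta(p(1−F)/F, (1−p)(1−F)/F) around it, locality frequencies likewise
around their lineage, and genotypes binomial(2, q). Under this model the
expected Weir–Cockerham θ between localities approximates the compounded F
— the closed form used by the recovery tests. Loci sit on synthetic
scaffolds at uniform 20 kb spacing so windowed operations are exercised;
monomorphic realisations are retained.

Shared-ancestral drift alone cannot create alleles truly private to one
lineage (those arise from post-split mutation), so the generator also
supports **lineage-private variant classes**: a configurable fraction of
loci whose alternate allele segregates only in one lineage, at a frequency
uniform on (0.05, 0.5). The bundled four-population study-design fixture
uses island 14%, mainland 5%, peripheral 4%, which encodes the structure it
is meant to emulate: an isolated island lineage whose value lies in
complementarity, two mutually redundant high-diversity central localities,
and a drifted low-diversity peripheral one. On this fixture the island
population has the largest leave-one-out contribution while a central
population wins budget-1 coverage and two populations cover > 90% of
alleles, verified across fixture seeds.

What the generator does **not** emulate: realistic site-frequency spectra
(uniform ancestral frequencies are flatter than neutral expectations),
linked selection, isolation-by-distance within localities, genotyping error
beyond symmetric missingness, and allele dropout structure specific to
restriction-site data. Passing tests therefore demonstrate estimator
correctness under the stated models, not robustness to every artefact of
real reduced-representation data.

The Wright–Fisher simulator is the independent oracle for the LD–N_e
relationship: non-overlapping generations, 2N_e haplotypes per chromosome,
random mating with Poisson crossover counts (rate per bp × length Morgans),
loci initialised i.i.d. at frequency 0.5, final diploids sampled without
replacement and returned unphased.

## Numerical and degenerate-input conventions

* Beta parameters for drift F < 1e−9 degenerate to an identity draw.
* Correlations over co-called samples with a constant vector are undefined
  and treated as "no evidence" (no pruning; pair dropped from LD scans).
* Ne bins whose implied estimate falls below 1e−6 are dropped (the
  α floor).
* All generators and resampling procedures take explicit seeds; the
  pipeline derives per-stage seeds from one master seed via spawned seed
  sequences, so stages are independently reproducible.
* Problem sizes in the test-suite simulations (e.g. 2 000–5 000 loci,
  20–60 samples, Wright–Fisher populations of 50–500 over 150–300
  generations) were chosen as the smallest at which the oracle
  distributions stabilise; the acceptance script uses a 3 000-locus
  fixture.

## Scope notes

Upstream read processing, alignment, genotype calling and catalogue
construction are out of scope: the genotype matrix is the entry point, and
invariant-site counts for autosomal heterozygosity are an input. Spatial
ancestry models, admixture graphs and outlier scans are likewise out of
scope. Where a published analysis of this kind reports them, this package's
pipeline covers the remaining tables end to end.
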