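# Methods

This note documents the models, numerical choices and limitations behind
`retqtl`. Empirical figures quoted here are the ones the shipped analysis
scripts and test suite themselves compute.

## Study design and data model

The pipeline targets a two-strain comparison (BALB/cByJ "C" vs
B6(Cg)-Tyr(c-2J)/J "B6a") on spotted two-color cDNA arrays in a balanced
dye swap: for each age (4 and 8 months), four biological replicate
hybridizations with C on Cy5 / B6a on Cy3 and four with the fluors
reversed — 16 chips. ch1 is always Cy3 and ch2 Cy5, so
M = log2(ch2/ch1) is the Cy5/Cy3 log ratio and A = log2 sqrt(ch1*ch2) the
spot's average log intensity. The reader accepts any balanced design with
at least two chips per orientation x age cell; the missing-value rule
generalizes accordingly (below).

## Normalization chain

The order of operations matters and is fixed:

1. **Lowess** (per chip): M' = M - g(A), with g a tricube-weighted local
   linear regression on fraction f = 0.33 of the data with 3 robustifying
   iterations (statsmodels' implementation of the standard Cleveland
   smoother), evaluated at the observed A values. Robust iterations keep
   outlier spots from bending the trend. Flagged spots and spots with a
   nonpositive channel are missing (NaN) throughout; nothing is imputed.
   A chip needs at least 10 non-missing (M, A) pairs.
2. **SD rescaling** (across chips): each chip's values are multiplied by
   median_k(s_k) / s_j, where s_j is the chip's SD over non-missing values
   (denominator n-1). Afterwards every chip's SD equals the pre-scaling
   median exactly (unit test at 1e-12). A zero-SD chip is an error, not a
   silent pass-through.
3. **Dye effect**: genes incorporate the two dyes unequally, and this
   gene-specific bias has the same sign in both orientations while the
   biological strain effect flips. With v1/v2 the per-gene means over the
   two orientations, D = (v1 + v2) / 2; correction subtracts D from
   C-on-Cy5 chips and maps B6a-on-Cy5 chips through v -> -v + D, after
   which every chip estimates log2(C/B6a).
4. **Missing-value filter**: a gene is dropped if half or more of its
   values in either orientation are missing (4 of 8 in the canonical
   design; ceil(n/2) otherwise). The threshold sits at the stated "four or
   more of eight" boundary and is tested there.

Probe-level normalization precedes gene-level analysis; multiple probes per
gene are collapsed by the per-chip median (robust to one bad clone). SD in
the rescale step is therefore a probe-level quantity when probes are
replicated.

**Known limitation — SD rescaling vs asymmetric signal.** Equalizing chip
SDs assumes regulated genes contribute negligibly to the per-chip SD. When
a large fraction of genes carries an effect at only one age, the
higher-variance chips are shrunk toward the median and the recovered
effects with them (about 17% at the synthetic defaults with a
one-age-only effect on 10% of 500 genes). With realistic regulated
fractions on ~20k-gene arrays the distortion is negligible, and with
effects present at both ages it cancels. The recovery tests that exercise
the full chain therefore plant effects at both ages; the age-dependency
contrast is tested on matrices that enter the chain after rescaling.

## Differential expression and permutation FDR

Comparisons: (1) all chips, (2) 4-month chips, (3) 8-month chips — each a
one-group t test of mean log2(C/B6a) against zero, t = mean / (sd/sqrt(n)),
two-sided p from t with n-1 df — and (4) age dependency, a Welch two-sample
t between the 8- and 4-month chip values per gene (Welch because equal
variances are not guaranteed; the choice is conservative). Genes need at
least 3 non-missing values per subset; a zero-SD gene has no defined t and
is excluded from FDR ranking with a warning.

The FDR follows the Significance Analysis of Microarrays permutation
scheme with exchangeability constant s0 = 0 (a plain t, matching the
one-group test above; an s0 can be supplied where shrinkage is wanted).
Null statistics come from random sign flips drawn per chip column
(one-group) or random age-label shuffles (two-sample), applied to all genes
at once so gene-gene correlation is preserved. For a threshold c,
q(c) = median over permutations of #{null |t| >= c} divided by
#{observed |t| >= c}; per gene, q = min over thresholds at or below its
|t| (the usual q-value monotonization), capped at 1. Defaults: 1000
permutations (minimum 100), seed recorded in the output header.

"Regulated" means (FC >= 1.2 or FC <= 0.8) and q < 0.05. The fold-change
boundaries are inclusive — a gene at FC exactly 0.8 is regulated — and the
conjunction binds both FC branches: a large fold change alone never
qualifies. Calibration: on pure-null simulations (500 genes, 1000
permutations, 10 seeds) the mean fraction of q < 0.05 calls is below the
nominal 0.05 (acceptance suite).

## Gene-set overrepresentation

For a term with n measured genes, r of them changed, in a universe of N
measured annotated genes with R changed:

    z = (r - nR/N) / sqrt( n (R/N) (1 - R/N) (1 - (n-1)/(N-1)) )

— the count standardized by its exact hypergeometric mean and variance
(verified against enumeration for every N <= 30). Zero-variance corners
(R = 0, R = N, n = N) define z = 0 with a warning. The permutation p
shuffles changed/unchanged labels over the measured genes and uses the
add-one estimator p = (1 + #{null z >= observed}) / (1 + n_perm), so p is
never exactly 0 and needs n_perm >= 1000 to resolve the p < 0.01 filter;
a published "0" is read as "< 0.001". The ranked list keeps terms with
p < 0.01, z >= 2, percent changed strictly > 10, and at least 2 changed
genes, sorted by p then z. N and R count only genes both on the array and
annotated. Up-regulated and down-regulated gene lists are analyzed
separately per age (four runs), as in the published four-block layout.
DAG rollup (genes propagated to ancestor terms) is optional because it is
not recoverable whether the original analysis used the full hierarchy or a
slim; both paths are supported and the rollup is idempotent and
cycle-checked.

## Candidate scoring

Genes overlap a QTL interval on closed megabase coordinates (a
boundary-touching gene counts — the interval "encompasses" its edge
genes). The haplotype filter requires at least one SNP per gene with
B6 != C and A != C; an unreported A allele ("?") can never establish a
pass. The evidence score is

    score = I[PosMed member] + I[regulated at either age]  in {0, 1, 2}.

"Either age" is the documented reading: a gene regulated only at 4 months
still earns the point. Genes absent from the array ("NP") are distinct
from FC = 1 and carry false regulated flags. PosMed is consumed as a
static keyword gene list; querying the service is out of scope.

The two shipped reference tables (`retqtl/data/table3.tsv`, `table5.tsv`)
transcribe the published Chr 6 (29 rows) and Chr 10 (16 rows) candidate
lists. Rescoring them from their own PosMed/fold-change columns reproduces
44 of the 45 printed scores; the one exception (Gkn1: no PosMed hit,
FC 1 and 0.9, printed score 1) contradicts the published rule applied to
its own inputs and is evidently a misprint in the source table. The row is
transcribed as printed, the implementation follows the rule, and the
corresponding per-row check is left failing by design (documented in the
table header and the test docstring).

## qPCR relative expression

dCt = Ct(target) - Ct(beta-actin), computed per biological replicate after
averaging technical triplicate wells (the pools, not the wells, are the
unit of replication). Fold relative to the calibrator group (B6a at
4 months, fold = 1 by construction):

    fold = (1 + AE) ^ (dCt_calibrator - dCt_group),  AE = 1.0 by default.

The exponent's sign follows the standard Livak orientation — a more
abundant target (lower dCt) gives fold > 1. Read literally, the source
text's "experimental minus control" ordering would invert this and report
fold < 1 for more-abundant targets, contradicting its own reported
direction of change; the conventional orientation is implemented. Folds
are invariant to any global Ct shift (property-tested).

Group comparison: one-way ANOVA, then Holm-Sidak stepdown on all pairwise
two-sample t tests — order the m raw p ascending,
adj_k = 1 - (1 - p_k)^(m - k + 1), running-max monotonized, clipped at 1
(cross-checked against statsmodels' holm-sidak). Tests run on the dCt
scale by default, where normality is more plausible than on folds; a flag
switches to folds since the original scale is not recoverable.

## ONL phenotype

The sampling scheme is fixed: 2 hemispheres x 9 sets x 3 positions = 54
thickness measurements per section, in micrometers. The per-animal mean
over non-missing slots is the unit of analysis — slots within an eye are
not independent, so raw points never enter the ANOVA. Missing slots
(retinal tears) are masked. Genotype association reuses the ANOVA /
Holm-Sidak machinery; the additivity gap,
mean(HET) - (mean(B6a/B6a) + mean(C/C)) / 2, is 0 under a purely additive
allele effect and NaN when the heterozygote/homozygote trio is incomplete
(e.g. knockout +/+ vs +/- comparisons). p values are invariant to unit
rescaling.

## Synthetic data: what it emulates, and what it does not

Generated intensities follow log2 ch1 = A - M/2, log2 ch2 = A + M/2 with
A ~ Uniform(6, 14) (a typical spotted-array log-intensity range) and

    M = c_chip * (orientation * s_gene(age) + noise) + d(A) + D_gene,

where s is the planted strain effect (default: 10% of genes at 1.0 log2
units, random sign), d(A) = 0.4 sin((A - 6)/2.5) the intensity-dependent
dye bias (nonlinear so the Lowess step is genuinely exercised), D_gene ~
N(0, 0.3) the sequence-specific per-gene dye effect, c_chip ~
exp(N(0, 0.1)) the per-chip scale, and noise N(0, 0.2). Missingness is an
independent per-spot flag (default 2%), never a blank cell. Defaults were
chosen once as plausible magnitudes for spotted cDNA arrays of this era.
At these settings the pipeline recovers the per-gene dye effect at
r = 0.975 and strain effects with +0.002 log2 bias (analysis script 02).

The generators do not emulate: spatial/print-tip artifacts, background
subtraction issues, correlated missingness (e.g. whole bad subgrids),
intensity-dependent variance, cross-hybridization between clones, or real
genome coordinates. Passing recovery tests therefore show the estimators
are correct under the stated stochastic model, not that the model captures
every failure mode of real slides.

SNP, GO, qPCR and ONL generators plant, respectively: a fraction of
haplotype-passing genes (with decoy SNPs including unknown-A cases), one
enriched term (80% of its genes changed over a 10% background), group
folds via dCt = dCt_cal - log2(fold)/log2(1+AE) with sigma_Ct = 0.2 and
triplicate pools, and additive genotype means (44/40/36 um, sigma = 2 um,
20 animals per genotype). All generators are byte-deterministic given a
seed, and every downstream test compares against the serialized truth,
never against hard-coded constants.

## Degenerate inputs and tie-breaking

Zero-SD genes/chips error or flag rather than divide by zero; q values and
Holm-Sidak adjustments are clipped to [0, 1]; the enrichment sort breaks p
ties by z descending; candidate tables sort by interval, score descending,
gene id, so output order is a pure function of content. Chromosome naming
("chr10" vs "10") is normalized on comparison.

## Problem sizes

The shipped analyses and tests run at 500 genes x 16 chips with 1000
permutations (100-run seed sweeps for the recovery-rate checks) — small
enough to re-run anywhere in minutes, large enough that the planted-truth
recovery criteria (dye-effect r > 0.9, FDR calibration, >= 95/100 GO
recoveries) are meaningful. The real study's scale (~42k probes) changes
only run time, not code paths.
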