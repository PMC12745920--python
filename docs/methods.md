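# Methods

`refugia` implements a complete two-population demographic-inference
pipeline of the kind used to test whether forest-understorey lineages
diverged in separate glacial refugia before the Last Glacial Maximum
(LGM, ~21 ka): post-calling SNP filters, joint site-frequency-spectrum
(JSFS) construction with hypergeometric down-projection, a diffusion
engine for the expected JSFS under nine divergence scenarios, composite-
likelihood fitting with AIC-based model selection, parametric-bootstrap
goodness of fit and divergence dating, plus the exploratory statistics
(private alleles, nucleotide diversity, Evanno delta-K, admixture
filtering, Schoener's niche overlap) that feed the refugium criteria.

## The diffusion model

Allele frequencies `(x, y)` in the two descendant populations follow the
Wright-Fisher diffusion

    d phi/d tau =   1/(2 nu1) d^2/dx^2 [x(1-x) phi]
                  + 1/(2 nu2) d^2/dy^2 [y(1-y) phi]
                  - d/dx [M12 (y - x) phi] - d/dy [M21 (x - y) phi]

with time `tau` in units of `2 N_ref` generations, sizes `nu_i` relative
to the ancestral effective size `N_ref`, and migration rates
`M_ij = 2 N_ref m_ij` (`m_ij` = fraction of population `i` replaced by
migrants from `j` per generation). New mutations enter each population
at rate `theta/2` per unit time at the lowest frequencies; the engine
computes spectra per unit `theta = 4 N_ref mu L` and the data determine
the scale through the analytically optimal `theta_hat`.

The ancestral population sits at the standard equilibrium (`phi = 1/x`
per unit theta, computed as the exact fixed point of the discrete
scheme) and splits at time `T_total` before the present. The nine
scenarios combine two families with one- or two-epoch migration
histories:

| family | sizes after the split | scenarios |
|---|---|---|
| vicariance | `(s, 1-s)`, constant | no migration; ancient symmetric migration (epoch 1 only); secondary contact (epoch 2 only) |
| founder | `(1-s, s -> nu2)`; the founded deme grows exponentially over the whole divergence time | no migration; symmetric; asymmetric; ancient symmetric; secondary contact symmetric; secondary contact asymmetric |

Free-parameter counts are (2, 4, 4) for the vicariance scenarios and
(3, 4, 5, 5, 5, 6) for the founder scenarios. Founder growth follows
`nu2(tau) = s (nu2/s)^(tau/T_total)` continuously across epoch
boundaries; because growth is attached to the whole divergence time, the
two-epoch founder scenarios change only their migration regime at the
epoch boundary. Founder scenarios designate population 2 as the founded
deme, so each is additionally fitted with the populations swapped to
test the opposite colonisation direction (vicariance scenarios cover
both assignments through `s`).

## Engine numerics

- **Grid.** Frequencies are discretized on a grid uniform in a
  tanh-transformed coordinate (crowding strength 2.5), refining toward
  the absorbing boundaries where the density is steep.
- **Finite volumes, operator splitting.** Each time step sweeps the two
  axes alternately (order alternates between steps to symmetrize the
  splitting). Drift uses conservative flux differencing of
  `(1/2) d^2[V phi]` and is solved implicitly; a trapezoidal
  (Crank-Nicolson) weighting with four implicit start-up steps gives
  second-order accuracy in the step size (default 0.005 time units).
- **Migration.** The advection term is discretized with centred
  interface fluxes and folded into the same per-axis implicit solve.
  Two earlier designs failed measurably and are worth recording: a pure
  upwind flux is CFL-stable only explicitly and its first-order
  numerical diffusion left persistent 5-12% errors at edge entries; and
  centred fluxes must not draw on the two absorbing corner cells (lost
  and fixed), whose accumulated mass otherwise leaks back and corrupted
  the adjacent entries by ~25%. Corner-adjacent interfaces therefore
  use one-sided interior values. Edge *lines* (a variant absent in one
  population) are genuine density, and their advective exchange with the
  interior -- migrant reintroduction of absent or fixed variants -- is
  physical and retained.
- **Mutation injection.** Half of each step's mutation influx is added
  before and half after the sweeps; this makes the scheme's fixed point
  the exact discrete equilibrium (`A phi + b = 0`) and removes an
  `O(dt)` bias at the singleton entries (2.6% at the default step before
  the fix, <0.1% after).
- **Sampling and extrapolation.** Expected entries are binomial-sampling
  integrals of `phi` with trapezoid weights; each entry is Richardson-
  extrapolated to zero grid spacing from three resolutions (default
  grids 40/50/60 for samples up to ~20). Tiny negative entries left by
  extrapolation are clipped to zero. The absorbing corners map onto the
  two masked spectrum corners.

Accuracy, measured rather than assumed: the relaxed single-population
spectrum matches `theta nu / i` to <1% (n=10), the T=0 spectrum matches
the single-pool closed form to <0.1%, and across 27 scenario/parameter
configurations every spectrum agrees entrywise with an independent
structured-coalescent Monte-Carlo oracle (msprime, branch-length
spectra, 30k genealogies) within 3 Monte-Carlo standard errors for
>=95% of unmasked entries. The faster preset used inside fitting loops
(grids 25/35/45, step 0.015) is accurate to ~0.7%, well below the
sampling noise of the spectra being fitted.

## Likelihood, optimization, model selection

The composite likelihood treats unmasked spectrum entries as independent
Poisson counts with mean `theta * M_ij` (valid for unlinked SNPs, hence
the single-SNP-per-locus filter). `theta_hat = sum D / sum M` is the
analytic optimum; profiling it out makes the Poisson and multinomial
formulations equivalent up to a data-only constant, so "multinomial"
log-likelihoods and these differ by an additive constant that cancels in
all comparisons. A model entry of zero where data are observed yields
`-inf` (with a warning outside optimization loops).

Optimization follows the staged multi-start protocol common in SFS
fitting: four rounds with per-parameter multiplicative perturbations
`2^U(-f, +f)` of the incumbent best, fold sizes (3, 2, 2, 1), replicate
counts (60, 70, 70, 80), and Nelder-Mead refinement in log-parameter
space capped at (10, 10, 10, 15) iterations. The best log-likelihood is
non-decreasing across rounds by construction (the incumbent is kept).
Default bounds: `s` in [0.01, 0.99], sizes in [1e-3, 100], `M` in
[0, 20] (floored at 1e-6 inside the log transform), `T` in [1e-3, 15].
Model selection uses `AIC = 2k - 2 logL` and Akaike weights
`w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2)`.

## Goodness of fit, dating, the pre-LGM test

The parametric bootstrap draws (by default 100) Poisson datasets from
`theta_hat * M`, records each replicate's log-likelihood and Pearson
chi-squared statistic (log10 copies stored for plotting), and flags
whether the empirical values fall inside the central 95% band. Two
modes: *evaluate* (default) scores replicates at the best-fit
parameters -- cheap, and exactly calibrated for the band-coverage check;
*refit* re-optimizes each replicate with a reduced schedule (folds
(3, 2, 1), reps (20, 20, 20)) and is required for parameter confidence
intervals (percentile 2.5-97.5 over the re-estimates). Per-replicate
divergence times in years use `T * 2 N_ref * g` with
`N_ref = theta_hat / (4 mu L)`; in evaluate mode only `theta_hat`
varies across replicates, in refit mode `T` does too. Defaults
`mu = 7e-9` per site per generation (the Arabidopsis spontaneous rate
commonly borrowed for herbs) and `g` = 10 years (weakly clonal
perennials) or 20 (strongly clonal); `L`, the surveyed length behind
`theta`, is deliberately a required input -- RADseq reports rarely print
it, and absolute dates scale linearly with `1/L`.

The pre-LGM test is a one-sided Wilcoxon signed-rank test of the
simulated times against a 20 ka null (zeros dropped; exact null
distribution up to n=25 untied values, normal approximation with tie
correction above), reported with the Hodges-Lehmann pseudomedian
(median of Walsh averages), the signed-rank-inversion confidence
interval, and the fraction of simulated times younger than the null.
The implementation reproduces R's `wilcox.test` (exact p, estimate and
CI) on reference samples.

## Filters and exploratory statistics

Genotype-level filters mask individual calls (DP in [10, 50] and
GQ >= 20 pass, bounds inclusive) rather than dropping sites, so
partially genotyped sites still feed the projected spectrum. Site-level
filters then drop sites with called-genotype fraction below `R`
(default 0.8 over all individuals; a per-population variant is
selectable) or observed heterozygosity above 0.65, and optionally keep
only the first surviving SNP per RAD locus. The order
genotype -> site -> single-SNP is fixed and the chain is idempotent.

Private alleles count (site, allele) pairs seen in exactly one
population (missing calls ignored). Nucleotide diversity uses the
unbiased per-site estimator `n/(n-1) (1 - sum p_a^2)` summed over
variant sites and divided by a caller-supplied surveyed-site total,
making the RADseq denominator explicit instead of implicit.

Cluster-number diagnostics implement Evanno's
`deltaK = |L(K+1) - 2L(K) + L(K-1)| / sd(L(K))` on replicate
log-likelihood traces; the admixture filter keeps populations whose
major cluster proportion strictly exceeds 0.5 with the second below
0.35; a proposed geo-genetic group is validated when at least two of
{distinct cluster, divergent network branch, geographic isolation}
hold for all members (isolation is expert judgment, supplied by the
caller; a distance-threshold helper is provided).

Niche overlap follows the gridded-density recipe: occurrence and
background clouds are kernel-smoothed (product-Gaussian, Scott plug-in
bandwidth unless given; bandwidth logged because published values rely
on package defaults) onto a 100x100 grid spanning the background
extent, occurrence density is divided by availability and renormalized,
and `D = 1 - 0.5 sum |z1 - z2|`.

## Synthetic data: what it does and does not emulate

The generator draws unlinked biallelic sites whose joint counts are
Poisson around the scenario's expected JSFS, assigns alleles to diploid
genotypes by simple random allocation, and adds per-genotype depth
(rounded normal, default 30 +- 6), quality (GQ ~ min(99, 4 DP) plus
small noise -- a fixture convention, not an error model) and uniform
missingness. Loci can carry several consecutive SNPs to exercise the
single-SNP filter. The true ancestral allele is the REF allele;
downstream folding is what discards that information. Defaults (20+20
haploid samples, ~5000 segregating sites, depth well inside the filter
window) mirror the scale of a per-species RADseq dataset after
filtering.

Not emulated: linkage within loci (sites are independent even within a
multi-SNP locus), allele-dropout or depth-dependent genotyping error,
selection, more than two demes, and reference-mapping artefacts.
Passing tests therefore validate the inference machinery, not
robustness to those real-data pathologies.

The independent oracle simulates one structured-coalescent genealogy
per site with msprime (sizes `2 N_ref nu`, times `2 N_ref T`
generations, backwards lineage-movement rates `M/2`, founder growth as
a continuous exponential rate) and averages branch-mode frequency
spectra, so oracle noise is genealogical only and its per-entry
standard errors give a calibrated agreement test.

## Experiment sizes and design choices

Validation experiments are sized for a single-CPU desk run and stated
in `refugia.experiments`: 30k genealogies per oracle configuration
(tolerances are expressed in Monte-Carlo SEs and scale accordingly), 10
parameter-recovery replicates per scenario at ~5000 segregating sites,
20 model-selection replicates per family with a deliberately light
schedule (folds (2, 1), reps (6, 8)) -- the vic/founder contrast at
this data size does not need the full protocol -- and 40 bootstrap-
coverage repetitions.

One practical observation from the end-to-end synthetic analysis: when
the observed spectrum is built by *projecting* partially genotyped
sites, each site spreads fractional mass over several entries, so the
observed spectrum is slightly under-dispersed relative to the Poisson
parametric bootstrap. The empirical log-likelihood then sits near (and
sometimes above) the top of the bootstrap band — the model fits "too
well". The band-coverage calibration uses integer Poisson spectra,
where the test is exact; on projected spectra the goodness-of-fit flag
should be read with this asymmetry in mind.

Known limitations: composite-likelihood AIC ignores residual linkage,
so real-data weights can be overconfident; absolute dates inherit the
full uncertainty of `mu`, `g` and `L`; the evaluate-mode bootstrap
understates parameter uncertainty relative to refit mode; and the
engine is validated for sample sizes up to ~20 per population --
larger spectra need larger grids.
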