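# refugia

Demographic inference of divergence between Pleistocene forest refugia
from reduced-representation (RADseq) SNP data.

Phylogeographic studies of temperate forest plants ask whether today's
disjunct populations descend from separate glacial refugia — which
requires showing that lineages *diverged before* the Last Glacial
Maximum (~21 ka) rather than during postglacial recolonisation, and
telling apart divergence modes: a **vicariance** event (an ancestral
range fragmenting into pieces `s` and `1-s`) versus a **founder** event
(a colonising deme starting at fraction `s` of the ancestor and growing
exponentially to `nu2`). `refugia` provides the full analysis stack
used for that question, exercisable end-to-end on synthetic data:

- post-calling genotype/site filters (DP ∈ [10,50], GQ ≥ 20,
  heterozygosity ≤ 0.65, presence ≥ R, one SNP per RAD locus);
- folded two-dimensional joint site-frequency spectra (2D-JSFS) with
  hypergeometric down-projection and a best-projection search;
- a Wright-Fisher **diffusion engine** computing the expected 2D-JSFS
  under nine divergence scenarios (3 vicariance + 6 founder, with
  ancient-migration and secondary-contact variants), validated
  entrywise against an independent structured-coalescent oracle
  (msprime);
- composite (Poisson) likelihood with analytic θ scaling, staged
  multi-start optimization (folds 3/2/2/1, reps 60/70/70/80), AIC and
  Akaike weights, founder scenarios fitted in both colonisation
  directions;
- parametric-bootstrap goodness of fit (100 simulations,
  log-likelihood and Pearson χ² bands), conversion of divergence times
  to years via `N_ref = θ̂/(4μL)` (μ = 7×10⁻⁹, generation time 10 or
  20 y), and a one-sided Wilcoxon signed-rank test against a 20 ka
  null with Hodges–Lehmann pseudomedian and confidence interval;
- the satellite statistics behind refugium criteria: private alleles,
  nucleotide diversity π, Evanno ΔK, the >50 %/<35 % admixture filter,
  two-of-three geo-genetic-group validation, and Schoener's D niche
  overlap on background-corrected 100×100 density grids.

The model/fit surface follows the statsmodels idiom: a
`DivergenceModel` built from data whose `fit()` returns a
`DivergenceResult` with estimates, `summary()`, goodness of fit,
dating and plots. See `docs/methods.md` for the model, numerics and
design decisions.

## Worked example

```python
import refugia as rf

# 1. a synthetic RADseq dataset: vicariance at s=0.3, T=0.4 (2N_ref gens)
cfg = rf.SimConfig(model_name="vic_no_mig", params={"s": 0.3, "T": 0.4},
                   n1=12, n2=12, n_sites=40_000, theta_per_dataset=1500.0,
                   missing_rate=0.08, seed=42)
gm = rf.simulate_genotype_dataset(cfg)

# 2. filter and build the folded joint SFS at a (10, 10) projection
filtered, tally = rf.apply_filters(gm, rf.FilterConfig())
spec = rf.build_jsfs(filtered, "pop1", "pop2", 10, 10, fold=True)

# 3. fit the scenario and date the split
dm = rf.DivergenceModel(spec, "vic_no_mig")
res = dm.fit(schedule=rf.OptimSchedule(folds=(3, 2, 1), reps=(20, 20, 20),
                                       maxiters=(10, 10, 15)), seed=1)
print(res.summary())
res.gof(n_sims=100, seed=2)
cc = rf.ConversionConstants(mu=7e-9, L=100 * cfg.n_sites, g=10)
print(res.pre_lgm_test(cc))
```

Output (abridged) from this exact script:

```
Divergence scenario fit
=======================================================
scenario:        vic_no_mig (vicariance)
orientation:     as-is
populations:     pop1 / pop2
sample sizes:    (10, 10) folded
segregating mass: 4704.8
-------------------------------------------------------
     s = 0.3003
     T = 0.4051
-------------------------------------------------------
log-likelihood:  -167.044
theta_hat:       1290
k (free params): 2
AIC:             338.088
{'p_one_sided': 1.97e-18, 'pseudomedian': 93.42, 'ci': (93.13, 93.70),
 'fraction_below_null': 0.0, 'n_nonzero': 100}
```

Read: the split fraction and divergence time are recovered (truth 0.3
and 0.4); with θ̂ ≈ 1.29×10³ over 4 Mb of surveyed RAD sequence,
`N_ref ≈ 11.5×10³`, the split dates to a pseudomedian ≈ 93 ka with
all 100 bootstrap replicates predating 20 ka — a clearly pre-LGM
divergence, as simulated. (The evaluate-mode bootstrap varies only θ̂
across replicates, hence the narrow interval; `refit=True` propagates
parameter uncertainty too.)

A `refugia` command-line tool wraps the same steps
(`refugia simulate | filter | sfs | expected | fit | gof | popstats |
groups | overlap`); `refugia fit AB.sfs --models all -o fits.tsv`
writes the AIC ranking table.

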