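"""Synthetic data under the nine divergence scenarios.

Everything the pipeline consumes can be generated here: expected/observed
joint spectra, structured-coalescent Monte-Carlo spectra (the independent
oracle used to validate the diffusion engine), RADseq-like genotype
datasets with per-genotype depth/quality/missingness, and cluster-
assignment matrices for the admixture filter.

Scaling conventions match the diffusion engine: the ancestral effective
size is the reference (``N_ref``), sizes are relative to it, scenario
times are in units of ``2 N_ref`` generations and migration rates are
``M = 2 N_ref m``.  The coalescent oracle therefore runs msprime with
haploid populations of size ``2 N_ref nu`` (taking ``N_ref = 1``), split
times ``2 T`` generations, backwards lineage-movement rates ``M/2``
(equal to the forward replacement fraction), and founded-deme growth as a
continuously varying coalescence rate via msprime's exponential
``growth_rate`` — not a stepwise approximation.  Branch-mode frequency
spectra divided by ``4 N_ref`` give the expected spectrum per unit theta.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .demography import ModelSpec, get_model
from .engine import EngineConfig, DEFAULT_ENGINE, expected_sfs
from .genotypes import MISSING, GenotypeMatrix
from .spectrum import Spectrum2D, poisson_sample


def default_gq_model(dp: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Fixture convention for genotype quality: GQ ~ min(99, 4*DP) with
    small integer noise.  Not a calling-error model; it exists so the GQ
    filter has realistic values to act on."""
    gq = np.minimum(99, np.round(4.0 * dp)).astype(np.int64)
    gq = gq + rng.integers(-3, 4, size=dp.shape)
    return np.clip(gq, 0, 99)


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    ``theta_per_dataset`` is the total mutation input ``4 N_ref mu L``
    that scales the expected spectrum into expected site counts.
    Coverage defaults sit comfortably inside the DP in [10, 50] filter
    window so that permissive-filter round trips keep every site.
    """

    model_name: str = "vic_no_mig"
    params: dict = field(default_factory=lambda: {"s": 0.5, "T": 0.2})
    n1: int = 20
    n2: int = 20
    n_sites: int = 5000
    theta_per_dataset: float = 1000.0
    coverage_mean: float = 30.0
    coverage_sd: float = 6.0
    gq_model: Callable = default_gq_model
    missing_rate: float = 0.0
    snps_per_locus: int = 1
    seed: int = 0

    def __post_init__(self):
        get_model(self.model_name)  # raises for unknown names
        if self.n1 < 2 or self.n2 < 2 or self.n1 % 2 or self.n2 % 2:
            raise ValueError("n1 and n2 must be even and at least 2")
        if self.n_sites < 1:
            raise ValueError("n_sites must be at least 1")
        if self.theta_per_dataset <= 0:
            raise ValueError("theta_per_dataset must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.snps_per_locus < 1:
            raise ValueError("snps_per_locus must be at least 1")


# -- structured-coalescent oracle ----------------------------------------


def _msprime_demography(model: ModelSpec, params: dict):
    """Translate a catalog scenario into an msprime demography.

    This is written directly from the scenario definitions (sizes,
    epochs, migration), independently of the diffusion engine's epoch
    machinery, so that agreement between the two is a genuine
    cross-validation.
    """
    import msprime

    p = model.validate(params)
    dem = msprime.Demography()
    # sizes are haploid-lineage pool sizes: 2 * N_ref * nu with N_ref = 1
    if model.family == "vicariance":
        nu1, nu2 = p["s"], 1.0 - p["s"]
        dem.add_population(name="pop1", initial_size=2 * nu1)
        dem.add_population(name="pop2", initial_size=2 * nu2)
    else:  # founder: pop1 keeps 1-s; pop2 grew from s to nu2
        t_total = p.get("T", 0.0) + p.get("T1", 0.0) + p.get("T2", 0.0)
        dem.add_population(name="pop1", initial_size=2 * (1.0 - p["s"]))
        if t_total > 0:
            growth = np.log(p["nu2"] / p["s"]) / (2 * t_total)
        else:
            growth = 0.0
        dem.add_population(name="pop2", initial_size=2 * p["nu2"],
                           growth_rate=growth)
    dem.add_population(name="anc", initial_size=2.0)

    # migration epochs; backwards lineage movement source->dest equals
    # forward replacement of source by migrants from dest
    def set_rates(time, m12, m21):
        if time == 0:
            dem.set_migration_rate(source="pop1", dest="pop2", rate=m12 / 2)
            dem.set_migration_rate(source="pop2", dest="pop1", rate=m21 / 2)
        else:
            dem.add_migration_rate_change(time=time, source="pop1",
                                          dest="pop2", rate=m12 / 2)
            dem.add_migration_rate_change(time=time, source="pop2",
                                          dest="pop1", rate=m21 / 2)

    name = model.name
    if name == "vic_no_mig":
        t_total = p["T"]
    elif name == "vic_anc_sym_mig":
        # forward: migration during T1 (old), none during T2 (recent)
        t_total = p["T1"] + p["T2"]
        set_rates(0, 0.0, 0.0)
        set_rates(2 * p["T2"], p["M"], p["M"])
    elif name == "vic_sec_contact_sym_mig":
        t_total = p["T1"] + p["T2"]
        set_rates(0, p["M"], p["M"])
        set_rates(2 * p["T2"], 0.0, 0.0)
    elif name == "founder_nomig":
        t_total = p["T"]
    elif name == "founder_sym":
        t_total = p["T"]
        set_rates(0, p["M"], p["M"])
    elif name == "founder_asym":
        t_total = p["T"]
        set_rates(0, p["M12"], p["M21"])
    elif name == "founder_anc_sym_mig":
        t_total = p["T1"] + p["T2"]
        set_rates(0, 0.0, 0.0)
        set_rates(2 * p["T2"], p["M"], p["M"])
    elif name == "founder_sec_contact_sym":
        t_total = p["T1"] + p["T2"]
        set_rates(0, p["M"], p["M"])
        set_rates(2 * p["T2"], 0.0, 0.0)
    elif name == "founder_sec_contact_asym":
        t_total = p["T1"] + p["T2"]
        set_rates(0, p["M12"], p["M21"])
        set_rates(2 * p["T2"], 0.0, 0.0)
    else:  # pragma: no cover
        raise ValueError(f"unknown model {name!r}")
    # a strictly positive split time keeps the sampled populations active
    # at time 0 even for the T=0 limiting case
    dem.add_population_split(time=max(2 * t_total, 1e-9),
                             derived=["pop1", "pop2"], ancestral="anc")
    dem.sort_events()
    return dem


def simulate_coalescent_jsfs(config: SimConfig, n_replicates: int,
                             ) -> Spectrum2D:
    """Monte-Carlo expected joint SFS per unit theta from independent
    two-population structured-coalescent genealogies (one genealogy per
    unlinked site).

    Uses branch-mode frequency spectra, so the only noise is genealogical.
    The returned spectrum carries a per-entry standard-error array in its
    ``mc_se`` attribute.
    """
    import msprime

    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    model = get_model(config.model_name)
    dem = _msprime_demography(model, config.params)
    reps = msprime.sim_ancestry(
        samples={"pop1": config.n1, "pop2": config.n2},
        demography=dem, ploidy=1, sequence_length=1,
        num_replicates=n_replicates, random_seed=config.seed or 1)
    shape = (config.n1 + 1, config.n2 + 1)
    total = np.zeros(shape)
    total_sq = np.zeros(shape)
    sets = None
    for ts in reps:
        if sets is None:
            sets = [ts.samples(population=0), ts.samples(population=1)]
        afs = ts.allele_frequency_spectrum(
            sample_sets=sets, mode="branch", polarised=True,
            span_normalise=True) / 4.0
        total += afs
        total_sq += afs * afs
    mean = total / n_replicates
    var = np.maximum(total_sq / n_replicates - mean ** 2, 0.0)
    se = np.sqrt(var / n_replicates)
    spec = Spectrum2D(mean, folded=False,
                      pop_labels=("pop1", "pop2"))
    spec.mc_se = se
    spec.n_replicates = n_replicates
    return spec


# -- observed spectra -----------------------------------------------------


def sample_observed_jsfs(expected: Spectrum2D, theta_hat: float,
                         seed: int) -> Spectrum2D:
    """Poisson-sample an observed spectrum from a per-unit-theta expected
    spectrum scaled by ``theta_hat`` (see :func:`refugia.spectrum.poisson_sample`)."""
    return poisson_sample(expected, theta_hat, seed)


# -- RADseq-like genotype datasets ----------------------------------------


def simulate_genotype_dataset(config: SimConfig,
                              engine: EngineConfig = DEFAULT_ENGINE,
                              ) -> GenotypeMatrix:
    """Generate unlinked biallelic SNP genotypes whose joint allele counts
    follow the scenario's expected (unfolded) JSFS.

    Per-genotype read depth is drawn from a rounded normal coverage model,
    genotype quality from ``config.gq_model``, and genotypes are masked at
    ``config.missing_rate``.  Sites are grouped into loci of
    ``config.snps_per_locus`` consecutive SNPs (1 = fully unlinked loci).
    The true ancestral allele is the REF allele by construction; folding
    downstream discards that information.
    """
    rng = np.random.default_rng(config.seed)
    model = get_model(config.model_name)
    exp = expected_sfs(model, config.params, config.n1, config.n2,
                       config=engine)
    lam = np.where(exp.mask, 0.0, config.theta_per_dataset * exp.data)
    counts = rng.poisson(lam)
    entries = np.argwhere(counts > 0)
    # site-level joint derived-allele counts, shuffled into genome order
    joint = np.repeat(entries, counts[entries[:, 0], entries[:, 1]], axis=0)
    rng.shuffle(joint, axis=0)
    n_var = len(joint)
    if n_var > config.n_sites:
        raise ValueError(
            f"drew {n_var} variant sites for n_sites={config.n_sites}; "
            "increase n_sites or lower theta_per_dataset")

    ndip1, ndip2 = config.n1 // 2, config.n2 // 2
    n_samples = ndip1 + ndip2
    genotypes = np.zeros((n_var, n_samples), dtype=np.int8)
    for k, (i, j) in enumerate(joint):
        hap1 = np.zeros(config.n1, dtype=np.int8)
        hap1[rng.choice(config.n1, size=i, replace=False)] = 1
        hap2 = np.zeros(config.n2, dtype=np.int8)
        hap2[rng.choice(config.n2, size=j, replace=False)] = 1
        genotypes[k, :ndip1] = hap1[0::2] + hap1[1::2]
        genotypes[k, ndip1:] = hap2[0::2] + hap2[1::2]

    dp = np.clip(np.round(rng.normal(config.coverage_mean, config.coverage_sd,
                                     size=genotypes.shape)), 0, None
                 ).astype(np.int32)
    gq = np.asarray(config.gq_model(dp, rng), dtype=np.int32)
    if config.missing_rate > 0:
        drop = rng.random(genotypes.shape) < config.missing_rate
        genotypes[drop] = MISSING

    locus_of_site = np.arange(n_var) // config.snps_per_locus
    locus_id = np.array([f"locus_{l:06d}" for l in locus_of_site],
                        dtype=object)
    snp_index = np.arange(n_var) % config.snps_per_locus
    samples = ([f"p1_{i:03d}" for i in range(ndip1)]
               + [f"p2_{i:03d}" for i in range(ndip2)])
    pop_map = {s: ("pop1" if s.startswith("p1_") else "pop2")
               for s in samples}
    gm = GenotypeMatrix(genotypes, dp, gq, locus_id, snp_index, samples,
                        pop_map, pos=snp_index + 1)
    gm.n_sites_surveyed = config.n_sites
    return gm


# -- cluster-assignment fixtures ------------------------------------------


def simulate_q_matrices(n_pops: int, k: int, admixture_profile,
                        seed: int = 0, jitter: float = 0.0) -> np.ndarray:
    """Per-population cluster-proportion rows.

    ``admixture_profile`` is an ``(n_pops, k)`` array of mixing weights
    whose rows must sum to 1; with ``jitter > 0`` rows get Dirichlet noise
    centred on the profile (concentration ``profile / jitter``).
    """
    profile = np.asarray(admixture_profile, dtype=float)
    if profile.shape != (n_pops, k):
        raise ValueError(f"profile shape {profile.shape} != ({n_pops}, {k})")
    if np.any(np.abs(profile.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("admixture profile rows must sum to 1")
    if jitter <= 0:
        return profile.copy()
    rng = np.random.default_rng(seed)
    out = np.empty_like(profile)
    for r in range(n_pops):
        alpha = np.maximum(profile[r] / jitter, 1e-3)
        out[r] = rng.dirichlet(alpha)
    return out
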