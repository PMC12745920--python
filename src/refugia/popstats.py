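"""Per-population exploratory statistics used as refugium evidence.

High private-allele counts and elevated nucleotide diversity in an area
are the classic genetic signature of long-term in-situ persistence; both
statistics are computed per population from the filtered genotype
matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix


def _allele_presence(gm: GenotypeMatrix, pop: str) -> tuple[np.ndarray,
                                                            np.ndarray]:
    """Per-site flags: (ref allele observed, alt allele observed) among
    the called genotypes of ``pop``."""
    g = gm.genotypes[:, gm.sample_indices(pop)]
    called = g != MISSING
    has_ref = np.any(called & (g < 2), axis=1)
    has_alt = np.any(called & (g > 0), axis=1)
    return has_ref, has_alt


def private_alleles(gm: GenotypeMatrix) -> dict[str, int]:
    """Count (site, allele) pairs observed in exactly one population.

    Missing genotypes are ignored; both the reference and the alternate
    allele of a site can be private (to different populations).  Requires
    at least two populations.
    """
    pops = gm.populations
    if len(pops) < 2:
        raise ValueError("private alleles are undefined for a single "
                         "population")
    ref = np.stack([_allele_presence(gm, p)[0] for p in pops])
    alt = np.stack([_allele_presence(gm, p)[1] for p in pops])
    counts = {}
    for k, pop in enumerate(pops):
        others = np.ones(len(pops), dtype=bool)
        others[k] = False
        ref_private = ref[k] & ~np.any(ref[others], axis=0)
        alt_private = alt[k] & ~np.any(alt[others], axis=0)
        counts[pop] = int(ref_private.sum() + alt_private.sum())
    return counts


def nucleotide_diversity(gm: GenotypeMatrix,
                         n_sites_surveyed: int) -> dict[str, float]:
    """Per-population nucleotide diversity (pi) per surveyed site.

    For each variant site with ``n >= 2`` called alleles in the
    population, the unbiased per-site heterozygosity is
    ``pi_site = n/(n-1) * (1 - sum_a p_a^2)``; sites with fewer than two
    alleles contribute zero.  The sum over variant sites is divided by
    ``n_sites_surveyed``, the total number of sites (variant and
    invariant) screened to find them -- RADseq VCFs do not carry that
    number, so the caller must supply it.
    """
    if n_sites_surveyed < gm.n_sites:
        raise ValueError("n_sites_surveyed cannot be smaller than the "
                         "number of variant sites")
    out = {}
    for pop in gm.populations:
        g = gm.genotypes[:, gm.sample_indices(pop)].astype(float)
        called = g != MISSING
        n = 2.0 * called.sum(axis=1)
        alt = np.where(called, g, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt / n
            h = 1.0 - p ** 2 - (1.0 - p) ** 2
            pi_site = np.where(n >= 2, n / np.maximum(n - 1, 1) * h, 0.0)
        out[pop] = float(np.nansum(pi_site)) / n_sites_surveyed
    return out


def population_summary(gm: GenotypeMatrix,
                       n_sites_surveyed: int) -> pd.DataFrame:
    """Table of per-population private-allele counts and pi."""
    pa = private_alleles(gm)
    pi = nucleotide_diversity(gm, n_sites_surveyed)
    return pd.DataFrame({
        "population": list(pa),
        "private_alleles": [pa[p] for p in pa],
        "pi": [pi[p] for p in pa],
        "n_sites_surveyed": n_sites_surveyed,
    })
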