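"""Post-calling genotype and site filters for RADseq SNP matrices.

Filter semantics follow the usual VCFtools/Stacks conventions: depth and
quality thresholds mask individual genotypes (they do not drop whole
sites, so partially genotyped sites can still feed the projected
spectrum); site-level rules then drop sites by presence fraction and
observed heterozygosity, and optionally thin to the first SNP per RAD
locus to keep sites unlinked.  The fixed order is genotype-level ->
site-level -> single-SNP; all three stages are idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the post-calling filter chain.

    Defaults mirror a typical RADseq pipeline: per-genotype depth within
    [10, 50] reads and quality at least 20 (inclusive bounds pass);
    per-site observed heterozygosity at most 0.65; at least 80% of
    individuals genotyped (70% is the common relaxation for sparser
    taxa); one SNP per locus.
    """

    min_dp: int = 10
    max_dp: int = 50
    min_gq: int = 20
    max_obs_het: float = 0.65
    min_presence: float = 0.8
    single_snp_per_locus: bool = True
    presence_per_population: bool = False

    def __post_init__(self):
        if not 0 <= self.max_obs_het <= 1:
            raise ValueError("max_obs_het must be in [0, 1]")
        if self.min_dp > self.max_dp:
            raise ValueError("min_dp must not exceed max_dp")


def apply_genotype_filters(gm: GenotypeMatrix,
                           cfg: FilterConfig) -> GenotypeMatrix:
    """Mask genotypes with DP outside [min_dp, max_dp] or GQ < min_gq.

    Bounds are inclusive-pass (DP = 10 and DP = 50 are kept with the
    defaults; GQ = 20 is kept).  Only the genotype calls change; DP/GQ
    values, site set and annotations are untouched.
    """
    if gm.dp is None:
        raise ValueError("genotype matrix lacks the DP field "
                         "required by the depth filter")
    if gm.gq is None:
        raise ValueError("genotype matrix lacks the GQ field "
                         "required by the quality filter")
    out = gm.copy()
    bad = ((gm.dp < cfg.min_dp) | (gm.dp > cfg.max_dp)
           | (gm.gq < cfg.min_gq))
    out.genotypes[bad] = MISSING
    return out


def _observed_het(genotypes: np.ndarray) -> np.ndarray:
    """Per-site fraction of heterozygous calls among non-missing ones
    (0 where a site has no calls)."""
    called = genotypes != MISSING
    n_called = called.sum(axis=1)
    n_het = (genotypes == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        het = np.where(n_called > 0, n_het / np.maximum(n_called, 1), 0.0)
    return het


def apply_site_filters(gm: GenotypeMatrix, cfg: FilterConfig,
                       ) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Drop sites by presence fraction, observed heterozygosity and
    (optionally) thin to the first SNP of each locus.

    Presence is the fraction of all individuals with a genotype call
    (``presence_per_population=True`` instead requires the fraction
    within every population); heterozygosity is the fraction of
    heterozygotes among called genotypes; the first SNP of a locus is
    the one with the smallest within-locus SNP index among sites still
    alive at that stage.  Returns the filtered matrix and a per-rule
    kept/dropped tally (rules applied in the order below; a site is
    charged to the first rule that removes it).
    """
    n0 = gm.n_sites
    called = gm.genotypes != MISSING
    if cfg.presence_per_population:
        pres_ok = np.ones(n0, dtype=bool)
        for pop in gm.populations:
            idx = gm.sample_indices(pop)
            pres_ok &= (called[:, idx].mean(axis=1) >= cfg.min_presence)
    else:
        pres_ok = called.mean(axis=1) >= cfg.min_presence

    het_ok = _observed_het(gm.genotypes) <= cfg.max_obs_het

    keep = pres_ok & het_ok
    tally = {
        "input_sites": n0,
        "dropped_presence": int((~pres_ok).sum()),
        "dropped_heterozygosity": int((pres_ok & ~het_ok).sum()),
        "dropped_extra_snps": 0,
    }
    if cfg.single_snp_per_locus:
        first = {}
        order = np.flatnonzero(keep)
        for i in order:
            loc = gm.locus_id[i]
            if loc not in first or gm.snp_index[i] < gm.snp_index[first[loc]]:
                first[loc] = i
        chosen = set(first.values())
        extra = [i for i in order if i not in chosen]
        keep[extra] = False
        tally["dropped_extra_snps"] = len(extra)
    tally["kept"] = int(keep.sum())
    return gm.take_sites(np.flatnonzero(keep)), tally


def apply_filters(gm: GenotypeMatrix, cfg: FilterConfig,
                  ) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Full chain: genotype-level masking, then site-level filters."""
    return apply_site_filters(apply_genotype_filters(gm, cfg), cfg)
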