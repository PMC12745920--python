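"""Joint site-frequency spectra from genotype matrices.

Each biallelic site with enough called alleles in both populations
contributes its hypergeometric down-projection to the requested sample
sizes, so partially genotyped sites are not wasted (the easySFS-style
convention).  The best-projection search scans candidate sizes for the
pair that maximizes the expected number of segregating sites in the
projected spectrum.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .genotypes import MISSING, GenotypeMatrix
from .spectrum import Spectrum2D, projection_matrix


@lru_cache(maxsize=4096)
def _hyper_column(c: int, d: int, n: int) -> np.ndarray:
    """Probabilities of drawing 0..n derived alleles when sampling n of c
    alleles of which d are derived."""
    return projection_matrix(c, n)[:, d].copy()


def _site_counts(gm: GenotypeMatrix, popA: str, popB: str):
    """Per-site (called alleles, derived alleles) for both populations."""
    out = []
    for pop in (popA, popB):
        g = gm.genotypes[:, gm.sample_indices(pop)].astype(np.int64)
        called = g != MISSING
        c = 2 * called.sum(axis=1)
        d = np.where(called, g, 0).sum(axis=1)
        out += [c, d]
    return out


def build_jsfs(gm: GenotypeMatrix, popA: str, popB: str,
               n1: int, n2: int, fold: bool = False,
               project_partial: bool = True) -> Spectrum2D:
    """Joint SFS for two populations at haploid sample sizes (n1, n2).

    Sites with at least ``n1``/``n2`` called alleles in the respective
    population contribute their hypergeometric projection (total mass 1
    per usable site, spread over entries); sites below either threshold
    are skipped.  With ``project_partial=False`` only sites genotyped in
    exactly ``n1``/``n2`` alleles are used, at their observed counts.
    Monomorphic-after-projection mass accumulates in the masked corners.
    """
    if n1 % 2 or n2 % 2:
        raise ValueError("sample sizes must be even (diploid samples)")
    for pop, n in ((popA, n1), (popB, n2)):
        if n > 2 * len(gm.sample_indices(pop)):
            raise ValueError(
                f"n={n} exceeds the alleles available in {pop!r}")
    c1, d1, c2, d2 = _site_counts(gm, popA, popB)
    data = np.zeros((n1 + 1, n2 + 1))
    for k in range(gm.n_sites):
        if c1[k] < n1 or c2[k] < n2:
            continue
        if not project_partial and (c1[k] != n1 or c2[k] != n2):
            continue
        h1 = _hyper_column(int(c1[k]), int(d1[k]), n1)
        h2 = _hyper_column(int(c2[k]), int(d2[k]), n2)
        data += np.outer(h1, h2)
    spec = Spectrum2D(data, folded=False, pop_labels=(popA, popB))
    return spec.fold() if fold else spec


def best_projection(gm: GenotypeMatrix, popA: str, popB: str,
                    ) -> tuple[int, int]:
    """Even sample sizes maximizing the segregating projected mass.

    For each candidate pair the score is the summed probability that a
    usable site remains polymorphic after projection.  Ties break toward
    larger ``n1p + n2p``, then larger ``n1p`` (prefer more alleles at
    equal information).  Raises if no site is usable at any size.
    """
    c1, d1, c2, d2 = _site_counts(gm, popA, popB)
    max1 = 2 * len(gm.sample_indices(popA))
    max2 = 2 * len(gm.sample_indices(popB))
    best, best_key = None, None
    for n1p in range(2, max1 + 1, 2):
        for n2p in range(2, max2 + 1, 2):
            usable = (c1 >= n1p) & (c2 >= n2p)
            if not np.any(usable):
                continue
            score = 0.0
            for k in np.flatnonzero(usable):
                h1 = _hyper_column(int(c1[k]), int(d1[k]), n1p)
                h2 = _hyper_column(int(c2[k]), int(d2[k]), n2p)
                score += 1.0 - h1[0] * h2[0] - h1[-1] * h2[-1]
            key = (round(score, 12), n1p + n2p, n1p)
            if best_key is None or key > best_key:
                best, best_key = (n1p, n2p), key
    if best is None:
        raise ValueError("no site is usable at any projection size")
    return best


def segregating_mass_1d(counts: list[tuple[int, int]], n: int) -> float:
    """Expected segregating sites when projecting 1D sites ``(c, d)``
    (called and derived alleles) to ``n`` alleles; sites with ``c < n``
    are excluded.  Exposed for enumeration cross-checks."""
    score = 0.0
    for c, d in counts:
        if c < n:
            continue
        h = _hyper_column(int(c), int(d), n)
        score += 1.0 - h[0] - h[-1]
    return score
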