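"""Diploid genotype matrices with per-genotype depth and quality.

The in-memory representation mirrors what a RADseq VCF carries: one row
per biallelic site, one column per sample, alt-allele dosage 0/1/2 with
``-1`` for missing, plus integer DP (read depth) and GQ (genotype
quality) arrays of the same shape, a per-site locus identifier with the
within-locus SNP order, and a sample -> population map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Sites x samples genotype calls with DP/GQ and a population map.

    Attributes
    ----------
    genotypes:
        ``(n_sites, n_samples)`` int8 array of alt-allele dosage
        {0, 1, 2} or ``MISSING`` (-1).
    dp, gq:
        Same-shape integer arrays of read depth and phred-like genotype
        quality.
    locus_id:
        Per-site locus identifier (string array); several sites may share
        a locus when a RAD fragment carries more than one SNP.
    snp_index:
        Within-locus SNP order (0-based, in genomic order).
    samples:
        Sample names, one per column.
    pop_map:
        Sample name -> population label; must cover every sample.
    """

    genotypes: np.ndarray
    dp: np.ndarray
    gq: np.ndarray
    locus_id: np.ndarray
    snp_index: np.ndarray
    samples: list[str]
    pop_map: dict[str, str]
    pos: np.ndarray = field(default=None)

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n_sites, n_samples = self.genotypes.shape
        if self.dp is not None:
            self.dp = np.asarray(self.dp, dtype=np.int32)
            if self.dp.shape != self.genotypes.shape:
                raise ValueError("dp shape mismatch")
            if np.any(self.dp < 0):
                raise ValueError("dp must be nonnegative")
        if self.gq is not None:
            self.gq = np.asarray(self.gq, dtype=np.int32)
            if self.gq.shape != self.genotypes.shape:
                raise ValueError("gq shape mismatch")
        self.locus_id = np.asarray(self.locus_id, dtype=object)
        self.snp_index = np.asarray(self.snp_index, dtype=np.int64)
        if len(self.locus_id) != n_sites or len(self.snp_index) != n_sites:
            raise ValueError("locus annotation length mismatch")
        if len(self.samples) != n_samples:
            raise ValueError("sample list length mismatch")
        missing_pops = [s for s in self.samples if s not in self.pop_map]
        if missing_pops:
            raise ValueError(f"samples without population: {missing_pops}")
        bad = (self.genotypes < MISSING) | (self.genotypes > 2)
        if np.any(bad):
            raise ValueError("genotype dosage outside {0,1,2,missing}")
        if self.pos is None:
            self.pos = self.snp_index + 1
        self.pos = np.asarray(self.pos, dtype=np.int64)

    # -- views -----------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]

    @property
    def populations(self) -> list[str]:
        seen = {}
        for s in self.samples:
            seen.setdefault(self.pop_map[s], None)
        return list(seen)

    def sample_indices(self, population: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.samples)
               if self.pop_map[s] == population]
        if not idx:
            raise ValueError(f"no samples in population {population!r}")
        return np.array(idx)

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.genotypes[index],
            None if self.dp is None else self.dp[index],
            None if self.gq is None else self.gq[index],
            self.locus_id[index],
            self.snp_index[index],
            list(self.samples),
            dict(self.pop_map),
            pos=self.pos[index],
        )

    def copy(self) -> "GenotypeMatrix":
        return self.take_sites(np.arange(self.n_sites))


# -- VCF and population-map i/o ------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=refugia
##INFO=<ID=LOC,Number=1,Type=String,Description="RAD locus identifier">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
"""

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Serialize as VCF 4.2 with GT:DP:GQ.  The locus identifier is used
    as the chromosome name and echoed in INFO/LOC; output is byte-stable
    for identical inputs (no timestamps)."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for locus in dict.fromkeys(gm.locus_id.tolist()):
            fh.write(f"##contig=<ID={locus}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for k in range(gm.n_sites):
            calls = []
            for j in range(gm.n_samples):
                calls.append(f"{_GT_STRINGS[int(gm.genotypes[k, j])]}:"
                             f"{int(gm.dp[k, j])}:{int(gm.gq[k, j])}")
            fh.write(f"{gm.locus_id[k]}\t{int(gm.pos[k])}\t"
                     f"{gm.locus_id[k]}_{int(gm.snp_index[k])}\tA\tT\t.\t"
                     f"PASS\tLOC={gm.locus_id[k]}\tGT:DP:GQ\t"
                     + "\t".join(calls) + "\n")


def read_vcf(path, pop_map: dict[str, str]) -> GenotypeMatrix:
    """Read a biallelic-SNP VCF with DP and GQ FORMAT fields.

    Sites are kept in file order; the chromosome name is taken as the
    locus identifier and the within-locus SNP order is the rank of the
    position within its locus.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    geno, dps, gqs, loci, positions = [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"only biallelic sites supported ({var.CHROM}:{var.POS})")
        g = var.gt_types.astype(np.int8)  # 0/1/2, 3 = unknown with gts012
        g[g == 3] = MISSING
        dp = var.format("DP")
        gq = var.format("GQ")
        if dp is None:
            raise ValueError("VCF lacks the per-genotype DP FORMAT field")
        if gq is None:
            raise ValueError("VCF lacks the per-genotype GQ FORMAT field")
        geno.append(g)
        dps.append(np.clip(dp.astype(np.int64).ravel(), 0, None))
        gqs.append(np.clip(gq.astype(np.int64).ravel(), 0, None))
        loci.append(var.CHROM)
        positions.append(var.POS)
    geno = np.array(geno, dtype=np.int8)
    if geno.size == 0:
        geno = np.empty((0, len(samples)), dtype=np.int8)
    loci = np.asarray(loci, dtype=object)
    positions = np.asarray(positions, dtype=np.int64)
    snp_index = np.zeros(len(loci), dtype=np.int64)
    for locus in set(loci.tolist()):
        sel = np.flatnonzero(loci == locus)
        snp_index[sel[np.argsort(positions[sel], kind="stable")]] = \
            np.arange(len(sel))
    return GenotypeMatrix(geno, np.array(dps, dtype=np.int32),
                          np.array(gqs, dtype=np.int32), loci, snp_index,
                          samples, dict(pop_map), pos=positions)


def write_pop_map(pop_map: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for sample, pop in pop_map.items():
            fh.write(f"{sample}\t{pop}\n")


def read_pop_map(path) -> dict[str, str]:
    """Two-column sample<TAB>population file."""
    pop_map = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"malformed population-map line: {line!r}")
            pop_map[parts[0]] = parts[1]
    return pop_map
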