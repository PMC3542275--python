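"""Diploid population simulation under the neutral site-frequency spectrum.

Segregating sites are placed region by region: the number of sites in a
region of L callable bases is Poisson with mean theta * a1 * L, where
a1 = sum_{i=1}^{n-1} 1/i for n sampled chromosomes (so that E[S/(a1*L)]
equals the generating per-site theta, i.e. Watterson's estimator is
unbiased under the scheme). Derived-allele counts are drawn from the
neutral spectrum P(i) proportional to 1/i, and the derived allele is
assigned to a uniform random subset of haplotypes. This reproduces the
expectations of Watterson's theta and Tajima's pi (and hence mean
Tajima's D ~ 0) without a coalescent engine; it does not generate
genealogical correlation between sites (no linkage disequilibrium).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .genome import BASES, SyntheticGenome, genic_intervals
from .intervals import Interval, complement

#: DNA complement-free alternative bases for substitution draws
_BASE_STR = "ACGT"


@dataclass
class Variant:
    chromosome: str
    position: int          # 0-based
    ref: str               # reference allele (1bp for SNPs, >1 for deletions)
    alt: str
    #: indices (0..2n-1) of haplotypes carrying the alternate allele
    carriers: np.ndarray

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class PopulationSample:
    clone_id: str
    barcode: str
    #: per-chromosome variants on each haplotype: {chrom: [(pos, ref, alt), ...]}
    haplotypes: Tuple[Dict[str, List[Tuple[int, str, str]]],
                      Dict[str, List[Tuple[int, str, str]]]]


@dataclass
class PopulationTruth:
    samples: List[PopulationSample]
    variants: List[Variant]   # sorted by (chrom, position)

    def write_vcf(self, path, genome: SyntheticGenome) -> None:
        """Phased truth VCF 4.2."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=capturepop-simulate\n")
            for name, seq in genome.chromosomes:
                fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            ids = [s.clone_id for s in self.samples]
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(ids) + "\n")
            for v in self.variants:
                carriers = set(int(c) for c in v.carriers)
                gts = []
                for k in range(len(self.samples)):
                    a = 1 if 2 * k in carriers else 0
                    b = 1 if 2 * k + 1 in carriers else 0
                    gts.append(f"{a}|{b}")
                fh.write(f"{v.chromosome}\t{v.position + 1}\t.\t{v.ref}\t{v.alt}\t"
                         ".\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


def harmonic(n_minus_1: int) -> float:
    """a1 = sum_{i=1}^{n-1} 1/i."""
    return float(np.sum(1.0 / np.arange(1, n_minus_1 + 1))) if n_minus_1 >= 1 else 0.0


def sample_sfs_counts(rng: np.random.Generator, n: int, size: int) -> np.ndarray:
    """Derived-allele counts drawn with P(i) proportional to 1/i, i in 1..n-1."""
    i = np.arange(1, n)
    p = (1.0 / i) / np.sum(1.0 / i)
    return rng.choice(i, size=size, p=p)


def make_barcodes(n: int, length: int = 8, min_dist: int = 3, seed: int = 7) -> List[str]:
    """Random index barcodes with pairwise Hamming distance >= min_dist."""
    rng = np.random.default_rng(seed)
    out: List[str] = []
    while len(out) < n:
        cand = "".join(_BASE_STR[i] for i in rng.integers(0, 4, size=length))
        if all(sum(a != b for a, b in zip(cand, bc)) >= min_dist for bc in out):
            out.append(cand)
    return out


def _region_classes(genome: SyntheticGenome) -> List[Tuple[str, str, int, int]]:
    """(class, chrom, start, end) covering the whole genome: genic spans
    (gene body + promoter, merged) vs everything else."""
    out = []
    genic = genic_intervals(genome, include_promoters=True)
    for name, seq in genome.chromosomes:
        for s, e in genic[name]:
            out.append(("genic", name, s, e))
        for s, e in complement(genic[name], len(seq)):
            out.append(("intergenic", name, s, e))
    return out


def simulate_population(
    genome: SyntheticGenome,
    n_clones: int,
    theta_genic: float = 0.0035,
    theta_intergenic: float = 0.0071,
    indel_rate: float = 0.0002,
    seed: int = 0,
) -> PopulationTruth:
    """Simulate diploid clones carrying neutral variation.

    theta values are per-site; genic regions (gene spans including introns
    and UTRs, plus promoters) use ``theta_genic`` and the remaining genome
    ``theta_intergenic``. ``indel_rate`` is the per-site theta-like rate for
    short (1-3bp) insertion/deletion polymorphisms, simulated with the same
    frequency-spectrum machinery.
    """
    if n_clones < 2:
        raise ValueError("n_clones must be >= 2")
    for th in (theta_genic, theta_intergenic):
        if not (0 <= th < 0.05):
            raise ValueError("theta per site must be in [0, 0.05)")
    if theta_genic < 0 or theta_intergenic < 0:
        raise ValueError("theta must be non-negative")

    rng = np.random.default_rng(seed)
    n = 2 * n_clones
    a1 = harmonic(n - 1)
    chrom_seq = genome.chrom_dict()

    variants: List[Variant] = []
    used: Dict[str, set] = {name: set() for name, _ in genome.chromosomes}

    for cls, chrom, start, end in _region_classes(genome):
        theta = theta_genic if cls == "genic" else theta_intergenic
        L = end - start
        if L <= 0:
            continue
        n_snp = rng.poisson(theta * a1 * L) if theta > 0 else 0
        n_ind = rng.poisson(indel_rate * a1 * L) if indel_rate > 0 else 0
        if n_snp + n_ind == 0:
            continue
        # sample distinct positions, keeping a 4bp guard band around indels
        positions = rng.choice(np.arange(start, end), size=min(n_snp + n_ind, L),
                               replace=False)
        counts = sample_sfs_counts(rng, n, len(positions))
        for j, pos in enumerate(positions[:n_snp]):
            pos = int(pos)
            if pos in used[chrom]:
                continue
            ref = chrom_seq[chrom][pos]
            if ref not in _BASE_STR:
                continue
            alt = _BASE_STR[(_BASE_STR.index(ref) + int(rng.integers(1, 4))) % 4]
            carriers = rng.choice(n, size=int(counts[j]), replace=False)
            variants.append(Variant(chrom, pos, ref, alt, np.sort(carriers)))
            used[chrom].add(pos)
        for j, pos in enumerate(positions[n_snp:], start=n_snp):
            pos = int(pos)
            span = range(pos - 4, pos + 8)
            if any(p in used[chrom] for p in span):
                continue
            size = int(rng.integers(1, 4))
            if pos + size + 1 >= end:
                continue
            anchor = chrom_seq[chrom][pos]
            if rng.random() < 0.5:  # deletion of `size` bases after the anchor
                ref = chrom_seq[chrom][pos:pos + size + 1]
                alt = anchor
            else:                    # insertion of `size` random bases
                ref = anchor
                alt = anchor + "".join(_BASE_STR[i] for i in rng.integers(0, 4, size=size))
            if "N" in ref:
                continue
            carriers = rng.choice(n, size=int(counts[j]), replace=False)
            variants.append(Variant(chrom, pos, ref, alt, np.sort(carriers)))
            used[chrom].update(span)

    variants.sort(key=lambda v: (v.chromosome, v.position))

    barcodes = make_barcodes(n_clones, seed=seed + 1)
    samples = []
    for k in range(n_clones):
        haps: Tuple[Dict[str, List[Tuple[int, str, str]]], ...] = ({}, {})
        samples.append(PopulationSample(f"clone{k:02d}", barcodes[k], haps))
    for v in variants:
        cset = set(int(c) for c in v.carriers)
        for h in cset:
            k, which = divmod(h, 2)
            samples[k].haplotypes[which].setdefault(v.chromosome, []).append(
                (v.position, v.ref, v.alt))
    return PopulationTruth(samples, variants)
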