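"""Synthetic genome and annotation generator.

Emulates a small multi-chromosome plant genome with gene models
(exons/introns/UTRs), 250 bp upstream promoter regions, retained-duplicate
gene pairs (near-identical paralogs, as produced by an ancient whole-genome
duplication), and randomly placed intergenic control regions that are used
downstream as putatively neutral loci.

Coordinates are 0-based half-open throughout; GFF3 output converts to
1-based closed on the way out.
"""

from __future__ import annotations

import textwrap
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .intervals import Interval, merge_intervals, overlaps

BASES = np.frombuffer(b"ACGT", dtype="S1")

PROMOTER_LEN = 250


class PlacementError(RuntimeError):
    """Raised when a feature cannot be placed without violating a constraint."""


@dataclass
class GeneModel:
    gene_id: str
    chromosome: str
    strand: str
    exons: List[Interval]                 # ordered by coordinate, disjoint
    utr5: List[Interval] = field(default_factory=list)
    utr3: List[Interval] = field(default_factory=list)
    promoter: Optional[Interval] = None   # 250bp upstream of TSS (may be truncated)
    duplicate_partner: Optional[str] = None
    priority: bool = False

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> Interval:
        return (self.start, self.end)

    @property
    def introns(self) -> List[Interval]:
        return [(self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)]


@dataclass
class SyntheticGenome:
    chromosomes: List[Tuple[str, str]]            # (name, sequence)
    gene_models: List[GeneModel]
    intergenic_controls: List[Tuple[str, int, int]]  # (chrom, start, end)

    def chrom_dict(self) -> Dict[str, str]:
        return dict(self.chromosomes)

    def chrom_lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes}

    def genes_by_id(self) -> Dict[str, GeneModel]:
        return {g.gene_id: g for g in self.gene_models}

    # ------------------------------------------------------------------ I/O

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.chromosomes:
                fh.write(f">{name}\n")
                fh.write(textwrap.fill(seq, 80))
                fh.write("\n")

    def write_gff3(self, path) -> None:
        """GFF3 (1-based closed) with gene/exon/UTR/promoter features."""
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for name, seq in self.chromosomes:
                fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
            for g in sorted(self.gene_models, key=lambda g: (g.chromosome, g.start)):
                attrs = [f"ID={g.gene_id}"]
                if g.duplicate_partner:
                    attrs.append(f"duplicate_partner={g.duplicate_partner}")
                if g.priority:
                    attrs.append("priority=1")
                fh.write(
                    f"{g.chromosome}\tcapturepop\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\t{';'.join(attrs)}\n"
                )
                for kind, ivs in (
                    ("exon", g.exons),
                    ("five_prime_UTR", g.utr5),
                    ("three_prime_UTR", g.utr3),
                ):
                    for i, (s, e) in enumerate(ivs, 1):
                        fh.write(
                            f"{g.chromosome}\tcapturepop\t{kind}\t{s + 1}\t{e}\t.\t"
                            f"{g.strand}\t.\tID={g.gene_id}.{kind}.{i};Parent={g.gene_id}\n"
                        )
                if g.promoter is not None:
                    s, e = g.promoter
                    fh.write(
                        f"{g.chromosome}\tcapturepop\tpromoter\t{s + 1}\t{e}\t.\t"
                        f"{g.strand}\t.\tID={g.gene_id}.promoter;Parent={g.gene_id}\n"
                    )

    def write_controls_bed(self, path) -> None:
        with open(path, "w") as fh:
            for i, (chrom, s, e) in enumerate(self.intergenic_controls):
                fh.write(f"{chrom}\t{s}\t{e}\tcontrol_{i:04d}\n")


def load_genome(fasta_path, gff3_path, controls_bed=None) -> SyntheticGenome:
    """Load a genome + annotation written by :meth:`SyntheticGenome.write_*`.

    Uses pyfaidx for the FASTA and gffutils for the GFF3, so externally
    produced files following the same feature vocabulary also load.
    """
    import gffutils
    from pyfaidx import Fasta

    fa = Fasta(str(fasta_path))
    chromosomes = [(name, str(fa[name][:]).upper()) for name in fa.keys()]
    db = gffutils.create_db(str(gff3_path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes: List[GeneModel] = []
    for gf in db.features_of_type("gene"):
        exons, utr5, utr3, promoter = [], [], [], None
        for child in db.children(gf):
            iv = (child.start - 1, child.end)
            if child.featuretype == "exon":
                exons.append(iv)
            elif child.featuretype == "five_prime_UTR":
                utr5.append(iv)
            elif child.featuretype == "three_prime_UTR":
                utr3.append(iv)
            elif child.featuretype == "promoter":
                promoter = iv
        genes.append(GeneModel(
            gene_id=gf.id,
            chromosome=gf.seqid,
            strand=gf.strand,
            exons=sorted(exons),
            utr5=sorted(utr5),
            utr3=sorted(utr3),
            promoter=promoter,
            duplicate_partner=(gf.attributes.get("duplicate_partner") or [None])[0],
            priority=bool(gf.attributes.get("priority")),
        ))
    controls = []
    if controls_bed is not None:
        with open(controls_bed) as fh:
            for line in fh:
                if line.strip():
                    parts = line.split("\t")
                    controls.append((parts[0], int(parts[1]), int(parts[2])))
    return SyntheticGenome(chromosomes, genes, controls)


# --------------------------------------------------------------------------
# generation


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=length)]


def _make_gene_structure(rng: np.random.Generator) -> Tuple[List[Interval], int]:
    """Relative exon intervals (from 0) and total span length."""
    n_exons = int(rng.integers(1, 6))
    exon_lens = rng.integers(80, 401, size=n_exons)
    intron_lens = rng.integers(80, 301, size=max(n_exons - 1, 0))
    exons = []
    pos = 0
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + int(el)))
        if i < n_exons - 1:
            pos += int(el) + int(intron_lens[i])
        else:
            pos += int(el)
    return exons, pos


def generate_genome(
    n_chrom: int = 2,
    chrom_lengths: Sequence[int] = (100_000, 100_000),
    n_genes: int = 40,
    n_controls: int = 10,
    duplicate_fraction: float = 0.0,
    priority_fraction: float = 0.0,
    duplicate_divergence: float = 0.05,
    control_length_range: Tuple[int, int] = (250, 301),
    min_gap: int = 600,
    seed: int = 0,
    max_tries: int = 500,
) -> SyntheticGenome:
    """Generate a random genome with non-overlapping gene models and controls.

    Parameters
    ----------
    duplicate_fraction
        Fraction of genes that belong to a retained-duplicate pair; the second
        member of each pair is a copy of the first diverged at
        ``duplicate_divergence`` per site (so paired exon identity is
        ~``1 - divergence``).
    min_gap
        Minimum distance between placed features (gene-with-promoter spans and
        controls). Keeps intergenic space available for control regions and for
        unambiguous feature classification downstream.
    """
    if len(chrom_lengths) != n_chrom:
        raise ValueError("chrom_lengths must have n_chrom entries")
    if any(l < 10_000 for l in chrom_lengths):
        raise ValueError("chromosome lengths must be >= 10kb")

    rng = np.random.default_rng(seed)
    chrom_names = [f"chr{i + 1}" for i in range(n_chrom)]
    seqs = {name: _random_sequence(rng, l) for name, l in zip(chrom_names, chrom_lengths)}
    occupied: Dict[str, List[Interval]] = {name: [] for name in chrom_names}

    def place(length: int, what: str) -> Tuple[str, int]:
        for _ in range(max_tries):
            ci = int(rng.integers(0, n_chrom))
            chrom = chrom_names[ci]
            clen = chrom_lengths[ci]
            if clen - length - 2 * min_gap <= 0:
                continue
            start = int(rng.integers(min_gap, clen - length - min_gap))
            cand = (start - min_gap, start + length + min_gap)
            if not any(overlaps(cand, iv) for iv in occupied[chrom]):
                occupied[chrom].append((start, start + length))
                return chrom, start
        raise PlacementError(
            f"could not place {what} of length {length} after {max_tries} tries "
            f"(constraint: no overlap, min_gap={min_gap})")

    # pair up duplicate genes: indices (0,1), (2,3), ... of the duplicate block
    n_dup = int(round(duplicate_fraction * n_genes))
    n_dup -= n_dup % 2
    n_priority = int(round(priority_fraction * n_genes))

    genes: List[GeneModel] = []
    i = 0
    while i < n_genes:
        exons_rel, span_len = _make_gene_structure(rng)
        strand = "+" if rng.random() < 0.5 else "-"
        # reserve room for the promoter on the upstream side
        chrom, start = place(span_len + PROMOTER_LEN, f"gene g{i:04d}")
        if strand == "+":
            gstart = start + PROMOTER_LEN
        else:
            gstart = start
        exons = [(gstart + s, gstart + e) for s, e in exons_rel]
        gene = GeneModel(gene_id=f"g{i:04d}", chromosome=chrom, strand=strand, exons=exons)
        gene.promoter = _promoter_interval(gene, len(seqs[chrom]))
        # terminal 40bp of the first/last exon become UTRs when exons are long enough
        if exons[0][1] - exons[0][0] >= 120:
            if strand == "+":
                gene.utr5 = [(exons[0][0], exons[0][0] + 40)]
                gene.utr3 = [(exons[-1][1] - 40, exons[-1][1])]
            else:
                gene.utr5 = [(exons[-1][1] - 40, exons[-1][1])]
                gene.utr3 = [(exons[0][0], exons[0][0] + 40)]
        genes.append(gene)
        i += 1
        # duplicate partner: identical structure, diverged sequence
        if len(genes) <= n_dup and len(genes) % 2 == 1 and i < n_genes:
            src = gene
            chrom2, start2 = place(span_len + PROMOTER_LEN, f"gene g{i:04d} (duplicate)")
            gstart2 = start2 + PROMOTER_LEN if strand == "+" else start2
            exons2 = [(gstart2 + s, gstart2 + e) for s, e in exons_rel]
            dup = GeneModel(gene_id=f"g{i:04d}", chromosome=chrom2, strand=strand,
                            exons=exons2)
            dup.promoter = _promoter_interval(dup, len(seqs[chrom2]))
            if src.utr5:
                off = gstart2 - gstart
                dup.utr5 = [(s + off, e + off) for s, e in src.utr5]
                dup.utr3 = [(s + off, e + off) for s, e in src.utr3]
            # copy source span sequence, then diverge per site
            src_seq = seqs[src.chromosome][src.start:src.end].copy()
            mut = rng.random(span_len) < duplicate_divergence
            if mut.any():
                shift = rng.integers(1, 4, size=int(mut.sum()))
                idx = (np.searchsorted(BASES, src_seq[mut]) + shift) % 4
                src_seq[mut] = BASES[idx]
            seqs[chrom2][dup.start:dup.end] = src_seq
            src.duplicate_partner = dup.gene_id
            dup.duplicate_partner = src.gene_id
            genes.append(dup)
            i += 1

    for g in genes[:n_priority]:
        g.priority = True

    controls: List[Tuple[str, int, int]] = []
    for j in range(n_controls):
        length = int(rng.integers(*control_length_range))
        chrom, start = place(length, f"intergenic control {j}")
        controls.append((chrom, start, start + length))

    chromosomes = [(name, seqs[name].tobytes().decode()) for name in chrom_names]
    return SyntheticGenome(chromosomes, genes, sorted(controls))


def _promoter_interval(gene: GeneModel, chrom_len: int) -> Interval:
    """250bp immediately upstream of the TSS, truncated at chromosome edges."""
    if gene.strand == "+":
        return (max(0, gene.start - PROMOTER_LEN), gene.start)
    return (gene.end, min(chrom_len, gene.end + PROMOTER_LEN))


def genic_intervals(genome: SyntheticGenome, include_promoters: bool = True
                    ) -> Dict[str, List[Interval]]:
    """Merged gene-span (optionally + promoter) intervals per chromosome."""
    per_chrom: Dict[str, List[Interval]] = {name: [] for name, _ in genome.chromosomes}
    for g in genome.gene_models:
        per_chrom[g.chromosome].append(g.span)
        if include_promoters and g.promoter is not None:
            per_chrom[g.chromosome].append(g.promoter)
    return {c: merge_intervals(ivs) for c, ivs in per_chrom.items()}
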