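"""Per-clone genotype calling and cross-clone candidate SNP filtering.

The caller is a minimal, self-contained diploid genotype-likelihood model
computed directly from pileup base observations. For base b_i with Phred
quality Q_i and error probability e_i = 10^(-Q_i/10):

    P(b_i | hom-ref) = 1 - e_i  if b_i = ref, else e_i / 3
    P(b_i | het)     = (1 - e_i)/2 + e_i/6  for b_i in {ref, alt}, else e_i/3
    P(b_i | hom-alt) = symmetric to hom-ref

with genotype priors (1 - 1.5p, p, p/2) for a heterozygosity prior p. The
call is the MAP genotype, and the variant (site) quality is
-10 log10 P(hom-ref | data), capped at 255.

Candidate SNPs are per-clone non-reference calls with depth >= 10 and
quality >= 30, further restricted to sites covered at >= 10X in every clone
with no insertion/deletion evidence at the site in any clone, then
classified by genomic feature (exon > 5'UTR > 3'UTR > intron > promoter >
intergenic precedence) and by position relative to baits (within-bait /
adjacent within a radius, default 500bp / off-target).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pysam

from .baits import BaitSet
from .coverage import DepthTrack
from .genome import SyntheticGenome

log = logging.getLogger(__name__)

HOM_REF, HET, HOM_ALT = "hom-ref", "het", "hom-alt"

FEATURE_PRECEDENCE = ["exon", "five_prime_UTR", "three_prime_UTR",
                      "intron", "promoter", "intergenic"]
FEATURE_LABELS = {"exon": "exon", "five_prime_UTR": "5'-UTR",
                  "three_prime_UTR": "3'-UTR", "intron": "intron",
                  "promoter": "promoter", "intergenic": "intergenic"}
POSITION_CLASSES = ["within-bait", "adjacent", "off-target"]


@dataclass
class PileupColumn:
    chromosome: str
    position: int
    ref: str
    #: sample -> list of (base, phred quality)
    observations: Dict[str, List[Tuple[str, int]]] = field(default_factory=dict)
    #: sample -> True when a read shows an insertion or deletion here
    indel_evidence: Dict[str, bool] = field(default_factory=dict)


@dataclass
class GenotypeCall:
    sample: str
    chromosome: str
    position: int
    ref: str
    genotype: str
    alt: Optional[str]
    quality: float
    depth: int


@dataclass
class CandidateSite:
    chromosome: str
    position: int
    ref: str
    alt: str
    #: sample -> GenotypeCall for samples with a non-reference call
    calls: Dict[str, GenotypeCall]
    feature_class: Optional[str] = None
    position_class: Optional[str] = None

    def allele_count(self, all_samples: Sequence[str]) -> int:
        """Alternate-allele dosage over 2N chromosomes (absent call = hom-ref)."""
        dose = {HET: 1, HOM_ALT: 2}
        return sum(dose.get(self.calls[s].genotype, 0)
                   for s in all_samples if s in self.calls)


@dataclass
class CandidateSNPSet:
    sites: List[CandidateSite]
    samples: List[str]

    def count_matrix(self):
        """Table of candidate counts by feature class and by bait position."""
        import pandas as pd
        feat = {FEATURE_LABELS[f]: 0 for f in FEATURE_PRECEDENCE}
        pos = {p: 0 for p in POSITION_CLASSES}
        for s in self.sites:
            feat[s.feature_class] += 1
            pos[s.position_class] += 1
        rows = [{"grouping": "feature", "class": k, "count": v} for k, v in feat.items()]
        rows += [{"grouping": "bait_position", "class": k, "count": v}
                 for k, v in pos.items()]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------- pileup

def pileup(
    alignments: Iterable[pysam.AlignedSegment],
    genome: SyntheticGenome,
    uniqueness_rule=None,
) -> Dict[Tuple[str, int], PileupColumn]:
    """Accumulate pileup columns from (already uniqueness-filtered, unless a
    rule is given) alignment records; the sample is taken from the RG tag."""
    from .coverage import unique_by_tag
    chrom_seq = genome.chrom_dict()
    columns: Dict[Tuple[str, int], PileupColumn] = {}

    def col(chrom: str, pos: int) -> PileupColumn:
        key = (chrom, pos)
        c = columns.get(key)
        if c is None:
            c = PileupColumn(chrom, pos, chrom_seq[chrom][pos])
            columns[key] = c
        return c

    for rec in alignments:
        if rec.is_unmapped:
            continue
        if uniqueness_rule is not None and not uniqueness_rule(rec):
            continue
        try:
            sample = rec.get_tag("RG") if rec.has_tag("RG") else "sample"
            chrom = rec.reference_name
            seq = rec.query_sequence
            quals = rec.query_qualities
            pairs = rec.get_aligned_pairs()
        except (ValueError, KeyError) as exc:  # malformed record
            log.warning("skipping malformed alignment %s: %s", rec.query_name, exc)
            continue
        prev_r = None
        for qpos, rpos in pairs:
            if qpos is not None and rpos is not None:
                c = col(chrom, rpos)
                c.observations.setdefault(sample, []).append(
                    (seq[qpos], int(quals[qpos]) if quals is not None else 30))
                prev_r = rpos
            elif qpos is None and rpos is not None:        # deletion
                c = col(chrom, rpos)
                c.indel_evidence[sample] = True
                prev_r = rpos
            elif qpos is not None and rpos is None:        # insertion
                if prev_r is not None:
                    col(chrom, prev_r).indel_evidence[sample] = True
    return columns


# --------------------------------------------------------------- calling

def _log10(p: float) -> float:
    return math.log10(p) if p > 0 else -999.0


def call_genotype(column: PileupColumn, sample: str, prior_het: float = 0.001
                  ) -> Optional[GenotypeCall]:
    """MAP diploid genotype for one sample at one column (None if no usable
    bases)."""
    obs = [(b, q) for b, q in column.observations.get(sample, ()) if b != "N"]
    if not obs:
        return None
    ref = column.ref
    # choose the alt allele with the highest count, then base order
    counts: Dict[str, int] = {}
    for b, _ in obs:
        if b != ref:
            counts[b] = counts.get(b, 0) + 1
    alt = max(counts, key=lambda b: (counts[b], -"ACGT".index(b))) if counts else None

    ll = {HOM_REF: 0.0, HET: 0.0, HOM_ALT: 0.0}
    for b, q in obs:
        e = 10.0 ** (-q / 10.0)
        is_ref = b == ref
        is_alt = alt is not None and b == alt
        ll[HOM_REF] += _log10((1 - e) if is_ref else e / 3)
        ll[HOM_ALT] += _log10((1 - e) if is_alt else e / 3)
        ll[HET] += _log10((1 - e) / 2 + e / 6 if (is_ref or is_alt) else e / 3)
    priors = {HOM_REF: 1 - 1.5 * prior_het, HET: prior_het, HOM_ALT: prior_het / 2}
    post = {g: ll[g] + _log10(priors[g]) for g in ll}
    if alt is None:
        post.pop(HET)
        post.pop(HOM_ALT)
    norm = max(post.values())
    lin = {g: 10.0 ** (p - norm) for g, p in post.items()}
    total = sum(lin.values())
    p_homref = lin.get(HOM_REF, 0.0) / total
    genotype = max(post, key=post.get)
    quality = min(255.0, -10.0 * _log10(p_homref)) if p_homref < 1 else 0.0
    return GenotypeCall(sample, column.chromosome, column.position, ref, genotype,
                        alt if genotype != HOM_REF else None, quality, len(obs))


def call_all(columns: Dict[Tuple[str, int], PileupColumn], samples: Sequence[str],
             prior_het: float = 0.001) -> Dict[str, List[GenotypeCall]]:
    out: Dict[str, List[GenotypeCall]] = {s: [] for s in samples}
    for key in sorted(columns):
        col = columns[key]
        for s in samples:
            if s in col.observations:
                call = call_genotype(col, s, prior_het)
                if call is not None:
                    out[s].append(call)
    return out


# -------------------------------------------------------------- filters

def per_clone_filter(calls: Iterable[GenotypeCall], min_depth: int = 10,
                     min_q: float = 30.0) -> List[GenotypeCall]:
    """Non-reference calls with depth >= min_depth and quality >= min_q
    (boundary values kept)."""
    return [c for c in calls
            if c.genotype != HOM_REF and c.depth >= min_depth and c.quality >= min_q]


def candidate_filter(
    per_clone_calls: Dict[str, List[GenotypeCall]],
    depth_tracks: Sequence[DepthTrack],
    indel_evidence: Dict[Tuple[str, int], Set[str]],
    min_depth: int = 10,
) -> CandidateSNPSet:
    """Cross-clone filter: keep union sites covered >= min_depth in every
    sample with no indel evidence at the site in any sample."""
    samples = sorted(per_clone_calls)
    track_by_sample = {t.sample_id: t for t in depth_tracks}
    for s in samples:
        if s not in track_by_sample:
            raise ValueError(f"missing depth track for sample {s!r}")
    by_site: Dict[Tuple[str, int], Dict[str, GenotypeCall]] = {}
    for s, calls in per_clone_calls.items():
        for c in calls:
            by_site.setdefault((c.chromosome, c.position), {})[s] = c
    sites: List[CandidateSite] = []
    for (chrom, pos) in sorted(by_site):
        if indel_evidence.get((chrom, pos)):
            continue
        if any(track_by_sample[s].depths[chrom][pos] < min_depth for s in samples):
            continue
        calls = by_site[(chrom, pos)]
        # consensus alt: the alt supported by the most clones
        alts: Dict[str, int] = {}
        for c in calls.values():
            if c.alt:
                alts[c.alt] = alts.get(c.alt, 0) + 1
        alt = max(alts, key=alts.get)
        ref = next(iter(calls.values())).ref
        sites.append(CandidateSite(chrom, pos, ref, alt,
                                   {s: c for s, c in calls.items() if c.alt == alt}))
    return CandidateSNPSet(sites, samples)


def indel_evidence_from_columns(columns: Dict[Tuple[str, int], PileupColumn]
                                ) -> Dict[Tuple[str, int], Set[str]]:
    return {key: {s for s, flag in col.indel_evidence.items() if flag}
            for key, col in columns.items() if col.indel_evidence}


# -------------------------------------------------------- classification

def build_feature_labels(genome: SyntheticGenome) -> Dict[str, np.ndarray]:
    """Per-base feature codes using exon > 5'UTR > 3'UTR > intron > promoter
    > intergenic precedence (lower code wins)."""
    order = {f: i for i, f in enumerate(FEATURE_PRECEDENCE)}
    labels = {c: np.full(l, order["intergenic"], dtype=np.uint8)
              for c, l in genome.chrom_lengths().items()}

    def paint(chrom, s, e, feature):
        code = order[feature]
        arr = labels[chrom]
        seg = arr[max(0, s):e]
        np.minimum(seg, code, out=seg)

    for g in genome.gene_models:
        if g.promoter:
            paint(g.chromosome, *g.promoter, "promoter")
        for s, e in g.introns:
            paint(g.chromosome, s, e, "intron")
        for s, e in g.exons:
            paint(g.chromosome, s, e, "exon")
    # UTRs outrank plain exon only below exon precedence-wise; paint them
    # after exons would lose, so repaint explicitly: a UTR base is a UTR.
    for g in genome.gene_models:
        for s, e in g.utr5:
            labels[g.chromosome][s:e] = order["five_prime_UTR"]
        for s, e in g.utr3:
            labels[g.chromosome][s:e] = order["three_prime_UTR"]
    return labels


def classify_snps(
    candidates: CandidateSNPSet,
    genome: SyntheticGenome,
    baitset: BaitSet,
    adjacent_radius: int = 500,
) -> CandidateSNPSet:
    """Assign one feature class and one bait-position class per site.

    "Adjacent" means within ``adjacent_radius`` bp of a bait edge,
    inclusive; distance 0 (inside a bait) is "within-bait".
    """
    feature = build_feature_labels(genome)
    lens = genome.chrom_lengths()
    # distance-to-bait per chromosome via sorted bait edges
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for b in baitset:
        by_chrom.setdefault(b.chromosome, []).append((b.start, b.end))
    for c in by_chrom:
        by_chrom[c].sort()
    for site in candidates.sites:
        if site.chromosome not in lens or not (0 <= site.position < lens[site.chromosome]):
            raise ValueError(f"site {site.chromosome}:{site.position} outside genome")
        code = feature[site.chromosome][site.position]
        site.feature_class = FEATURE_LABELS[FEATURE_PRECEDENCE[code]]
        site.position_class = _position_class(
            by_chrom.get(site.chromosome, []), site.position, adjacent_radius)
    return candidates


def _position_class(baits: List[Tuple[int, int]], pos: int, radius: int) -> str:
    import bisect
    if not baits:
        return "off-target"
    i = bisect.bisect_right(baits, (pos, float("inf")))
    dist = float("inf")
    for j in (i - 1, i):
        if 0 <= j < len(baits):
            s, e = baits[j]
            if s <= pos < e:
                return "within-bait"
            dist = min(dist, s - pos if pos < s else pos - (e - 1))
    return "adjacent" if dist <= radius else "off-target"


# ------------------------------------------------------------------- I/O

def write_vcf(candidates: CandidateSNPSet, genome: SyntheticGenome, path) -> None:
    """Candidate VCF 4.2 with feature/position INFO tags and per-sample GT."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=capturepop-call\n")
        for name, seq in genome.chromosomes:
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write('##INFO=<ID=FEAT,Number=1,Type=String,Description="Feature class">\n')
        fh.write('##INFO=<ID=BPOS,Number=1,Type=String,Description="Bait position class">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(candidates.samples) + "\n")
        gt = {HET: "0/1", HOM_ALT: "1/1"}
        for s in candidates.sites:
            qual = max((c.quality for c in s.calls.values()), default=0.0)
            info_parts = []
            if s.feature_class:
                info_parts.append(f"FEAT={s.feature_class}")
            if s.position_class:
                info_parts.append(f"BPOS={s.position_class}")
            info = ";".join(info_parts) or "."
            gts = [gt.get(s.calls[x].genotype, "0/0") if x in s.calls else "0/0"
                   for x in candidates.samples]
            fh.write(f"{s.chromosome}\t{s.position + 1}\t.\t{s.ref}\t{s.alt}\t"
                     f"{qual:.0f}\tPASS\t{info}\tGT\t" + "\t".join(gts) + "\n")
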