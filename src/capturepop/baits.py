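"""Bait (capture probe) design: target extraction, tiling, budget allocation.

Two tiling strategies are implemented:

* end-to-end — the original design: regions shorter than 150bp receive a
  single centered bait; longer regions are tiled with 120bp baits placed
  end-to-end, the final bait shifted flush with the region end (overlapping
  its predecessor rather than overhanging).
* optimized — exploits the ~80bp of flanking sequence recovered around each
  bait ("wings"): regions up to 300bp receive one centered bait; longer
  regions are tiled with evenly spaced baits leaving inter-bait gaps of at
  most 150bp, the minimal bait count being k = ceil((L + 150) / 270).

All intervals are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .genome import SyntheticGenome, PROMOTER_LEN
from .intervals import Interval, merge_intervals, union_length

BAIT_LEN = 120
#: regions shorter than this get one bait under end-to-end tiling
SINGLE_BAIT_MAX = 150
#: maximum region length served by a single bait under optimized tiling
OPT_SINGLE_MAX = 300
#: maximum allowed inter-bait gap under optimized tiling
OPT_MAX_GAP = 150


@dataclass(frozen=True)
class TargetRegion:
    chromosome: str
    start: int
    end: int
    target_class: str                  # exon | promoter | intergenic
    gene_id: Optional[str] = None
    priority: bool = False
    gene_ids: Tuple[str, ...] = ()     # union of gene ids after merging

    def __post_init__(self):
        if self.end - self.start < 1:
            raise ValueError("target region length must be >= 1")
        if self.gene_id and not self.gene_ids:
            object.__setattr__(self, "gene_ids", (self.gene_id,))

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Bait:
    chromosome: str
    start: int
    end: int
    target_class: str
    gene_id: Optional[str] = None

    def __post_init__(self):
        if self.end - self.start != BAIT_LEN:
            raise ValueError("baits must be exactly 120bp")

    @property
    def interval(self) -> Interval:
        return (self.start, self.end)


@dataclass
class DesignBudget:
    max_baits: int
    priority_gene_ids: Set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.max_baits <= 0:
            raise ValueError("max_baits must be positive")


@dataclass
class DesignStats:
    n_baits: int
    cumulative_bp: int
    baits_per_mb: Dict[str, float]
    counts_by_class: Dict[str, int]


BaitSet = List[Bait]


# ---------------------------------------------------------------- targets

def extract_targets(
    genome: SyntheticGenome,
    promoter_len: int = PROMOTER_LEN,
    n_intergenic: int = 0,
    intergenic_len: int = 120,
    min_gap_to_gene: int = 500,
    seed: int = 0,
) -> List[TargetRegion]:
    """Exon targets for every exon, one promoter target per gene, and
    ``n_intergenic`` control targets sampled from intergenic space.

    When the genome carries pre-placed intergenic controls they are used
    directly (up to ``n_intergenic``); otherwise control targets are drawn
    uniformly from non-genic, non-promoter space, allocated to chromosomes
    proportionally to length (largest-remainder rounding, so per-chromosome
    counts differ from exact proportionality by at most 1).
    """
    targets: List[TargetRegion] = []
    chrom_lens = genome.chrom_lengths()
    for g in genome.gene_models:
        for s, e in g.exons:
            targets.append(TargetRegion(g.chromosome, s, e, "exon", g.gene_id,
                                        priority=g.priority))
        # promoter, truncated at the chromosome edge
        if g.strand == "+":
            ps, pe = max(0, g.start - promoter_len), g.start
        else:
            ps, pe = g.end, min(chrom_lens[g.chromosome], g.end + promoter_len)
        if pe > ps:
            targets.append(TargetRegion(g.chromosome, ps, pe, "promoter", g.gene_id,
                                        priority=g.priority))

    if n_intergenic > 0:
        if genome.intergenic_controls:
            for chrom, s, e in genome.intergenic_controls[:n_intergenic]:
                targets.append(TargetRegion(chrom, s, e, "intergenic"))
        else:
            targets.extend(_sample_intergenic(genome, n_intergenic, intergenic_len,
                                              min_gap_to_gene, seed))
    return targets


def proportional_allocation(weights: Sequence[float], total: int) -> List[int]:
    """Largest-remainder apportionment of ``total`` among ``weights``."""
    w = np.asarray(weights, dtype=float)
    exact = total * w / w.sum()
    base = np.floor(exact).astype(int)
    rem = total - int(base.sum())
    order = np.argsort(-(exact - base), kind="stable")
    for i in order[:rem]:
        base[i] += 1
    return base.tolist()


def _sample_intergenic(genome, n, length, min_gap, seed) -> List[TargetRegion]:
    from .genome import genic_intervals
    rng = np.random.default_rng(seed)
    genic = genic_intervals(genome)
    out: List[TargetRegion] = []
    names = [c for c, _ in genome.chromosomes]
    lens = [len(s) for _, s in genome.chromosomes]
    counts = proportional_allocation(lens, n)
    for chrom, clen, want in zip(names, lens, counts):
        forbidden = merge_intervals([(max(0, s - min_gap), min(clen, e + min_gap))
                                     for s, e in genic[chrom]])
        placed: List[Interval] = []
        tries = 0
        while len(placed) < want:
            tries += 1
            if tries > 200 * max(want, 1):
                raise RuntimeError(
                    f"cannot place {want} intergenic targets on {chrom}: "
                    f"insufficient non-genic space")
            s = int(rng.integers(0, clen - length))
            iv = (s, s + length)
            if any(s < fe and fs < iv[1] for fs, fe in forbidden):
                continue
            if any(s < pe and ps < iv[1] for ps, pe in placed):
                continue
            placed.append(iv)
        out.extend(TargetRegion(chrom, s, e, "intergenic") for s, e in sorted(placed))
    return out


# ---------------------------------------------------------------- tiling

def _centered_bait(region: TargetRegion) -> Bait:
    # symmetric extension into flanks; ties broken toward the lower coordinate
    start = region.start + (region.length - BAIT_LEN) // 2
    return Bait(region.chromosome, start, start + BAIT_LEN,
                region.target_class, region.gene_id)


def tile_end_to_end(region: TargetRegion) -> List[Bait]:
    """Original tiling: <150bp -> one centered bait; otherwise end-to-end
    with the last bait flush to the region end."""
    L = region.length
    if L < SINGLE_BAIT_MAX:
        return [_centered_bait(region)]
    k = -(-L // BAIT_LEN)  # ceil
    starts = [region.start + i * BAIT_LEN for i in range(k - 1)]
    starts.append(region.end - BAIT_LEN)
    return [Bait(region.chromosome, s, s + BAIT_LEN, region.target_class, region.gene_id)
            for s in starts]


def optimized_bait_count(L: int) -> int:
    """Minimal k such that k evenly spaced baits leave gaps <= 150bp."""
    if L <= OPT_SINGLE_MAX:
        return 1
    return -(-(L + OPT_MAX_GAP) // (BAIT_LEN + OPT_MAX_GAP))


def tile_optimized(region: TargetRegion) -> List[Bait]:
    """Wing-aware tiling: one centered bait up to 300bp, else the minimal
    number of evenly spaced baits with every inter-bait gap <= 150bp, first
    and last flush with the region ends."""
    L = region.length
    k = optimized_bait_count(L)
    if k == 1:
        return [_centered_bait(region)]
    span = L - BAIT_LEN
    starts = [region.start + round(i * span / (k - 1)) for i in range(k)]
    return [Bait(region.chromosome, s, s + BAIT_LEN, region.target_class, region.gene_id)
            for s in starts]


def merge_close_targets(targets: Iterable[TargetRegion], max_gap: int = 150
                        ) -> List[TargetRegion]:
    """Merge same-chromosome targets separated by gaps strictly less than
    ``max_gap`` into single spanning regions (idempotent, order-independent).

    A merged region inherits the union of gene ids; its class is the first
    class in exon > promoter > intergenic precedence among members.
    """
    by_chrom: Dict[str, List[TargetRegion]] = {}
    for t in targets:
        by_chrom.setdefault(t.chromosome, []).append(t)
    prec = {"exon": 0, "promoter": 1, "intergenic": 2}
    out: List[TargetRegion] = []
    for chrom in sorted(by_chrom):
        ts = sorted(by_chrom[chrom], key=lambda t: (t.start, t.end))
        group = [ts[0]]
        for t in ts[1:]:
            if t.start - max(x.end for x in group) < max_gap:
                group.append(t)
            else:
                out.append(_merge_group(group, prec))
                group = [t]
        out.append(_merge_group(group, prec))
    return out


def _merge_group(group: List[TargetRegion], prec) -> TargetRegion:
    if len(group) == 1:
        return group[0]
    gene_ids = tuple(sorted({gid for t in group for gid in t.gene_ids}))
    cls = min((t.target_class for t in group), key=lambda c: prec[c])
    return TargetRegion(group[0].chromosome, min(t.start for t in group),
                        max(t.end for t in group), cls,
                        gene_id=gene_ids[0] if gene_ids else None,
                        priority=any(t.priority for t in group),
                        gene_ids=gene_ids)


# ----------------------------------------------------------- allocation

def allocate_budget(
    per_gene_baits: Dict[str, List[Bait]],
    budget: DesignBudget,
    gene_order: Optional[Sequence[str]] = None,
    preallocated: Optional[List[Bait]] = None,
) -> BaitSet:
    """Select baits under a total budget.

    ``preallocated`` baits (promoter and intergenic baits in the original
    design) are included first and count against the budget. All baits of
    priority genes are then included. Remaining capacity is filled by
    round-robin over the non-priority genes in ``gene_order`` (default:
    genome order as given by the dict), pass p taking the p-th remaining
    bait of each gene, stopping exactly when the budget is reached.
    """
    if gene_order is None:
        gene_order = list(per_gene_baits)
    selected: BaitSet = list(preallocated or [])
    if len(selected) > budget.max_baits:
        raise ValueError("preallocated baits alone exceed the budget")

    priority = [g for g in gene_order if g in budget.priority_gene_ids]
    others = [g for g in gene_order if g not in budget.priority_gene_ids]
    for g in priority:
        selected.extend(per_gene_baits.get(g, []))
    if len(selected) > budget.max_baits:
        raise ValueError(
            f"priority baits ({len(selected)}) exceed budget ({budget.max_baits})")

    remaining = budget.max_baits - len(selected)
    queues = {g: list(per_gene_baits.get(g, [])) for g in others}
    p = 0
    while remaining > 0:
        took = False
        for g in others:
            q = queues[g]
            if p < len(q):
                selected.append(q[p])
                took = True
                remaining -= 1
                if remaining == 0:
                    break
        if not took:
            break
        p += 1
    return selected


def design_baits(
    targets: Iterable[TargetRegion],
    strategy: str = "end2end",
    budget: Optional[DesignBudget] = None,
    merge_gap: Optional[int] = None,
) -> BaitSet:
    """Tile every target and (optionally) allocate under a budget.

    ``merge_gap`` pre-merges close targets (the optimized design uses 150).
    Exon baits are budget-allocated per gene; promoter and intergenic baits
    are preallocated, as in the original design.
    """
    tile = {"end2end": tile_end_to_end, "optimized": tile_optimized}[strategy]
    targets = list(targets)
    if merge_gap is not None:
        targets = merge_close_targets(targets, merge_gap)
    per_gene: Dict[str, List[Bait]] = {}
    prealloc: List[Bait] = []
    priority_ids: Set[str] = set()
    for t in sorted(targets, key=lambda t: (t.chromosome, t.start)):
        baits = tile(t)
        if t.target_class == "exon" and t.gene_id is not None:
            per_gene.setdefault(t.gene_id, []).extend(baits)
            if t.priority:
                priority_ids.add(t.gene_id)
        else:
            prealloc.extend(baits)
    if budget is None:
        out = prealloc + [b for g in per_gene for b in per_gene[g]]
        return sorted(out, key=lambda b: (b.chromosome, b.start))
    if not budget.priority_gene_ids:
        budget = DesignBudget(budget.max_baits, priority_ids)
    return allocate_budget(per_gene, budget, preallocated=prealloc)


# ---------------------------------------------------------------- stats

def design_stats(baitset: BaitSet, chrom_lengths: Optional[Dict[str, int]] = None
                 ) -> DesignStats:
    """Bait count, cumulative (union) bp, per-chromosome density, class counts."""
    by_chrom: Dict[str, List[Interval]] = {}
    counts: Dict[str, int] = {}
    for b in baitset:
        by_chrom.setdefault(b.chromosome, []).append(b.interval)
        counts[b.target_class] = counts.get(b.target_class, 0) + 1
    cumulative = sum(union_length(ivs) for ivs in by_chrom.values())
    density: Dict[str, float] = {}
    if chrom_lengths:
        for chrom, clen in chrom_lengths.items():
            density[chrom] = len(by_chrom.get(chrom, [])) / (clen / 1e6)
    return DesignStats(len(baitset), cumulative, density, counts)


# ------------------------------------------------------------------- I/O

def write_bed(baitset: BaitSet, path) -> None:
    counters: Dict[Tuple[Optional[str], str], int] = {}
    with open(path, "w") as fh:
        for b in sorted(baitset, key=lambda b: (b.chromosome, b.start)):
            key = (b.gene_id, b.target_class)
            counters[key] = counters.get(key, 0) + 1
            name = f"{b.gene_id or 'NA'}:{b.target_class}:{counters[key]}"
            fh.write(f"{b.chromosome}\t{b.start}\t{b.end}\t{name}\t0\t+\n")


def read_bed(path) -> BaitSet:
    out: BaitSet = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, s, e = parts[0], int(parts[1]), int(parts[2])
            gene_id, cls = None, "exon"
            if len(parts) > 3 and ":" in parts[3]:
                gid, cls = parts[3].split(":")[:2]
                gene_id = None if gid == "NA" else gid
            out.append(Bait(chrom, s, e, cls, gene_id))
    return out
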