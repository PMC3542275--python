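"""Per-base depth and capture-efficiency analytics.

Depth is computed per uniquely-mapped alignment record (both mates counted
independently; deleted reference bases do not contribute), matching the
per-record semantics of genomeCoverageBed. The genome is partitioned into
bait / adjacent (within a flank, default 250bp, of a bait) / off-target
bases, and summaries report the fraction of each class covered at given
thresholds. Wing-decay profiles quantify how far usable coverage extends
beyond isolated baits, and an OLS regression of per-bait mean depth on
absolute mean-centred GC content quantifies the GC dependence of capture
efficiency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pysam
from scipy import stats

from .baits import Bait, BaitSet
from .genome import SyntheticGenome

log = logging.getLogger(__name__)

CLASS_BAIT, CLASS_ADJACENT, CLASS_OFF = 0, 1, 2
CLASS_NAMES = {CLASS_BAIT: "bait", CLASS_ADJACENT: "adjacent", CLASS_OFF: "off_target"}


@dataclass
class DepthTrack:
    sample_id: str
    depths: Dict[str, np.ndarray]      # chrom -> int array, one value per base

    def total(self) -> int:
        return int(sum(int(d.sum()) for d in self.depths.values()))


@dataclass
class RegionClassMap:
    labels: Dict[str, np.ndarray]      # chrom -> uint8 array of CLASS_* codes
    flank: int = 250

    def counts(self) -> Dict[str, int]:
        out = {name: 0 for name in CLASS_NAMES.values()}
        for arr in self.labels.values():
            for code, name in CLASS_NAMES.items():
                out[name] += int((arr == code).sum())
        return out


@dataclass
class WingProfile:
    side: str                           # left | right
    mean_depth: np.ndarray              # indexed by distance-1 from the bait edge

    def width_at_threshold(self, t: float) -> int:
        """Largest d such that mean depth >= t at every distance <= d
        (contiguous from the bait edge)."""
        below = np.nonzero(self.mean_depth < t)[0]
        return int(below[0]) if below.size else len(self.mean_depth)


@dataclass
class GCRegressionResult:
    gc: np.ndarray
    mean_depth: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


# ----------------------------------------------------------------- depth

def unique_by_tag(rec: pysam.AlignedSegment) -> bool:
    """Uniqueness from the simulator's truth tag (XU:i:1)."""
    return rec.has_tag("XU") and rec.get_tag("XU") == 1


def unique_by_mapq(rec: pysam.AlignedSegment, min_mapq: int = 1) -> bool:
    """Uniqueness proxy for real alignments: MAPQ >= threshold and neither
    secondary nor supplementary."""
    return (rec.mapping_quality >= min_mapq and not rec.is_secondary
            and not rec.is_supplementary)


def compute_depth(
    alignments: Iterable[pysam.AlignedSegment],
    genome: SyntheticGenome,
    uniqueness_rule=unique_by_tag,
    sample_id: Optional[str] = None,
) -> DepthTrack:
    """Per-base depth over uniquely mapped records.

    When ``sample_id`` is given only records whose RG tag matches are
    counted (the simulator pools samples into one truth SAM).
    """
    lens = genome.chrom_lengths()
    depths = {c: np.zeros(l, dtype=np.int32) for c, l in lens.items()}
    for rec in alignments:
        if rec.is_unmapped or not uniqueness_rule(rec):
            continue
        if sample_id is not None and rec.get_tag("RG") != sample_id:
            continue
        chrom = rec.reference_name
        if chrom not in depths:
            raise ValueError(f"alignment reference {chrom!r} not in genome")
        for s, e in rec.get_blocks():
            depths[chrom][s:e] += 1
    return DepthTrack(sample_id or "all", depths)


def depth_tracks_from_sam(sam_path, genome, samples: Sequence[str],
                          uniqueness_rule=unique_by_tag) -> List[DepthTrack]:
    """One DepthTrack per sample from a pooled (RG-tagged) SAM file."""
    lens = genome.chrom_lengths()
    tracks = {s: {c: np.zeros(l, dtype=np.int32) for c, l in lens.items()}
              for s in samples}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or not uniqueness_rule(rec):
                continue
            rg = rec.get_tag("RG") if rec.has_tag("RG") else None
            if rg not in tracks:
                continue
            for s, e in rec.get_blocks():
                tracks[rg][rec.reference_name][s:e] += 1
    return [DepthTrack(s, d) for s, d in tracks.items()]


# ------------------------------------------------------------ class map

def classify_genome(baitset: BaitSet, genome: SyntheticGenome, flank: int = 250
                    ) -> RegionClassMap:
    """Exact 3-way partition of the genome; bait label wins over adjacent."""
    lens = genome.chrom_lengths()
    labels = {c: np.full(l, CLASS_OFF, dtype=np.uint8) for c, l in lens.items()}
    for b in baitset:
        arr = labels[b.chromosome]
        s = max(0, b.start - flank)
        e = min(len(arr), b.end + flank)
        adj = arr[s:e]
        adj[adj == CLASS_OFF] = CLASS_ADJACENT
    for b in baitset:
        labels[b.chromosome][b.start:b.end] = CLASS_BAIT
    return RegionClassMap(labels, flank)


# ------------------------------------------------------------- summaries

def coverage_summary(
    tracks: Sequence[DepthTrack],
    class_map: RegionClassMap,
    thresholds: Sequence[int] = (1, 10),
):
    """Per-sample and mean fraction of bases covered >= t per region class,
    plus genome-wide bp covered >= 10X in all samples and in >= 1 sample.

    Returns (pandas.DataFrame, dict of genome-wide counts).
    """
    import pandas as pd
    if any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be positive")
    rows = []
    chroms = list(class_map.labels)
    class_bases = class_map.counts()
    for tr in tracks:
        for t in thresholds:
            cov = {name: 0 for name in CLASS_NAMES.values()}
            for c in chroms:
                lab = class_map.labels[c]
                ok = tr.depths[c] >= t
                for code, name in CLASS_NAMES.items():
                    cov[name] += int((ok & (lab == code)).sum())
            for name in CLASS_NAMES.values():
                denom = class_bases[name]
                rows.append({
                    "sample": tr.sample_id, "threshold": t, "region_class": name,
                    "bases_covered": cov[name],
                    "fraction": cov[name] / denom if denom else np.nan,
                })
    df = pd.DataFrame(rows)
    mean = (df.groupby(["threshold", "region_class"], as_index=False)["fraction"]
            .mean().assign(sample="MEAN"))
    df = pd.concat([df, mean], ignore_index=True)

    all10 = 0
    any10 = 0
    for c in chroms:
        stack = np.stack([tr.depths[c] >= 10 for tr in tracks])
        all10 += int(stack.all(axis=0).sum())
        any10 += int(stack.any(axis=0).sum())
    return df, {"bp_ge10x_all_samples": all10, "bp_ge10x_any_sample": any10}


# ------------------------------------------------------- isolated baits

def select_isolated_baits(baitset: BaitSet, isolation: int = 1000,
                          double_gap: int = 0
                          ) -> Tuple[List[Bait], List[Tuple[Bait, Bait]]]:
    """Single baits with no neighbour within ``isolation`` bp of either edge,
    and immediately adjacent bait pairs (gap <= ``double_gap``) with no third
    bait within ``isolation`` bp of the pair's outer edges."""
    by_chrom: Dict[str, List[Bait]] = {}
    for b in baitset:
        by_chrom.setdefault(b.chromosome, []).append(b)
    singles: List[Bait] = []
    doubles: List[Tuple[Bait, Bait]] = []
    for chrom, bs in by_chrom.items():
        bs = sorted(bs, key=lambda b: b.start)
        n = len(bs)
        for i, b in enumerate(bs):
            gap_prev = b.start - bs[i - 1].end if i > 0 else None
            gap_next = bs[i + 1].start - b.end if i < n - 1 else None
            if (gap_prev is None or gap_prev >= isolation) and \
               (gap_next is None or gap_next >= isolation):
                singles.append(b)
            elif gap_next is not None and gap_next <= double_gap:
                gap_pp = b.start - bs[i - 1].end if i > 0 else None
                gap_nn = bs[i + 2].start - bs[i + 1].end if i < n - 2 else None
                if (gap_pp is None or gap_pp >= isolation) and \
                   (gap_nn is None or gap_nn >= isolation):
                    doubles.append((b, bs[i + 1]))
    return singles, doubles


def wing_decay(
    tracks: Sequence[DepthTrack],
    units: Sequence,                     # Baits or (Bait, Bait) pairs
    max_distance: int = 1000,
    threshold: float = 10.0,
) -> Tuple[WingProfile, WingProfile]:
    """Mean depth at each distance 1..max_distance from the outer edges of
    isolated single baits or double-bait pairs, over baits and samples."""
    if not units:
        log.warning("no qualifying baits for wing decay; empty profile")
        empty = WingProfile("left", np.zeros(0))
        return empty, WingProfile("right", np.zeros(0))
    sums = {"left": np.zeros(max_distance), "right": np.zeros(max_distance)}
    counts = {"left": np.zeros(max_distance), "right": np.zeros(max_distance)}
    for u in units:
        if isinstance(u, tuple):
            chrom, left_edge, right_edge = u[0].chromosome, u[0].start, u[1].end
        else:
            chrom, left_edge, right_edge = u.chromosome, u.start, u.end
        for tr in tracks:
            arr = tr.depths[chrom]
            # left wing: distances 1.. from the bait's left edge, moving left
            lo = max(0, left_edge - max_distance)
            seg = arr[lo:left_edge][::-1]
            sums["left"][:len(seg)] += seg
            counts["left"][:len(seg)] += 1
            seg = arr[right_edge:right_edge + max_distance]
            sums["right"][:len(seg)] += seg
            counts["right"][:len(seg)] += 1
    with np.errstate(invalid="ignore"):
        left = np.where(counts["left"] > 0, sums["left"] / counts["left"], 0.0)
        right = np.where(counts["right"] > 0, sums["right"] / counts["right"], 0.0)
    return WingProfile("left", left), WingProfile("right", right)


def covered_span(core_bp: int, left: WingProfile, right: WingProfile,
                 threshold: float = 10.0) -> Dict[str, int]:
    """Total span covered at >= threshold: core bp plus both wing widths."""
    lw = left.width_at_threshold(threshold)
    rw = right.width_at_threshold(threshold)
    return {"core_bp": core_bp, "wing_bp": lw + rw, "total_bp": core_bp + lw + rw,
            "left_width": lw, "right_width": rw}


# ---------------------------------------------------------- GC regression

def gc_content(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0


def gc_vs_depth(
    genome: SyntheticGenome,
    baitset: BaitSet,
    tracks: Sequence[DepthTrack],
    min_separation: int = 120,
    excluded_samples: Sequence[str] = (),
) -> GCRegressionResult:
    """OLS of per-bait mean depth on |GC - mean(GC)| over isolated baits.

    Qualifying baits are single baits separated from any other bait by at
    least ``min_separation`` bp; mean depth is taken across all non-excluded
    samples over the bait's bases.
    """
    singles, _ = select_isolated_baits(baitset, isolation=min_separation)
    if len(singles) < 10:
        raise ValueError(f"only {len(singles)} qualifying baits (need >= 10)")
    use = [t for t in tracks if t.sample_id not in set(excluded_samples)]
    chrom_seq = genome.chrom_dict()
    gc = np.array([gc_content(chrom_seq[b.chromosome][b.start:b.end]) for b in singles])
    depth = np.array([
        np.mean([t.depths[b.chromosome][b.start:b.end].mean() for t in use])
        for b in singles])
    x = np.abs(gc - gc.mean())
    if np.allclose(x.var(), 0):
        raise ValueError("zero variance in |GC - mean GC| predictor")
    res = stats.linregress(x, depth)
    return GCRegressionResult(gc, depth, float(res.slope), float(res.intercept),
                              float(res.rvalue ** 2), float(res.pvalue), len(singles))


# ------------------------------------------------------ duplicate genes

def duplicate_compare(
    tracks: Sequence[DepthTrack],
    gene_baits: Dict[str, List[Bait]],
    duplicate_flags: Dict[str, bool],
) -> Dict[str, Dict[str, float]]:
    """Mean and variance of gene-level depth (mean depth over the gene's
    bait bases, averaged over samples) for duplicated vs single-copy genes."""
    by_class: Dict[str, List[float]] = {"duplicated": [], "single_copy": []}
    for gid, baits in gene_baits.items():
        if not baits:
            continue
        vals = []
        for t in tracks:
            per_bait = [t.depths[b.chromosome][b.start:b.end].mean() for b in baits]
            vals.append(np.mean(per_bait))
        cls = "duplicated" if duplicate_flags.get(gid, False) else "single_copy"
        by_class[cls].append(float(np.mean(vals)))
    if not by_class["duplicated"] or not by_class["single_copy"]:
        raise ValueError("both duplicate classes must be non-empty")
    out = {}
    for cls, vals in by_class.items():
        arr = np.array(vals)
        out[cls] = {"n": len(arr), "mean": float(arr.mean()),
                    "variance": float(arr.var())}
    out["ratio"] = {
        "mean": (out["duplicated"]["mean"] / out["single_copy"]["mean"]
                 if out["single_copy"]["mean"] else np.nan),
        "variance": (out["duplicated"]["variance"] / out["single_copy"]["variance"]
                     if out["single_copy"]["variance"] else np.nan),
    }
    return out


# ------------------------------------------------------------------- I/O

def write_bedgraph(track: DepthTrack, path) -> None:
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track.sample_id}"\n')
        for chrom in track.depths:
            arr = track.depths[chrom]
            edges = np.nonzero(np.diff(arr))[0] + 1
            starts = np.concatenate([[0], edges])
            ends = np.concatenate([edges, [len(arr)]])
            for s, e in zip(starts, ends):
                if arr[s]:
                    fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]}\n")
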