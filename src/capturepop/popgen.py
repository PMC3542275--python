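"""Multilocus nucleotide-diversity estimation.

Callable regions (every base covered >= 10X in all clones) are assembled
around gene spans and intergenic control regions, extended by contiguous
callable flanking runs (capped, default 500bp beyond the annotated span) and
merged across adjacent genes when the intervening bases are callable. For
each region, segregating sites with minor-allele counts over the n = 2 x
clones sampled chromosomes feed the standard estimators:

    Watterson's theta_w = S / (a1 * L),         a1 = sum_{i=1}^{n-1} 1/i
    Tajima's pi        = (1/L) * sum_s (n/(n-1)) * 2 p_s (1 - p_s)
    Tajima's D         = (pi*L - S/a1) / sqrt(e1*S + e2*S*(S-1))

with the usual constants a2, b1, b2, c1, c2, e1, e2. Per-site statistics
require only allele counts, so unphased diploid genotypes are handled
exactly. D is undefined for S = 0; such regions contribute zeros to the
theta/pi means but are excluded from D averages.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .genome import SyntheticGenome
from .intervals import Interval, merge_intervals

log = logging.getLogger(__name__)


@dataclass
class RegionAlignmentMatrix:
    region_id: str
    region_class: str                  # genic | intergenic
    duplicate_status: str = "n/a"      # single_copy | duplicated | n/a
    L: int = 0                         # callable sites
    allele_counts: List[int] = field(default_factory=list)
    n: int = 0                         # sampled chromosomes (2 x clones)
    chromosome: str = ""
    intervals: List[Interval] = field(default_factory=list)

    def __post_init__(self):
        bad = [c for c in self.allele_counts if not (1 <= c <= self.n - 1)]
        if bad:
            raise ValueError(f"allele counts must lie in [1, n-1]; got {bad[:3]}")
        if self.L < len(self.allele_counts):
            raise ValueError("L must be >= number of segregating sites")

    @property
    def S(self) -> int:
        return len(self.allele_counts)


@dataclass
class DiversityResult:
    region_id: str
    region_class: str
    duplicate_status: str
    L: int
    S: int
    theta_w: float
    pi: float
    D: Optional[float]      # None when S = 0
    constants: Dict[str, float] = field(default_factory=dict)


# -------------------------------------------------------------- constants

def tajima_constants(n: int) -> Dict[str, float]:
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


# ------------------------------------------------------------- estimators

def watterson_theta(S: int, n: int, L: int) -> float:
    """Watterson's per-site theta, S / (a1 * L)."""
    if L <= 0:
        raise ValueError("L must be >= 1")
    if n < 2:
        raise ValueError("n must be >= 2")
    return S / (tajima_constants(n)["a1"] * L)


def tajima_pi(allele_counts: Sequence[int], n: int, L: int) -> float:
    """Per-site mean pairwise diversity from allele counts.

    Exactly equals the mean pairwise difference count among the n sampled
    chromosomes divided by L.
    """
    if L <= 0:
        raise ValueError("L must be >= 1")
    total = 0.0
    for c in allele_counts:
        p = c / n
        total += (n / (n - 1)) * 2.0 * p * (1.0 - p)
    return total / L


def tajimas_d(S: int, pi_total: float, n: int) -> float:
    """Tajima's D from the segregating-site count and total (not per-site)
    pairwise diversity. Undefined for S = 0."""
    if S < 1:
        raise ValueError("Tajima's D is undefined for S = 0")
    k = tajima_constants(n)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    return (pi_total - S / k["a1"]) / np.sqrt(var)


def diversity(matrix: RegionAlignmentMatrix) -> DiversityResult:
    S, n, L = matrix.S, matrix.n, matrix.L
    theta = watterson_theta(S, n, L)
    pi = tajima_pi(matrix.allele_counts, n, L)
    D = tajimas_d(S, pi * L, n) if S >= 1 else None
    return DiversityResult(matrix.region_id, matrix.region_class,
                           matrix.duplicate_status, L, S, theta, pi, D,
                           tajima_constants(n))


# ---------------------------------------------------------------- regions

def callable_mask(depth_tracks, min_depth: int = 10) -> Dict[str, np.ndarray]:
    """Bases covered >= min_depth in every sample."""
    chroms = list(depth_tracks[0].depths)
    return {c: np.all(np.stack([t.depths[c] >= min_depth for t in depth_tracks]),
                      axis=0)
            for c in chroms}


def _runs(mask: np.ndarray) -> List[Interval]:
    """Maximal runs of True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def _extend_seed(mask: np.ndarray, start: int, end: int, cap: int) -> Interval:
    """Extend a seed interval through contiguous callable runs at each edge,
    at most ``cap`` bp beyond the seed."""
    lo = start
    while lo > 0 and mask[lo - 1] and start - lo < cap:
        lo -= 1
    hi = end
    n = len(mask)
    while hi < n and mask[hi] and hi - end < cap:
        hi += 1
    return lo, hi


def assemble_regions(
    candidates,
    mask: Dict[str, np.ndarray],
    genome: SyntheticGenome,
    controls: Optional[Sequence[Tuple[str, int, int]]] = None,
    n_chromosomes: Optional[int] = None,
    flank_cap: int = 500,
    duplicate_flags: Optional[Dict[str, bool]] = None,
) -> List[RegionAlignmentMatrix]:
    """Build per-region allele-count matrices from a candidate SNP set.

    ``candidates`` is a CandidateSNPSet (variants module) or any object with
    ``sites`` carrying (chromosome, position, allele_count) and ``samples``.
    Genic regions seed on gene spans; intergenic regions on the control
    intervals. Seeds are extended through contiguous callable runs (up to
    ``flank_cap`` bp beyond the seed) and genic regions are merged when
    their extended intervals meet. A control whose core interval overlaps an
    assembled genic region is an error; control flank extension stops at
    genic boundaries. L counts callable bases only.
    """
    if controls is None:
        controls = genome.intergenic_controls
    n = n_chromosomes or 2 * len(candidates.samples)
    duplicate_flags = duplicate_flags or {
        g.gene_id: g.duplicate_partner is not None for g in genome.gene_models}

    # --- genic: extend each gene span, then merge overlapping extensions
    ext_by_chrom: Dict[str, List[Tuple[int, int, str]]] = {}
    for g in genome.gene_models:
        lo, hi = _extend_seed(mask[g.chromosome], g.start, g.end, flank_cap)
        ext_by_chrom.setdefault(g.chromosome, []).append((lo, hi, g.gene_id))

    regions: List[RegionAlignmentMatrix] = []
    genic_intervals_by_chrom: Dict[str, List[Interval]] = {}
    for chrom, items in ext_by_chrom.items():
        items.sort()
        merged: List[Tuple[int, int, List[str]]] = []
        for lo, hi, gid in items:
            if merged and lo <= merged[-1][1]:
                prev = merged[-1]
                merged[-1] = (prev[0], max(prev[1], hi), prev[2] + [gid])
            else:
                merged.append((lo, hi, [gid]))
        genic_intervals_by_chrom[chrom] = [(lo, hi) for lo, hi, _ in merged]
        for lo, hi, gids in merged:
            flags = [duplicate_flags.get(g, False) for g in gids]
            status = "duplicated" if any(flags) else "single_copy"
            regions.append(_make_matrix(
                "+".join(gids), "genic", status, chrom, lo, hi, mask[chrom],
                candidates, n))

    # --- intergenic controls
    for i, (chrom, s, e) in enumerate(controls):
        genic_ivs = genic_intervals_by_chrom.get(chrom, [])
        if any(s < ge and gs < e for gs, ge in genic_ivs):
            raise ValueError(
                f"intergenic control {chrom}:{s}-{e} overlaps a genic region")
        lo, hi = _extend_seed(mask[chrom], s, e, flank_cap)
        for gs, ge in genic_ivs:           # stop flanks at genic boundaries
            if ge <= s:
                lo = max(lo, ge)
            if gs >= e:
                hi = min(hi, gs)
        regions.append(_make_matrix(
            f"control_{i:04d}", "intergenic", "n/a", chrom, lo, hi, mask[chrom],
            candidates, n))
    return regions


def _make_matrix(rid, cls, status, chrom, lo, hi, mask, candidates, n
                 ) -> RegionAlignmentMatrix:
    region_mask = mask[lo:hi]
    L = int(region_mask.sum())
    counts = []
    for site in candidates.sites:
        if site.chromosome == chrom and lo <= site.position < hi \
                and mask[site.position]:
            ac = site.allele_count(candidates.samples)
            if 1 <= ac <= n - 1:
                counts.append(ac)
    ivs = [(int(s + lo), int(e + lo)) for s, e in _runs(region_mask)]
    return RegionAlignmentMatrix(rid, cls, status, L, counts, n, chrom, ivs)


# --------------------------------------------------------------- summary

@dataclass
class RegionSetSummary:
    table: "object"                    # pandas DataFrame

    def __str__(self):
        return self.table.to_string(index=False)


def summarize(results: Sequence[DiversityResult], sd_ddof: int = 0) -> RegionSetSummary:
    """Table-style summary: mean (SD) of L, S, theta_w, pi and D per region
    class, with genic rows split by duplicate status. SD is the population
    SD by default (``sd_ddof=0``). D averages over regions with defined D."""
    import pandas as pd

    def row(name, rs):
        if not rs:
            warnings.warn(f"no regions in class {name!r}; row omitted", stacklevel=2)
            return None
        arr = lambda f: np.array([f(r) for r in rs], dtype=float)
        ds = np.array([r.D for r in rs if r.D is not None], dtype=float)
        out = {"regions": name, "n": len(rs)}
        for col, f in (("length", lambda r: r.L), ("S", lambda r: r.S),
                       ("theta", lambda r: r.theta_w), ("pi", lambda r: r.pi)):
            v = arr(f)
            out[col] = v.mean()
            out[f"{col}_sd"] = v.std(ddof=sd_ddof) if len(v) > sd_ddof else 0.0
        out["D"] = ds.mean() if ds.size else np.nan
        out["D_sd"] = (ds.std(ddof=sd_ddof) if ds.size > sd_ddof else 0.0) \
            if ds.size else np.nan
        out["n_D"] = int(ds.size)
        return out

    genic = [r for r in results if r.region_class == "genic"]
    rows = [
        row("All genes", genic),
        row("Single copy genes", [r for r in genic if r.duplicate_status == "single_copy"]),
        row("Duplicated genes", [r for r in genic if r.duplicate_status == "duplicated"]),
        row("Intergenic", [r for r in results if r.region_class == "intergenic"]),
    ]
    return RegionSetSummary(pd.DataFrame([r for r in rows if r is not None]))


# ------------------------------------------------------------------- I/O

def write_region_tsv(results: Sequence[DiversityResult], path) -> None:
    import pandas as pd
    pd.DataFrame([{
        "region_id": r.region_id, "class": r.region_class,
        "duplicate_status": r.duplicate_status, "L": r.L, "S": r.S,
        "theta_w": r.theta_w, "pi": r.pi,
        "D": r.D if r.D is not None else np.nan,
    } for r in results]).to_csv(path, sep="\t", index=False)
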