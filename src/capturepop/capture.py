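"""Hybridization-capture sequencing simulator.

Fragments are sheared to a truncated-normal length distribution and captured
around baits: an on-target fragment's midpoint is uniform over the bait
extended by half a fragment length on each side, so fragment overhang
produces the characteristic coverage "wings" flanking each bait. Capture
efficiency is thinned by a quadratic GC penalty (maximal near the genome
mean GC, reduced at both extremes), and a configurable fraction of fragments
is drawn uniformly from the whole genome as off-target background. Paired
100bp reads are taken from the two fragment ends with Phred+33 qualities and
substitution errors at the per-base rate 10^(-Q/10).

The simulator emits the reads as pooled, barcoded FASTQ plus a ground-truth
SAM giving each read's true origin — no aligner is involved. Reads whose
fragment lies inside a retained-duplicate gene and whose reference sequence
is identical in the paralog are flagged non-unique (XU:i:0, MAPQ 0); all
others are unique (XU:i:1, MAPQ 60). Custom tags record the fragment origin
(XO:Z:chrom:start-end) and source haplotype (XH:i).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam
from scipy.stats import truncnorm

from .baits import BaitSet
from .genome import SyntheticGenome
from .population import PopulationSample
from .qc import FastqRecord

log = logging.getLogger(__name__)

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class CaptureModel:
    """Parameters of the fragment/capture process.

    fragment_median
        Median (= mean, the distribution being symmetric before truncation)
        sheared-fragment length in bp.
    fragment_sd
        Standard deviation of fragment length.
    fragment_min, fragment_max
        Truncation bounds of the length distribution.
    gc_penalty
        Curvature c of the capture-efficiency curve
        eff(gc) = clip(1 - c * (gc - gc_mean)^2, 0.05, 1).
    gc_mean
        Centre of the efficiency curve; None -> genome mean GC.
    off_target_fraction
        Probability that a fragment is drawn uniformly from the genome
        instead of around a bait.
    mean_on_target_depth
        Target expected read depth at bait centres.
    overhang
        When False, fragment midpoints are pinned to the bait midpoint
        instead of uniform over the bait +- half a fragment length; with a
        fixed 120bp fragment length this collapses fragments onto the baits
        exactly (a degenerate model useful for testing).
    """

    fragment_median: float = 180.0
    fragment_sd: float = 40.0
    fragment_min: float = 60.0
    fragment_max: float = 400.0
    gc_penalty: float = 40.0
    gc_mean: Optional[float] = None
    off_target_fraction: float = 0.03
    mean_on_target_depth: float = 30.0
    overhang: bool = True

    def __post_init__(self):
        if not (0.0 <= self.off_target_fraction < 1.0):
            raise ValueError("off_target_fraction must be in [0, 1)")
        if self.mean_on_target_depth <= 0:
            raise ValueError("mean_on_target_depth must be positive")

    def draw_lengths(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.fragment_sd <= 0 or self.fragment_max - self.fragment_min < 1e-9:
            return np.full(size, self.fragment_median)
        a = (self.fragment_min - self.fragment_median) / self.fragment_sd
        b = (self.fragment_max - self.fragment_median) / self.fragment_sd
        return truncnorm.rvs(a, b, loc=self.fragment_median, scale=self.fragment_sd,
                             size=size, random_state=rng)

    def efficiency(self, gc: np.ndarray, gc_mean: float) -> np.ndarray:
        return np.clip(1.0 - self.gc_penalty * (np.asarray(gc) - gc_mean) ** 2,
                       0.05, 1.0)


# ------------------------------------------------------------- fragments

def apply_variants(
    ref_seq: str,
    frag_start: int,
    frag_end: int,
    variants: Sequence[Tuple[int, str, str]],
) -> Tuple[str, List[Tuple[int, int]]]:
    """Build the haplotype fragment sequence and its CIGAR against the
    reference. ``variants`` are (pos, ref, alt), sorted, and only those fully
    inside [frag_start, frag_end) are applied. Returns (query, cigar) with
    cigar as (op, length) using op codes 0=M, 1=I, 2=D.
    """
    parts: List[str] = []
    cigar: List[Tuple[int, int]] = []

    def emit(op: int, length: int):
        if length <= 0:
            return
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + length)
        else:
            cigar.append((op, length))

    cur = frag_start
    for pos, ref, alt in variants:
        if pos < cur or pos + len(ref) > frag_end:
            continue
        if pos > cur:
            parts.append(ref_seq[cur:pos])
            emit(0, pos - cur)
        if len(ref) == 1 and len(alt) == 1:          # SNP
            parts.append(alt)
            emit(0, 1)
        elif len(ref) > len(alt):                    # deletion (anchored)
            parts.append(alt)
            emit(0, 1)
            emit(2, len(ref) - 1)
        else:                                        # insertion (anchored)
            parts.append(alt)
            emit(0, 1)
            emit(1, len(alt) - 1)
        cur = pos + len(ref)
    if cur < frag_end:
        parts.append(ref_seq[cur:frag_end])
        emit(0, frag_end - cur)
    return "".join(parts), cigar


def slice_alignment(
    cigar: List[Tuple[int, int]], ref_start: int, q_from: int, q_to: int
) -> Tuple[int, List[Tuple[int, int]]]:
    """Sub-alignment covering query positions [q_from, q_to).

    Returns (reference start of the slice, cigar of the slice). The slice
    CIGAR consumes exactly q_to - q_from query bases: insertions that fall
    on a slice boundary become soft clips (op 4) so SAM length invariants
    hold; boundary deletions are dropped.
    """
    out: List[Tuple[int, int]] = []
    q = 0
    r = ref_start
    slice_ref_start = None
    for op, length in cigar:
        q_consumes = op in (0, 1)
        r_consumes = op in (0, 2)
        if q_consumes:
            lo, hi = max(q, q_from), min(q + length, q_to)
            if lo < hi:
                if op == 0 and slice_ref_start is None:
                    slice_ref_start = r + (lo - q)
                out.append((op, hi - lo))
            q += length
        elif r_consumes and out and q_from < q < q_to:
            out.append((op, length))     # interior deletion
        if r_consumes:
            r += length
        if q >= q_to:
            break
    # boundary fixes: leading/trailing D dropped, leading/trailing I -> S
    while out and out[0][0] == 2:
        out.pop(0)
    while out and out[-1][0] == 2:
        out.pop()
    if out and out[0][0] == 1:
        out[0] = (4, out[0][1])
    if out and out[-1][0] == 1:
        out[-1] = (4, out[-1][1])
    merged: List[Tuple[int, int]] = []
    for op, length in out:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + length)
        else:
            merged.append((op, length))
    if not any(op == 0 for op, _ in merged):   # degenerate: slice inside an indel
        merged = [(0, q_to - q_from)]
    return (slice_ref_start if slice_ref_start is not None else ref_start), merged


def _duplicate_maps(genome: SyntheticGenome):
    """(chrom, start, end, partner_chrom, partner_start) for each duplicated gene."""
    by_id = genome.genes_by_id()
    out = []
    for g in genome.gene_models:
        if g.duplicate_partner and g.duplicate_partner in by_id:
            p = by_id[g.duplicate_partner]
            out.append((g.chromosome, g.start, g.end, p.chromosome, p.start - g.start))
    return out


# -------------------------------------------------------------- simulate

def simulate_capture_reads(
    genome: SyntheticGenome,
    samples: Sequence[PopulationSample],
    baitset: BaitSet,
    capture_model: CaptureModel,
    read_length: int = 100,
    seed: int = 0,
    fastq1_path=None,
    fastq2_path=None,
    sam_path=None,
    mean_quality: float = 35.0,
    quality_sd: float = 3.0,
    error_rate: Optional[float] = None,
    barcode_mismatch_rate: float = 0.0,
) -> Tuple[List[FastqRecord], List[FastqRecord], List[pysam.AlignedSegment], pysam.AlignmentHeader]:
    """Simulate a pooled capture sequencing run.

    ``error_rate`` None derives per-base substitution errors from the drawn
    qualities (10^(-Q/10)); an explicit value overrides that rate uniformly
    (0 gives error-free reads). Returns the mate-1 and mate-2 FASTQ records,
    the truth SAM records, and the SAM header; files are written when paths
    are given.
    """
    if not baitset:
        raise ValueError("baitset is empty")
    if read_length > 2 * capture_model.fragment_median:
        log.warning("read length %d exceeds 2x median fragment length %.0f",
                    read_length, capture_model.fragment_median)

    rng = np.random.default_rng(seed)
    chrom_seq = genome.chrom_dict()
    chrom_names = [c for c, _ in genome.chromosomes]
    chrom_lens = np.array([len(s) for _, s in genome.chromosomes], dtype=float)
    gc_mean = capture_model.gc_mean
    if gc_mean is None:
        tot = sum(s.count("G") + s.count("C") for _, s in genome.chromosomes)
        gc_mean = tot / float(chrom_lens.sum())
    dup_maps = _duplicate_maps(genome)

    # --- calibration: expected read records covering a bait centre per
    # fragment (mates count independently, so overlapping mates count twice)
    fl = capture_model.draw_lengths(rng, 2000)
    if capture_model.overhang:
        p_cover = float(np.mean(2 * np.minimum(fl, read_length) / (120.0 + fl)))
    else:
        p_cover = float(np.mean(np.minimum(2, 2 * read_length / fl)))
    eff_samples = []
    for _ in range(min(400, 4 * len(baitset))):
        b = baitset[int(rng.integers(0, len(baitset)))]
        L = float(capture_model.draw_lengths(rng, 1)[0])
        mid = rng.uniform(b.start - L / 2, b.end + L / 2)
        s = int(round(mid - L / 2))
        e = s + int(round(L))
        seq = chrom_seq[b.chromosome][max(0, s):e]
        if seq:
            gc = (seq.count("G") + seq.count("C")) / len(seq)
            eff_samples.append(capture_model.efficiency(np.array([gc]), gc_mean)[0])
    eff_bar = float(np.mean(eff_samples)) if eff_samples else 1.0
    lam = capture_model.mean_on_target_depth / (p_cover * eff_bar)

    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in zip(chrom_names, chrom_lens)],
        "RG": [{"ID": s.clone_id, "SM": s.clone_id, "BC": s.barcode} for s in samples],
        "PG": [{"ID": "capturepop", "PN": "capturepop-simulate"}],
    })

    fq1: List[FastqRecord] = []
    fq2: List[FastqRecord] = []
    sam_records: List[pysam.AlignedSegment] = []
    frag_counter = 0

    import bisect

    for sample in samples:
        # merge the clone's variants per chromosome per haplotype, sorted,
        # with a parallel position index for fast fragment slicing
        hap_vars: List[Dict[str, Tuple[List[int], List[Tuple[int, str, str]]]]] = []
        for h in (0, 1):
            hv = {}
            for c, vs in sample.haplotypes[h].items():
                vs = sorted(vs)
                hv[c] = ([v[0] for v in vs], vs)
            hap_vars.append(hv)

        frags: List[Tuple[str, int, int]] = []   # (chrom, start, end) accepted on-target
        for b in baitset:
            n = rng.poisson(lam)
            if n == 0:
                continue
            Ls = capture_model.draw_lengths(rng, n)
            if capture_model.overhang:
                mids = rng.uniform(b.start - Ls / 2, b.end + Ls / 2)
            else:
                mids = np.full(n, (b.start + b.end) / 2.0)
            for L, mid in zip(Ls, mids):
                s = int(round(mid - L / 2))
                e = s + int(round(L))
                clen = len(chrom_seq[b.chromosome])
                s, e = max(0, s), min(clen, e)
                if e - s < 30:
                    continue
                seq = chrom_seq[b.chromosome][s:e]
                gc = (seq.count("G") + seq.count("C")) / len(seq)
                if rng.random() < capture_model.efficiency(np.array([gc]), gc_mean)[0]:
                    frags.append((b.chromosome, s, e))
        p_off = capture_model.off_target_fraction
        if p_off > 0 and frags:
            n_off = rng.poisson(len(frags) * p_off / (1.0 - p_off))
            Ls = capture_model.draw_lengths(rng, n_off)
            cidx = rng.choice(len(chrom_names), size=n_off, p=chrom_lens / chrom_lens.sum())
            for L, ci in zip(Ls, cidx):
                clen = int(chrom_lens[ci])
                s = int(rng.integers(0, max(1, clen - int(L))))
                frags.append((chrom_names[ci], s, min(clen, s + int(round(L)))))

        for chrom, s, e in frags:
            h = int(rng.integers(0, 2))
            positions, variants = hap_vars[h].get(chrom, ([], []))
            lo = bisect.bisect_left(positions, s - 4)
            hi = bisect.bisect_right(positions, e)
            query, cigar = apply_variants(chrom_seq[chrom], s, e, variants[lo:hi])
            qlen = len(query)
            unique = True
            for dchrom, ds, de, pchrom, off in dup_maps:
                if chrom == dchrom and s >= ds and e <= de:
                    if chrom_seq[pchrom][s + off:e + off] == chrom_seq[chrom][s:e]:
                        unique = False
                    break
            rid = f"frag{frag_counter:08d}"
            frag_counter += 1
            r1_len = min(read_length, qlen)
            r2_len = min(read_length, qlen)
            r1_ref, r1_cig = slice_alignment(cigar, s, 0, r1_len)
            r2_ref, r2_cig = slice_alignment(cigar, s, qlen - r2_len, qlen)
            obs_bc = sample.barcode
            if barcode_mismatch_rate > 0 and rng.random() < barcode_mismatch_rate:
                i = int(rng.integers(0, len(obs_bc)))
                obs_bc = obs_bc[:i] + "ACGT"[int(rng.integers(0, 4))] + obs_bc[i + 1:]
            for mate, (q_from, q_to, ref_pos, cig) in enumerate(
                    ((0, r1_len, r1_ref, r1_cig),
                     (qlen - r2_len, qlen, r2_ref, r2_cig)), start=1):
                sub = query[q_from:q_to]
                quals = np.clip(np.round(rng.normal(mean_quality, quality_sd, len(sub))),
                                13, 41).astype(np.uint8)
                rate = (np.full(len(sub), error_rate) if error_rate is not None
                        else 10.0 ** (-quals.astype(np.float64) / 10.0))
                err = rng.random(len(sub)) < rate
                if err.any():
                    arr = np.frombuffer(sub.encode(), dtype="S1").copy()
                    for i in np.nonzero(err)[0]:
                        arr[i] = "ACGT".replace(arr[i].decode(), "")[
                            int(rng.integers(0, 3))].encode()
                    sub = arr.tobytes().decode()
                a = pysam.AlignedSegment(header)
                a.query_name = rid
                a.reference_name = chrom
                a.reference_start = ref_pos
                a.cigartuples = cig or [(0, len(sub))]
                a.query_sequence = sub
                a.query_qualities = quals.tolist()
                a.mapping_quality = 60 if unique else 0
                a.is_paired = True
                a.is_proper_pair = True
                a.is_read1 = mate == 1
                a.is_read2 = mate == 2
                a.is_reverse = mate == 2
                a.mate_is_reverse = mate == 1
                a.next_reference_name = chrom
                a.next_reference_start = r2_ref if mate == 1 else r1_ref
                a.template_length = (e - s) if mate == 1 else -(e - s)
                a.set_tag("RG", sample.clone_id)
                a.set_tag("XU", 1 if unique else 0)
                a.set_tag("XO", f"{chrom}:{s}-{e}")
                a.set_tag("XH", h)
                sam_records.append(a)
                qual_str = (quals + 33).tobytes().decode()
                if mate == 1:
                    fq1.append(FastqRecord(rid, sub, qual_str, 1, obs_bc))
                else:
                    fq2.append(FastqRecord(rid, revcomp(sub), qual_str[::-1], 2, obs_bc))

    if fastq1_path:
        from .qc import write_fastq
        write_fastq(fq1, fastq1_path)
    if fastq2_path:
        from .qc import write_fastq
        write_fastq(fq2, fastq2_path)
    if sam_path:
        with pysam.AlignmentFile(str(sam_path), "w", header=header) as out:
            for a in sam_records:
                out.write(a)
    return fq1, fq2, sam_records, header
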