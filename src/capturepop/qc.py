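"""Read preprocessing: demultiplexing, quality filtering, trimming, re-pairing.

A read passes quality control when its mean Phred quality is >= 30, its
minimum quality is >= 13, and it contains no undetermined (N) bases. An N
occurring only near an end of the read (within the terminal 10bp of either
end) triggers trimming of that end through the innermost terminal N; the
trimmed read is then re-tested against the same criteria and must retain at
least 50bp. Demultiplexing assigns a read to a sample when exactly one
barcode lies within the allowed Hamming distance (default 1) of the
observed index; ties and larger distances leave the read unassigned.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

from Bio.SeqIO.QualityIO import FastqGeneralIterator

log = logging.getLogger(__name__)

PHRED_OFFSET = 33
TERMINAL_WINDOW = 10
MIN_LENGTH_AFTER_TRIM = 50


@dataclass
class FastqRecord:
    read_id: str
    sequence: str
    qualities: str          # Phred+33 encoded
    mate: int = 1
    barcode: str = ""

    def __post_init__(self):
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and quality strings differ in length")

    @property
    def phred(self) -> List[int]:
        return [ord(c) - PHRED_OFFSET for c in self.qualities]


@dataclass
class QCReport:
    raw: Dict[str, int] = field(default_factory=dict)
    demultiplexed: Dict[str, int] = field(default_factory=dict)
    qc_passed: Dict[str, int] = field(default_factory=dict)
    trimmed: Dict[str, int] = field(default_factory=dict)
    paired_retained: Dict[str, int] = field(default_factory=dict)
    unassigned: int = 0

    def fractions(self) -> Dict[str, Dict[str, float]]:
        out: Dict[str, Dict[str, float]] = {}
        for sample in self.demultiplexed:
            d = self.demultiplexed[sample] or 1
            out[sample] = {
                "qc_passed": self.qc_passed.get(sample, 0) / d,
                "trimmed": self.trimmed.get(sample, 0) / d,
                "paired_retained": self.paired_retained.get(sample, 0) / d,
            }
        return out

    def to_frame(self):
        import pandas as pd
        rows = []
        for sample in sorted(self.demultiplexed):
            rows.append({
                "sample": sample,
                "demultiplexed": self.demultiplexed.get(sample, 0),
                "qc_passed": self.qc_passed.get(sample, 0),
                "trimmed": self.trimmed.get(sample, 0),
                "paired_retained": self.paired_retained.get(sample, 0),
            })
        return pd.DataFrame(rows)


# ------------------------------------------------------------------- I/O

def _open(path, mode="rt"):
    path = str(path)
    return gzip.open(path, mode) if path.endswith(".gz") else open(path, mode)


def read_fastq(path, mate: int = 1) -> Iterator[FastqRecord]:
    """Parse FASTQ; the index barcode is taken from an Illumina-style
    description field ``<lane>:N:0:<barcode>`` when present."""
    with _open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            parts = title.split()
            read_id = parts[0]
            m = mate
            if read_id.endswith(("/1", "/2")):
                m = int(read_id[-1])
                read_id = read_id[:-2]
            barcode = ""
            if len(parts) > 1:
                fields = parts[1].split(":")
                if len(fields) == 4:
                    barcode = fields[3]
            yield FastqRecord(read_id, seq, qual, m, barcode)


def write_fastq(records: Iterable[FastqRecord], path) -> None:
    with _open(path, "wt") as fh:
        for r in records:
            comment = f" 1:N:0:{r.barcode}" if r.barcode else ""
            fh.write(f"@{r.read_id}/{r.mate}{comment}\n{r.sequence}\n+\n{r.qualities}\n")


def read_barcode_map(path) -> Dict[str, str]:
    """TSV of (sample, index sequence)."""
    out: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                sample, bc = line.split()[:2]
                out[sample] = bc.upper()
    return out


# ----------------------------------------------------------- demultiplex

def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    records: Iterable[FastqRecord],
    barcode_map: Dict[str, str],
    max_mismatch: int = 1,
) -> Tuple[Dict[str, List[FastqRecord]], List[FastqRecord]]:
    """Assign reads to samples by index barcode.

    A read is assigned iff exactly one sample barcode is within
    ``max_mismatch`` of the observed index; otherwise it is unassigned.
    """
    barcodes = list(barcode_map.values())
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcodes in barcode map")
    lengths = {len(b) for b in barcodes}
    if len(lengths) != 1:
        raise ValueError("barcodes must all have the same length")
    for i, a in enumerate(barcodes):
        for b in barcodes[i + 1:]:
            if hamming(a, b) <= 2 * max_mismatch:
                warnings.warn(
                    f"barcodes {a} and {b} are within {2 * max_mismatch} mismatches; "
                    "some reads may be unassignable", stacklevel=2)
    assigned: Dict[str, List[FastqRecord]] = {s: [] for s in barcode_map}
    unassigned: List[FastqRecord] = []
    items = list(barcode_map.items())
    for rec in records:
        hits = [s for s, bc in items
                if len(rec.barcode) == len(bc) and hamming(rec.barcode, bc) <= max_mismatch]
        if len(hits) == 1:
            assigned[hits[0]].append(rec)
        else:
            unassigned.append(rec)
    return assigned, unassigned


# -------------------------------------------------------------- filtering

def quality_filter(
    record: FastqRecord,
    mean_q: float = 30.0,
    min_q: int = 13,
    terminal_window: int = TERMINAL_WINDOW,
    min_length: int = MIN_LENGTH_AFTER_TRIM,
) -> Tuple[str, Optional[FastqRecord]]:
    """Apply the quality criteria; returns (status, record-or-None) with
    status in {"pass", "trimmed", "fail"}."""
    if not record.sequence:
        return "fail", None
    n_positions = [i for i, b in enumerate(record.sequence) if b == "N"]
    seq, qual = record.sequence, record.qualities
    trimmed = False
    if n_positions:
        L = len(seq)
        left_ns = [i for i in n_positions if i < terminal_window]
        right_ns = [i for i in n_positions if i >= L - terminal_window]
        if len(left_ns) + len(right_ns) != len(n_positions):
            return "fail", None      # N in the interior of the read
        lo = max(left_ns) + 1 if left_ns else 0
        hi = min(right_ns) if right_ns else L
        if hi - lo < min_length:
            return "fail", None
        seq, qual = seq[lo:hi], qual[lo:hi]
        trimmed = True
    phred = [ord(c) - PHRED_OFFSET for c in qual]
    if "N" in seq or not phred:
        return "fail", None
    if sum(phred) / len(phred) < mean_q or min(phred) < min_q:
        return "fail", None
    out = FastqRecord(record.read_id, seq, qual, record.mate, record.barcode)
    return ("trimmed" if trimmed else "pass"), out


def repair(
    passed_mate1: Iterable[FastqRecord],
    passed_mate2: Iterable[FastqRecord],
) -> Tuple[List[Tuple[FastqRecord, FastqRecord]], int]:
    """Keep only reads whose mate also passed; returns (pairs, n_orphans).

    Pairs are emitted in mate-1 input order regardless of mate-2 order.
    """
    m2: Dict[str, FastqRecord] = {}
    for r in passed_mate2:
        if r.read_id in m2:
            raise ValueError(f"duplicate read id in mate-2 stream: {r.read_id}")
        m2[r.read_id] = r
    pairs: List[Tuple[FastqRecord, FastqRecord]] = []
    seen1 = set()
    orphans = 0
    for r in passed_mate1:
        if r.read_id in seen1:
            raise ValueError(f"duplicate read id in mate-1 stream: {r.read_id}")
        seen1.add(r.read_id)
        mate = m2.pop(r.read_id, None)
        if mate is None:
            orphans += 1
        else:
            pairs.append((r, mate))
    orphans += len(m2)
    return pairs, orphans


def run_qc(
    records1: Iterable[FastqRecord],
    records2: Iterable[FastqRecord],
    barcode_map: Dict[str, str],
    max_mismatch: int = 1,
    mean_q: float = 30.0,
    min_q: int = 13,
) -> Tuple[Dict[str, List[Tuple[FastqRecord, FastqRecord]]], QCReport]:
    """Full preprocessing: demultiplex both mates, filter, re-pair."""
    report = QCReport()
    records1, records2 = list(records1), list(records2)
    report.raw = {"total": len(records1) + len(records2)}
    a1, u1 = demultiplex(records1, barcode_map, max_mismatch)
    a2, u2 = demultiplex(records2, barcode_map, max_mismatch)
    report.unassigned = len(u1) + len(u2)
    pairs_by_sample: Dict[str, List[Tuple[FastqRecord, FastqRecord]]] = {}
    for sample in barcode_map:
        report.demultiplexed[sample] = len(a1[sample]) + len(a2[sample])
        passed1, passed2 = [], []
        n_pass = n_trim = 0
        for recs, sink in ((a1[sample], passed1), (a2[sample], passed2)):
            for rec in recs:
                status, out = quality_filter(rec, mean_q, min_q)
                if status != "fail":
                    sink.append(out)
                    n_pass += 1
                    n_trim += status == "trimmed"
        report.qc_passed[sample] = n_pass
        report.trimmed[sample] = n_trim
        pairs, _ = repair(passed1, passed2)
        pairs_by_sample[sample] = pairs
        report.paired_retained[sample] = 2 * len(pairs)
    return pairs_by_sample, report
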