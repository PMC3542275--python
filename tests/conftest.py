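"""Shared fixtures: one moderately sized simulated capture experiment is
built once per session and reused by the coverage, variant and diversity
tests (error-free reads, no indel polymorphism, known truth)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np
import pytest

import capturepop as cp
from capturepop import coverage as cov
from capturepop import popgen as pg
from capturepop import variants as var


@dataclass
class Bundle:
    genome: "cp.SyntheticGenome"
    truth: "cp.PopulationTruth"
    baitset: list
    fq1: list
    fq2: list
    sam: list
    tracks: List[cov.DepthTrack]
    mask: Dict[str, np.ndarray]
    columns: dict
    candidates: "var.CandidateSNPSet"
    samples: List[str] = field(default_factory=list)


@pytest.fixture(scope="session")
def bundle() -> Bundle:
    """5 diploid clones, 2 x 60kb chromosomes, error-free 15X capture."""
    genome = cp.generate_genome(
        n_chrom=2, chrom_lengths=[60_000, 60_000], n_genes=20, n_controls=6,
        duplicate_fraction=0.2, priority_fraction=0.1, seed=11)
    truth = cp.simulate_population(genome, n_clones=5, theta_genic=0.0035,
                                   theta_intergenic=0.0071, indel_rate=0.0, seed=12)
    targets = cp.extract_targets(genome, n_intergenic=6)
    baitset = cp.design_baits(targets)
    model = cp.CaptureModel(mean_on_target_depth=15, off_target_fraction=0.03)
    fq1, fq2, sam, _ = cp.simulate_capture_reads(
        genome, truth.samples, baitset, model, read_length=100, seed=13,
        error_rate=0.0)
    samples = [s.clone_id for s in truth.samples]
    by_sample = {s: [] for s in samples}
    for r in sam:
        by_sample[r.get_tag("RG")].append(r)
    tracks = [cov.compute_depth(by_sample[s], genome, sample_id=s) for s in samples]
    mask = pg.callable_mask(tracks, 10)
    columns = var.pileup(sam, genome, uniqueness_rule=cov.unique_by_tag)
    calls = var.call_all(columns, samples)
    filtered = {s: var.per_clone_filter(c) for s, c in calls.items()}
    candidates = var.candidate_filter(
        filtered, tracks, var.indel_evidence_from_columns(columns))
    var.classify_snps(candidates, genome, baitset)
    return Bundle(genome, truth, baitset, fq1, fq2, sam, tracks, mask,
                  columns, candidates, samples)
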