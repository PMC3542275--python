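"""Coverage analytics: per-record depth semantics, genome partition,
isolated-bait selection, wing decay, GC regression, duplicate comparison."""

import numpy as np
import pysam
import pytest

import capturepop as cp
from capturepop.baits import Bait
from capturepop import coverage as cov


def make_genome(length=10_000, seed=0):
    rng = np.random.default_rng(seed)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
    return cp.SyntheticGenome([("chr1", seq)], [], [])


def make_record(header, start, length=100, cigar=None, unique=True, rg="s1"):
    a = pysam.AlignedSegment(header)
    a.query_name = f"r{start}"
    a.reference_name = "chr1"
    a.reference_start = start
    a.cigartuples = cigar or [(0, length)]
    qlen = sum(l for op, l in a.cigartuples if op in (0, 1))
    a.query_sequence = "A" * qlen
    a.query_qualities = [35] * qlen
    a.set_tag("RG", rg)
    a.set_tag("XU", 1 if unique else 0)
    a.mapping_quality = 60 if unique else 0
    return a


@pytest.fixture
def header():
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 10_000}]})


# ----------------------------------------------------------------- depth

def test_single_read_depth(header):
    g = make_genome()
    track = cov.compute_depth([make_record(header, 0, 100)], g)
    assert track.depths["chr1"][:100].tolist() == [1] * 100
    assert track.depths["chr1"][100:].sum() == 0


def test_overlapping_mates_double_count(header):
    g = make_genome()
    recs = [make_record(header, 0, 100), make_record(header, 50, 100)]
    d = cov.compute_depth(recs, g).depths["chr1"]
    assert d[:50].tolist() == [1] * 50
    assert d[50:100].tolist() == [2] * 50
    assert d[100:150].tolist() == [1] * 50


def test_non_unique_record_contributes_nothing(header):
    g = make_genome()
    d = cov.compute_depth([make_record(header, 0, 100, unique=False)], g)
    assert d.total() == 0


def test_deleted_bases_do_not_contribute(header):
    g = make_genome()
    rec = make_record(header, 0, cigar=[(0, 50), (2, 10), (0, 50)])
    d = cov.compute_depth([rec], g).depths["chr1"]
    assert d[:50].sum() == 50 and d[50:60].sum() == 0 and d[60:110].sum() == 50


def test_unknown_reference_raises(header):
    g = cp.SyntheticGenome([("chrX", "A" * 100)], [], [])
    with pytest.raises(ValueError):
        cov.compute_depth([make_record(header, 0, 50)], g)


def test_depth_conservation_on_simulation(bundle):
    total_aligned = sum(
        sum(e - s for s, e in r.get_blocks())
        for r in bundle.sam if r.get_tag("XU") == 1)
    assert sum(t.total() for t in bundle.tracks) == total_aligned


# ------------------------------------------------------------- partition

def test_classify_single_bait_flanks():
    g = make_genome()
    cmap = cov.classify_genome([Bait("chr1", 1000, 1120, "exon")], g, flank=250)
    lab = cmap.labels["chr1"]
    assert (lab[1000:1120] == cov.CLASS_BAIT).all()
    assert (lab[750:1000] == cov.CLASS_ADJACENT).all()
    assert (lab[1120:1370] == cov.CLASS_ADJACENT).all()
    assert (lab[:750] == cov.CLASS_OFF).all() and (lab[1370:] == cov.CLASS_OFF).all()


def test_classify_close_baits_gap_is_adjacent():
    g = make_genome()
    baits = [Bait("chr1", 1000, 1120, "exon"), Bait("chr1", 1220, 1340, "exon")]
    lab = cov.classify_genome(baits, g).labels["chr1"]
    assert (lab[1120:1220] == cov.CLASS_ADJACENT).all()


def test_classify_empty_baitset_all_off_target():
    g = make_genome()
    cmap = cov.classify_genome([], g)
    assert cmap.counts() == {"bait": 0, "adjacent": 0, "off_target": 10_000}


def test_partition_is_exact_on_simulation(bundle):
    cmap = cov.classify_genome(bundle.baitset, bundle.genome)
    counts = cmap.counts()
    assert sum(counts.values()) == sum(bundle.genome.chrom_lengths().values())


# ------------------------------------------------------------- summaries

def test_uniform_depth_summary():
    g = make_genome()
    cmap = cov.classify_genome([Bait("chr1", 1000, 1120, "exon")], g)
    tr = cov.DepthTrack("s1", {"chr1": np.full(10_000, 20, dtype=np.int32)})
    df, gw = cov.coverage_summary([tr], cmap)
    assert (df[df["sample"] == "s1"]["fraction"] == 1.0).all()
    assert gw == {"bp_ge10x_all_samples": 10_000, "bp_ge10x_any_sample": 10_000}


def test_step_track_half_covered():
    g = make_genome()
    cmap = cov.classify_genome([Bait("chr1", 1000, 1120, "exon")], g)
    d = np.zeros(10_000, dtype=np.int32)
    d[1000:1060] = 15                       # half the bait bases
    tr = cov.DepthTrack("s1", {"chr1": d})
    df, _ = cov.coverage_summary([tr], cmap, thresholds=[10])
    bait_frac = df[(df["sample"] == "s1") & (df["region_class"] == "bait")]
    assert bait_frac["fraction"].item() == 0.5


def test_all_samples_threshold_strict():
    g = make_genome()
    cmap = cov.classify_genome([Bait("chr1", 1000, 1120, "exon")], g)
    t1 = cov.DepthTrack("a", {"chr1": np.full(10_000, 5, dtype=np.int32)})
    t2 = cov.DepthTrack("b", {"chr1": np.full(10_000, 15, dtype=np.int32)})
    _, gw = cov.coverage_summary([t1, t2], cmap)
    assert gw["bp_ge10x_all_samples"] == 0
    assert gw["bp_ge10x_any_sample"] == 10_000


def test_fractions_non_increasing_in_threshold(bundle):
    cmap = cov.classify_genome(bundle.baitset, bundle.genome)
    df, _ = cov.coverage_summary(bundle.tracks, cmap, thresholds=[1, 10, 20])
    mean = df[df["sample"] == "MEAN"].pivot(index="region_class",
                                            columns="threshold", values="fraction")
    for cls in mean.index:
        vals = mean.loc[cls, [1, 10, 20]].tolist()
        assert vals == sorted(vals, reverse=True)


def test_invalid_threshold_rejected():
    g = make_genome()
    cmap = cov.classify_genome([], g)
    with pytest.raises(ValueError):
        cov.coverage_summary([], cmap, thresholds=[0])


# -------------------------------------------------------- isolated baits

def test_three_well_separated_baits_are_singles():
    baits = [Bait("chr1", s, s + 120, "exon") for s in (0, 2120, 4240)]
    singles, doubles = cov.select_isolated_baits(baits)
    assert len(singles) == 3 and not doubles


def test_end_to_end_pair_is_double():
    baits = [Bait("chr1", 5000, 5120, "exon"), Bait("chr1", 5120, 5240, "exon")]
    singles, doubles = cov.select_isolated_baits(baits)
    assert not singles and len(doubles) == 1


def test_isolated_selection_matches_quadratic_oracle():
    rng = np.random.default_rng(3)
    starts = np.sort(rng.choice(np.arange(0, 60_000, 40), size=20, replace=False))
    baits = [Bait("chr1", int(s), int(s) + 120, "exon") for s in starts]
    singles, doubles = cov.select_isolated_baits(baits, isolation=1000)

    def gap(a, b):
        return b.start - a.end if b.start >= a.end else b.start - a.end

    oracle_singles = []
    for b in baits:
        others = [o for o in baits if o is not b]
        if all(o.end + 1000 <= b.start or o.start >= b.end + 1000 for o in others):
            oracle_singles.append(b)
    oracle_doubles = []
    for i, a in enumerate(baits):
        for b in baits[i + 1:]:
            if b.start - a.end <= 0 and b.start >= a.start:
                rest = [o for o in baits if o is not a and o is not b]
                if all(o.end + 1000 <= a.start or o.start >= b.end + 1000
                       for o in rest):
                    oracle_doubles.append((a, b))
    assert {id(b) for b in singles} == {id(b) for b in oracle_singles}
    assert len(doubles) == len(oracle_doubles)


# ------------------------------------------------------------ wing decay

def test_constructed_track_width_80():
    d = np.zeros(10_000, dtype=np.int32)
    bait = Bait("chr1", 5000, 5120, "exon")
    d[5000:5120] = 30
    d[5120:5200] = 12                       # 80bp right wing at >= 10X
    d[5200:5400] = 5
    d[4920:5000] = 12                       # 80bp left wing
    d[4700:4920] = 5
    tr = cov.DepthTrack("s1", {"chr1": d})
    left, right = cov.wing_decay([tr], [bait], max_distance=500)
    assert left.width_at_threshold(10) == 80
    assert right.width_at_threshold(10) == 80
    span = cov.covered_span(120, left, right, 10)
    assert span["total_bp"] == 120 + 160


@pytest.fixture(scope="module")
def sparse_sim():
    """Two clones captured over well-isolated baits (1.2kb gaps) with a
    strong GC penalty; supports wing and GC-regression checks."""
    genome = cp.generate_genome(n_chrom=1, chrom_lengths=[500_000], n_genes=8,
                                n_controls=2, seed=61)
    truth = cp.simulate_population(genome, n_clones=2, indel_rate=0.0, seed=62)
    baits = [Bait("chr1", s, s + 120, "exon") for s in range(1000, 495_000, 1320)]
    model = cp.CaptureModel(mean_on_target_depth=15, off_target_fraction=0.0,
                            gc_penalty=60.0)
    _, _, sam, _ = cp.simulate_capture_reads(genome, truth.samples, baits,
                                             model, seed=63)
    samples = [s.clone_id for s in truth.samples]
    by_sample = {s: [] for s in samples}
    for r in sam:
        by_sample[r.get_tag("RG")].append(r)
    tracks = [cov.compute_depth(by_sample[s], genome, sample_id=s) for s in samples]
    return genome, baits, tracks


def test_wing_symmetry_on_simulation(sparse_sim):
    genome, baits, tracks = sparse_sim
    singles, _ = cov.select_isolated_baits(baits, isolation=1000)
    assert len(singles) == len(baits)
    left, right = cov.wing_decay(tracks, singles, max_distance=400)
    near_l = left.mean_depth[:100].mean()
    near_r = right.mean_depth[:100].mean()
    assert near_l > 0 and near_r > 0
    assert abs(near_l - near_r) / max(near_l, near_r) < 0.25


def test_empty_units_warns_and_returns_empty():
    left, right = cov.wing_decay([], [], max_distance=100)
    assert len(left.mean_depth) == 0 and len(right.mean_depth) == 0


# --------------------------------------------------------- GC regression

def test_gc_regression_exact_linear_case():
    """depth = 50 - 100*|GC-mean| exactly -> R^2 = 1, slope = -100."""
    rng = np.random.default_rng(5)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 100_000))
    g = cp.SyntheticGenome([("chr1", seq)], [], [])
    baits = [Bait("chr1", s, s + 120, "exon") for s in range(0, 99_000, 1000)]
    gc = np.array([cov.gc_content(seq[b.start:b.end]) for b in baits])
    x = np.abs(gc - gc.mean())
    depth_vals = 50 - 100 * x
    d = np.zeros(100_000)
    for b, v in zip(baits, depth_vals):
        d[b.start:b.end] = v
    tr = cov.DepthTrack("s1", {"chr1": d})
    res = cov.gc_vs_depth(g, baits, [tr])
    assert res.r_squared == pytest.approx(1.0, abs=1e-9)
    assert res.slope == pytest.approx(-100.0, abs=1e-6)


def test_gc_regression_null_case():
    rng = np.random.default_rng(6)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 600_000))
    g = cp.SyntheticGenome([("chr1", seq)], [], [])
    baits = [Bait("chr1", s, s + 120, "exon") for s in range(0, 599_000, 1200)]
    assert len(baits) >= 500
    d = rng.normal(30, 3, 600_000)          # depth independent of GC
    tr = cov.DepthTrack("s1", {"chr1": d})
    res = cov.gc_vs_depth(g, baits, [tr])
    assert res.r_squared < 0.02


def test_gc_penalty_detected_in_simulation(sparse_sim):
    """With the quadratic GC penalty on, depth declines significantly with
    |GC - mean GC| across many isolated baits."""
    genome, baits, tracks = sparse_sim
    res = cov.gc_vs_depth(genome, baits, tracks, min_separation=120)
    assert res.n >= 300
    assert res.slope < 0
    assert res.p_value < 0.01


def test_excluded_sample_changes_depths(sparse_sim):
    genome, baits, tracks = sparse_sim
    all_res = cov.gc_vs_depth(genome, baits, tracks)
    sub_res = cov.gc_vs_depth(genome, baits, tracks,
                              excluded_samples=[tracks[0].sample_id])
    assert all_res.n == sub_res.n
    assert not np.allclose(all_res.mean_depth, sub_res.mean_depth)


# ------------------------------------------------------ duplicate genes

def test_duplicate_compare_hand_fixture():
    d = np.zeros(1000)
    d[100:220] = 20                          # gene A bait
    d[500:620] = 30                          # gene B bait
    tr = cov.DepthTrack("s1", {"chr1": d})
    gene_baits = {"A": [Bait("chr1", 100, 220, "exon", "A")],
                  "B": [Bait("chr1", 500, 620, "exon", "B")]}
    out = cov.duplicate_compare([tr], gene_baits, {"A": True, "B": False})
    assert out["duplicated"]["mean"] == 20.0
    assert out["single_copy"]["mean"] == 30.0
    assert out["ratio"]["mean"] == pytest.approx(2 / 3)


def test_duplicate_compare_all_zero_depth():
    tr = cov.DepthTrack("s1", {"chr1": np.zeros(1000)})
    gene_baits = {"A": [Bait("chr1", 100, 220, "exon", "A")],
                  "B": [Bait("chr1", 500, 620, "exon", "B")]}
    out = cov.duplicate_compare([tr], gene_baits, {"A": True, "B": False})
    assert out["duplicated"]["mean"] == 0.0 and out["single_copy"]["mean"] == 0.0


def test_duplicate_compare_similar_classes_on_simulation(bundle):
    gene_baits = {}
    for b in bundle.baitset:
        if b.gene_id:
            gene_baits.setdefault(b.gene_id, []).append(b)
    flags = {g.gene_id: g.duplicate_partner is not None
             for g in bundle.genome.gene_models}
    out = cov.duplicate_compare(bundle.tracks, gene_baits, flags)
    # identical capture model for both classes: means within 25%
    assert 0.75 < out["ratio"]["mean"] < 1.33
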