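# Methods

This note documents the models behind `capturepop`, the parameters that
matter, the design choices made where the design was genuinely open, and
what the synthetic data do and do not establish about real experiments.

## Bait tiling

All intervals are internally 0-based half-open; GFF3 I/O converts from
1-based closed coordinates. Baits are always 120bp.

**End-to-end tiling** (the classical design). Target regions shorter than
150bp receive a single bait centered on the region; the bait extends
symmetrically into the flanks when the region is shorter than 120bp, with
ties broken toward the lower coordinate. Regions of 150bp or more are tiled
at offsets 0, 120, 240, …, with the final bait shifted flush to the region
end — overlapping its predecessor rather than overhanging the target —
so every tiled base stays on target.

**Optimized tiling** exploits the wings: fragments longer than baits return
usable coverage ~80bp beyond each bait edge, so full tiling wastes probes.
Regions up to 300bp receive one centered bait (flanks are recovered by the
wings). Longer regions receive `k = ceil((L + 150) / 270)` baits — the
smallest count for which evenly spaced 120bp baits leave every inter-bait
gap ≤150bp (verified against brute-force search in the tests) — placed
with first and last baits flush to the region ends and interior gaps equal
to within 1bp. Targets separated by gaps strictly less than 150bp are
pre-merged and treated as one region, since the intervening sequence is
recovered anyway.

**Budget allocation.** Promoter and intergenic baits are included first and
count against the budget. All baits of priority genes are then protected.
Remaining capacity is filled round-robin: pass *p* takes the *p*-th
remaining bait of every non-priority gene in genome order (chromosome,
then start — the allocation order was an open choice; genome order is
deterministic and reproducible), truncating mid-pass exactly at the
budget. This makes the selection monotone: growing the budget never
removes a previously selected bait.

## Synthetic genome and population

The generator emulates a small plant-like genome: uniform-random base
composition (mean GC 0.5), genes of 1–5 exons (80–400bp) separated by
80–300bp introns, terminal 40bp UTR annotations on single-span genes, a
250bp promoter immediately upstream of the TSS (strand-aware, truncated at
chromosome edges), and intergenic control regions of 250–300bp placed at
least 600bp from any gene. A configurable fraction of genes form
retained-duplicate pairs — the second copy has identical exon structure and
a span sequence diverged at 5% per site by default, emulating paralogs
retained from an ancient whole-genome duplication.

Population variation is simulated without a coalescent engine: for each
region class (genic = gene spans + promoters; intergenic = the remainder)
the number of segregating sites is Poisson with mean θ·a₁·L, derived-allele
counts follow the neutral spectrum P(i) ∝ 1/i over 1..n−1, and carriers are
drawn uniformly without replacement from the 2n haplotypes. Under this
scheme E[S/(a₁L)] = θ and E[π] = θ exactly, so Watterson's and Tajima's
estimators are unbiased and mean Tajima's D ≈ 0 — which is what the
estimator tests exploit. What the scheme does *not* generate: genealogical
correlation between sites (linkage disequilibrium), recombination
structure, or demography-driven skews of the frequency spectrum. Passing
recovery tests therefore validate the estimators and the pipeline plumbing,
not robustness to realistic haplotype structure. Default diversity levels
are θ_genic = 0.0035 and θ_intergenic = 0.0071 per site — typical reported
magnitudes for genic vs intergenic variation in outcrossing trees — and
short (1–3bp) indel polymorphisms are generated by the same machinery at a
low rate (default 2×10⁻⁴ per site) with a 4bp guard band around each.

## Capture model

A fragment's length is truncated-normal (default median 180bp, SD 40,
bounds 60–400). Shearing protocols are usually characterised only by a
median (~150–200bp here), so the distribution family and its parameters
are exposed rather than fixed. An on-target fragment's midpoint
is uniform over the bait extended by half a fragment length on each side;
the overhang of fragments beyond bait edges is what produces wing coverage,
decaying roughly linearly to zero at one fragment length from the edge.
Capture efficiency is thinned by a quadratic GC penalty,
`eff = clip(1 − c·(GC − GC_mean)², 0.05, 1)` with c = 40 by default,
centred on the genome mean — a minimal model reproducing the depth
reduction at both GC extremes. A configurable fraction of fragments
(default 3%) is background drawn uniformly from the genome.

Per-bait fragment counts are calibrated so the expected *read* depth at
bait centres equals `mean_on_target_depth`: the Poisson mean per bait is
`depth / (E[2·min(fl, read_len)/(120 + fl)] · E[eff])`, both expectations
estimated by Monte Carlo at run time. Mates are counted independently
(overlapping mates double-count), matching the per-record depth semantics
used downstream.

Reads (default 2×100bp) are cut from the two fragment ends; mate 2 is
emitted reverse-complemented in FASTQ. Qualities are normal (mean Q35,
SD 3) clipped to [13, 41]; substitution errors occur at 10^(−Q/10) per base
unless an explicit `error_rate` overrides (0 = error-free). Indels in reads
arise only from haplotype indel polymorphisms, carried through CIGARs;
insertions cut by a read boundary become soft clips. The truth SAM is
emitted directly — no aligner — with each read's true position, mate
information, RG sample tag, fragment origin (XO) and haplotype (XH). Reads
whose fragment lies inside a duplicated gene with a sequence-identical
paralog region are flagged non-unique (XU:i:0, MAPQ 0); at the default 5%
divergence this is rare (a ~180bp identical stretch), so exercising the
uniqueness filter requires lowering the divergence.

## Read QC

A read passes when mean Q ≥30, min Q ≥13 and it has no Ns. "Near either
end" for N-trimming needs a concrete width: it is defined as the terminal
10bp, which bounds the information lost to trimming; Ns elsewhere fail the
read. Trimmed reads are re-tested against the same thresholds and must
retain ≥50bp (shorter reads map poorly). Demultiplexing assigns a read iff
exactly one barcode is within 1 mismatch; orphans whose mate failed QC are
discarded rather than kept single-end.

## Coverage analytics

Depth counts uniquely mapped records per base (deleted reference bases
excluded). For simulated data uniqueness comes from the truth tag; for real
alignments the default proxy is MAPQ ≥1 and not secondary/supplementary,
configurable. The genome is partitioned exactly into bait / adjacent
(within 250bp of a bait) / off-target, bait labels winning where flanks
overlap baits. Isolated single baits have no neighbour within 1000bp;
double baits are pairs at gap 0 (configurable epsilon) with no third bait
within 1000bp of the pair. Wing width at threshold t is contiguous from the
bait edge: the last distance before mean depth first drops below t — no
monotone smoothing is applied. The GC regression is ordinary least squares
of per-bait mean depth (across non-excluded samples) on |GC − mean GC| over
single baits ≥120bp from any other bait.

## Genotype calling and SNP filters

The caller is a deliberately minimal, fully testable diploid likelihood
model (documented in `capturepop.variants`); agreement with any particular
production caller is not claimed. Per-base error εᵢ = 10^(−Qᵢ/10);
genotype likelihoods are products of per-base terms (hom-ref: 1−εᵢ for ref
else εᵢ/3; het: (1−εᵢ)/2 + εᵢ/6 for ref/alt else εᵢ/3; hom-alt symmetric);
priors (1−1.5p, p, p/2) with p = 0.001; the call is the MAP genotype and
the variant quality is −10·log₁₀ P(hom-ref | data), capped at 255. The
"quality ≥30" per-clone filter is applied to this site-level variant
quality (the alternative reading — genotype quality — is noted; variant
quality matches the 1-in-1000 error interpretation). Multiallelic columns
keep the best-supported alternate only. Candidate SNPs must be ≥10X in
every clone with no indel evidence in any clone. Feature classification
uses one label per site with exon > 5′-UTR > 3′-UTR > intron > promoter >
intergenic precedence, where UTR bases (annotated within terminal exons)
are reported as UTR, matching annotations that list UTRs separately.
Bait-position classes use distance to the nearest bait: 0 = within-bait,
≤500bp = adjacent (inclusive), else off-target; the 250bp coverage flank
and the 500bp SNP-adjacency radius are deliberately separate parameters.

## Region assembly and diversity

The callable mask is the set of bases ≥10X in all clones. Genic regions
seed on gene spans and extend through contiguous callable runs up to 500bp
beyond the span (the cap prevents runaway merges through well-covered
intergenic stretches and is configurable); regions whose extensions meet
merge into one, inheriting all gene ids and "duplicated" status if any
member is duplicated. Intergenic regions seed on the control intervals;
their flank extension stops at genic-region boundaries, and a control whose
core overlaps a genic region is an error. L counts callable bases only —
uncallable bases interior to a gene are excluded.

θ_w, π and D are computed per region from alternate-allele dosages summed
over clones (hom-ref = 0, het = 1, hom-alt = 2); per-site statistics need
no phasing. Regions with S = 0 contribute zeros to θ/π means but are
excluded from D averages (D is undefined there; the count of contributing
regions is reported). Summaries report unweighted means and population SD
(divisor N, configurable) per class — the L-weighted alternative is noted
as an option. n = 2 × clones throughout.

## Problem sizes and numerical choices

The test suite and the acceptance script use deliberately small synthetic
experiments — genomes of 40kb–1Mb, 2–6 clones, 15–40X target depth, a few
hundred baits — chosen so every stage's expected behaviour is measurable
with tight Monte-Carlo error while the whole suite stays fast. Estimator
identities (π vs pairwise counting, Tajima's D vs an independent
re-derivation) are exact to 1e−12/1e−9; stochastic recovery checks use 5–10%
tolerances consistent with their sampling variance at these sizes.
Tie-breaks: bait centering rounds toward the lower coordinate; round-robin
order is genome order; MAP genotype ties resolve to the earlier genotype in
(hom-ref, het, hom-alt) order. Degenerate inputs (empty bait sets, empty
regions, S = 0, zero-variance GC predictors, all-N pileup columns) raise
explicit errors or return defined empty results as documented per function.

## Known limitations

No linkage disequilibrium or recombination in the population model; no PCR
duplicates, optical artifacts or adapter read-through in the read model;
no mappability or repeat modelling (the truth SAM sidesteps alignment
entirely, so alignment-driven artifacts — mismapping between close
paralogs in particular — are represented only through the non-uniqueness
flag); indels are detected solely as exclusion evidence, not genotyped;
no outgroup, hence only folded-spectrum statistics.
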