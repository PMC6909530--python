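# Methods

## Problem and model

`delcall` detects long deletions (> 50 bp) in a donor genome from paired-end
reads mapped to a reference. Presence of a deletion is treated as an image
classification problem: the reference is partitioned into consecutive,
non-overlapping 50 bp windows, each window's pileup is rendered as a
256×256 RGB image, and a convolutional network scores the window as deletion
(1) or wild-type (0). Window-level decisions are then consolidated and
sharpened by an unsupervised curation stage (clustering + pointer-based
breakpoint refinement) that operates directly on per-position signature
tracks. The pipeline is

    reads → signature tracks → window images → CNN scores
          → candidate intervals → clustering screen → refined breakpoints → VCF

### Signatures

For a region, three per-position tracks are computed:

- **depth** — aligned bases of primary, non-duplicate records;
- **split count** — records that are supplementary or clipped ≥ 10 bases
  (`min_clip`, configurable). By default support is assigned at the clip
  coordinate itself (`split_mode="clip"`), concentrating the evidence exactly
  on the breakpoints; spreading it over the whole aligned span
  (`split_mode="span"`) is available but smears breakpoint evidence into the
  flanks and, because the feature value m (below) then dips *below* the
  deletion-interior level just outside each breakpoint, it systematically
  degrades pointer refinement — this was measured, not assumed, during
  development;
- **discordant count** — pairs with |observed insert − μ| ≥ 3σ, spread over
  the pair's outer span and counted once per pair, so the interior of an
  encompassed deletion receives support even where no read aligns.

Library insert statistics (μ, σ) are estimated robustly as the median and
1.4826·MAD of observed proper-pair inserts, which is insensitive to the
inflated inserts of encompassing pairs.

## Pileup-image encoding

Bases map to dominant colours A→(255,0,0), T→(0,255,0), C→(0,0,255),
G→(0,0,0); non-ACGT symbols render as background white. A column covered by
n_d discordant pairs and n_s split reads carries a column-wide auxiliary
level clamp(n_d + n_s, 0, 235); each base then adds its per-base auxiliary
value n_d + (is_paired + is_discordant + mapq>20 + is_split). The two
auxiliary channels carry different payloads: the first the per-base sum
above, the second the four bits read as a 4-bit binary number. The second
channel makes the map (base, bits) → colour injective across all 64
combinations — with a single summed payload, distinct bit patterns with equal
sums would collide — while the first preserves the natural "more signature,
stronger tint" monotonicity. Both channels clamp at 235 so every colour stays
inside the per-base range (A: (255,0,0)…(255,235,235), analogously for
T/C/G; for G the auxiliary values fill all three channels). The full
64-row table is shipped at `docs/encoding_table.tsv` and regenerated by
`delcall encoding-table`.

Windows render 50 columns × 5 px wide with 3 px margins on a white canvas;
bases stack bottom-up in deterministic (mapped start, read name) order, one
pixel row per base, truncated at `depth_scale` = 200 rows. Bar height is
therefore read depth, the classifier's primary cue. Three renderers exist —
a column-object reference implementation, a single-window vectorized path,
and a batched scan path with globally computed column counts — and the test
suite asserts they are byte-identical. The batched path's column counts are
also the more faithful ones: a pair whose outer span covers a column
contributes its tint even when neither read touches the window.

Windows are labeled 1 when ≥ 50% of the window lies inside a known deletion
(heterozygous and homozygous alike — labels mark regions, not genotypes).

## Curation

**Depth filter.** The depth track is smoothed with a 61 bp sliding window
into f = γ·D̄/(σ_w + ε), assigned to the window centre (shrunken windows at
track edges). D̄ tracks the depth level, σ_w penalizes fluctuation, γ scales
the score. Defaults γ = 4, ε = 1: at 20–50× coverage this places wild-type f
(≈ γ·√depth) on the same order as the split/discordant counts, so no single
component dominates the clustering distance. ε keeps f finite where window
depth is constant.

**Clustering.** Each position becomes C = (f, −split, −discordant); counts
are negated so all components fall inside a deletion. Lloyd k-means with
k = 3 runs under the weighted even-power distance
√(Σ_k η_k|C_ik − C_jk|^p), defaults η = (2, 1, 1), p = 2 — the depth weight
above 1 because depth is the sharpest boundary signal. Farthest-point
initialization with 10 seeded restarts, ties broken toward the lowest
cluster index, best restart by within-cluster cost; clusters are relabeled
upstream/middle/downstream by median position. For p = 2 the metric equals
Euclidean distance on √η-scaled coordinates, which the test suite exploits
to cross-check the implementation against scikit-learn's k-means.

**Screening.** The cluster with the minimum mean feature value
m = depth − split − discordant is the putative deletion. A candidate is
kept only if that cluster forms a *largely contiguous block between the
other clusters*: within the block's central span (10–90% position
quantiles, trimming ragged edges caused by cluster-boundary jitter at the
breakpoints) at least τ = 0.6 of positions must belong to the cluster, and
both other clusters must have positions on both sides of the block. Noise
clusters from wild-type regions are spatially scattered (occupancy near the
region density, ~1/3) and fail the test. Candidates whose region shows
neither split nor discordant support (max count < 3) are rejected outright:
every real deletion ≥ 50 bp is bracketed by encompassing pairs and junction
reads by construction, so a bare depth dip is an artifact.

**Breakpoint refinement.** β₁/β₂ are the extreme positions of the
minimum-mean cluster and m̄₂ its mean feature value. Each pointer moves
independently, one base at a time: where m < m̄₂ the pointer is inside
deletion-like signal and extends outward until the next position clears m̄₂;
where m ≥ m̄₂ it has overshot into the flank and retracts inward until m
drops below m̄₂ *for 5 consecutive positions* (`RETRACT_RUN`) — the sustained
run requirement suppresses single-position noise dips, whose effect on
refinement error was the largest noise term observed in development. With
clip-point split assignment, m is constant (−number of encompassing pairs)
across a homozygous deletion interior and steps up sharply at the first
non-deleted position, so the walk lands within a base or two of the truth.

## CNN

Implemented directly on numpy (im2col convolutions, max pooling, dense
layers, softmax cross-entropy, Adam at lr 10⁻³), with all randomness —
initialization, shuffling, validation split — behind one seed; building,
training and inference are bit-reproducible, and inference on uint8 images
uses a fused integer-pooling fast path verified to match the float path.
Presets:

- `default`: 3 conv+pool blocks (32/64/128 filters, 3×3 kernels, 2×2
  max-pool), 256-unit dense layer, 2-way softmax, on the raw 256×256×3 input.
- `small`: the same topology behind a fixed 4×4 average-pool front end, with
  8/16/32 filters and a 64-unit dense layer. This is the desk-scale preset
  used by all built-in benchmarks: it trains in about a minute on one CPU at
  the benchmark sizes while keeping depth resolution (a 24× bar is 6 pixel
  rows after pooling, a 12× heterozygous bar 3).

Default batch size 128. Training sets are assembled from labeled scenes with
the wild-type class downsampled to ≤ 2× the deletion class, since genome
windows are overwhelmingly label-0.

## Caller

Every 50 bp window is scored; windows with probability ≥ 0.5 are merged into
candidates, tolerating up to 2 sub-threshold windows inside a run (mid-sized
heterozygous deletions at 24× occasionally show 2-window dips) and dropping
candidates < 50 bp. Each candidate is curated over its interval ± 800 bp of
flank — wider than the discordant-signal reach of one insert (~456 bp), so
the far flank anchors a clean wild-type cluster. Accepted candidates take
their refined breakpoints (falling back to the window interval, flagged
IMPRECISE, if refinement collapses); refined calls that overlap are unioned.
Output is VCF 4.2 with SVTYPE=DEL, END, SVLEN, the mean classifier
probability and window support; parsing the emitted VCF reproduces the call
list exactly.

**Evaluation** matches calls to truth one-to-one, greedily by reciprocal
overlap with a 50% threshold, and reports precision TP/(TP+FP), sensitivity
TP/(TP+FN), F = 2PS/(P+S) (undefined values reported as missing), and
per-side breakpoint distances of matched pairs. **Coverage titration**
down-samples reads by fragment (both mates kept or dropped together,
deterministic in fragment name and seed), retrains and re-evaluates at each
target coverage.

## Simulator

The simulator is the package's study-condition generator, not a test
convenience: 100 bp paired-end reads, insert length Normal(456, 60)
truncated at 2·read length (the insert profile of typical high-throughput
paired-end libraries), coverages in the 10–60× range, homozygous and
heterozygous deletions 50 bp–10 kb. A diploid donor is built by removing
homozygous deletions from both haplotypes and heterozygous ones from
alternating haplotypes; fragments are drawn per haplotype (half coverage
each) and mapped back *analytically* through the donor→reference coordinate
map. A read whose donor span crosses a deletion junction becomes a
soft-clipped primary record plus a supplementary record for the clipped
piece (≥ 15 bp), exactly as aligners expose split reads; a fragment
bracketing a deletion gets observed insert = fragment insert + deletion
length exactly. Mapping quality is fixed at 60; base-call errors are off by
default (uniform substitution rate available) since every downstream
signature is positional.

What the simulator does **not** emulate: repeats and mis-mapping, GC or
position-dependent coverage bias, indel sequencing errors, chimeric
artifacts, multi-allelic or complex SVs overlapping the deletion. Passing
benchmarks therefore demonstrate correctness of the method's machinery and
its behaviour under idealized signal/noise, not performance on real
sequencing data, where mapping noise is the dominant error source.

## Benchmark scales and observed behaviour

All benchmarks are seeded and run on one CPU; sizes were chosen so the whole
suite completes comfortably in a test session while keeping enough truth
events for the stated tolerances to be meaningful:

- breakpoint recovery: 50 replicates, one homozygous deletion of 200–2000 bp
  in a ~16 kb region at 30×; ≥ 90% of replicates within 10 bp (observed:
  50/50 at development seeds);
- candidate screening at 24×: 30 true candidates (alternating zygosity,
  300–2000 bp) and 30 wild-type decoys; ≥ 90% retention and ≥ 90% rejection;
- end-to-end: train on a 1 Mb chromosome with 20 known deletions
  (100–3000 bp, mixed zygosity, 24×), call a 2 Mb chromosome with 20
  deletions; precision and sensitivity ≥ 0.85 at 50% reciprocal overlap;
- coverage titration: 48× source scenes down-sampled to 12/24/36/48×,
  retraining per coverage; sensitivity non-decreasing within 0.05 (the test
  scene carries 20 truth deletions so a single miss equals the noise band).

## Known limitations

- Heterozygous deletions at ≤ 24× are the weak regime: the depth contrast is
  half, so cluster boundaries jitter and a small fraction of true
  heterozygous candidates (≈ 5–10% in development runs) are screened out or
  refined tens of bases off. Homozygous refinement is near-exact.
- Deletions shorter than ~150 bp span at most 2–3 windows and depend on a
  single window's classification; the 50 bp window grid bounds resolution.
- The curation stage assumes one deletion per candidate region; two true
  deletions closer than the curation flank (800 bp) may merge.
- Genotype is not emitted; calls mark presence only.
- The `default` CNN preset on raw 256×256 input is provided for completeness
  and contract-tested, but training it at desk scale is impractical; all
  benchmarks use `small`.
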