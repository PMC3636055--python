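# Methods

This note documents the models, parameter choices, and numerical
conventions behind `hemaepi`, and what its synthetic-data tests do and do
not demonstrate about real data.

## Coordinates and read handling

All coordinates are 0-based half-open `[start, end)` (BED-native); the
TSS of a minus-strand gene is `end − 1`. Reads are deduplicated to one
per (chromosome, 5′ position, strand) before any counting. A read's
"position" everywhere downstream is its strand-aware shifted position —
`start + s` on the plus strand, `end − 1 − s` on the minus strand — with
`s` equal to half the fragment size (75 bp for 150 bp fragments), so
that, for fragments sampled symmetrically around a binding event, plus
and minus reads re-center onto the event. Shifted positions falling off
a chromosome clamp to the boundary with a logged warning. Y-chromosome
records are dropped at load by default (mixed-donor designs include
female subjects). Touching intervals merge during union operations:
islands are built from gap-free window tilings, so adjacency means
continuity.

## Island calling

The caller follows the windowed broad-domain scheme. For one library of
`N` deduplicated reads on a genome of length `G` with uniquely mappable
fraction `f` (0.68 for a human assembly at 25 bp reads; 1.0 for the
synthetic genome, which has no mappability structure):

- background rate per window: `λ = N·w / (f·G)` for window size `w`;
- eligibility threshold: the smallest integer `k ≥ 1` with
  `P(X ≥ k | Poisson(λ)) < p_e`, with `p_e = 0.20` (the caller's
  published default; only the island-level FDR is a headline parameter);
- islands: maximal runs of eligible windows separated by at most `g`
  ineligible windows, scored `Σ −ln P(X ≥ k_i | λ)` over eligible
  windows. For extreme counts where the Poisson tail underflows, the
  score term falls back to the Stirling bound `k ln(k/λ) − k + λ`.

Default per-mark settings use `w = 200` throughout, with gaps of 1
window for H3K4me1/H3K4me3, 2 for H2A.Z, 3 for BRG1, and 3 (600 bp) for
the broad marks H3K27me1/H3K27me3 — the classic broad-domain setting at
this window size. Window sizes and gaps are per-mark configuration, so
other published parameterizations are expressible directly. PolII
"peaks" come from the same caller at `w = 200, g = 0` with the matched
control; imported peak BED files are equally accepted by the gene-binding
rule (a gene is PolII-bound when a peak overlaps TSS−5 kb to TES+3 kb,
strand-relative).

**Significance.** With a matched input control, each island's ChIP count
is tested against a Poisson expectation
`max(max(c_ctrl, 1) · N_chip/N_ctrl, λ · L/w)` where `c_ctrl` is the
control count over the island span and `L` the island length; the second
term is a genome-background floor. Without it, islands whose local
control count is 0–1 by sampling noise are tested against an
unrealistically small expectation and short background runs leak through
even at FDR 10⁻⁵; the floor (the local/global-lambda device familiar
from point-source peak callers) removes them without affecting true
domains, and keeps the test monotone in the ChIP count. q-values are
Benjamini–Hochberg across all candidate islands; islands with
`q ≤ 10⁻⁵` survive. Without any control library the caller falls back,
with a logged notice, to an E-value filter: `p` under the genomic
background times the candidate count, kept when ≤ 100 by default.

**Nibbling.** Window-level islands can overshoot the underlying enriched
region by up to a window per side. For each end, candidate cuts are
scanned at 10 bp steps strictly inside the outermost window; the cut
maximizing density(retained portion) − density(removed portion) is
applied when the difference is positive *and* the removed portion is
sparser than the island-wide mean (the gate that keeps uniform edges
untrimmed). Because each trim changes the island-wide mean, the two ends
are re-scanned alternately until neither moves; the fixed point makes
the operation idempotent. Nibbling runs after FDR filtering, so trimming
never changes which islands survive. Scores and read counts are
recomputed over the retained span.

## Promoter states and lineage tracking

K4/K27 presence is island overlap with `[TSS−500, TSS+501)` (both flanks
inclusive under half-open arithmetic), giving the four-state partition.
Lineages are rooted trees of parent→child edges. For a parent's bivalent
promoters, each child contributes one of {remained_bivalent, lost_K27,
lost_K4, lost_both}; promoters newly bivalent in a child are traced to
parent-state origins {had_K4_only, had_K27_only, had_neither}. The two
tables are disjoint by construction for any edge. The membership matrix
over all types orders genes by descending bivalent-type count, then
lexicographic pattern, then gene id — fully deterministic.

## Enhancers

Candidates per type: merged union of H2A.Z and H3K4me1 post-FDR islands,
minus anything overlapping a TSS ± 500 bp zone (the same window as
promoter classification; "outside a promoter" is otherwise undefined).
Cross-type identity on unified regions uses ≥ 1 bp overlap. Class
assignment is a function of the presence vector only, so CPE / CSPE /
shared-subset partition the catalog exactly. Gene association considers
genes whose strand-relative windows `[TSS−20 kb, TSS−0.5 kb]` or
`[TES, TES+20 kb]` overlap the region and picks the minimum distance
from region midpoint to the nearer of TSS/TES; exact ties break to the
lexicographically smaller gene id. Enhancer bivalency is ≥ 1 bp overlap
with any H3K27me3 island. Expression comparisons remove the global top
5% of RPKM values first and use the two-sided two-sample
Kolmogorov–Smirnov test (exact where sample sizes permit, asymptotic
otherwise).

## Expression

RPKM = `c / ((L_exon/1000)·(N/10⁶))`. A read counts toward a gene when
its shifted position falls in any exon; reads in overlapping genes count
for each. Pairwise differential expression uses the exact conditional
test for two Poisson-distributed libraries: given a gene's total count
`n = c_A + c_B`, the split is Binomial(`n`, `N_A/(N_A+N_B)`); the
two-sided p-value doubles the smaller tail (capped at 1), and BH runs
per comparison. A gene is "up in A" when additionally
`log₂((c_A+1)/N_A · N_B/(c_B+1)) ≥ 5` — the fold-change gate is read as
log₂, since a natural-log or log₁₀ gate of 5 would pass essentially
nothing. Negative-binomial dispersion modeling is deliberately out of
scope: downstream analyses consume only the called up-sets, the gate is
dominated by the fold-change arm at realistic depths, and overdispersion
cannot create 32-fold normalized ratios, so the null behavior of the
intersection (type-specific) calls is conservative. Expression grouping
sorts descending by RPKM with ties broken by gene id and splits into
near-equal groups (sizes differ by ≤ 1, larger groups first).

## Profiles

TSS profiles: shifted read positions within ± 3 kb of each TSS are
binned at 10 bp by strand-oriented offset (minus-strand offsets
inverted), summed over TSSs, smoothed by a centered 9-bin moving average
whose window truncates at the vector ends, and divided by `N/10⁷`.
A read near two anchors contributes to both. The ± 75 bp shift applies
to TSS profiles as well as region profiles for consistency; it is
configurable off. Size-normalized profiles divide each region into 50
equal bins (regions shorter than 50 bp are skipped with a notice) and
normalize counts by bin length, region count, and `N/10⁷`, so regions of
different sizes with identical relative read placement give identical
profiles.

## H3K27me3 domain dynamics

Per-type islands are united across all cell types; each united region of
length `L` splits into `n = ⌈L/2000⌉` fragments of length `⌊L/n⌋` or
`⌈L/n⌉` tiling left to right (longer fragments first) — "equal"
fragmentation does not resolve remainders, so lengths within a region
differ by at most 1 bp and sum exactly to `L`. The fragment × cell-type
matrix holds shifted-read counts per 10⁷ library reads. Clustering is
k-means (squared Euclidean, k-means++ init, 10 restarts, ≤ 300
iterations, tolerance 10⁻⁴) with a fixed seed; clusters are relabeled by
descending total read sum for display. Only determinism and
planted-class recovery are asserted — the exact variant used in any
particular published analysis is unknowable from parameters alone.

## The synthetic generator

The generator emulates the *inputs* of a multi-cell-type epigenome
comparison at desk scale, with defaults: 2 chromosomes × 5 Mb, 300 genes
on a jittered grid (≥ ~24 kb between TSSs), five cell types
(ESC → HSPC → {pRBC, T, B}), background 5×10⁻³ reads/bp per library
(≈ 50 k reads per mark and type), 25 bp reads from 150 bp fragments with
strand-symmetric placement around sampled fragment centers. Promoter
states evolve along the lineage by a root prior and per-edge transition
matrices whose defaults exercise every resolution and establishment
category. States instantiate domains: H3K4me3 1–2 kb and H3K27me3
4–8 kb centered on the TSS (the broad-domain size matching the scale at
which such domains are observed in progenitor cells), plus 60 distal
H3K27me3 domains of 4–20 kb with cross-type presence patterns. Planted
enrichment folds are per-mark — 5× for the broad K27 marks, 8–12× for
point-source promoter/enhancer marks, reflecting the stronger local
enrichment of sharp marks in real ChIP data. CpG islands are assigned
after state planting: promoters whose realized states carry H3K4me3 in
all four blood types receive a CpG island with probability 0.9, others
0.3, so the planted probabilities are recoverable from the realized
consistency classes. Enhancers (1–2 kb; CPEs in all four blood types,
CSPEs in one) carry H2A.Z and/or H3K4me1; a portion of each type's CSPEs
is planted 3–18 kb upstream of that type's planted type-specific genes so
enhancer–expression association tests have signal. Placement reserves
TSS ± 6 kb and keeps ≥ 2 kb between planted features — more than the
caller's largest gap-bridging distance — so distinct planted features
cannot fuse into one called island and each planted domain is a scorable
unit.

Expression counts are negative binomial with variance `μ + φμ²`,
`φ = 0.02` (BCV ≈ 0.14, appropriate for homogeneous sorted primary-cell
populations), per-gene means lognormal around 50, and type-specific
genes elevated 2⁶-fold in their own type only. With the log₂ ≥ 5 gate
sitting one doubling below the planted fold, recovery sensitivity is
governed by the biological coefficient of variation; at BCV ≈ 0.14 and
these depths planted genes are recovered at ≥ 95% sensitivity with
essentially no false calls, while larger dispersions would erode the
2× headroom. All randomness derives from one seed through SeedSequence
spawning (per-stream keys hashed with CRC32, not Python's salted
`hash`), so output is bit-reproducible across runs and platforms for a
fixed numpy version.

**What the generator does not model:** sequence content, mappability
structure (effective fraction 1.0), duplicate-read artifacts,
copy-number variation, promoter-proximal H2A.Z, chromatin–expression
coupling beyond the planted type-specific genes and their enhancers, and
domain-size growth along the lineage. Passing recovery tests therefore
demonstrates the correctness and operating characteristics of the
algorithms under idealized Poisson/NB sampling — not performance on real
libraries, where mappability gaps, input biases, and inter-replicate
variability dominate.

## Problem sizes in the test suite

The shipped tests run the full pipeline end to end on the default
synthetic bundle (≈ 2.3 M reads over 8 marks × 5 types; ~30 s) and score
recoveries on reduced mark panels per analysis (e.g. H3K27me3-only
simulations across 5 seeds for domain recovery, 2 000-gene expression
tables across 10 seeds for type-specific calls). These sizes give every
scored category dozens-to-hundreds of events while keeping the whole
suite to a few minutes on one CPU.

## Known limitations

- The significance model is Poisson with a scaled-control expectation;
  it does not model input overdispersion.
- Isoform-level expression and per-TSS isoform states are out of scope;
  each gene model carries one TSS.
- The DE test is exact-binomial rather than a dispersion-aware NB test;
  p-values are not comparable to NB-based tools even where the up-sets
  agree.
- E-value mode (no control) uses a simple candidate-count bound, not a
  full random-background island-score distribution.
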