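# Methods

This note records the model implemented by `drre-kit`, its parameters, the
scope of the synthetic-data generator, and the main numerical choices. It
describes what the code computes; it makes no empirical claims beyond that.

## Coordinates and primitive operations

All intervals are 0-based, half-open `[start, end)` on a named chromosome
(BED convention). GTF exon records (1-based, inclusive) are converted on
parsing by subtracting one from the start. Two intervals overlap iff they
share at least one base; book-ended intervals (`a.end == b.start`) do not
overlap but are merged by `merge_intervals`, which returns sorted, disjoint,
non-book-ended intervals per chromosome. `RegionSet` answers overlap and
covered-base queries with binary search over sorted merged intervals.

A gene's TSS is the 5′-most position over all transcripts: the minimum exon
start on the plus strand, the maximum exon end minus one on the minus strand.
*Projected exons* are the per-gene union of exons across transcripts; the
*first intron* is the gap between projected exons nearest the TSS in
transcription direction.

Signal tracks are step functions (bedGraph semantics). Positions not covered
by any step have value 0; `max_over` and `mean_over` therefore include gaps
as zeros, and `mean_over` divides by the full interval length.

## Expression

Condition means are taken over replicates of FPKM values. A gene is
differentially expressed at a timepoint when

    fold = (mean_regeneration + ε) / (mean_control + ε),   ε = 0.01

satisfies `fold ≥ θ` (up) or `1/fold ≥ θ` (down), with `θ = 1.7`. The
boundary is inclusive. Profile classes over the three control timepoints:
*variable* if `(max + ε)/(min + ε) > 2`; otherwise *high* (>30 FPKM),
*moderate* ((5, 30]), *low* ((1, 5]), or *silenced* (≤1). Coregulation is
the Pearson correlation of `log(FPKM + ε)` vectors; it is NaN when either
vector is constant.

## Gene clustering

For each chromosome, windows of 30 kb advanced by 10 kb start at 0. With `N`
genes genome-wide, `K` of them DE (one direction, one timepoint), `n` gene
TSSs in a window and `k` of them DE, the window p-value is the hypergeometric
upper tail `P(X ≥ k)`. BH correction runs over all windows containing at
least one gene. Windows with `k ≥ 3`, `p ≤ 0.05` and `q ≤ 0.05` survive;
overlapping or book-ended surviving windows merge into one cluster whose
members are the DE genes with TSS in the merged span and whose p/q are the
minima over the merged windows. *Hotspots* are 1 Mb windows containing the
starts of ≥2 clusters; contiguous flagged windows merge. Per-cluster
coregulation is the mean pairwise log-Pearson r over members in the
regeneration condition.

## Chromatin accessibility and the DRRE taxonomy

ATAC fragment lengths: nucleosome-free <100 bp; mononucleosomal 180–247 bp
inclusive; anything else *other*. Concordant peaks are replicate-1 peaks
overlapping at least one replicate-2 peak; the replicate-1 coordinates and
summit are kept and the height becomes the mean of the peak's own height and
its overlapping partners'. A damage peak is differential if (a) it overlaps
no control peak (`presence_only`) or (b)

    (h_reg + ε) / (max over overlapping control heights + ε) ≥ 1.5

(`height_fold`, boundary inclusive), where heights are per-base maxima from
signal tracks when tracks are supplied and the stored peak heights otherwise.
A differential region is *emerging* when it overlaps neither the control open
set nor the L3 open set, *increasing* otherwise.

## Annotation, usage, features, conservation

Annotation is decided by the summit with precedence CP → FI → proximal →
distal. CP is an unstranded ±100 bp window around a TSS; FI is containment
in a first projected intron; proximal is ±2 kb of a TSS; everything else is
distal and carries the nearest gene. Ties break by absolute distance, then
gene id. Distances are signed and strand-aware (negative = upstream).

An emerging element is *reused* if its region overlaps ≥1 reference
open-chromatin set from another stage or tissue; the classifier refuses
reference sets matching the assayed condition (L3 wing) and duplicate
labels. Chromatin-feature status within a 500 bp expanded window is
*marked* (peak overlap), else *higher_signal* (strictly greater mean damage
signal over the element), else *not_marked*; the element is *active* when
any of H3K4me1, H3K27ac, PolII is not `not_marked`. ΔΔCt fold enrichment is
`2^(−ΔΔCt)` with `ΔCt = mean Ct_target − mean Ct_reference` per condition
and `ΔΔCt = ΔCt_regeneration − ΔCt_control`; its SEM is delta-method
propagated: `fold · ln 2 · sqrt(Σ s²/n)` over the four Ct means (a
single-replicate mean contributes zero variance).

Conservation profiles average track values at each offset in ±flank around
summits. A species counts as conserved at an element when its alignment mask
covers ≥τ (default 0.5) of the element's bases.

## Cross species

Species up-regulation uses a 1.5-fold injured/uninjured rule with the same
pseudocount. The regeneration core is the set of fly genes up-regulated
after damage (early ∪ mid) with ≥1 up-regulated ortholog in *both*
zebrafish and mouse; it is counted in fly genes. Ortholog enrichment is a
permutation test: draw `|fly_up|` genes uniformly without replacement from
the background B times and report `p = (1 + #{draws ≥ observed}) / (B + 1)`
— conservative by construction, with the hypergeometric tail as exact
reference. The zebrafish chromatin arm reuses the fly machinery with a
500 bp CP window, injured-only peaks as emerging, and embryonic open
chromatin as the single reusage reference.

## Synthetic-data generator

`simulate_study(SimConfig)` builds a two-chromosome genome (2 Mb each, 400
genes on a jittered grid), FPKM tables with log-normal baselines and
multiplicative replicate noise (σ = 0.05), four planted 5-gene clusters,
30 emerging and 50 increasing peaks among 150 background peaks, reference
open sets containing planted reused regions, ChIP marks on a fixed subset,
conservation tracks elevated at conserved summits, species alignment masks,
ortholog tables and species expression with 12 planted core genes, and a
fragment-length sample. All randomness flows from `SimConfig.seed` through
`numpy.random.SeedSequence.spawn`, one stream per data layer, so layers are
independently reproducible.

Planted effects are placed with deliberate margins relative to the decision
thresholds (DE folds ≥2 against θ = 1.7; accessibility folds ≥2 against
θ = 1.5; background jitter bounded below 1.2×) so that threshold rules
recover the planted truth deterministically at the default noise level; the
generator is a correctness instrument, not a realism benchmark. Background
DE genes are excluded from planted-cluster neighborhoods so cluster
membership is unambiguous. `null_study` keeps the genome and marginal
signal statistics but plants no clusters, no differential peaks, and no core
genes; DE labels in the truth are random, condition-symmetric peaks carry
equal heights, and ortholog up-status is independent of fly status.

Limitations: the generator does not model read-level noise, mapping
artifacts, peak-caller variability, overdispersed counts, or correlated
replicate structure; chromatin tracks are rectangles, not realistic
coverage; the species arm's tables are noise-free. Real-data effect sizes
near the thresholds will not be recovered with the certainty the synthetic
bundles show.

## Numerical choices

- Hypergeometric tails come from `scipy.stats.hypergeom.sf`; BH correction
  from `statsmodels.stats.multitest.multipletests`.
- Pearson correlation uses `numpy.corrcoef` on log-transformed values.
- The permutation test vectorizes without-replacement draws by ranking
  uniform keys (`argpartition`), avoiding a Python loop over permutations.
- Pipeline manifests record SHA-256 digests, row counts, seed, version and
  the full parameter set (JSON, sorted keys) per output and contain no
  timestamps, so identical inputs yield byte-identical manifests.
- Interval queries use `numpy.searchsorted` over per-chromosome sorted
  arrays; all boundary comparisons are written to respect the half-open
  convention exactly.
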