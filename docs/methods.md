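# Methods

This note documents the models and numerical choices behind `cnaevo`, in
the spirit of a methods supplement: what is assumed, what the defaults
mean, and what a passing test does and does not establish.

## 1. The clonal-evolution simulator

The simulator models a passaged cell culture as a branching process in
discrete passage time. One passage applies, in order:

1. **Mutation.** Every surviving clone draws k ~ Poisson(`event_rate`);
   if k ≥ 1 it spawns a one-cell child carrying k new segmental events
   (kind from `kind_weights` over gain/loss/cn-LOH, size log-uniform on
   `event_size_dist`, position uniform by chromosome length, homolog
   chosen at random, placement rejected if it overlaps the clone's own
   events on that homolog). Independently, with probability `wgd_prob` a
   clone without a prior doubling spawns a genome-doubled child.
2. **Selection + drift.** Cell counts are resampled once from
   Multinomial(`bottleneck_size`, p) with p_i ∝ count_i · w_i. The
   survival weight w_i is the product of per-event fitness factors
   (Normal(`fitness_mean`, `fitness_sd`), floored at 0.05), times
   `wgd_fitness` on genome doubling, times `aneuploidy_tolerance` if the
   clone carries any ≥ 1 Mbp event. Folding selection and drift into one
   multinomial keeps an independent oracle re-implementation to a dozen
   lines; the test suite compares mean surviving-clone counts against
   exactly such a rewrite.

Events never revert (perfect phylogeny); the true MCF of an event in a
sample is the summed fraction of clones carrying it, which by construction
satisfies the containment and pigeonhole invariants the reconstruction
stage assumes.

**Regime presets.** The defaults are free parameters chosen to reproduce a
qualitative contrast, not measured rates. Stable checkpoint-knockout
regimes (RB1/CDKN2A-like: fitness mean 0.85, `aneuploidy_tolerance` 0.05)
essentially never yield a surviving clone with a large aberration.
The unstable regime (TP53-like: event rate 0.4/clone/passage, `wgd_prob`
0.05, `wgd_fitness` 2.0, tolerance 1.2) makes a genome-doubled sweep the
typical outcome within a ~24-passage series, after which further segmental
events accumulate — saltatory evolution through WGD. `wgd_prob`/
`wgd_fitness` were raised from an initial guess (0.02/1.6) because the
weaker setting left most simulated series without a completed sweep at the
sampled passages, contradicting the ubiquity of genome doubling the
unstable phenotype is meant to emulate.

**Bottleneck.** Default 1000 cells (300 in the heavier test scenarios).
This is far below a physical passage's cell count; it is an *effective*
population size that makes drift visible on the 20–45-passage scale, as
observed in real passaging series.

## 2. Array emulation

Probes are uniformly spaced (default 1/50 kb), 30% heterozygous, with a
random homolog carrying the B allele. Mixture-averaged per-homolog copy
numbers give expected logR = log2(total/2) (diploid-centered; a
median-centering mode subtracts the genome-wide median, which is what many
real pipelines do and what makes absolute ploidy unidentifiable without a
grid fit) and expected BAF = B-copies/total. Homozygous probes sit at BAF
0/1 regardless of copy number. Noise is independent Gaussian per probe
(defaults σ_logR = 0.15, σ_BAF = 0.03, typical of a good genotyping
array); no GC waves or spatial artifacts are modeled, so a green
round-trip test establishes correctness of the identities and estimators,
not robustness to real-array systematics.

A `complex` truth event is emulated as a +1 gain on one homolog over its
left half stacked with a −1 loss on the other homolog over its right half
— an undecipherable mosaic of the kind real data show in pericentromeric
regions.

## 3. Segmentation

Recursive interval segmentation on logR: at each step the interval whose
pooled two-sample t-statistic against the rest of the region is maximal is
accepted if |t| exceeds the Bonferroni-corrected critical value (level
α = 0.01 over all candidate intervals, ≥ `min_probes` = 10 probes inside
and outside), and recursion continues on the parts. A single best split
point was tried first and rejected: for an event interior to a region the
single-split statistic is diluted by a factor ~n_event/n_side (best t ≈
3.5 for a 5 Mbp loss at 20% clone fraction under default noise — below
any sensible critical value), which would make segmentation, not the
clone-size floor, the binding detection constraint. Scanning intervals
restores the intended power; a boundary split is the special case of an
interval touching a region edge.

Because copy-neutral LOH leaves logR flat, the same scan runs on the
folded heterozygous-BAF track |BAF − 0.5| and its breakpoints are pooled
with the logR ones. Pooled breakpoints can fall closer together than
`min_probes`; such fragments are absorbed into the neighbour with the
closer mean before merging. Adjacent segments merge only when both the
mean logR (within `merge_tol` = 0.1) and the BAF band half-split (within
0.05) agree.

**BAF bands.** Het-probe band centers are 0.5 ± m with the moment
estimator m = √max(0, E[(BAF−0.5)²] − σ̂²); σ̂ is the sample-level BAF
noise estimated from homozygous probes (σ̂² = 2 E[min(BAF, 1−BAF)²],
accounting for clipping at 0/1). The estimator is exact on noiseless
signal and unbiased under balanced mirrored bands, unlike the folded mean.

## 4. Event calling and MCF estimation

Thresholds (defaults): gain if rebased logR > 0.1, loss if < −0.1, cn-LOH
if |logR| ≤ 0.05 with band split ≥ 0.06 and ≥ 10 het probes. A gain/loss
call whose BAF-derived and logR-derived MCFs disagree by > 0.35 is flagged
`complex` (multi-copy or stacked states are not decomposed — they are
annotated and excluded from tree building). Estimated MCFs ≤ 0.10 (the
clone-size floor) are suppressed: array data cannot support clones below
~10% of cells, and the floor — not the logR/BAF cutoffs — is designed to
be the binding constraint for ≥ 1 Mbp events. Empirically the smallest
grid fraction detected in ≥ 95% of replicates is 15–20%: estimates at a
true fraction of exactly 0.10 straddle the strict > 0.10 cut, so the
reliable threshold sits one grid step above the floor.

**Ploidy and WGD.** Implied allele-specific copies per segment are scored
by length-weighted squared distance to non-negative integers. Under
diploid-centered logR the total is identified directly (2·2^logR), so the
fitted ψ is the grid value nearest the length-weighted mean total — a grid
argmin over ψ would be ill-defined there because ψ cancels from the score.
Under median centering the total is ψ·2^logR and ψ ∈ [1.5, 5] (step 0.05)
is grid-searched, preferring the smaller ψ at near-ties; a pure doubling
with no segmental events is then genuinely unidentifiable (every integer ψ
fits) and resolves to diploid — detecting it requires an odd-total
segment, which the tests exercise. `wgd_flag` = (ψ̂ ≥ 3). A flagged sample
is re-called against the tetraploid baseline: logR rebased by −log2(ψ/2)
and the single-step identities scaled to baseline copy number ref
(loss f = ref(1−2^logR), gain f = ref(2^logR−1), BAF routes scaled by
ref/2; cn-LOH is baseline-free). Without rebasing, a swept WGD reads as a
genome-wide gain/BAF contradiction and every chromosome is flagged
complex.

**Cross-sample matrix.** Events unify across samples when kinds match and
segments reciprocally overlap ≥ 0.8 (WGD by kind alone); the unified
segment is the intersection; absence is MCF 0. Because breakpoints are
found independently per sample, a neighbouring subclonal event can shift a
boundary enough to fail the 0.8 match, leaving a spurious 0 where the
alteration is in fact clonal. A targeted re-genotyping pass therefore
re-measures every zero cell on the unified segment in that sample's
probes, applying the same thresholds and floor — standard practice in
longitudinal pipelines, and the difference between an MCF RMSE of ~0.03
and gross 1.0-versus-0.0 errors.

## 5. Subclone tree reconstruction

Complete-linkage agglomeration under Chebyshev distance on MCF profiles,
cut at τ = 0.10 (the detectability scale of the data); cluster profiles
are per-sample medians. Stem clusters (MCF ≥ 1 − τ everywhere) chain under
the normal root in descending-mean order; remaining clusters attach
greedily, in descending mean MCF, to the feasible parent (containment and
post-attachment pigeonhole at tolerance τ) minimizing the summed profile
gap, ties broken by genome order; infeasible clusters are reported
unplaced, never dropped. Every constructed tree re-validates both
constraint families on construction.

The greedy rule is one declared choice among valid reconstructions, so
its correctness contract is *oracle-set membership*: an exhaustive
enumerator over parent assignments (≤ 7 clusters) returns every
constraint-satisfying tree, and the greedy output must always be a member.
Identity with the true tree is a different matter: when a sibling clone is
dominated by another in every sample, the constraints genuinely admit
chaining it below the winner, and no MCF-based method can tell the two
arrangements apart. Recovery tests therefore score ancestor–descendant
pairs whose orientation is shared by *every* enumerated tree of the true
profiles; ambiguous pairs are excluded from both precision and recall.
Over 100 simulated series (5 samples, ≤ 8 detectable clones, default
noise) precision and recall on identifiable pairs are 1.0 and MCF RMSE
≈ 0.03 — which establishes the pipeline loses essentially nothing the
data determine, not that it resolves what the data leave open.

**Clone proportions and replacement.** A node's own fraction is its MCF
minus its children's (clipped at 0, renormalized if clipping moved the
total; the root's own fraction is the wild-type compartment). The
dominant-clone replacement detector reports the first sampled passage
whose dominant node is on a different lineage than the previous dominant
(neither ancestor nor descendant) — succession down one lineage is not a
replacement.

## 6. Group statistics

W is the rank-sum of group 1 with midranks under ties. For combined
n ≤ 12 the null distribution is enumerated completely over all
C(n1+n2, n1) assignments of the observed midranks (exact even under
ties); two-sided p = min(1, 2·min(P(W ≤ w), P(W ≥ w))). Larger groups use
the normal approximation with tie and continuity correction; the result
records which mode ran. Holm's step-down adjusts across the requested
pairs — conservative, valid under any dependence, and appropriate for a
handful of comparisons. The per-chromosome gain/loss summary TSV stands in
for circos-style burden graphics.

## 7. Known limitations

* Overlapping alterations from different clones produce mosaic states the
  caller flags complex rather than decomposes; MCFs in such regions are
  unreliable by design.
* Subclonal genome doubling (fraction well below 1) falls between the
  diploid and tetraploid baselines; the genome-wide logR/BAF contradiction
  then yields complex flags rather than events, until the doubled clone
  sweeps.
* The detectability floor, probe density and noise defaults describe a
  good genotyping array; other platforms need re-configuration.
* The simulator's regimes are qualitative stand-ins for knockout biology;
  nothing in them is calibrated to measured per-gene event rates.
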