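# Methods

This note records the models, parameter choices, and numerical decisions
behind `estrodyn`, and what the synthetic benchmark does and does not
establish about real data.

## Study design being modeled

A paired mRNA / small-RNA sequencing time course in an estrogen-starved
ER+ cell line: estradiol added at time zero, libraries at
t ∈ {0, 1, 2, 3, 4, 5, 6, 8, 12, 24} h with three biological replicates
(30 libraries per assay).  All stages key on a sample metadata table
(`sample_id`, `time_h`, `replicate`); the time grid is not hard-coded and
any strictly increasing grid starting at 0 with ≥ 2 replicates per point
works.

## Differential expression

**Normalization.** Median-of-ratios size factors: for genes with positive
counts in all samples, factor_s = median_g(count_gs / geomean_g), then
rescaled so the factors' geometric mean is 1 (this makes factors
comparable across datasets; it shifts all log fold changes by 0).  The
estimator assumes most genes are unchanged; in simulations where 75% of
genes respond, null-gene normalized means acquire a small (~4%)
composition bias — real datasets, with a far smaller responsive fraction,
are closer to the assumption than the benchmark is.

**Dispersion.** Per-gene method of moments on normalized counts:
α = max(10⁻⁸, (v − m)/m²) with v the df-pooled within-timepoint variance
and m the grand mean.  No empirical-Bayes shrinkage is applied; with 20
within-group degrees of freedom (10 × 3 design) the median α̂ recovers a
simulated α = 0.05 within [0.02, 0.10].  The DE backend is a plain,
oracle-checkable NB Wald test by design; nothing downstream depends on its
internals, so a shrinkage-based test can be substituted behind the same
interface.

**Test.** For time t vs 0, z = (ln m_t − ln m_0) / se with
se² = (1/m₀ + α)/n₀ + (1/m_t + α)/n_t (delta method on Var = m + αm²).
z is referenced against a t distribution with the design's pooled
within-group df (20 here) rather than a normal: with three replicates the
normal reference is measurably anticonservative (null rejection ~0.07 at
the 0.05 level in simulation; the t reference gives ~0.054, inside three
binomial SDs of nominal at 2000 genes).  Reported log2 fold change is
log2((m_t + c)/(m₀ + c)) with pseudocount c = 0.5 normalized counts; genes
with all-zero counts in both groups return (lfc 0, p 1) so matrix shapes
stay stable.  BH adjustment is applied within each timepoint contrast,
not across contrasts.

**Filters.** Responsive ⇔ mean normalized count across *all* samples
≥ 500 (interpreting "across the time series" as the grand mean over the 30
libraries; configurable) AND ≥ 1 time point with p_adj < 0.05 and
|log2fc| ≥ 1.  The census counts, per responsive gene, time points meeting
that same joint condition.

## Temporal clustering

Clustered signal: the per-gene log2 fold-change trajectory vs t0 (0 at
t = 0 by construction), standardized to unit maximum absolute value so
amplitude does not dominate shape.  Trajectories are PCHIP-interpolated
onto an hourly grid (25 points over 0–24 h) — PCHIP passes exactly through
observations and cannot overshoot between knots — then decomposed to full
depth with a Daubechies-3 wavelet in periodized (orthonormal) mode, and the
concatenated coefficients are Ward/Euclidean-clustered and cut at k = 3.
Note pywt's periodization pads odd-length signals, so exact Parseval
equality holds on even dyadic lengths; reconstruction is exact at any
length.

Semantic labels come from cluster centroids on the *linear* fold scale
(time zero = 1): with b = centroid(0), f = centroid(24), m = max,
repressed ⇔ f < b(1 − δ); transient ⇔ m > max(b, f)(1 + δ); induced
otherwise (δ = 0.1).  If the heuristic fails to produce one label of each
kind, clusters are ranked: smallest f/b → repressed, largest pulse excess
→ transient, remainder → induced, so exactly one of each label is always
emitted.

GATA3-like vs mirror-image groups: genes in the repressed and transient
classes are correlated (Pearson) against a drop-then-partially-recover
template; r ≥ 0.7 → template-like, r ≤ −0.7 → opposite.  By default the
template is derived from the data (the repressed class is subclustered in
two and the falling subcentroid with the stronger late recovery is used);
a canonical analytic template is available when the repressed class is
small.  The ±0.7 threshold is a choice, not an estimate — the printed
group sizes of any particular dataset are not reproducible quantities.

## Characteristic directions

For consecutive time points, expression is taken as log2(normalized + 1)
(the direction's derivation assumes roughly Gaussian data).  The unit
vector b ∝ Σ_γ⁻¹(μ_b − μ_a) uses the within-class covariance shrunk
toward an isotropic target, Σ_γ = γΣ̂ + (1 − γ)(tr Σ̂ / d)I, computed in
the subspace spanned by the (globally centered) samples, with d the rank
of that subspace; γ defaults to 0.5.  Restricted to that subspace the
computation is algebraically identical to the dense gene-space solve with
the same shrinkage target, which is what the oracle test verifies (cosine
similarity is 1 to ~15 digits).  The sign is fixed so b·(μ_b − μ_a) ≥ 0,
giving exact antisymmetry under group swap.

Characteristic sets take genes in decreasing b² until a fraction θ = 0.5
of the squared-coefficient energy is covered (a `top_n` rule is also
provided; when a planted signal is spread uniformly over k genes the
energy rule stops near k/2 by construction, so recovery experiments on
fixed-size planted sets use `top_n`).  A `low_signal` flag marks
directions whose largest b² is below 3/n_genes; this fires only when the
energy is spread nearly uniformly (many genes moving together).  It is
*not* a null detector at this design's sample sizes: with 3 + 3 samples
the direction lives in a ≤ 5-dimensional subspace and pure-noise
directions concentrate max b² around 8/n, well above the cutoff.

## Target-site enrichment and ranking

miRNA families are keyed on mature nucleotides 2–8 (the extended seed);
family expression is the maximum (configurable: sum) of member mean RPMM,
thresholded at 50.  Site classes on the UTR (DNA, 5′→3′): 8mer =
revcomp(nt 2–8) + A; 7mer-m8 = revcomp(nt 2–8) not followed by A;
7mer-1A = revcomp(nt 2–7) + A not preceded by the m8-matching base.  An
8mer is reported once, never additionally as its constituent 7mers; 6mer
sites are excluded as a weak class.  U↔T conversion happens at the scanner
boundary.

The default score is binary (genes in the set with ≥ 1 site).  Null sets
are the first k elements of N = 1000 independent permutations of the
expressed-gene background, drawn once per interval and shared across
families — this makes the matrix deterministic given the seed,
family-order independent, and gives nested null sets (adding a gene to a
set can only add to its null scores), which yields the monotonicity
property that enlarging a set with a target gene never increases p.
p = (1 + #{null ≥ obs})/(1 + N) is bounded away from 0 so −log₁₀ p is
always finite.  Optional UTR-length-decile matching of null sets is
available (off by default).  Families are ranked by Σ −log₁₀ p over the
nine intervals, ties broken lexicographically.

Deliberate divergences from heavier master-regulator pipelines:
conservation weighting (needs multi-species alignments) and network-hub
scoring (needs interaction networks) are not implemented; the decision
structure — site presence vs a permutation null, summed over intervals —
is preserved.

Because enrichment p-values are discrete (integer scores), perfect
uniformity under the null is unattainable; at the calibration fixture's
sizes (400-gene background, 50% site prevalence, sets of 60) the largest
single-score mass keeps the KS distance from uniform around 0.08–0.15
across 200 simulations.

## Synthetic-data generator

The generator *is* the benchmark definition; its defaults are fixed, not
tuning knobs.  600 genes split evenly into transient / induced / repressed
/ null; per-gene baselines log-normal around 1000 (σ_log = 0.5) so the
mean-expression filter is genuinely exercised; NB dispersion α = 0.05
(typical bulk RNA-seq scale); per-sample depth factors log-normal
(σ = 0.15) so size-factor estimation is non-trivial.

Archetypes (t in hours, b = baseline, amplitude a = `effect_size` = 2):

- transient: b·(1 + a·exp(−(t − p)²/2w²)), peak p drawn from the measured
  points in [2, 6] h, width w ∈ [0.75, p/3] so the pulse has decayed at
  t = 0;
- induced: b·(1 + a·g(t)/g(24)), Hill g = tʰ/(tʰ + kʰ), k ∈ [2, 5],
  h ∈ [1.5, 3]; the relative change at 24 h equals a exactly;
- repressed: b·(1 − a_r(1 − e^{−t/0.5}) + a_r·r(1 − e^{−t/6})) with drop
  a_r = 1 − 1/`effect_size` (floor at half of baseline) and r = 0
  (monotone) for half the class; the other half is GATA3-like with
  a_r = 0.6, r = 1/3 (plateau at 60% of time zero).  The fast initial term
  (τ = 0.5 h) makes μ(0) = b exactly while preserving the plateau
  1 − a + a·r;
- null: constant b.

The master miRNA follows the induced form normalized to a sixfold *ratio*
at 24 h (k = 8, h = 2, giving ~2× by 4 h); other miRNAs are flat with
baselines spread over ~3 decades of RPMM.  UTRs are i.i.d. uniform ACGT,
rejection-sampled until no seed match to *any* configured family remains
except the 8mer sites planted at recorded positions in 30 target genes
drawn round-robin from the three responsive classes.  miRNA seeds are
drawn mutually distinct with no cross-family pattern collisions inside
planted sites, so "no site outside planted positions" can be verified by
exhaustive scan.

Everything derives from one seed via `numpy` `SeedSequence` spawning
(splitmix-style), with fixed spawn keys per component, so a configuration
reproduces a bit-identical dataset and the full pipeline reproduces
identical output checksums.

What the benchmark does not emulate: GC/length biases, batch effects,
isomiRs, correlated gene programs, UTR sequence composition structure,
non-canonical or conserved-site targeting.  Recovery on this benchmark
shows the *logic* of each stage is correct under its stated noise model;
it does not certify sensitivity/specificity numbers on real libraries.

## Problem sizes used in validation

Recovery experiments run at the design scale above (600 genes × 30
samples; 21 miRNA families; 1000 permutations; 50 seeded replications of
the master-recovery experiment; 200 null-calibration simulations) — sizes
at which every documented property is measurable in minutes on one CPU.

## Known limitations

- The NB test's t reference with pooled-df is a pragmatic small-sample
  correction, not an exact likelihood result; at n = 3 replicates its null
  rejection rate is ~0.054 at the 0.05 level in simulation.
- Median-of-ratios normalization biases null-gene means when a large
  fraction of the transcriptome responds (see above).
- The `low_signal` flag detects uniform-energy directions, not the absence
  of signal, at small sample counts.
- The characteristic-set size under the energy rule scales with how
  concentrated the direction is, so set sizes are not comparable across
  intervals with different signal spread.
- miRNA response calls are deliberately uncorrected across the nine
  per-timepoint screens; the union false-positive rate for a flat miRNA is
  bounded in simulation (≤ 10%) but is not a controlled error rate.
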