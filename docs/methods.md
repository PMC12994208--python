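# Methods

This note records the models, numerical choices and limitations behind
`sedtaph`. It is written for users who want to know exactly what each stage
computes and what the synthetic benchmarks do and do not demonstrate.

## Read-count confidence and filtering

Reads are assumed to have passed a phylogenetic assignment filter with known
accuracy; the per-read false-positive rate defaults to `fpr = 0.04`
(1 − 0.96). A taxon supported by `n` reads is wrongly present with
probability `P = fpr^n`, treating reads as independent. The analysis scope
keeps taxa with `P < 1e-4` (three or more reads at the default rate), a
European-native flag, and a usable taxonomic rank.

Negative-control filtering removes taxa whose proportion of a control
library's own total exceeds 2 % (strict inequality, so a taxon at exactly
2 % survives). The comparison uses the control's total, not the
experimental sample's. Whether multiple control libraries are screened
one-by-one or pooled is not a settled convention; both are available and
per-batch is the default, being the stricter reading.

## Plant guilds

Guilds are groups of taxa whose relative read frequencies co-vary across
samples:

1. **Correlation.** Pearson correlation (pmcc) between taxon frequency
   vectors (count / sample total, never raw counts, so sequencing depth
   cancels). Taxa with zero frequency variance (tolerance 1e-12 for float
   residue) have undefined correlations and are excluded, ending up in the
   unassigned bucket of every profile.
2. **Distance.** `d = 1 − (pmcc + 1)/2`, an affine bijection of [−1, 1]
   onto [0, 1]; perfect co-occurrence → 0, independence → 0.5, perfect
   avoidance → 1.
3. **Ordination.** Classical (Torgerson) metric scaling into 10 dimensions:
   double-centre the squared distances, eigendecompose, scale eigenvectors
   by √eigenvalue. Negative eigenvalues (the matrix is generally
   non-Euclidean) are truncated to zero with a warning. Each axis's sign is
   fixed by making its largest-magnitude loading positive, so output is
   deterministic; axes are ordered by decreasing eigenvalue.
4. **Hypercube clustering.** Each axis is cut into three equal sections and
   taxa sharing a cell over the first three axes form a group; each group
   is probed with one more axis at a time and splits only while the split
   is substantial (a second subgroup of at least two members and the
   largest subgroup keeping < 90 % of members — the 0.9 threshold is
   configurable). Singletons are unassigned.

   Section geometry matters. With a shared 10-axis request and low-rank
   co-occurrence structure, trailing axes carry near-zero eigenvalues: pure
   noise. Stretching each axis's own [min, max] over three sections makes
   such an axis exactly as divisive as an informative one and shatters
   tight clusters. The default therefore uses a *shared* section width — a
   third of the widest axis's range, with the three intervals centred on
   each axis's midpoint, as when every ordination axis is drawn at the same
   scale — so an axis whose spread fits inside one section never splits
   anything. Intervals are half-open, closed at the top, so boundary points
   fall in the lower section. The per-axis variant remains available
   (`section_scale="axis"`).
5. **Validation.** The pairwise association test is a one-sided permutation
   test on pmcc (labels permuted independently per taxon,
   `p = (1 + #{perm ≥ obs}) / (1 + n_perm)`, default 999 permutations).
   A guild is *simple* when every member pair has p < 0.05, otherwise
   *complex* with the most-connected member as anchor (ties lexicographic).
   Guild-level enrichment is the upper-tail binomial probability
   P(X ≥ x), X ~ Bin(m, p0), with m the number of member pairs tested
   (k(k−1)/2; interpreting the trial count as the member count k is
   selectable) and p0 the false-discovery rate (0.05 or 0.01).
6. **Profiles and ∂.** A sample's guild profile is the proportion of its
   filtered reads per guild, with an explicit unassigned remainder. The
   profile distance ∂ is the Euclidean norm over guild coordinates only.
   For proportion vectors the attainable maximum is √2 (two disjoint
   certainties), and the implementation treats √2 as the bound.

## Stratification test

The proportion behind a count c of t reads is Beta(1 + c, t − c + 1) — the
posterior under a uniform prior. For each taxon observed in either of two
adjacent samples, the overlap coefficient of the two Beta densities
(∫ min(f₁, f₂) dθ) measures compatibility; any taxon with overlap < α
(default 0.05, optional Bonferroni) makes the pair *stratified*. Pairs with
summed reads ≤ 50 are not evaluable. The overlap is computed exactly: the
log-density difference has at most one interior stationary point, hence at
most two roots (found by Brent bracketing, xtol 1e-14), and the overlap is
the sum of regularised-incomplete-beta masses of the lower density between
roots. Agreement with a 200k-point Riemann grid is ~1e-8, well inside the
1e-6 target.

The overlap coefficient is not a calibrated p-value; it is conservative, so
flagging at α = 0.05 keeps the null flag rate at or below roughly the
nominal level (measured ≈ 0.05–0.06 at depth 500 over 1,000 null pairs).

## Diffusion bound

For each taxon present in both samples of an adjacent pair separated by x
cm, λ = −ln(p₁/p₂)/x with the larger proportion as donor, so λ ≥ 0.
Per-taxon λ values mix genuine environmental change with any diffusion;
since one physical λ should govern the whole pair, the *highest* cluster of
values caps the possible diffusion rate. Clustering is 1-D k-means on
log λ, k ∈ {2..5} by best silhouette (k = 1 when values are effectively
constant); the cap is the mean of the highest cluster. Applying it as
C_diff = e^{−λx}·p₂·s₁_total and summing gives the percentage of the
receiving sample's reads explicable by diffusion — an upper bound, not an
estimate: taxa whose λ reflects true change inflate it.

## Sediment-influx depositional model

Adjacent-pair profile distances are averaged per sediment type: same-type
pairs give ∂1, type-change pairs give ∂2 (a type-change pair is credited to
both flanking types; a directional option exists). With cl the local
compositional proportion (cs = 1 − cl), ∂xloc the local change, id the
inter-sediment guild difference and e1, e2 ∈ [−1, 1] rate modifiers:

    ∂1 = ∂xloc + (∂xloc / cl) · cs · (1 + e1)
    ∂2 = ∂xloc + id · cs · (1 + e2)

The first equation reads the influx term as the per-unit local change rate
(∂xloc/cl) scaled by the sediment fraction — so ∂1 = ∂xloc at cl = 1 and
influx inflates apparent change as cl shrinks; a product reading
(∂xloc·cl·cs·(1+e1)) is available behind `eq7="product"`. The score is

    fit = (∂1ᵢ−∂1)² + (∂2ᵢ−∂2)² + (∂2ᵢ/∂1ᵢ − ∂2/∂1)²

with the ratio term dropped (and flagged) when either ∂1 is zero.

**Search.** Monte-Carlo chains start at random grid values of (e1, e2) in
[−1, 1]²; at each visited point the full inner grid over cl ∈ (0.01..1],
∂xloc, id ∈ [0..2] at step 0.01 (100×201×201 ≈ 4.04 million combinations)
is scanned exhaustively; the chain moves one of e1/e2 by ±step (reflecting
at the bounds) and stops after 20 consecutive non-improving moves; chains
repeat (1,000 by default) and per-point results are memoised so revisits
are free. The inner scan is exact but not brute-force: for fixed
(e1, e2, cl, ∂xloc) the last two fit terms are a convex quadratic in the
predicted ∂2, so the minimum over the id grid lies at a grid neighbour of
the clamped continuous minimiser. A full brute-force scan is retained for
cross-checking and the two are asserted equal in tests.

**Identifiability.** Two observations cannot pin five parameters: the
optimum is a one-dimensional ridge, and the literal argmin's position along
it is decided by discretisation rounding. The fit therefore reports both
the literal global argmin (whose fit reaches machine zero when the
observations come from on-grid parameters) and `cl_upper` — the largest cl
whose best grid fit lies within the quantisation quantum (step/2)² of the
global minimum. `cl_upper` is a deterministic upper bound on local
provenance; it, not the argmin's cl, feeds security classification and any
comparison of sediment types. Unique recovery of all five parameters is not
claimed anywhere.

**Security.** A sample is insecure when its sediment type's `cl_upper` ≤
0.5 or it is coarse sand; secure when `cl_upper` ≥ 0.85 or it is a
laminated clay/silt; otherwise unknown. Insecure evidence takes precedence
(in doubt, a sample is not treated as secure). Thresholds are configurable.

## Biodiversity

Per sample, diversity is the inverse Simpson index 1/λ_s, λ_s = Σ pᵢ² over
taxon read proportions; it equals the taxon count for uniform compositions.
Only secure samples with a numeric age and more than 50 reads enter. A
1,000-year window slides in 500-year steps; centers are multiples of the
step covering every eligible age, membership is |age − center| ≤ 500
inclusive, and each window averages 1/λ_s per domain (marine vs
terrestrial: metadata wins, otherwise the dominant guild decides, marine
only on a strict maximum).

## Clade support from shared SNPs

The alignment is a gap-concatenation of read alignments (5-base gap runs
separate blocks of the ancient row). A SNP site is a column where the
ancient row is covered and the covered taxa show two or more states;
its sharing set is the reference taxa matching the ancient state, and
exclusive sharing (a singleton sharing set) supports a clade of that taxon
with the ancient sequence. The damage filter chain masks, in order: `clip`
bases (default 5) at both ends of every read block; singleton states
(shared by no reference — candidate damage); transitions relative to the
reference plurality state (C↔T/G↔A, the deamination classes; plurality
ties are masked, conservatively); and optionally columns with any
incomplete reference. Bases are case-insensitive; N is missing; internal
coordinates are 0-based half-open, reports 1-based.

## Synthetic landscapes

The generator produces the structure the pipeline assumes, with full ground
truth: disjoint guild blocks with Dirichlet composition archetypes
(concentration 3, moderately uneven); per-core latent guild weights from a
soft-max Gaussian random walk (step s.d. 1.5 — strong swings so that the
co-occurrence signal dominates multinomial shot noise at 5,000 reads per
sample); per-sediment-class distal influx environments, each its own walk
around a class-specific archetype drifting at 0.3× the local rate (a large
source catchment integrates and varies more slowly than a local patch; a
lagged-local variant is available); observed composition
cl·local + (1−cl)·influx with cl by sediment class (defaults: clay/silt
0.95, fine sand 0.7, medium 0.55, coarse 0.4); optional diffusion mixing
each sample toward the one below with weight e^{−λx} applied to pre-mix
compositions; multinomial counts at the configured depth; linear age–depth;
one seed drives everything through per-core sub-streams, so output is
byte-identical per seed and stable under core reordering.

Defaults: 4 guild blocks over 40 taxa, 6 cores × 10 samples (silt above
coarse sand), 5,000 reads per sample. The benchmark scales used elsewhere
(22 cores for ~200 adjacent pairs; 60 Monte-Carlo chains per fit; 1,000
null pairs at depth 500) keep the full suite within a few minutes on one
CPU while leaving every conclusion unchanged at larger sizes.

What the generator does *not* emulate: taxonomic assignment error,
reference-database bias, DNA damage and fragment-length structure at the
read level, genome-size weighting of read counts, non-linear age–depth
relationships, and compositional overdispersion beyond the multinomial.
Passing benchmarks therefore demonstrate algorithmic correctness and
statistical behaviour under the stated model, not robustness to every
property of real sedaDNA.

## Numerical conventions

- Boundary points of hypercube sections go to the lower section (intervals
  closed at the top).
- The permutation p-value uses the add-one estimator, never zero.
- Beta-overlap root bracketing works on [1e-12, 1−1e-12]; identical
  parameter pairs short-circuit to exactly 1.
- Monte-Carlo chains compare fits strictly (<); equal fits do not reset the
  failure counter. Cache-key iteration is sorted, so tie-breaking is
  deterministic.
- λ estimates for taxa with a zero count in either sample are undefined and
  excluded (logged), not imputed.
- Grid indices are held as integers (e1 = i·step) to avoid float drift
  along chains.
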