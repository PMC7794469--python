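# Methods

## The model

`chromoseed` treats a chromatin region as a self-avoiding chain of
tangent spheres. Each bead covers one Hi-C bin (2 kb or 5 kb of DNA);
consecutive bead centers sit exactly one bead diameter apart, no two
non-adjacent centers may come closer than one diameter, and every center
is confined to a sphere whose volume is the cell's nuclear volume scaled
by the genomic fraction the region represents. The defaults follow a
beads-on-a-string fiber of mass density 165 bp per 11 nm, giving a 25 nm
bead at 2 kb; the bead diameter is an asserted constant rather than a
quantity derived from the density (a cylinder-equivalent sphere would
give ≈29 nm), and both are configurable. Two beads are "in contact"
(available for a Hi-C ligation) when their centers are within the
ligation threshold d_c = 80 nm. The confinement applies to bead centers;
the ≤1-radius difference versus bead surfaces is absorbed into the
proportional-volume convention.

Built-in cell presets carry the nuclear volumes and ploidy-adjusted
genome sizes used throughout: pre-MBT embryos (nuclear cycles 9–13,
335 µm³, 350 Mb diploid), post-MBT embryos (stages 5–8, 524 µm³,
350 Mb), and S2R+ cells (292 µm³, 700 Mb tetraploid). A 4 Mb region in
S2R+ is thus confined to a 736 nm-radius sphere, 2000 beads at 2 kb.

There is no energy function, no dynamics, and no chromatin-state
dependence of bead properties: the null model expresses volume
confinement and chain connectivity alone.

## Hi-C propensities

Contact matrices are optionally ICE-balanced (iterative correction until
non-masked marginals equalize; bins with zero marginal or below the 2%
coverage quantile are masked), then normalized by the mean count of
adjacent bins: p_obs(i,j) = C(i,j) / E_diag(1). Since immediately
adjacent beads are always within d_c (bond 25 nm < 80 nm), adjacent
pairs anchor the propensity scale at 1. The diagonal is never used;
propensities are computed from balanced counts by default. Propensities
are scale-invariant in the raw counts.

## Null-ensemble growth

Chains are grown bead by bead. Bead 1 is uniform in the confinement
sphere; at each later step K = 32 trial directions are drawn uniformly
on the bond sphere, trials that collide or leave the sphere are
discarded, and one survivor is chosen uniformly. The chain's importance
weight accrues the Rosenbluth factor (valid trials / K), which makes the
weighted ensemble target the uniform distribution over all realizable
confined self-avoiding chains. The population is grown in lockstep with
checkpoints every ⌈n/20⌉ beads: when the weight-based effective sample
size falls below half the population, or any chains have died (no valid
trial), systematic resampling proportional to weight replaces the
population and re-equalizes weights, preserving total weight. Dead slots
are also replaced at the final checkpoint, so the returned population
retains its requested size under conditions where unassisted growth
loses most chains. Everything is reproducible from a single master seed,
from which per-chain, per-segment seeds are derived.

Weighted contact probabilities p_null(i,j) are the weight-normalized
frequencies of conformations with beads i,j within d_c. On 12–15-bead
systems these agree entrywise within 0.02 with a naive
rejection-sampling oracle (uniform random walks, rejected on any
violation), which is the independent correctness reference for the
sampler.

A note on Monte Carlo resolution: repeated resampling duplicates
ancestry, so the number of distinct early-bead ancestors is ~20% of the
population. Seed-to-seed variation of a 50-bead contact map at 10⁴
chains is ≈0.045 entrywise (max) — comparisons between two
independently grown maps should use this scale, not the nominal 1/√N.

## Specific-interaction calling

Every testable pair (|i−j| ≥ 2, both bins unmasked, nonzero observed
propensity) receives an empirical p-value against bootstrap replicates
of the null. Replicates follow the Bag of Little Bootstraps: a subset of
b chains (default min(1300, N), ≤1% of a production ensemble of 2×10⁵)
is resampled multinomially up to the full size N, with resample counts
multiplying the chains' importance weights. By default every replicate
draws a fresh subset; splitting the M replicates over a few shared
disjoint subsets is available but degenerates at small s — the replicate
distribution then collapses onto s atoms because the conditional
multinomial noise at size N is tiny, quantizing p-values to multiples of
1/s — hence the fresh-subset default.

Replicate maps and the observed propensities are quantile-normalized
onto a pooled common reference (the mean of all sorted vectors, ranks
preserved, ties averaged) before comparison. The p-value is the share of
replicates whose normalized null probability reaches the normalized
observed propensity, with add-one smoothing so p ≥ 1/(M+1); small p
therefore marks pairs far above random collision, following the method's
textual definition (the fraction of replicates that *exceed* the
observation). Benjamini–Hochberg correction runs over the tested family,
and pairs with q below α = 0.01 and a nonzero observed count are the
specific interactions. M = 5000 replicates by default.

## Hi-C-concordant ensemble growth

Constrained chains use the same growth mechanics, with each trial
position for bead t additionally scored by a Bernoulli factor per target
pair (j, t): the calibrated target probability if the trial is within
d_c of bead j, its complement otherwise. The contact side of the factor
is capped at 1 and the miss side floored at 10⁻³, so calibration can
push geometrically hard targets (q → 1) arbitrarily strongly without
ever zeroing a chain's weight. Trials are chosen proportionally to the
product of these factors, and the Rosenbluth-style weight (sum of trial
scores / K) keeps the weighted ensemble aimed at prior × likelihood.
With an empty target map the sampler is bit-identical to the null
sampler given the same master seed.

Because per-step factors compound along the chain, raw targets over- or
under-shoot at the ensemble level. An iterative calibration
(iterative-proportional-fitting flavour) therefore repeats: grow a batch
(default 2000–2500 chains), aggregate its contact map, and multiply each
target pair's bias by clip(q/p_sim, 1/κ, κ) with κ = 3 (maximal boost
when p_sim = 0). The per-round correlation to the target is a noisy
batch estimate, so the plateau rule (stop when improvement < 10⁻³)
requires two consecutive stalled rounds, and among rounds whose
correlation ties the best within that tolerance the latest — most
calibrated — bias state is returned. Targets are min(p_obs, 1) on the
selected pairs (contact probabilities are proportions of chains and so
bounded by 1); selection modes are the called specific pairs, all
nonzero pairs, or an equal-size random sample of non-called pairs.

Map agreement is quantified by Pearson r over pairs i < j (diagonal
excluded) and by a stratum-adjusted correlation r′: one Pearson r per
genomic distance, combined with weights proportional to stratum size
times the product of the two stratum standard deviations, which removes
the shared distance-decay trend that inflates the plain r.

## Single-cell structure analytics

Per conformation the pairwise spatial-distance map is the primary
object. Boundary strength at bin i is the mean distance between the w
bins before i and the w bins from i on, divided by the mean of the two
windows' internal mean distances (w = 10 bins; curve ends padded with
1). Single-cell boundaries are local maxima ≥ 2.2, kept greedily in
decreasing strength with separation ≥ w. Note that this ratio is
confounded by genomic separation — a featureless straight rod scores
≈2.7 everywhere — so a boundary alone is not a domain call.

TAD-like domains are the intervals between adjacent boundaries (region
ends act as flanks; a conformation without internal boundaries
contributes zero domains) that pass a compaction test: all distances are
first divided by the conformation's median distance at the same genomic
separation, each interval bin is reduced to its mean normalized distance
to the rest of the interval and to equal-width flanks, and a one-sided
rank-sum test asks whether the within values are smaller. The decay
normalization is what makes the rod yield no domains, and the per-bin
aggregation avoids the massive pseudo-replication of testing thousands
of dependent pairwise distances directly. BH correction runs across the
conformation's candidate intervals; q < 0.05 is reported. Intervals
shorter than 3 bins are untestable and skipped.

Ensemble-level statistics: boundary probability per bin and the
domain-count histogram over a weighted random sample of conformations
(default 5000, seed recorded); peak enrichment as the mean boundary
probability at offsets around peak centers relative to the regional
mean (strandless); hierarchical clustering of conformations (Ward
linkage on upper-triangle distance-map vectors) with clusters relabelled
1..k by increasing mean radius of gyration; virtual 4C as an anchor row
of any symmetric pair map; and many-body contact fractions — the
weighted share of conformations with all loci mutually within d_c, with
a conditional form restricted to conformations already satisfying a
sub-pair contact.

## Synthetic data

The fixture generator emulates only the statistical structure the
method consumes. Toy Hi-C maps are negative-binomial draws around
μ(i,j) = c·|i−j|^γ × TAD enrichments × loop enrichment, with γ = −1 and
dispersion 0.1 by default and c = 1000 expected counts at adjacent bins
(typical of deep Hi-C binned at 2 kb; at much shallower depth,
single-count shot noise — not the calling machinery — limits recovery).
For end-to-end recovery studies the power-law baseline can be replaced
by a per-separation profile, e.g. the null ensemble's own stratum means:
a pure power law demands short-range contact probabilities below what
any tangent-sphere chain can produce (beads 4 apart span ≤100 nm and
are nearly always in contact), which no sampler could match, whereas
real Hi-C baselines are themselves generated by chromatin physics.
The canonical recovery fixture implants three 3× TADs and three 8×
loops on the null baseline; under the default dispersion a weaker 5×
implant is erased by the count noise itself in a non-negligible share of
draws.

Labelled conformations are grown with the same kernel as the real
samplers (so every fixture chain satisfies bond, self-avoidance and
confinement invariants exactly), using optional per-bead Gaussian
tethers: a globule pair with a known junction (tether centers ±70 nm,
σ = 20 nm, a ±2-bead linear ramp across the junction so the spatial
midpoint of the transit coincides with the labelled bin), single compact
globules, plain confined coils, and labelled globule/coil mixtures.
Fixture weights are reset to 1 — they are labelled samples for pipeline
testing, not importance-weighted estimators.

What passing these tests does and does not show: the fixtures carry
idealized, known-truth structure; they validate the machinery
(normalization, calling, growth, calibration, boundary statistics), not
biological fidelity on real nuclei, and contain no trans contacts,
no unmappable regions, and no replicate-to-replicate biological
variability.

## Numerical and design choices

- Off-lattice tangent-sphere bonds (exactly one diameter); simplest
  model satisfying the bead-chain description.
- K = 32 uniform trial directions; spatial collision checks are exact
  (no grid approximation) inside numba kernels; squared distances
  throughout.
- Checkpoints every ⌈n/20⌉ beads, ESS trigger 0.5, systematic
  resampling; total weight preserved by construction.
- Production defaults: 2×10⁵ null chains, 5×10⁴ constrained chains;
  desk-scale studies in the test-suite use 10³–2×10⁴ chains and 30–200
  beads so the whole suite runs in minutes on one CPU.
- Monte Carlo p-values use +1 smoothing; BH is applied over the
  testable family only (|i−j| ≥ 2, nonzero observed).
- Bias ratio clip κ = 3 per calibration round; plateau tolerance 10⁻³
  with patience 2; calibrated factor cap 50 (kernel-side contact cap 1,
  miss floor 10⁻³).
- Degenerate inputs: all-masked matrices, zero adjacent signal,
  constant maps in correlations (NaN with error flag), conditional
  many-body fractions whose condition never fires (flagged invalid),
  intervals shorter than 3 bins (skipped) are all rejected or flagged
  explicitly rather than silently processed.

## Known limitations

- The likelihood acts at the placement step of the later bead of each
  pair; there is no lookahead, so very strong long-range targets rely on
  the calibration loop and importance weights rather than on guided
  growth.
- Repeated resampling collapses ancestry; early-bead statistics have an
  effective sample size well below the nominal chain count (see the
  Monte Carlo note above). Estimates are unbiased; comparisons must use
  the measured seed-to-seed scale.
- Random confined self-avoiding chains genuinely form transient
  domain-like blobs, so the single-cell domain pipeline reports nonzero
  TAD-like rates on null chains; bead-order-permuted distance maps, by
  contrast, have no sequence locality at all and yield essentially zero
  boundaries. The two are not comparable nulls.
- Boundary-strength values depend on the compression regime (chain
  extent relative to confinement); the 2.2 threshold is meaningful for
  confined chromatin-like chains, not for swollen free chains.
- The quantile normalization pools all genomic distances into one
  reference; a per-distance stratified normalization is a possible
  refinement.
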