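# chromoseed

Reconstruction of large ensembles of single-cell 3D chromatin
conformations from population Hi-C contact maps, with statistical
identification of the specific interactions that drive folding.

Population Hi-C averages millions of cells; most of its contacts are
random collisions expected from polymer physics and nuclear confinement
alone. `chromoseed` separates the two: it grows a physical null
ensemble of random, self-avoiding, sphere-confined chromatin chains,
tests every Hi-C pair against bootstrap replicates of that null, and
then grows a second ensemble of chains constrained by the surviving
*specific* interactions — yielding thousands of single-cell 3D
conformations whose aggregate reproduces the measured Hi-C map and
which can be interrogated individually: conformational heterogeneity,
single-cell TAD-like domains and their boundaries, boundary enrichment
at insulator-protein peaks, virtual 4C, and many-body contacts. It is
aimed at chromatin-structure researchers working with high-resolution
(2–5 kb) Hi-C of compact genomes such as *Drosophila*.

## Model and statistics

Chromatin is a chain of tangent 25 nm beads (165 bp/11 nm fiber; one
bead per 2 kb bin), confined to a sphere holding the region's share of
the nuclear volume; beads within d_c = 80 nm can ligate. Hi-C counts
are ICE-balanced and normalized to propensities
p_obs(i,j) = C(i,j)/E_diag(1), with E_diag(1) the mean adjacent-bin
count, so neighbouring loci average to 1.

The null ensemble is grown monomer-by-monomer with Rosenbluth-weighted
sequential importance sampling and checkpoint resampling; weighted
contact frequencies give the random-collision probability
p_null(i,j) = Σ_k I_k(i,j) w_k / Σ_k w_k. Significance uses the Bag of
Little Bootstraps: each of M = 5000 replicates resamples a ~1300-chain
subset up to the full ensemble size; after quantile normalization, a
pair's p-value is the share of replicates whose null probability
reaches p_obs, and Benjamini–Hochberg q < 0.01 defines the specific
set. Constrained ensembles grow with the same mechanics plus per-pair
Bernoulli likelihood factors, iteratively calibrated so the aggregated
contact map matches the targets; agreement is reported as Pearson r and
the distance-stratum-adjusted r′.

## Worked example

A 0.2 Mb study region (100 beads at 2 kb) in S2R+ geometry, with a
synthetic Hi-C map carrying three TADs (3×) and three loops (8×) on the
null ensemble's own distance decay:

```python
import numpy as np
import chromoseed as cs

params = cs.params_for_cell("s2r+", region_length_mb=0.2)
null = cs.build_null_ensemble(
    cs.GrowthConfig(n_beads=100, n_chains=10_000, master_seed=11), params)

pn = cs.contact_probability(null).p_null
prof = np.array([1.0] + [np.mean([pn[i, i+s] for i in range(100-s)])
                         for s in range(1, 100)])
spec = cs.ToySpec(n_bins=100,
                  tads=[(5, 35, 3.0), (35, 65, 3.0), (65, 95, 3.0)],
                  loops=[(10, 60, 8.0), (20, 80, 8.0), (40, 90, 8.0)],
                  seed=1, decay_profile=prof)
matrix, truth = cs.generate_toy_hic(spec)

pmap = cs.compute_propensity(cs.ice_balance(matrix))
calls = cs.call_specific_interactions(
    pmap, null, cs.BootstrapConfig(n_replicates=2000, seed=3))
target = cs.select_targets(pmap, calls, mode="specific")
ens, _ = cs.build_hic_ensemble(
    target, params,
    cs.GrowthConfig(n_beads=100, n_chains=5000, master_seed=5),
    rounds=12, batch=2500)

sim = cs.simulate_contact_map(ens)
r = cs.map_correlation(sim, target.q_target, mask=target.support)
rp = cs.map_correlation(sim, target.q_target, mode="distance_adjusted",
                        mask=target.support)
stats = cs.boundary_probability(ens, sample_size=2000, seed=7)
```

This prints (via the obvious `print` statements):

```
confinement radius: 271 nm
null ensemble: 10000 chains
specific interactions: 904 of 4654 tested pairs (19.4%)
implanted loops recovered: 3/3
simulated vs target map: r = 0.97, r' = 0.72
conformations with >= 1 TAD-like domain: 99.9%
```

Reading: the caller retains ~19% of pairs on this small, strongly
structured region (genome-wide on real data the specific fraction is
5–6%); all implanted loops are among them. The ensemble grown from the
specific calls alone reproduces the target map at r = 0.97 — specific
interactions suffice to drive the folding — and r′ = 0.72 shows the
agreement survives removal of the distance-decay trend. Nearly every
conformation of this TAD-dense region carries at least one
significantly compacted TAD-like domain, individually called from its
spatial-distance map (strength threshold 2.2, rank-sum q < 0.05).

The same pipeline is scriptable from the shell:

```bash
chromoseed simulate --bins 100 --tads 5:35:3,35:65:3,65:95:3 \
    --loops 10:60:8 --seed 1 --out toy.tsv
chromoseed prep --matrix toy.tsv --format coo-triplet --chrom chrT \
    --res 2000 --n-bins 100 --out prep.h5
chromoseed null --n-beads 100 --n-chains 10000 --cell s2r+ --seed 11 \
    --out null.h5
chromoseed call --prep prep.h5 --null null.h5 --replicates 2000 \
    --seed 3 --out calls.bedpe
chromoseed build --prep prep.h5 --calls calls.bedpe --mode specific \
    --n-chains 5000 --radius 271 --seed 5 --out ensemble.h5
chromoseed analyze --ensemble ensemble.h5 --clusters 5 --sample 2000 \
    --seed 7 --outdir results/
```

See `docs/methods.md` for the model, the samplers, the statistics and
their limitations.

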