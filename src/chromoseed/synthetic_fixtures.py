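"""Synthetic Hi-C maps, conformations and annotations with known truth.

Everything the pipeline consumes can be generated here: toy contact
matrices with power-law distance decay, TAD blocks and loops under
negative-binomial noise; labelled conformation ensembles (compact
globules, random coils, globule pairs with a known junction) built with
the same growth kernel as the real samplers so every chain satisfies
the physical invariants; and peak/state BED tables. These fixtures
carry the statistical structure the method tests for — they are not a
biological simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chain_model import Ensemble, PhysicalParams
from .hic_io import ContactMatrix, GenomicBinning
from .null_ensemble import GrowthConfig, _grow_population

__all__ = [
    "ToySpec",
    "generate_toy_hic",
    "generate_labeled_conformations",
    "generate_peaks",
]


@dataclass
class ToySpec:
    """Recipe for a synthetic Hi-C matrix.

    Expected counts follow c * |i-j|^decay, multiplied by the enrichment
    of every TAD covering the pair and of any loop at the pair; counts
    are drawn negative-binomially with var = mu + dispersion * mu^2.
    """

    n_bins: int = 100
    decay_exponent: float = -1.0
    tads: list[tuple[int, int, float]] = field(default_factory=list)
    loops: list[tuple[int, int, float]] = field(default_factory=list)
    noise_dispersion: float = 0.1
    base_count: float = 1000.0  # adjacent-bin depth typical of deep Hi-C at 2 kb
    seed: int = 0
    #: optional per-separation baseline (index s = mean count at |i-j| = s,
    #: relative to index 1) replacing the power law — e.g. the stratum means
    #: of a polymer null ensemble, so that implanted enrichments sit on a
    #: physically realizable background
    decay_profile: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_bins < 20:
            raise ValueError("need at least 20 bins")
        for lo, hi, enr in self.tads:
            if not (0 <= lo < hi <= self.n_bins):
                raise ValueError(f"TAD ({lo}, {hi}) out of range")
        for i, j, enr in self.loops:
            if enr <= 1:
                raise ValueError("loop enrichment must exceed 1")
            if not (0 <= i < self.n_bins and 0 <= j < self.n_bins):
                raise ValueError(f"loop ({i}, {j}) out of range")


def expected_counts(spec: ToySpec) -> np.ndarray:
    """Noise-free expected matrix for a toy spec (zero diagonal)."""
    n = spec.n_bins
    i, j = np.indices((n, n))
    sep = np.abs(i - j)
    mu = np.zeros((n, n))
    nz = sep > 0
    if spec.decay_profile is not None:
        prof = np.asarray(spec.decay_profile, dtype=float)
        if prof.size < n:
            raise ValueError("decay_profile shorter than n_bins")
        mu[nz] = spec.base_count * prof[sep[nz]] / prof[1]
    else:
        mu[nz] = spec.base_count * sep[nz].astype(float) ** spec.decay_exponent
    for lo, hi, enr in spec.tads:
        inside = (i >= lo) & (i < hi) & (j >= lo) & (j < hi)
        mu[inside & nz] *= enr
    for li, lj, enr in spec.loops:
        mu[li, lj] *= enr
        mu[lj, li] *= enr
    return mu


def generate_toy_hic(spec: ToySpec,
                     binning: GenomicBinning | None = None):
    """Draw a toy contact matrix; returns (ContactMatrix, labels).

    ``labels`` holds boolean matrices 'loop' and 'tad' marking implanted
    pairs, plus the noise-free expected matrix under 'mu'.
    """
    if binning is None:
        binning = GenomicBinning(chrom="chrT", start=0, resolution=2000,
                                 n_bins=spec.n_bins)
    if binning.n_bins != spec.n_bins:
        raise ValueError("binning size mismatch")
    n = spec.n_bins
    mu = expected_counts(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed % (2 ** 31), 41]))
    counts = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    m = mu[iu, ju]
    if spec.noise_dispersion > 0:
        r = 1.0 / spec.noise_dispersion
        p = r / (r + m)
        draw = rng.negative_binomial(r, p)
    else:
        draw = m
    counts[iu, ju] = draw
    counts[ju, iu] = draw
    loop_mask = np.zeros((n, n), dtype=bool)
    for li, lj, _ in spec.loops:
        loop_mask[li, lj] = loop_mask[lj, li] = True
    tad_mask = np.zeros((n, n), dtype=bool)
    i, j = np.indices((n, n))
    for lo, hi, _ in spec.tads:
        tad_mask |= (i >= lo) & (i < hi) & (j >= lo) & (j < hi) & (i != j)
    labels = {"loop": loop_mask, "tad": tad_mask, "mu": mu}
    return ContactMatrix(binning=binning, counts=counts), labels


_FIXTURE_PARAMS = dict(bead_diameter_nm=25.0, ligation_threshold_nm=80.0)


def generate_labeled_conformations(kind: str, n: int, seed: int = 0,
                                   n_beads: int = 50,
                                   junction: int | None = None):
    """Grow labelled conformation ensembles; returns (Ensemble, labels).

    kinds:
      * ``coil`` — random confined self-avoiding chains (the null model
        at fixture scale; 200 nm sphere), labels all 0;
      * ``globule-pair`` — each chain tethered to two well-separated
        Gaussian centers switching at ``junction`` (default the middle
        bead), giving two compact globules with a sharp spatial boundary;
        labels give the junction bin;
      * ``mixture`` — half compact globules (single tether), half
        extended coils, shuffled; labels 0 = globule, 1 = coil.

    Importance weights are reset to 1: fixtures are labelled samples for
    pipeline testing, not importance-weighted estimators.
    """
    seed = int(seed) % (2 ** 31 - 1)
    if kind == "coil":
        params = PhysicalParams(confinement_radius_nm=200.0, **_FIXTURE_PARAMS)
        cfg = GrowthConfig(n_beads=n_beads, n_chains=n, master_seed=seed)
        ens = _grow_population(n_beads, cfg, params)
        labels = np.zeros(len(ens), dtype=int)
    elif kind == "globule-pair":
        if junction is None:
            junction = n_beads // 2
        params = PhysicalParams(confinement_radius_nm=300.0, **_FIXTURE_PARAMS)
        cfg = GrowthConfig(n_beads=n_beads, n_chains=n, master_seed=seed)
        centers = np.zeros((n_beads, 3))
        # symmetric ramp across the junction so the spatial midpoint of the
        # inter-globule transit coincides with the labelled junction bin
        half_gap = 70.0
        ramp = 2
        for t in range(n_beads):
            if t < junction - ramp:
                centers[t, 0] = -half_gap
            elif t >= junction + ramp:
                centers[t, 0] = half_gap
            else:
                frac = (t - (junction - ramp)) / (2.0 * ramp)
                centers[t, 0] = -half_gap + 2.0 * half_gap * frac
        sigma2 = np.full(n_beads, 20.0 ** 2)
        ens = _grow_population(n_beads, cfg, params, tether=(centers, sigma2))
        labels = np.full(len(ens), junction, dtype=int)
    elif kind == "mixture":
        params = PhysicalParams(confinement_radius_nm=300.0, **_FIXTURE_PARAMS)
        n_glob = n // 2
        centers = np.zeros((n_beads, 3))
        sigma2 = np.full(n_beads, 30.0 ** 2)
        cfg_g = GrowthConfig(n_beads=n_beads, n_chains=n_glob, master_seed=seed)
        glob = _grow_population(n_beads, cfg_g, params,
                                tether=(centers, sigma2))
        cfg_c = GrowthConfig(n_beads=n_beads, n_chains=n - n_glob,
                             master_seed=seed + 1)
        coil = _grow_population(n_beads, cfg_c, params)
        confs = glob.conformations + coil.conformations
        labels = np.concatenate([np.zeros(len(glob), int),
                                 np.ones(len(coil), int)])
        rng = np.random.default_rng(np.random.SeedSequence([seed, 51]))
        order = rng.permutation(len(confs))
        confs = [confs[i] for i in order]
        labels = labels[order]
        ens = Ensemble(conformations=confs, params=params, kind="null",
                       provenance={"fixture": "mixture", "master_seed": seed})
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    for c in ens.conformations:
        c.weight = 1.0
    ens.provenance["fixture"] = kind
    return ens, labels


def generate_peaks(boundary_sites: list[int], background_sites: int,
                   binning: GenomicBinning, seed: int = 0) -> pd.DataFrame:
    """BED-style peak table: one peak per boundary site plus random
    background peaks, one bin wide each."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2 ** 31), 61]))
    bins = list(boundary_sites)
    if background_sites > 0:
        bins += list(rng.integers(0, binning.n_bins, size=background_sites))
    rows = []
    for k, b in enumerate(bins):
        start = binning.bin_start(int(b))
        rows.append((binning.chrom, start, start + binning.resolution,
                     f"peak{k}"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
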