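"""Single-cell structural analytics over conformation ensembles.

Works on the 3D chains produced by the samplers: spatial-distance maps,
compactness, hierarchical clustering of conformations, domain-boundary
calling from distance-ratio profiles, TAD-like domain testing,
boundary-probability aggregation with peak enrichment, virtual 4C
tracks, and many-body contact fractions.

A "TAD-like structure" here is a single-conformation feature: a
contiguous interval whose internal spatial distances are significantly
smaller than its distances to equally wide flanking segments, assessed
per conformation with a one-sided rank-sum test and BH correction
across that conformation's candidate intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu

from .chain_model import Conformation, Ensemble
from .hic_io import GenomicBinning
from .specific_calls import bh_adjust

__all__ = [
    "BoundaryProfile",
    "DomainCallSet",
    "CompactnessStats",
    "distance_map",
    "compactness",
    "cluster_conformations",
    "boundary_strength",
    "call_boundaries",
    "call_tad_like",
    "boundary_probability",
    "peak_enrichment",
    "virtual_4c",
    "multibody_fraction",
]


def distance_map(conf: Conformation) -> np.ndarray:
    """Pairwise spatial distances (nm) between beads of one chain."""
    return squareform(pdist(conf.coords))


@dataclass
class CompactnessStats:
    rg: float
    end_to_end: float


def compactness(conf: Conformation) -> CompactnessStats:
    """Radius of gyration and end-to-end distance of one chain."""
    x = conf.coords
    centroid = x.mean(axis=0)
    rg = float(np.sqrt(((x - centroid) ** 2).sum(axis=1).mean()))
    e2e = float(np.linalg.norm(x[-1] - x[0]))
    return CompactnessStats(rg=rg, end_to_end=e2e)


@dataclass
class ClusterResult:
    assignments: np.ndarray        # 1..k, ordered by increasing mean R_g
    proportions: np.ndarray        # weighted share of each cluster
    mean_rg: np.ndarray            # per cluster
    contact_maps: list[np.ndarray]  # weighted aggregate per cluster


def cluster_conformations(ensemble: Ensemble, k: int,
                          d_c: float | None = None) -> ClusterResult:
    """Ward-linkage hierarchical clustering of conformations.

    Conformations are embedded as upper-triangle vectors of their
    distance maps; clusters are relabelled 1..k by increasing mean
    radius of gyration, so cluster 1 is always the most compact.
    """
    N = len(ensemble)
    if k < 2 or k > N:
        raise ValueError("need 2 <= k <= ensemble size")
    from . import _growth

    if d_c is None:
        d_c = ensemble.params.ligation_threshold_nm
    vecs = np.stack([pdist(c.coords) for c in ensemble])
    Z = linkage(vecs, method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    rgs = np.array([compactness(c).rg for c in ensemble])
    w = ensemble.weights
    order = np.argsort([rgs[raw == lab].mean() for lab in range(1, k + 1)])
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    assignments = relabel[raw - 1]
    coords = ensemble.coords_array
    proportions = np.empty(k)
    mean_rg = np.empty(k)
    maps = []
    for lab in range(1, k + 1):
        sel = assignments == lab
        proportions[lab - 1] = w[sel].sum() / w.sum()
        mean_rg[lab - 1] = rgs[sel].mean()
        maps.append(_growth.weighted_contact_map(coords[sel], w[sel], float(d_c)))
    return ClusterResult(assignments=assignments, proportions=proportions,
                         mean_rg=mean_rg, contact_maps=maps)


# ---------------------------------------------------------------------------
# boundaries and TAD-like domains


@dataclass
class BoundaryProfile:
    strength: np.ndarray
    boundaries: list[int]
    threshold: float = 2.2
    window: int = 10


@dataclass
class DomainCallSet:
    intervals: list[tuple[int, int]]
    q_values: list[float]

    @property
    def n_domains(self) -> int:
        return len(self.intervals)


def boundary_strength(dmap: np.ndarray, w: int = 10) -> np.ndarray:
    """Spatial-distance-ratio boundary profile.

    For bin i the strength is the mean distance between the w bins
    before i and the w bins from i on, divided by the average of the two
    windows' internal mean distances. Values near 1 mean no insulation;
    the first/last w bins, where a full window does not fit, are padded
    with 1.
    """
    n = dmap.shape[0]
    if w < 2:
        raise ValueError("window must be >= 2")
    if n < 2 * w:
        raise ValueError("need at least 2*w bins")
    strength = np.ones(n)
    iu = np.triu_indices(w, k=1)
    for i in range(w, n - w + 1):
        left = slice(i - w, i)
        right = slice(i, i + w)
        inter = dmap[left, right].mean()
        intra_l = dmap[left, left][iu].mean()
        intra_r = dmap[right, right][iu].mean()
        denom = 0.5 * (intra_l + intra_r)
        if i < n:
            strength[i] = inter / denom if denom > 0 else 1.0
    return strength


def call_boundaries(strength: np.ndarray, threshold: float = 2.2,
                    min_sep: int = 10) -> list[int]:
    """Local maxima of the strength curve above threshold, kept greedily
    in decreasing strength order with pairwise separation >= min_sep."""
    if threshold <= 1:
        raise ValueError("threshold must exceed 1")
    n = strength.size
    candidates = [i for i in range(1, n - 1)
                  if strength[i] >= threshold
                  and strength[i] >= strength[i - 1]
                  and strength[i] >= strength[i + 1]]
    kept: list[int] = []
    for i in sorted(candidates, key=lambda i: -strength[i]):
        if all(abs(i - j) >= min_sep for j in kept):
            kept.append(i)
    return sorted(kept)


def _decay_normalize(dmap: np.ndarray) -> np.ndarray:
    """Divide each distance by the conformation's median distance at the
    same genomic separation, removing the trivial polymer distance decay."""
    n = dmap.shape[0]
    z = np.ones_like(dmap)
    iu, ju = np.triu_indices(n, k=1)
    sep = ju - iu
    vals = dmap[iu, ju]
    med = np.ones(n)
    for s in range(1, n):
        m = vals[sep == s]
        if m.size:
            med[s] = np.median(m)
    norm = vals / np.where(med[sep] > 0, med[sep], 1.0)
    z[iu, ju] = norm
    z[ju, iu] = norm
    return z


def call_tad_like(dmap: np.ndarray, boundaries: list[int],
                  alpha: float = 0.05) -> DomainCallSet:
    """Test intervals between adjacent boundaries for TAD-like compaction.

    Region ends act as flanking boundaries, but a conformation without
    any internal boundary contributes no candidates (the whole region is
    not counted as a domain). Each candidate interval is tested one-sided:
    its within-interval pairwise distances must be smaller than its
    distances to equal-width flanks *after* dividing every distance by the
    conformation's median distance at the same genomic separation — the
    decay adjustment is essential, since raw flank distances span larger
    genomic separations and are trivially larger even for a featureless
    chain (a straight rod shows no domains under this test). BH
    correction runs across the conformation's candidates and intervals
    with q < alpha are reported.
    """
    n = dmap.shape[0]
    if not boundaries:
        return DomainCallSet(intervals=[], q_values=[])
    z = _decay_normalize(dmap)
    edges = [0] + sorted(boundaries) + [n]
    candidates = []
    pvals = []
    for a, b in zip(edges[:-1], edges[1:]):
        width = b - a
        if width < 3:
            continue
        lo = max(0, a - width)
        hi = min(n, b + width)
        if lo == a and b == hi:
            continue
        # aggregate to one within / one cross value per bin before the
        # rank-sum: individual pairwise distances are strongly dependent,
        # and testing them directly overstates the evidence wildly
        within = np.empty(width)
        cross = np.empty(width)
        for k, i in enumerate(range(a, b)):
            others = np.concatenate([z[i, a:i], z[i, i + 1:b]])
            within[k] = others.mean()
            flank_parts = []
            if lo < a:
                flank_parts.append(z[i, lo:a])
            if b < hi:
                flank_parts.append(z[i, b:hi])
            cross[k] = np.concatenate(flank_parts).mean()
        stat = mannwhitneyu(within, cross, alternative="less")
        candidates.append((a, b))
        pvals.append(stat.pvalue)
    if not candidates:
        return DomainCallSet(intervals=[], q_values=[])
    q = bh_adjust(np.asarray(pvals))
    keep = q < alpha
    return DomainCallSet(
        intervals=[c for c, k in zip(candidates, keep) if k],
        q_values=[float(v) for v, k in zip(q, keep) if k])


@dataclass
class BoundaryStats:
    probability: np.ndarray          # per-bin boundary frequency
    domain_counts: np.ndarray        # histogram over number of TAD-like domains
    frac_with_domain: float          # conformations with >= 1 TAD-like domain
    sample_size: int
    seed: int


def boundary_probability(ensemble: Ensemble, sample_size: int = 5000,
                         seed: int = 0, w: int = 10, threshold: float = 2.2,
                         alpha: float = 0.05) -> BoundaryStats:
    """Boundary frequency and domain-count distribution over a random
    sample of conformations (weighted draw, with replacement)."""
    N = len(ensemble)
    if sample_size > N:
        raise ValueError("sample_size exceeds ensemble size")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2 ** 31), 31]))
    probs = ensemble.weights / ensemble.total_weight
    picks = rng.choice(N, size=sample_size, replace=True, p=probs)
    n = ensemble.n_beads
    hits = np.zeros(n)
    counts: list[int] = []
    for k in picks:
        dmap = distance_map(ensemble.conformations[k])
        s = boundary_strength(dmap, w=w)
        bnd = call_boundaries(s, threshold=threshold, min_sep=w)
        for b in bnd:
            hits[b] += 1
        counts.append(call_tad_like(dmap, bnd, alpha=alpha).n_domains)
    counts_arr = np.asarray(counts)
    hist = np.bincount(counts_arr) / sample_size
    return BoundaryStats(probability=hits / sample_size, domain_counts=hist,
                         frac_with_domain=float((counts_arr >= 1).mean()),
                         sample_size=sample_size, seed=seed)


def peak_enrichment(profile: np.ndarray, peaks: pd.DataFrame,
                    binning: GenomicBinning, flank: int = 20000) -> np.ndarray:
    """Mean profile around peak centers, relative to the regional mean.

    Returns the enrichment curve over offsets -flank..+flank (in bins);
    strand is ignored since boundary probability is strandless.
    """
    n = binning.n_bins
    half = flank // binning.resolution
    centers = []
    for row in peaks.itertuples(index=False):
        if row.chrom != binning.chrom:
            continue
        center_bp = (int(row.start) + int(row.end)) // 2
        b = binning.bin_of(center_bp)
        if 0 <= b < n:
            centers.append(b)
    if not centers:
        raise ValueError("no usable peaks overlap the region")
    global_mean = profile.mean()
    if global_mean == 0:
        raise ValueError("profile is identically zero")
    curve = np.full(2 * half + 1, np.nan)
    for off in range(-half, half + 1):
        vals = [profile[c + off] for c in centers if 0 <= c + off < n]
        if vals:
            curve[off + half] = np.mean(vals) / global_mean
    return curve


def virtual_4c(pair_map: np.ndarray, anchor) -> np.ndarray:
    """One anchor row of a symmetric pair map as a 1D track; an interval
    anchor (lo, hi) averages its rows."""
    n = pair_map.shape[0]
    if np.isscalar(anchor):
        a = int(anchor)
        if not 0 <= a < n:
            raise ValueError("anchor outside region")
        return pair_map[a].copy()
    lo, hi = anchor
    if not (0 <= lo < hi <= n):
        raise ValueError("anchor interval outside region")
    return pair_map[lo:hi].mean(axis=0)


@dataclass
class MultibodyResult:
    fraction: float
    distances: dict[tuple, np.ndarray]  # per locus pair, per-chain distances
    conditional_valid: bool = True


def _locus_bins(locus) -> np.ndarray:
    if np.isscalar(locus):
        return np.array([int(locus)])
    lo, hi = locus
    return np.arange(int(lo), int(hi))


def multibody_fraction(ensemble: Ensemble, loci: list, d_c: float | None = None,
                       condition: tuple | None = None) -> MultibodyResult:
    """Weighted fraction of conformations with all loci mutually in contact.

    A locus is a bin or a (lo, hi) bin interval; the locus-locus distance
    in a chain is the minimum bead-pair distance. With ``condition`` =
    (a, b) the fraction is computed among conformations where loci a and
    b are already in contact; if the condition is never met the result
    carries ``conditional_valid=False``.
    """
    if len(loci) < 2:
        raise ValueError("need at least two loci")
    if d_c is None:
        d_c = ensemble.params.ligation_threshold_nm
    coords = ensemble.coords_array
    w = ensemble.weights
    bins = [_locus_bins(l) for l in loci]
    n_loci = len(bins)
    N = coords.shape[0]
    dmat = np.empty((N, n_loci, n_loci))
    for a in range(n_loci):
        for b in range(a + 1, n_loci):
            xa = coords[:, bins[a], :]
            xb = coords[:, bins[b], :]
            diff = xa[:, :, None, :] - xb[:, None, :, :]
            d = np.sqrt((diff ** 2).sum(-1)).min(axis=(1, 2))
            dmat[:, a, b] = d
            dmat[:, b, a] = d
    all_contact = np.ones(N, dtype=bool)
    for a in range(n_loci):
        for b in range(a + 1, n_loci):
            all_contact &= dmat[:, a, b] < d_c
    distances = {(a, b): dmat[:, a, b]
                 for a in range(n_loci) for b in range(a + 1, n_loci)}
    if condition is not None:
        a, b = condition
        cond = dmat[:, a, b] < d_c
        if not cond.any():
            return MultibodyResult(fraction=float("nan"), distances=distances,
                                   conditional_valid=False)
        frac = float((w * (all_contact & cond)).sum() / (w * cond).sum())
        return MultibodyResult(fraction=frac, distances=distances)
    frac = float((w * all_contact).sum() / w.sum())
    return MultibodyResult(fraction=frac, distances=distances)
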