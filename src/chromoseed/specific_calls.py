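"""Bootstrap significance testing of Hi-C pairs against the polymer null.

Every tested bin pair receives an empirical p-value: the fraction of
bootstrap replicates of the null ensemble whose random-collision contact
probability at that pair reaches the observed Hi-C propensity. Replicates
come from the Bag of Little Bootstraps (BLB): small disjoint subsets of
chains are resampled up to the full ensemble size, which approximates
the full bootstrap at a fraction of the cost. Null and observed maps are
quantile-normalized onto a common scale before comparison. Pairs whose
Benjamini-Hochberg-adjusted p-value falls below alpha (default 0.01) and
that carry a nonzero observed count are reported as specific
interactions — contacts beyond what volume confinement alone explains.

Only pairs with |i - j| >= 2 and nonzero observed propensity are tested:
adjacent pairs define the propensity normalization and are contacts by
construction, and the diagonal is never used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from . import _growth
from .chain_model import Ensemble
from .hic_io import GenomicBinning, PropensityMap

__all__ = [
    "BootstrapConfig",
    "ReplicateMaps",
    "SpecificCallSet",
    "tested_pairs",
    "blb_replicates",
    "quantile_normalize",
    "pair_pvalues",
    "bh_adjust",
    "call_specific",
    "call_specific_interactions",
    "tally_types",
]


@dataclass
class BootstrapConfig:
    """BLB layout: M replicates over little-bootstrap subsets of b chains.

    By default (``n_subsets=None``) every replicate draws its own chain
    subset without replacement, so the replicate distribution smoothly
    approximates the estimator's subsample variability; setting
    ``n_subsets`` instead splits the M replicates over that many shared
    disjoint subsets. The default subset size is ~1300 chains (<=1% of a
    production ensemble of 2x10^5, and close to the N^0.6 little-
    bootstrap scaling there), capped at the ensemble size.
    """

    n_replicates: int = 5000
    subset_size: int | None = None
    n_subsets: int | None = None
    seed: int = 0

    DEFAULT_SUBSET = 1300

    def __post_init__(self) -> None:
        if self.n_replicates < 100:
            raise ValueError("need at least 100 replicates")
        if self.n_subsets is not None and self.n_subsets < 1:
            raise ValueError("need at least one subset")

    def resolved_subset_size(self, n_chains: int) -> int:
        if self.subset_size is not None:
            b = self.subset_size
            if b > n_chains:
                raise ValueError("subset size exceeds ensemble size")
        else:
            b = min(self.DEFAULT_SUBSET, n_chains)
        return b


@dataclass
class ReplicateMaps:
    """Bootstrap p_null values over the tested pairs, one row per replicate."""

    pair_i: np.ndarray
    pair_j: np.ndarray
    values: np.ndarray  # (M, n_pairs)
    n_bins: int

    @property
    def n_replicates(self) -> int:
        return self.values.shape[0]

    def full_map(self, m: int) -> np.ndarray:
        out = np.zeros((self.n_bins, self.n_bins))
        out[self.pair_i, self.pair_j] = self.values[m]
        out[self.pair_j, self.pair_i] = self.values[m]
        return out


@dataclass
class SpecificCallSet:
    """Per-pair p/q values and the retained specific interactions."""

    binning: GenomicBinning
    pair_i: np.ndarray
    pair_j: np.ndarray
    p: np.ndarray
    q: np.ndarray
    specific: np.ndarray
    alpha: float = 0.01
    propensity: np.ndarray | None = None

    def _matrix(self, vec: np.ndarray, fill) -> np.ndarray:
        n = self.binning.n_bins
        out = np.full((n, n), fill, dtype=vec.dtype if vec.dtype != bool else bool)
        out[self.pair_i, self.pair_j] = vec
        out[self.pair_j, self.pair_i] = vec
        return out

    @property
    def p_values(self) -> np.ndarray:
        return self._matrix(self.p, np.nan)

    @property
    def q_values(self) -> np.ndarray:
        return self._matrix(self.q, np.nan)

    @property
    def specific_mask(self) -> np.ndarray:
        return self._matrix(self.specific, False)

    @property
    def n_specific(self) -> int:
        return int(self.specific.sum())

    def to_bedpe(self) -> pd.DataFrame:
        b = self.binning
        sel = self.specific
        i, j = self.pair_i[sel], self.pair_j[sel]
        prop = (self.propensity[sel] if self.propensity is not None
                else np.full(sel.sum(), np.nan))
        return pd.DataFrame({
            "chrom1": b.chrom,
            "start1": b.start + i * b.resolution,
            "end1": b.start + (i + 1) * b.resolution,
            "chrom2": b.chrom,
            "start2": b.start + j * b.resolution,
            "end2": b.start + (j + 1) * b.resolution,
            "propensity": prop,
            "p": self.p[sel],
            "q": self.q[sel],
        })


def tested_pairs(p_obs: PropensityMap, min_sep: int = 2):
    """Indices (i, j), i < j, of testable pairs: separation >= min_sep,
    both bins unmasked, observed propensity positive and finite."""
    n = p_obs.n_bins
    iu, ju = np.triu_indices(n, k=min_sep)
    vals = p_obs.p_obs[iu, ju]
    keep = np.isfinite(vals) & (vals > 0)
    return iu[keep], ju[keep]


def blb_replicates(ensemble: Ensemble, config: BootstrapConfig,
                   pair_i: np.ndarray, pair_j: np.ndarray,
                   d_c: float | None = None) -> ReplicateMaps:
    """Bag-of-Little-Bootstraps replicate contact maps.

    Each replicate is built from a chain subset of size ``b`` drawn
    without replacement (a fresh subset per replicate by default, or
    ``M/s`` replicates per shared disjoint subset when ``n_subsets`` is
    set), resampled multinomially up to the full ensemble size N. The
    resample counts multiply the chains' importance weights when
    averaging contact indicators.
    """
    if d_c is None:
        d_c = ensemble.params.ligation_threshold_nm
    N = len(ensemble)
    b = config.resolved_subset_size(N)
    M = config.n_replicates
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed) % (2 ** 31), 11]))
    coords = ensemble.coords_array
    weights = ensemble.weights
    pi64 = pair_i.astype(np.int64)
    pj64 = pair_j.astype(np.int64)
    values = np.empty((M, pair_i.size))
    n_bins = ensemble.n_beads
    # indicator rows are computed once per chain, on first use
    ind_cache = np.zeros((N, pair_i.size), dtype=np.int8)
    have_ind = np.zeros(N, dtype=bool)

    def indicators(members: np.ndarray) -> np.ndarray:
        new = members[~have_ind[members]]
        if new.size:
            ind_cache[new] = _growth.contact_indicators(
                coords[new], pi64, pj64, float(d_c)).astype(np.int8)
            have_ind[new] = True
        return ind_cache[members].astype(np.float64)

    if config.n_subsets is None:
        members = np.empty((M, b), dtype=np.int64)
        for m in range(M):
            members[m] = rng.choice(N, size=b, replace=False)
        indicators(np.unique(members))
        counts = rng.multinomial(N, np.full(b, 1.0 / b), size=M)
        cw = counts * weights[members]
        values[:] = 0.0
        _growth.blb_weighted_means(ind_cache, members, cw, values)
    else:
        s = config.n_subsets
        if s * b > N:
            s = max(1, N // b)
        chosen = rng.choice(N, size=s * b, replace=False)
        per = np.full(s, M // s)
        per[: M % s] += 1
        row = 0
        for si in range(s):
            members = chosen[si * b: (si + 1) * b]
            ind = indicators(members)
            counts = rng.multinomial(N, np.full(b, 1.0 / b), size=per[si])
            cw = counts * weights[members]  # (per, b)
            values[row: row + per[si]] = (cw @ ind) / cw.sum(axis=1, keepdims=True)
            row += per[si]
    return ReplicateMaps(pair_i=pair_i, pair_j=pair_j, values=values,
                         n_bins=n_bins)


def quantile_normalize(replicates: np.ndarray, p_obs_vec: np.ndarray):
    """Map all replicate vectors and the observed vector onto a common
    reference distribution (the mean of all sorted vectors), preserving
    within-vector ranks. Returns (normalized replicates, normalized obs).
    """
    stacked = np.vstack([replicates, p_obs_vec[None, :]])
    n_vec, n_val = stacked.shape
    if n_val == 0:
        return replicates.copy(), p_obs_vec.copy()
    sorted_vals = np.sort(stacked, axis=1)
    ref = sorted_vals.mean(axis=0)
    if np.allclose(stacked.max(axis=1), stacked.min(axis=1)):
        # all-constant maps carry no rank information; pass through
        return replicates.copy(), p_obs_vec.copy()
    grid = np.arange(1, n_val + 1)
    out = np.empty_like(stacked)
    for r in range(n_vec):
        ranks = rankdata(stacked[r], method="average")
        out[r] = np.interp(ranks, grid, ref)
    return out[:-1], out[-1]


def pair_pvalues(norm_replicates: np.ndarray, norm_obs: np.ndarray) -> np.ndarray:
    """Empirical p-value per pair: share of replicates whose null contact
    probability reaches the observed propensity, with add-one smoothing
    so p is never zero. Small p marks pairs far above the null."""
    M = norm_replicates.shape[0]
    exceed = (norm_replicates >= norm_obs[None, :]).sum(axis=0)
    return (1.0 + exceed) / (M + 1.0)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment over the tested family."""
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def call_specific(binning: GenomicBinning, pair_i, pair_j, p, q,
                  p_obs: PropensityMap, alpha: float = 0.01) -> SpecificCallSet:
    """Retain pairs with q < alpha and a nonzero observed contact."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    obs = p_obs.p_obs[pair_i, pair_j]
    specific = (q < alpha) & (obs > 0)
    return SpecificCallSet(binning=binning, pair_i=pair_i, pair_j=pair_j,
                           p=p, q=q, specific=specific, alpha=alpha,
                           propensity=obs)


def call_specific_interactions(p_obs: PropensityMap, ensemble: Ensemble,
                               config: BootstrapConfig | None = None,
                               alpha: float = 0.01,
                               min_sep: int = 2) -> SpecificCallSet:
    """Full pipeline: BLB replicates, quantile normalization, empirical
    p-values, BH adjustment, and the specific-interaction call."""
    config = config or BootstrapConfig()
    pi, pj = tested_pairs(p_obs, min_sep=min_sep)
    reps = blb_replicates(ensemble, config, pi, pj)
    obs_vec = p_obs.p_obs[pi, pj]
    norm_reps, norm_obs = quantile_normalize(reps.values, obs_vec)
    p = pair_pvalues(norm_reps, norm_obs)
    q = bh_adjust(p)
    return call_specific(p_obs.binning, pi, pj, p, q, p_obs, alpha=alpha)


_TYPE_KEYS = ("A-A", "A-I", "A-P", "I-I", "I-P", "P-P", "any-U")


def tally_types(calls: SpecificCallSet, states: np.ndarray) -> dict[str, float]:
    """Proportions of called pairs by unordered chromatin-state pair.

    ``states`` assigns each bin one of {A, I, P, U} (active, inactive,
    polycomb, undetermined); pairs touching an unknown or unannotated bin
    count as 'any-U'. Proportions sum to 1 over called pairs.
    """
    sel = calls.specific
    i, j = calls.pair_i[sel], calls.pair_j[sel]
    counts = dict.fromkeys(_TYPE_KEYS, 0)
    for a, b in zip(i, j):
        sa = states[a] if a < len(states) else "U"
        sb = states[b] if b < len(states) else "U"
        if sa not in "AIP" or sb not in "AIP":
            counts["any-U"] += 1
        else:
            key = "-".join(sorted((sa, sb)))
            counts[key] += 1
    total = sum(counts.values())
    if total == 0:
        return dict.fromkeys(_TYPE_KEYS, 0.0)
    return {k: v / total for k, v in counts.items()}
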