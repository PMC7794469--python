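"""Confined random-polymer null model.

Generates the reference ensemble of self-avoiding, sphere-confined
chains by sequential importance sampling: monomers are added one at a
time with Rosenbluth weighting, and at predetermined checkpoint lengths
the population is resampled proportionally to the weights whenever the
effective sample size degrades. The weighted ensemble targets the
uniform distribution over all geometrically realizable chains within
the confinement, and the weighted contact frequencies give the
probability of random (non-specific) collisions expected from volume
confinement alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from . import _growth
from .chain_model import Conformation, Ensemble, PhysicalParams

__all__ = [
    "GrowthConfig",
    "NullContactMap",
    "ChainDeath",
    "grow_chain",
    "build_null_ensemble",
    "contact_probability",
]


class ChainDeath(RuntimeError):
    """Raised when a growing chain runs out of valid trial moves."""


@dataclass
class GrowthConfig:
    """Controls for sequential chain growth.

    ``n_trial_directions`` is the number K of candidate directions per
    step; ``checkpoints`` are the chain lengths at which the population
    may be resampled (default: every ceil(n/20) beads); resampling fires
    when the effective sample size falls below
    ``resample_trigger * n_chains``.
    """

    n_beads: int
    n_chains: int = 200_000
    n_trial_directions: int = 32
    checkpoints: list[int] | None = None
    resample_trigger: float = 0.5
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trial_directions < 1:
            raise ValueError("need at least one trial direction")
        if self.checkpoints is not None:
            cps = list(self.checkpoints)
            if any(b <= a for a, b in zip(cps, cps[1:])):
                raise ValueError("checkpoints must be strictly increasing")
            if cps and cps[-1] > self.n_beads:
                raise ValueError("checkpoints cannot exceed n_beads")

    def resolved_checkpoints(self) -> list[int]:
        if self.checkpoints is not None:
            cps = list(self.checkpoints)
        else:
            step = max(1, math.ceil(self.n_beads / 20))
            cps = list(range(step, self.n_beads, step))
        if not cps or cps[-1] != self.n_beads:
            cps.append(self.n_beads)
        return cps


@dataclass
class NullContactMap:
    """Weighted random-collision contact probabilities from an ensemble."""

    p_null: np.ndarray
    n_effective: float
    params: PhysicalParams
    d_c: float = 80.0


def _empty_targets(n_beads: int):
    return (np.zeros(n_beads + 1, dtype=np.int64),
            np.zeros(0, dtype=np.int64),
            np.zeros(0, dtype=np.float64))


def _no_tether(n_beads: int):
    return np.zeros((n_beads, 3)), np.ones(n_beads)


def grow_chain(config: GrowthConfig, params: PhysicalParams,
               seed: int) -> Conformation:
    """Grow a single self-avoiding confined chain; weight is the
    Rosenbluth factor relative to K trials per step."""
    radius = params.radius
    if radius < params.bead_diameter_nm:
        raise ValueError("confinement radius smaller than one bead")
    n = config.n_beads
    coords = np.zeros((n, 3))
    indptr, idx, val = _empty_targets(n)
    tc, ts2 = _no_tether(n)
    t, dlogw = _growth.grow_segment(
        coords, 0, n, params.bead_diameter_nm, radius,
        config.n_trial_directions, params.ligation_threshold_nm,
        indptr, idx, val, tc, ts2, False, int(seed) % (2 ** 31 - 1))
    if dlogw <= _growth.DEAD:
        raise ChainDeath(f"chain died at bead {t}")
    return Conformation(coords=coords, weight=float(np.exp(dlogw)),
                        rng_seed=int(seed))


def _grow_population(n_beads: int, config: GrowthConfig, params: PhysicalParams,
                     q_csr=None, tether=None, kind: str = "null") -> Ensemble:
    """Shared driver: grow a population segment by segment with checkpoint
    resampling. ``q_csr`` supplies per-pair contact-target terms (CSR by
    column) and ``tether`` optional per-bead Gaussian centers."""
    radius = params.radius
    if radius < params.bead_diameter_nm:
        raise ValueError("confinement radius smaller than one bead")
    N = config.n_chains
    coords = np.zeros((N, n_beads, 3))
    lengths = np.zeros(N, dtype=np.int64)
    logw = np.zeros(N)
    if q_csr is None:
        q_csr = _empty_targets(n_beads)
    indptr, idx, val = q_csr
    if tether is None:
        tc, ts2 = _no_tether(n_beads)
        use_tether = False
    else:
        tc, ts2 = tether
        use_tether = True

    seed_rng = np.random.default_rng(
        np.random.SeedSequence([int(config.master_seed) % (2 ** 31), 1]))
    resample_rng = np.random.default_rng(
        np.random.SeedSequence([int(config.master_seed) % (2 ** 31), 2]))

    n_resamples = 0
    for cp in config.resolved_checkpoints():
        seeds = seed_rng.integers(0, 2 ** 31 - 1, size=N)
        _growth.grow_population_segment(
            coords, lengths, logw, cp, params.bead_diameter_nm, radius,
            config.n_trial_directions, params.ligation_threshold_nm,
            indptr, idx, val, tc, ts2, use_tether, seeds)
        alive = logw > _growth.DEAD
        if not alive.any():
            raise ChainDeath("all chains died; confinement too tight for "
                             "this chain length / bead size")
        w_rel = np.zeros(N)
        w_rel[alive] = np.exp(logw[alive] - logw[alive].max())
        ess = w_rel.sum() ** 2 / (w_rel ** 2).sum()
        n_dead = N - int(alive.sum())
        # resample on degraded ESS or to replace dead chains; at the final
        # checkpoint only dead slots justify it (pure end-duplication would
        # add correlation without benefit)
        fire = (ess < config.resample_trigger * N or n_dead > 0) \
            if cp < n_beads else n_dead > 0
        if config.resample_trigger > 0 and fire:
            probs = w_rel / w_rel.sum()
            # systematic resampling preserves the total weight
            u0 = resample_rng.random()
            positions = (u0 + np.arange(N)) / N
            picks = np.searchsorted(np.cumsum(probs), positions)
            picks = np.clip(picks, 0, N - 1)
            coords = coords[picks].copy()
            lengths = lengths[picks].copy()
            total_logw = logsumexp(logw[alive])
            logw = np.full(N, total_logw - np.log(N))
            n_resamples += 1

    alive = logw > _growth.DEAD
    w = np.exp(logw[alive] - logw[alive].max())
    w = w / w.mean()
    confs = [Conformation(coords=coords[k], weight=float(wk))
             for k, wk in zip(np.nonzero(alive)[0], w)]
    return Ensemble(
        conformations=confs, params=params, kind=kind,
        provenance={
            "master_seed": int(config.master_seed),
            "n_chains_requested": N,
            "n_chains_alive": int(alive.sum()),
            "survival_fraction": float(alive.mean()),
            "n_resamples": n_resamples,
            "n_trial_directions": config.n_trial_directions,
        })


def build_null_ensemble(config: GrowthConfig, params: PhysicalParams) -> Ensemble:
    """Grow the null ensemble of random confined self-avoiding chains.

    Fully reproducible from ``config.master_seed``; chains that die
    between checkpoints are replaced by resampling, so the returned
    population retains (close to) the requested size.
    """
    return _grow_population(config.n_beads, config, params, kind="null")


def contact_probability(ensemble: Ensemble, d_c: float | None = None) -> NullContactMap:
    """Weighted contact frequencies: p(i,j) = sum_k I_k(i,j) w_k / sum_k w_k,
    with I_k = 1 iff beads i and j of chain k are within d_c."""
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    if d_c is None:
        d_c = ensemble.params.ligation_threshold_nm
    if d_c <= 0:
        raise ValueError("d_c must be positive")
    p = _growth.weighted_contact_map(ensemble.coords_array, ensemble.weights,
                                     float(d_c))
    return NullContactMap(p_null=p, n_effective=ensemble.effective_sample_size,
                          params=ensemble.params, d_c=float(d_c))
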