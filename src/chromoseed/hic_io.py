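"""Hi-C matrix input, balancing and propensity normalization.

Contact matrices are binned, symmetric count matrices over one genomic
region. Propensities rescale counts by the mean count of adjacent bins
(|i - j| = 1), so that immediately neighbouring loci — which are assumed
always able to form a ligation product — average to 1. All downstream
significance testing and ensemble construction operate on propensities,
never on raw counts, which removes library-depth effects.

Coordinates are 0-based, half-open throughout; BED input is converted to
bin indices on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomicBinning",
    "ContactMatrix",
    "PropensityMap",
    "read_contact_matrix",
    "write_contact_matrix",
    "ice_balance",
    "compute_propensity",
    "read_bed",
    "read_state_bed",
    "write_bedpe",
    "write_bedgraph",
]


@dataclass(frozen=True)
class GenomicBinning:
    """Uniform binning of one genomic region.

    Bin ``i`` covers ``[start + i*resolution, start + (i+1)*resolution)``.
    """

    chrom: str
    start: int
    resolution: int
    n_bins: int

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.n_bins < 2:
            raise ValueError("need at least 2 bins")
        if self.start < 0:
            raise ValueError("start must be non-negative")

    @property
    def end(self) -> int:
        return self.start + self.n_bins * self.resolution

    def bin_start(self, i: int) -> int:
        return self.start + i * self.resolution

    def bin_of(self, pos: int) -> int:
        """Bin index containing base-pair position ``pos`` (may be out of range)."""
        return (pos - self.start) // self.resolution

    @classmethod
    def from_region(cls, chrom: str, start: int, end: int, resolution: int) -> "GenomicBinning":
        n = (end - start) // resolution
        return cls(chrom=chrom, start=start, resolution=resolution, n_bins=n)


@dataclass
class ContactMatrix:
    """Symmetric binned Hi-C count matrix for one region."""

    binning: GenomicBinning
    counts: np.ndarray
    balanced: bool = False
    mask: np.ndarray | None = None  # True = bin excluded (low coverage)
    converged: bool = True

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.shape != (self.binning.n_bins, self.binning.n_bins):
            raise ValueError(
                f"counts shape {c.shape} does not match n_bins={self.binning.n_bins}"
            )
        if not np.allclose(c, c.T, rtol=0, atol=1e-8):
            raise ValueError("matrix not symmetric")
        if not np.all(np.isfinite(c)):
            raise ValueError("counts contain non-finite values")
        if (c < 0).any():
            raise ValueError("counts contain negative values")
        self.counts = c
        if self.mask is None:
            self.mask = np.zeros(self.binning.n_bins, dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.binning.n_bins


@dataclass
class PropensityMap:
    """Contact propensities: counts divided by the mean adjacent-bin count.

    ``p_obs(i, j) = C(i, j) / E_diag(1)`` where ``E_diag(1)`` is the mean
    count over non-masked pairs at genomic distance one bin. By
    construction the first off-diagonal averages to 1. Masked bins carry
    NaN rows/columns.
    """

    binning: GenomicBinning
    p_obs: np.ndarray
    e_diag1: float
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.zeros(self.binning.n_bins, dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.binning.n_bins


def read_contact_matrix(path, format: str, binning: GenomicBinning) -> ContactMatrix:
    """Read a contact matrix from dense TSV or COO triplet TSV.

    COO rows are ``(bin_i, bin_j, count)`` with 0-based indices; the
    matrix is symmetrized by mirroring each triplet. Dense input must be
    symmetric already.
    """
    n = binning.n_bins
    if format == "dense-tsv":
        counts = np.loadtxt(path, delimiter="\t", ndmin=2)
        if counts.shape != (n, n):
            raise ValueError(f"dense matrix shape {counts.shape}, expected {(n, n)}")
        return ContactMatrix(binning=binning, counts=counts)
    if format == "coo-triplet":
        counts = np.zeros((n, n))
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["i", "j", "count"])
        for line_no, row in enumerate(df.itertuples(index=False), start=1):
            i, j, c = int(row.i), int(row.j), float(row.count)
            if c < 0:
                raise ValueError(f"negative count at line {line_no}")
            if i >= n or j >= n or i < 0 or j < 0:
                raise ValueError(f"bin index out of range at line {line_no}")
            counts[i, j] += c
            if i != j:
                counts[j, i] += c
        return ContactMatrix(binning=binning, counts=counts)
    raise ValueError(f"unknown format {format!r}")


def write_contact_matrix(matrix: ContactMatrix, path, format: str = "dense-tsv") -> None:
    if format == "dense-tsv":
        np.savetxt(path, matrix.counts, delimiter="\t", fmt="%.10g")
    elif format == "coo-triplet":
        i, j = np.nonzero(np.triu(matrix.counts))
        df = pd.DataFrame({"i": i, "j": j, "count": matrix.counts[i, j]})
        df.to_csv(path, sep="\t", header=False, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def ice_balance(matrix: ContactMatrix, max_iter: int = 200, tol: float = 1e-5,
                mask_quantile: float = 0.02) -> ContactMatrix:
    """Iterative correction (matrix balancing) of a raw contact matrix.

    Rows/columns are rescaled until every non-masked marginal is within
    ``tol`` (relative) of the mean marginal. Bins with zero raw marginal,
    or below the ``mask_quantile`` quantile of positive marginals, are
    masked and excluded from balancing.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    c = matrix.counts.copy()
    marg = c.sum(axis=1)
    mask = marg == 0
    positive = marg[~mask]
    if mask_quantile > 0 and positive.size:
        cut = np.quantile(positive, mask_quantile)
        mask |= marg < cut
    if mask.all():
        raise ValueError("all bins masked; matrix has no usable coverage")
    work = c.copy()
    work[mask, :] = 0.0
    work[:, mask] = 0.0
    converged = False
    for _ in range(max_iter):
        s = work.sum(axis=1)
        s_valid = s[~mask]
        mean = s_valid.mean()
        if mean == 0:
            raise ValueError("matrix sums to zero on non-masked bins")
        rel = s_valid / mean
        if np.abs(rel - 1).max() < tol:
            converged = True
            break
        b = np.ones_like(s)
        b[~mask] = rel
        work /= np.outer(b, b)
    if not converged:
        warnings.warn("ICE did not converge within max_iter", RuntimeWarning)
    # keep overall scale comparable to the input
    scale = c[~mask][:, ~mask].sum() / max(work[~mask][:, ~mask].sum(), 1e-300)
    work *= scale
    return ContactMatrix(binning=matrix.binning, counts=work, balanced=True,
                         mask=mask, converged=converged)


def compute_propensity(matrix: ContactMatrix) -> PropensityMap:
    """Normalize counts by the mean adjacent-bin count (``E_diag(1)``)."""
    c = matrix.counts
    n = matrix.n_bins
    mask = matrix.mask
    idx = np.arange(n - 1)
    keep = ~(mask[idx] | mask[idx + 1])
    adj = c[idx[keep], idx[keep] + 1]
    if adj.size == 0 or adj.mean() == 0:
        raise ValueError("no adjacent-bin signal; cannot normalize")
    e1 = float(adj.mean())
    p = c / e1
    p[mask, :] = np.nan
    p[:, mask] = np.nan
    return PropensityMap(binning=matrix.binning, p_obs=p, e_diag1=e1, mask=mask.copy())


# ---------------------------------------------------------------------------
# interval / pair formats


def read_bed(path) -> pd.DataFrame:
    """Read a BED file (first 3+ columns); returns chrom/start/end [/name]."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = cols + list(df.columns[len(cols):])
    return df


def read_state_bed(path, binning: GenomicBinning,
                   default: str = "U") -> np.ndarray:
    """Read a chromatin-state BED (name column in {A, I, P, U}) into a
    per-bin state array; uncovered bins get ``default``."""
    df = read_bed(path)
    states = np.full(binning.n_bins, default, dtype="<U1")
    for row in df.itertuples(index=False):
        if row.chrom != binning.chrom:
            continue
        lo = max(binning.bin_of(int(row.start)), 0)
        hi = min(binning.bin_of(int(row.end) - 1) + 1, binning.n_bins)
        if hi > lo:
            states[lo:hi] = str(row.name)[0]
    return states


def write_bedpe(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(binning: GenomicBinning, values: np.ndarray, path) -> None:
    starts = binning.start + np.arange(binning.n_bins) * binning.resolution
    df = pd.DataFrame({
        "chrom": binning.chrom,
        "start": starts,
        "end": starts + binning.resolution,
        "value": values,
    })
    df.to_csv(path, sep="\t", header=False, index=False)
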