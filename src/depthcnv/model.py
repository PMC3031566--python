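"""Negative-binomial read-depth model.

Bin counts of uniquely mapping short reads are overdispersed relative to
Poisson.  We model the count in a diploid bin as negative binomial with mean
``lam = n_reads * bin_size / genome_size`` and a variance-to-mean ratio (VMR)
``d``; the size parameter of the distribution is then ``mu / (d - 1)`` so
that the variance is ``d * mu``.  Copy-number classes 1, 2 and 3 have means
``lam/2``, ``lam`` and ``3*lam/2`` with the same VMR.

Integer read-count thresholds separating loss / neutral / gain are chosen to
minimise the mass of misclassified bins across the three class distributions,
and the model's false-discovery rate (FDR) is the total misclassified mass:
the expected number of miscalled bins per bin drawn from each class, summed
over the two class boundaries.  Because the FDR shrinks as bins grow (more
reads per bin separate the class distributions), the smallest bin size
meeting a target FDR can be located by bisection over a fixed search grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
from scipy import stats

__all__ = [
    "ModelParams",
    "CopyClassDistributions",
    "expected_reads_per_bin",
    "nbinom_pmf_class",
    "class_distribution",
    "optimize_thresholds",
    "select_bin_size",
    "BinSizeError",
]

#: Bin-size search grid: multiples of 100 bp.
GRID_STEP = 100
GRID_MIN = 100
GRID_MAX = 10_000_000

#: Upper quantile defining the truncation point of the count support.
SUPPORT_QUANTILE = 1.0 - 1e-9


class BinSizeError(ValueError):
    """No bin size on the search grid achieves the requested FDR."""

    def __init__(self, fdr_target: float, best_fdr: float):
        self.fdr_target = fdr_target
        self.best_fdr = best_fdr
        super().__init__(
            f"no bin size on the grid achieves FDR <= {fdr_target:g}; "
            f"best achievable FDR is {best_fdr:.3g} at bin size {GRID_MAX} bp"
        )


@dataclass
class ModelParams:
    """Fitted model parameters for one dataset.

    Attributes
    ----------
    n_reads, genome_size, bin_size:
        Inputs: uniquely mapping read count, (mappable) genome size in bases,
        and the bin size in bases.
    lam:
        Expected reads per diploid bin, ``n_reads * bin_size / genome_size``.
    vmr:
        Variance/mean ratio ``d`` (1 is the Poisson limit).
    fdr_target, fdr_achieved:
        Requested and achieved misclassification fractions.
    t_loss, t_gain:
        Integer count thresholds: a bin with count < t_loss is a loss, one
        with count > t_gain is a gain, anything else is neutral.
    """

    n_reads: int
    genome_size: float
    bin_size: int
    lam: float
    vmr: float
    fdr_target: float
    t_loss: int
    t_gain: int
    fdr_achieved: float

    def to_text(self) -> str:
        """Flat key=value serialisation used for provenance (`params.txt`)."""
        keys = (
            "n_reads genome_size bin_size lam vmr fdr_target "
            "t_loss t_gain fdr_achieved"
        ).split()
        return "\n".join(f"{k}={getattr(self, k)}" for k in keys) + "\n"

    def write(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_text())


@dataclass
class CopyClassDistributions:
    """Count distributions for copy-number classes 1, 2 and 3."""

    lam: float
    vmr: float
    means: tuple = field(init=False)
    support_max: int = field(init=False)

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.vmr < 1:
            raise ValueError("vmr must be >= 1 (1 is the Poisson limit)")
        self.means = (self.lam / 2.0, self.lam, 3.0 * self.lam / 2.0)
        q = [class_distribution(c, self.lam, self.vmr).ppf(SUPPORT_QUANTILE)
             for c in (1, 2, 3)]
        self.support_max = int(max(q))

    def frozen(self, copy_number: int):
        return class_distribution(copy_number, self.lam, self.vmr)


def expected_reads_per_bin(n_reads: float, bin_size: float,
                           genome_size: float) -> float:
    """Mean reads per diploid bin: ``n * b / g``."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    if n_reads < 0 or bin_size < 0:
        raise ValueError("n_reads and bin_size must be non-negative")
    return n_reads * bin_size / genome_size


def class_distribution(copy_number: int, lam: float, vmr: float):
    """Frozen scipy distribution of bin counts for one copy-number class.

    Negative binomial with mean ``mu = copy_number * lam / 2`` and size
    ``r = mu / (vmr - 1)`` (variance ``vmr * mu``); the Poisson distribution
    with mean ``mu`` in the limit ``vmr == 1``.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    if vmr < 1:
        raise ValueError("vmr must be >= 1")
    mu = copy_number * lam / 2.0
    if vmr == 1:
        return stats.poisson(mu)
    r = mu / (vmr - 1.0)
    p = r / (r + mu)  # scipy's nbinom success probability
    return stats.nbinom(r, p)


def nbinom_pmf_class(count, copy_number: int, lam: float, vmr: float):
    """pmf of the class distribution at ``count`` (vectorised)."""
    if np.any(np.asarray(count) < 0):
        raise ValueError("count must be non-negative")
    return class_distribution(copy_number, lam, vmr).pmf(count)


def _misclass_parts(lam: float, vmr: float):
    """Per-threshold misclassification mass for the loss and gain cuts.

    Returns ``(t_grid, L, G)`` where for threshold ``t``:

    * ``L[t] = P1(X >= t) + P2(X < t)``  — mass misclassified around t_loss
    * ``G[t] = P2(X > t) + P3(X <= t)``  — mass misclassified around t_gain

    The total misclassified mass of a pair ``(t_loss, t_gain)`` is
    ``L[t_loss] + G[t_gain]``; the two terms are separable, so each cut can
    be optimised on its own.
    """
    dists = CopyClassDistributions(lam, vmr)
    d1, d2, d3 = (dists.frozen(c) for c in (1, 2, 3))
    t = np.arange(0, dists.support_max + 2)
    # sf(t-1) = P(X >= t); cdf(t-1) = P(X < t); both exact (no truncation).
    L = d1.sf(t - 1) + d2.cdf(t - 1)
    G = d2.sf(t) + d3.cdf(t)
    return t, L, G


def _tie_break(cand_l: np.ndarray, cand_g: np.ndarray, lam: float):
    """Among tied optimal cuts pick the pair whose midpoint is closest to
    ``lam``, then the lexicographically smallest pair.

    At large ``lam`` the misclassification mass underflows to an exactly-flat
    minimum over long runs of thresholds, so the tie sets can hold thousands
    of candidates; for each loss cut only the gain cuts bracketing
    ``2*lam - t_loss`` can win, which keeps this linear in the tie-set size.
    """
    cand_l = np.sort(np.asarray(cand_l, dtype=np.int64))
    cand_g = np.sort(np.asarray(cand_g, dtype=np.int64))
    best = None
    for tl in cand_l:
        target = 2.0 * lam - tl
        j = np.searchsorted(cand_g, target)
        for tg in cand_g[max(0, j - 1):j + 1]:
            key = (abs((tl + tg) / 2.0 - lam), tl, tg)
            if best is None or key < best:
                best = key
    return int(best[1]), int(best[2])


def optimize_thresholds(lam: float, vmr: float):
    """Optimal integer loss/gain thresholds and the resulting FDR.

    Minimises the total misclassified probability mass of the CN{1,2,3}
    class distributions over all integer threshold pairs.  Classification
    rule: count < t_loss -> loss, count > t_gain -> gain, otherwise neutral.
    The FDR is the summed misclassified mass
    ``P1(X >= t_loss) + P2(X < t_loss) + P2(X > t_gain) + P3(X <= t_gain)``.

    Returns
    -------
    (t_loss, t_gain, fdr) : (int, int, float)
    """
    t, L, G = _misclass_parts(lam, vmr)
    cand_l = t[L == L.min()]
    cand_g = t[G == G.min()]
    t_loss, t_gain = _tie_break(cand_l, cand_g, lam)
    if t_loss >= t_gain:
        # Degenerate overlap (tiny lam): fall back to a constrained joint
        # search over pairs with t_loss < t_gain.
        total = L[:, None] + G[None, :]
        ii, jj = np.triu_indices(len(t), k=1)
        vals = total[ii, jj]
        best = vals.min()
        sel = vals == best
        t_loss, t_gain = _tie_break(np.unique(t[ii[sel]]),
                                    np.unique(t[jj[sel]]), lam)
        # re-pick jointly among the exact tied pairs
        pairs = [(int(a), int(b)) for a, b in zip(t[ii[sel]], t[jj[sel]])]
        pairs.sort(key=lambda p: (abs((p[0] + p[1]) / 2 - lam), p[0], p[1]))
        t_loss, t_gain = pairs[0]
    fdr = float(L[t_loss] + G[t_gain])
    return t_loss, t_gain, fdr


def achieved_fdr(n_reads: float, genome_size: float, bin_size: float,
                 vmr: float) -> float:
    """FDR achieved at a given bin size (helper for the bin-size search)."""
    lam = expected_reads_per_bin(n_reads, bin_size, genome_size)
    if lam <= 0:
        return 1.0
    return optimize_thresholds(lam, vmr)[2]


def select_bin_size(n_reads: float, genome_size: float, vmr: float = 3.0,
                    fdr_target: float = 0.01) -> ModelParams:
    """Smallest bin size on the search grid whose achieved FDR meets target.

    The grid is every multiple of 100 bp from 100 bp to 10 Mbp.  The achieved
    FDR is non-increasing in bin size (more reads per bin separate the
    classes), so the smallest admissible size is found by bisection.

    Raises
    ------
    BinSizeError
        If even the largest grid bin size exceeds ``fdr_target``.
    """
    if not (0.0 < fdr_target < 1.0):
        raise ValueError("fdr_target must be in (0, 1)")
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")

    grid_max = min(GRID_MAX, int(genome_size // GRID_STEP) * GRID_STEP)
    grid_max = max(grid_max, GRID_MIN)
    n_grid = (grid_max - GRID_MIN) // GRID_STEP + 1

    def fdr_at(idx: int) -> float:
        return achieved_fdr(n_reads, genome_size,
                            GRID_MIN + idx * GRID_STEP, vmr)

    # expand geometrically from the smallest bin size (cheap evaluations),
    # then bisect the admissibility boundary; fdr is non-increasing in the
    # bin size so this finds the smallest admissible grid point
    if fdr_at(0) <= fdr_target:
        hi = 0
    else:
        lo, hi = 0, 1
        while hi < n_grid - 1 and fdr_at(hi) > fdr_target:
            lo = hi
            hi = min(hi * 4, n_grid - 1)
        f_hi = fdr_at(hi)
        if f_hi > fdr_target:
            raise BinSizeError(fdr_target, f_hi)
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if fdr_at(mid) <= fdr_target:
                hi = mid
            else:
                lo = mid
    bin_size = GRID_MIN + hi * GRID_STEP
    lam = expected_reads_per_bin(n_reads, bin_size, genome_size)
    t_loss, t_gain, fdr = optimize_thresholds(lam, vmr)
    return ModelParams(
        n_reads=int(n_reads), genome_size=float(genome_size),
        bin_size=int(bin_size), lam=lam, vmr=vmr, fdr_target=fdr_target,
        t_loss=t_loss, t_gain=t_gain, fdr_achieved=fdr,
    )
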