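"""Bias correction of binned read depth.

Two corrections are applied, in this order:

1. **Mapability** — counts are divided by the fraction of uniquely mappable
   positions in the bin; bins below a mapability floor (default 25%) are
   masked rather than overcorrected.
2. **GC content** — bins are grouped by GC fraction in 0.1% increments, the
   mean mapability-corrected depth per group is smoothed with a locally
   weighted quadratic regression (LOESS), and each bin receives an additive
   correction ``median(depth) - fitted(gc)``.  Depths are then rescaled
   multiplicatively so the total unmasked depth is unchanged (the correction
   is neutral with respect to the total number of reads).

For bisulfite-converted libraries, the GC fraction itself is replaced by an
*effective* GC: unmethylated cytosines are read out as thymine, so each
cytosine contributes only its methylation fraction to the G+C tally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .depth import BinTrack, MethylationMap

__all__ = [
    "GcCurve",
    "mapability_correct",
    "gc_correct",
    "effective_gc",
    "loess_fit",
]

GC_INCREMENT = 0.001  # 0.1% GC groups
MIN_GC_GROUPS = 10
MIN_UNMASKED_BINS = 200


@dataclass
class GcCurve:
    """Depth-versus-GC relationship used for the correction."""

    gc_grid: np.ndarray      # occupied GC grid points (fractions)
    mean_depth: np.ndarray   # mean depth of bins in each group
    n_bins: np.ndarray       # bins per group (fit weights)
    fitted: np.ndarray       # LOESS-smoothed curve on gc_grid

    def predict(self, gc: np.ndarray) -> np.ndarray:
        """Fitted depth at arbitrary GC values (nearest occupied group)."""
        idx = np.searchsorted(self.gc_grid, gc)
        idx = np.clip(idx, 0, len(self.gc_grid) - 1)
        left = np.clip(idx - 1, 0, len(self.gc_grid) - 1)
        use_left = (np.abs(gc - self.gc_grid[left])
                    < np.abs(gc - self.gc_grid[idx]))
        return self.fitted[np.where(use_left, left, idx)]


def loess_fit(x: np.ndarray, y: np.ndarray, weights: Optional[np.ndarray]
              = None, span: float = 0.3, degree: int = 2) -> np.ndarray:
    """Locally weighted polynomial regression evaluated at the data points.

    Tricube kernel over the ``ceil(span * n)`` nearest neighbours, with
    optional multiplicative prior weights (here: bins per GC group).  This is
    the classic LOESS local fit without robustness iterations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    w_prior = np.ones(n) if weights is None else np.asarray(weights, float)
    q = max(degree + 1, int(np.ceil(span * n)))
    q = min(q, n)
    out = np.empty(n)
    order = np.argsort(x)
    xs, ys, ws = x[order], y[order], w_prior[order]
    for k, xi in enumerate(xs):
        d = np.abs(xs - xi)
        idx = np.argpartition(d, q - 1)[:q]
        h = d[idx].max()
        if h == 0:
            out[k] = np.average(ys[idx], weights=ws[idx])
            continue
        tw = (1 - (d[idx] / h) ** 3) ** 3
        tw = np.clip(tw, 0, None) * ws[idx]
        X = np.vander(xs[idx] - xi, degree + 1, increasing=True)
        W = np.sqrt(tw)
        try:
            beta, *_ = np.linalg.lstsq(X * W[:, None], ys[idx] * W,
                                       rcond=None)
            out[k] = beta[0]
        except np.linalg.LinAlgError:
            out[k] = np.average(ys[idx], weights=tw)
    inv = np.empty(n, dtype=int)
    inv[order] = np.arange(n)
    return out[inv]


def mapability_correct(track: BinTrack, min_map: float = 0.25) -> BinTrack:
    """Scale counts by inverse mapability; mask low-mapability bins.

    ``counts[i] /= mapability[i]`` where ``mapability[i] >= min_map``; bins
    with mapability below ``min_map`` are masked to prevent overcorrection.
    Already-masked bins stay masked and are not rescaled.
    """
    if track.mapability is None:
        raise ValueError("track has no mapability vector")
    out = track.copy()
    low = out.mapability < min_map
    ok = ~out.mask & ~low
    out.counts[ok] = out.counts[ok] / out.mapability[ok]
    out.mask |= low
    return out


def fit_gc_curve(track: BinTrack, span: float = 0.3, degree: int = 2,
                 increment: float = GC_INCREMENT) -> GcCurve:
    """Group unmasked bins by GC (0.1% default increments) and smooth the
    per-group mean depth with LOESS weighted by group occupancy."""
    ok = ~track.mask & np.isfinite(track.gc)
    gc = np.round(track.gc[ok] / increment).astype(np.int64)
    depth = track.counts[ok]
    groups, inverse = np.unique(gc, return_inverse=True)
    sums = np.bincount(inverse, weights=depth)
    counts = np.bincount(inverse)
    means = sums / counts
    grid = groups * increment
    fitted = loess_fit(grid, means, weights=counts, span=span, degree=degree)
    return GcCurve(gc_grid=grid, mean_depth=means, n_bins=counts,
                   fitted=fitted)


def gc_correct(track: BinTrack, span: float = 0.3,
               increment: float = GC_INCREMENT,
               min_groups: int = MIN_GC_GROUPS,
               min_bins: int = MIN_UNMASKED_BINS) -> BinTrack:
    """LOESS GC-bias correction, neutral with respect to total depth.

    Each unmasked bin receives the additive correction
    ``median(depth) - fitted(gc_bin)``; corrected depths are floored at zero
    and finally rescaled so that the total unmasked depth equals its
    pre-correction value.  With too little data to fit a curve (<10 occupied
    GC groups or <200 unmasked bins) the correction is the identity, with a
    warning.
    """
    if track.gc is None:
        raise ValueError("track has no gc vector")
    out = track.copy()
    ok = ~out.mask & np.isfinite(out.gc)
    if ok.sum() < min_bins or \
            len(np.unique(np.round(out.gc[ok] / increment))) < min_groups:
        warnings.warn(
            f"{track.chrom}: too few bins or GC groups for a GC fit; "
            "applying identity correction")
        return out
    curve = fit_gc_curve(out, span=span, increment=increment)
    depth = out.counts[ok]
    total_before = depth.sum()
    med = np.median(depth)
    corrected = depth + (med - curve.predict(out.gc[ok]))
    corrected = np.maximum(corrected, 0.0)
    total_after = corrected.sum()
    if total_after > 0:
        corrected *= total_before / total_after
    out.counts[ok] = corrected
    return out


def effective_gc(n_g: np.ndarray, n_c: np.ndarray, n_mappable: np.ndarray,
                 meth_frac_sum: np.ndarray, meth_n: np.ndarray,
                 mean_fraction: float) -> np.ndarray:
    """Methylation-adjusted GC fraction per bin for bisulfite libraries.

    Bisulfite treatment converts unmethylated cytosines to uracil (read as
    thymine) while methylated cytosines are protected, so a cytosine with
    methylation fraction ``m`` contributes ``m`` to the bin's G+C tally.
    Guanines are unaffected on the read strand and contribute fully.

    Parameters
    ----------
    n_g, n_c, n_mappable:
        Per-bin guanine, cytosine and total mappable-base counts.
    meth_frac_sum, meth_n:
        Per-bin sum of observed per-cytosine methylation fractions and the
        number of cytosines with an observation; cytosines absent from the
        methylation map contribute ``mean_fraction``.
    mean_fraction:
        Genome-wide mean methylation fraction.

    Returns the effective GC fraction, with NaN for bins having zero
    mappable bases (the caller should mask these).
    """
    n_g = np.asarray(n_g, float)
    n_c = np.asarray(n_c, float)
    n_mappable = np.asarray(n_mappable, float)
    meth_frac_sum = np.asarray(meth_frac_sum, float)
    meth_n = np.asarray(meth_n, float)
    if np.any(meth_n > n_c):
        raise ValueError("more observed cytosines than cytosines in bin")
    adjusted_c = meth_frac_sum + (n_c - meth_n) * mean_fraction
    with np.errstate(invalid="ignore", divide="ignore"):
        gc = (n_g + adjusted_c) / n_mappable
    gc = np.where(n_mappable > 0, gc, np.nan)
    return gc


def bin_base_composition(fasta_path, chrom: str, chrom_length: int,
                         bin_size: int):
    """Per-bin G, C and mappable-base (A/C/G/T, i.e. non-N) counts from a
    reference FASTA.  Ambiguity codes other than N are counted as mappable
    non-GC bases."""
    from pyfaidx import Fasta

    n_bins = -(-chrom_length // bin_size)
    n_g = np.zeros(n_bins, dtype=np.int64)
    n_c = np.zeros(n_bins, dtype=np.int64)
    n_map = np.zeros(n_bins, dtype=np.int64)
    with Fasta(str(fasta_path)) as fa:
        seq = str(fa[chrom][:chrom_length]).upper()
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    bins = np.arange(len(arr)) // bin_size
    n_g[:] = np.bincount(bins[arr == ord("G")], minlength=n_bins)[:n_bins]
    n_c[:] = np.bincount(bins[arr == ord("C")], minlength=n_bins)[:n_bins]
    n_map[:] = np.bincount(bins[arr != ord("N")], minlength=n_bins)[:n_bins]
    return n_g, n_c, n_map


def standard_gc(n_g, n_c, n_mappable) -> np.ndarray:
    """Plain GC fraction over mappable bases; NaN where none are mappable."""
    n_mappable = np.asarray(n_mappable, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        gc = (np.asarray(n_g, float) + np.asarray(n_c, float)) / n_mappable
    return np.where(n_mappable > 0, gc, np.nan)


def bin_methylation(meth: MethylationMap, chrom: str, chrom_length: int,
                    bin_size: int):
    """Aggregate a methylation map into per-bin (fraction sum, count)."""
    n_bins = -(-chrom_length // bin_size)
    frac = meth.fractions(chrom)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    if len(frac):
        bins = frac["pos"].to_numpy() // bin_size
        if bins.max() >= n_bins:
            raise ValueError(f"methylation record beyond {chrom} length")
        np.add.at(sums, bins, frac["fraction"].to_numpy())
        np.add.at(counts, bins, 1)
    return sums, counts
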