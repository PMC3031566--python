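"""Circular binary segmentation (CBS) and copy-number calling.

Corrected bin depths are segmented by recursive CBS: within each segment the
arc ``(i, j]`` maximising the circular two-sample t-statistic (arc versus the
rest of the segment, pooled segment variance) is located, and the split is
accepted when its permutation p-value falls below ``alpha``.  Segmentation
runs on ``log2(depth / median)`` (half-minimum pseudocount for zero bins),
which stabilises the variance across copy-number levels.

The permutation test is exact in its decisions: pruning uses a sound upper
bound on the maximal arc statistic (the range of the centred cumulative sums
bounds every arc sum), and early stopping only rejects a split once enough
permutation exceedances have accumulated that the full-permutation p-value
could not fall below ``alpha``.  Decisions therefore match a brute-force
scan of every permutation, at a fraction of the cost.

Masked bins are removed before segmentation and coordinates re-expanded
afterwards: a segment may span a masked gap, and gap bases stay inside the
genomic interval of the segment to their left.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .depth import BinTrack
from .model import ModelParams

__all__ = ["Segment", "cbs_segment", "segment_track", "call_segments",
           "log_ratio"]

#: number of small/large arc lengths scanned exactly per permutation before
#: the range bound takes over
_EXACT_K = 20
_PERM_BATCH = 128

try:  # JIT kernel for the exact fallback scan; pure-numpy path without it
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = None


def _scan_exceeds_py(S, m, w, k_lo, k_hi, cut):
    """Does any admissible arc with k in [k_lo, k_hi] reach |D| >= cut[k]?"""
    for k in range(k_lo, k_hi + 1):
        c = cut[k]
        n = m - k  # starts 0..n
        hi = m - w - k  # largest interior start
        i = 0
        while i <= n:
            if (i == 0 or i >= w) and (i == n or i <= hi):
                d = S[i + k] - S[i]
                if d >= c or -d >= c:
                    return True
                i += 1
            elif i < w:
                i = w
            else:
                i = n
    return False


if _njit is not None:
    _scan_exceeds = _njit(cache=False, fastmath=False)(_scan_exceeds_py)
else:  # pragma: no cover
    _scan_exceeds = _scan_exceeds_py


@dataclass
class Segment:
    """A genomic interval of constant copy number (0-based half-open)."""

    chrom: str
    start: int
    end: int
    n_bins: int
    mean_depth: float
    copy_number: float = float("nan")
    call: str = "neutral"

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty segment {self.chrom}:{self.start}-{self.end}")


def log_ratio(depth: np.ndarray) -> np.ndarray:
    """log2(depth / median) with half-minimum pseudocount for zero bins."""
    depth = np.asarray(depth, dtype=float)
    pos = depth[depth > 0]
    if pos.size == 0:
        return np.zeros_like(depth)
    floor = pos.min() / 2.0
    med = np.median(depth)
    if med <= 0:
        med = pos.min()
    return np.log2(np.maximum(depth, floor) / med)


def _arc_factor(m: int, k) -> float:
    return np.sqrt(m / (np.asarray(k, dtype=float) * (m - np.asarray(k))))


def _zero_invalid(absD: np.ndarray, m: int, k: int, w: int) -> None:
    """Zero arc starts violating the min-width flank constraint, in place.

    An arc (i, i+k] is admissible when each non-empty flank has at least
    ``w`` bins: i == 0 or i >= w, and i + k == m or i + k <= m - w.
    Works on the last axis of 1-D or 2-D arrays.
    """
    n = m - k + 1  # number of starts
    lo = min(w, n - 1)
    if lo > 1:
        absD[..., 1:lo] = 0.0
    hi = m - w - k + 1
    if hi < n - 1:
        absD[..., max(hi, 1):n - 1] = 0.0


def _max_arc_stat(x: np.ndarray, w: int) -> Optional[Tuple[float, int, int]]:
    """Exhaustive maximal circular arc t-statistic for one vector.

    Returns ``(t_max, i, j)`` for the best admissible arc ``(i, j]`` or None
    when no admissible arc exists or the vector is constant.
    """
    m = len(x)
    if m < 2 * w:
        return None
    sigma = float(np.std(x, ddof=1))
    if sigma == 0:
        return None
    S = np.empty(m + 1)
    S[0] = 0.0
    np.cumsum(x - x.mean(), out=S[1:])
    best = (-1.0, -1, -1)
    for k in range(w, m - w + 1):
        D = S[k:] - S[:-k]
        absD = np.abs(D)
        _zero_invalid(absD, m, k, w)
        i = int(np.argmax(absD))
        t = absD[i] * float(_arc_factor(m, k)) / sigma
        if t > best[0]:
            best = (float(t), i, i + k)
    if best[1] < 0:
        return None
    return best


def _perm_decision(x: np.ndarray, t_obs: float, w: int, alpha: float,
                   n_perm: int, rng: np.random.Generator) -> Tuple[bool, float]:
    """Permutation test of the maximal arc statistic.

    Returns ``(accept_split, p_value_estimate)``.  The accept/reject decision
    equals that of evaluating every one of the ``n_perm`` permutations
    exhaustively (see module docstring).
    """
    m = len(x)
    sigma = float(np.std(x, ddof=1))
    mu = float(x.mean())
    ks_all = np.arange(w, m - w + 1)
    if ks_all.size == 0:
        return False, 1.0
    # arc lengths scanned exactly on every permutation
    exact = ks_all[(ks_all < w + _EXACT_K) | (ks_all > m - w - _EXACT_K)]
    mid = ks_all[(ks_all >= w + _EXACT_K) & (ks_all <= m - w - _EXACT_K)]
    bound_factor = _arc_factor(m, mid).max() / sigma if mid.size else 0.0
    # per-k |arc sum| needed to reach t_obs (exact fallback cutoffs)
    cut = np.full(m + 1, np.inf)
    if mid.size:
        cut[mid] = t_obs * sigma / _arc_factor(m, mid)

    # unbiased p-value (count+1)/(n_perm+1): never zero, so a vanishing
    # alpha always degenerates to a single segment
    reject_at = alpha * (n_perm + 1) - 1  # count >= this => p >= alpha
    n_exceed = 0
    n_done = 0
    batch = 16  # grows; small first batches let null segments stop early
    while n_done < n_perm:
        b = min(batch, n_perm - n_done)
        batch = min(batch * 4, _PERM_BATCH * 4)
        X = rng.permuted(np.broadcast_to(x, (b, m)), axis=-1)
        S = np.zeros((b, m + 1))
        np.cumsum(X - mu, axis=1, out=S[:, 1:])
        peak = np.zeros(b)
        for k in exact:
            D = S[:, k:] - S[:, :-k]
            absD = np.abs(D)
            _zero_invalid(absD, m, int(k), w)
            np.maximum(peak, absD.max(axis=1)
                       * (float(_arc_factor(m, k)) / sigma), out=peak)
        exceeds = peak >= t_obs
        if mid.size:
            R = S.max(axis=1) - S.min(axis=1)
            rows = np.nonzero(~exceeds & (R * bound_factor >= t_obs))[0]
            for row in rows:
                if _scan_exceeds(np.ascontiguousarray(S[row]), m, w,
                                 int(mid[0]), int(mid[-1]), cut):
                    exceeds[row] = True
        n_exceed += int(exceeds.sum())
        n_done += b
        if n_exceed >= reject_at:
            return False, (n_exceed + 1) / (n_done + 1)
    p = (n_exceed + 1) / (n_perm + 1)
    return p < alpha, p


def cbs_segment(depth: Sequence[float], mask: Optional[np.ndarray] = None,
                alpha: float = 0.01, min_width: int = 2,
                n_perm: int = 1000, seed: int = 0) -> List[int]:
    """Recursive circular binary segmentation of one chromosome.

    Parameters
    ----------
    depth:
        Per-bin depth (corrected counts); segmentation itself operates on
        ``log2(depth / median)``.
    mask:
        Bins to exclude; they are removed before segmentation and breakpoint
        indices are re-expanded to the original coordinates afterwards.
    alpha:
        Permutation significance level required to accept a split.
    min_width:
        Minimum number of (unmasked) bins per resulting segment.
    n_perm, seed:
        Permutation count and RNG seed; output is deterministic given the
        seed.

    Returns
    -------
    list of int
        Sorted original bin indices at which a new segment starts (the
        index 0 is never included).
    """
    depth = np.asarray(depth, dtype=float)
    if mask is None:
        mask = np.zeros(len(depth), dtype=bool)
    keep = ~np.asarray(mask, dtype=bool)
    orig_idx = np.nonzero(keep)[0]
    x_full = log_ratio(depth[keep])
    m_full = len(x_full)
    if m_full == 0:
        return []
    ss = np.random.SeedSequence(seed)
    breakpoints: List[int] = []  # compacted indices
    stack = [(0, m_full)]
    while stack:
        s, e = stack.pop()
        x = x_full[s:e]
        found = _max_arc_stat(x, min_width)
        if found is None:
            continue
        t_obs, i, j = found
        rng = np.random.Generator(np.random.PCG64(ss.spawn(1)[0]))
        accept, _p = _perm_decision(x, t_obs, min_width, alpha, n_perm, rng)
        if not accept:
            continue
        cuts = [c for c in (i, j) if 0 < c < len(x)]
        parts = []
        prev = 0
        for c in cuts:
            breakpoints.append(s + c)
            parts.append((s + prev, s + c))
            prev = c
        parts.append((s + prev, e))
        # recurse deepest-first in deterministic order
        for part in reversed(parts):
            if part[1] - part[0] >= 2 * min_width:
                stack.append(part)
    breakpoints.sort()
    return [int(orig_idx[b]) for b in breakpoints]


def segment_track(track: BinTrack, alpha: float = 0.01, min_width: int = 2,
                  n_perm: int = 1000, seed: int = 0) -> List[Segment]:
    """Segment one BinTrack into genomic Segments with mean depths.

    Segments tile the unmasked extent of the chromosome: the first segment
    starts at the first unmasked bin, the last ends at the last unmasked
    bin, and interior boundaries sit at the start of the first bin of the
    following segment (masked gaps stay with the left segment).
    """
    keep = ~track.mask
    if not keep.any():
        return []
    bps = cbs_segment(track.counts, track.mask, alpha=alpha,
                      min_width=min_width, n_perm=n_perm, seed=seed)
    idx = np.nonzero(keep)[0]
    bounds = [int(idx[0])] + bps + [int(idx[-1]) + 1]
    segments = []
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        inside = idx[(idx >= b0) & (idx < b1)]
        start = int(track.bin_start(b0))
        end = int(track.bin_end(b1 - 1))
        segments.append(Segment(
            chrom=track.chrom, start=start, end=end, n_bins=len(inside),
            mean_depth=float(track.counts[inside].mean()),
        ))
    return segments


def call_segments(segments: List[Segment], params: ModelParams,
                  lam_diploid: Optional[float] = None,
                  altered_fraction: Optional[float] = None) -> List[Segment]:
    """Assign absolute copy numbers and gain/loss calls to segments.

    ``copy_number = 2 * mean_depth / lam_diploid`` where the diploid anchor
    is the genome-wide median unmasked corrected depth; when more than half
    of the genome is altered (``altered_fraction > 0.5``) the anchor falls
    back to the modelled ``lam``.  Calls apply the model's per-bin
    thresholds to the segment mean: gain if above ``t_gain``, loss if below
    ``t_loss``.
    """
    if lam_diploid is None:
        lam_diploid = params.lam
    if altered_fraction is not None and altered_fraction > 0.5:
        lam_diploid = params.lam
    if lam_diploid == 0:
        raise ValueError("diploid anchor depth is zero")
    out = []
    for s in segments:
        cn = 2.0 * s.mean_depth / lam_diploid
        if s.mean_depth > params.t_gain:
            call = "gain"
        elif s.mean_depth < params.t_loss:
            call = "loss"
        else:
            call = "neutral"
        out.append(Segment(chrom=s.chrom, start=s.start, end=s.end,
                           n_bins=s.n_bins, mean_depth=s.mean_depth,
                           copy_number=cn, call=call))
    return out


def diploid_anchor(tracks) -> float:
    """Genome-wide median unmasked depth across BinTracks."""
    vals = np.concatenate([t.counts[~t.mask] for t in tracks])
    if vals.size == 0:
        raise ValueError("no unmasked bins")
    return float(np.median(vals))
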