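"""Synthetic data generation and the sensitivity/specificity harness.

The generator reproduces the validation protocol used to characterise the
caller: a single chromosome is covered with bins whose counts are drawn from
the negative-binomial model at copy number 2 (VMR 3 by default), and one
copy-number alteration is seeded by drawing the bins inside a chosen
interval from the copy-number-3 (or 1) distribution.  The full pipeline is
run on each simulated track and a trial is scored as detected when both
edges of some gain/loss call match the seeded interval within one bin size;
any call failing that both-ends test is a false positive, and specificity
is one minus the fraction of trials with at least one false positive.

The generator works at bin level (it draws per-bin counts rather than
emitting individual reads) because the protocol is defined on distributions
of reads per region; an optional read-level emitter places uniform read
starts at the same density to exercise the I/O path end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .correction import gc_correct, mapability_correct
from .depth import BinTrack
from .model import ModelParams, select_bin_size
from .segmentation import Segment, call_segments, diploid_anchor, \
    segment_track

__all__ = ["TrialSpec", "TrialResult", "simulate_counts", "emit_reads",
           "score_trial", "run_trial", "run_trials"]

#: default chromosome length (a large human chromosome)
DEFAULT_CHROM_LENGTH = 247_000_000


@dataclass
class TrialSpec:
    """Parameters of one simulated trial."""

    chrom_length: int = DEFAULT_CHROM_LENGTH
    coverage: float = 0.5
    read_length: int = 76
    vmr: float = 3.0
    cna_start: int = 0
    cna_size: int = 2_000_000
    cna_copy_number: int = 3
    fdr_target: float = 0.01
    snap_to_bins: bool = True
    chrom: str = "chr1"

    @property
    def n_reads(self) -> int:
        return int(self.coverage * self.chrom_length / self.read_length)

    def model(self) -> ModelParams:
        return select_bin_size(self.n_reads, self.chrom_length,
                               vmr=self.vmr, fdr_target=self.fdr_target)


@dataclass
class TrialResult:
    """Outcome of scoring one trial against the seeded truth."""

    detected: bool
    n_false_positives: int
    called_edges: List[Tuple[int, int]] = field(default_factory=list)


def _nbinom_draw(rng: np.random.Generator, mu: float, vmr: float,
                 size: int) -> np.ndarray:
    if vmr == 1:
        return rng.poisson(mu, size).astype(float)
    r = mu / (vmr - 1.0)
    p = r / (r + mu)
    return rng.negative_binomial(r, p, size).astype(float)


def simulate_counts(spec: TrialSpec, seed: int,
                    params: Optional[ModelParams] = None):
    """Draw one simulated BinTrack plus its truth interval.

    Bin counts are negative binomial with mean ``c * lam / 2`` at the
    spec's VMR, ``c = 2`` outside the seeded alteration and
    ``c = cna_copy_number`` inside.  Mapability is 1.0 and GC flat by
    default (biases can be injected on the returned track).  The truth
    interval is snapped to bin boundaries unless ``snap_to_bins`` is off.

    Returns
    -------
    (track, truth, params) : (BinTrack, (start, end), ModelParams)
    """
    import warnings

    if params is None:
        params = spec.model()
    b = params.bin_size
    n_bins = -(-spec.chrom_length // b)
    rng = np.random.default_rng(seed)
    counts = _nbinom_draw(rng, params.lam, spec.vmr, n_bins)
    start, size = spec.cna_start, spec.cna_size
    if size < b:
        warnings.warn("seeded alteration smaller than one bin; "
                      "undetectable by construction")
    # edge bins are assigned by majority overlap (nearest bin boundary), so
    # in off-grid mode the depth signal changes within half a bin of the
    # true edge and the residual error is recoverable by breakpoint
    # refinement
    b0 = int(round(start / b))
    b1 = int(round((start + size) / b))
    if spec.snap_to_bins:
        truth = (b0 * b, min(b1 * b, spec.chrom_length))
    else:
        truth = (start, min(start + size, spec.chrom_length))
    if b1 > b0 and spec.cna_copy_number != 2:
        mu = spec.cna_copy_number * params.lam / 2.0
        counts[b0:b1] = _nbinom_draw(rng, mu, spec.vmr, b1 - b0)
    track = BinTrack(chrom=spec.chrom, bin_size=b,
                     chrom_length=spec.chrom_length, counts=counts,
                     mapability=np.ones(n_bins), gc=None)
    return track, truth, params


def emit_reads(track: BinTrack, seed: int) -> np.ndarray:
    """Place uniform read-start positions matching the per-bin counts.

    Exercises the binning I/O path: binning the returned positions at the
    track's bin size reproduces ``track.counts`` exactly.
    """
    rng = np.random.default_rng(seed)
    positions = []
    for i, c in enumerate(np.rint(track.counts).astype(int)):
        lo = int(track.bin_start(i))
        hi = int(track.bin_end(i))
        positions.append(rng.integers(lo, hi, size=c))
    return np.sort(np.concatenate(positions))


def score_trial(calls: Sequence[Segment], truth: Tuple[int, int],
                bin_size: int) -> TrialResult:
    """Score gain/loss calls against the seeded truth interval.

    A trial is detected when both edges of some call lie within one bin
    size of the corresponding truth edges; every call failing that
    both-ends test counts as one false positive.
    """
    detected = False
    n_fp = 0
    edges = []
    for c in calls:
        if c.call == "neutral":
            continue
        edges.append((c.start, c.end))
        if abs(c.start - truth[0]) <= bin_size and \
                abs(c.end - truth[1]) <= bin_size:
            detected = True
        else:
            n_fp += 1
    return TrialResult(detected=detected, n_false_positives=n_fp,
                       called_edges=edges)


def _auto_min_width(lam: float) -> int:
    # low coverage favours sensitivity (2); high coverage favours a low
    # false-positive rate (4)
    return 2 if lam < 100 else 4


def run_trial(spec: TrialSpec, seed: int,
              params: Optional[ModelParams] = None,
              alpha: float = 0.01, min_width: Optional[int] = None,
              n_perm: int = 1000) -> TrialResult:
    """Simulate one track, run the full pipeline on it, and score it."""
    track, truth, params = simulate_counts(spec, seed, params=params)
    track = mapability_correct(track)
    if track.gc is not None:
        track = gc_correct(track)
    if min_width is None:
        min_width = _auto_min_width(params.lam)
    segs = segment_track(track, alpha=alpha, min_width=min_width,
                         n_perm=n_perm, seed=seed)
    anchor = diploid_anchor([track])
    calls = call_segments(segs, params, lam_diploid=anchor)
    return score_trial([s for s in calls if s.call != "neutral"], truth,
                       params.bin_size)


def run_trials(spec: TrialSpec, n_trials: int, seed: int,
               alpha: float = 0.01, min_width: Optional[int] = None,
               n_perm: int = 1000) -> Tuple[float, float]:
    """Sensitivity and specificity over repeated seeded trials.

    Per-trial seeds are derived deterministically from the master seed, so
    identical master seeds give identical results.  Sensitivity is the
    fraction of trials detected; specificity is one minus the fraction of
    trials with one or more false-positive calls.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    params = spec.model()  # shared across trials; the spec fixes the design
    child_seeds = np.random.SeedSequence(seed).generate_state(n_trials) \
        % (2 ** 31)
    n_det = 0
    n_fp_trials = 0
    for ts in child_seeds:
        res = run_trial(spec, int(ts), params=params, alpha=alpha,
                        min_width=min_width, n_perm=n_perm)
        n_det += res.detected
        n_fp_trials += res.n_false_positives >= 1
    return n_det / n_trials, 1.0 - n_fp_trials / n_trials
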