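"""Input/output and binning.

Reads aligned read start positions (BED or SAM/BAM), annotation tracks
(bedGraph or fixed-step wiggle), per-cytosine methylation reports, and writes
segment calls as a SEG-style TSV.  All coordinates are 0-based half-open
internally; BED is native, and the SEG output is documented as such.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BinTrack",
    "MethylationMap",
    "load_reads",
    "bin_counts",
    "load_track",
    "load_methylation",
    "load_genome_file",
    "write_segments",
    "read_segments",
]


@dataclass
class BinTrack:
    """Per-chromosome fixed-size bin annotations.

    ``counts`` holds raw (later corrected) read counts, ``mapability`` the
    fraction of uniquely mappable positions per bin, ``gc`` the (effective)
    GC fraction, and ``mask`` marks bins excluded from all downstream
    statistics.  All vectors share length ``ceil(chrom_length / bin_size)``;
    a trailing partial bin is kept and flagged via ``partial_last``.
    """

    chrom: str
    bin_size: int
    chrom_length: int
    counts: np.ndarray
    mapability: Optional[np.ndarray] = None
    gc: Optional[np.ndarray] = None
    mask: np.ndarray = None

    def __post_init__(self):
        n = self.n_bins
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.counts) != n:
            raise ValueError(
                f"{self.chrom}: expected {n} bins, got {len(self.counts)}")
        if self.mask is None:
            self.mask = np.zeros(n, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        for name in ("mapability", "gc"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if len(v) != n:
                    raise ValueError(f"{self.chrom}: {name} length mismatch")
                setattr(self, name, v)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return -(-self.chrom_length // self.bin_size)

    @property
    def partial_last(self) -> bool:
        return self.chrom_length % self.bin_size != 0

    def copy(self) -> "BinTrack":
        return BinTrack(
            chrom=self.chrom, bin_size=self.bin_size,
            chrom_length=self.chrom_length, counts=self.counts.copy(),
            mapability=None if self.mapability is None else self.mapability.copy(),
            gc=None if self.gc is None else self.gc.copy(),
            mask=self.mask.copy(),
        )

    def bin_start(self, i) -> np.ndarray:
        return np.asarray(i) * self.bin_size

    def bin_end(self, i) -> np.ndarray:
        return np.minimum((np.asarray(i) + 1) * self.bin_size,
                          self.chrom_length)


@dataclass
class MethylationMap:
    """Per-cytosine methylation observations.

    One record per (chrom, 0-based position): the number of reads observing
    methylation at that cytosine and the total number of observations.
    """

    records: pd.DataFrame  # columns: chrom, pos, strand, n_meth, n_total

    def __post_init__(self):
        df = self.records
        if (df["n_meth"] > df["n_total"]).any():
            bad = df[df["n_meth"] > df["n_total"]].iloc[0]
            raise ValueError(
                f"n_methylated > n_total at {bad['chrom']}:{bad['pos']}")
        if (df["n_meth"] < 0).any() or (df["n_total"] < 0).any():
            raise ValueError("methylation counts must be non-negative")
        if df.duplicated(subset=["chrom", "pos"]).any():
            dup = df[df.duplicated(subset=["chrom", "pos"])].iloc[0]
            raise ValueError(
                f"duplicate methylation record at {dup['chrom']}:{dup['pos']}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def mean_fraction(self) -> float:
        """Genome-wide methylation fraction (total meth / total obs)."""
        tot = self.records["n_total"].sum()
        if tot == 0:
            return 0.0
        return float(self.records["n_meth"].sum() / tot)

    def fractions(self, chrom: str) -> pd.DataFrame:
        """Positions and per-cytosine methylation fractions for one chrom.

        Positions with zero observations get the genome-wide mean fraction.
        """
        sub = self.records[self.records["chrom"] == chrom]
        frac = np.where(sub["n_total"] > 0,
                        sub["n_meth"] / sub["n_total"].replace(0, 1),
                        self.mean_fraction)
        return pd.DataFrame({"pos": sub["pos"].to_numpy(),
                             "fraction": frac})


def load_genome_file(path: Union[str, Path]) -> Dict[str, int]:
    """Read a two-column 'genome file' (chrom<TAB>length) into a dict."""
    out: Dict[str, int] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{ln}: expected 'chrom length'")
        out[parts[0]] = int(parts[1])
    return out


def load_reads(path: Union[str, Path], fmt: Optional[str] = None,
               chrom_lengths: Optional[Dict[str, int]] = None,
               ) -> Dict[str, np.ndarray]:
    """Load uniquely-mapping read start positions, per chromosome, sorted.

    Parameters
    ----------
    path:
        BED file (chrom, start, end per line) or SAM/BAM alignment file.
    fmt:
        'bed', 'sam' or 'bam'; inferred from the file extension when None.
    chrom_lengths:
        Declared chromosome lengths.  Records on undeclared chromosomes are
        skipped with a warning.

    Unmapped or zero-length records are dropped; the number dropped is
    logged.  Positions are 0-based read start coordinates.
    """
    path = Path(path)
    if fmt is None:
        ext = path.suffix.lower().lstrip(".")
        fmt = ext if ext in ("bed", "bam", "sam") else "bed"
    if fmt == "bed":
        positions = _load_reads_bed(path)
    elif fmt in ("bam", "sam"):
        positions = _load_reads_alignment(path)
    else:
        raise ValueError(f"unsupported read format: {fmt!r}")
    out: Dict[str, np.ndarray] = {}
    for chrom, pos in positions.items():
        if chrom_lengths is not None and chrom not in chrom_lengths:
            warnings.warn(
                f"skipping {len(pos)} reads on undeclared chromosome "
                f"{chrom!r}")
            continue
        out[chrom] = np.sort(np.asarray(pos, dtype=np.int64))
    return out


def _load_reads_bed(path: Path) -> Dict[str, list]:
    positions: Dict[str, list] = {}
    n_dropped = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: malformed BED line")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise ValueError(f"{path}:{ln}: malformed BED line") from e
            if end <= start:
                n_dropped += 1
                continue
            positions.setdefault(parts[0], []).append(start)
    if n_dropped:
        logger.info("dropped %d zero-length records from %s", n_dropped, path)
    return positions


def _load_reads_alignment(path: Path) -> Dict[str, list]:
    import pysam

    positions: Dict[str, list] = {}
    n_dropped = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for rec in af.fetch(until_eof=True):
            if rec.is_unmapped or rec.reference_name is None:
                n_dropped += 1
                continue
            positions.setdefault(rec.reference_name, []).append(
                rec.reference_start)
    if n_dropped:
        logger.info("dropped %d unmapped records from %s", n_dropped, path)
    return positions


def bin_counts(positions: Sequence[int], chrom_length: int,
               bin_size: int) -> np.ndarray:
    """Count read starts per fixed-size bin (0-based half-open bins).

    A read is assigned to bin ``floor(start / bin_size)``.  The trailing
    partial bin (when ``chrom_length % bin_size != 0``) is kept.
    """
    if bin_size <= 0 or chrom_length <= 0:
        raise ValueError("bin_size and chrom_length must be positive")
    pos = np.asarray(positions, dtype=np.int64)
    n_bins = -(-chrom_length // bin_size)
    if pos.size == 0:
        return np.zeros(n_bins, dtype=np.int64)
    if pos.min() < 0 or pos.max() >= chrom_length:
        bad = pos[(pos < 0) | (pos >= chrom_length)][0]
        raise ValueError(
            f"read start {bad} outside chromosome of length {chrom_length}")
    return np.bincount(pos // bin_size, minlength=n_bins).astype(np.int64)


def _iter_track_intervals(path: Path):
    """Yield (chrom, start, end, value) from a bedGraph or fixed-step wiggle."""
    chrom, pos, step, span = None, None, None, 1
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom = fields["chrom"]
                pos = int(fields["start"]) - 1  # wiggle is 1-based
                step = int(fields.get("step", 1))
                span = int(fields.get("span", 1))
                continue
            parts = line.split()
            if len(parts) == 1 and chrom is not None:
                val = float(parts[0])
                yield ln, chrom, pos, pos + span, val
                pos += step
            elif len(parts) >= 4:
                yield ln, parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            else:
                raise ValueError(f"{path}:{ln}: malformed track line")


def load_track(path: Union[str, Path], chrom_lengths: Dict[str, int],
               bin_size: int):
    """Average a [0,1]-valued track (bedGraph / fixed-step wiggle) into bins.

    Interval values are averaged into bins weighted by the number of bases
    the interval covers inside the bin; bases not covered by any interval
    count as value 0.  Returns ``(values, covered)`` dicts per chromosome,
    where ``covered`` marks bins touched by at least one interval (fully
    uncovered bins should be masked by the caller).
    """
    path = Path(path)
    sums = {c: np.zeros(-(-L // bin_size)) for c, L in chrom_lengths.items()}
    covered = {c: np.zeros(-(-length // bin_size), dtype=bool)
               for c, length in chrom_lengths.items()}
    for ln, chrom, start, end, val in _iter_track_intervals(path):
        if not (0.0 <= val <= 1.0):
            raise ValueError(
                f"{path}:{ln}: track value {val} outside [0, 1]")
        if chrom not in chrom_lengths:
            continue
        end = min(end, chrom_lengths[chrom])
        if end <= start:
            continue
        b0, b1 = start // bin_size, (end - 1) // bin_size
        for b in range(b0, b1 + 1):
            lo = max(start, b * bin_size)
            hi = min(end, (b + 1) * bin_size)
            sums[chrom][b] += val * (hi - lo)
            covered[chrom][b] = True
    values = {}
    for chrom, L in chrom_lengths.items():
        widths = np.minimum(
            (np.arange(len(sums[chrom])) + 1) * bin_size, L) - \
            np.arange(len(sums[chrom])) * bin_size
        values[chrom] = sums[chrom] / widths
    return values, covered


def load_methylation(path: Union[str, Path]) -> MethylationMap:
    """Read a per-cytosine methylation report.

    Tab-separated columns: chrom, pos (0-based), strand, n_methylated,
    n_total.  A header line starting with 'chrom' is allowed.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["chrom", "pos", "strand", "n_meth", "n_total"],
        dtype={"chrom": str, "strand": str},
    )
    if len(df) and str(df.iloc[0]["pos"]).lower() in ("pos", "position"):
        df = df.iloc[1:].reset_index(drop=True)
    df["pos"] = df["pos"].astype(np.int64)
    df["n_meth"] = df["n_meth"].astype(np.int64)
    df["n_total"] = df["n_total"].astype(np.int64)
    return MethylationMap(df)


SEG_COLUMNS = ["chrom", "start", "end", "n_bins", "mean_depth",
               "copy_number", "call"]


def write_segments(segments: Iterable, path: Union[str, Path]) -> None:
    """Write segments as a SEG-style TSV (0-based half-open intervals)."""
    rows = []
    for s in segments:
        rows.append((s.chrom, int(s.start), int(s.end), int(s.n_bins),
                     float(s.mean_depth), float(s.copy_number), s.call))
    df = pd.DataFrame(rows, columns=SEG_COLUMNS)
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping segments on {chrom}")
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_segments(path: Union[str, Path]) -> List:
    """Read a SEG-style TSV back into Segment objects (round-trip reader)."""
    from .segmentation import Segment

    df = pd.read_csv(path, sep="\t")
    return [
        Segment(chrom=str(r.chrom), start=int(r.start), end=int(r.end),
                n_bins=int(r.n_bins), mean_depth=float(r.mean_depth),
                copy_number=float(r.copy_number), call=str(r.call))
        for r in df.itertuples()
    ]
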