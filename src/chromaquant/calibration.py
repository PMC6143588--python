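"""Spike-in calibrated ChIP-seq normalization and binned coverage tracks.

In a spike-in design a fixed amount of foreign-species chromatin (here a
``spike_`` chromosome namespace, standing in for a concatenated reference
genome) is added to every sample before immunoprecipitation.  Because the
spike-in amount is constant across samples, the per-sample factor that
equalizes spike-derived signal makes target-genome signal quantitatively
comparable across conditions.  A plain library-size mode (scale to a fixed
number of target-genome fragments, by default 10 million, or 1 million for
uncalibrated samples) is provided as well, since either normalization can be
selected per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .genomic_core import Fragment, GenomicInterval

__all__ = [
    "AssignmentCounts",
    "NormalizationFactor",
    "CoverageTrack",
    "count_genome_assignment",
    "normalization_factor",
    "coverage_track",
    "average_tracks",
    "write_bedgraph",
    "write_bigwig",
    "LIBRARY_REFERENCE_CALIBRATED",
    "LIBRARY_REFERENCE_UNCALIBRATED",
    "SPIKEIN_REFERENCE",
]

#: library-size reference counts: calibrated samples are scaled to 10 million
#: target fragments, uncalibrated (e.g. plain factor ChIP) to 1 million.
LIBRARY_REFERENCE_CALIBRATED = 10_000_000
LIBRARY_REFERENCE_UNCALIBRATED = 1_000_000
#: spike-in mode reference count (scaled spike fragments per sample).
SPIKEIN_REFERENCE = 1_000_000


@dataclass(frozen=True)
class AssignmentCounts:
    """Fragment counts after partitioning a concatenated-genome alignment
    into target-genome and spike-in-genome fragments."""

    n_target: int
    n_spike: int

    def __post_init__(self) -> None:
        if self.n_target < 0 or self.n_spike < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_target + self.n_spike


@dataclass(frozen=True)
class NormalizationFactor:
    """Per-sample multiplicative scaling applied to raw coverage."""

    sample_id: str
    mode: Literal["library", "spikein"]
    reference_count: int
    factor: float

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError(
                f"sample {self.sample_id!r}: factor must be > 0"
            )


def count_genome_assignment(
    fragments: Iterable[Fragment], spike_prefix: str
) -> AssignmentCounts:
    """Partition fragments by chromosome namespace: chromosomes whose name
    starts with *spike_prefix* belong to the spike-in genome."""
    if not spike_prefix:
        raise ValueError("spike_prefix must be non-empty")
    n_spike = 0
    n_total = 0
    for frag in fragments:
        n_total += 1
        if frag.chrom.startswith(spike_prefix):
            n_spike += 1
    return AssignmentCounts(n_target=n_total - n_spike, n_spike=n_spike)


def normalization_factor(
    counts: AssignmentCounts,
    mode: Literal["library", "spikein"],
    reference_count: int | None = None,
    sample_id: str = "",
) -> NormalizationFactor:
    """Compute the per-sample scaling factor.

    ``library`` mode: ``R / n_target`` with R defaulting to 10 million (use
    1 million for uncalibrated samples).  ``spikein`` mode: ``R / n_spike``
    with R defaulting to 1 million — after scaling, every sample carries the
    same total spike-derived signal, which is the calibration.
    """
    if mode == "library":
        R = LIBRARY_REFERENCE_CALIBRATED if reference_count is None \
            else reference_count
        denom = counts.n_target
        what = "target"
    elif mode == "spikein":
        R = SPIKEIN_REFERENCE if reference_count is None else reference_count
        denom = counts.n_spike
        what = "spike-in"
    else:
        raise ValueError(f"mode must be 'library' or 'spikein', got {mode!r}")
    if denom <= 0:
        raise ValueError(
            f"sample {sample_id or '<unnamed>'}: cannot normalize with zero "
            f"{what} fragments"
        )
    return NormalizationFactor(
        sample_id=sample_id, mode=mode, reference_count=R, factor=R / denom
    )


@dataclass
class CoverageTrack:
    """Binned, normalization-scaled per-base coverage over a genome.

    Each bin holds the *mean per-base* fragment coverage within the bin,
    multiplied by the sample's normalization factor.  Vector length per
    chromosome is ``ceil(length / bin_size)``; a partial last bin averages
    over the full ``bin_size`` so that total signal is conserved.
    """

    chrom_sizes: dict[str, int]
    bin_size: int
    data: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        for chrom, length in self.chrom_sizes.items():
            n_bins = -(-length // self.bin_size)
            if chrom not in self.data:
                self.data[chrom] = np.zeros(n_bins)
            elif len(self.data[chrom]) != n_bins:
                raise ValueError(
                    f"{chrom}: expected {n_bins} bins, "
                    f"got {len(self.data[chrom])}"
                )

    def same_binning(self, other: "CoverageTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and self.chrom_sizes == other.chrom_sizes
        )

    def total_signal(self, chroms: Sequence[str] | None = None) -> float:
        """Sum of bin values x bin_size (total scaled coverage-bp)."""
        chroms = list(self.data) if chroms is None else chroms
        return float(
            sum(self.data[c].sum() for c in chroms) * self.bin_size
        )

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        """Mean scaled per-base coverage over ``[start, end)``, clipped to
        the chromosome; the mean is over the clipped length.

        Approximates per-base coverage by each bin's mean, so it is exact
        whenever coverage is constant within bins.
        """
        if chrom not in self.data:
            raise KeyError(f"unknown chromosome {chrom!r}")
        start = max(start, 0)
        end = min(end, self.chrom_sizes[chrom])
        if end <= start:
            return 0.0
        values = self.data[chrom]
        bs = self.bin_size
        first, last = start // bs, (end - 1) // bs
        if first == last:
            return float(values[first])
        # overlap-weighted mean of the touched bins
        acc = values[first] * ((first + 1) * bs - start)
        acc += values[last] * (end - last * bs)
        if last - first > 1:
            acc += values[first + 1:last].sum() * bs
        return float(acc / (end - start))

    def integral(self, chrom: str, x0: float, x1: float) -> float:
        """Exact integral of the binned step function over ``[x0, x1)``
        (float bounds allowed), clipped to the chromosome."""
        if chrom not in self.data:
            raise KeyError(f"unknown chromosome {chrom!r}")
        values = self.data[chrom]
        bs = self.bin_size
        x0 = max(x0, 0.0)
        x1 = min(x1, float(self.chrom_sizes[chrom]))
        if x1 <= x0:
            return 0.0
        first = int(x0 // bs)
        last = int(np.ceil(x1 / bs)) - 1
        if first == last:
            return float(values[first] * (x1 - x0))
        acc = values[first] * ((first + 1) * bs - x0)
        acc += values[last] * (x1 - last * bs)
        if last - first > 1:
            acc += values[first + 1:last].sum() * bs
        return float(acc)

    def binned_means(
        self, chrom: str, start: int, end: int, n_bins: int
    ) -> np.ndarray:
        """Mean coverage in *n_bins* equal sub-intervals of ``[start, end)``:
        an exact, area-preserving proportional rescaling of the step
        function (the sum of bin means times the sub-interval width equals
        the integral over the whole span)."""
        edges = start + (end - start) * np.arange(n_bins + 1) / n_bins
        width = (end - start) / n_bins
        out = np.empty(n_bins)
        for i in range(n_bins):
            out[i] = self.integral(chrom, edges[i], edges[i + 1]) / width
        return out

    def scale(self, factor: float) -> "CoverageTrack":
        return CoverageTrack(
            dict(self.chrom_sizes),
            self.bin_size,
            {c: v * factor for c, v in self.data.items()},
        )


def coverage_track(
    fragments: Iterable[Fragment],
    chrom_sizes: Mapping[str, int],
    bin_size: int = 50,
    factor: float = 1.0,
) -> CoverageTrack:
    """Build a scaled binned coverage track from fragments.

    Bin value = (sum over fragments of overlap bp with the bin) / bin_size
    x factor.  Fragments are clipped to the chromosome; a fragment on a
    chromosome absent from *chrom_sizes* is an error.
    """
    track = CoverageTrack(dict(chrom_sizes), bin_size)
    # per-chromosome start/end event lists -> per-base diff -> binned sums
    starts: dict[str, list[int]] = {}
    ends: dict[str, list[int]] = {}
    for frag in fragments:
        if frag.chrom not in track.chrom_sizes:
            raise KeyError(
                f"fragment on unknown chromosome {frag.chrom!r}"
            )
        length = track.chrom_sizes[frag.chrom]
        s, e = max(frag.start, 0), min(frag.end, length)
        if e <= s:
            continue
        starts.setdefault(frag.chrom, []).append(s)
        ends.setdefault(frag.chrom, []).append(e)
    for chrom in starts:
        length = track.chrom_sizes[chrom]
        diff = np.zeros(length + 1)
        np.add.at(diff, np.asarray(starts[chrom]), 1.0)
        np.add.at(diff, np.asarray(ends[chrom]), -1.0)
        per_base = np.cumsum(diff[:-1])
        n_bins = len(track.data[chrom])
        padded = np.zeros(n_bins * bin_size)
        padded[:length] = per_base
        track.data[chrom] = (
            padded.reshape(n_bins, bin_size).sum(axis=1) / bin_size * factor
        )
    return track


def average_tracks(
    tracks: Sequence[CoverageTrack],
) -> tuple[CoverageTrack, CoverageTrack]:
    """Per-bin mean and standard error of the mean across replicates.

    SEM uses the sample standard deviation (ddof=1) divided by sqrt(n);
    replicate tracks must share chromosome sizes and bin size.
    """
    if len(tracks) < 2:
        raise ValueError("need >= 2 replicate tracks")
    first = tracks[0]
    for t in tracks[1:]:
        if not first.same_binning(t):
            raise ValueError("replicate tracks have mismatched binning")
    n = len(tracks)
    mean = CoverageTrack(dict(first.chrom_sizes), first.bin_size)
    sem = CoverageTrack(dict(first.chrom_sizes), first.bin_size)
    for chrom in first.data:
        stack = np.stack([t.data[chrom] for t in tracks])
        mean.data[chrom] = stack.mean(axis=0)
        sem.data[chrom] = stack.std(axis=0, ddof=1) / np.sqrt(n)
    return mean, sem


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write a 4-column 0-based half-open bedGraph, merging runs of equal
    value and omitting zero runs."""
    with open(path, "w") as handle:
        for chrom in track.data:
            values = track.data[chrom]
            length = track.chrom_sizes[chrom]
            bs = track.bin_size
            change = np.flatnonzero(np.diff(values)) + 1
            block_starts = np.concatenate(([0], change))
            block_ends = np.concatenate((change, [len(values)]))
            for b0, b1 in zip(block_starts, block_ends):
                value = values[b0]
                if value == 0:
                    continue
                handle.write(
                    f"{chrom}\t{b0 * bs}\t{min(b1 * bs, length)}"
                    f"\t{value:.6g}\n"
                )


def write_bigwig(track: CoverageTrack, path) -> None:
    """Optional bigWig export (requires :mod:`pyBigWig`)."""
    try:
        import pyBigWig
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("bigWig export requires pyBigWig") from exc
    bw = pyBigWig.open(str(path), "w")
    header = [(c, l) for c, l in track.chrom_sizes.items()]
    bw.addHeader(header)
    for chrom, _ in header:
        values = track.data[chrom]
        bs = track.bin_size
        length = track.chrom_sizes[chrom]
        starts = np.arange(len(values)) * bs
        ends = np.minimum(starts + bs, length)
        keep = values != 0
        if keep.any():
            bw.addEntries(
                [chrom] * int(keep.sum()),
                starts[keep].tolist(),
                ends=ends[keep].tolist(),
                values=values[keep].astype(float).tolist(),
            )
    bw.close()
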