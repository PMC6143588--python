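"""Strand-aware metagene matrices, averaged profiles and heatmap ordering.

Two matrix layouts are supported: the scaled layout (fixed-width flanks
around a gene body rescaled to a common number of bins — by default 5 kb
flanks, a 10 kb normalized body and 50 bp bins, i.e. 100 + 200 + 100 = 400
columns) and the TSS-centred layout (fixed window around the TSS,
optionally split by fragment strand into sense and antisense signal).
Rows of minus-strand genes are reversed so that column 0 is always the 5'
end.  Profiles winsorize each column at an upper quantile before averaging,
damping the contribution of outlier loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import CoverageTrack, coverage_track
from .genomic_core import Fragment, GeneModel

__all__ = [
    "MetageneMatrix",
    "MetageneProfile",
    "scaled_metagene_matrix",
    "tss_matrix",
    "metagene_profile",
    "sort_heatmap",
]


@dataclass
class MetageneMatrix:
    """Row-per-gene matrix of scaled coverage with a column layout.

    ``layout`` is ``(n_up, n_body, n_down)`` for scaled matrices or
    ``(n_tss,)`` for TSS-centred ones; columns are ordered 5' -> 3'.
    """

    row_ids: list[str]
    layout: tuple[int, ...]
    bin_size: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), sum(self.layout)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.row_ids)} rows x {sum(self.layout)} columns"
            )

    @property
    def n_columns(self) -> int:
        return sum(self.layout)

    def body_columns(self) -> slice:
        """Columns of the gene-body section (all columns for TSS layout)."""
        if len(self.layout) == 3:
            return slice(self.layout[0], self.layout[0] + self.layout[1])
        return slice(0, self.layout[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.row_ids, name="row_id")
        )

    def subset(self, row_ids: Sequence[str]) -> "MetageneMatrix":
        pos = {r: i for i, r in enumerate(self.row_ids)}
        idx = [pos[r] for r in row_ids]
        return MetageneMatrix(
            list(row_ids), self.layout, self.bin_size, self.values[idx]
        )


@dataclass
class MetageneProfile:
    """Per-column mean and standard error across rows."""

    layout: tuple[int, ...]
    mean: np.ndarray
    sem: np.ndarray

    def __post_init__(self) -> None:
        if len(self.mean) != sum(self.layout) or len(self.sem) != len(self.mean):
            raise ValueError("profile length does not match layout")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sem": self.sem})


def scaled_metagene_matrix(
    track: CoverageTrack,
    genes: Sequence[GeneModel],
    flank_up: int = 5000,
    flank_dn: int = 5000,
    region_size: int = 10000,
    bin_size: int = 50,
) -> MetageneMatrix:
    """Scaled metagene matrix over each gene's longest isoform.

    Upstream flank bins are fixed ``bin_size`` genomic bins 5' of the TSS;
    body bins map proportionally onto the TSS..TTS span (each normalized
    bin averages coverage over its genomic sub-interval, an area-preserving
    rescaling); downstream bins follow the TTS.  Minus-strand rows are
    computed on mirrored windows so column 0 is the 5' flank for every
    gene.  Flanks running past a chromosome end average over the clipped
    region only; genes shorter than one bin still yield finite rows.
    """
    for name, value in [
        ("flank_up", flank_up), ("flank_dn", flank_dn),
        ("region_size", region_size),
    ]:
        if value % bin_size != 0:
            raise ValueError(f"{name} must be divisible by bin_size")
    n_up = flank_up // bin_size
    n_body = region_size // bin_size
    n_dn = flank_dn // bin_size
    rows = np.empty((len(genes), n_up + n_body + n_dn))
    row_ids = []
    for gi, gene in enumerate(genes):
        t = gene.longest_transcript()
        row_ids.append(gene.gene_id)
        start, end = t.interval.start, t.interval.end
        up = np.empty(n_up)
        dn = np.empty(n_dn)
        if t.strand == "+":
            for k in range(n_up):
                a = start - flank_up + k * bin_size
                up[k] = track.mean_over(t.chrom, a, a + bin_size)
            body = track.binned_means(t.chrom, start, end, n_body)
            for k in range(n_dn):
                a = end + k * bin_size
                dn[k] = track.mean_over(t.chrom, a, a + bin_size)
        else:
            # mirrored: upstream flank sits right of the span, 5'->3' runs
            # right-to-left in genomic coordinates
            for k in range(n_up):
                b = end + flank_up - k * bin_size
                up[k] = track.mean_over(t.chrom, b - bin_size, b)
            body = track.binned_means(t.chrom, start, end, n_body)[::-1]
            for k in range(n_dn):
                b = start - k * bin_size
                dn[k] = track.mean_over(t.chrom, b - bin_size, b)
        rows[gi] = np.concatenate([up, body, dn])
    return MetageneMatrix(row_ids, (n_up, n_body, n_dn), bin_size, rows)


def _strand_tracks(
    fragments: Sequence[Fragment],
    chrom_sizes: Mapping[str, int],
    bin_size: int,
) -> tuple[CoverageTrack, CoverageTrack]:
    plus = [f for f in fragments if f.strand == "+"]
    minus = [f for f in fragments if f.strand == "-"]
    if len(plus) + len(minus) != len(fragments):
        raise ValueError(
            "sense/antisense profiling requires stranded fragments"
        )
    return (
        coverage_track(plus, chrom_sizes, bin_size),
        coverage_track(minus, chrom_sizes, bin_size),
    )


def tss_matrix(
    source: CoverageTrack | Sequence[Fragment],
    genes: Sequence[GeneModel],
    halfwidth: int = 5000,
    bin_size: int = 50,
    strand_mode: Literal["all", "sense", "antisense"] = "all",
    chrom_sizes: Mapping[str, int] | None = None,
) -> MetageneMatrix:
    """TSS-centred matrix: ``2 * halfwidth / bin_size`` columns oriented
    5' -> 3' around each gene's (longest isoform) TSS.

    *source* may be a prebuilt :class:`CoverageTrack` (``strand_mode="all"``
    only) or a list of fragments with *chrom_sizes*; ``sense``/``antisense``
    modes count only fragments on the same/opposite strand as the gene and
    require stranded fragments.
    """
    if halfwidth % bin_size != 0:
        raise ValueError("halfwidth must be divisible by bin_size")
    n_cols = 2 * halfwidth // bin_size
    if isinstance(source, CoverageTrack):
        if strand_mode != "all":
            raise ValueError(
                "sense/antisense modes need stranded fragments, not a track"
            )
        tracks = {"+": source, "-": source}
    else:
        if chrom_sizes is None:
            raise ValueError("chrom_sizes required with fragment input")
        if strand_mode == "all":
            track = coverage_track(source, chrom_sizes, bin_size)
            tracks = {"+": track, "-": track}
        else:
            plus, minus = _strand_tracks(source, chrom_sizes, bin_size)
            if strand_mode == "sense":
                tracks = {"+": plus, "-": minus}
            else:
                tracks = {"+": minus, "-": plus}
    rows = np.empty((len(genes), n_cols))
    row_ids = []
    for gi, gene in enumerate(genes):
        t = gene.longest_transcript()
        row_ids.append(gene.gene_id)
        track = tracks[t.strand]
        row = np.empty(n_cols)
        if t.strand == "+":
            for k in range(n_cols):
                a = t.tss - halfwidth + k * bin_size
                row[k] = track.mean_over(t.chrom, a, a + bin_size)
        else:
            for k in range(n_cols):
                b = t.tss + 1 + halfwidth - k * bin_size
                row[k] = track.mean_over(t.chrom, b - bin_size, b)
        rows[gi] = row
    return MetageneMatrix(row_ids, (n_cols,), bin_size, rows)


def metagene_profile(
    matrix: MetageneMatrix, exclude_p: float = 0.01
) -> MetageneProfile:
    """Average matrix rows into a profile with per-column winsorization.

    For each column, values above its ``1 - exclude_p`` quantile (linear
    interpolation) are capped at that quantile before the mean and SEM are
    taken; ``exclude_p=0`` gives plain column means.  SEM uses the sample
    standard deviation over rows divided by sqrt(n rows).
    """
    if matrix.values.shape[0] == 0:
        raise ValueError("matrix has no rows")
    if not 0 <= exclude_p < 1:
        raise ValueError("exclude_p must be in [0, 1)")
    values = matrix.values
    if exclude_p > 0:
        caps = np.quantile(values, 1 - exclude_p, axis=0)
        values = np.minimum(values, caps)
    n = values.shape[0]
    mean = values.mean(axis=0)
    sem = (
        values.std(axis=0, ddof=1) / np.sqrt(n)
        if n > 1
        else np.zeros_like(mean)
    )
    return MetageneProfile(matrix.layout, mean, sem)


def sort_heatmap(
    matrix: MetageneMatrix, key_matrix: MetageneMatrix
) -> list[str]:
    """Row ordering by descending mean of the key matrix's body columns,
    stable under ties; the ordering can be applied to *matrix* (and any
    sibling matrix) via :meth:`MetageneMatrix.subset`."""
    if matrix.row_ids != key_matrix.row_ids:
        raise ValueError("matrix and key matrix must share row ids")
    keys = key_matrix.values[:, key_matrix.body_columns()].mean(axis=1)
    order = np.argsort(-keys, kind="stable")
    return [matrix.row_ids[i] for i in order]
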