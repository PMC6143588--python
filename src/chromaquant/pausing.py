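"""Pol II pausing-index computation and between-genotype comparison.

The pausing index (PI) of a transcript is the ratio of read density in the
promoter window (200 bp upstream to 300 bp downstream of the TSS) to read
density in the gene-body window (300 bp downstream of the TSS to 1000 bp
downstream of the TTS).  For genes with multiple isoforms, the isoform
longer than 200 nt with the maximum PI represents the gene.  Density is
the count of fragment midpoints in the (chromosome-clipped) window divided
by the clipped window length; a 5'-end counting mode is available behind a
flag.  Genes with zero body-window counts have an undefined PI and are
excluded from distributions rather than assigned infinity.

Comparisons between genotypes use per-gene PI differences, empirical CDFs
and the Mann-Whitney U test (exact for small untied samples, normal
approximation with tie correction and continuity correction otherwise).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_core import (
    Fragment,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
    body_window,
    clip_to_chromosome,
    promoter_window,
)

__all__ = [
    "PausingRecord",
    "RankTestResult",
    "BoxplotSummary",
    "FragmentIndex",
    "window_density",
    "transcript_pausing_index",
    "gene_pausing_index",
    "pausing_table",
    "delta_pausing",
    "ecdf",
    "mann_whitney",
    "boxplot_summary",
]

logger = logging.getLogger(__name__)

#: minimum isoform length for the pausing analysis (strictly greater than).
MIN_ISOFORM_LENGTH = 200

CountMode = Literal["midpoint", "five_prime"]


@dataclass(frozen=True)
class PausingRecord:
    """Per-gene (or per-transcript) pausing index with its inputs.

    ``pausing_index`` is ``None`` when undefined (zero body density, empty
    clipped window, or no isoform passing the length filter).
    """

    gene_id: str
    transcript_id: str | None
    promoter_density: float | None
    body_density: float | None
    pausing_index: float | None

    @property
    def defined(self) -> bool:
        return self.pausing_index is not None


@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    p_value: float
    alternative: Literal["two_sided", "greater", "less"]
    n1: int
    n2: int
    method: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.statistic <= self.n1 * self.n2:
            raise ValueError("U must lie in [0, n1*n2]")
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value must lie in [0, 1]")


@dataclass(frozen=True)
class BoxplotSummary:
    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    n_outliers: int


class FragmentIndex:
    """Sorted per-chromosome midpoint / 5'-end positions for fast window
    counting (two binary searches per window)."""

    def __init__(self, fragments: Iterable[Fragment]) -> None:
        mids: dict[str, list[int]] = {}
        fives: dict[str, list[int]] = {}
        for frag in fragments:
            mids.setdefault(frag.chrom, []).append(frag.midpoint)
            fives.setdefault(frag.chrom, []).append(frag.five_prime)
        self._mid = {c: np.sort(np.asarray(v)) for c, v in mids.items()}
        self._five = {c: np.sort(np.asarray(v)) for c, v in fives.items()}

    def count(
        self, iv: GenomicInterval, mode: CountMode = "midpoint"
    ) -> int:
        table = self._mid if mode == "midpoint" else self._five
        if iv.chrom not in table:
            return 0
        positions = table[iv.chrom]
        return int(
            np.searchsorted(positions, iv.end, side="left")
            - np.searchsorted(positions, iv.start, side="left")
        )


def _as_index(
    fragments: Iterable[Fragment] | FragmentIndex,
) -> FragmentIndex:
    if isinstance(fragments, FragmentIndex):
        return fragments
    return FragmentIndex(fragments)


def window_density(
    fragments: Iterable[Fragment] | FragmentIndex,
    window: GenomicInterval,
    chrom_sizes: Mapping[str, int],
    mode: CountMode = "midpoint",
) -> float | None:
    """Fragment density in a window: positions inside the clipped window
    divided by the clipped length (fragments per bp).  ``None`` when the
    window clips to nothing."""
    clipped = clip_to_chromosome(window, chrom_sizes)
    if clipped is None:
        return None
    index = _as_index(fragments)
    return index.count(clipped, mode) / len(clipped)


def transcript_pausing_index(
    fragments: Iterable[Fragment] | FragmentIndex,
    t: TranscriptModel,
    chrom_sizes: Mapping[str, int],
    mode: CountMode = "midpoint",
) -> PausingRecord:
    """PI of one isoform: promoter density over body density.

    Isoforms of length <= 200 nt are filtered (record with all-``None``
    densities), zero body density makes the PI undefined, and zero promoter
    density with positive body density gives PI = 0.
    """
    if t.length <= MIN_ISOFORM_LENGTH:
        return PausingRecord(t.gene_id, t.transcript_id, None, None, None)
    index = _as_index(fragments)
    prom = window_density(index, promoter_window(t), chrom_sizes, mode)
    body = window_density(index, body_window(t), chrom_sizes, mode)
    if prom is None or body is None or body == 0:
        return PausingRecord(t.gene_id, t.transcript_id, prom, body, None)
    return PausingRecord(t.gene_id, t.transcript_id, prom, body, prom / body)


def gene_pausing_index(
    fragments: Iterable[Fragment] | FragmentIndex,
    g: GeneModel,
    chrom_sizes: Mapping[str, int],
    mode: CountMode = "midpoint",
) -> PausingRecord:
    """Gene-level PI: among isoforms longer than 200 nt with a defined PI,
    the record with the maximum PI; undefined if no isoform qualifies."""
    index = _as_index(fragments)
    best: PausingRecord | None = None
    for t in g.transcripts:
        record = transcript_pausing_index(index, t, chrom_sizes, mode)
        if record.defined and (
            best is None or record.pausing_index > best.pausing_index
        ):
            best = record
    if best is None:
        return PausingRecord(g.gene_id, None, None, None, None)
    return best


def pausing_table(
    samples: Mapping[str, Iterable[Fragment] | FragmentIndex],
    genes: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int],
    mode: CountMode = "midpoint",
) -> pd.DataFrame:
    """One row per (sample, gene) with the chosen isoform, densities and
    PI (NaN where undefined).  The number of PI-undefined genes per sample
    is logged."""
    if not samples:
        raise ValueError("need at least one sample")
    rows = []
    for sample_id, fragments in samples.items():
        index = _as_index(fragments)
        n_undefined = 0
        for gene in genes:
            record = gene_pausing_index(index, gene, chrom_sizes, mode)
            if not record.defined:
                n_undefined += 1
            rows.append(
                {
                    "sample": sample_id,
                    "gene_id": record.gene_id,
                    "transcript_id": record.transcript_id,
                    "promoter_density": record.promoter_density,
                    "body_density": record.body_density,
                    "pausing_index": record.pausing_index,
                }
            )
        logger.info(
            "sample %s: %d of %d genes have undefined pausing index",
            sample_id, n_undefined, len(genes),
        )
    return pd.DataFrame(rows).astype({"pausing_index": float})


def delta_pausing(
    table: pd.DataFrame, sample_a: str, sample_b: str
) -> pd.DataFrame:
    """Per-gene PI(b) - PI(a); only genes with a defined PI in both samples
    get a value, the rest are NaN-flagged."""
    pivot = table.pivot(
        index="gene_id", columns="sample", values="pausing_index"
    )
    for sample in (sample_a, sample_b):
        if sample not in pivot.columns:
            raise KeyError(f"sample {sample!r} not in table")
    delta = pivot[sample_b] - pivot[sample_a]
    return pd.DataFrame(
        {
            "gene_id": pivot.index,
            "delta_pi": delta.to_numpy(),
            "defined": (~delta.isna()).to_numpy(),
        }
    ).reset_index(drop=True)


def ecdf(values: Sequence[float]) -> "EmpiricalCDF":
    """Right-continuous empirical CDF, F(x) = #{values <= x} / n."""
    arr = np.asarray(
        [v for v in values if np.isfinite(v)], dtype=float
    )
    if arr.size == 0:
        raise ValueError("ecdf needs at least one finite value")
    return EmpiricalCDF(np.sort(arr))


class EmpiricalCDF:
    def __init__(self, sorted_values: np.ndarray) -> None:
        self.values = sorted_values
        self.n = len(sorted_values)

    def __call__(self, x):
        return np.searchsorted(self.values, x, side="right") / self.n

    def table(self) -> pd.DataFrame:
        """Evaluation table at the observed points."""
        uniq = np.unique(self.values)
        return pd.DataFrame({"x": uniq, "F": self(uniq)})


def _exact_mann_whitney_p(
    u: float, n1: int, n2: int, alternative: str
) -> float:
    """Exact p-value by full enumeration of the null distribution of U
    (no ties).  Cheap for n1 + n2 <= 12: at most C(12, 6) = 924
    arrangements of ranks between the samples."""
    from itertools import combinations

    n = n1 + n2
    us = []
    ranks = range(n)
    for combo in combinations(ranks, n1):
        r1 = sum(combo)
        us.append(r1 - n1 * (n1 - 1) / 2)
    us = np.asarray(us)
    if alternative == "greater":
        return float(np.mean(us >= u))
    if alternative == "less":
        return float(np.mean(us <= u))
    p = 2 * min(np.mean(us >= u), np.mean(us <= u))
    return float(min(p, 1.0))


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    alternative: Literal["two_sided", "greater", "less"] = "two_sided",
) -> RankTestResult:
    """Mann-Whitney U test of x against y.

    U is computed from midranks with tie correction.  The p-value is exact
    (full enumeration of rank assignments) when ``n1 + n2 <= 12`` and there
    are no ties, otherwise a normal approximation with tie-corrected
    variance and continuity correction is used.  If every value in both
    samples is identical the test is uninformative and p = 1 is returned
    with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.all(pooled == pooled[0]):
        warnings.warn(
            "all values identical across both samples; test uninformative",
            stacklevel=2,
        )
        return RankTestResult(
            n1 * n2 / 2, 1.0, alternative, n1, n2, method="degenerate"
        )
    ranks = stats.rankdata(pooled)  # midranks
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    if not has_ties and n1 + n2 <= 12:
        p = _exact_mann_whitney_p(u1, n1, n2, alternative)
        method = "exact"
    else:
        scipy_alt = {"two_sided": "two-sided", "greater": "greater",
                     "less": "less"}[alternative]
        _, p = stats.mannwhitneyu(
            x, y, alternative=scipy_alt, method="asymptotic",
            use_continuity=True,
        )
        p = float(p)
        method = "normal_approx"
    return RankTestResult(u1, p, alternative, n1, n2, method=method)


def boxplot_summary(values: Sequence[float]) -> BoxplotSummary:
    """Quartiles by linear interpolation and Tukey whiskers: the farthest
    data points within 1.5 x IQR beyond the quartiles; points beyond the
    whiskers are outliers."""
    arr = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if arr.size == 0:
        raise ValueError("boxplot_summary needs at least one finite value")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    return BoxplotSummary(
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        n_outliers=int(arr.size - inside.size),
    )
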