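"""Occupancy-based gene classification and expression grouping.

Two target-calling rules are provided, matching the two conventions used
for different factors: gene-body overlap (a peak overlapping the annotated
transcript span by at least 1 bp) and TSS-window containment (a peak fully
within the 10 kb region surrounding the TSS).  Genes are also split into
four equal-size expression groups (High / Intermediate / Low / No) by FPKM
rank.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .genomic_core import GeneModel, Peak

__all__ = [
    "OccupancyCall",
    "gene_body_targets",
    "tss_window_targets",
    "expression_groups",
    "occupancy_split",
    "EXPRESSION_GROUP_LABELS",
]

EXPRESSION_GROUP_LABELS = ("High", "Intermediate", "Low", "No")

Rule = Literal["gene_body_overlap", "tss_window_containment"]


@dataclass(frozen=True)
class OccupancyCall:
    gene_id: str
    is_target: bool
    rule: Rule
    supporting_peaks: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.is_target != bool(self.supporting_peaks):
            raise ValueError(
                f"{self.gene_id}: is_target must match supporting peak list"
            )


def _peaks_by_chrom(
    peaks: Sequence[Peak],
) -> dict[str, tuple[np.ndarray, np.ndarray, list[str], np.ndarray]]:
    """Per chromosome: peak starts (sorted), ends, names, and the running
    maximum of ends in start order (for overlap queries)."""
    index: dict[str, list[int]] = {}
    for i, peak in enumerate(peaks):
        index.setdefault(peak.chrom, []).append(i)
    out = {}
    for chrom, idx in index.items():
        idx.sort(key=lambda i: (peaks[i].start, peaks[i].end))
        starts = np.array([peaks[i].start for i in idx])
        ends = np.array([peaks[i].end for i in idx])
        names = [peaks[i].name for i in idx]
        out[chrom] = (starts, ends, names, np.maximum.accumulate(ends))
    return out


def _peaks_overlapping(
    index, chrom: str, start: int, end: int
) -> list[str]:
    """Names of peaks overlapping [start, end) by >= 1 bp (half-open)."""
    if chrom not in index:
        return []
    starts, ends, names, _ = index[chrom]
    lo = int(np.searchsorted(starts, end, side="left"))
    hits = [names[i] for i in range(lo) if ends[i] > start]
    return hits


def _peaks_contained(
    index, chrom: str, start: int, end: int
) -> list[str]:
    """Names of peaks fully within [start, end)."""
    if chrom not in index:
        return []
    starts, ends, names, _ = index[chrom]
    lo = int(np.searchsorted(starts, start, side="left"))
    hi = int(np.searchsorted(starts, end, side="left"))
    return [names[i] for i in range(lo, hi) if ends[i] <= end]


def gene_body_targets(
    genes: Sequence[GeneModel], peaks: Sequence[Peak]
) -> list[OccupancyCall]:
    """Call a gene a target iff at least one peak overlaps (>= 1 bp,
    half-open intersection) the genomic span of at least one isoform.

    The "gene body" here is the full TSS..TTS transcript span, not the
    offset windows used for the pausing index.
    """
    index = _peaks_by_chrom(peaks)
    calls = []
    for gene in genes:
        hits: dict[str, None] = {}
        for t in gene.transcripts:
            for name in _peaks_overlapping(
                index, t.chrom, t.interval.start, t.interval.end
            ):
                hits[name] = None
        calls.append(
            OccupancyCall(
                gene.gene_id,
                bool(hits),
                "gene_body_overlap",
                tuple(hits),
            )
        )
    return calls


def tss_window_targets(
    genes: Sequence[GeneModel],
    peaks: Sequence[Peak],
    halfwidth: int = 5000,
) -> list[OccupancyCall]:
    """Call a gene a target iff at least one peak is *entirely contained*
    in ``[tss - halfwidth, tss + halfwidth)`` of at least one isoform.
    Partial overlap with the window is not sufficient."""
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive")
    index = _peaks_by_chrom(peaks)
    calls = []
    for gene in genes:
        hits: dict[str, None] = {}
        for t in gene.transcripts:
            lo = max(t.tss - halfwidth, 0)
            for name in _peaks_contained(
                index, t.chrom, lo, t.tss + halfwidth
            ):
                hits[name] = None
        calls.append(
            OccupancyCall(
                gene.gene_id,
                bool(hits),
                "tss_window_containment",
                tuple(hits),
            )
        )
    return calls


def expression_groups(
    expression: pd.DataFrame,
    no_group: Literal["quartile", "fpkm_zero"] = "quartile",
) -> pd.DataFrame:
    """Split genes into four expression groups of near-equal size.

    Genes are sorted by FPKM descending (ties broken by gene_id ascending)
    and cut into contiguous rank blocks labelled High, Intermediate, Low,
    No; when sizes cannot be equal, earlier groups get the extra gene
    (n=9 -> 3,2,2,2).  With ``no_group="fpkm_zero"`` the No group is instead
    exactly the FPKM == 0 genes and the remaining genes are split into
    three near-equal rank blocks.

    Returns a DataFrame with columns gene_id, fpkm, group in input order.
    """
    if (expression["fpkm"] < 0).any():
        raise ValueError("FPKM values must be non-negative")
    order = expression.sort_values(
        ["fpkm", "gene_id"], ascending=[False, True], kind="stable"
    )
    gene_ids = order["gene_id"].tolist()
    n = len(gene_ids)
    group_of: dict[str, str] = {}
    if no_group == "quartile":
        ranked, labels = gene_ids, EXPRESSION_GROUP_LABELS
    elif no_group == "fpkm_zero":
        zero = set(expression.loc[expression["fpkm"] == 0, "gene_id"])
        for g in zero:
            group_of[g] = "No"
        ranked = [g for g in gene_ids if g not in zero]
        labels = EXPRESSION_GROUP_LABELS[:3]
    else:
        raise ValueError(f"unknown no_group scheme {no_group!r}")
    k = len(labels)
    m = len(ranked)
    base, rem = divmod(m, k)
    cursor = 0
    for j, label in enumerate(labels):
        size = base + (1 if j < rem else 0)
        for g in ranked[cursor:cursor + size]:
            group_of[g] = label
        cursor += size
    return pd.DataFrame(
        {
            "gene_id": expression["gene_id"],
            "fpkm": expression["fpkm"],
            "group": [group_of[g] for g in expression["gene_id"]],
        }
    )


def occupancy_split(
    genes: Sequence[GeneModel],
    peaks: Sequence[Peak],
    rule: Rule = "gene_body_overlap",
    halfwidth: int = 5000,
) -> tuple[set[str], set[str]]:
    """Partition genes into (high occupancy, low occupancy) gene-id sets:
    high = targets under *rule*, low = all remaining genes."""
    if rule == "gene_body_overlap":
        calls = gene_body_targets(genes, peaks)
    elif rule == "tss_window_containment":
        calls = tss_window_targets(genes, peaks, halfwidth=halfwidth)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    high = {c.gene_id for c in calls if c.is_target}
    low = {g.gene_id for g in genes} - high
    return high, low


def calls_to_frame(calls: Iterable[OccupancyCall]) -> pd.DataFrame:
    """Tabular form of occupancy calls for TSV export."""
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "rule": [c.rule for c in calls],
            "is_target": [c.is_target for c in calls],
            "n_peaks": [len(c.supporting_peaks) for c in calls],
            "peaks": [",".join(c.supporting_peaks) for c in calls],
        }
    )
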