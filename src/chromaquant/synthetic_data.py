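"""Synthetic annotation, fragments, peaks, expression and SILAC tables with
known ground truth.

The generator emulates a two-genotype (wild type vs double knockout)
chromatin experiment: genes of varying length and expression; RNA Pol II
ChIP fragments drawn from a promoter-peak + gene-body-uniform mixture with a
configurable per-condition pausing fraction; histone-acetylation fragments
as TSS-flanking peaks with condition-dependent amplitude; spike-in
fragments on a dedicated spike chromosome at sample-specific depth; truth
peaks for occupancy calling; and SILAC forward/reverse ratio tables with a
planted enriched subset.

Because the promoter mixture component is truncated to the promoter window
and the body component is uniform over the body window, the analytic
expectation of the pausing index is exact::

    PI(p, L) = (p / 500) / ((1 - p) / (L + 700)) = p (L + 700) / (500 (1 - p))

for pausing fraction p and transcript length L.  Every generator is fully
deterministic given the configuration seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_core import (
    Fragment,
    GeneModel,
    GenomicInterval,
    Peak,
    TranscriptModel,
    body_window,
    promoter_window,
)

__all__ = [
    "SimulationConfig",
    "simulate_annotation",
    "simulate_expression",
    "simulate_polII_fragments",
    "simulate_acetylation_fragments",
    "simulate_spikein_fragments",
    "truth_peaks",
    "simulate_silac_table",
    "expected_pausing_index",
    "build_truth_table",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic experiment.

    Defaults emulate the study conditions: wild type (``WT``) with a 0.30
    pausing fraction versus double knockout (``DKO``) with 0.45, increased
    TSS-flanking acetylation in the knockout, and a constant spike-in
    amount whose sequenced depth varies per sample.
    """

    seed: int = 0
    chrom_name: str = "chr1"
    chrom_length: int = 2_000_000
    spike_chrom_length: int = 200_000
    spike_prefix: str = "spike_"
    n_genes: int = 100
    gene_length_range: tuple[int, int] = (1_000, 8_000)
    intergenic_gap_min: int = 2_000
    second_isoform_fraction: float = 0.3
    pausing_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"WT": 0.30, "DKO": 0.45}
    )
    fragments_per_gene_scale: float = 20.0
    fragment_length: int = 200
    promoter_peak_offset: int = 50
    promoter_peak_sd: float = 60.0
    acetylation_amplitude: Mapping[str, float] = field(
        default_factory=lambda: {"WT": 1.0, "DKO": 1.6}
    )
    acetylation_fragments_per_gene: float = 30.0
    acetylation_background_fraction: float = 0.10
    acetylation_flank_offset: int = 500
    acetylation_flank_sd: float = 150.0
    spike_depth: Mapping[str, int] = field(
        default_factory=lambda: {"WT": 50_000, "DKO": 50_000}
    )

    def __post_init__(self) -> None:
        for cond, p in self.pausing_fraction.items():
            if not 0 <= p < 1:
                raise ValueError(
                    f"pausing_fraction[{cond!r}] must be in [0, 1), got {p}"
                )
        if self.gene_length_range[0] <= 200:
            raise ValueError("minimum gene length must exceed 200 bp")
        if self.gene_length_range[0] > self.gene_length_range[1]:
            raise ValueError("gene_length_range must be (min, max)")
        for name, value in [
            ("n_genes", self.n_genes),
            ("chrom_length", self.chrom_length),
            ("spike_chrom_length", self.spike_chrom_length),
            ("fragment_length", self.fragment_length),
            ("intergenic_gap_min", self.intergenic_gap_min),
        ]:
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        for cond, a in self.acetylation_amplitude.items():
            if a < 0:
                raise ValueError(
                    f"acetylation_amplitude[{cond!r}] must be >= 0"
                )

    @property
    def spike_chrom(self) -> str:
        return self.spike_prefix + "2L"


def _rng(cfg_seed: int, tag: str) -> np.random.Generator:
    """Independent, deterministic stream per (seed, operation) pair."""
    return np.random.default_rng([cfg_seed, zlib.crc32(tag.encode())])


def expected_pausing_index(p: float, L: int) -> float:
    """Analytic pausing index for the generator's mixture model.

    With fraction *p* of fragment midpoints spread over the 500 bp promoter
    window and 1 - p spread uniformly over the L + 700 bp body window, the
    promoter density is p/500 and the body density (1 - p)/(L + 700), so

        PI = p (L + 700) / (500 (1 - p)).
    """
    if not 0 <= p < 1:
        raise ValueError(f"p must be in [0, 1), got {p}")
    if L <= 200:
        raise ValueError(f"transcript length must exceed 200, got {L}")
    return p * (L + 700) / (500.0 * (1.0 - p))


# ---------------------------------------------------------------------------
# Annotation / expression
# ---------------------------------------------------------------------------


def simulate_annotation(
    cfg: SimulationConfig,
) -> tuple[list[GeneModel], dict[str, int]]:
    """Place non-overlapping genes on the target chromosome.

    Gene lengths are uniform in ``gene_length_range``; successive genes are
    separated by at least ``intergenic_gap_min`` (plus a random extra gap);
    strands are random.  A ``second_isoform_fraction`` of genes receive one
    shorter isoform sharing the TSS, exercising the max-pausing-index
    isoform rule downstream.  A margin of 10 kb at each chromosome end keeps
    analysis windows and metagene flanks on-chromosome.
    """
    rng = _rng(cfg.seed, "annotation")
    lo, hi = cfg.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=cfg.n_genes)
    margin = 10_000
    min_span = lengths.sum() + (cfg.n_genes - 1) * cfg.intergenic_gap_min
    avail = cfg.chrom_length - 2 * margin
    if min_span > avail:
        raise ValueError(
            f"{cfg.n_genes} genes need {min_span} bp but only {avail} bp "
            f"are available; increase chrom_length"
        )
    # distribute the slack as random extra gaps
    slack = avail - min_span
    extra = rng.multinomial(slack, np.ones(cfg.n_genes) / cfg.n_genes) \
        if slack > 0 else np.zeros(cfg.n_genes, dtype=int)
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    second = rng.random(cfg.n_genes) < cfg.second_isoform_fraction

    genes: list[GeneModel] = []
    cursor = margin
    width = len(str(cfg.n_genes))
    for i in range(cfg.n_genes):
        cursor += int(extra[i])
        start = cursor
        end = start + int(lengths[i])
        cursor = end + cfg.intergenic_gap_min
        gene_id = f"g{i:0{width}d}"
        strand = str(strands[i])
        iv = GenomicInterval(cfg.chrom_name, start, end, strand)
        transcripts = [TranscriptModel(f"{gene_id}.t1", gene_id, iv)]
        if second[i] and lengths[i] > 600:
            # shorter isoform sharing the TSS, still > 200 nt
            short_len = int(rng.integers(300, max(301, int(lengths[i] * 0.6))))
            if strand == "+":
                short_iv = GenomicInterval(
                    cfg.chrom_name, start, start + short_len, "+"
                )
            else:
                short_iv = GenomicInterval(
                    cfg.chrom_name, end - short_len, end, "-"
                )
            transcripts.append(
                TranscriptModel(f"{gene_id}.t2", gene_id, short_iv)
            )
        genes.append(GeneModel(gene_id, tuple(transcripts)))
    chrom_sizes = {
        cfg.chrom_name: cfg.chrom_length,
        cfg.spike_chrom: cfg.spike_chrom_length,
    }
    return genes, chrom_sizes


def simulate_expression(
    genes: Sequence[GeneModel], cfg: SimulationConfig
) -> pd.DataFrame:
    """Per-gene FPKM-like expression: 25% of genes silent (FPKM 0), the
    rest log-normal (median ~10 FPKM, about one decade of spread)."""
    if not genes:
        raise ValueError("genes must be non-empty")
    rng = _rng(cfg.seed, "expression")
    n = len(genes)
    n_zero = n // 4
    fpkm = np.exp(rng.normal(np.log(10.0), 1.0, size=n))
    silent = rng.choice(n, size=n_zero, replace=False)
    fpkm[silent] = 0.0
    return pd.DataFrame(
        {"gene_id": [g.gene_id for g in genes], "fpkm": fpkm}
    )


# ---------------------------------------------------------------------------
# Fragment generators
# ---------------------------------------------------------------------------


def _fragments_from_midpoints(
    midpoints: np.ndarray,
    chrom: str,
    strands: np.ndarray | Sequence[str],
    fragment_length: int,
) -> list[Fragment]:
    half = fragment_length // 2
    out = []
    for mid, strand in zip(midpoints, strands):
        start = int(mid) - half
        out.append(
            Fragment(
                GenomicInterval(
                    chrom, start, start + fragment_length, str(strand)
                )
            )
        )
    return out


def _truncated_normal(
    rng: np.random.Generator,
    centre: float,
    sd: float,
    low: int,
    high: int,
    size: int,
) -> np.ndarray:
    """Integer draws from N(centre, sd) truncated to [low, high) by
    rejection; falls back to uniform if the window has negligible mass."""
    out = np.empty(size, dtype=np.int64)
    filled = 0
    for _ in range(200):
        if filled >= size:
            break
        draw = rng.normal(centre, sd, size=max(size - filled, 16) * 2)
        draw = draw[(draw >= low) & (draw < high)]
        take = min(len(draw), size - filled)
        out[filled:filled + take] = np.floor(draw[:take]).astype(np.int64)
        filled += take
    if filled < size:  # pragma: no cover - pathological parameters
        out[filled:] = rng.integers(low, high, size=size - filled)
    return out


def simulate_polII_fragments(
    genes: Sequence[GeneModel],
    expression: pd.DataFrame,
    condition: str,
    cfg: SimulationConfig,
    fragments_per_gene: float | None = None,
) -> list[Fragment]:
    """RNA Pol II ChIP fragments from the promoter/body mixture.

    Per gene, ``Poisson(fragments_per_gene_scale x FPKM)`` fragments are
    generated (or a fixed expected count via *fragments_per_gene*).  Each
    fragment midpoint falls, with probability ``pausing_fraction[condition]``,
    in a truncated normal centred ``promoter_peak_offset`` bp downstream of
    the TSS (sd ``promoter_peak_sd``) restricted to the promoter window of
    the gene's longest isoform, and otherwise uniformly in the body window.
    Fragments carry the gene's strand and have fixed length centred on the
    midpoint.
    """
    p = cfg.pausing_fraction[condition]
    rng = _rng(cfg.seed, f"polII:{condition}")
    fpkm = dict(zip(expression["gene_id"], expression["fpkm"]))
    fragments: list[Fragment] = []
    for gene in genes:
        t = gene.longest_transcript()
        if fragments_per_gene is not None:
            n = int(rng.poisson(fragments_per_gene))
        else:
            n = int(rng.poisson(cfg.fragments_per_gene_scale
                                * fpkm.get(gene.gene_id, 0.0)))
        if n == 0:
            continue
        n_prom = int(rng.binomial(n, p))
        prom = promoter_window(t)
        body = body_window(t)
        mids = np.empty(n, dtype=np.int64)
        if t.strand == "+":
            centre = t.tss + cfg.promoter_peak_offset
        else:
            centre = t.tss - cfg.promoter_peak_offset
        mids[:n_prom] = _truncated_normal(
            rng, centre, cfg.promoter_peak_sd, prom.start, prom.end, n_prom
        )
        mids[n_prom:] = rng.integers(body.start, body.end, size=n - n_prom)
        fragments.extend(
            _fragments_from_midpoints(
                mids, gene.chrom, [t.strand] * n, cfg.fragment_length
            )
        )
    return fragments


def simulate_acetylation_fragments(
    genes: Sequence[GeneModel],
    expression: pd.DataFrame,
    condition: str,
    cfg: SimulationConfig,
    depth_factor: float = 1.0,
) -> list[Fragment]:
    """Histone-acetylation ChIP fragments: TSS-flanking double peak plus
    uniform background.

    Per expressed gene the signal budget is
    ``acetylation_fragments_per_gene x amplitude[condition] x depth_factor``
    midpoints drawn from two normals centred at TSS +/- 500 bp (sd 150 bp);
    an additional ``acetylation_background_fraction`` of the total signal is
    placed uniformly over the target chromosome.  *depth_factor* emulates
    per-sample sequencing depth and applies to signal and background alike
    (spike-in calibration is what removes it again).
    """
    a = cfg.acetylation_amplitude[condition]
    rng = _rng(cfg.seed, f"acetyl:{condition}:{depth_factor}")
    fpkm = dict(zip(expression["gene_id"], expression["fpkm"]))
    fragments: list[Fragment] = []
    n_signal_total = 0
    for gene in genes:
        if fpkm.get(gene.gene_id, 0.0) <= 0:
            continue
        t = gene.longest_transcript()
        n = int(rng.poisson(
            cfg.acetylation_fragments_per_gene * a * depth_factor
        ))
        if n == 0:
            continue
        n_signal_total += n
        side = rng.random(n) < 0.5
        centres = np.where(
            side,
            t.tss - cfg.acetylation_flank_offset,
            t.tss + cfg.acetylation_flank_offset,
        )
        mids = np.floor(
            rng.normal(centres, cfg.acetylation_flank_sd)
        ).astype(np.int64)
        np.clip(mids, 1_000, cfg.chrom_length - 1_000, out=mids)
        fragments.extend(
            _fragments_from_midpoints(
                mids, gene.chrom, ["."] * n, cfg.fragment_length
            )
        )
    n_bg = int(rng.poisson(
        cfg.acetylation_background_fraction * max(n_signal_total, 1)
    ))
    bg_mids = rng.integers(1_000, cfg.chrom_length - 1_000, size=n_bg)
    fragments.extend(
        _fragments_from_midpoints(
            bg_mids, cfg.chrom_name, ["."] * n_bg, cfg.fragment_length
        )
    )
    return fragments


def simulate_spikein_fragments(
    cfg: SimulationConfig, sample: str
) -> list[Fragment]:
    """Exactly ``spike_depth[sample]`` fragments uniform over the spike
    chromosome.  The spike-in amount is condition-independent by
    construction — the biological assumption behind calibration."""
    depth = cfg.spike_depth[sample]
    rng = _rng(cfg.seed, f"spike:{sample}")
    half = cfg.fragment_length // 2
    mids = rng.integers(
        half, cfg.spike_chrom_length - half, size=depth
    )
    return _fragments_from_midpoints(
        mids, cfg.spike_chrom, ["."] * depth, cfg.fragment_length
    )


def truth_peaks(
    genes: Sequence[GeneModel],
    occupancy_plan: Mapping[str, bool],
    n_distractors: int = 0,
    cfg: SimulationConfig | None = None,
) -> list[Peak]:
    """One peak inside the gene body of each planned target gene; optional
    intergenic distractor peaks (requires *cfg* for geometry/seed)."""
    peaks: list[Peak] = []
    for gene in genes:
        if not occupancy_plan.get(gene.gene_id, False):
            continue
        span = gene.span
        width = min(500, len(span) // 2)
        mid = (span.start + span.end) // 2
        peaks.append(
            Peak(
                GenomicInterval(
                    gene.chrom, mid - width // 2, mid + width // 2 + 1
                ),
                name=f"peak_{gene.gene_id}",
                score=100.0,
            )
        )
    if n_distractors:
        if cfg is None:
            raise ValueError("distractor peaks require a SimulationConfig")
        rng = _rng(cfg.seed, "distractor_peaks")
        spans = sorted(
            (g.span.start, g.span.end) for g in genes
        )
        placed = 0
        while placed < n_distractors:
            start = int(rng.integers(0, cfg.chrom_length - 400))
            iv = GenomicInterval(cfg.chrom_name, start, start + 400)
            if any(s < iv.end and iv.start < e for s, e in spans):
                continue
            peaks.append(Peak(iv, name=f"distractor_{placed}", score=10.0))
            placed += 1
    return peaks


def simulate_silac_table(
    n_proteins: int,
    n_enriched: int,
    effect_log2: float,
    noise_sd: float,
    seed: int,
) -> pd.DataFrame:
    """SILAC forward/reverse heavy/light ratio table with a planted
    methylation-enriched subset.

    Enriched proteins have oriented me3/unmod log2-ratios drawn from
    ``Normal(effect_log2, noise_sd)`` in both experiments, all others from
    ``Normal(0, noise_sd)``.  Raw ratios follow the label-swap convention:
    in the forward experiment the heavy extract met the modified bait, so
    ``ratio_forward_HL = 2**oriented``; in the reverse experiment labels are
    swapped, so ``ratio_reverse_HL = 2**(-oriented)``.
    """
    if n_enriched > n_proteins:
        raise ValueError("n_enriched must be <= n_proteins")
    if effect_log2 < 0:
        raise ValueError("effect_log2 must be >= 0")
    rng = np.random.default_rng([seed, zlib.crc32(b"silac")])
    enriched = np.zeros(n_proteins, dtype=bool)
    enriched[:n_enriched] = True
    mean = np.where(enriched, effect_log2, 0.0)
    oriented_fwd = rng.normal(mean, noise_sd)
    oriented_rev = rng.normal(mean, noise_sd)
    width = len(str(n_proteins))
    return pd.DataFrame(
        {
            "protein_id": [f"P{i:0{width}d}" for i in range(n_proteins)],
            "ratio_forward_HL": 2.0 ** oriented_fwd,
            "ratio_reverse_HL": 2.0 ** (-oriented_rev),
            "true_enriched": enriched,
        }
    )


# ---------------------------------------------------------------------------
# Ground truth assembly
# ---------------------------------------------------------------------------


def build_truth_table(
    genes: Sequence[GeneModel],
    expression: pd.DataFrame,
    condition: str,
    cfg: SimulationConfig,
    occupancy_plan: Mapping[str, bool] | None = None,
) -> pd.DataFrame:
    """Per-gene ground truth: expression, pausing fraction, analytic
    expected pausing index (longest isoform), occupancy label, and the
    rank-quartile expression group."""
    p = cfg.pausing_fraction[condition]
    fpkm = dict(zip(expression["gene_id"], expression["fpkm"]))
    rows = []
    order = expression.sort_values(
        ["fpkm", "gene_id"], ascending=[False, True]
    )["gene_id"].tolist()
    n = len(order)
    base, rem = divmod(n, 4)
    sizes = [base + (1 if k < rem else 0) for k in range(4)]
    labels = ["High", "Intermediate", "Low", "No"]
    group_of = {}
    cursor = 0
    for size, label in zip(sizes, labels):
        for g in order[cursor:cursor + size]:
            group_of[g] = label
        cursor += size
    for gene in genes:
        t = gene.longest_transcript()
        rows.append(
            {
                "gene_id": gene.gene_id,
                "fpkm": fpkm.get(gene.gene_id, 0.0),
                "pausing_fraction": p,
                "expected_pausing_index": expected_pausing_index(p, t.length),
                "occupancy": (
                    "target"
                    if occupancy_plan and occupancy_plan.get(gene.gene_id)
                    else "non-target"
                ),
                "expression_group": group_of.get(gene.gene_id, "No"),
            }
        )
    return pd.DataFrame(rows)
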