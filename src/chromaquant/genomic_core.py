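"""Genomic interval data model, BED/GTF/BED12 I/O, fragment deduplication,
and the promoter / gene-body windows used by the pausing-index analysis.

All coordinates are internally 0-based half-open (the BED convention); GTF's
1-based closed coordinates are converted on ingestion.  The transcription
start site (TSS) of a minus-strand transcript is ``end - 1`` — the TSS is a
base, not a boundary — and the same holds for the transcription termination
site (TTS) of a plus-strand transcript.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "GeneModel",
    "Fragment",
    "Peak",
    "read_bed",
    "write_bed",
    "read_gene_models",
    "write_bed12",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bam_fragments",
    "deduplicate_fragments",
    "promoter_window",
    "body_window",
    "clip_to_chromosome",
]

#: promoter window geometry: 200 bp upstream through 300 bp downstream of the
#: TSS base, in transcription direction (500 bp total).
PROMOTER_UPSTREAM = 200
PROMOTER_DOWNSTREAM = 300
#: gene-body window: from 300 bp downstream of the TSS to 1000 bp downstream
#: of the TTS, in transcription direction.
BODY_TSS_OFFSET = 300
BODY_TTS_EXTENSION = 1000

Strand = Literal["+", "-", "."]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded).  A negative
    ``start`` is tolerated so that analysis windows of genes near a
    chromosome edge can be represented before :func:`clip_to_chromosome`;
    coordinates read from files must be non-negative.
    """

    chrom: str
    start: int
    end: int
    strand: Strand = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the half-open intervals share >= 1 bp on the same chrom."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        """True iff *other* lies entirely within this interval."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class TranscriptModel:
    """One isoform: a stranded genomic span with derived TSS/TTS bases."""

    transcript_id: str
    gene_id: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(
                f"transcript {self.transcript_id!r} must be stranded"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def length(self) -> int:
        return len(self.interval)

    @property
    def tss(self) -> int:
        """Position of the first transcribed base."""
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1

    @property
    def tts(self) -> int:
        """Position of the last transcribed base."""
        if self.interval.strand == "+":
            return self.interval.end - 1
        return self.interval.start


@dataclass(frozen=True)
class GeneModel:
    """A gene with one or more isoforms sharing gene_id and chromosome."""

    gene_id: str
    transcripts: tuple[TranscriptModel, ...]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id!r} has no transcripts")
        chroms = {t.chrom for t in self.transcripts}
        if len(chroms) != 1:
            raise ValueError(
                f"gene {self.gene_id!r} spans chromosomes {sorted(chroms)}"
            )
        for t in self.transcripts:
            if t.gene_id != self.gene_id:
                raise ValueError(
                    f"transcript {t.transcript_id!r} has gene_id "
                    f"{t.gene_id!r}, expected {self.gene_id!r}"
                )

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def span(self) -> GenomicInterval:
        """Union interval of all isoforms (strand of the first isoform)."""
        return GenomicInterval(
            self.chrom,
            min(t.interval.start for t in self.transcripts),
            max(t.interval.end for t in self.transcripts),
            self.transcripts[0].strand,
        )

    def longest_transcript(self) -> TranscriptModel:
        """Longest isoform; ties broken by transcript_id for determinism."""
        return max(self.transcripts, key=lambda t: (t.length, t.transcript_id))


@dataclass(frozen=True)
class Fragment:
    """One deduplicable aligned fragment (a read pair's span)."""

    interval: GenomicInterval

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def midpoint(self) -> int:
        return (self.interval.start + self.interval.end) // 2

    @property
    def five_prime(self) -> int:
        """5' end base: start on + / unstranded, end - 1 on -."""
        if self.interval.strand == "-":
            return self.interval.end - 1
        return self.interval.start


@dataclass(frozen=True)
class Peak:
    """A called peak interval (consumed, never produced, by this package)."""

    interval: GenomicInterval
    name: str = "."
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(f"peak score must be >= 0, got {self.score}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


class BedParseError(ValueError):
    """Raised for malformed BED/GTF lines, naming the offending line."""


# ---------------------------------------------------------------------------
# Standard-format I/O
# ---------------------------------------------------------------------------


def _parse_bed_line(line: str, lineno: int) -> tuple[GenomicInterval, list[str]]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise BedParseError(
            f"line {lineno}: expected >= 3 tab-separated fields, "
            f"got {len(fields)}"
        )
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise BedParseError(
            f"line {lineno}: non-integer coordinates {fields[1]!r}, "
            f"{fields[2]!r}"
        ) from exc
    strand: Strand = "."
    if len(fields) >= 6 and fields[5] in ("+", "-"):
        strand = fields[5]  # type: ignore[assignment]
    if start < 0:
        raise BedParseError(f"line {lineno}: negative start {start}")
    try:
        iv = GenomicInterval(chrom, start, end, strand)
    except ValueError as exc:
        raise BedParseError(f"line {lineno}: {exc}") from exc
    return iv, fields


def read_bed(path, kind: Literal["fragment", "peak"] = "fragment"):
    """Read a BED3/BED6 file as a list of :class:`Fragment` or :class:`Peak`.

    Strand column 6 is honoured when present and valid, otherwise intervals
    are unstranded.  Lines starting with ``track``, ``browser`` or ``#`` are
    skipped.  Malformed data lines raise :class:`BedParseError` naming the
    line number.
    """
    if kind not in ("fragment", "peak"):
        raise ValueError(f"kind must be 'fragment' or 'peak', got {kind!r}")
    out = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            iv, fields = _parse_bed_line(line, lineno)
            if kind == "fragment":
                out.append(Fragment(iv))
            else:
                name = fields[3] if len(fields) >= 4 else "."
                score = 0.0
                if len(fields) >= 5 and fields[4] not in (".", ""):
                    score = float(fields[4])
                out.append(Peak(iv, name=name, score=score))
    return out


def write_bed(items: Iterable[Fragment | Peak], path) -> None:
    """Write fragments or peaks as BED6 (name ``.``/peak name, score 0/peak
    score).  Round-trips (chrom, start, end, strand) exactly."""
    with open(path, "w") as handle:
        for item in items:
            iv = item.interval
            if isinstance(item, Peak):
                name, score = item.name, item.score
            else:
                name, score = ".", 0
            handle.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}"
                f"\t{iv.strand}\n"
            )


def _group_transcripts(transcripts: list[TranscriptModel]) -> list[GeneModel]:
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    return [GeneModel(g, tuple(ts)) for g, ts in by_gene.items()]


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if " " in part:
            key, _, value = part.partition(" ")
            out[key] = value.strip().strip('"')
    return out


def read_gene_models(
    path, format: Literal["bed12", "gtf"] = "bed12"
) -> list[GeneModel]:
    """Read gene models from BED12 or GTF, grouped into :class:`GeneModel`.

    GTF ``transcript`` feature lines (1-based closed) are converted to
    0-based half-open on ingestion; for GTFs without explicit transcript
    features, exon lines are unioned per transcript.  BED12 uses column 4 as
    ``transcript_id`` (``gene|transcript`` splits on ``|``, else the gene is
    the transcript id).  A transcript without strand is an error; an empty
    file yields an empty list with a warning.
    """
    transcripts: list[TranscriptModel] = []
    if format == "bed12":
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                if not line.strip() or line.startswith(("track", "#")):
                    continue
                iv, fields = _parse_bed_line(line, lineno)
                if len(fields) < 6 or fields[5] not in ("+", "-"):
                    raise BedParseError(
                        f"line {lineno}: gene model requires a strand"
                    )
                name = fields[3] if len(fields) >= 4 else f"tx{lineno}"
                gene_id, _, tx_id = name.partition("|")
                transcripts.append(
                    TranscriptModel(tx_id or name, gene_id, iv)
                )
    elif format == "gtf":
        # exon fallback: (gene_id, transcript_id) -> [chrom, start, end, strand]
        exon_span: dict[tuple[str, str], list] = {}
        seen_transcript_feature: set[tuple[str, str]] = set()
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 9:
                    raise BedParseError(
                        f"line {lineno}: expected 9 GTF fields, "
                        f"got {len(fields)}"
                    )
                feature = fields[2]
                if feature not in ("transcript", "exon"):
                    continue
                if fields[6] not in ("+", "-"):
                    raise BedParseError(
                        f"line {lineno}: transcript without strand"
                    )
                try:
                    start = int(fields[3]) - 1  # 1-based closed -> half-open
                    end = int(fields[4])
                except ValueError as exc:
                    raise BedParseError(
                        f"line {lineno}: non-integer coordinates"
                    ) from exc
                attrs = _parse_gtf_attributes(fields[8])
                gene_id = attrs.get("gene_id", "")
                tx_id = attrs.get("transcript_id", gene_id)
                if not gene_id:
                    raise BedParseError(f"line {lineno}: missing gene_id")
                key = (gene_id, tx_id)
                if feature == "transcript":
                    seen_transcript_feature.add(key)
                    transcripts.append(
                        TranscriptModel(
                            tx_id,
                            gene_id,
                            GenomicInterval(fields[0], start, end, fields[6]),
                        )
                    )
                else:
                    span = exon_span.setdefault(
                        key, [fields[0], start, end, fields[6]]
                    )
                    span[1] = min(span[1], start)
                    span[2] = max(span[2], end)
        for (gene_id, tx_id), (chrom, start, end, strand) in exon_span.items():
            if (gene_id, tx_id) not in seen_transcript_feature:
                transcripts.append(
                    TranscriptModel(
                        tx_id, gene_id, GenomicInterval(chrom, start, end, strand)
                    )
                )
    else:
        raise ValueError(f"format must be 'bed12' or 'gtf', got {format!r}")

    if not transcripts:
        warnings.warn(f"no gene models found in {path}", stacklevel=2)
        return []
    return _group_transcripts(transcripts)


def write_bed12(genes: Iterable[GeneModel], path) -> None:
    """Write gene models as single-block BED12, one line per isoform,
    named ``gene_id|transcript_id``."""
    with open(path, "w") as handle:
        for gene in genes:
            for t in gene.transcripts:
                iv = t.interval
                handle.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}"
                    f"\t{gene.gene_id}|{t.transcript_id}\t0\t{iv.strand}"
                    f"\t{iv.start}\t{iv.end}\t0\t1"
                    f"\t{len(iv)},\t0,\n"
                )


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column ``chrom.sizes`` TSV (name, length)."""
    sizes: dict[str, int] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise BedParseError(
                    f"line {lineno}: expected 'chrom<TAB>length'"
                )
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as handle:
        for chrom, length in sizes.items():
            handle.write(f"{chrom}\t{length}\n")


def read_bam_fragments(path) -> list[Fragment]:
    """Optional BAM ingestion: properly paired reads collapse to one fragment
    per pair (leftmost start to rightmost end); single-end reads become
    fragments of read length.  Requires :mod:`pysam`."""
    try:
        import pysam
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "BAM ingestion requires pysam (install chromaquant[bam])"
        ) from exc
    fragments = []
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            strand = "-" if read.is_reverse else "+"
            if read.is_paired:
                if not read.is_proper_pair or not read.is_read1:
                    continue
                start = min(read.reference_start, read.next_reference_start)
                end = start + abs(read.template_length)
                # read1's mate orientation defines the fragment strand
                strand = "-" if read.template_length < 0 else "+"
            else:
                start, end = read.reference_start, read.reference_end
            fragments.append(
                Fragment(
                    GenomicInterval(read.reference_name, start, end, strand)
                )
            )
    return fragments


# ---------------------------------------------------------------------------
# Fragment deduplication and analysis windows
# ---------------------------------------------------------------------------


def deduplicate_fragments(fragments: Iterable[Fragment]) -> list[Fragment]:
    """Keep exactly one fragment per distinct (chrom, start, end, strand) key,
    preserving the input order of first occurrences.

    This is the fragment-level equivalent of PCR-duplicate removal on
    paired-end alignments: a duplicate read pair maps to the identical
    fragment span and strand.
    """
    seen: set[tuple[str, int, int, str]] = set()
    out: list[Fragment] = []
    for frag in fragments:
        key = (frag.chrom, frag.start, frag.end, frag.strand)
        if key not in seen:
            seen.add(key)
            out.append(frag)
    return out


def promoter_window(
    t: TranscriptModel,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> GenomicInterval:
    """Promoter window: *upstream* bp upstream through *downstream* bp
    downstream of the TSS base, in transcription direction — with the
    defaults, always exactly 500 bp before chromosome clipping.

    On the + strand this is ``[tss - 200, tss + 300)``; on the - strand,
    with the TSS at ``end - 1``, the mirror image ``[tss - 299, tss + 201)``.
    """
    tss = t.tss
    if t.strand == "+":
        start = tss - upstream
        end = tss + downstream
    else:
        start = tss - downstream + 1
        end = tss + upstream + 1
    return GenomicInterval(t.chrom, start, end, t.strand)


def body_window(
    t: TranscriptModel,
    tss_offset: int = BODY_TSS_OFFSET,
    tts_extension: int = BODY_TTS_EXTENSION,
) -> GenomicInterval:
    """Gene-body window: *tss_offset* (300) bp downstream of the TSS
    through *tts_extension* (1000) bp downstream of the TTS, in
    transcription direction — length L + 700 for a transcript of length L
    with the defaults.

    + strand: ``[start + 300, end + 1000)``; - strand:
    ``[start - 1000, end - 300)``.
    """
    iv = t.interval
    if t.strand == "+":
        return GenomicInterval(
            iv.chrom, iv.start + tss_offset, iv.end + tts_extension, "+"
        )
    return GenomicInterval(
        iv.chrom, iv.start - tts_extension, iv.end - tss_offset, "-"
    )


def clip_to_chromosome(
    iv: GenomicInterval, chrom_sizes: Mapping[str, int]
) -> GenomicInterval | None:
    """Intersect *iv* with ``[0, chrom length)``; ``None`` if empty.

    Unknown chromosomes are an error — silent clipping would mask a
    chromosome-naming mismatch between annotation and fragments.
    """
    if iv.chrom not in chrom_sizes:
        raise KeyError(f"unknown chromosome {iv.chrom!r}")
    start = max(iv.start, 0)
    end = min(iv.end, chrom_sizes[iv.chrom])
    if end <= start:
        return None
    return GenomicInterval(iv.chrom, start, end, iv.strand)
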