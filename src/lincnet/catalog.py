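"""Transcript catalogs: GTF I/O, interval indexing, novelty calls and distance utilities.

Coordinates are 0-based half-open internally; GTF is 1-based inclusive at the
boundary.  A transcript is an ordered list of disjoint exons on one chromosome
and strand; its "span" is the genomic interval from the first exon start to the
last exon end, and its spliced length is the sum of exon lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator

from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass
class TranscriptModel:
    """Exon-resolved transcript structure.

    ``exons`` are (start, end) tuples, sorted and pairwise disjoint, all on
    ``chrom``/``strand``.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript with no exons")
        exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        for s, e in exons:
            if not (0 <= s < e):
                raise ValueError(f"{self.transcript_id}: invalid exon [{s}, {e})")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(
                    f"{self.transcript_id}: overlapping exons [{s1},{e1}) and [{s2},{e2})"
                )
        object.__setattr__(self, "exons", exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(e - s for s, e in self.exons)

    @property
    def spliced_length(self) -> int:
        """Sum of exon lengths (the mature transcript length, not genomic span)."""
        return sum(self.exon_lengths)

    @property
    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        """Ordered (donor, acceptor) pairs; empty for single-exon transcripts."""
        return tuple((e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]))

    def tss(self) -> int:
        """Position of the first transcribed base (0-based).

        Span start on "+", span end − 1 on "−" (the last coordinate of the
        half-open span is the first base read by the polymerase).
        """
        if self.strand == "+":
            return self.start
        if self.strand == "-":
            return self.end - 1
        raise ValueError(f"{self.transcript_id}: TSS undefined for unstranded transcript")


def transcript_stats(t: TranscriptModel) -> tuple[int, tuple[int, ...], int]:
    """(exon count, exon lengths, spliced transcript length) for one transcript."""
    return t.exon_count, t.exon_lengths, t.spliced_length


class TranscriptCatalog:
    """A collection of transcripts with a per-chromosome interval index.

    Also serves as the reference annotation container; gene loci are the
    groups of transcripts sharing a ``gene_id``.
    """

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.transcripts: list[TranscriptModel] = sorted(
            transcripts, key=lambda t: (t.chrom, t.start, t.end, t.transcript_id)
        )
        self._by_id: dict[str, TranscriptModel] = {}
        for t in self.transcripts:
            if t.transcript_id in self._by_id:
                raise ValueError(f"duplicate transcript_id {t.transcript_id}")
            self._by_id[t.transcript_id] = t
        self._index: dict[str, IntervalTree] = {}
        for t in self.transcripts:
            tree = self._index.setdefault(t.chrom, IntervalTree())
            tree[t.start : t.end] = t

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._by_id

    def get(self, transcript_id: str) -> TranscriptModel:
        return self._by_id[transcript_id]

    @property
    def transcript_ids(self) -> list[str]:
        return [t.transcript_id for t in self.transcripts]

    @property
    def gene_ids(self) -> list[str]:
        return sorted({t.gene_id for t in self.transcripts})

    def overlapping(self, chrom: str, start: int, end: int) -> list[TranscriptModel]:
        """Transcripts whose span overlaps [start, end) on ``chrom``."""
        tree = self._index.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        return sorted(hits, key=lambda t: (t.start, t.end, t.transcript_id))

    def gene_spans(self) -> list[GenomicInterval]:
        """Locus-level spans: per gene_id, min exon start to max exon end per chrom."""
        spans: dict[tuple[str, str], list[int]] = {}
        for t in self.transcripts:
            key = (t.gene_id, t.chrom)
            if key in spans:
                spans[key][0] = min(spans[key][0], t.start)
                spans[key][1] = max(spans[key][1], t.end)
            else:
                spans[key] = [t.start, t.end]
        return sorted(
            (GenomicInterval(chrom, s, e) for (_, chrom), (s, e) in spans.items()),
            key=lambda iv: (iv.chrom, iv.start, iv.end),
        )


# --------------------------------------------------------------------------
# GTF I/O


def read_gtf(path: str) -> TranscriptCatalog:
    """Read exon features from a GTF into a :class:`TranscriptCatalog`.

    GTF 1-based inclusive coordinates become internal 0-based half-open.
    Exon lines may appear in any order; they are grouped by transcript_id.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            feat = feature_from_line(line)
            if feat.featuretype != "exon":
                continue
            try:
                tid = feat.attributes["transcript_id"][0]
            except KeyError:
                raise ValueError(f"{path}:{lineno}: exon feature without transcript_id")
            gid = feat.attributes.get("gene_id", [tid])[0]
            # gffutils keeps GTF 1-based starts; convert to 0-based half-open
            exons.setdefault(tid, []).append((feat.start - 1, feat.end))
            meta.setdefault(tid, (gid, feat.seqid, feat.strand))
    models = [
        TranscriptModel(tid, gid, chrom, strand, tuple(ex))
        for tid, ex in exons.items()
        for gid, chrom, strand in (meta[tid],)
    ]
    return TranscriptCatalog(models)


def write_gtf(catalog: TranscriptCatalog, path: str, source: str = "lincnet") -> None:
    """Write exon features (1-based inclusive) in deterministic order."""
    with open(path, "w") as fh:
        for t in catalog:
            for s, e in t.exons:
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )


# --------------------------------------------------------------------------
# Novelty classification


@dataclass(frozen=True)
class NoveltyCall:
    """Outcome of comparing one catalog transcript against the reference.

    status is exactly one of ``known_match`` (identical intron chain to a
    reference transcript on the same chromosome and strand), ``exonic_overlap``
    (≥1 bp same-strand exon–exon overlap) or ``novel``.
    """

    transcript_id: str
    status: str
    evidence: str = ""


def _exonic_overlap_bp(t: TranscriptModel, r: TranscriptModel) -> int:
    total = 0
    for s1, e1 in t.exons:
        for s2, e2 in r.exons:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def classify_novelty(catalog: TranscriptCatalog, reference: TranscriptCatalog) -> list[NoveltyCall]:
    """Partition catalog transcripts into known_match / exonic_overlap / novel.

    Intron-chain equality is only meaningful for spliced transcripts: a
    single-exon transcript has an empty chain, so it can at best be an
    exonic_overlap.  Antisense overlap does not count (strand-aware), matching
    the convention that antisense transcripts are instead caught downstream by
    the strand-agnostic distance filter.
    """
    # index reference intron chains for multi-exon matching
    chains: dict[tuple, str] = {}
    for r in reference:
        if r.exon_count >= 2:
            chains.setdefault((r.chrom, r.strand, r.intron_chain), r.transcript_id)

    calls = []
    for t in catalog:
        status, evidence = "novel", ""
        if t.exon_count >= 2:
            ref_id = chains.get((t.chrom, t.strand, t.intron_chain))
            if ref_id is not None:
                calls.append(NoveltyCall(t.transcript_id, "known_match", ref_id))
                continue
        overlap = 0
        for r in reference.overlapping(t.chrom, t.start, t.end):
            if r.strand != t.strand:
                continue
            overlap += _exonic_overlap_bp(t, r)
        if overlap > 0:
            status, evidence = "exonic_overlap", str(overlap)
        calls.append(NoveltyCall(t.transcript_id, status, evidence))
    return calls


# --------------------------------------------------------------------------
# Distances and neighbor pairs


def _gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap in bp between two half-open intervals; 0 if they overlap or touch."""
    if a_start < b_end and b_start < a_end:
        return 0
    return max(a_start - b_end, b_start - a_end, 0)


def distance_to_nearest_gene(t: TranscriptModel, reference: TranscriptCatalog) -> float:
    """Strand-agnostic bp distance from a transcript span to the nearest gene locus.

    Returns 0 on any overlap and ``math.inf`` when the reference is empty.
    """
    spans = [iv for iv in reference.gene_spans() if iv.chrom == t.chrom]
    if not reference.transcripts:
        return math.inf
    if not spans:
        return math.inf
    return min(_gap(t.start, t.end, iv.start, iv.end) for iv in spans)


def tss_distance(a: TranscriptModel, b: TranscriptModel) -> int:
    """Absolute distance between two TSSs; undefined across chromosomes."""
    if a.chrom != b.chrom:
        raise ValueError("TSS distance undefined across chromosomes")
    return abs(a.tss() - b.tss())


@dataclass(frozen=True)
class NeighborPair:
    """A cross pair with gene-body gap < max_gap, strand ignored."""

    id_a: str
    id_b: str
    gap: int
    tss_distance: int
    chrom: str


def neighbor_pairs(
    set_a: TranscriptCatalog,
    set_b: TranscriptCatalog,
    max_gap: int = 10_000,
) -> list[NeighborPair]:
    """All (a, b) pairs whose span-to-span gap is strictly below ``max_gap``.

    Relative orientation is ignored for pairing (it is reported via the two
    transcripts, not filtered on).  Order is deterministic: chromosome, then
    coordinates, then ids.
    """
    pairs = []
    for a in set_a:
        # widen the query window by max_gap so non-overlapping neighbors are hit
        lo = max(0, a.start - max_gap)
        for b in set_b.overlapping(a.chrom, lo, a.end + max_gap):
            g = _gap(a.start, a.end, b.start, b.end)
            if g < max_gap:
                pairs.append(
                    NeighborPair(a.transcript_id, b.transcript_id, g, tss_distance(a, b), a.chrom)
                )
    pairs.sort(key=lambda p: (p.chrom, p.gap, p.id_a, p.id_b))
    return pairs
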