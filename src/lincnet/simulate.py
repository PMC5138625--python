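"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the full input set of the analysis: a toy genome with
multi-exon reference genes separated by intergenic gaps, a merged transcript
catalog containing known, overlapping and intergenic transcripts (with coding
vs noncoding sequence composition and deliberate funnel decoys), FPKM panels
across tissues and developmental stages with planted tissue-specific
transcripts, cis-correlated lincRNA:gene neighbor pairs, and stage-specific
co-expression modules with designated hub genes.

Everything is driven by one :class:`SimulationConfig`; a fixed seed yields
byte-identical output files.  Randomness is split into per-stage
``numpy.random.default_rng([seed, stage])`` streams so each sub-generator can
be re-run independently with the same result.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import TranscriptCatalog, TranscriptModel, write_gtf
from .coding import longest_orf

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# Codons over-represented in the planted ORFs (a GC-ending usage bias), giving
# the hexamer feature real signal against uniform noncoding background.
_PREFERRED_CODONS = [
    "GCC", "GAG", "CTG", "AAG", "GAC", "TTC", "ATC", "AAC", "GGC", "CAG",
    "GTG", "ACC", "TCC", "CGC", "TAC", "TGC", "CAC", "TGG", "CCC", "AGC",
]
_STOPS = {"TAA", "TAG", "TGA"}
_ALL_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_SENSE_CODONS = [c for c in _ALL_CODONS if c not in _STOPS]

_TISSUE_NAMES = ["heart", "liver", "muscle", "brain", "ovary", "testis", "kidney", "spleen"]
_STAGE_NAMES = ["oocyte", "zygote", "two_cell", "four_cell", "eight_cell", "morula", "blastocyst"]


class PlacementError(RuntimeError):
    """Raised when the requested transcripts cannot be placed in the genome."""


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the default study conditions.

    The default catalog holds 250 transcripts engineered so that each funnel
    stage removes a known subset and exactly 35 lincRNAs survive; the default
    stage panel plants 4 modules x 50 genes plus 100 noise genes over 6 stages
    with 2 replicates each.
    """

    seed: int = 0
    # genome / annotation
    n_chromosomes: int = 3
    n_reference_genes: int = 60
    intergenic_gap_range: tuple[int, int] = (8_000, 25_000)
    ref_exon_count_range: tuple[int, int] = (3, 9)
    ref_exon_length_range: tuple[int, int] = (100, 300)
    intron_length_range: tuple[int, int] = (200, 1_500)
    # transcript catalog
    n_known_transcripts: int = 90
    n_overlapping_novel: int = 40
    n_intergenic_noncoding: int = 35
    n_intergenic_coding: int = 25
    n_intergenic_close: int = 30
    n_single_exon_decoys: int = 20
    n_short_decoys: int = 10
    min_intergenic_distance: int = 500
    orf_length_range_coding: tuple[int, int] = (450, 900)
    noncoding_length_range: tuple[int, int] = (300, 1_500)
    max_noncoding_orf: int = 150
    n_training_per_class: int = 300
    # expression: tissue panel
    n_tissues: int = 6
    replicates_per_tissue: int = 2
    tissue_specific_fraction: float = 0.6
    n_cis_pairs: int = 20
    cis_pair_correlation: float = 0.9
    # expression: stage panel
    n_stages: int = 6
    replicates_per_stage: int = 2
    n_modules: int = 4
    genes_per_module: int = 50
    n_noise_genes: int = 100
    module_noise_sd: float = 0.5
    hub_fraction: float = 0.1
    linc_module_fraction: float = 0.15

    def __post_init__(self) -> None:
        counts = [
            self.n_chromosomes, self.n_reference_genes, self.n_known_transcripts,
            self.n_overlapping_novel, self.n_intergenic_noncoding, self.n_intergenic_coding,
            self.n_intergenic_close, self.n_single_exon_decoys, self.n_short_decoys,
            self.n_tissues, self.n_stages, self.replicates_per_stage, self.n_modules,
            self.genes_per_module, self.n_noise_genes, self.n_cis_pairs,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be non-negative")
        if not (0.0 <= self.cis_pair_correlation <= 1.0):
            raise ValueError("cis_pair_correlation must lie in [0, 1]")
        if not (0.0 <= self.hub_fraction <= 1.0):
            raise ValueError("hub_fraction must lie in [0, 1]")
        if self.n_modules > self.n_stages:
            raise ValueError("need at least one stage per module")
        if self.n_cis_pairs > self.n_intergenic_noncoding:
            raise ValueError("cannot plant more cis pairs than intergenic noncoding transcripts")
        if self.intergenic_gap_range[0] > self.intergenic_gap_range[1]:
            raise ValueError("invalid intergenic_gap_range")

    @property
    def tissues(self) -> list[str]:
        names = _TISSUE_NAMES[: self.n_tissues]
        names += [f"tissue{i}" for i in range(len(names) + 1, self.n_tissues + 1)]
        return names

    @property
    def stages(self) -> list[str]:
        names = _STAGE_NAMES[: self.n_stages]
        names += [f"stage{i}" for i in range(len(names) + 1, self.n_stages + 1)]
        return names


# Design classes and the funnel stage each one is built to fail at
DESIGN_CLASSES = (
    "known", "overlapping", "single_exon_decoy", "short_decoy",
    "intergenic_close", "intergenic_coding", "intergenic_noncoding",
)
EXPECTED_VERDICT = {
    "known": "known_removal",
    "overlapping": "known_removal",
    "single_exon_decoy": "multi_exon",
    "short_decoy": "min_length",
    "intergenic_close": "min_distance",
    "intergenic_coding": "noncoding",
    "intergenic_noncoding": "lincRNA",
}


@dataclass
class SyntheticTruth:
    """Planted labels consumed by all recovery tests."""

    design_class: dict[str, str] = field(default_factory=dict)  # transcript -> class
    coding_label: dict[str, str] = field(default_factory=dict)  # transcript -> coding|noncoding
    novelty_label: dict[str, str] = field(default_factory=dict)  # known|overlapping|intergenic
    specific_tissue: dict[str, str | None] = field(default_factory=dict)
    cis_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    module_label: dict[str, str] = field(default_factory=dict)  # gene -> module id | "noise"
    hub_flag: dict[str, bool] = field(default_factory=dict)
    stage_of_module: dict[str, str] = field(default_factory=dict)

    def expected_verdicts(self) -> dict[str, str]:
        """First-fail funnel stage (or 'lincRNA') implied by each design class."""
        return {tid: EXPECTED_VERDICT[c] for tid, c in self.design_class.items()}

    def expected_funnel_counts(self, stages: tuple[str, ...]) -> dict[str, dict[str, int]]:
        """input/passed/removed per stage implied purely by the design classes."""
        verdicts = self.expected_verdicts()
        remaining = len(verdicts)
        out: dict[str, dict[str, int]] = {}
        for stage in stages:
            removed = sum(1 for v in verdicts.values() if v == stage)
            out[stage] = {"input": remaining, "removed": removed, "passed": remaining - removed}
            remaining -= removed
        return out

    @property
    def lincrna_ids(self) -> list[str]:
        return sorted(t for t, c in self.design_class.items() if c == "intergenic_noncoding")

    def to_json(self) -> str:
        return json.dumps(
            {
                "design_class": self.design_class,
                "coding_label": self.coding_label,
                "novelty_label": self.novelty_label,
                "specific_tissue": self.specific_tissue,
                "cis_pairs": [list(p) for p in self.cis_pairs],
                "module_label": self.module_label,
                "hub_flag": self.hub_flag,
                "stage_of_module": self.stage_of_module,
            },
            indent=2,
            sort_keys=True,
        )


# --------------------------------------------------------------------------
# sequence models


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _coding_weights() -> np.ndarray:
    w = np.array([3.0 if c in _PREFERRED_CODONS else 0.15 for c in _SENSE_CODONS])
    return w / w.sum()


_CODING_W = _coding_weights()


def coding_sequence(rng: np.random.Generator, orf_length: int, utr_range: tuple[int, int] = (30, 120)) -> str:
    """UTR5 + planted ATG..stop ORF with codon-usage-biased body + UTR3.

    ``orf_length`` includes start and stop codons and is rounded down to a
    multiple of three (minimum 9 nt).
    """
    orf_length = max(9, orf_length - orf_length % 3)
    n_body = orf_length // 3 - 2
    body = "".join(np.array(_SENSE_CODONS)[rng.choice(len(_SENSE_CODONS), size=n_body, p=_CODING_W)])
    stop = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
    utr5 = _random_seq(rng, int(rng.integers(*utr_range)))
    utr3 = _random_seq(rng, int(rng.integers(*utr_range)))
    return utr5 + "ATG" + body + stop + utr3


def noncoding_sequence(rng: np.random.Generator, length: int, max_orf: int = 150) -> str:
    """Uniform-composition sequence whose longest ORF is capped at ``max_orf``.

    Long accidental ORFs are interrupted by replacing an in-frame codon with a
    stop, mimicking the stop-codon-interrupted structure of noncoding RNA.
    """
    seq = list(_random_seq(rng, length))
    while True:
        _, start, orf_len = longest_orf("".join(seq))
        if orf_len <= max_orf:
            return "".join(seq)
        cut = start + 3 * (max_orf // 6)  # in-frame, near the middle of the cap
        seq[cut : cut + 3] = list(("TAA", "TAG", "TGA")[rng.integers(0, 3)])


def generate_training_sequences(
    config: SimulationConfig, n_per_class: int | None = None, stream: int = 3
) -> tuple[list[str], list[str]]:
    """Seeded coding/noncoding training sets from the catalog sequence models."""
    rng = np.random.default_rng([config.seed, stream])
    n = n_per_class if n_per_class is not None else config.n_training_per_class
    coding = [
        coding_sequence(rng, int(rng.integers(*config.orf_length_range_coding)))
        for _ in range(n)
    ]
    noncoding = [
        noncoding_sequence(
            rng, int(rng.integers(*config.noncoding_length_range)), config.max_noncoding_orf
        )
        for _ in range(n)
    ]
    return coding, noncoding


# --------------------------------------------------------------------------
# annotation


def _split_exons(rng: np.random.Generator, total: int, n_exons: int, min_exon: int = 30) -> list[int]:
    """Split ``total`` nt into ``n_exons`` parts, each at least ``min_exon``."""
    if total < n_exons * min_exon:
        raise PlacementError(f"cannot split {total} nt into {n_exons} exons of >= {min_exon} nt")
    extra = total - n_exons * min_exon
    if n_exons == 1:
        return [total]
    cuts = np.sort(rng.integers(0, extra + 1, size=n_exons - 1))
    parts = np.diff(np.concatenate([[0], cuts, [extra]]))
    return [min_exon + int(p) for p in parts]


def _build_structure(
    rng: np.random.Generator,
    start: int,
    spliced_length: int,
    n_exons: int,
    intron_range: tuple[int, int],
) -> tuple[tuple[int, int], ...]:
    """Exon coordinates for a transcript of given spliced length at ``start``."""
    exon_lengths = _split_exons(rng, spliced_length, n_exons)
    exons = []
    pos = start
    for i, length in enumerate(exon_lengths):
        exons.append((pos, pos + length))
        pos += length
        if i < n_exons - 1:
            pos += int(rng.integers(*intron_range))
    return tuple(exons)


def generate_annotation(
    config: SimulationConfig,
) -> tuple[TranscriptCatalog, dict[str, np.ndarray]]:
    """Reference annotation (one multi-exon transcript per gene) plus genome.

    Genes are laid left to right per chromosome, separated by gaps drawn from
    ``intergenic_gap_range``; the genome is random background into which gene
    (coding-like) sequences are stamped.  Returns the annotation and the
    genome as mutable per-chromosome base arrays.
    """
    rng = np.random.default_rng([config.seed, 1])
    if config.n_reference_genes == 0:
        genome = {"chr1": np.array(list(_random_seq(rng, 2_000)))}
        return TranscriptCatalog([]), genome

    per_chrom = np.array_split(np.arange(config.n_reference_genes), config.n_chromosomes)
    transcripts = []
    genome: dict[str, np.ndarray] = {}
    for ci, gene_idx in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        cursor = 0
        chrom_transcripts = []
        for gi in gene_idx:
            cursor += int(rng.integers(config.intergenic_gap_range[0], config.intergenic_gap_range[1] + 1))
            n_exons = int(rng.integers(config.ref_exon_count_range[0], config.ref_exon_count_range[1] + 1))
            spliced = sum(
                int(rng.integers(config.ref_exon_length_range[0], config.ref_exon_length_range[1] + 1))
                for _ in range(n_exons)
            )
            exons = _build_structure(rng, cursor, spliced, n_exons, config.intron_length_range)
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"PGENE{gi + 1:04d}"
            chrom_transcripts.append(TranscriptModel(f"{gid}.1", gid, chrom, strand, exons))
            cursor = exons[-1][1]
        cursor += int(rng.integers(config.intergenic_gap_range[0], config.intergenic_gap_range[1] + 1))
        genome[chrom] = np.array(list(_random_seq(rng, cursor)))
        transcripts.extend(chrom_transcripts)

    reference = TranscriptCatalog(transcripts)
    for t in reference:
        seq = coding_sequence(rng, t.spliced_length - 2 * 60, utr_range=(60, 61))
        if len(seq) < t.spliced_length:  # codon rounding can shave a couple of nt
            seq += _random_seq(rng, t.spliced_length - len(seq))
        _stamp(genome, t, seq[: t.spliced_length])
    return reference, genome


def _stamp(genome: dict[str, np.ndarray], t: TranscriptModel, spliced: str) -> None:
    """Write a spliced sequence into the genome across a transcript's exons."""
    assert len(spliced) == t.spliced_length
    payload = spliced if t.strand != "-" else reverse_complement(spliced)
    pos = 0
    for s, e in t.exons:
        genome[t.chrom][s:e] = list(payload[pos : pos + (e - s)])
        pos += e - s


def extract_transcript_sequences(
    catalog: TranscriptCatalog, genome: dict[str, np.ndarray]
) -> dict[str, str]:
    """Spliced transcript sequences from the genome ('-' strand reverse-complemented)."""
    out = {}
    for t in catalog:
        raw = "".join("".join(genome[t.chrom][s:e]) for s, e in t.exons)
        out[t.transcript_id] = reverse_complement(raw) if t.strand == "-" else raw
    return out


# --------------------------------------------------------------------------
# transcript catalog


@dataclass
class _Gap:
    """Intergenic interval bounded by gene spans (or chromosome ends)."""

    chrom: str
    left_end: int | None  # end of the gene to the left, None at chromosome start
    right_start: int | None
    cursor: int  # next free coordinate
    untouched: bool = True

    def limit(self, margin: int) -> int:
        return (self.right_start - margin) if self.right_start is not None else 10**12


def _collect_gaps(reference: TranscriptCatalog, genome: dict[str, np.ndarray]) -> list[_Gap]:
    gaps = []
    spans_by_chrom: dict[str, list] = {}
    for iv in reference.gene_spans():
        spans_by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(genome):
        spans = sorted(spans_by_chrom.get(chrom, []), key=lambda iv: iv.start)
        prev_end: int | None = None
        for iv in spans:
            gaps.append(_Gap(chrom, prev_end, iv.start, cursor=prev_end or 0))
            prev_end = iv.end
        gaps.append(_Gap(chrom, prev_end, None, cursor=prev_end or 0))
    return gaps


def _place_intergenic(
    rng: np.random.Generator,
    gaps: list[_Gap],
    span: int,
    margin: int,
    dist_range: tuple[int, int] | None,
    need_fresh_interior: bool,
) -> tuple[str, int, _Gap]:
    """Find a genomic start for an intergenic transcript of genomic span ``span``.

    ``dist_range`` pins the distance from the left gene (fresh interior gaps
    only); otherwise the transcript goes at least ``margin`` bp from both
    neighbors, after any previously placed transcript in the gap.
    """
    order = rng.permutation(len(gaps))
    for gi in order:
        gap = gaps[gi]
        if need_fresh_interior:
            if not (gap.untouched and gap.left_end is not None and gap.right_start is not None):
                continue
            d = int(rng.integers(dist_range[0], dist_range[1] + 1))
            start = gap.left_end + d
        else:
            base = gap.cursor if not gap.untouched else (
                (gap.left_end + margin) if gap.left_end is not None else gap.cursor + margin
            )
            start = base + int(rng.integers(20, 200))
        if start + span <= gap.limit(margin):
            gap.cursor = start + span
            gap.untouched = False
            return gap.chrom, start, gap
    raise PlacementError(
        f"no intergenic gap can host a transcript of span {span} "
        f"(margin {margin}, pinned distance {dist_range})"
    )


def generate_transcript_catalog(
    reference: TranscriptCatalog,
    genome: dict[str, np.ndarray],
    config: SimulationConfig,
) -> tuple[TranscriptCatalog, dict[str, str], SyntheticTruth]:
    """Merged-assembly-style catalog with planted funnel classes.

    Returns (catalog, transcript sequences, truth).  Intergenic transcript
    sequences are stamped into the genome so transcript FASTA and genome FASTA
    stay consistent.
    """
    rng = np.random.default_rng([config.seed, 2])
    if len(reference) == 0:
        if config.n_known_transcripts or config.n_overlapping_novel:
            raise PlacementError("cannot derive transcripts from an empty reference")
        if config.n_reference_genes == 0 and not any([
            config.n_intergenic_noncoding, config.n_intergenic_coding,
            config.n_intergenic_close, config.n_single_exon_decoys, config.n_short_decoys,
        ]):
            return TranscriptCatalog([]), {}, SyntheticTruth()

    truth = SyntheticTruth()
    transcripts: list[TranscriptModel] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"TCONS_{counter:08d}"

    ref_list = list(reference)

    # -- known: copy a reference intron chain, optionally extending terminal exons
    for _ in range(config.n_known_transcripts):
        r = ref_list[rng.integers(0, len(ref_list))]
        exons = list(r.exons)
        ext5, ext3 = int(rng.integers(0, 50)), int(rng.integers(0, 50))
        exons[0] = (max(0, exons[0][0] - ext5), exons[0][1])
        exons[-1] = (exons[-1][0], exons[-1][1] + ext3)
        tid = new_id()
        transcripts.append(TranscriptModel(tid, f"XLOC_{tid}", r.chrom, r.strand, tuple(exons)))
        truth.design_class[tid] = "known"
        truth.coding_label[tid] = "coding"
        truth.novelty_label[tid] = "known"

    # -- overlapping novels: share >=1 exonic bp with a gene, new intron chain
    for _ in range(config.n_overlapping_novel):
        r = ref_list[rng.integers(0, len(ref_list))]
        s0, e0 = r.exons[0]
        first = (s0 + int(rng.integers(0, min(30, e0 - s0 - 10))), e0 + int(rng.integers(20, 80)))
        gap_after = int(rng.integers(100, 400))
        second_len = int(rng.integers(80, 250))
        second = (first[1] + gap_after, first[1] + gap_after + second_len)
        tid = new_id()
        transcripts.append(TranscriptModel(tid, f"XLOC_{tid}", r.chrom, r.strand, (first, second)))
        truth.design_class[tid] = "overlapping"
        truth.coding_label[tid] = "noncoding"
        truth.novelty_label[tid] = "overlapping"

    # -- intergenic classes, placed into the gaps between gene loci
    gaps = _collect_gaps(reference, genome)
    margin = config.min_intergenic_distance
    planted: list[tuple[TranscriptModel, str]] = []  # (transcript, spliced sequence)
    cis_partner: dict[str, str] = {}

    def add_intergenic(
        design: str,
        seq: str,
        n_exons: int,
        dist_range: tuple[int, int] | None = None,
        fresh: bool = False,
    ) -> TranscriptModel:
        intron_total = 0 if n_exons == 1 else sum(
            int(rng.integers(150, 600)) for _ in range(n_exons - 1)
        )
        # build structure at origin to learn the span, then shift to placement
        rng_state = rng.integers(0, 2**31)
        local = np.random.default_rng(rng_state)
        exons0 = _build_structure(local, 0, len(seq), n_exons, (150, 600))
        span = exons0[-1][1]
        chrom, start, gap = _place_intergenic(rng, gaps, span, margin, dist_range, fresh)
        exons = tuple((s + start, e + start) for s, e in exons0)
        strand = "+" if rng.random() < 0.5 else "-"
        tid = new_id()
        t = TranscriptModel(tid, f"XLOC_{tid}", chrom, strand, exons)
        transcripts.append(t)
        planted.append((t, seq))
        truth.design_class[tid] = design
        truth.novelty_label[tid] = "intergenic"
        truth.coding_label[tid] = "coding" if design == "intergenic_coding" else "noncoding"
        if fresh and gap.left_end is not None and gap.right_start is not None:
            left_gene = next(
                r.transcript_id for r in reference
                if r.chrom == chrom and r.end == gap.left_end
            )
            cis_partner[tid] = left_gene
        return t

    # near-gene decoys (<500 bp) first: they need untouched interior gaps
    for _ in range(config.n_intergenic_close):
        seq = noncoding_sequence(
            rng, int(rng.integers(*config.noncoding_length_range)), config.max_noncoding_orf
        )
        add_intergenic("intergenic_close", seq, int(rng.integers(2, 5)),
                       dist_range=(100, margin - 20), fresh=True)

    # cis lincRNAs: pinned 600–4000 bp from their partner gene (also fresh gaps)
    n_cis = config.n_cis_pairs
    for i in range(config.n_intergenic_noncoding):
        seq = noncoding_sequence(
            rng, int(rng.integers(*config.noncoding_length_range)), config.max_noncoding_orf
        )
        if i < n_cis:
            near = i < n_cis // 2  # bimodal TSS-distance planting
            rng_range = (600, 1500) if near else (2500, 4000)
            add_intergenic("intergenic_noncoding", seq, int(rng.integers(2, 5)),
                           dist_range=rng_range, fresh=True)
        else:
            add_intergenic("intergenic_noncoding", seq, int(rng.integers(2, 5)))

    for _ in range(config.n_intergenic_coding):
        seq = coding_sequence(rng, int(rng.integers(*config.orf_length_range_coding)))
        add_intergenic("intergenic_coding", seq, int(rng.integers(2, 6)))

    for _ in range(config.n_single_exon_decoys):
        seq = noncoding_sequence(rng, int(rng.integers(300, 800)), config.max_noncoding_orf)
        add_intergenic("single_exon_decoy", seq, 1)

    for _ in range(config.n_short_decoys):
        seq = noncoding_sequence(rng, int(rng.integers(120, 200)), config.max_noncoding_orf)
        add_intergenic("short_decoy", seq, 2)

    # grow chromosomes if an intergenic transcript ran past the right end
    for t in transcripts:
        if t.end + 1_000 > len(genome[t.chrom]):
            extra = _random_seq(rng, t.end + 1_000 - len(genome[t.chrom]))
            genome[t.chrom] = np.concatenate([genome[t.chrom], np.array(list(extra))])

    for t, seq in planted:
        _stamp(genome, t, seq)

    catalog = TranscriptCatalog(transcripts)
    sequences = extract_transcript_sequences(catalog, genome)

    # cis pairs: planted on the surviving lincRNAs that sit near a partner gene
    rho = config.cis_pair_correlation
    for tid in sorted(cis_partner):
        if truth.design_class[tid] == "intergenic_noncoding":
            truth.cis_pairs.append((tid, cis_partner[tid], rho))
    return catalog, sequences, truth


# --------------------------------------------------------------------------
# expression panels


def _lognormal_fpkm(rng: np.random.Generator, mean_log2: float, sd_log2: float, size: int) -> np.ndarray:
    return np.power(2.0, mean_log2 + sd_log2 * rng.standard_normal(size))


@dataclass
class ExpressionPanels:
    """Output of :func:`generate_expression`: both FPKM panels plus the truth
    completed with tissue/module/hub labels."""

    tissue_matrix: pd.DataFrame
    tissue_design: pd.Series
    stage_matrix: pd.DataFrame
    stage_design: pd.Series
    truth: SyntheticTruth


def generate_expression(
    truth: SyntheticTruth,
    catalog: TranscriptCatalog,
    reference: TranscriptCatalog,
    config: SimulationConfig,
) -> ExpressionPanels:
    """Plant expression structure into tissue and stage FPKM panels.

    Tissue panel rows are catalog + reference transcripts; planted
    tissue-specific transcripts exceed 0.1 FPKM only in their tissue, broad
    ones everywhere; cis pairs share correlated profiles at the planted rho.
    Stage panel rows are module and noise genes; module genes follow a pulse
    profile peaking at their module's stage plus Gaussian noise (hub genes get
    the least noise).  The input truth is not modified; the returned copy
    carries the tissue/module/hub labels.
    """
    import copy

    truth = copy.deepcopy(truth)
    rng = np.random.default_rng([config.seed, 4])
    if config.replicates_per_stage < 2:
        import warnings

        warnings.warn("replicates_per_stage < 2 makes correlation p-values degenerate",
                      stacklevel=2)

    tissues = config.tissues
    t_samples = [f"{t}_r{r + 1}" for t in tissues for r in range(config.replicates_per_tissue)]
    t_design = pd.Series([s.rsplit("_r", 1)[0] for s in t_samples], index=t_samples, name="tissue")
    n_ts = len(t_samples)

    cis_linc = {a: (b, rho) for a, b, rho in truth.cis_pairs}
    cis_gene_profile: dict[str, np.ndarray] = {}

    features = sorted(set(catalog.transcript_ids) | set(reference.transcript_ids))
    lincs = truth.lincrna_ids
    specific_pool = [t for t in lincs if t not in cis_linc]
    n_specific = int(round(config.tissue_specific_fraction * len(specific_pool)))
    specific = {
        t: tissues[i % len(tissues)] for i, t in enumerate(specific_pool[:n_specific])
    }

    rows = {}
    for fid in features:
        if fid in cis_linc:
            partner, rho = cis_linc[fid]
            z_g = cis_gene_profile.setdefault(partner, rng.standard_normal(n_ts))
            z_l = rho * z_g + np.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal(n_ts)
            rows[fid] = np.power(2.0, 3.0 + 1.5 * z_l)
            truth.specific_tissue[fid] = None
        elif fid in specific:
            tissue = specific[fid]
            vals = rng.uniform(0.0, 0.05, size=n_ts)
            mask = (t_design == tissue).values
            vals[mask] = _lognormal_fpkm(rng, 4.0, 1.0, mask.sum())
            rows[fid] = vals
            truth.specific_tissue[fid] = tissue
        else:
            truth.specific_tissue[fid] = None
            rows[fid] = None  # filled below so cis gene profiles are known first
    for fid in features:
        if rows[fid] is None:
            if fid in cis_gene_profile:
                rows[fid] = np.power(2.0, 4.0 + 1.5 * cis_gene_profile[fid])
            else:
                rows[fid] = _lognormal_fpkm(rng, 2.0, 0.5, n_ts)
    tissue_matrix = pd.DataFrame({s: [rows[f][i] for f in features] for i, s in enumerate(t_samples)},
                                 index=features)

    # ---- stage panel
    stages = config.stages
    s_samples = [f"{st}_r{r + 1}" for st in stages for r in range(max(1, config.replicates_per_stage))]
    s_design = pd.Series([s.rsplit("_r", 1)[0] for s in s_samples], index=s_samples, name="stage")
    n_ss = len(s_samples)

    module_ids = [f"MOD{i + 1}" for i in range(config.n_modules)]
    peak_stages = [stages[i] for i in rng.permutation(config.n_stages)[: config.n_modules]]
    truth.stage_of_module = dict(zip(module_ids, peak_stages))

    n_linc_members = int(round(config.linc_module_fraction * config.genes_per_module))
    linc_pool = list(lincs)
    mrna_counter = 0
    gene_rows = {}
    for m, mid in enumerate(module_ids):
        members = []
        for _ in range(config.genes_per_module):
            if len(members) < n_linc_members and linc_pool:
                members.append(linc_pool.pop(0))
            else:
                mrna_counter += 1
                members.append(f"MRNA{mrna_counter:04d}")
        n_hubs = max(1, int(round(config.hub_fraction * len(members)))) if members else 0
        hub_set = set(rng.choice(len(members), size=n_hubs, replace=False)) if members else set()
        profile = np.where((s_design == truth.stage_of_module[mid]).values, 5.0, 1.0)
        for gi, g in enumerate(members):
            is_hub = gi in hub_set
            sd = config.module_noise_sd / 5.0 if is_hub else config.module_noise_sd
            vals = profile + sd * rng.standard_normal(n_ss)
            gene_rows[g] = np.maximum(np.power(2.0, vals) - 1.0, 0.0)
            truth.module_label[g] = mid
            truth.hub_flag[g] = bool(is_hub)
    for i in range(config.n_noise_genes):
        g = f"NOISE{i + 1:04d}"
        gene_rows[g] = np.maximum(np.power(2.0, 2.0 + 1.0 * rng.standard_normal(n_ss)) - 1.0, 0.0)
        truth.module_label[g] = "noise"
        truth.hub_flag[g] = False
    stage_matrix = pd.DataFrame(
        {s: [gene_rows[g][i] for g in gene_rows] for i, s in enumerate(s_samples)},
        index=list(gene_rows),
    )
    return ExpressionPanels(tissue_matrix, t_design, stage_matrix, s_design, truth)


def generate_term_annotation(
    truth: SyntheticTruth, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Term→gene annotation with one planted enriched term per module.

    Each module gets a term covering ~60% of its members plus a sprinkling of
    background genes; additional random terms draw uniformly from the whole
    stage-panel universe.  Returns (term_gene table, term metadata table).
    """
    rng = np.random.default_rng([config.seed, 5])
    universe = sorted(truth.module_label)
    categories = ["BP", "MF", "CC"]
    rows, meta = [], []
    for i, module in enumerate(sorted(truth.stage_of_module)):
        term = f"TERM:{module}"
        members = sorted(g for g, m in truth.module_label.items() if m == module)
        n_in = max(1, int(round(0.6 * len(members))))
        chosen = [members[j] for j in rng.choice(len(members), size=n_in, replace=False)]
        others = [g for g in universe if truth.module_label[g] != module]
        n_bg = max(1, len(chosen) // 10)
        chosen += [others[j] for j in rng.choice(len(others), size=n_bg, replace=False)]
        rows += [{"term": term, "gene": g} for g in sorted(set(chosen))]
        meta.append({"term": term, "name": f"planted {module} process",
                     "category": categories[i % 3]})
    for i in range(10):
        term = f"TERM:RAND{i + 1:02d}"
        size = min(int(rng.integers(10, 40)), len(universe))
        chosen = [universe[j] for j in rng.choice(len(universe), size=size, replace=False)]
        rows += [{"term": term, "gene": g} for g in sorted(set(chosen))]
        meta.append({"term": term, "name": f"random set {i + 1}", "category": categories[i % 3]})
    return pd.DataFrame(rows), pd.DataFrame(meta)


# --------------------------------------------------------------------------
# bundle + writers


@dataclass
class SimulationBundle:
    config: SimulationConfig
    reference: TranscriptCatalog
    genome: dict[str, np.ndarray]
    catalog: TranscriptCatalog
    sequences: dict[str, str]
    truth: SyntheticTruth
    tissue_matrix: pd.DataFrame
    tissue_design: pd.Series
    stage_matrix: pd.DataFrame
    stage_design: pd.Series
    coding_train: list[str]
    noncoding_train: list[str]
    term_gene: pd.DataFrame
    term_meta: pd.DataFrame


def simulate_all(config: SimulationConfig) -> SimulationBundle:
    """Run every sub-generator under one seed and return the full bundle."""
    reference, genome = generate_annotation(config)
    catalog, sequences, truth = generate_transcript_catalog(reference, genome, config)
    coding_train, noncoding_train = generate_training_sequences(config)
    panels = generate_expression(truth, catalog, reference, config)
    truth = panels.truth
    term_gene, term_meta = generate_term_annotation(truth, config)
    return SimulationBundle(
        config, reference, genome, catalog, sequences, truth,
        panels.tissue_matrix, panels.tissue_design,
        panels.stage_matrix, panels.stage_design,
        coding_train, noncoding_train, term_gene, term_meta,
    )


def _write_fasta(path: Path, records: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name in records:
            fh.write(f">{name}\n")
            seq = records[name]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_bundle(bundle: SimulationBundle, outdir: str | Path) -> dict[str, Path]:
    """Write every pipeline input to ``outdir`` deterministically; returns paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference_gtf": out / "reference.gtf",
        "catalog_gtf": out / "catalog.gtf",
        "genome_fasta": out / "genome.fa",
        "transcripts_fasta": out / "transcripts.fa",
        "coding_train_fasta": out / "training_coding.fa",
        "noncoding_train_fasta": out / "training_noncoding.fa",
        "tissue_fpkm": out / "tissue_fpkm.tsv",
        "tissue_design": out / "tissue_design.tsv",
        "stage_fpkm": out / "stage_fpkm.tsv",
        "stage_design": out / "stage_design.tsv",
        "term_gene": out / "term_gene.tsv",
        "term_meta": out / "term_meta.tsv",
        "truth_json": out / "truth.json",
        "truth_tsv": out / "truth_transcripts.tsv",
    }
    write_gtf(bundle.reference, paths["reference_gtf"])
    write_gtf(bundle.catalog, paths["catalog_gtf"])
    _write_fasta(paths["genome_fasta"], {c: "".join(bundle.genome[c]) for c in sorted(bundle.genome)})
    _write_fasta(paths["transcripts_fasta"], dict(sorted(bundle.sequences.items())))
    _write_fasta(paths["coding_train_fasta"],
                 {f"coding_{i + 1:04d}": s for i, s in enumerate(bundle.coding_train)})
    _write_fasta(paths["noncoding_train_fasta"],
                 {f"noncoding_{i + 1:04d}": s for i, s in enumerate(bundle.noncoding_train)})
    bundle.tissue_matrix.round(6).to_csv(paths["tissue_fpkm"], sep="\t")
    bundle.tissue_design.to_frame().to_csv(paths["tissue_design"], sep="\t")
    bundle.stage_matrix.round(6).to_csv(paths["stage_fpkm"], sep="\t")
    bundle.stage_design.to_frame().to_csv(paths["stage_design"], sep="\t")
    bundle.term_gene.to_csv(paths["term_gene"], sep="\t", index=False)
    bundle.term_meta.to_csv(paths["term_meta"], sep="\t", index=False)
    paths["truth_json"].write_text(bundle.truth.to_json() + "\n")
    rows = [
        {
            "transcript_id": tid,
            "design_class": cls,
            "coding_label": bundle.truth.coding_label[tid],
            "novelty_label": bundle.truth.novelty_label[tid],
            "specific_tissue": bundle.truth.specific_tissue.get(tid) or "",
            "expected_verdict": EXPECTED_VERDICT[cls],
        }
        for tid, cls in sorted(bundle.truth.design_class.items())
    ]
    pd.DataFrame(rows).to_csv(paths["truth_tsv"], sep="\t", index=False)
    return paths
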