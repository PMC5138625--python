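"""The lincRNA identification funnel.

Five filters applied in a fixed order to a merged transcript catalog:

1. ``known_removal`` — drop transcripts matching the reference annotation
   (identical intron chain) or overlapping reference exons on the same strand;
2. ``multi_exon`` — keep spliced transcripts (exon count ≥ 2);
3. ``min_length`` — keep spliced length ≥ 200 nt;
4. ``min_distance`` — keep transcripts ≥ 500 bp from any annotated gene locus
   (strand-agnostic);
5. ``noncoding`` — keep transcripts whose coding probability is below the
   model threshold.

Survivors are the lincRNA call set.  The report records input/passed/removed
counts per stage and, per transcript, the first failing stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .catalog import TranscriptCatalog, classify_novelty, distance_to_nearest_gene
from .coding import CodingModel, HexamerTable, coding_probability, extract_features

STAGES = ("known_removal", "multi_exon", "min_length", "min_distance", "noncoding")


@dataclass
class FunnelThresholds:
    min_exons: int = 2
    min_length_nt: int = 200
    min_distance_bp: int = 500


@dataclass
class FilterReport:
    """Per-stage funnel counts and per-transcript verdicts.

    ``verdicts`` maps transcript_id to the first failing stage, or ``"lincRNA"``
    for survivors.  ``passed(stage k) == input(stage k+1)`` by construction.
    """

    stage_input: dict[str, int] = field(default_factory=dict)
    stage_passed: dict[str, int] = field(default_factory=dict)
    stage_removed: dict[str, int] = field(default_factory=dict)
    verdicts: dict[str, str] = field(default_factory=dict)
    coding_threshold: float = 0.5

    @property
    def lincrna_ids(self) -> list[str]:
        return sorted(tid for tid, v in self.verdicts.items() if v == "lincRNA")

    def to_rows(self) -> list[dict]:
        return [
            {
                "stage": s,
                "input": self.stage_input[s],
                "passed": self.stage_passed[s],
                "removed": self.stage_removed[s],
            }
            for s in STAGES
        ]


def classify_lincrnas(
    catalog: TranscriptCatalog,
    reference: TranscriptCatalog,
    sequences: Mapping[str, str],
    model: CodingModel,
    hexamers: HexamerTable,
    thresholds: FunnelThresholds | None = None,
) -> tuple[list[str], FilterReport]:
    """Run the five-stage funnel; returns (lincRNA ids, FilterReport)."""
    thresholds = thresholds or FunnelThresholds()
    missing = [t.transcript_id for t in catalog if t.transcript_id not in sequences]
    if missing:
        raise ValueError(
            f"{len(missing)} transcripts missing from FASTA: {', '.join(sorted(missing)[:10])}"
        )

    report = FilterReport(coding_threshold=model.threshold)
    novelty = {c.transcript_id: c.status for c in classify_novelty(catalog, reference)}

    surviving = list(catalog)
    for stage in STAGES:
        report.stage_input[stage] = len(surviving)
        kept = []
        for t in surviving:
            if stage == "known_removal":
                ok = novelty[t.transcript_id] == "novel"
            elif stage == "multi_exon":
                ok = t.exon_count >= thresholds.min_exons
            elif stage == "min_length":
                ok = t.spliced_length >= thresholds.min_length_nt
            elif stage == "min_distance":
                ok = distance_to_nearest_gene(t, reference) >= thresholds.min_distance_bp
            else:  # noncoding
                feats = extract_features(sequences[t.transcript_id], hexamers)
                ok = coding_probability(feats, model) < model.threshold
            if ok:
                kept.append(t)
            else:
                report.verdicts[t.transcript_id] = stage
        report.stage_passed[stage] = len(kept)
        report.stage_removed[stage] = len(surviving) - len(kept)
        surviving = kept

    for t in surviving:
        report.verdicts[t.transcript_id] = "lincRNA"
    return sorted(t.transcript_id for t in surviving), report
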