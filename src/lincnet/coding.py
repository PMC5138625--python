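"""Coding-potential features and classifier.

Four sequence features drive the classifier: longest ORF length, ORF coverage,
the Fickett TESTCODE statistic, and an in-frame hexamer usage log-likelihood
ratio learned from coding vs noncoding training sequences.  A logistic
regression combines them into a coding probability; transcripts below the
decision threshold are treated as noncoding.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

STOP_CODONS = {"TAA", "TAG", "TGA"}
BASES = "ACGT"
ALL_HEXAMERS = ["".join(p) for p in product(BASES, repeat=6)]
HEXAMER_INDEX = {h: i for i, h in enumerate(ALL_HEXAMERS)}

FEATURE_NAMES = ("orf_length", "orf_coverage", "fickett_score", "hexamer_llr")


# --------------------------------------------------------------------------
# Longest ORF


def longest_orf(sequence: str) -> tuple[int, int, int]:
    """Longest ATG→stop open reading frame over the three sense frames.

    Returns ``(frame, start_offset, orf_length_nt)``; length includes the stop
    codon.  Returns ``(0, 0, 0)`` when no complete ORF exists.  Codons
    containing ``N`` break any ORF running through them.
    """
    seq = sequence.upper()
    best = (0, 0, 0)
    n = len(seq)
    for frame in range(3):
        start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if "N" in codon:
                start = None  # ORFs containing N are skipped
                continue
            if codon in STOP_CODONS:
                if start is not None:
                    length = pos + 3 - start
                    if length > best[2]:
                        best = (frame, start, length)
                    start = None
            elif codon == "ATG" and start is None:
                start = pos
    return best


# --------------------------------------------------------------------------
# Fickett TESTCODE
#
# Published TESTCODE lookup tables: for each base, a position parameter
# (max/min ratio of counts over the three codon positions) and a content
# parameter (base fraction) are mapped through 10-interval probability
# tables and combined with fixed weights.

_POSITION_PROB = {
    "A": (0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22),
    "C": (0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23),
    "G": (0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08),
    "T": (0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09),
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_PARA = (1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0)

_CONTENT_PROB = {
    "A": (0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21),
    "C": (0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31),
    "G": (0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29),
    "T": (0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58),
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_PARA = (0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.17, 0.0, 0.0)


def _lookup(value: float, thresholds: Sequence[float], probs: Sequence[float]) -> float:
    for thr, prob in zip(thresholds, probs):
        if value >= thr:
            return prob
    return probs[-1]


def fickett_score(sequence: str) -> float:
    """Fickett TESTCODE statistic of a nucleotide sequence.

    Combines, for each base, the codon-position bias (max/min+1 count ratio
    over the three frames) and the overall composition through the published
    lookup tables.  Deterministic; sequences shorter than 200 nt trigger a
    warning, >10% non-ACGT content is an error.
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    n_bad = sum(1 for c in seq if c not in BASES)
    if n_bad > 0.1 * len(seq):
        raise ValueError(f"{n_bad}/{len(seq)} non-ACGT characters exceeds 10%")
    if len(seq) < 200:
        warnings.warn("Fickett score is unreliable below 200 nt", stacklevel=2)

    score = 0.0
    for base in BASES:
        counts = [0, 0, 0]
        for i, c in enumerate(seq):
            if c == base:
                counts[i % 3] += 1
        position_value = max(counts) / (min(counts) + 1)
        content_value = sum(counts) / len(seq)
        score += _lookup(position_value, _POSITION_PARA, _POSITION_PROB[base]) * _POSITION_WEIGHT[base]
        score += _lookup(content_value, _CONTENT_PARA, _CONTENT_PROB[base]) * _CONTENT_WEIGHT[base]
    return score


def fickett_score_bounds() -> tuple[float, float]:
    """Attainable [min, max] of the TESTCODE statistic implied by the tables."""
    lo = sum(min(_POSITION_PROB[b]) * _POSITION_WEIGHT[b] + min(_CONTENT_PROB[b]) * _CONTENT_WEIGHT[b] for b in BASES)
    hi = sum(max(_POSITION_PROB[b]) * _POSITION_WEIGHT[b] + max(_CONTENT_PROB[b]) * _CONTENT_WEIGHT[b] for b in BASES)
    return lo, hi


# --------------------------------------------------------------------------
# Hexamer usage


@dataclass
class HexamerTable:
    """Per-hexamer log(f_coding / f_noncoding) over the ACGT 6-mer alphabet."""

    log_ratio: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.log_ratio) != set(ALL_HEXAMERS):
            raise ValueError("hexamer table must cover all 4096 ACGT hexamers")
        if not all(math.isfinite(v) for v in self.log_ratio.values()):
            raise ValueError("hexamer table entries must be finite")


def _orf_hexamers(seq: str) -> list[str]:
    """In-frame hexamers inside the longest ORF; sliding 6-mers if no ORF ≥ 6 nt."""
    seq = seq.upper()
    _, start, length = longest_orf(seq)
    if length >= 6:
        region = seq[start : start + length]
        step = 3
    else:
        region, step = seq, 1
    return [
        region[i : i + 6]
        for i in range(0, len(region) - 5, step)
        if all(c in BASES for c in region[i : i + 6])
    ]


def _hexamer_freqs(sequences: Iterable[str], pseudocount: float) -> np.ndarray:
    counts = np.full(4096, pseudocount, dtype=float)
    for seq in sequences:
        for h in _orf_hexamers(seq):
            counts[HEXAMER_INDEX[h]] += 1
    return counts / counts.sum()


def train_hexamer_table(
    coding: Sequence[str], noncoding: Sequence[str], pseudocount: float = 1.0
) -> HexamerTable:
    """Learn log(f_coding / f_noncoding) hexamer usage from training sequences."""
    if not coding or not noncoding:
        raise ValueError("need at least one sequence per class")
    fc = _hexamer_freqs(coding, pseudocount)
    fn = _hexamer_freqs(noncoding, pseudocount)
    log_ratio = np.log(fc) - np.log(fn)
    return HexamerTable({h: float(log_ratio[i]) for i, h in enumerate(ALL_HEXAMERS)})


def hexamer_llr(sequence: str, table: HexamerTable) -> float:
    """Mean per-hexamer log-likelihood ratio; 0 for sequences shorter than 6 nt."""
    if len(sequence) < 6:
        return 0.0
    hexamers = _orf_hexamers(sequence)
    if not hexamers:
        return 0.0
    return float(np.mean([table.log_ratio[h] for h in hexamers]))


# --------------------------------------------------------------------------
# Feature extraction and logistic model


@dataclass(frozen=True)
class CodingPotentialFeatures:
    orf_length: int
    orf_coverage: float
    fickett_score: float
    hexamer_llr: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.orf_coverage <= 1.0):
            raise ValueError("ORF coverage must lie in [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.orf_length, self.orf_coverage, self.fickett_score, self.hexamer_llr],
            dtype=float,
        )


def extract_features(sequence: str, table: HexamerTable) -> CodingPotentialFeatures:
    seq = sequence.upper()
    _, _, orf_len = longest_orf(seq)
    coverage = orf_len / len(seq) if seq else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fickett = fickett_score(seq) if seq else 0.0
    return CodingPotentialFeatures(orf_len, coverage, fickett, hexamer_llr(seq, table))


@dataclass
class CodingModel:
    """Logistic model over the four coding-potential features.

    Features are standardized with the stored training means/scales before the
    linear predictor is applied.  ``threshold`` is the coding-probability cut:
    transcripts with probability below it are called noncoding.
    """

    coefficients: np.ndarray
    intercept: float
    feature_means: np.ndarray
    feature_scales: np.ndarray
    threshold: float = 0.5
    trained: bool = True

    def to_json(self) -> str:
        return json.dumps(
            {
                "features": list(FEATURE_NAMES),
                "coefficients": self.coefficients.tolist(),
                "intercept": self.intercept,
                "feature_means": self.feature_means.tolist(),
                "feature_scales": self.feature_scales.tolist(),
                "threshold": self.threshold,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CodingModel":
        d = json.loads(text)
        return cls(
            np.asarray(d["coefficients"], dtype=float),
            float(d["intercept"]),
            np.asarray(d["feature_means"], dtype=float),
            np.asarray(d["feature_scales"], dtype=float),
            float(d["threshold"]),
        )


def _feature_matrix(features: Sequence[CodingPotentialFeatures]) -> np.ndarray:
    return np.vstack([f.as_array() for f in features])


def train_coding_model(
    features: Sequence[CodingPotentialFeatures],
    labels: Sequence[int],
    threshold: float = 0.5,
) -> CodingModel:
    """Fit the logistic coding-potential model (label 1 = coding)."""
    y = np.asarray(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("training labels must contain both classes")
    X = _feature_matrix(features)
    means = X.mean(axis=0)
    scales = X.std(axis=0)
    scales[scales == 0] = 1.0
    Xs = (X - means) / scales
    clf = LogisticRegression(C=np.inf, max_iter=5000)  # unpenalized fit
    clf.fit(Xs, y)
    return CodingModel(clf.coef_[0].copy(), float(clf.intercept_[0]), means, scales, threshold)


def coding_probability(
    features: CodingPotentialFeatures | Sequence[CodingPotentialFeatures],
    model: CodingModel,
) -> float | np.ndarray:
    """Probability that a transcript is protein-coding under the model."""
    single = isinstance(features, CodingPotentialFeatures)
    X = _feature_matrix([features] if single else features)
    Xs = (X - model.feature_means) / model.feature_scales
    z = Xs @ model.coefficients + model.intercept
    p = 1.0 / (1.0 + np.exp(-z))
    return float(p[0]) if single else p
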