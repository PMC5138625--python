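"""Expression analyses: detection breadth, Jensen-Shannon tissue specificity,
neighbor-pair correlations with a random null, TSS-distance profiles, and
2^-ddCt qPCR quantification.

The container is an FPKM matrix (features × samples) with a design table
mapping each sample to a condition (tissue or developmental stage).
Condition-level expression is the mean FPKM over that condition's samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon


@dataclass
class ExpressionMatrix:
    """Non-negative FPKM values over named features × named samples."""

    values: pd.DataFrame
    design: pd.Series  # sample -> condition

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("FPKM values must be non-negative")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("feature and sample ids must be unique")
        missing = set(self.values.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"design table missing samples: {sorted(missing)}")
        self.design = self.design.loc[self.values.columns]

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.design:
            seen.setdefault(c)
        return list(seen)

    def condition_means(self) -> pd.DataFrame:
        """Mean FPKM per condition (features × conditions, design order)."""
        means = self.values.T.groupby(self.design).mean().T
        return means[self.conditions]


def read_expression(matrix_path: str, design_path: str) -> ExpressionMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t", index_col=0).iloc[:, 0]
    return ExpressionMatrix(values, design)


# --------------------------------------------------------------------------
# Detection breadth and specificity


def detection_breadth(matrix: ExpressionMatrix, threshold: float = 0.1) -> pd.Series:
    """Number of conditions in which each feature is detected (mean FPKM strictly
    above ``threshold``)."""
    means = matrix.condition_means()
    return (means > threshold).sum(axis=1)


@dataclass(frozen=True)
class SpecificityResult:
    feature_id: str
    density: np.ndarray  # probability vector over conditions
    scores: np.ndarray  # 1 - JSdist(p, e_t) per condition
    max_score: float
    argmax_condition: str


def specificity_score(matrix: ExpressionMatrix) -> list[SpecificityResult]:
    """Jensen-Shannon specificity per feature.

    The expression density p is log10(condition mean FPKM + 1) normalized to
    sum to 1; the score against condition t is 1 − JSdist(p, e_t) where JSdist
    is the Jensen-Shannon distance (square root of the base-2 JS divergence)
    and e_t the unit vector for t.  A feature is maximally specific (score 1)
    iff its expression is confined to one condition.  All-zero features are
    reported with NaN scores and should be excluded from summaries.
    """
    conditions = matrix.conditions
    if len(conditions) < 2:
        raise ValueError("specificity requires at least two conditions")
    logged = np.log10(matrix.condition_means().values + 1.0)
    results = []
    eye = np.eye(len(conditions))
    for fid, row in zip(matrix.values.index, logged):
        total = row.sum()
        if total == 0:
            results.append(
                SpecificityResult(fid, np.full(len(conditions), np.nan),
                                  np.full(len(conditions), np.nan), float("nan"), "")
            )
            continue
        p = row / total
        scores = np.array([1.0 - jensenshannon(p, eye[t], base=2) for t in range(len(conditions))])
        best = int(np.argmax(scores))
        results.append(SpecificityResult(fid, p, scores, float(scores[best]), conditions[best]))
    return results


def specificity_table(results: Iterable[SpecificityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"feature_id": r.feature_id, "max_score": r.max_score, "condition": r.argmax_condition}
            for r in results
        ]
    ).set_index("feature_id")


# --------------------------------------------------------------------------
# Neighbor-pair correlations


@dataclass(frozen=True)
class PairCorrelation:
    id_a: str
    id_b: str
    pair_class: str  # linc_mRNA | mRNA_mRNA | random
    r: float  # Pearson on log2(FPKM + 0.05); NaN if undefined
    gap: int = -1
    tss_distance: int = -1


def pair_correlations(
    matrix: ExpressionMatrix,
    pairs: Sequence[tuple[str, str]],
    pair_class: str,
    gaps: Sequence[int] | None = None,
    tss_distances: Sequence[int] | None = None,
) -> list[PairCorrelation]:
    """Pearson correlation of log2(FPKM + 0.05) across samples for each pair.

    Pairs with a member absent from the matrix are reported with NaN rather
    than silently dropped; zero-variance members also yield NaN (flagged by
    value, since Pearson r is undefined there).
    """
    if matrix.values.shape[1] < 3:
        raise ValueError("pair correlation requires at least 3 samples")
    logged = np.log2(matrix.values + 0.05)
    out = []
    for i, (a, b) in enumerate(pairs):
        gap = gaps[i] if gaps is not None else -1
        tss = tss_distances[i] if tss_distances is not None else -1
        if a not in logged.index or b not in logged.index:
            out.append(PairCorrelation(a, b, pair_class, float("nan"), gap, tss))
            continue
        x, y = logged.loc[a].values, logged.loc[b].values
        if np.std(x) == 0 or np.std(y) == 0:
            r = float("nan")
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        out.append(PairCorrelation(a, b, pair_class, r, gap, tss))
    return out


def random_pair_null(
    matrix: ExpressionMatrix,
    n_pairs: int,
    seed: int,
    exclude: Iterable[tuple[str, str]] = (),
) -> list[PairCorrelation]:
    """Seeded uniform sample of unordered feature pairs (class ``random``),
    without replacement, excluding true neighbor pairs."""
    features = list(matrix.values.index)
    if len(features) < 2:
        raise ValueError("need at least two features")
    banned = {frozenset(p) for p in exclude}
    n_available = len(features) * (len(features) - 1) // 2 - len(banned)
    if n_pairs > n_available:
        raise ValueError(f"requested {n_pairs} pairs but only {n_available} available")
    rng = np.random.default_rng(seed)
    chosen: list[tuple[str, str]] = []
    seen: set[frozenset] = set(banned)
    while len(chosen) < n_pairs:
        i, j = rng.choice(len(features), size=2, replace=False)
        key = frozenset((features[i], features[j]))
        if key in seen:
            continue
        seen.add(key)
        chosen.append(tuple(sorted((features[i], features[j]))))
    return pair_correlations(matrix, chosen, "random")


def tss_distance_profile(
    pairs: Sequence[PairCorrelation], window: int = 4000, bin_size: int = 400
) -> pd.DataFrame:
    """Fraction of pairs per TSS-distance bin and pair class.

    Pairs at distance strictly below ``window`` are split into window/bin_size
    equal bins; per class the fractions sum to 1 over bins.
    """
    if window % bin_size != 0:
        raise ValueError("bin size must divide the window")
    n_bins = window // bin_size
    classes = sorted({p.pair_class for p in pairs})
    counts = {c: np.zeros(n_bins) for c in classes}
    for p in pairs:
        if 0 <= p.tss_distance < window:
            counts[p.pair_class][p.tss_distance // bin_size] += 1
    data = {}
    for c in classes:
        total = counts[c].sum()
        data[c] = counts[c] / total if total > 0 else counts[c]
    index = [f"[{i * bin_size},{(i + 1) * bin_size})" for i in range(n_bins)]
    return pd.DataFrame(data, index=index)


# --------------------------------------------------------------------------
# qPCR relative quantification


def ddct_fold_change(measurements: pd.DataFrame, calibrator: str) -> pd.Series:
    """Relative expression 2^-ddCt per sample.

    ``measurements`` has one row per sample with columns ``ct_target`` and
    ``ct_reference``.  dCt = Ct_target − Ct_reference; ddCt is taken relative
    to the calibrator sample, whose fold change is 1 by construction.
    """
    for col in ("ct_target", "ct_reference"):
        if col not in measurements.columns:
            raise ValueError(f"missing column {col!r}")
        if measurements[col].isna().any():
            bad = measurements.index[measurements[col].isna()].tolist()
            raise ValueError(f"missing Ct values for samples: {bad}")
    if calibrator not in measurements.index:
        raise ValueError(f"calibrator sample {calibrator!r} not in table")
    dct = measurements["ct_target"] - measurements["ct_reference"]
    ddct = dct - dct.loc[calibrator]
    return np.power(2.0, -ddct).rename("fold_change")
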