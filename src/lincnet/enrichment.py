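"""Fisher-exact functional enrichment of gene lists against annotated terms.

A local replacement for web-service GO enrichment: each term annotated in the
background is tested one-sided (greater) with Fisher's exact test on the 2×2
table (in module & annotated, in module & not, out & annotated, out & not),
which equals the hypergeometric upper tail P(X ≥ k).  p-values are
Benjamini–Hochberg adjusted within each term category.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests


@dataclass
class TermAnnotation:
    """term id → gene set, with optional name/category metadata per term."""

    gene_sets: dict[str, frozenset[str]]
    names: dict[str, str]
    categories: dict[str, str]  # BP | MF | CC (or any user label)

    @classmethod
    def from_table(
        cls, term_gene: pd.DataFrame, term_meta: pd.DataFrame | None = None
    ) -> "TermAnnotation":
        """Build from a two-column (term, gene) table plus optional metadata
        (term, name, category)."""
        sets: dict[str, set[str]] = {}
        for term, gene in zip(term_gene.iloc[:, 0], term_gene.iloc[:, 1]):
            sets.setdefault(str(term), set()).add(str(gene))
        names, categories = {}, {}
        if term_meta is not None:
            for _, row in term_meta.iterrows():
                term = str(row.iloc[0])
                names[term] = str(row.iloc[1]) if len(row) > 1 else term
                categories[term] = str(row.iloc[2]) if len(row) > 2 else "BP"
        return cls({t: frozenset(g) for t, g in sets.items()},
                   {t: names.get(t, t) for t in sets},
                   {t: categories.get(t, "BP") for t in sets})


def fisher_enrichment(
    module_genes: Iterable[str],
    background_genes: Iterable[str],
    annotations: TermAnnotation,
    adjust: bool = True,
) -> pd.DataFrame:
    """One-sided Fisher enrichment of a module against its background.

    Annotations are restricted to the background universe; terms with no
    annotated background gene are skipped, and terms hitting no module gene
    are absent from the result.  Output columns: term, name, category, k, n,
    K, N, p, p_adjusted, fold_enrichment — sorted by p then term id.
    """
    module = set(module_genes)
    background = set(background_genes)
    if not module:
        raise ValueError("empty module gene list")
    if not module <= background:
        raise ValueError("module genes must be a subset of the background")
    n, N = len(module), len(background)

    rows = []
    for term in sorted(annotations.gene_sets):
        annotated = annotations.gene_sets[term] & background
        K = len(annotated)
        if K == 0:
            continue  # unannotated in this universe: untestable
        k = len(module & annotated)
        if k == 0:
            continue
        table = [[k, n - k], [K - k, (N - n) - (K - k)]]
        _, p = fisher_exact(table, alternative="greater")
        rows.append(
            {
                "term": term,
                "name": annotations.names.get(term, term),
                "category": annotations.categories.get(term, "BP"),
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p": float(p),
                "fold_enrichment": (k / n) / (K / N),
            }
        )
    result = pd.DataFrame(
        rows,
        columns=["term", "name", "category", "k", "n", "K", "N", "p", "fold_enrichment"],
    )
    if result.empty:
        result["p_adjusted"] = pd.Series(dtype=float)
        return result
    if adjust:
        adjusted = pd.Series(index=result.index, dtype=float)
        for _, idx in result.groupby("category").groups.items():
            adjusted.loc[idx] = multipletests(result.loc[idx, "p"], method="fdr_bh")[1]
        result["p_adjusted"] = adjusted
    else:
        result["p_adjusted"] = result["p"]
    return result.sort_values(["p", "term"]).reset_index(drop=True)
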