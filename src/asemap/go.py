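"""GO-term enrichment comparison: what changes when mutation-linked genes go?

DE genes on the mutant chromosome are a mixture of genuine responses and
linked allele-specific expression.  To quantify how much linked genes
distort downstream interpretation, enrichment is run twice — on the full
DE list and on the list with same-chromosome genes removed (keeping the
mutated gene itself) — and the two enriched-term sets are compared with the
Jaccard coefficient.  A Cohen's-kappa network over term gene memberships
shows which affected terms are mutually redundant.

Enrichment is the classic one-sided hypergeometric over-representation
test with Benjamini-Hochberg adjustment; pre-computed enrichment tables
from any external tool can be substituted for the comparison step.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "remove_linked_genes",
    "go_enrich",
    "jaccard",
    "cohen_kappa",
    "term_overlap_network",
]


def remove_linked_genes(de_genes, annotation: pd.DataFrame, mutant_gene: str) -> list:
    """Drop DE genes on the mutant gene's chromosome, keeping the mutant gene.

    ``annotation`` maps gene -> chrom.  Order of the remaining genes is
    preserved.
    """
    if mutant_gene not in annotation.index:
        raise KeyError(f"mutant gene {mutant_gene!r} missing from annotation")
    mutant_chrom = annotation.loc[mutant_gene, "chrom"]
    chroms = annotation["chrom"].reindex(pd.Index(de_genes))
    return [
        g
        for g, c in zip(de_genes, chroms)
        if g == mutant_gene or c != mutant_chrom
    ]


def go_enrich(
    gene_list,
    universe,
    go_annotation: pd.DataFrame,
    alpha: float = 0.05,
    min_term_size: int = 5,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of GO terms in a gene list.

    ``go_annotation`` is a two-column (gene_id, term_id) table.  Only genes
    in the universe count; terms with fewer than ``min_term_size`` annotated
    universe genes are skipped.  Returns terms with BH-adjusted p < alpha,
    ordered by ascending p.
    """
    universe = pd.Index(universe).unique()
    if len(universe) == 0:
        raise ValueError("empty gene universe")
    gene_list = pd.Index(gene_list).unique()
    stray = gene_list.difference(universe)
    if len(stray):
        raise ValueError(f"gene list not contained in universe: {sorted(stray)[:10]}")

    ann = go_annotation[go_annotation["gene_id"].isin(universe)]
    N = len(universe)
    n = len(gene_list)
    in_list = ann["gene_id"].isin(gene_list)
    term_total = ann.groupby("term_id")["gene_id"].nunique()
    term_hits = ann.loc[in_list].groupby("term_id")["gene_id"].nunique()

    terms = term_total[term_total >= min_term_size]
    if terms.empty:
        return pd.DataFrame(columns=["term_id", "hits", "term_size", "pvalue", "padj"])
    k = term_hits.reindex(terms.index, fill_value=0).to_numpy()
    K = terms.to_numpy()
    pvals = stats.hypergeom.sf(k - 1, N, K, n)  # P(X >= k)
    padj = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame(
        {"term_id": terms.index, "hits": k, "term_size": K, "pvalue": pvals, "padj": padj}
    )
    out = out[out["padj"] < alpha].sort_values(
        ["pvalue", "term_id"], kind="stable", ignore_index=True
    )
    return out


def jaccard(set_a, set_b) -> float:
    """|A intersect B| / |A union B|; two empty sets agree perfectly (1.0)."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        warnings.warn("Jaccard of two empty sets defined as 1.0")
        return 1.0
    return len(a & b) / len(a | b)


def cohen_kappa(members_a, members_b, universe) -> float:
    """Chance-corrected agreement of two gene-set membership vectors.

    The 2x2 table over the universe (in both / only A / only B / neither)
    yields kappa = (po - pe) / (1 - pe).  Degenerate tables where expected
    agreement is 1 give kappa 1 for identical vectors, else 0.
    """
    uni = pd.Index(universe).unique()
    in_a = uni.isin(set(members_a))
    in_b = uni.isin(set(members_b))
    n = len(uni)
    if n == 0:
        raise ValueError("empty universe")
    a = int((in_a & in_b).sum())
    b = int((in_a & ~in_b).sum())
    c = int((~in_a & in_b).sum())
    d = n - a - b - c
    po = (a + d) / n
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
    if 1.0 - pe < 1e-12:
        return 1.0 if po >= 1.0 - 1e-12 else 0.0
    return (po - pe) / (1.0 - pe)


def term_overlap_network(
    enriched_terms,
    go_annotation: pd.DataFrame,
    universe,
    kappa_threshold: float = 0.4,
) -> pd.DataFrame:
    """Edges between enriched terms whose annotated gene sets overlap (kappa > threshold)."""
    uni = pd.Index(universe).unique()
    ann = go_annotation[go_annotation["gene_id"].isin(uni)]
    members = {t: set(g) for t, g in ann.groupby("term_id")["gene_id"]}
    terms = list(enriched_terms)
    missing = [t for t in terms if t not in members]
    if missing:
        raise KeyError(f"terms absent from annotation: {missing[:10]}")
    rows = []
    for i, ta in enumerate(terms):
        for tb in terms[i + 1 :]:
            k = cohen_kappa(members[ta], members[tb], uni)
            if k > kappa_threshold:
                rows.append((ta, tb, k))
    return pd.DataFrame(rows, columns=["term_a", "term_b", "kappa"])
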