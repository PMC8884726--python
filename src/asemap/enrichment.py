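"""Chromosome-level enrichment of DE genes and mapping-window statistics.

Under the null that DE genes fall uniformly over the annotated genome, the
number landing on one chromosome is Binomial(total DE, chromosome's share
of annotated genes).  A one-sided exact binomial tail with a Bonferroni
correction across chromosomes flags chromosomes carrying more DE genes
than chance — the signature of linked allele-specific expression around a
causal mutation.  Companion statistics count DE genes inside a fixed
window centred on the mapping peak and calibrate that count against
randomly placed windows.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "binomial_enrichment",
    "nearby_de_genes",
    "random_window_gene_fraction",
]

UNPLACED = "unplaced"


def binomial_enrichment(
    annotation: pd.DataFrame,
    de_genes,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided binomial test of DE-gene over-representation per chromosome.

    Parameters
    ----------
    annotation
        Gene-indexed frame with a ``chrom`` column (the gene universe).
        Genes with missing chromosome are pooled into an "unplaced" stratum
        that is counted in totals but not tested.
    de_genes
        Iterable of DE gene ids; must all be present in the annotation.

    Returns one row per tested chromosome: gene counts, the exact tail
    probability P(X >= k) with p0 = chromosome share of annotated genes,
    the Bonferroni-adjusted p (factor = chromosomes tested), and the
    enriched flag (adjusted p < alpha).
    """
    de_genes = pd.Index(de_genes)
    missing = de_genes.difference(annotation.index)
    if len(missing):
        raise KeyError(f"DE genes absent from annotation: {sorted(missing)[:10]}")
    if len(de_genes) == 0:
        warnings.warn("zero DE genes: empty enrichment result")
        return pd.DataFrame(
            columns=[
                "chrom", "genes_on_chrom", "total_genes", "de_on_chrom",
                "total_de", "p0", "pvalue", "padj", "enriched",
            ]
        )

    chrom = annotation["chrom"].astype("object").where(annotation["chrom"].notna(), UNPLACED)
    total_genes = len(annotation)
    total_de = len(de_genes)
    de_chrom = chrom.loc[de_genes]

    counts = chrom.value_counts()
    tested = [c for c in counts.index if c != UNPLACED]
    n_unplaced = int(counts.get(UNPLACED, 0))
    if n_unplaced:
        warnings.warn(f"{n_unplaced} genes without chromosome assignment excluded from testing")

    rows = []
    n_tests = len(tested)
    for c in tested:
        n_c = int(counts[c])
        k = int((de_chrom == c).sum())
        p0 = n_c / total_genes
        p = float(stats.binom.sf(k - 1, total_de, p0))  # P(X >= k), exact
        padj = min(1.0, p * n_tests)
        rows.append((c, n_c, total_genes, k, total_de, p0, p, padj, padj < alpha))
    out = pd.DataFrame(
        rows,
        columns=[
            "chrom", "genes_on_chrom", "total_genes", "de_on_chrom",
            "total_de", "p0", "pvalue", "padj", "enriched",
        ],
    )
    return out.sort_values("pvalue", kind="stable").reset_index(drop=True)


def nearby_de_genes(
    de_positions: pd.DataFrame,
    peak,
    window: float = 20e6,
    chrom_length: float | None = None,
) -> dict:
    """Count DE genes in a window centred on the mapping peak.

    The window is the closed interval [peak - window/2, peak + window/2] on
    the peak chromosome, truncated at chromosome bounds when
    ``chrom_length`` is given.  ``de_positions`` holds one row per DE gene
    with ``chrom`` and ``start``.  Returns the count, the exact percentage
    of all DE genes, and that percentage rounded to the nearest integer.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    lo = peak.pos - window / 2.0
    hi = peak.pos + window / 2.0
    lo = max(lo, 1)
    if chrom_length is not None:
        hi = min(hi, chrom_length)
    on_chrom = de_positions[de_positions["chrom"].astype(str) == str(peak.chrom)]
    count = int(((on_chrom["start"] >= lo) & (on_chrom["start"] <= hi)).sum())
    total = len(de_positions)
    percent = 100.0 * count / total if total else 0.0
    return {
        "chrom": str(peak.chrom),
        "window_start": float(lo),
        "window_end": float(hi),
        "count": count,
        "total_de": total,
        "percent": percent,
        "percent_rounded": int(round(percent)),
    }


def random_window_gene_fraction(
    annotation: pd.DataFrame,
    chrom_lengths: dict[str, int] | pd.Series,
    window: float = 20e6,
    iterations: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """Mean fraction of annotated genes inside a randomly placed window.

    Windows of fixed width are dropped uniformly over all valid start
    positions genome-wide (a chromosome is chosen with probability
    proportional to its number of valid starts), and the fraction of all
    genes whose start falls inside is averaged over ``iterations`` draws.
    """
    rng = np.random.default_rng() if rng is None else rng
    lengths = pd.Series(chrom_lengths, dtype=float)
    valid = (lengths - window + 1).clip(lower=0)
    if (valid <= 0).all():
        raise ValueError("window longer than every chromosome")
    lengths = lengths[valid > 0]
    valid = valid[valid > 0]
    probs = valid / valid.sum()
    total = len(annotation)
    by_chrom = {
        str(c): np.sort(grp["start"].to_numpy(dtype=float))
        for c, grp in annotation.groupby("chrom", sort=False)
    }
    chroms = rng.choice(len(lengths), size=iterations, p=probs.to_numpy())
    starts = rng.uniform(1, valid.to_numpy()[chroms] + 1)
    fractions = np.empty(iterations)
    for i, (ci, s) in enumerate(zip(chroms, starts)):
        pos = by_chrom.get(str(lengths.index[ci]))
        if pos is None:
            fractions[i] = 0.0
            continue
        count = np.searchsorted(pos, s + window - 1, side="right") - np.searchsorted(
            pos, s, side="left"
        )
        fractions[i] = count / total
    return float(fractions.mean())
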