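"""Classify DE genes in a four-genotype cross: linked ASE or mutation response?

A cross of two different mutant alleles of the same gene (m1/+ x +/m2)
yields four genotypes — +/+, m1/+, +/m2 and m1/m2 — and, crucially, lets
the two wild-type chromosomes be tracked.  Two expression patterns are
distinguishable for a DE gene on the mutant chromosome:

* **ASE-linked**: expression tracks carriage of one parental wild-type
  chromosome.  Genotypes sharing the wild-type copy from one parent
  ({+/+, m1/+} or {+/+, +/m2}) form one expression level, the other two
  genotypes the other level.
* **Mutation response**: expression tracks functional-allele dosage
  (2, 1, 1, 0) — wild types and compound heterozygotes sit at opposite
  extremes with both heterozygote classes intermediate.

Each gene is scored by fitting both patterns as linear models on
log(normalised count + 1) and comparing AIC.  A call requires the winning
model to beat both the rival *and* a no-pattern (constant mean) model by a
margin (default 2 AIC units); anything less is AMBIGUOUS.  Response calls
must additionally show the dosage ordering (compound heterozygotes deviate
from wild types in a consistent direction, heterozygotes in between).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import size_factors

__all__ = [
    "ASE_LINKED",
    "MUTATION_RESPONSE",
    "AMBIGUOUS",
    "GENOTYPE_ORDER",
    "PatternCall",
    "classify_gene",
    "classify_chromosome",
]

ASE_LINKED = "ASE_LINKED"
MUTATION_RESPONSE = "MUTATION_RESPONSE"
AMBIGUOUS = "AMBIGUOUS"

#: Canonical genotype labels: wild type, het for allele m1, het for allele m2,
#: compound heterozygote.
GENOTYPE_ORDER = ("wt", "het_m1", "het_m2", "comphet")

# genotype groups sharing one parental wild-type chromosome
_ASE_PARTITIONS = (
    ("wt", "het_m1"),  # share the + copy from the m2 parent
    ("wt", "het_m2"),  # share the + copy from the m1 parent
)


@dataclass
class PatternCall:
    """Classification of one gene with the fit scores behind it."""

    gene: str
    call: str
    aic_ase: float
    aic_response: float
    aic_null: float
    ase_partition: tuple | None
    group_means: dict

    def scores(self) -> dict:
        return {
            "aic_ase": self.aic_ase,
            "aic_response": self.aic_response,
            "aic_null": self.aic_null,
        }


def _aic(y: np.ndarray, fitted: np.ndarray, k_params: int) -> float:
    n = len(y)
    rss = float(np.sum((y - fitted) ** 2))
    return n * np.log(max(rss, 1e-300) / n) + 2 * k_params


def classify_gene(
    norm_counts: pd.Series,
    genotypes: pd.Series,
    gene: str = "",
    delta: float = 2.0,
    dosage: dict | None = None,
    consistency_tol: float = 0.25,
) -> PatternCall:
    """Call one gene ASE-linked, mutation-response, or ambiguous.

    Parameters
    ----------
    norm_counts
        Size-factor-normalised counts per sample.
    genotypes
        Sample -> genotype label (wt / het_m1 / het_m2 / comphet); all four
        groups must be present with >= 2 samples.
    delta
        AIC margin a winning model must achieve over both the rival model
        and the constant-mean null.
    dosage
        Functional-allele dose per genotype; default 2/1/1/0.  Override to
        weight alleles of unequal severity.
    consistency_tol
        Tolerance (fraction of the wt-to-comphet span) by which heterozygote
        means may fall outside the wt-comphet interval in a response call.
    """
    genotypes = genotypes.reindex(norm_counts.index)
    missing = [g for g in GENOTYPE_ORDER if (genotypes == g).sum() < 2]
    if missing:
        raise ValueError(f"genotype groups with < 2 samples: {missing}")
    if dosage is None:
        dosage = {"wt": 2.0, "het_m1": 1.0, "het_m2": 1.0, "comphet": 0.0}

    y = np.log1p(norm_counts.to_numpy(dtype=float))
    labels = genotypes.to_numpy()
    means = {g: float(y[labels == g].mean()) for g in GENOTYPE_ORDER}

    if np.allclose(y, y[0]):
        warnings.warn(f"gene {gene or '<unnamed>'}: zero variance; AMBIGUOUS")
        return PatternCall(gene, AMBIGUOUS, np.nan, np.nan, np.nan, None, means)

    # null: one mean (params: mean + variance)
    aic_null = _aic(y, np.full_like(y, y.mean()), 2)

    # ASE: two means over a wild-type-chromosome partition; best of the two
    aic_parts = []
    for part in _ASE_PARTITIONS:
        in_part = np.isin(labels, part)
        fitted = np.where(in_part, y[in_part].mean(), y[~in_part].mean())
        aic_parts.append(_aic(y, fitted, 3))
    best_idx = int(np.argmin(aic_parts))
    aic_ase = aic_parts[best_idx]
    ase_partition = _ASE_PARTITIONS[best_idx]

    # response: linear in functional-allele dosage (params: intercept, slope, variance)
    dose = np.array([dosage[g] for g in labels], dtype=float)
    X = np.column_stack([np.ones_like(dose), dose])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    aic_response = _aic(y, X @ coef, 3)

    ase_wins = aic_ase <= min(aic_response, aic_null) - delta
    response_wins = aic_response <= min(aic_ase, aic_null) - delta

    if response_wins:
        span = means["comphet"] - means["wt"]
        direction = np.sign(span)
        if direction == 0:
            response_wins = False
        else:
            lo = min(means["wt"], means["comphet"]) - consistency_tol * abs(span)
            hi = max(means["wt"], means["comphet"]) + consistency_tol * abs(span)
            if not all(lo <= means[g] <= hi for g in ("het_m1", "het_m2")):
                response_wins = False

    if ase_wins:
        call = ASE_LINKED
    elif response_wins:
        call = MUTATION_RESPONSE
    else:
        call = AMBIGUOUS
    return PatternCall(gene, call, aic_ase, aic_response, aic_null, ase_partition, means)


def classify_chromosome(
    counts: pd.DataFrame,
    genotypes: pd.Series,
    de_results: pd.DataFrame,
    annotation: pd.DataFrame,
    mutant_chrom: str,
    mutant_gene: str | None = None,
    genome_wide: bool = False,
    delta: float = 2.0,
) -> pd.DataFrame:
    """Classify every DE gene on the mutant chromosome (or genome-wide).

    Counts are size-factor normalised first, so classification is invariant
    to per-sample sequencing depth.  The mutated gene itself is excluded.
    Returns one row per gene: call, the three AIC scores, and the four
    group means (log scale).
    """
    de_genes = de_results.index[de_results["de"]]
    chroms = annotation["chrom"].astype(str).reindex(de_genes)
    if not genome_wide:
        de_genes = de_genes[(chroms == str(mutant_chrom)).to_numpy()]
    if mutant_gene is not None:
        de_genes = de_genes[de_genes != mutant_gene]

    norm = counts / size_factors(counts)
    rows = []
    for g in de_genes:
        pc = classify_gene(norm.loc[g], genotypes, gene=g, delta=delta)
        rows.append(
            {
                "gene_id": g,
                "call": pc.call,
                "aic_ase": pc.aic_ase,
                "aic_response": pc.aic_response,
                "aic_null": pc.aic_null,
                **{f"mean_{k}": v for k, v in pc.group_means.items()},
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "call", "aic_ase", "aic_response", "aic_null",
            *(f"mean_{g}" for g in GENOTYPE_ORDER),
        ],
    )
    return out.set_index("gene_id")
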